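"""Strain typing from amplicon barcode reads.

Two Dunaliella salina strains (A = CCAP 19/12, C = CCAP 19/15) are
distinguished in mixed cultures by short haplotypes over strain-diagnostic
SNPs on two ~200 bp amplicons: a chloroplast locus and the nuclear ITS2.
Diagnostic sites are chosen by the multi-allele Nei G_ST computed from
pure reference cultures; reads are then reduced to their bases at those
sites and matched exactly against the reference haplotypes.

At the chloroplast locus the haplotypes are fully strain-specific. At
ITS2 one haplotype is specific to strain A while the other is carried by
all of strain C but also by a minority (~20%) of strain A reads; counting
the shared haplotype as the C allele therefore over-reports strain C at
low frequency, which the linear calibration p_ITS2 = alpha + beta * p
absorbs downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

BASES = ("A", "T", "G", "C", "-")  # '-' is a gap/deletion allele


class CalibrationError(ValueError):
    pass


@dataclass
class StrainRefPanel:
    """Per-strain base counts at each site of an amplicon.

    ``counts[strain]`` is a mapping site -> length-5 array of counts over
    ``BASES``. Sites are 0-based coordinates on the amplicon.
    """

    counts: Dict[str, Dict[int, np.ndarray]]
    locus: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("panel needs at least 2 strains")
        for strain, sites in self.counts.items():
            for site, arr in sites.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(BASES),):
                    raise ValueError(f"counts at {strain}:{site} must have {len(BASES)} entries")
                if np.any(arr < 0):
                    raise ValueError("counts must be >= 0")
                sites[site] = arr

    @property
    def strains(self) -> List[str]:
        return sorted(self.counts)

    @property
    def sites(self) -> List[int]:
        all_sites = set()
        for sites in self.counts.values():
            all_sites.update(sites)
        return sorted(all_sites)

    def site_matrix(self, site: int) -> np.ndarray:
        """Strains x bases count matrix at one site (strains in sorted order)."""
        return np.array([self.counts[s].get(site, np.zeros(len(BASES))) for s in self.strains])

    @classmethod
    def from_tsv(cls, path, locus: str = "") -> "StrainRefPanel":
        df = pd.read_csv(path, sep="\t")
        needed = {"strain", "site", "base", "count"}
        if not needed <= set(df.columns):
            raise ValueError(f"panel table must have columns {sorted(needed)}")
        counts: Dict[str, Dict[int, np.ndarray]] = {}
        for _, row in df.iterrows():
            site_counts = counts.setdefault(row["strain"], {}).setdefault(
                int(row["site"]), np.zeros(len(BASES))
            )
            site_counts[BASES.index(str(row["base"]))] += row["count"]
        return cls(counts, locus)

    def to_tsv(self, path) -> None:
        rows = []
        for strain in self.strains:
            for site, arr in sorted(self.counts[strain].items()):
                for j, base in enumerate(BASES):
                    if arr[j] > 0:
                        rows.append((strain, site, base, arr[j]))
        pd.DataFrame(rows, columns=["strain", "site", "base", "count"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class HaplotypeTable:
    """Reference haplotypes over the selected SNP positions of one locus.

    ``tags[h]`` is ``'A'`` or ``'C'`` for strain-specific haplotypes; a
    haplotype carried by several strains is tagged ``'shared'`` and its
    per-strain carriage frequencies recorded. Shared haplotypes count
    toward the C allele (the ITS2 convention; the calibration absorbs the
    strain-A carriage).
    """

    locus: str
    positions: Sequence[int]
    haplotypes: List[str]
    tags: Dict[str, str]
    carriage: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def allele_of(self, hap: str) -> str:
        tag = self.tags[hap]
        return "C" if tag in ("C", "shared") else "A"


@dataclass(frozen=True)
class CalibrationMap:
    """Linear map p -> alpha + beta p from strain frequency to observed allele frequency."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.alpha + self.beta > 1 + 1e-12 or self.beta < 0:
            raise CalibrationError(
                f"calibration (alpha={self.alpha}, beta={self.beta}) leaves [0,1]"
            )

    def __call__(self, p):
        return its2_expected(p, self)


IDENTITY_CALIBRATION = CalibrationMap(0.0, 1.0)
#: Calibration measured on reference mixtures at the ITS2 locus.
DEFAULT_ITS2_CALIBRATION = CalibrationMap(0.19, 0.79)


@dataclass
class ReadCounts:
    """Classified read counts for one line x timepoint at one locus."""

    n_C: int
    n_A: int
    dropped: int = 0
    non_covering: int = 0

    @property
    def total_matched(self) -> int:
        return self.n_C + self.n_A

    @property
    def total(self) -> int:
        return self.total_matched + self.dropped + self.non_covering

    @property
    def match_fraction(self):
        if self.total == 0:
            return np.nan
        return self.total_matched / self.total


def gst(site_counts) -> float:
    """Multi-allele Nei G_ST = 1 - H_S/H_T at one site.

    ``site_counts`` is a strains x alleles count matrix. Within-strain
    frequencies are normalised per strain; H_S is their unweighted mean
    expected heterozygosity, H_T the expected heterozygosity of the
    equal-weight pooled frequencies (strains contribute 1/I each,
    regardless of read depth). Returns 0 when H_T = 0 (monomorphic site).
    """
    counts = np.asarray(site_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a strains x alleles matrix with >= 2 strains")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("every strain needs nonzero total at the site")
    p = counts / totals[:, None]
    h_s = float(np.mean(1.0 - np.sum(p * p, axis=1)))
    pooled = p.mean(axis=0)
    h_t = float(1.0 - np.sum(pooled * pooled))
    if h_t == 0:
        return 0.0
    # H_T >= H_S analytically (convexity of sum p^2 under equal-weight
    # pooling), so clamp pure rounding noise at the boundaries
    return float(np.clip(1.0 - h_s / h_t, 0.0, 1.0))


def gst_per_site(panel: StrainRefPanel) -> Dict[int, float]:
    """G_ST at every panel site; sites where a strain has no reads are skipped."""
    out: Dict[int, float] = {}
    skipped = []
    for site in panel.sites:
        mat = panel.site_matrix(site)
        if np.any(mat.sum(axis=1) == 0):
            skipped.append(site)
            continue
        out[site] = gst(mat)
    if skipped:
        warnings.warn(f"sites skipped for zero coverage in some strain: {skipped}")
    return out


def select_snps(gst_by_site: Dict[int, float], threshold: float) -> List[int]:
    """Sites with G_ST strictly above the threshold, in coordinate order."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    chosen = sorted(site for site, g in gst_by_site.items() if g > threshold)
    if not chosen:
        warnings.warn(f"no site exceeds G_ST threshold {threshold}")
    return chosen


def build_haplotypes(
    panel: StrainRefPanel,
    sites: Sequence[int],
    focal_strains: Sequence[str] = ("A", "C"),
    shared_min_freq: float = 0.05,
) -> HaplotypeTable:
    """Build reference haplotypes from per-site majority/observed bases.

    For each focal strain the majority-base haplotype is recorded. A
    haplotype whose per-site bases are also carried at frequency
    >= ``shared_min_freq`` in another focal strain is tagged ``shared``;
    its carriage in each strain is estimated as the minimum across sites
    of the per-site base frequency (exact under complete linkage
    disequilibrium among the selected SNPs, which site-wise counts cannot
    verify directly).
    """
    if not sites:
        raise ValueError("no sites given")
    strains = list(focal_strains)
    freq = {}
    for strain in strains:
        mats = []
        for site in sites:
            arr = panel.counts[strain].get(site)
            if arr is None or arr.sum() == 0:
                raise ValueError(f"strain {strain} has no coverage at site {site}")
            mats.append(arr / arr.sum())
        freq[strain] = np.array(mats)  # sites x bases
    haps = {}
    for strain in strains:
        haps[strain] = "".join(BASES[j] for j in np.argmax(freq[strain], axis=1))
    if len(set(haps.values())) == 1:
        raise ValueError("all strains share the same haplotype at the selected sites")

    table_haps: List[str] = []
    tags: Dict[str, str] = {}
    carriage: Dict[str, Dict[str, float]] = {}
    for strain in strains:
        h = haps[strain]
        if h in table_haps:
            continue
        carry = {}
        for other in strains:
            per_site = [
                freq[other][k, BASES.index(base)] for k, base in enumerate(h)
            ]
            carry[other] = float(min(per_site))
        carriers = [s for s in strains if carry[s] >= shared_min_freq]
        table_haps.append(h)
        if len(carriers) > 1:
            tags[h] = "shared"
            carriage[h] = carry
        else:
            tags[h] = strain
    return HaplotypeTable(panel.locus, list(sites), table_haps, tags, carriage)


def classify_reads(reads, table: HaplotypeTable) -> ReadCounts:
    """Classify merged amplicon reads by exact haplotype match.

    ``reads`` is a path to a FASTA/FASTQ file or an iterable of sequence
    strings / SeqRecords. Each read's bases at the table's SNP positions
    are concatenated and matched exactly (no mismatch tolerance) against
    the reference haplotypes; non-matching reads are dropped and counted,
    reads too short to cover all positions are counted separately.
    """
    seqs = _iter_sequences(reads)
    max_pos = max(table.positions)
    counts = {"A": 0, "C": 0}
    dropped = 0
    non_covering = 0
    hap_allele = {h: table.allele_of(h) for h in table.haplotypes}
    for seq in seqs:
        if len(seq) <= max_pos:
            non_covering += 1
            continue
        key = "".join(seq[p] for p in table.positions)
        allele = hap_allele.get(key)
        if allele is None:
            dropped += 1
        else:
            counts[allele] += 1
    return ReadCounts(counts["C"], counts["A"], dropped, non_covering)


def _iter_sequences(reads):
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        path = str(reads)
        fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
        return (str(rec.seq).upper() for rec in SeqIO.parse(path, fmt))

    def gen():
        for r in reads:
            if hasattr(r, "seq"):
                yield str(r.seq).upper()
            else:
                yield str(r).upper()

    return gen()


def its2_expected(p, cal: CalibrationMap):
    """Expected ITS2 allele-C frequency alpha + beta p for strain-C frequency p."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    q = cal.alpha + cal.beta * p
    if np.any((q < -1e-12) | (q > 1 + 1e-12)):
        raise CalibrationError("calibrated frequency leaves [0, 1]")
    return q.item() if q.ndim == 0 else q


def fit_calibration(mixture_fractions, observed_fractions):
    """OLS line through (known mixture fraction, observed allele fraction).

    Returns ``(CalibrationMap, adjusted_r2)``. This is the analysis of the
    reference-mixture dilution series used to correct ITS2 allele
    frequencies for shared-haplotype carriage.
    """
    x = np.asarray(mixture_fractions, dtype=float)
    y = np.asarray(observed_fractions, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 mixture points")
    if np.ptp(x) == 0:
        raise ValueError("mixture fractions are all equal; slope undefined")
    beta, alpha = np.polyfit(x, y, 1)
    resid = y - (alpha + beta * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = x.size
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    # guard tiny negative rounding before constructing the map
    alpha = max(float(alpha), 0.0)
    return CalibrationMap(alpha, float(beta)), adj_r2
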