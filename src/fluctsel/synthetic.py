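"""Synthetic serial-transfer experiments with the model's generative structure.

The default configuration reproduces the design of the salinity
experiment the package analyses: three constant treatments (0.8, 2.4 and
3.2 M NaCl, 5 lines each), four fluctuating AR(1) treatments
(autocorrelation -0.5, 0, 0.5 and 0.9; unit variance around 2.4 M; 40
lines each), 37 transfers alternating 3- and 4-day intervals, sequencing
at transfers {6, 7, 8, 14, 21, 22, 23, 30, 37}, overdispersed read depths
with means 1422 (chloroplast) and 3407 (ITS2), the shared-haplotype ITS2
calibration p_ITS2 = 0.19 + 0.79 p, and attrition of lines over time (a
per-transfer line-death probability calibrated so roughly a quarter of
fluctuating lines survive to the last transfer, as in the real
experiment; constant lines rarely die).

Two generative modes are provided. The *macroscopic* mode draws latent
logit-frequency increments directly from the fitted Gaussian process
(drift s_bar * d, variance (25/7) * sigma_s^2 * d per d-day interval) —
the exact model the inference engine assumes, used for parameter-recovery
tests. The *mechanistic* mode computes a per-transfer selection
coefficient from a reaction norm applied to the realised salinities (plus
Gaussian residual noise), bridging the reaction-norm prediction layer and
the macroscopic description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .barcode import DEFAULT_ITS2_CALIBRATION, CalibrationMap, HaplotypeTable
from .environment import TreatmentSpec, SalinitySeries, simulate_ar1, transfer_schedule
from .reaction_norms import (
    ReactionNormBi,
    bivariate_selection_at,
    selection_at,
    variance_inflation_factor,
)

#: Fixed effects of the published fit, used as default generating truth.
PUBLISHED_FIXED_EFFECTS = {
    "theta_intercept": 0.0927,
    "theta_mu": -0.0994,
    "theta_mu2": -0.0353,
    "theta_sigma2": -0.0765,
    "theta_rho2": 0.0882,
    "psi0_mean": -3.80,
}
#: Variance components of the published fit.
PUBLISHED_VARIANCE_COMPONENTS = {"v_psi0": 4.9e-5, "sigma0_sq": 0.0196, "sigma1_sq": 0.129}

DEFAULT_SEQUENCED_TRANSFERS = (6, 7, 8, 14, 21, 22, 23, 30, 37)


def default_treatments(
    n_fluctuating: int = 40,
    n_constant: int = 5,
    n_transfers: int = 37,
) -> List[Tuple[TreatmentSpec, int]]:
    """The experimental design: (treatment, number of lines) pairs."""
    out = [
        (TreatmentSpec(0.8, 0.0, 0.0, n_transfers, constant=True), n_constant),
        (TreatmentSpec(2.4, 0.0, 0.0, n_transfers, constant=True), n_constant),
        (TreatmentSpec(3.2, 0.0, 0.0, n_transfers, constant=True), n_constant),
    ]
    for rho in (-0.5, 0.0, 0.5, 0.9):
        out.append((TreatmentSpec(2.4, 1.0, rho, n_transfers), n_fluctuating))
    return out


@dataclass
class ExperimentConfig:
    """Configuration of one synthetic experiment."""

    treatments: List[Tuple[TreatmentSpec, int]] = field(default_factory=default_treatments)
    n_transfers: int = 37
    sequenced_transfers: Tuple[int, ...] = DEFAULT_SEQUENCED_TRANSFERS
    mode: str = "macroscopic"  # or "mechanistic"
    fixed_effects: Dict[str, float] = field(default_factory=lambda: dict(PUBLISHED_FIXED_EFFECTS))
    variance_components: Dict[str, float] = field(default_factory=lambda: dict(PUBLISHED_VARIANCE_COMPONENTS))
    reaction_norm: Optional[object] = None  # ReactionNormUni/Bi for mechanistic mode
    residual_sd: float = 0.0  # per-day selection noise, mechanistic mode
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION
    depth_chloro: float = 1422.0
    depth_its2: float = 3407.0
    depth_dispersion: float = 5.0  # negative-binomial size; larger = less overdispersed
    attrition_fluct: float = 0.037  # per-transfer death probability, fluctuating lines
    attrition_const: float = 0.005
    first_duration: int = 3

    def __post_init__(self):
        if self.mode not in ("macroscopic", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "mechanistic" and self.reaction_norm is None:
            raise ValueError("mechanistic mode requires a reaction norm")
        if max(self.sequenced_transfers) > self.n_transfers:
            raise ValueError("sequenced transfer beyond n_transfers")
        q = self.calibration
        if not (0 <= q.alpha and q.alpha + q.beta <= 1 + 1e-12):
            raise ValueError("calibration leaves [0, 1]")


@dataclass
class SyntheticExperiment:
    """One generated experiment, in the TSV dialects the fitters read."""

    salinities: List[SalinitySeries]
    counts: pd.DataFrame  # line_id, transfer, day, locus, n_C, N_total
    treatments: pd.DataFrame  # line_id, mean, variance, autocorrelation
    true_latents: pd.DataFrame  # line_id, transfer, day, psi_true
    attrition: pd.DataFrame  # line_id, last_transfer
    config: ExperimentConfig
    seed: int


def _mean_selection_from_effects(fx: Dict[str, float], spec: TreatmentSpec) -> float:
    mu = spec.mean_deviation
    return (
        fx["theta_intercept"]
        + fx.get("theta_mu", 0.0) * mu
        + fx.get("theta_mu2", 0.0) * mu * mu
        + fx.get("theta_sigma2", 0.0) * spec.variance
        + fx.get("theta_rho2", 0.0) * spec.predictability
        + fx.get("theta_rho", 0.0) * spec.autocorrelation
    )


def generate_experiment(config: ExperimentConfig, seed: int) -> SyntheticExperiment:
    """Generate salinities, latent trajectories and read counts for all lines.

    The master seed spawns per-line child generators deterministically,
    so any single line can be re-generated in isolation.
    """
    master = np.random.SeedSequence(seed)
    durations, start_days = transfer_schedule(config.n_transfers, config.first_duration)
    seq_idx = np.array(config.sequenced_transfers) - 1  # 0-based intervals
    vif = variance_inflation_factor([3, 4])
    fx = config.fixed_effects
    vc = config.variance_components

    sal_list: List[SalinitySeries] = []
    count_rows = []
    treat_rows = []
    latent_rows = []
    attr_rows = []

    line_no = 0
    for spec, n_lines in config.treatments:
        for _ in range(n_lines):
            line_no += 1
            line_id = f"L{line_no:03d}"
            child = np.random.default_rng(master.spawn(1)[0])
            series = simulate_ar1(spec, child, config.first_duration, line_id)
            sal_list.append(series)
            treat_rows.append((line_id, spec.mean_salinity, spec.variance, spec.autocorrelation))

            # latent trajectory at the end of every transfer
            psi0 = fx["psi0_mean"] + np.sqrt(max(vc.get("v_psi0", 0.0), 0.0)) * child.standard_normal()
            if config.mode == "macroscopic":
                s_bar = _mean_selection_from_effects(fx, spec)
                sig = vc["sigma0_sq"] if spec.variance == 0 else vc["sigma1_sq"]
                incr = s_bar * durations + np.sqrt(vif * sig * durations) * child.standard_normal(
                    config.n_transfers
                )
            else:
                rn = config.reaction_norm
                E = series.deviations
                if isinstance(rn, ReactionNormBi):
                    E_prev = np.concatenate([[E[0]], E[:-1]])
                    s = bivariate_selection_at(rn, E_prev, E)
                else:
                    s = selection_at(rn, E)
                s = np.atleast_1d(s) + config.residual_sd * child.standard_normal(config.n_transfers)
                incr = s * durations
            psi = psi0 + np.cumsum(incr)

            # attrition: line dies before a uniformly-thinned transfer
            death_p = config.attrition_const if spec.variance == 0 else config.attrition_fluct
            alive = child.random(config.n_transfers) >= death_p
            dead_at = np.argmin(alive) if not alive.all() else config.n_transfers
            last_transfer = config.n_transfers if alive.all() else dead_at  # 1-based count alive
            attr_rows.append((line_id, int(last_transfer)))

            for k in seq_idx:
                transfer = k + 1
                if transfer > last_transfer:
                    continue
                day = start_days[k]
                latent_rows.append((line_id, transfer, day, psi[k]))
                p = special.expit(psi[k])
                q = config.calibration.alpha + config.calibration.beta * p
                N = _nb_depth(child, config.depth_chloro, config.depth_dispersion)
                M = _nb_depth(child, config.depth_its2, config.depth_dispersion)
                n = child.binomial(N, p) if N > 0 else 0
                m = child.binomial(M, q) if M > 0 else 0
                count_rows.append((line_id, transfer, day, "chloroplast", n, N))
                count_rows.append((line_id, transfer, day, "its2", m, M))

    counts = pd.DataFrame(
        count_rows, columns=["line_id", "transfer", "day", "locus", "n_C", "N_total"]
    )
    treatments = pd.DataFrame(
        treat_rows, columns=["line_id", "mean", "variance", "autocorrelation"]
    )
    latents = pd.DataFrame(latent_rows, columns=["line_id", "transfer", "day", "psi_true"])
    attrition = pd.DataFrame(attr_rows, columns=["line_id", "last_transfer"])
    return SyntheticExperiment(sal_list, counts, treatments, latents, attrition, config, seed)


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Overdispersed sequencing depth: Poisson with gamma-mixed mean."""
    if mean <= 0:
        return 0
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return int(rng.poisson(lam))


# ---------------------------------------------------------------------------
# read-level emission


def generate_reads(
    experiment: SyntheticExperiment,
    locus: str,
    line_id: str,
    transfer: int,
    table: HaplotypeTable,
    read_length: int = 200,
    contamination: float = 0.0,
    seed: int = 0,
):
    """Emit merged FASTQ records realising a counts-table cell.

    Produces exactly ``n_C`` reads carrying the C-tagged haplotype bases
    and ``N - n_C`` carrying the A haplotype at the table's SNP positions,
    with deterministic-seeded random filler elsewhere and constant
    quality. A ``contamination`` fraction of extra reads carries a
    non-reference haplotype, exercising the dropped-read accounting.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    sub = experiment.counts.query(
        "line_id == @line_id and transfer == @transfer and locus == @locus"
    )
    if len(sub) != 1:
        raise ValueError(f"no counts for {line_id} transfer {transfer} locus {locus}")
    n_C = int(sub["n_C"].iloc[0])
    N = int(sub["N_total"].iloc[0])
    rng = np.random.default_rng(seed)
    hap_by_allele = {}
    for h in table.haplotypes:
        hap_by_allele[table.allele_of(h)] = h
    backbone = rng.choice(list("ATGC"), size=read_length)
    n_contam = rng.binomial(N, contamination) if contamination > 0 else 0

    records = []
    alleles = ["C"] * n_C + ["A"] * (N - n_C)
    for i, allele in enumerate(alleles):
        seq = backbone.copy()
        for pos, base in zip(table.positions, hap_by_allele[allele]):
            seq[pos] = base
        records.append(_fastq_record(f"{line_id}_t{transfer}_{locus}_{i}", seq, SeqRecord, Seq))
    for i in range(n_contam):
        seq = backbone.copy()
        for pos, base in zip(table.positions, hap_by_allele["A"]):
            seq[pos] = base
        # corrupt one SNP position so no reference haplotype matches
        pos0 = table.positions[0]
        options = [b for b in "ATGC" if b != seq[pos0]]
        seq[pos0] = rng.choice(options)
        records.append(_fastq_record(f"{line_id}_t{transfer}_{locus}_contam_{i}", seq, SeqRecord, Seq))
    return records


def _fastq_record(name, seq_array, SeqRecord, Seq):
    rec = SeqRecord(Seq("".join(seq_array)), id=name, description="")
    rec.letter_annotations["phred_quality"] = [35] * len(seq_array)
    return rec


def write_fastq(records, path) -> None:
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# pair extraction for the transfer model


def transfer_pairs(experiment: SyntheticExperiment) -> pd.DataFrame:
    """Consecutive sequenced-transfer pairs in the transfer-model layout."""
    cfg = experiment.config
    sal = {s.line_id: s for s in experiment.salinities}
    wide = experiment.counts.pivot_table(
        index=["line_id", "transfer", "day"],
        columns="locus",
        values=["n_C", "N_total"],
    )
    rows = []
    for line_id, sub in experiment.counts.groupby("line_id"):
        transfers = np.sort(sub["transfer"].unique())
        for t0, t1 in zip(transfers[:-1], transfers[1:]):
            if t1 != t0 + 1:
                continue
            series = sal[line_id]
            rec = {
                "line_id": line_id,
                "transfer": int(t1),
                "E_prev": series.deviations[t0 - 1],
                "E_cur": series.deviations[t1 - 1],
                "duration": series.durations[t1 - 1],
            }
            for t, sfx in ((t0, "0"), (t1, "1")):
                cell = wide.loc[(line_id, t)]
                rec[f"n{sfx}"] = float(cell[("n_C", "chloroplast")].iloc[0])
                rec[f"N{sfx}"] = float(cell[("N_total", "chloroplast")].iloc[0])
                rec[f"m{sfx}"] = float(cell[("n_C", "its2")].iloc[0])
                rec[f"M{sfx}"] = float(cell[("N_total", "its2")].iloc[0])
            rows.append(rec)
    return pd.DataFrame(rows)


def simulate_transfer_pairs(
    rnb: ReactionNormBi,
    n_pairs: int,
    sigma_s_sq: float,
    depth: int,
    seed: int,
    rho: float = 0.5,
    calibration: CalibrationMap = DEFAULT_ITS2_CALIBRATION,
) -> pd.DataFrame:
    """Standalone pairs of consecutive transfers from the per-transfer model.

    Salinity deviations at the two transfers are standard binormal with
    correlation ``rho``; the logit frequency advances by
    ``duration * s(E_prev, E_cur)`` plus Gaussian process noise of
    variance ``duration^2 * sigma_s_sq``, and both endpoints are observed
    through the dual-locus binomial model at the given depth.
    """
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_pairs)
    z2 = rng.standard_normal(n_pairs)
    e_prev = z1
    e_cur = rho * z1 + np.sqrt(1 - rho * rho) * z2
    d = np.where(rng.random(n_pairs) < 0.5, 3.0, 4.0)
    s = bivariate_selection_at(rnb, e_prev, e_cur)
    psi0 = rng.normal(-1.0, 1.0, n_pairs)
    psi1 = psi0 + d * s + d * np.sqrt(sigma_s_sq) * rng.standard_normal(n_pairs)
    rows = {}
    for sfx, psi in (("0", psi0), ("1", psi1)):
        p = special.expit(psi)
        q = calibration.alpha + calibration.beta * p
        rows[f"N{sfx}"] = np.full(n_pairs, depth, dtype=float)
        rows[f"M{sfx}"] = np.full(n_pairs, depth, dtype=float)
        rows[f"n{sfx}"] = rng.binomial(depth, p).astype(float)
        rows[f"m{sfx}"] = rng.binomial(depth, q).astype(float)
    rows["E_prev"], rows["E_cur"], rows["duration"] = e_prev, e_cur, d
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# a small reference panel + haplotype table for end-to-end read tests


def demo_panel_and_table(locus: str = "chloroplast"):
    """A miniature strain panel and its haplotype table, for read-level demos.

    The chloroplast-like panel has two fully fixed diagnostic SNPs; the
    ITS2-like panel has three SNPs whose C-type haplotype is carried by
    ~20% of strain A reads, mimicking the shared-haplotype situation.
    """
    from .barcode import StrainRefPanel, build_haplotypes, gst_per_site, select_snps

    if locus == "chloroplast":
        counts = {
            "A": {10: _base_counts(T=100), 50: _base_counts(G=100), 120: _base_counts(A=60, C=40)},
            "B": {10: _base_counts(T=100), 50: _base_counts(G=100), 120: _base_counts(A=100)},
            "C": {10: _base_counts(C=100), 50: _base_counts(A=100), 120: _base_counts(A=100)},
        }
        threshold = 0.8
    elif locus == "its2":
        counts = {
            "A": {
                15: _base_counts(T=80, C=20),
                60: _base_counts(G=80, A=20),
                110: _base_counts(T=80, G=20),
            },
            "B": {15: _base_counts(T=100), 60: _base_counts(G=100), 110: _base_counts(T=100)},
            "C": {15: _base_counts(C=100), 60: _base_counts(A=100), 110: _base_counts(G=100)},
        }
        threshold = 0.2
    else:
        raise ValueError(f"unknown locus {locus!r}")
    panel = StrainRefPanel(counts, locus)
    sites = select_snps(gst_per_site(panel), threshold)
    table = build_haplotypes(panel, sites)
    return panel, table


def _base_counts(A=0, T=0, G=0, C=0, gap=0):
    return np.array([A, T, G, C, gap], dtype=float)
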