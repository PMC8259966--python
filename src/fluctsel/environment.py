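"""Serial-transfer salinity regimes.

Environments are characterised by three treatment-level parameters: the
temporal mean ``mu_E`` of salinity (M NaCl), its variance ``sigma2_E``
(M^2) and its lag-1 autocorrelation ``rho_E``. Fluctuating regimes are
stationary first-order autoregressive (AR(1)) series; the *predictability*
of a regime is the squared autocorrelation, symmetric in the sign of rho.

Salinity covariates used elsewhere in the package are deviations from the
reference salinity 2.4 M, the mean of all fluctuating treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reference salinity (M NaCl); environmental covariates are deviations from it.
REFERENCE_SALINITY = 2.4

#: Physically realisable salinity range: media are mixed from 0 M and 4.8 M stocks.
SALINITY_MIN = 0.0
SALINITY_MAX = 4.8


class InvalidTreatmentError(ValueError):
    """Raised when treatment parameters do not define a stationary regime."""


@dataclass(frozen=True)
class TreatmentSpec:
    """Parameters of one salinity treatment.

    Parameters
    ----------
    mean_salinity:
        Temporal mean of salinity, M NaCl.
    variance:
        Temporal variance of salinity, M^2. Zero for constant treatments.
    autocorrelation:
        Lag-1 autocorrelation of the AR(1) process, in (-1, 1). Ignored
        (conventionally 0) when ``variance == 0``.
    n_transfers:
        Number of serial transfers in the regime.
    constant:
        Marks a constant treatment; implies ``variance == 0``.
    """

    mean_salinity: float
    variance: float = 0.0
    autocorrelation: float = 0.0
    n_transfers: int = 37
    constant: bool = False

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise InvalidTreatmentError(f"variance must be >= 0, got {self.variance}")
        if self.constant and self.variance != 0:
            raise InvalidTreatmentError("constant treatment requires variance = 0")
        if self.variance > 0 and abs(self.autocorrelation) >= 1:
            raise InvalidTreatmentError(
                f"|autocorrelation| must be < 1 for a stationary process, "
                f"got {self.autocorrelation}"
            )
        if self.n_transfers <= 0:
            raise InvalidTreatmentError("n_transfers must be positive")

    @property
    def mean_deviation(self) -> float:
        """Treatment mean as deviation from the 2.4 M reference (mu_E)."""
        return self.mean_salinity - REFERENCE_SALINITY

    @property
    def predictability(self) -> float:
        """Squared autocorrelation rho_E^2."""
        return predictability(self.autocorrelation)


@dataclass
class SalinitySeries:
    """One line's realised environment on the serial-transfer time base.

    ``salinities[k]`` is the salinity applied during transfer interval ``k``
    (0-based), which lasts ``durations[k]`` days and ends at day
    ``start_days[k]`` (cumulative, counted from inoculation at day 0).
    """

    salinities: np.ndarray
    durations: np.ndarray
    start_days: np.ndarray
    treatment: TreatmentSpec
    n_clamped: int = 0
    line_id: str = ""
    deviations: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.salinities = np.asarray(self.salinities, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.start_days = np.asarray(self.start_days, dtype=float)
        n = len(self.salinities)
        if not (len(self.durations) == len(self.start_days) == n):
            raise ValueError("salinities, durations and start_days must align")
        self.deviations = self.salinities - REFERENCE_SALINITY

    def __len__(self) -> int:
        return len(self.salinities)


def predictability(rho: float) -> float:
    """Environmental predictability rho^2, symmetric in the sign of rho."""
    if abs(rho) >= 1:
        raise InvalidTreatmentError(f"|rho| must be < 1, got {rho}")
    return rho * rho


def transfer_schedule(n_transfers: int, first_duration: int = 3):
    """Alternating 3/4-day transfer schedule.

    Returns ``(durations, start_days)`` where durations alternate 3 and 4
    days starting from ``first_duration`` and start_days are cumulative
    sums (day at the end of each interval; every two consecutive intervals
    span one week).
    """
    if n_transfers <= 0:
        raise ValueError("n_transfers must be positive")
    if first_duration not in (3, 4):
        raise ValueError("first_duration must be 3 or 4")
    other = 7 - first_duration
    durations = np.where(np.arange(n_transfers) % 2 == 0, first_duration, other)
    durations = durations.astype(float)
    return durations, np.cumsum(durations)


def simulate_ar1(
    spec: TreatmentSpec,
    seed,
    first_duration: int = 3,
    line_id: str = "",
) -> SalinitySeries:
    """Simulate a stationary AR(1) salinity series for one line.

    The first value is drawn from the stationary distribution
    N(mean, variance); successive values follow
    ``x[t+1] = mean + rho * (x[t] - mean) + innovation`` with innovation
    variance ``variance * (1 - rho^2)``, so the marginal law is stationary.
    Salinities are clamped to the physical range [0, 4.8] M and the number
    of clamped values recorded.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_transfers
    durations, start_days = transfer_schedule(n, first_duration)
    if spec.variance == 0:
        x = np.full(n, spec.mean_salinity)
        n_clamped = 0
    else:
        rho = spec.autocorrelation
        sd_stat = np.sqrt(spec.variance)
        sd_innov = np.sqrt(spec.variance * (1 - rho * rho))
        x = np.empty(n)
        x[0] = spec.mean_salinity + sd_stat * rng.standard_normal()
        eps = sd_innov * rng.standard_normal(n - 1)
        for t in range(1, n):
            x[t] = spec.mean_salinity + rho * (x[t - 1] - spec.mean_salinity) + eps[t - 1]
        clipped = np.clip(x, SALINITY_MIN, SALINITY_MAX)
        n_clamped = int(np.sum(clipped != x))
        x = clipped
    return SalinitySeries(x, durations, start_days, spec, n_clamped, line_id)


def salinity_frame(series_list) -> pd.DataFrame:
    """Long-format salinity table: line_id, transfer (1-based), day, salinity_M."""
    rows = []
    for s in series_list:
        for k in range(len(s)):
            rows.append((s.line_id, k + 1, s.start_days[k], s.salinities[k]))
    return pd.DataFrame(rows, columns=["line_id", "transfer", "day", "salinity_M"])


def write_salinity_tsv(series_list, path) -> None:
    salinity_frame(series_list).to_csv(path, sep="\t", index=False)


def read_salinity_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"line_id", "transfer", "day", "salinity_M"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"salinity table missing columns: {sorted(missing)}")
    return df
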