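"""Normality-gated correlation workflow and surgical-energy utilities.

The analysis layer mirrors a typical two-device agreement study: per-eye
opacity values from several densitometry methods are cross-correlated,
with the coefficient chosen by variable type and distribution --
Kendall's tau-b for ordinal/discrete variables, Pearson's r when both
variables pass a Kolmogorov-Smirnov normality check, Spearman's rho
otherwise.  Cumulative dissipated energy (CDE) correlations exclude eyes
operated with the femtosecond laser, whose CDE is reduced by design.

The KS test is run against a normal with parameters estimated from the
sample, which invalidates the textbook KS null distribution; p-values are
therefore Lilliefors-corrected via a seeded Monte-Carlo null, cached per
sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

CorrelationMethod = Literal["pearson", "spearman", "kendall_tau_b"]

#: Default densitometry/clinical columns entering the correlation matrix,
#: in display order.
DEFAULT_VARIABLES = (
    "lens_scheimpflug_pct",
    "nucleus_scheimpflug_pct",
    "linear_scheimpflug_pct",
    "grade_ordinal",
    "lens_ssoct_piu",
    "nucleus_ssoct_piu",
    "linear_ssoct_au",
    "cde_pcts",
    "cdva",
)

#: Variables treated as ordinal/discrete (forcing Kendall's tau-b).
ORDINAL_VARIABLES = frozenset({"grade_ordinal", "cdva"})

#: Variables measured only for eyes operated without the femtosecond laser.
CDE_VARIABLES = frozenset({"cde_pcts"})


@dataclass
class CohortRecord:
    """Per-eye measurements feeding the statistics layer.

    Densities are on their native scales (PIU 0-255 for SS-OCT lens and
    nucleus, [0, 1] arbitrary units for SS-OCT linear, percent for the
    Scheimpflug methods).  ``grade_ordinal`` is a 0-5 ordinal severity
    grade; ``cde_pcts`` is cumulative dissipated energy in percent-seconds
    (``None`` for femtosecond-laser eyes); ``cdva`` is decimal Snellen
    acuity.
    """

    eye_id: str
    lens_ssoct_piu: float
    nucleus_ssoct_piu: float
    linear_ssoct_au: float
    lens_scheimpflug_pct: float
    nucleus_scheimpflug_pct: float
    linear_scheimpflug_pct: float
    grade_ordinal: int
    cde_pcts: Optional[float] = None
    cdva: Optional[float] = None
    femto_flag: bool = False

    def __post_init__(self) -> None:
        if self.grade_ordinal not in {0, 1, 2, 3, 4, 5}:
            raise ValueError(f"grade_ordinal must be in 0..5, got {self.grade_ordinal}")
        if self.cde_pcts is not None and self.cde_pcts < 0:
            raise ValueError("cde_pcts must be >= 0")
        if not 0 <= self.lens_ssoct_piu <= 255 or not 0 <= self.nucleus_ssoct_piu <= 255:
            raise ValueError("SS-OCT PIU densities must lie in [0, 255]")
        if not 0 <= self.linear_ssoct_au <= 1:
            raise ValueError("SS-OCT linear density must lie in [0, 1]")


@dataclass
class CorrelationResult:
    """One correlation cell: method, coefficient, two-sided p, sample size."""

    method: CorrelationMethod
    coefficient: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.coefficient <= 1 + 1e-12:
            raise ValueError(f"|coefficient| > 1: {self.coefficient}")
        if self.n < 3:
            raise ValueError("correlation requires n >= 3")


def _as_clean_array(values: Sequence[float], name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1D")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def _ks_statistic_fitted(x: np.ndarray) -> float:
    """KS distance between the empirical CDF and a normal fit to the sample."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the fitted-normal KS statistic."""
    rng = np.random.default_rng([seed, n])
    samples = rng.standard_normal((n_reps, n))
    mu = samples.mean(axis=1, keepdims=True)
    sd = samples.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((samples - mu) / sd, axis=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d = np.maximum(i / n - cdf, cdf - (i - 1) / n).max(axis=1)
    d.sort()
    return d


def ks_normality(
    values: Sequence[float], n_reps: int = 10_000, mc_seed: int = 12345
) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Tests the sample against a normal with the sample's own mean and
    standard deviation.  Because the parameters are fitted, the p-value
    uses a Lilliefors-style Monte-Carlo null distribution (``n_reps``
    simulated normal samples of the same size, fixed seed); the naive KS
    p-value would be strongly anticonservative.

    Returns ``(statistic, p_value)``.
    """
    x = _as_clean_array(values)
    if len(x) < 5:
        raise ValueError("normality test requires n >= 5")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no distribution to test")
    d = _ks_statistic_fitted(x)
    null = _lilliefors_null(len(x), n_reps, mc_seed)
    # p = P(D_null >= d), with +1 smoothing to keep p > 0.
    n_ge = len(null) - np.searchsorted(null, d, side="left")
    p = (n_ge + 1) / (len(null) + 1)
    return d, float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation; two-sided p from the t-distribution."""
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    _check_pair(xa, ya)
    r, p = sps.pearsonr(xa, ya)
    return CorrelationResult("pearson", float(r), float(p), len(xa))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks (ties averaged)."""
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    _check_pair(xa, ya)
    rho, p = sps.spearmanr(xa, ya)
    return CorrelationResult("spearman", float(rho), float(p), len(xa))


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's tau-b with tie correction.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where C/D are concordant/
    discordant pair counts, n0 = n(n-1)/2 and n1, n2 are the tied-pair
    counts within x and y.  The p-value uses the normal approximation with
    tie-adjusted variance.
    """
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    _check_pair(xa, ya)
    tau, p = sps.kendalltau(xa, ya, variant="b", method="asymptotic")
    if np.isnan(tau):
        raise ValueError("tau-b undefined: all pairs tied in one variable")
    return CorrelationResult("kendall_tau_b", float(tau), float(p), len(xa))


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")


def select_method(
    x: Sequence[float],
    y: Sequence[float],
    x_is_ordinal: bool = False,
    y_is_ordinal: bool = False,
    alpha: float = 0.05,
) -> CorrelationMethod:
    """Choose the correlation coefficient the way the workflow prescribes.

    Ordinal or discrete variables force Kendall's tau-b.  Otherwise both
    samples are screened with the Lilliefors-corrected KS normality test:
    Pearson if both pass at ``alpha``, Spearman if either fails.
    """
    if x_is_ordinal or y_is_ordinal:
        return "kendall_tau_b"
    _, px = ks_normality(x)
    _, py = ks_normality(y)
    if px > alpha and py > alpha:
        return "pearson"
    return "spearman"


_CORRELATORS = {"pearson": pearson, "spearman": spearman, "kendall_tau_b": kendall_tau_b}


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    x_is_ordinal: bool = False,
    y_is_ordinal: bool = False,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Run the automatically selected correlation on one pair."""
    method = select_method(x, y, x_is_ordinal, y_is_ordinal, alpha)
    return _CORRELATORS[method](x, y)


def cohort_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    """Tabulate a cohort as a DataFrame (one row per eye)."""
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in cohort])


def correlation_matrix(
    cohort: Sequence[CohortRecord],
    variable_list: Sequence[str] = DEFAULT_VARIABLES,
    exclude_femto_for_cde: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise correlation table over cohort variables.

    Each cell holds a :class:`CorrelationResult` (or ``None`` when fewer
    than 3 complete pairs exist).  Missing values are deleted pairwise.
    Pairs involving CDE are restricted to eyes operated without the
    femtosecond laser when ``exclude_femto_for_cde`` is set.  The method
    per pair follows :func:`select_method`.
    """
    df = cohort_frame(cohort)
    for v in variable_list:
        if v not in df.columns:
            raise KeyError(f"unknown cohort variable: {v}")
    out = pd.DataFrame(index=list(variable_list), columns=list(variable_list), dtype=object)
    for i, vx in enumerate(variable_list):
        for j, vy in enumerate(variable_list):
            if j < i:
                out.iat[i, j] = out.iat[j, i]
                continue
            sub = df
            if exclude_femto_for_cde and (vx in CDE_VARIABLES or vy in CDE_VARIABLES):
                sub = df[~df["femto_flag"]]
            pair = sub[[vx, vy]].dropna()
            if i == j:
                if len(pair) >= 3 and np.ptp(pair[vx].to_numpy(dtype=float)) > 0:
                    method = "kendall_tau_b" if vx in ORDINAL_VARIABLES else "pearson"
                    out.iat[i, j] = CorrelationResult(method, 1.0, 0.0, len(pair))
                else:
                    out.iat[i, j] = None
                continue
            if len(pair) < 3:
                out.iat[i, j] = None
                continue
            try:
                out.iat[i, j] = correlate(
                    pair[vx].to_numpy(dtype=float),
                    pair[vy].to_numpy(dtype=float),
                    x_is_ordinal=vx in ORDINAL_VARIABLES,
                    y_is_ordinal=vy in ORDINAL_VARIABLES,
                    alpha=alpha,
                )
            except ValueError:
                out.iat[i, j] = None
    return out


_METHOD_TAG = {"pearson": "r", "spearman": "rho", "kendall_tau_b": "t"}


def format_correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Render a correlation matrix as strings with method tags and stars.

    Stars mark two-sided significance: ``*`` p < 0.05, ``**`` p < 0.01,
    ``***`` p < 0.001.
    """
    def fmt(cell):
        if cell is None:
            return ""
        stars = ""
        for cut, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if cell.p_value < cut:
                stars = s
                break
        return f"{cell.coefficient:.2f} {_METHOD_TAG[cell.method]}{stars} (n={cell.n})"

    return matrix.map(fmt)


def sample_size_for_correlation(
    rho: float, power: float = 0.90, alpha_two_sided: float = 0.05
) -> int:
    """Sample size to detect a nonzero correlation via the Fisher z-transform.

    n = ceil(((z_{1-alpha/2} + z_power) / atanh(rho))^2 + 3), floored at 4.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1); rho=0 gives a divergent size")
    if not 0 < power < 1 or not 0 < alpha_two_sided < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    za = sps.norm.ppf(1 - alpha_two_sided / 2)
    zb = sps.norm.ppf(power)
    n = math.ceil(((za + zb) / math.atanh(rho)) ** 2 + 3)
    return max(n, 4)


def cde(average_power_pct: float, phaco_time_s: float) -> float:
    """Cumulative dissipated energy in percent-seconds.

    CDE (%s) = average phacoemulsification power (%) x phacoemulsification
    time (s), with power taken as a fraction (power/100), matching the
    clinically reported magnitude of a few percent-seconds.
    """
    if not 0 <= average_power_pct <= 100:
        raise ValueError("average power must lie in [0, 100] percent")
    if phaco_time_s < 0:
        raise ValueError("phaco time must be >= 0")
    return average_power_pct / 100.0 * phaco_time_s
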