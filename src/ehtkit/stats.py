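"""Shared statistics: rank-sum test, Pearson correlation, Dixon's Q gate, ΔΔCt.

The rank-sum test is the workhorse comparison for small biological samples
(no distributional assumption); qPCR fold changes use the ΔΔCt method with a
Dixon outlier gate on technical triplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ehtkit.exceptions import ConfigurationError

__all__ = [
    "TestResult",
    "CorrelationResult",
    "wilcoxon_rank_sum",
    "pearson",
    "dixon_filter",
    "delta_delta_ct",
]

# Dixon r10 two-sided critical value, n = 3, alpha = 0.05
DIXON_Q_CRIT_N3 = 0.970

#: Exact null enumeration is used up to this per-group size (and no ties).
EXACT_N_MAX = 8


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample location test."""

    statistic: float
    pvalue: float
    method: str  # "exact" | "approximate" | "not-applicable"
    n_x: int
    n_y: int

    def __post_init__(self):
        if self.method != "not-applicable" and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of range: {self.pvalue}")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t-test p-value."""

    r: float
    pvalue: float
    n: int
    applicable: bool = True


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) test
# ---------------------------------------------------------------------------

def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of the Mann-Whitney U statistic.

    ``counts[u]`` is the number of arrangements of ``n1`` ranks among
    ``n1 + n2`` that give U = u, i.e. the coefficients of the Gaussian
    binomial [n1+n2 choose n1]_q, built by multiplying out
    prod_{i=1..n1} (1 - q^{n2+i}) / (1 - q^i).
    """
    u_max = n1 * n2
    counts = np.zeros(u_max + 1, dtype=float)
    counts[0] = 1.0
    for i in range(1, n1 + 1):
        # divide by (1 - q^i): running sum with stride i
        for u in range(i, u_max + 1):
            counts[u] += counts[u - i]
        # multiply by (1 - q^{n2+i}): subtract shifted copy, high to low
        for u in range(u_max, n2 + i - 1, -1):
            counts[u] -= counts[u - (n2 + i)]
    return counts


def wilcoxon_rank_sum(x, y, method: str = "auto") -> TestResult:
    """Two-sided unpaired two-sample Wilcoxon (rank-sum) test.

    With ``method="auto"``, full exact enumeration of the null distribution
    is used when both samples are tie-free and ``min(n) <= EXACT_N_MAX``;
    otherwise a normal approximation with midranks, tie correction and
    continuity correction.  ``method="exact"`` / ``"approximate"`` force one
    code path (exact requires tie-free data).

    Returns the rank sum of ``x`` as the statistic.  Swapping the samples
    leaves the two-sided p-value unchanged.
    """
    if method not in ("auto", "exact", "approximate"):
        raise ConfigurationError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if method == "exact" and has_ties:
        raise ConfigurationError("exact enumeration requires tie-free data")
    use_exact = method == "exact" or (
        method == "auto" and not has_ties and min(n1, n2) <= EXACT_N_MAX
    )
    if use_exact:
        counts = _exact_u_distribution(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=w, pvalue=p, method="exact", n_x=n1, n_y=n2)

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:  # all values identical
        return TestResult(statistic=w, pvalue=1.0, method="approximate", n_x=n1, n_y=n2)
    # continuity correction toward the mean
    z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u) if u != mean_u else 0.0
    p_one = sps.norm.sf(abs(z))
    if not has_ties:
        # Edgeworth kurtosis term; the null distribution is symmetric so the
        # skewness term vanishes.  kappa4 = -n1 n2 (N+1)(n1^2+n2^2+n1 n2+N)/120.
        kappa4 = -n1 * n2 * (n + 1) * (n1**2 + n2**2 + n1 * n2 + n) / 120.0
        za = abs(z)
        p_one += sps.norm.pdf(za) * (kappa4 / (24.0 * var_u**2)) * (za**3 - 3 * za)
        p_one = min(max(p_one, 0.0), 1.0)
    p = min(1.0, 2.0 * p_one)
    return TestResult(statistic=w, pvalue=p, method="approximate", n_x=n1, n_y=n2)


# ---------------------------------------------------------------------------
# Pearson correlation with Student t-test
# ---------------------------------------------------------------------------

def pearson(x, y) -> CorrelationResult:
    """Pearson R with two-sided p from t = R sqrt((n-2)/(1-R^2)) on n-2 df.

    Constant input yields a not-applicable result (R undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ConfigurationError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=float("nan"), pvalue=float("nan"), n=n, applicable=False)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), pvalue=float(p), n=n)


# ---------------------------------------------------------------------------
# Dixon's Q outlier gate on technical triplicates
# ---------------------------------------------------------------------------

def dixon_filter(triplicate, sd_gate: float = 0.3, q_crit: float = DIXON_Q_CRIT_N3):
    """Gate a technical triplicate: remove at most one gross outlier.

    If the sample standard deviation is at or below ``sd_gate`` (cycles) the
    triplicate is returned unchanged.  Otherwise Dixon's Q (r10 variant,
    gap / range for the most extreme value) is computed and the suspect is
    removed when Q exceeds the critical value (0.970 at n = 3, alpha = 0.05,
    two-sided).

    Returns
    -------
    (values, removed)
        ``values`` — kept values (length 3, or 2 after removal);
        ``removed`` — the removed value, or ``None``.
    """
    values = np.asarray(triplicate, dtype=float)
    if values.size != 3:
        raise ConfigurationError(f"dixon_filter expects exactly 3 values, got {values.size}")
    if float(np.std(values, ddof=1)) <= sd_gate:
        return values, None
    lo, mid, hi = np.sort(values)
    rng = hi - lo
    if rng == 0:
        return values, None
    gap_low, gap_high = mid - lo, hi - mid
    suspect, gap = (lo, gap_low) if gap_low > gap_high else (hi, gap_high)
    q = gap / rng
    if q > q_crit:
        keep = np.sort(values)[[1, 2]] if suspect == lo else np.sort(values)[[0, 1]]
        return keep, float(suspect)
    return values, None


# ---------------------------------------------------------------------------
# Delta-Ct / delta-delta-Ct fold changes
# ---------------------------------------------------------------------------

def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    sd_gate: float = 0.3,
    mode: str = "ddct",
) -> pd.DataFrame:
    """Fold changes by the ΔΔCt method with Dixon-gated technical triplicates.

    The table needs columns ``sample``, ``condition``, ``gene``, ``ct``
    (one row per technical replicate).  Per (sample, gene) the triplicate is
    gated with :func:`dixon_filter` and averaged; ΔCt = mean Ct(gene) − mean
    Ct(reference); ΔΔCt = ΔCt − mean ΔCt over the control-condition samples
    of the same gene; fold change = 2^(−ΔΔCt), i.e. amplification efficiency
    is taken as exactly 2.  ``mode="dct"`` stops at relative expression
    2^(−ΔCt) (single normalization to the reference gene).

    Samples lacking the reference gene are flagged (``skipped=True``) and
    carry NaN results.
    """
    required = {"sample", "condition", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"Ct table missing columns: {sorted(missing)}")
    if mode not in ("ddct", "dct"):
        raise ConfigurationError(f"mode must be 'ddct' or 'dct', got {mode!r}")
    if reference_gene not in set(table["gene"]):
        raise ConfigurationError(f"reference gene {reference_gene!r} absent from table")

    def gated_mean(values):
        vals = np.asarray(values, dtype=float)
        if vals.size == 3:
            vals, _ = dixon_filter(vals, sd_gate=sd_gate)
        return float(vals.mean())

    means = (
        table.groupby(["sample", "condition", "gene"])["ct"].apply(gated_mean).rename("ct_mean")
    ).reset_index()

    ref = means[means["gene"] == reference_gene].set_index("sample")["ct_mean"]
    genes = means[means["gene"] != reference_gene].copy()
    genes["skipped"] = ~genes["sample"].isin(ref.index)
    genes["delta_ct"] = genes["ct_mean"] - genes["sample"].map(ref)

    if mode == "dct":
        genes["rel_expression"] = 2.0 ** (-genes["delta_ct"])
        return genes.reset_index(drop=True)

    if control_condition not in set(table["condition"]):
        raise ConfigurationError(f"control condition {control_condition!r} absent from table")
    baseline = (
        genes[(genes["condition"] == control_condition) & ~genes["skipped"]]
        .groupby("gene")["delta_ct"]
        .mean()
    )
    genes["delta_delta_ct"] = genes["delta_ct"] - genes["gene"].map(baseline)
    genes["fold_change"] = 2.0 ** (-genes["delta_delta_ct"])
    return genes.reset_index(drop=True)
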