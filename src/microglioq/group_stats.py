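"""Group statistics: Grubbs outlier exclusion, Kruskal-Wallis, Dunn's post hoc.

The analysis pipeline mirrors common prism-style practice for small animal
cohorts: per-animal values are summarized as arithmetic mean +- sample SD
(n-1 denominator); a single-pass two-sided Grubbs test (alpha = 0.05) may
exclude at most one value per group, applied to the densitometric metric
only; group differences are tested with the tie-corrected Kruskal-Wallis
H (chi-square approximation) followed by Dunn's z comparisons of each
treated group against the control, Bonferroni-adjusted over the number of
comparisons. Mid-ranks are used for ties throughout.

Significance symbols: ``***`` p <= 0.001, ``**`` p <= 0.01, ``*`` p <= 0.05,
``n.s.`` otherwise (boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: metrics recognized by :func:`run_group_analysis`
METRICS = ("density", "percent_area", "mean_ri")


@dataclass
class GroupSamples:
    """Per-animal values of one metric in one group."""

    label: str
    values: np.ndarray
    metric: str = "mean_ri"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValidationError(f"group {self.label!r}: need >= 2 values")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"group {self.label!r}: non-finite values")


@dataclass
class Comparison:
    group: str
    z: float
    p_raw: float
    p_adjusted: float
    symbol: str


@dataclass
class GrubbsOutcome:
    index: int | None
    value: float | None
    G: float
    G_critical: float


@dataclass
class TestResult:
    """Omnibus + post hoc results for one metric."""

    metric: str
    H: float
    p_global: float
    comparisons: list[Comparison]
    alpha: float = 0.05
    excluded_outliers: list[tuple[str, float, float]] = field(default_factory=list)
    group_summaries: list[dict] = field(default_factory=list)


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need >= 2 values to summarize")
    return float(values.mean()), float(values.std(ddof=1))


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)), t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValidationError("Grubbs requires n >= 3")
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsOutcome:
    """Single-pass two-sided Grubbs test for one outlier.

    G = max |x_i - mean| / SD; the most extreme value is flagged iff
    G > G_critical. At most one value is ever flagged (no iteration).
    A zero-SD sample is untestable and returns no outlier (G = nan).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("Grubbs requires n >= 3")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return GrubbsOutcome(index=None, value=None, G=float("nan"),
                             G_critical=grubbs_critical(x.size, alpha))
    dev = np.abs(x - mean)
    i = int(np.argmax(dev))
    G = float(dev[i] / sd)
    G_crit = grubbs_critical(x.size, alpha)
    if G > G_crit:
        return GrubbsOutcome(index=i, value=float(x[i]), G=G, G_critical=G_crit)
    return GrubbsOutcome(index=None, value=None, G=G, G_critical=G_crit)


def _ranks_and_ties(groups: list[GroupSamples]):
    pooled = np.concatenate([g.values for g in groups])
    ranks = sps.rankdata(pooled)  # mid-ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(((counts**3 - counts)).sum())
    return pooled, ranks, tie_sum


def kruskal_wallis(groups: list[GroupSamples]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    H = [12 / (N(N+1)) * sum R_g^2 / n_g - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)],
    p from the chi-square upper tail with k-1 df. All pooled values equal
    is the degenerate case H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis requires >= 2 groups")
    pooled, ranks, tie_sum = _ranks_and_ties(groups)
    N = len(pooled)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    start = 0
    h = 0.0
    for g in groups:
        n_g = len(g.values)
        R_g = ranks[start:start + n_g].sum()
        h += R_g**2 / n_g
        start += n_g
    H = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    correction = 1.0 - tie_sum / (N**3 - N)
    H /= correction
    p = float(sps.chi2.sf(H, df=len(groups) - 1))
    return float(H), p


def significance_symbol(p: float) -> str:
    """Map a p-value to the printed significance symbol."""
    if not (0 <= p <= 1):
        raise ValidationError(f"p-value outside [0, 1]: {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def dunns_test(
    groups: list[GroupSamples],
    control_label: str,
    mode: str = "vs_control",
    adjustment: str = "bonferroni",
) -> list[Comparison]:
    """Dunn's rank-based z comparisons with Bonferroni adjustment.

    For each non-control group g:
    z = (meanrank_g - meanrank_ctrl) /
        sqrt((N(N+1)/12 - T) * (1/n_g + 1/n_ctrl)),   T = sum(t^3-t) / (12(N-1));
    p_raw is two-sided standard normal, p_adjusted = min(1, m * p_raw) with m
    the number of comparisons. ``mode='all_pairs'`` compares every pair
    instead (off by default; the cohort design compares against control).
    """
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ValidationError(f"control group {control_label!r} not present in {labels}")
    if len(groups) < 2:
        raise ValidationError("Dunn's test requires >= 2 groups")
    if adjustment != "bonferroni":
        raise ValidationError("only bonferroni adjustment is supported")
    pooled, ranks, tie_sum = _ranks_and_ties(groups)
    N = len(pooled)
    T = tie_sum / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_ranks = {}
    sizes = {}
    start = 0
    for g in groups:
        n_g = len(g.values)
        mean_ranks[g.label] = ranks[start:start + n_g].mean()
        sizes[g.label] = n_g
        start += n_g
    if mode == "vs_control":
        pairs = [(g.label, control_label) for g in groups if g.label != control_label]
    elif mode == "all_pairs":
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    m = len(pairs)
    var_term = N * (N + 1) / 12.0 - T
    out = []
    for a, b in pairs:
        se = np.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = float(2 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, m * p_raw)
        name = a if mode == "vs_control" else f"{a}_vs_{b}"
        out.append(Comparison(group=name, z=float(z), p_raw=p_raw,
                              p_adjusted=p_adj, symbol=significance_symbol(p_adj)))
    return out


def run_group_analysis(
    table,
    metric: str,
    control_label: str,
    alpha: float = 0.05,
) -> TestResult:
    """Full pipeline for one metric over a per-animal value table.

    ``table`` is a DataFrame with columns ``group`` and ``value`` (one row
    per animal), groups in first-appearance order. Grubbs exclusion
    (single pass, per group) is applied only when ``metric ==
    'percent_area'`` — the densitometric readout — never to densities or
    ramification indices. Kruskal-Wallis then Dunn's vs control follow on
    the (possibly reduced) samples.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    if "group" not in table.columns or "value" not in table.columns:
        raise ValidationError("table needs 'group' and 'value' columns")
    order = list(dict.fromkeys(table["group"]))
    excluded: list[tuple[str, float, float]] = []
    groups: list[GroupSamples] = []
    for label in order:
        vals = np.asarray(table.loc[table["group"] == label, "value"], dtype=float)
        if metric == "percent_area" and len(vals) >= 3 and vals.std(ddof=1) > 0:
            res = grubbs_test(vals, alpha=alpha)
            if res.index is not None:
                excluded.append((label, res.value, res.G))
                vals = np.delete(vals, res.index)
        groups.append(GroupSamples(label=label, values=vals, metric=metric))
    H, p_global = kruskal_wallis(groups)
    comparisons = dunns_test(groups, control_label)
    summaries = []
    for g in groups:
        mean, sd = summarize(g.values)
        summaries.append({"group": g.label, "metric": metric, "n": len(g.values),
                          "mean": mean, "sd": sd})
    return TestResult(metric=metric, H=H, p_global=p_global, comparisons=comparisons,
                      alpha=alpha, excluded_outliers=excluded, group_summaries=summaries)
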