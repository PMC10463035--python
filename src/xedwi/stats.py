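"""Normality-gated cohort statistics for longitudinal imaging biomarkers.

Every test routes through a Shapiro–Wilk normality gate at α = 0.05 on the
analysis quantity (paired differences for paired comparisons; each margin
for correlations): parametric (paired t, Pearson, repeated-measures ANOVA)
when the gate passes, nonparametric (Wilcoxon signed-rank, Spearman,
Friedman) otherwise. The routing decision and its p-value are carried in
every result so a reader can see which branch produced each number. All
p-values are two-tailed and unadjusted by default; Holm-adjusted columns
are opt-in (multiplicity is reported, not silently corrected away).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "CohortTable", "StatResult", "normality_gate", "paired_compare",
    "zone_omnibus", "correlate", "longitudinal_report",
    "hodges_lehmann", "signed_rank_ci",
]

REGIONS = ("global", "upper", "middle", "lower")


@dataclass
class StatResult:
    """One statistical comparison: routing, test statistic, effect and CI."""

    test: str
    n: int
    statistic: float
    p: float
    estimate: float
    effect_name: str
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    route: str = ""
    normality_p: float = float("nan")
    degenerate: bool = False
    notes: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.degenerate and not (0.0 <= self.p <= 1.0):
            raise ParameterError(f"p-value {self.p} outside [0, 1]")

    def to_row(self) -> dict:
        return {"test": self.test, "n": self.n, "statistic": self.statistic,
                "p": self.p, "estimate": self.estimate, "effect": self.effect_name,
                "ci_low": self.ci_low, "ci_high": self.ci_high, "route": self.route,
                "normality_p": self.normality_p, "degenerate": self.degenerate,
                "notes": self.notes}


class CohortTable:
    """Per-subject, per-visit, per-region summary values joined with covariates.

    ``measurements`` is long-format with columns
    (subject, visit, region, metric, mean, median, sd, n_voxels);
    ``covariates`` is wide per (subject, visit). The (subject, visit,
    region, metric) key must be unique and visits come from a declared
    ordered set.
    """

    MEAS_KEY = ["subject", "visit", "region", "metric"]

    def __init__(self, measurements: pd.DataFrame, covariates: pd.DataFrame | None = None,
                 visits: tuple | None = None):
        meas = measurements.copy()
        missing = [c for c in self.MEAS_KEY + ["mean", "median"] if c not in meas.columns]
        if missing:
            raise ParameterError(f"measurements missing columns {missing}")
        if meas.duplicated(self.MEAS_KEY).any():
            raise ParameterError("duplicate (subject, visit, region, metric) rows")
        self.visits = tuple(visits) if visits else tuple(pd.unique(meas["visit"]))
        unknown = set(meas["visit"]) - set(self.visits)
        if unknown:
            raise ParameterError(f"visits {unknown} not in declared set {self.visits}")
        self.measurements = meas
        self.covariates = covariates.copy() if covariates is not None else None

    @property
    def metrics(self) -> list:
        return sorted(self.measurements["metric"].unique())

    @property
    def regions(self) -> list:
        known = list(self.measurements["region"].unique())
        return [r for r in REGIONS if r in known] or known

    def subject_values(self, metric: str, region: str, visit: str, value: str = "mean") -> pd.Series:
        sel = self.measurements.query("metric == @metric and region == @region and visit == @visit")
        return sel.set_index("subject")[value]

    def paired(self, metric: str, region: str, visit_a: str, visit_b: str,
               value: str = "mean") -> tuple[np.ndarray, np.ndarray, int]:
        """Matched per-subject values at two visits; returns (a, b, n_excluded)."""
        a = self.subject_values(metric, region, visit_a, value)
        b = self.subject_values(metric, region, visit_b, value)
        joined = pd.concat([a.rename("a"), b.rename("b")], axis=1)
        complete = joined.dropna()
        return complete["a"].to_numpy(), complete["b"].to_numpy(), len(joined) - len(complete)

    def covariate_values(self, name: str, visit: str) -> pd.Series:
        if self.covariates is None or name not in self.covariates.columns:
            raise ParameterError(f"covariate {name!r} not available")
        sel = self.covariates[self.covariates["visit"] == visit]
        return sel.set_index("subject")[name]


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

@dataclass
class GateResult:
    route: str            # "parametric" | "nonparametric"
    p: float
    degenerate: bool = False
    note: str = ""


def normality_gate(values, alpha: float = 0.05) -> GateResult:
    """Shapiro–Wilk gate on the analysis quantity.

    n < 3 forces the nonparametric route (with a note); a constant vector is
    flagged degenerate and routed nonparametrically.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        return GateResult("nonparametric", float("nan"), note="n < 3: normality untestable")
    if np.ptp(x) == 0:
        return GateResult("nonparametric", float("nan"), degenerate=True, note="constant sample")
    stat, p = sps.shapiro(x)
    route = "parametric" if p >= alpha else "nonparametric"
    return GateResult(route, float(p))


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def _signed_rank_lower_quantile(n: int, alpha: float = 0.05) -> int:
    """Largest k with P(W⁺ ≤ k) ≤ α/2 under the signed-rank null.

    Exact (dynamic programming over rank sums) for n ≤ 25, normal
    approximation above.
    """
    if n <= 25:
        counts = np.array([1.0])
        for i in range(1, n + 1):
            new = np.zeros(counts.size + i)
            new[: counts.size] += counts
            new[i:] += counts
            counts = new
        cdf = np.cumsum(counts) / counts.sum()
        ks = np.nonzero(cdf <= alpha / 2)[0]
        return int(ks[-1]) if ks.size else -1
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return int(np.floor(mean + sps.norm.ppf(alpha / 2) * sd - 0.5))


def hodges_lehmann(d: np.ndarray) -> float:
    """Hodges–Lehmann one-sample estimate: median of the Walsh averages."""
    d = np.asarray(d, float)
    i, j = np.triu_indices(d.size)
    return float(np.median((d[i] + d[j]) / 2.0))


def signed_rank_ci(d: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Distribution-free CI of the pseudo-median from the Walsh averages."""
    d = np.asarray(d, float)
    i, j = np.triu_indices(d.size)
    walsh = np.sort((d[i] + d[j]) / 2.0)
    k = _signed_rank_lower_quantile(d.size, alpha)
    if k < 0 or walsh.size < 2:
        return float(walsh.min()), float(walsh.max())
    return float(walsh[k]), float(walsh[walsh.size - 1 - k])


def _paired_from_arrays(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
                        n_excluded: int = 0) -> StatResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ParameterError("paired samples have different lengths")
    if a.size < 2:
        raise ParameterError(f"need >= 2 complete pairs, got {a.size}")
    d = b - a
    n = d.size
    extras = {"n_excluded": n_excluded}
    if np.allclose(d, 0.0):
        return StatResult(test="paired-degenerate", n=n, statistic=0.0, p=1.0,
                          estimate=0.0, effect_name="mean difference",
                          ci_low=0.0, ci_high=0.0, route="none",
                          degenerate=True, notes="all differences zero", extras=extras)
    gate = normality_gate(d, alpha)
    if gate.route == "parametric":
        res = sps.ttest_rel(b, a)
        md = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(n))
        tcrit = float(sps.t.ppf(1 - alpha / 2, n - 1))
        return StatResult(test="paired-t", n=n, statistic=float(res.statistic),
                          p=float(res.pvalue), estimate=md, effect_name="mean difference",
                          ci_low=md - tcrit * se, ci_high=md + tcrit * se,
                          route=gate.route, normality_p=gate.p, extras=extras)
    nz = d[d != 0]
    extras["n_zero_differences"] = int(n - nz.size)
    hl = hodges_lehmann(d)
    lo, hi = signed_rank_ci(d, alpha)
    if nz.size < 1:
        return StatResult(test="wilcoxon", n=n, statistic=0.0, p=1.0, estimate=hl,
                          effect_name="median difference", ci_low=lo, ci_high=hi,
                          route=gate.route, normality_p=gate.p, degenerate=True,
                          notes="all nonzero differences dropped", extras=extras)
    method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       method=method)
    return StatResult(test="wilcoxon", n=n, statistic=float(res.statistic),
                      p=float(res.pvalue), estimate=hl, effect_name="median difference",
                      ci_low=lo, ci_high=hi, route=gate.route, normality_p=gate.p,
                      notes=gate.note, extras=extras)


def paired_compare(table: CohortTable, metric: str, region: str, visit_a: str,
                   visit_b: str, value: str = "mean", alpha: float = 0.05) -> StatResult:
    """Paired two-visit comparison (visit_b − visit_a) of subject values.

    Route (paired t vs Wilcoxon signed-rank) decided by the normality gate
    on the paired differences. Subjects missing either visit are excluded
    and counted in ``extras['n_excluded']``.
    """
    a, b, n_excluded = table.paired(metric, region, visit_a, visit_b, value)
    return _paired_from_arrays(a, b, alpha=alpha, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# zone omnibus
# ---------------------------------------------------------------------------

def zone_omnibus(table: CohortTable, metric: str, visit: str, value: str = "mean",
                 alpha: float = 0.05, holm: bool = False):
    """Across-zone omnibus test at one visit, plus pairwise post-hocs.

    Repeated-measures ANOVA across the three zones when every zone's sample
    passes the normality gate, Friedman otherwise. Pairwise zone contrasts
    reuse :func:`paired_compare` machinery; unadjusted p-values by default
    with an optional Holm column.
    """
    zones = ("upper", "middle", "lower")
    cols = {z: table.subject_values(metric, z, visit, value) for z in zones}
    wide = pd.concat([cols[z].rename(z) for z in zones], axis=1).dropna()
    n = len(wide)
    extras = {"n_incomplete_dropped": int(len(pd.concat(cols.values(), axis=1)) - n)}
    if n < 3:
        raise ParameterError(f"zone omnibus needs >= 3 complete subjects, got {n}")
    arr = wide.to_numpy()
    if np.allclose(arr, arr[:, :1]):
        omnibus = StatResult(test="omnibus-degenerate", n=n, statistic=0.0, p=1.0,
                             estimate=0.0, effect_name="zone spread", route="none",
                             degenerate=True, notes="all zones identical", extras=extras)
        return omnibus, {}
    gates = [normality_gate(arr[:, z], alpha) for z in range(3)]
    parametric = all(g.route == "parametric" for g in gates)
    gate_p = float(np.nanmin([g.p for g in gates]))
    if parametric:
        from statsmodels.stats.anova import AnovaRM

        long = wide.reset_index().melt(id_vars="subject", var_name="zone", value_name="value")
        fit = AnovaRM(long, depvar="value", subject="subject", within=["zone"]).fit()
        row = fit.anova_table.iloc[0]
        omnibus = StatResult(test="rm-anova", n=n, statistic=float(row["F Value"]),
                             p=float(row["Pr > F"]), estimate=float(np.ptp(arr.mean(axis=0))),
                             effect_name="max zone-mean difference", route="parametric",
                             normality_p=gate_p, extras=extras)
    else:
        stat, p = sps.friedmanchisquare(arr[:, 0], arr[:, 1], arr[:, 2])
        omnibus = StatResult(test="friedman", n=n, statistic=float(stat), p=float(p),
                             estimate=float(np.ptp(np.median(arr, axis=0))),
                             effect_name="max zone-median difference", route="nonparametric",
                             normality_p=gate_p, extras=extras)
    pairs = {}
    raw_p = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        key = f"{zones[i]}-vs-{zones[j]}"
        pairs[key] = _paired_from_arrays(arr[:, i], arr[:, j], alpha=alpha)
        raw_p.append(pairs[key].p)
    if holm:
        order = np.argsort(raw_p)
        m = len(raw_p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw_p[idx])
            adj[idx] = min(1.0, running)
        for k, key in enumerate(pairs):
            pairs[key].extras["p_holm"] = float(adj[k])
    return omnibus, pairs


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1:
        return float("nan"), float("nan")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def correlate(table: CohortTable, metric_x: str, metric_y: str, region: str = "global",
              visit: str | None = None, value: str = "mean",
              alpha: float = 0.05) -> StatResult:
    """Gated Pearson/Spearman correlation of an imaging metric with another
    metric or a covariate column, across subjects at one visit.

    ``metric_y`` may name either a measurement metric (summarised over the
    same region) or a covariate column. Pearson is used when both margins
    pass the normality gate; the Fisher-z 95% CI is reported on the Pearson
    route.
    """
    visit = visit or table.visits[0]
    x = table.subject_values(metric_x, region, visit, value)
    if metric_y in table.measurements["metric"].unique():
        y = table.subject_values(metric_y, region, visit, value)
    else:
        y = table.covariate_values(metric_y, visit)
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise ParameterError(f"correlation needs >= 3 complete pairs, got {n}")
    xv, yv = joined["x"].to_numpy(), joined["y"].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return StatResult(test="correlation-degenerate", n=n, statistic=0.0, p=1.0,
                          estimate=float("nan"), effect_name="r", route="none",
                          degenerate=True, notes="zero variance in a margin")
    gx, gy = normality_gate(xv, alpha), normality_gate(yv, alpha)
    gate_p = float(np.nanmin([gx.p, gy.p]))
    if gx.route == "parametric" and gy.route == "parametric":
        r, p = sps.pearsonr(xv, yv)
        lo, hi = _fisher_ci(float(r), n, alpha)
        return StatResult(test="pearson", n=n, statistic=float(r), p=float(p),
                          estimate=float(r), effect_name="r", ci_low=lo, ci_high=hi,
                          route="parametric", normality_p=gate_p)
    r, p = sps.spearmanr(xv, yv)
    return StatResult(test="spearman", n=n, statistic=float(r), p=float(p),
                      estimate=float(r), effect_name="rho",
                      route="nonparametric", normality_p=gate_p)


# ---------------------------------------------------------------------------
# longitudinal report
# ---------------------------------------------------------------------------

def _visit_summary(vals: np.ndarray, alpha: float = 0.05) -> dict:
    n = vals.size
    mean = float(vals.mean())
    med = float(np.median(vals))
    if n > 1:
        se = vals.std(ddof=1) / np.sqrt(n)
        tcrit = sps.t.ppf(1 - alpha / 2, n - 1)
        lo, hi = mean - tcrit * se, mean + tcrit * se
    else:
        lo = hi = float("nan")
    return {"n": n, "mean": mean, "median": med, "ci_low": float(lo), "ci_high": float(hi)}


def longitudinal_report(table: CohortTable, metrics=None, regions=None,
                        value: str = "mean", alpha: float = 0.05):
    """Per metric × region: visit summaries, paired p and routing decisions.

    Returns ``(DataFrame, text)`` where the frame has one row per
    metric × region and the text mirrors a baseline/follow-up/p-value
    results table. Requires exactly two declared visits.
    """
    if len(table.visits) != 2:
        raise ParameterError(f"longitudinal report needs two visits, got {table.visits}")
    va, vb = table.visits
    metrics = metrics or table.metrics
    regions = regions or table.regions
    rows = []
    for metric in metrics:
        for region in regions:
            a, b, n_excl = table.paired(metric, region, va, vb, value)
            res = _paired_from_arrays(a, b, alpha=alpha, n_excluded=n_excl)
            sa, sb = _visit_summary(a, alpha), _visit_summary(b, alpha)
            rows.append({
                "metric": metric, "region": region, "n": res.n,
                "n_excluded": n_excl,
                f"{va}_mean": sa["mean"], f"{va}_median": sa["median"],
                f"{va}_ci_low": sa["ci_low"], f"{va}_ci_high": sa["ci_high"],
                f"{vb}_mean": sb["mean"], f"{vb}_median": sb["median"],
                f"{vb}_ci_low": sb["ci_low"], f"{vb}_ci_high": sb["ci_high"],
                "difference": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "test": res.test, "route": res.route, "normality_p": res.normality_p,
                "p": res.p, "degenerate": res.degenerate,
            })
    frame = pd.DataFrame(rows)
    lines = [f"Longitudinal comparison  {va} vs {vb}  (paired, two-tailed)",
             "=" * 72,
             f"{'metric':<10}{'region':<9}{'n':>3}  {va:>16}  {vb:>16}  {'p':>8}  test"]
    for _, r in frame.iterrows():
        fa = f"{r[f'{va}_mean']:.4g} ({r[f'{va}_ci_low']:.4g}-{r[f'{va}_ci_high']:.4g})"
        fb = f"{r[f'{vb}_mean']:.4g} ({r[f'{vb}_ci_low']:.4g}-{r[f'{vb}_ci_high']:.4g})"
        lines.append(f"{r['metric']:<10}{r['region']:<9}{r['n']:>3}  {fa:>16}  {fb:>16}"
                     f"  {r['p']:>8.3g}  {r['test']}")
    return frame, "\n".join(lines)
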