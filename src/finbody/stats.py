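"""Bout-level statistics for fin-body coordination.

Covers the bespoke procedures used to characterise coordination:

* exact binomial tests of whether a conditioned subset of bouts carries
  positive attack angles more (or less) often than the overall chance
  level;
* proportions of *conflicting* fin-body actions (lift generated during
  nose-down steering) with bootstrap CIs;
* a robust (Theil-Sen) attack-angle : posture-change slope over shallow
  climbs;
* posture summaries during steep climbs;
* equal-count binning for visualising attack angle vs posture change;
* standard group tests (paired t, one/two-way ANOVA with Tukey HSD,
  Kruskal-Wallis, Kolmogorov-Smirnov, Spearman/Pearson) on the
  appropriate units of analysis (clutch means for sibling comparisons,
  pooled bouts otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ChanceTestResult",
    "ConflictResult",
    "ClimbPostureSummary",
    "chance_level_binomial",
    "conflict_proportions",
    "robust_shallow_slope",
    "climb_posture_stats",
    "binned_means",
    "paired_t",
    "two_way_anova",
    "tukey_posthoc",
    "group_tests",
]

# Nose-down/up conflict analysis defaults: the attack-angle baseline is the
# lower asymptote (gamma0) of the wild-type 1 wpf four-parameter sigmoid
# fit, and posture changes beyond +-1 deg count as directed steering.
CONFLICT_BASELINE = -1.59  # deg
CONFLICT_THRESHOLD = 1.0  # deg


@dataclass(frozen=True)
class ChanceTestResult:
    """Exact binomial comparison of a subset against an overall chance rate."""

    n_subset: int
    n_success: int
    p_chance: float
    p_value: float
    direction: Literal["above", "below"]


def chance_level_binomial(
    n_success: int,
    n_subset: int,
    p_chance: float,
    sided: Literal["observed", "two"] = "observed",
) -> ChanceTestResult:
    """Exact binomial tail probability against a chance success rate.

    With ``sided='observed'`` (default) the test is one-sided in the
    direction of the observed deviation from expectation: the upper tail
    P(X >= k) when k is above n*p, the lower tail P(X <= k) otherwise.
    """
    if not 0 < p_chance < 1:
        raise ValueError(f"p_chance must lie in (0, 1), got {p_chance}")
    if not 0 <= n_success <= n_subset:
        raise ValueError(f"need 0 <= n_success <= n_subset, got {n_success}/{n_subset}")
    direction = "above" if n_success >= n_subset * p_chance else "below"
    if sided == "two":
        p = float(sps.binomtest(n_success, n_subset, p_chance).pvalue)
    elif direction == "above":
        p = float(sps.binom.sf(n_success - 1, n_subset, p_chance))
    else:
        p = float(sps.binom.cdf(n_success, n_subset, p_chance))
    return ChanceTestResult(
        n_subset=n_subset, n_success=n_success, p_chance=p_chance,
        p_value=p, direction=direction,
    )


@dataclass(frozen=True)
class ConflictResult:
    """Proportion of bouts with attack angle above baseline in a subset."""

    condition: str  # 'nose_down' or 'nose_up'
    baseline: float
    threshold: float
    n_subset: int
    proportion: float | None  # None when the subset is empty (undefined)
    ci95: tuple[float, float] | None


def _proportion_with_ci(success: np.ndarray, n_boot: int, rng) -> tuple[float, tuple[float, float]]:
    prop = float(np.mean(success))
    n = success.size
    draws = rng.integers(0, n, size=(n_boot, n))
    boot = success[draws].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return prop, (float(lo), float(hi))


def conflict_proportions(
    bouts: pd.DataFrame,
    baseline: float = CONFLICT_BASELINE,
    threshold: float = CONFLICT_THRESHOLD,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[ConflictResult, ConflictResult]:
    """Conflicting / synergistic fin-body action proportions.

    The *nose-down* result conditions on posture change < -threshold and
    reports the proportion of those bouts with attack angle above
    ``baseline`` (conflicting: lift during body-mediated diving); the
    *nose-up* result conditions on posture change > +threshold
    (synergistic).  Bootstrap percentile 95% CIs over bouts; empty subsets
    are reported as undefined, not zero.
    """
    rng = np.random.default_rng(seed)
    attack = np.asarray(bouts["attack_angle_deg"], float)
    r = np.asarray(bouts["posture_change_deg"], float)
    out = []
    for name, mask in (("nose_down", r < -threshold), ("nose_up", r > threshold)):
        success = (attack[mask] > baseline).astype(float)
        if success.size == 0:
            out.append(ConflictResult(name, baseline, threshold, 0, None, None))
            continue
        prop, ci = _proportion_with_ci(success, n_boot, rng)
        out.append(ConflictResult(name, baseline, threshold, int(success.size), prop, ci))
    return tuple(out)


def robust_shallow_slope(
    bouts: pd.DataFrame,
    r_range: tuple[float, float] = (0.0, 3.0),
) -> float:
    """Theil-Sen slope of attack angle vs posture change on shallow climbs.

    The median of all pairwise slopes, restricted to bouts with posture
    changes inside ``r_range`` (inclusive).  Returns NaN when fewer than
    two distinct posture changes fall in range.
    """
    r = np.asarray(bouts["posture_change_deg"], float)
    gamma = np.asarray(bouts["attack_angle_deg"], float)
    mask = (r >= r_range[0]) & (r <= r_range[1]) & np.isfinite(r) & np.isfinite(gamma)
    r, gamma = r[mask], gamma[mask]
    if np.unique(r).size < 2:
        return float("nan")
    return float(sps.theilslopes(gamma, r).slope)


@dataclass
class ClimbPostureSummary:
    """Posture statistics restricted to steep climbs."""

    climb_threshold: float
    n_climbs: int
    mean_abs_posture: float
    postures: np.ndarray  # sorted posture values among climbs
    cumulative_fraction: np.ndarray

    @property
    def empty(self) -> bool:
        return self.n_climbs == 0


def climb_posture_stats(bouts: pd.DataFrame, climb_threshold: float = 20.0) -> ClimbPostureSummary:
    """Mean |posture| and the posture ECDF during steep climbs.

    A climb is steep when its trajectory exceeds ``climb_threshold`` deg.
    """
    traj = np.asarray(bouts["trajectory_deg"], float)
    posture = np.asarray(bouts["posture_deg"], float)
    sel = posture[traj > climb_threshold]
    if sel.size == 0:
        return ClimbPostureSummary(climb_threshold, 0, float("nan"),
                                   np.array([]), np.array([]))
    ordered = np.sort(sel)
    cumfrac = np.arange(1, ordered.size + 1) / ordered.size
    return ClimbPostureSummary(climb_threshold, int(sel.size),
                               float(np.mean(np.abs(sel))), ordered, cumfrac)


def binned_means(x, y, n_bins: int) -> pd.DataFrame:
    """Means of equally sized bins: sort by x, split into contiguous groups.

    Groups have (near-)equal counts; when n is not divisible the remainder
    goes to the leftmost bins.  Returns per-bin mean x, mean y and count.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} points, got {x.size}")
    order = np.argsort(x, kind="stable")
    rows = [
        {"mean_x": float(np.mean(x[idx])), "mean_y": float(np.mean(y[idx])),
         "count": int(idx.size)}
        for idx in np.array_split(order, n_bins)
    ]
    return pd.DataFrame(rows)


# --- group tests -----------------------------------------------------------


def paired_t(a, b) -> dict:
    """Paired t-test on matched group means (e.g. sibling clutches)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.all(a - b == 0):  # identical groups: no evidence of a difference
        return {"test": "paired_t", "t": 0.0, "p": 1.0, "df": int(a.size - 1)}
    res = sps.ttest_rel(a, b)
    return {"test": "paired_t", "t": float(res.statistic), "p": float(res.pvalue),
            "df": int(res.df)}


def two_way_anova(table: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA (no interaction) on a clutch x age style summary table."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{value} ~ C({factor_a}) + C({factor_b})", data=table).fit()
    return sm.stats.anova_lm(model, typ=2)


def tukey_posthoc(table: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    """Tukey HSD (studentized range) across levels of ``group``."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(table[value].to_numpy(), table[group].to_numpy())
    return pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])


def group_tests(
    table: pd.DataFrame,
    value: str,
    factor_a: str = "age",
    factor_b: str = "clutch",
    alpha: float = 0.05,
    heteroscedastic: bool = False,
) -> dict:
    """Standard dispatch for group comparisons on a summary table.

    One row per clutch x age (or per larva).  Runs a two-way ANOVA with the
    given factors; if the main effect of ``factor_a`` is significant at
    ``alpha``, follows with Tukey HSD across its levels.  With
    ``heteroscedastic=True`` the factor-a effect is instead assessed with a
    Kruskal-Wallis test.
    """
    report: dict = {"value": value, "alpha": alpha}
    if heteroscedastic:
        groups = [g[value].to_numpy() for _, g in table.groupby(factor_a)]
        stat, p = sps.kruskal(*groups)
        report["kruskal"] = {"H": float(stat), "p": float(p)}
        report["significant"] = bool(p < alpha)
        return report
    anova = two_way_anova(table, value, factor_a, factor_b)
    report["anova"] = anova
    p_main = float(anova.loc[f"C({factor_a})", "PR(>F)"])
    report["p_main"] = p_main
    report["significant"] = bool(p_main < alpha)
    if report["significant"]:
        report["tukey"] = tukey_posthoc(table, value, factor_a)
    return report
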