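"""Well/condition summaries and the statistical tests of the workflow.

Per-object records are aggregated into per-well summaries (object counts,
areas, percentage of budding organoids vs spheroids) and per-condition
summaries normalized to a control condition (e.g. plain ENR medium).

The tests mirror how such organoid data are analyzed in practice:

* Mann–Whitney U for non-normal two-sample comparisons, with an exact
  p-value by full enumeration of the U distribution for small tie-free
  samples (the default in Prism-style analyses of n = 4–5 wells);
* one-way ANOVA with Bonferroni or Tukey post-hoc comparisons;
* one-tailed Fisher's exact test for 2x2 incidence tables.

The exact Mann–Whitney distribution is computed in-package by the standard
counting recursion, so printed two-sided p-values such as 2/252 = 0.0079
(complete separation at n = 5 per group) and 2/70 = 0.0286 (n = 4) come out
of the enumeration, not a normal approximation.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComputationError, InputError
from .segmentation import OrganoidRecord

__all__ = [
    "WellSummary",
    "ConditionSummary",
    "TestResult",
    "summarize_well",
    "normalize_to_control",
    "formation_efficiency",
    "mann_whitney",
    "one_way_anova",
    "fisher_exact_one_tailed",
]


@dataclass
class WellSummary:
    """Aggregate statistics for one imaged well/field."""

    field_id: str
    condition: str
    n_objects: int  # non-junk (when junk excluded)
    n_junk: int
    mean_area_px: Optional[float]
    median_area_px: Optional[float]
    mean_area_um2: Optional[float]
    median_area_um2: Optional[float]
    pct_budding: Optional[float]
    pct_spheroid: Optional[float]
    percentages_defined: bool
    junk_excluded: bool
    border_excluded: bool


@dataclass
class ConditionSummary:
    """Per-condition aggregate with control-normalized values."""

    condition: str
    well_values: list[float]
    mean: float
    normalized_well_values: list[float]
    normalized_mean: float


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    sidedness: str
    exact: bool
    posthoc: Optional[pd.DataFrame] = None
    details: dict = field(default_factory=dict)


def summarize_well(
    objects: Sequence[OrganoidRecord],
    pixel_size_um: Optional[float] = None,
    field_id: str = "",
    condition: str = "",
    exclude_junk: bool = True,
    exclude_border: bool = False,
) -> WellSummary:
    """Summarize one well's classified objects.

    Junk objects are excluded from area statistics and class percentages by
    default; percentages are over non-junk objects so that
    ``pct_budding + pct_spheroid == 100`` whenever every non-junk object is
    classified.  A well with zero non-junk objects yields a summary with
    ``n_objects = 0`` and undefined (``None``) percentages rather than an
    exception.
    """
    objs = list(objects)
    if exclude_border:
        objs = [o for o in objs if not o.on_border]
    junk = [o for o in objs if o.class_label == "junk"]
    kept = [o for o in objs if o.class_label != "junk"] if exclude_junk else objs

    areas = np.array([o.area_px for o in kept], dtype=float)
    n = len(kept)
    n_budding = sum(o.class_label == "budding" for o in kept)
    n_spheroid = sum(o.class_label == "spheroid" for o in kept)
    defined = n > 0
    mean_px = float(areas.mean()) if defined else None
    med_px = float(np.median(areas)) if defined else None
    factor = pixel_size_um**2 if pixel_size_um else None
    return WellSummary(
        field_id=field_id,
        condition=condition,
        n_objects=n,
        n_junk=len(junk),
        mean_area_px=mean_px,
        median_area_px=med_px,
        mean_area_um2=(mean_px * factor) if (defined and factor) else None,
        median_area_um2=(med_px * factor) if (defined and factor) else None,
        pct_budding=(100.0 * n_budding / n) if defined else None,
        pct_spheroid=(100.0 * n_spheroid / n) if defined else None,
        percentages_defined=defined,
        junk_excluded=exclude_junk,
        border_excluded=exclude_border,
    )


def normalize_to_control(
    summaries: Sequence[WellSummary],
    control: str,
    metric: str = "mean_area_px",
) -> list[ConditionSummary]:
    """Normalize per-well metric values to the control condition's mean.

    Every well's value of ``metric`` is divided by the mean of the control
    condition's wells, so the control's normalized mean is exactly 1.  This
    is the convention behind "average values normalized to the control
    medium" plots: normalize within an experiment, then pool.
    """
    by_cond: dict[str, list[float]] = {}
    order: list[str] = []
    for s in summaries:
        v = getattr(s, metric)
        if v is None:
            continue
        if s.condition not in by_cond:
            by_cond[s.condition] = []
            order.append(s.condition)
        by_cond[s.condition].append(float(v))
    if control not in by_cond or not by_cond[control]:
        raise InputError(f"control condition {control!r} has no wells with {metric}")
    control_mean = float(np.mean(by_cond[control]))
    if control_mean == 0:
        raise ComputationError("control condition mean is zero; cannot normalize")
    out = []
    for cond in order:
        vals = by_cond[cond]
        norm = [v / control_mean for v in vals]
        out.append(ConditionSummary(
            condition=cond,
            well_values=vals,
            mean=float(np.mean(vals)),
            normalized_well_values=norm,
            normalized_mean=float(np.mean(vals)) / control_mean,
        ))
    return out


def formation_efficiency(n_formed: int, n_seeded: int) -> float:
    """Percentage of seeded crypts that formed a viable organoid."""
    if n_seeded <= 0:
        raise InputError("n_seeded must be positive")
    if n_formed < 0:
        raise InputError("n_formed must be non-negative")
    return 100.0 * n_formed / n_seeded


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _u_count_distribution(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments giving each U value, for tie-free samples.

    ``counts[u]`` is the number of the C(n1+n2, n1) equally likely rank
    assignments to the first sample that produce U = u; equivalently the
    number of partitions of u into at most n1 parts, each at most n2 (the
    coefficients of the Gaussian binomial [n1+n2 choose n1]_x).  Computed by
    the exact polynomial product  prod_{i=1}^{n1} (1 - x^(n2+i)) / (1 - x^i).
    """
    max_u = n1 * n2
    counts = np.zeros(max_u + 1, dtype=np.int64)
    counts[0] = 1
    for i in range(1, n1 + 1):
        for u in range(i, max_u + 1):          # multiply by 1/(1 - x^i)
            counts[u] += counts[u - i]
        for u in range(max_u, n2 + i - 1, -1):  # multiply by (1 - x^(n2+i))
            counts[u] -= counts[u - n2 - i]
    return counts


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two-sided",
) -> TestResult:
    """Mann–Whitney U test.

    For tie-free samples with total n <= 20 the p-value is exact, from the
    full enumeration of the U count distribution; otherwise mid-ranks are
    used with the normal approximation (tie-corrected variance, 0.5
    continuity correction).  The two-sided p is twice the smaller one-sided
    tail, capped at 1 — the convention that reproduces the printed values
    for complete separation at n = 4 or 5 per group (0.0286 and 0.0079).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if sidedness not in ("two-sided", "greater", "less"):
        raise InputError(f"unknown sidedness: {sidedness}")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # mid-ranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # = #{(i,j): x_i > y_j} + half-ties
    has_ties = np.unique(combined).size < combined.size
    use_exact = (n1 + n2 <= 20) and not has_ties

    if use_exact:
        counts = _u_count_distribution(n1, n2)
        total = counts.sum()
        u_int = int(round(u1))
        p_greater = counts[u_int:].sum() / total  # P(U >= u1)
        p_less = counts[: u_int + 1].sum() / total
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p_greater = p_less = 1.0
        else:
            sd = math.sqrt(var)
            p_greater = sps.norm.sf((u1 - 0.5 - mu) / sd)
            p_less = sps.norm.cdf((u1 + 0.5 - mu) / sd)

    if sidedness == "greater":
        p = p_greater
    elif sidedness == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(
        test="mann-whitney",
        statistic=float(u1),
        p_value=float(p),
        sidedness=sidedness,
        exact=use_exact,
        details={"n_x": int(n1), "n_y": int(n2), "ties": bool(has_ties)},
    )


# ---------------------------------------------------------------------------
# ANOVA with post-hoc comparisons
# ---------------------------------------------------------------------------

def one_way_anova(
    groups: Sequence[Sequence[float]],
    posthoc: str = "bonferroni",
    group_names: Optional[Sequence[str]] = None,
) -> TestResult:
    """One-way ANOVA with Bonferroni or Tukey post-hoc pairwise comparisons.

    The Bonferroni post-hoc multiplies each raw pairwise two-sided t-test
    p-value by the number of comparisons (capped at 1).  Tukey's HSD uses
    the studentized-range distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InputError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise InputError(f"group {i} has n={g.size}; need n >= 2")
    if posthoc not in ("bonferroni", "tukey"):
        raise InputError(f"unknown post-hoc method: {posthoc}")
    names = list(group_names) if group_names else [f"group{i}" for i in range(len(arrays))]

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        f_stat, p = sps.f_oneway(*arrays)
    if not np.isfinite(f_stat):
        # zero within-group variance: either every value equal (no effect)
        # or constant groups with different means (complete separation)
        means = [g.mean() for g in arrays]
        if np.ptp(means) > 0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat, p = 0.0, 1.0

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    rows = []
    if posthoc == "bonferroni":
        m = len(pairs)
        for i, j in pairs:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                t, raw = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
            raw = 1.0 if not np.isfinite(raw) else float(raw)
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "statistic": float(t) if np.isfinite(t) else 0.0,
                "p_raw": raw,
                "p_adjusted": min(1.0, raw * m),
            })
    else:
        res = sps.tukey_hsd(*arrays)
        for i, j in pairs:
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "statistic": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adjusted": float(res.pvalue[i, j]),
            })
    table = pd.DataFrame(rows)
    return TestResult(
        test=f"one-way-anova+{posthoc}",
        statistic=float(f_stat),
        p_value=float(p),
        sidedness="two-sided",
        exact=False,
        posthoc=table,
        details={"n_groups": len(arrays)},
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (one-tailed)
# ---------------------------------------------------------------------------

def fisher_exact_one_tailed(table: Sequence[Sequence[int]]) -> TestResult:
    """One-tailed Fisher's exact test on a 2x2 count table.

    The p-value is the hypergeometric tail probability in the direction of
    the observed association: tables with a positive association (ad >= bc)
    are tested against "greater", negative ones against "less".  The tail is
    the sum of hypergeometric point masses at least as extreme as observed.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputError(f"need a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise InputError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise InputError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or a + c == 0 or c + d == 0 or b + d == 0:
        raise InputError("both margins must be positive")
    # X = top-left count, hypergeometric with population `total`,
    # `row1` draws, `col1` successes
    hg = sps.hypergeom(total, col1, row1)
    direction = "greater" if a * d >= b * c else "less"
    lo = max(0, row1 - (total - col1))
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = hg.pmf(ks)
    if direction == "greater":
        p = float(pmf[ks >= a].sum())
    else:
        p = float(pmf[ks <= a].sum())
    return TestResult(
        test="fisher-exact",
        statistic=float(a),
        p_value=min(1.0, p),
        sidedness=f"one-tailed ({direction})",
        exact=True,
        details={"direction": direction, "table": t.tolist()},
    )


def wells_to_dataframe(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    """One row per well, suitable for ``summaries.csv``."""
    rows = []
    for s in summaries:
        rows.append({
            "field_id": s.field_id,
            "condition": s.condition,
            "n_objects": s.n_objects,
            "n_junk": s.n_junk,
            "mean_area_px": s.mean_area_px,
            "median_area_px": s.median_area_px,
            "mean_area_um2": s.mean_area_um2,
            "median_area_um2": s.median_area_um2,
            "pct_budding": s.pct_budding,
            "pct_spheroid": s.pct_spheroid,
            "percentages_defined": s.percentages_defined,
            "junk_excluded": s.junk_excluded,
            "border_excluded": s.border_excluded,
        })
    return pd.DataFrame(rows)


def conditions_to_dataframe(conds: Sequence[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for c in conds:
        rows.append({
            "condition": c.condition,
            "n_wells": len(c.well_values),
            "mean": c.mean,
            "normalized_mean": c.normalized_mean,
        })
    return pd.DataFrame(rows)
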