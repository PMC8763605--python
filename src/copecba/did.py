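"""Difference-in-difference (DID) cost analysis.

For each report row the analysis takes per-dyad 12-month-minus-baseline
cost changes, averages them by arm, and reports the between-arm
difference of those mean changes:

    DID = (mean Delta_cope) - (mean Delta_usual),  Delta = cost_m12 - cost_bl

A dyad-period with no recorded cost in a category contributes $0 (the
cost-accounting convention, not missing data). Uncertainty comes from a
nonparametric percentile bootstrap over dyads within arm; hypothesis
tests are two-sided Wilcoxon rank-sum tests on the per-dyad changes with
a Bonferroni-corrected threshold over the test family (18 tests by
default: the 15 report rows with between-dyad variation plus the
health-care and formal/social subtotals and the grand total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .categories import (
    GRAND_TOTAL,
    REPORT_ROWS,
    SUBTOTALS,
    TESTED_COMPONENT_ROWS,
    TESTED_SUBTOTAL_ROWS,
)
from .errors import DataError, ParameterError


@dataclass(frozen=True)
class TestFamily:
    """A familywise multiple-testing correction (Bonferroni)."""

    __test__ = False  # not a pytest class, despite the name

    n_tests: int = 18
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ParameterError("n_tests must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests


def bonferroni_threshold(family: TestFamily) -> float:
    """Per-test significance threshold alpha / m, rounded to 5 decimals
    for reporting."""
    return round(family.threshold, 5)


# --- per-dyad changes --------------------------------------------------------


def dyad_deltas(cost_lines: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad month12-minus-baseline change for every report row.

    Returns a frame indexed by dyad with an ``arm`` column, one column per
    report row, subtotal columns, and a grand total. Absent
    category-periods count as zero cost.
    """
    arms = cost_lines.groupby("dyad_id")["arm"].nunique()
    bad = arms[arms > 1].index.tolist()
    if bad:
        raise DataError(f"dyad(s) appear in both arms: {bad}")

    pivot = cost_lines.pivot_table(
        index="dyad_id", columns=["period", "report_category"],
        values="cost_usd2019", aggfunc="sum", fill_value=0.0,
    )
    deltas = pd.DataFrame(index=pivot.index)
    for row in REPORT_ROWS:
        m12 = pivot[("month12", row)] if ("month12", row) in pivot else 0.0
        bl = pivot[("baseline", row)] if ("baseline", row) in pivot else 0.0
        deltas[row] = m12 - bl
    for name, members in SUBTOTALS.items():
        deltas[name] = deltas[list(members)].sum(axis=1)
    deltas[GRAND_TOTAL] = deltas[list(REPORT_ROWS)].sum(axis=1)
    arm_map = cost_lines.drop_duplicates("dyad_id").set_index("dyad_id")["arm"]
    deltas.insert(0, "arm", arm_map.reindex(deltas.index))
    return deltas


def _period_means(cost_lines: pd.DataFrame) -> pd.DataFrame:
    """Arm x period mean per-dyad cost for each report row (zeros for
    dyads without records in a category-period)."""
    n_by_arm = cost_lines.groupby("arm")["dyad_id"].nunique()
    sums = cost_lines.groupby(["arm", "period", "report_category"])[
        "cost_usd2019"
    ].sum()
    out = {}
    for arm in n_by_arm.index:
        for period in ("baseline", "month12"):
            for row in REPORT_ROWS:
                total = sums.get((arm, period, row), 0.0)
                out[(arm, period, row)] = total / n_by_arm[arm]
    return out


# --- inference ---------------------------------------------------------------


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Uses the exact null distribution when both samples have at most 12
    observations and carry no ties, and the normal approximation with tie
    and continuity corrections otherwise. Returns 1.0 when every value in
    both samples is identical (the test carries no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 12 and y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bootstrap_ci(
    cope_deltas,
    usual_deltas,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the DID of means.

    Dyads are resampled with replacement within arm; the interval is the
    (alpha/2, 1 - alpha/2) percentile range of the resampled DID.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    x = np.asarray(cope_deltas, dtype=float)
    y = np.asarray(usual_deltas, dtype=float)
    if x.size == 1 and y.size == 1:
        warnings.warn("single dyad per arm: degenerate bootstrap interval")
        point = float(x.mean() - y.mean())
        return point, point
    rng = np.random.default_rng(seed)
    bx = x[rng.integers(0, x.size, size=(B, x.size))].mean(axis=1)
    by = y[rng.integers(0, y.size, size=(B, y.size))].mean(axis=1)
    diff = bx - by
    lo, hi = np.quantile(diff, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# --- the report --------------------------------------------------------------

TABLE_COLUMNS = [
    "row", "mean_bl_cope", "mean_m12_cope", "delta_cope",
    "mean_bl_usual", "mean_m12_usual", "delta_usual",
    "did", "ci_low", "ci_high", "p_value", "significant",
]


def did_table(
    cost_lines: pd.DataFrame,
    family: TestFamily = TestFamily(),
    B: int = 10_000,
    seed: int = 7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full DID cost report: component rows, block subtotals, grand total.

    All statistics are computed on unrounded per-dyad data, so each
    subtotal's DID equals the sum of its components' DIDs exactly.
    Bootstrap resampling draws whole dyads, jointly across rows, keeping
    the rows' intervals consistent with one another.
    """
    deltas = dyad_deltas(cost_lines)
    arms_present = set(deltas["arm"])
    if not {"cope", "usual_care"} <= arms_present:
        raise DataError(f"both arms required, found {sorted(arms_present)}")
    means = _period_means(cost_lines)
    all_rows = list(REPORT_ROWS) + list(SUBTOTALS) + [GRAND_TOTAL]
    xmat = deltas.loc[deltas["arm"] == "cope", all_rows].to_numpy(float)
    ymat = deltas.loc[deltas["arm"] == "usual_care", all_rows].to_numpy(float)

    # joint dyad resampling, chunked over bootstrap replicates
    rng = np.random.default_rng(seed)
    n1, n2 = xmat.shape[0], ymat.shape[0]
    boot = np.empty((B, len(all_rows)))
    done = 0
    while done < B:
        chunk = min(1000, B - done)
        ix = rng.integers(0, n1, size=(chunk, n1))
        iy = rng.integers(0, n2, size=(chunk, n2))
        boot[done:done + chunk] = xmat[ix].mean(axis=1) - ymat[iy].mean(axis=1)
        done += chunk
    ci = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)

    tested = set(TESTED_COMPONENT_ROWS) | set(TESTED_SUBTOTAL_ROWS)
    records = []
    for j, row in enumerate(all_rows):
        x, y = xmat[:, j], ymat[:, j]
        did = float(x.mean() - y.mean())
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # deterministic rows: a rank test is not applicable unless the
            # two arms are identical constants
            p = 1.0 if x[0] == y[0] else float("nan")
        else:
            p = rank_sum_test(x, y)
        if row in REPORT_ROWS:
            mb_c = means[("cope", "baseline", row)]
            mm_c = means[("cope", "month12", row)]
            mb_u = means[("usual_care", "baseline", row)]
            mm_u = means[("usual_care", "month12", row)]
        else:
            members = SUBTOTALS.get(row, REPORT_ROWS)
            mb_c = sum(means[("cope", "baseline", r)] for r in members)
            mm_c = sum(means[("cope", "month12", r)] for r in members)
            mb_u = sum(means[("usual_care", "baseline", r)] for r in members)
            mm_u = sum(means[("usual_care", "month12", r)] for r in members)
        records.append({
            "row": row,
            "mean_bl_cope": mb_c, "mean_m12_cope": mm_c,
            "delta_cope": float(x.mean()),
            "mean_bl_usual": mb_u, "mean_m12_usual": mm_u,
            "delta_usual": float(y.mean()),
            "did": did, "ci_low": float(ci[0, j]), "ci_high": float(ci[1, j]),
            "p_value": p,
            "significant": bool(row in tested and np.isfinite(p)
                                and p < family.threshold),
        })
    return pd.DataFrame(records, columns=TABLE_COLUMNS)


def render_did_table(table: pd.DataFrame) -> str:
    """Plain-text rendering in the published row order."""
    lines = [f"{'row':<26}{'DID':>12}  {'95% CI':>24}  {'p':>8}"]
    for r in table.itertuples(index=False):
        p = "—" if not np.isfinite(r.p_value) else f"{r.p_value:.2f}"
        lines.append(
            f"{r.row:<26}{r.did:>12.2f}  "
            f"({r.ci_low:>10.2f}, {r.ci_high:>10.2f})  {p:>8}"
        )
    return "\n".join(lines)
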