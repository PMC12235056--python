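"""Nonparametric statistical battery for the outcome table.

The surgical-sequence effect on alignment is tested with unpaired
Mann-Whitney U tests (exact small-sample distribution), the construct
effect on stability with Friedman tests across the paired conditions,
followed by Fisher-LSD-style unadjusted pairwise rank comparisons gated on
a significant omnibus (no multiplicity adjustment -- that is the LSD
procedure by definition).  Alpha is .05 two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .joints import DOF_NAMES

__all__ = [
    "TestResult",
    "mann_whitney",
    "friedman",
    "fisher_lsd",
    "boxplot_stats",
    "report",
]

ALPHA = 0.05

#: Group size at or below which the exact Mann-Whitney null distribution is
#: enumerated instead of the tie-corrected normal approximation.
EXACT_N_MAX = 10


@dataclass
class TestResult:
    """One hypothesis test: statistic, p-value and context."""

    test: str
    statistic: float
    p_value: float
    n: tuple
    dof_label: str = ""
    pairwise: dict[str, "TestResult"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("non-finite test statistic")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def mann_whitney(
    group_a: np.ndarray,
    group_b: np.ndarray,
    dof_label: str = "",
    two_sided: bool = True,
) -> TestResult:
    """Unpaired Mann-Whitney U test.

    The exact permutation distribution is used when both groups have at
    most :data:`EXACT_N_MAX` observations and the data are tie-free (the
    study's n of 5 per group demands exact small-sample inference); larger
    samples or ties fall back to the normal approximation with tie
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = max(len(a), len(b)) <= EXACT_N_MAX
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided" if two_sided else "greater", method=method
    )
    return TestResult(
        test=f"mann_whitney_{method}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        dof_label=dof_label,
    )


#: Block count at or below which the tie-free Friedman p-value is taken from
#: the permutation null distribution instead of the chi-square approximation
#: (which is markedly conservative at the study's n of 5).
FRIEDMAN_EXACT_N_MAX = 12

_friedman_null_cache: dict[tuple[int, int], np.ndarray] = {}


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Friedman chi-square from within-block (mid-)ranks, with tie correction."""
    n, k = ranks.shape
    R = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float((R**2).sum()) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:  # every block completely tied: no information
        return 0.0
    return stat / correction


def _friedman_null(n: int, k: int, n_sim: int = 200_000) -> np.ndarray:
    """Simulated tie-free null distribution of the Friedman statistic.

    For tie-free data the null distribution depends on (n, k) only (ranks
    are independent uniform permutations per block), so one derandomised
    simulation per shape is cached and reused.
    """
    key = (n, k)
    if key not in _friedman_null_cache:
        rng = np.random.default_rng(abs(hash(("friedman", n, k))) % (2**31))
        ranks = np.argsort(rng.random((n_sim, n, k)), axis=2) + 1
        R = ranks.sum(axis=1)
        stats = 12.0 / (n * k * (k + 1)) * (R.astype(float) ** 2).sum(axis=1) - 3.0 * n * (k + 1)
        _friedman_null_cache[key] = np.sort(stats)
    return _friedman_null_cache[key]


def friedman(blocks: np.ndarray, dof_label: str = "") -> TestResult:
    """Friedman test on a complete shoulders x conditions block matrix.

    Ties are handled with mid-ranks and the usual tie correction.  For
    tie-free matrices with at most :data:`FRIEDMAN_EXACT_N_MAX` blocks the
    p-value comes from the permutation null distribution of the statistic
    (the chi-square reference is conservative at small n); otherwise the
    chi-square approximation with k-1 degrees of freedom is used.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be a 2-D (shoulders x conditions) matrix")
    n, k = blocks.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 conditions")
    if n < 2:
        raise ValueError("Friedman test needs at least 2 blocks")
    if not np.isfinite(blocks).all():
        raise ValueError("block matrix has missing cells")
    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    stat = _friedman_statistic(ranks)
    tie_free = all(len(np.unique(row)) == k for row in blocks)
    if tie_free and n <= FRIEDMAN_EXACT_N_MAX:
        null = _friedman_null(n, k)
        # upper tail with the add-one rule (p never exactly 0) and a small
        # slack against float round-off in the statistic
        p = (float((null >= stat - 1e-9).sum()) + 1.0) / (len(null) + 1.0)
        method = "friedman_permutation"
    else:
        p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
        method = "friedman_chisq"
    return TestResult(
        test=method, statistic=float(stat), p_value=max(min(p, 1.0), 0.0), n=(n, k),
        dof_label=dof_label,
    )


def fisher_lsd(
    blocks: np.ndarray,
    condition_labels: list[str],
    pairs: list[tuple[str, str]],
    alpha: float = ALPHA,
    dof_label: str = "",
) -> TestResult:
    """Fisher-LSD post hoc rank comparisons after a Friedman omnibus.

    Pairwise comparisons use the Conover rank-sum t statistic on the
    within-block ranks, unadjusted for multiplicity, and are only evaluated
    when the omnibus Friedman test is significant at ``alpha`` (the least
    significant difference gate); otherwise the pairwise map is empty and
    the omnibus result is returned as "not evaluated".
    """
    blocks = np.asarray(blocks, dtype=float)
    omnibus = friedman(blocks, dof_label=dof_label)
    n, k = blocks.shape
    for a, b in pairs:
        if a not in condition_labels or b not in condition_labels:
            raise ValueError(f"pair ({a}, {b}) references a condition absent from the blocks")
    result = TestResult(
        test="friedman_lsd",
        statistic=omnibus.statistic,
        p_value=omnibus.p_value,
        n=(n, k),
        dof_label=dof_label,
    )
    if omnibus.p_value > alpha:
        return result  # LSD gating: post hoc suppressed

    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    R = ranks.sum(axis=0)
    df = (n - 1) * (k - 1)
    a2 = float((ranks**2).sum())
    b2 = float((R**2).sum()) / n
    denom_core = 2.0 * n * (a2 - b2) / df
    for ca, cb in pairs:
        ia, ib = condition_labels.index(ca), condition_labels.index(cb)
        diff = R[ia] - R[ib]
        if denom_core <= 0:  # all blocks rank identically: no residual variance
            p = 1.0 if diff == 0 else 0.0
            tstat = 0.0 if diff == 0 else float(np.sign(diff)) * 1e12
        else:
            tstat = diff / np.sqrt(denom_core)
            p = float(2.0 * sps.t.sf(abs(tstat), df))
        result.pairwise[f"{ca}_vs_{cb}"] = TestResult(
            test="conover_lsd_t",
            statistic=float(tstat),
            p_value=min(1.0, p),
            n=(n, k),
            dof_label=dof_label,
        )
    return result


def boxplot_stats(values: np.ndarray, whiskers: str = "minmax") -> dict[str, object]:
    """Quartile box statistics for the figure-style box plots.

    ``whiskers='minmax'`` extends whiskers to the extreme values (figure
    caption convention) and marks no outliers; ``whiskers='tukey'`` uses the
    1.5-IQR fences and reports points beyond them as outliers -- the two
    conventions the emulated figures mix, kept behind a flag.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty values")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    if whiskers == "minmax":
        lo, hi = float(values.min()), float(values.max())
        outliers: list[float] = []
    elif whiskers == "tukey":
        fence_lo, fence_hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        inside = values[(values >= fence_lo) & (values <= fence_hi)]
        lo, hi = float(inside.min()), float(inside.max())
        outliers = [float(v) for v in values[(values < fence_lo) | (values > fence_hi)]]
    else:
        raise ValueError("whiskers must be 'minmax' or 'tukey'")
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": lo,
        "whisker_high": hi,
        "outliers": outliers,
        "n": int(len(values)),
    }


def report(
    outcome_table: pd.DataFrame,
    whiskers: str = "minmax",
    alpha: float = ALPHA,
) -> dict[str, pd.DataFrame]:
    """Full statistical report on an outcome table.

    Returns three data frames: ``alignment`` (per-DOF group comparison with
    Mann-Whitney p), ``stability`` (per-DOF Friedman + LSD pairwise p for
    the lesion vs each construct) and ``boxplot`` (per group/condition/DOF
    quartile statistics).  Degrees of freedom with no finite data are
    omitted with a warning.
    """
    import warnings

    if outcome_table.empty:
        raise ValueError("empty outcome table")
    recon = ["cc_only", "construct1", "construct2", "construct3", "construct4"]
    align_rows, stab_rows, box_rows = [], [], []
    for d in DOF_NAMES:
        acol, scol = f"alignment_{d}", f"stability_{d}"
        if acol in outcome_table and outcome_table[acol].notna().any():
            sub = outcome_table[outcome_table["condition"].isin(recon)]
            a = sub.loc[sub["group"] == "AC_first", acol].to_numpy()
            b = sub.loc[sub["group"] == "CC_first", acol].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                mw = mann_whitney(a, b, dof_label=d)
                align_rows.append(
                    {
                        "dof": d,
                        "ac_first_median": float(np.median(a)),
                        "cc_first_median": float(np.median(b)),
                        "median_diff": float(np.median(b) - np.median(a)),
                        "U": mw.statistic,
                        "p_value": mw.p_value,
                    }
                )
            for group in ("AC_first", "CC_first"):
                vals = sub.loc[sub["group"] == group, acol].to_numpy()
                if len(vals):
                    box_rows.append(
                        {"dof": d, "panel": "alignment", "cell": group}
                        | {k: v for k, v in boxplot_stats(vals, whiskers).items() if k != "outliers"}
                    )
        elif acol in outcome_table:
            warnings.warn(f"alignment DOF '{d}' has no data; omitted", stacklevel=2)

        if scol in outcome_table and outcome_table[scol].notna().any():
            pivot = outcome_table.pivot_table(
                index="shoulder", columns="condition", values=scol
            )
            conds = [c for c in ("rockwood5", *recon) if c in pivot.columns]
            if len(conds) >= 3 and pivot[conds].notna().all().all():
                pairs = [("rockwood5", c) for c in conds if c.startswith("construct")]
                res = fisher_lsd(pivot[conds].to_numpy(), conds, pairs, alpha, dof_label=d)
                row = {"dof": d, "friedman_chi2": res.statistic, "friedman_p": res.p_value}
                for name, pr in res.pairwise.items():
                    row[f"p_{name}"] = pr.p_value
                stab_rows.append(row)
            for cond in pivot.columns:
                vals = pivot[cond].dropna().to_numpy()
                if len(vals):
                    box_rows.append(
                        {"dof": d, "panel": "stability", "cell": cond}
                        | {k: v for k, v in boxplot_stats(vals, whiskers).items() if k != "outliers"}
                    )
    return {
        "alignment": pd.DataFrame(align_rows),
        "stability": pd.DataFrame(stab_rows),
        "boxplot": pd.DataFrame(box_rows),
    }
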