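"""Statistical comparison of score distributions across variant groups.

Four groups are compared pairwise: ClinVar pathogenic/likely-pathogenic,
ClinVar benign/likely-benign, population (gnomAD-style) variants, and the
full in-silico set of possible missense variants.  Group membership is
non-exclusive, so one variant may contribute a value to several groups.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

GROUP_NAMES = ("ClinVar_pathogenic", "ClinVar_benign", "gnomAD", "InSilico")

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class GroupedScores:
    """Values of one score partitioned (non-exclusively) into the four groups."""

    score_name: str
    groups: dict[str, list[float]] = field(
        default_factory=lambda: {g: [] for g in GROUP_NAMES})

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUP_NAMES)
        if unknown:
            raise ValueError(f"unknown group name(s): {sorted(unknown)}")
        for g in GROUP_NAMES:
            self.groups.setdefault(g, [])

    def sizes(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.groups.items()}


@dataclass
class PairwiseTest:
    """Welch t-test result for one group pair, with per-group quartiles."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t_stat: float
    df: float
    p_value: float
    stars: str
    quartiles_a: tuple[float, float, float]
    quartiles_b: tuple[float, float, float]


def significance_stars(p: float) -> str:
    """Asterisk annotation: '*' p<0.05, '**' p<0.01, '***' p<0.001 (strict)."""
    if math.isnan(p):
        return ""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def compare_groups(
    gs: GroupedScores,
    min_n: int = 2,
    student: bool = False,
    bonferroni: bool = False,
) -> list[PairwiseTest]:
    """All six pairwise t-tests between the four variant groups.

    Welch's unequal-variance t-test by default (``student=True`` pools
    variances).  Raw p-values are starred; ``bonferroni=True`` multiplies
    each p by the number of performed tests before starring.  Pairs with a
    group below ``min_n`` values are skipped with a warning.
    """
    arrays = {
        g: np.asarray(v, dtype=float) for g, v in gs.groups.items()
    }
    pairs = [
        (a, b) for a, b in itertools.combinations(GROUP_NAMES, 2)
        if len(arrays[a]) >= min_n and len(arrays[b]) >= min_n
    ]
    skipped = [
        (a, b) for a, b in itertools.combinations(GROUP_NAMES, 2)
        if (a, b) not in pairs
    ]
    for a, b in skipped:
        logger.warning(
            "skipping %s vs %s for %s: group too small (n=%d, n=%d)",
            a, b, gs.score_name, len(arrays[a]), len(arrays[b]))
    if not pairs:
        logger.warning("no testable group pair for %s", gs.score_name)
        return []

    results: list[PairwiseTest] = []
    for a, b in pairs:
        va, vb = arrays[a], arrays[b]
        res = stats.ttest_ind(va, vb, equal_var=student)
        # scipy returns nan when both samples are constant and equal; the
        # samples are then literally indistinguishable.
        t = float(res.statistic)
        p = float(res.pvalue)
        if math.isnan(t) and np.array_equal(va, vb):
            t, p = 0.0, 1.0
        df = float(getattr(res, "df", np.nan))
        p_starred = min(p * len(pairs), 1.0) if bonferroni else p
        results.append(PairwiseTest(
            group_a=a, group_b=b, n_a=len(va), n_b=len(vb),
            t_stat=t, df=df, p_value=p_starred,
            stars=significance_stars(p_starred),
            quartiles_a=_quartiles(va), quartiles_b=_quartiles(vb),
        ))
    return results


def tests_to_rows(score_name: str, tests: list[PairwiseTest]) -> list[dict]:
    """Flatten test results for the stats export table."""
    return [
        {
            "score": score_name, "group_a": t.group_a, "group_b": t.group_b,
            "n_a": t.n_a, "n_b": t.n_b, "t": t.t_stat, "df": t.df,
            "p": t.p_value, "stars": t.stars,
        }
        for t in tests
    ]
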