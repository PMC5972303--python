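"""Risk-score grouping for grouped calibration statistics.

Subjects are ranked by their fitted risk score ``beta_hat' z_i`` and split
into ``D`` near-equal groups (group 1 = lowest risk). The global GB test
omits group ``D`` as the reference; the extreme-risk test omits the median
group so the retained groups form balanced lower and upper tails. An
optional "no less than 5 expected events" collapsing rule merges sparse
groups, with expected events per group measured by sums of Cox–Snell
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cox import CoxFit, ResidualSet
from .data import SurvivalDataset

__all__ = [
    "RiskGrouping",
    "risk_scores",
    "assign_groups",
    "indicator_design",
    "attach_expected_events",
    "collapse_groups",
]


@dataclass
class RiskGrouping:
    """Partition of subjects into D ordered risk-score groups.

    ``labels`` are 1..D with group 1 the lowest risk; ``boundaries`` are
    the D-1 upper-edge scores of groups 1..D-1. ``reference_group`` is the
    group omitted from the grouped-martingale vector ``H`` (group D for
    the global test, the median group for the extreme-risk test).
    """

    D: int
    labels: np.ndarray
    boundaries: np.ndarray
    reference_group: int | None = None
    sizes: np.ndarray = None  # type: ignore[assignment]
    expected_events: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sizes is None:
            self.sizes = np.bincount(self.labels, minlength=self.D + 1)[1:]
        if self.reference_group is not None and not (1 <= self.reference_group <= self.D):
            raise ValueError("reference_group out of range")

    @property
    def retained_groups(self) -> np.ndarray:
        if self.reference_group is None:
            raise ValueError("reference_group not set")
        return np.array([d for d in range(1, self.D + 1) if d != self.reference_group])

    @property
    def median_group(self) -> int:
        return (self.D + 1) // 2

    def with_reference(self, reference_group: int) -> "RiskGrouping":
        return replace(self, reference_group=reference_group)


def risk_scores(fit: CoxFit, data: SurvivalDataset) -> np.ndarray:
    """Linear predictor ``beta_hat' z_i`` for each subject (no baseline term)."""
    return fit.linear_predictor(data)


def assign_groups(scores: np.ndarray, D: int, reference_group: int | None = None) -> RiskGrouping:
    """Split subjects into D contiguous risk-score groups of near-equal size.

    Subjects are stable-sorted by (score, original index) and cut into
    blocks of size ``ceil(n/D)`` or ``floor(n/D)``, the lower-risk groups
    taking the larger size first. The stable tie policy makes the grouping
    a deterministic function of (scores, input order, D) even when scores
    are heavily tied, as with genotype-based risk scores.
    """
    scores = np.asarray(scores, float)
    n = len(scores)
    if D < 3:
        raise ValueError("need at least D = 3 risk groups")
    if D > n:
        raise ValueError(f"D = {D} exceeds the number of subjects n = {n}")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, D)
    sizes = np.full(D, base)
    sizes[:rem] += 1
    labels = np.empty(n, dtype=np.int64)
    labels[order] = np.repeat(np.arange(1, D + 1), sizes)
    edges = np.cumsum(sizes)[:-1]
    boundaries = scores[order][edges - 1]
    return RiskGrouping(D=D, labels=labels, boundaries=boundaries, reference_group=reference_group, sizes=sizes)


def indicator_design(grouping: RiskGrouping) -> np.ndarray:
    """``n x (D-1)`` indicator matrix; reference-group rows are all-zero.

    Column order follows increasing group id over the retained groups.
    """
    retained = grouping.retained_groups
    return (grouping.labels[:, None] == retained[None, :]).astype(float)


def attach_expected_events(grouping: RiskGrouping, resid: ResidualSet) -> RiskGrouping:
    """Populate per-group expected events as sums of Cox–Snell residuals."""
    exp_ev = np.bincount(grouping.labels, weights=resid.cox_snell, minlength=grouping.D + 1)[1:]
    return replace(grouping, expected_events=exp_ev)


def collapse_groups(grouping: RiskGrouping, min_expected: float = 5.0) -> RiskGrouping:
    """Merge sparse groups until every group has >= ``min_expected`` expected events.

    Deterministic policy: repeatedly take the group with the smallest
    expected events (ties: smaller id) among deficient groups and merge it
    toward the distribution's center — the lowest-risk group merges
    upward, the highest-risk downward, and an interior group merges with
    the neighbor holding fewer expected events (ties resolved toward the
    center). Merging toward the center preserves the identity of the
    extreme groups for as long as possible, which is where the
    extreme-risk statistic draws its signal. Raises if fewer than 3 groups
    would remain. The reference group is reset to ``None``; callers pick
    the reference appropriate to their test on the collapsed grouping.
    """
    if grouping.expected_events is None:
        raise ValueError("expected_events not populated; call attach_expected_events first")
    exp_ev = list(map(float, grouping.expected_events))
    sizes = list(map(int, grouping.sizes))
    bounds = list(map(float, grouping.boundaries))
    members: list[list[int]] = [[d] for d in range(1, grouping.D + 1)]
    while True:
        D = len(exp_ev)
        deficient = [i for i in range(D) if exp_ev[i] < min_expected]
        if not deficient:
            break
        if D <= 3:
            raise ValueError(
                "collapsing would leave fewer than 3 risk groups; grouped test not applicable"
            )
        i = min(deficient, key=lambda k: (exp_ev[k], k))
        center = (D - 1) / 2.0
        if i == 0:
            j = 1
        elif i == D - 1:
            j = D - 2
        else:
            left, right = exp_ev[i - 1], exp_ev[i + 1]
            if left < right:
                j = i - 1
            elif right < left:
                j = i + 1
            else:  # tie: merge toward the center
                j = i + 1 if i < center else i - 1
        lo, hi = min(i, j), max(i, j)
        exp_ev[lo] += exp_ev[hi]
        sizes[lo] += sizes[hi]
        members[lo] += members[hi]
        del exp_ev[hi], sizes[hi], members[hi], bounds[lo]
    new_D = len(exp_ev)
    relabel = np.empty(grouping.D + 1, dtype=np.int64)
    for new_id, olds in enumerate(members, start=1):
        for old in olds:
            relabel[old] = new_id
    return RiskGrouping(
        D=new_D,
        labels=relabel[grouping.labels],
        boundaries=np.asarray(bounds),
        reference_group=None,
        sizes=np.asarray(sizes),
        expected_events=np.asarray(exp_ev),
    )
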