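"""Grouped-martingale calibration tests for fitted Cox models.

Two tests are provided, both built on the vector ``H`` of risk-group sums
of martingale residuals and its estimated covariance ``Sigma_hat``:

* the global (Gronnesby–Borgan style) score test ``T = H' Sigma^-1 H``
  over D risk-score groups with the last group omitted, compared to a
  chi-square with D-1 degrees of freedom; and
* the extreme-risk (ER) test, which omits the *median* group, scales the
  retained components to unit variance, and takes the maximum over nested
  symmetric tail sets ``R_c`` (the c lowest plus c highest groups) of the
  average squared scaled component, ``T_max = max_c T~_c / n_c``. The
  null distribution of ``T_max`` is intractable, so significance is
  estimated by Monte Carlo: draw replicate ``H~`` vectors from a mean-zero
  multivariate Gaussian with the estimated correlation matrix and recompute
  the max statistic.

The ER test targets miscalibration concentrated in the tails of the risk
distribution — e.g., from omitted gene–environment interactions or
additive (rather than multiplicative) covariate effects — where a global
test dilutes the signal across all groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import CoxFit, ResidualSet, _full_group_information, _sigma_from_blocks, residuals
from .data import SurvivalDataset
from .grouping import RiskGrouping, assign_groups, attach_expected_events, collapse_groups, risk_scores

__all__ = [
    "GroupedMartingales",
    "GBResult",
    "ERResult",
    "grouped_sums",
    "scale_h",
    "extreme_sets",
    "er_statistic",
    "er_pvalue",
    "er_test",
    "gb_test",
    "joint_tests",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GroupedMartingales:
    """Grouped martingale sums H with covariance, and their scaled form."""

    H: np.ndarray
    sigma: np.ndarray
    group_ids: np.ndarray
    reference_group: int
    H_tilde: np.ndarray | None = None
    sigma_tilde: np.ndarray | None = None


@dataclass
class GBResult:
    """Global grouped-calibration score test result."""

    statistic: float
    df: int
    p_value: float
    per_group_H: np.ndarray
    sigma: np.ndarray
    grouping: RiskGrouping
    method: str = "chisq"
    n_null_replicates: int | None = None


@dataclass
class ERResult:
    """Extreme-risk calibration test result with all intermediates."""

    t_max: float
    p_value: float
    per_set_stats: list[tuple[int, int, float]]  # (c, n_c, T~_c / n_c)
    n_null_replicates: int
    seed: object
    grouping: RiskGrouping
    gm: GroupedMartingales
    pvalue_estimator: str = "(1 + #{t_s >= t_max}) / (R + 1)"


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def grouped_sums(resid: ResidualSet, grouping: RiskGrouping) -> np.ndarray:
    """Sum martingale residuals within each retained (non-reference) group.

    The sums over *all* D groups total zero (the omitted group's sum is
    minus the sum of the retained ones), which is why one group must be
    dropped for identifiability.
    """
    full = np.bincount(grouping.labels, weights=resid.martingale, minlength=grouping.D + 1)[1:]
    return full[grouping.retained_groups - 1]


def scale_h(gm: GroupedMartingales) -> GroupedMartingales:
    """Scale H so each component has unit variance; Sigma becomes a correlation.

    ``H~_d = H_d / sqrt(Sigma_dd)`` and ``Sigma~ = S^-1/2 Sigma S^-1/2``
    with ``S = diag(Sigma)``.
    """
    dd = np.diag(gm.sigma)
    if np.any(dd <= 0):
        raise ValueError("degenerate risk group: nonpositive variance in Sigma_hat")
    s = 1.0 / np.sqrt(dd)
    sigma_tilde = gm.sigma * np.outer(s, s)
    np.fill_diagonal(sigma_tilde, 1.0)
    return GroupedMartingales(
        H=gm.H,
        sigma=gm.sigma,
        group_ids=gm.group_ids,
        reference_group=gm.reference_group,
        H_tilde=gm.H * s,
        sigma_tilde=sigma_tilde,
    )


def extreme_sets(D: int) -> list[np.ndarray]:
    """Nested symmetric extreme-risk group sets for odd D.

    With the median group excluded, set ``c`` holds the ``c`` lowest and
    ``c`` highest risk groups: for D = 11 the sets are {1,11}, {1,2,10,11},
    ..., up to all 10 non-median groups. Even D is rejected: the tails
    cannot be balanced around a median group.
    """
    if D < 3:
        raise ValueError("need D >= 3")
    if D % 2 == 0:
        raise ValueError("extreme-risk sets require an odd number of groups D")
    return _extreme_sets_general(D, (D + 1) // 2)


def _extreme_sets_general(D: int, reference: int) -> list[np.ndarray]:
    n_low, n_high = reference - 1, D - reference
    return [
        np.concatenate([np.arange(1, c + 1), np.arange(D - c + 1, D + 1)])
        for c in range(1, min(n_low, n_high) + 1)
    ]


def _set_masks(sets: list[np.ndarray], group_ids: np.ndarray) -> np.ndarray:
    """(n_sets, m) boolean masks mapping group ids to positions in H~."""
    pos = {g: i for i, g in enumerate(group_ids)}
    masks = np.zeros((len(sets), len(group_ids)), dtype=bool)
    for k, s in enumerate(sets):
        masks[k, [pos[g] for g in s]] = True
    return masks


def er_statistic(gm_scaled: GroupedMartingales, sets: list[np.ndarray]) -> tuple[float, list[tuple[int, int, float]]]:
    """Max over extreme sets of the average squared scaled martingale sum."""
    if gm_scaled.H_tilde is None:
        raise ValueError("call scale_h first")
    masks = _set_masks(sets, gm_scaled.group_ids)
    sq = gm_scaled.H_tilde**2
    per_set = []
    for c, mask in enumerate(masks, start=1):
        n_c = int(mask.sum())
        per_set.append((c, n_c, float(sq[mask].sum() / n_c)))
    t_max = max(v for _, _, v in per_set)
    return t_max, per_set


def _mvn_sqrt(sigma_tilde: np.ndarray) -> np.ndarray:
    """Square root of a correlation matrix via spectral decomposition.

    Negative eigenvalues (Sigma~ can be numerically semi-definite because
    the full set of group sums is linearly constrained) are clipped at 0.
    """
    sigma_tilde = np.asarray(sigma_tilde, float)
    if sigma_tilde.ndim != 2 or sigma_tilde.shape[0] != sigma_tilde.shape[1]:
        raise ValueError("sigma_tilde must be square")
    if not np.allclose(sigma_tilde, sigma_tilde.T, atol=1e-8):
        raise ValueError("sigma_tilde must be symmetric")
    vals, vecs = np.linalg.eigh(sigma_tilde)
    if vals.min() < -1e-6 * max(1.0, vals.max()):
        raise ValueError("sigma_tilde is not positive semidefinite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def er_pvalue(
    t_max: float,
    sigma_tilde: np.ndarray,
    n_replicates: int = 1000,
    seed=None,
    sets: list[np.ndarray] | None = None,
    group_ids: np.ndarray | None = None,
) -> float:
    """Monte Carlo empirical p-value for the extreme-risk max statistic.

    Draws ``n_replicates`` mean-zero Gaussian vectors with covariance
    ``sigma_tilde``, recomputes the max statistic for each, and returns
    ``(1 + #{t_s >= t_max}) / (n_replicates + 1)``. The add-one estimator
    keeps p strictly positive; ties with the observed value are counted as
    exceedances (conservative; they have probability zero under the
    continuous null draws).
    """
    if n_replicates < 100:
        raise ValueError("use at least 100 null replicates")
    m = np.asarray(sigma_tilde).shape[0]
    if group_ids is None:
        # consecutive ids with a gap where the median (reference) group was
        D = m + 1
        ref = (D + 1) // 2
        group_ids = np.array([g for g in range(1, D + 1) if g != ref])
    if sets is None:
        sets = _extreme_sets_general(m + 1, (m + 2) // 2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = _mvn_sqrt(sigma_tilde)
    draws = rng.standard_normal((n_replicates, m)) @ A.T
    masks = _set_masks(sets, group_ids)
    n_c = masks.sum(axis=1).astype(float)
    stats_sets = (draws**2) @ masks.T.astype(float) / n_c
    t_s = stats_sets.max(axis=1)
    return float((1 + np.count_nonzero(t_s >= t_max)) / (n_replicates + 1))


# ---------------------------------------------------------------------------
# shared machinery: one extended-information evaluation serves both tests
# ---------------------------------------------------------------------------


class _GroupedMachinery:
    """Grouping, martingale sums and information blocks for one fit.

    Computes the indicator-model score/information once over all D groups;
    the reference-omitted ``(H, Sigma_hat)`` of either test is then an
    exact sub-block Schur complement.
    """

    def __init__(
        self,
        fit: CoxFit,
        data: SurvivalDataset,
        D: int,
        collapse: bool = False,
        min_expected: float = 5.0,
    ):
        scores = risk_scores(fit, data)
        grouping = assign_groups(scores, D)
        self.resid = residuals(fit, data)
        grouping = attach_expected_events(grouping, self.resid)
        self.collapsed = False
        if collapse:
            pre_D = grouping.D
            grouping = collapse_groups(grouping, min_expected=min_expected)
            self.collapsed = grouping.D < pre_D
        self.grouping = grouping
        self.D = grouping.D
        (
            self.score_full,
            self.J_bb,
            self.J_bg_full,
            self.J_gg_full,
        ) = _full_group_information(fit, data, grouping.labels, grouping.D)

    def martingales(self, reference: int) -> GroupedMartingales:
        retained = np.array([d - 1 for d in range(1, self.D + 1) if d != reference])
        H, sigma = _sigma_from_blocks(
            self.J_bb, self.J_bg_full, self.J_gg_full, self.score_full, retained
        )
        return GroupedMartingales(
            H=H, sigma=sigma, group_ids=retained + 1, reference_group=reference
        )


def _gb_from_machinery(mach: _GroupedMachinery, p_value_method, n_replicates, seed) -> GBResult:
    gm = mach.martingales(reference=mach.D)
    df = mach.D - 1
    try:
        T = float(gm.H @ np.linalg.solve(gm.sigma, gm.H))
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular Sigma_hat in global test; using pseudo-inverse", RuntimeWarning
        )
        T = float(gm.H @ np.linalg.pinv(gm.sigma) @ gm.H)
    T = max(T, 0.0)
    if p_value_method == "chisq":
        p = float(stats.chi2.sf(T, df))
        n_rep = None
    elif p_value_method == "simulation":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        A = _mvn_sqrt(np.asarray(gm.sigma))
        draws = rng.standard_normal((n_replicates, df)) @ A.T
        t_s = np.einsum("ri,ri->r", draws @ np.linalg.pinv(gm.sigma), draws)
        p = float((1 + np.count_nonzero(t_s >= T)) / (n_replicates + 1))
        n_rep = n_replicates
    else:
        raise ValueError("p_value_method must be 'chisq' or 'simulation'")
    grouping = mach.grouping.with_reference(mach.D)
    return GBResult(
        statistic=T,
        df=df,
        p_value=p,
        per_group_H=gm.H,
        sigma=gm.sigma,
        grouping=grouping,
        method=p_value_method,
        n_null_replicates=n_rep,
    )


def _er_from_machinery(mach: _GroupedMachinery, n_replicates, seed) -> ERResult:
    ref = (mach.D + 1) // 2
    gm = scale_h(mach.martingales(reference=ref))
    sets = _extreme_sets_general(mach.D, ref)
    if not sets:
        raise ValueError("no extreme sets available (too few groups)")
    t_max, per_set = er_statistic(gm, sets)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = er_pvalue(
        t_max,
        gm.sigma_tilde,
        n_replicates=n_replicates,
        seed=rng,
        sets=sets,
        group_ids=gm.group_ids,
    )
    grouping = mach.grouping.with_reference(ref)
    return ERResult(
        t_max=t_max,
        p_value=p,
        per_set_stats=per_set,
        n_null_replicates=n_replicates,
        seed=seed,
        grouping=grouping,
        gm=gm,
    )


# ---------------------------------------------------------------------------
# public tests
# ---------------------------------------------------------------------------


def gb_test(
    fit: CoxFit,
    data: SurvivalDataset,
    D: int = 11,
    collapse: bool = False,
    min_expected: float = 5.0,
    p_value_method: str = "chisq",
    n_replicates: int = 1000,
    seed=None,
) -> GBResult:
    """Global grouped-calibration score test.

    Groups subjects into D risk-score groups, omits group D, and compares
    ``T = H' Sigma_hat^-1 H`` to a chi-square with D-1 degrees of freedom
    (default), or to a Gaussian simulation null with ``p_value_method=
    "simulation"``. With ``collapse=True`` sparse groups (< ``min_expected``
    expected events) are merged first and the degrees of freedom adjust.
    """
    mach = _GroupedMachinery(fit, data, D, collapse=collapse, min_expected=min_expected)
    return _gb_from_machinery(mach, p_value_method, n_replicates, seed)


def er_test(
    fit: CoxFit,
    data: SurvivalDataset,
    D: int = 11,
    n_replicates: int = 1000,
    seed=None,
    collapse: bool = False,
    min_expected: float = 5.0,
) -> ERResult:
    """Extreme-risk calibration test with Monte Carlo empirical p-value.

    Pipeline: risk scores -> D groups (median group as reference) ->
    martingale residual group sums -> extended-model information ->
    unit-variance scaling -> max over nested symmetric tail sets ->
    Gaussian simulation p-value with ``n_replicates`` draws. Requires an
    odd initial D so the tails are balanced around the median group. The
    result is bit-reproducible given (data, D, n_replicates, seed).
    """
    if D % 2 == 0:
        raise ValueError("the extreme-risk test requires an odd number of groups D")
    mach = _GroupedMachinery(fit, data, D, collapse=collapse, min_expected=min_expected)
    return _er_from_machinery(mach, n_replicates, seed)


def joint_tests(
    fit: CoxFit,
    data: SurvivalDataset,
    D: int = 11,
    n_replicates: int = 1000,
    seed=None,
    collapse: bool = False,
    min_expected: float = 5.0,
    gb_p_value_method: str = "chisq",
) -> tuple[GBResult, ERResult]:
    """Run the global and extreme-risk tests sharing one information pass.

    Both tests use the same risk grouping and the same extended-model
    observed information; only the omitted reference group differs. Used
    by the simulation harness where the duplicated information evaluation
    would dominate the cost.
    """
    if D % 2 == 0:
        raise ValueError("the extreme-risk test requires an odd number of groups D")
    mach = _GroupedMachinery(fit, data, D, collapse=collapse, min_expected=min_expected)
    gb = _gb_from_machinery(mach, gb_p_value_method, n_replicates, seed)
    er = _er_from_machinery(mach, n_replicates, seed)
    return gb, er
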