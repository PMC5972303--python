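"""Simulation studies: type-I error, power, and calibration diagnostics.

Reproduces the evaluation design for the grouped calibration tests:
replicate cohorts are simulated under a generating model, a working Cox
model is fitted, and both the global and extreme-risk tests are run at
D = 11 risk groups; rejection rates at the 0.05 level are aggregated with
binomial Monte Carlo standard errors. Observed-vs-expected calibration
curves and log-log survival curves by allele count provide the matching
visual diagnostics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import joint_tests
from .cox import ConvergenceError, SingularityError, fit_cox, residuals
from .data import SurvivalDataset
from .grouping import assign_groups, attach_expected_events, indicator_design, risk_scores
from .simulate import SimulationConfig, calibrate_censoring, simulate_cohort

__all__ = [
    "ExperimentResult",
    "CalibrationCurve",
    "run_type1_study",
    "run_power_study",
    "calibration_curve",
    "loglog_survival_curve",
]


@dataclass
class ExperimentResult:
    """Aggregated rejection rates for one simulation scenario."""

    config: SimulationConfig
    working_covariates: list[str]
    n_replicates: int
    level: float
    D: int
    er_replicates: int
    seed: int
    rejections: dict[str, int]
    n_completed: int
    n_failures: int
    collapse_count: int
    gb_statistics: np.ndarray
    gb_pvalues: np.ndarray
    er_pvalues: np.ndarray

    @property
    def rates(self) -> dict[str, float]:
        return {k: v / self.n_completed for k, v in self.rejections.items()}

    @property
    def mc_se(self) -> dict[str, float]:
        out = {}
        for k, r in self.rates.items():
            out[k] = float(np.sqrt(r * (1 - r) / self.n_completed))
        return out

    @property
    def collapse_frequency(self) -> float:
        return self.collapse_count / self.n_completed

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for test in ("gb", "er"):
            rows.append(
                {
                    "model": self.config.model,
                    "n": self.config.n,
                    "p": self.config.p,
                    "event_rate": self.config.target_event_rate,
                    "ltfu_rate": self.config.ltfu_rate,
                    "alpha": self.config.alpha,
                    "test": test,
                    "rejection_rate": self.rates[test],
                    "mc_se": self.mc_se[test],
                    "n_replicates": self.n_completed,
                    "n_failures": self.n_failures,
                    "collapse_frequency": self.collapse_frequency,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _run_scenario(
    config: SimulationConfig,
    working_covariates: Sequence[str] | None,
    n_replicates: int,
    seed: int,
    D: int,
    er_replicates: int,
    level: float,
    collapse: bool,
    ties: str,
) -> ExperimentResult:
    cfg = config.resolved()
    tau_c = calibrate_censoring(cfg) if cfg.ltfu_rate > 0 else None
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    rej = {"gb": 0, "er": 0}
    gb_T, gb_p, er_p = [], [], []
    n_fail = 0
    n_collapsed = 0
    for child in children:
        data_ss, test_ss = child.spawn(2)
        data = simulate_cohort(cfg, rng=data_ss, tau_c=tau_c)
        try:
            fit = fit_cox(data, ties=ties, covariates=working_covariates)
            gb, er = joint_tests(
                fit,
                data,
                D=D,
                n_replicates=er_replicates,
                seed=np.random.default_rng(test_ss),
                collapse=collapse,
            )
        except (ConvergenceError, SingularityError, ValueError):
            n_fail += 1
            continue
        rej["gb"] += gb.p_value < level
        rej["er"] += er.p_value < level
        gb_T.append(gb.statistic)
        gb_p.append(gb.p_value)
        er_p.append(er.p_value)
        n_collapsed += er.grouping.D < D
    n_done = n_replicates - n_fail
    if n_done == 0:
        raise RuntimeError("every replicate failed to fit")
    return ExperimentResult(
        config=cfg,
        working_covariates=list(working_covariates) if working_covariates else [],
        n_replicates=n_replicates,
        level=level,
        D=D,
        er_replicates=er_replicates,
        seed=seed,
        rejections=rej,
        n_completed=n_done,
        n_failures=n_fail,
        collapse_count=n_collapsed,
        gb_statistics=np.asarray(gb_T),
        gb_pvalues=np.asarray(gb_p),
        er_pvalues=np.asarray(er_p),
    )


def run_type1_study(
    configs,
    working_covariates: Sequence[str] | None = None,
    n_replicates: int = 2000,
    seed: int = 0,
    D: int = 11,
    er_replicates: int = 1000,
    level: float = 0.05,
    collapse: bool = False,
    ties: str = "breslow",
):
    """Type-I error study: simulate under the null, fit the same model, test.

    ``configs`` is one :class:`SimulationConfig` or an iterable of them;
    the working model uses ``working_covariates`` (default: every
    simulated covariate, i.e., a correctly specified fit for null
    scenarios). Replicates whose fit fails are excluded and counted.
    Returns an :class:`ExperimentResult` (or a list of them).
    """
    if isinstance(configs, SimulationConfig):
        return _run_scenario(
            configs, working_covariates, n_replicates, seed, D, er_replicates, level, collapse, ties
        )
    return [
        _run_scenario(c, working_covariates, n_replicates, seed + i, D, er_replicates, level, collapse, ties)
        for i, c in enumerate(configs)
    ]


def run_power_study(
    base_config: SimulationConfig,
    effect_param: str,
    effect_grid: Sequence[float],
    working_covariates: Sequence[str] | None = None,
    n_replicates: int = 500,
    seed: int = 0,
    D: int = 11,
    er_replicates: int = 500,
    level: float = 0.05,
    collapse: bool = False,
    ties: str = "breslow",
) -> pd.DataFrame:
    """Power across an effect-size grid for a misspecified working model.

    ``base_config`` is the generating (alternative) model; ``effect_param``
    names the varied coefficient (``"beta_ge"``, ``"beta_z1z2"`` or
    ``"beta_g"``) and the Weibull scale is recalibrated at every grid
    point so the marginal event rate is held fixed. The working model fits
    only ``working_covariates`` — the misspecification under study.
    Returns one tidy row per (effect, test).
    """
    rows = []
    results = []
    for k, effect in enumerate(effect_grid):
        cfg = dataclasses.replace(base_config, **{effect_param: effect}, lambda_=None)
        if cfg.target_event_rate is None:
            raise ValueError("base_config must use target_event_rate so lambda recalibrates")
        res = _run_scenario(
            cfg, working_covariates, n_replicates, seed + k, D, er_replicates, level, collapse, ties
        )
        results.append(res)
        for test in ("gb", "er"):
            rows.append(
                {
                    "model": cfg.model,
                    effect_param: effect,
                    "test": test,
                    "power": res.rates[test],
                    "mc_se": res.mc_se[test],
                    "n_replicates": res.n_completed,
                    "n_failures": res.n_failures,
                    "collapse_frequency": res.collapse_frequency,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["results"] = results
    return table


# ---------------------------------------------------------------------------
# calibration diagnostics
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Observed vs expected events per risk group (calibration plot data)."""

    group: np.ndarray
    size: np.ndarray
    expected: np.ndarray
    observed: np.ndarray
    observed_count: np.ndarray
    H: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "size": self.size,
                "expected_events": self.expected,
                "observed_events": self.observed,
                "observed_event_count": self.observed_count,
                "martingale_sum": self.H,
            }
        )


def calibration_curve(fit, data: SurvivalDataset, D: int = 11) -> CalibrationCurve:
    """Observed-vs-expected average event counts across D risk groups.

    Expected events per group sum the fitted cumulative hazards
    ``exp(beta_hat' z_i) Lambda0_hat(x_i)`` (Cox–Snell residuals); the
    group totals sum to the event count. Observed events per group come
    from refitting a Cox model in which the risk-group indicators replace
    the covariates and summing its per-subject cumulative hazards, so each
    group's observed-minus-expected difference tracks the grouped
    martingale sums. Points far from the identity line flag groups whose
    predicted risk is biased.
    """
    scores = risk_scores(fit, data)
    grouping = assign_groups(scores, D, reference_group=D)
    resid = residuals(fit, data)
    grouping = attach_expected_events(grouping, resid)
    if np.any(grouping.sizes == 0):
        raise ValueError("empty risk group")
    expected = grouping.expected_events
    H_full = np.bincount(grouping.labels, weights=resid.martingale, minlength=D + 1)[1:]
    # indicator-only working model for the observed curve
    K = indicator_design(grouping)
    kcols = [f"K{g}" for g in grouping.retained_groups]
    ind_data = SurvivalDataset(data.time, np.asarray(data.event), pd.DataFrame(K, columns=kcols))
    ind_fit = fit_cox(ind_data, ties=fit.ties)
    obs_cs = residuals(ind_fit, ind_data).cox_snell
    observed = np.bincount(grouping.labels, weights=obs_cs, minlength=D + 1)[1:]
    observed_count = np.bincount(grouping.labels, weights=np.asarray(data.event, float), minlength=D + 1)[1:]
    return CalibrationCurve(
        group=np.arange(1, D + 1),
        size=grouping.sizes,
        expected=expected,
        observed=observed,
        observed_count=observed_count,
        H=H_full,
    )


def loglog_survival_curve(
    fit,
    data: SurvivalDataset,
    genotype_columns: Sequence[str] | None = None,
    t0: float = 10.0,
    reference_count: int | None = None,
    min_group_size: int = 20,
) -> pd.DataFrame:
    """Predicted vs observed log(-log S(t0)) by cumulative risk-allele count.

    Predicted survival averages the fitted ``S_i(t0)`` within groups of
    subjects sharing a total risk-allele count; observed survival comes
    from a Cox model comparing each allele-count group to the reference
    group (default: the count closest to the cohort mean, whose observed
    log hazard ratio is 0 by construction). Sparse groups (fewer than
    ``min_group_size`` subjects) are flagged, not dropped.
    """
    if genotype_columns is None:
        genotype_columns = [c for c in data.covariate_names if c.startswith("G")]
    if not genotype_columns:
        raise ValueError("no genotype columns available")
    counts = data.design(genotype_columns).sum(axis=1).astype(int)
    if reference_count is None:
        reference_count = int(round(counts.mean()))
    levels = np.unique(counts)
    if reference_count not in levels:
        reference_count = int(levels[np.argmin(np.abs(levels - reference_count))])
    s_pred = np.exp(-fit.cumulative_hazard(data, times=np.full(data.n, t0)))
    # observed: one-hot allele-count model, reference level omitted
    other = [lv for lv in levels if lv != reference_count]
    onehot = pd.DataFrame(
        {f"count_{lv}": (counts == lv).astype(float) for lv in other}
    )
    cdata = SurvivalDataset(data.time, np.asarray(data.event), onehot)
    cfit = fit_cox(cdata, ties=fit.ties)
    lam0 = cfit.cumulative_hazard(
        SurvivalDataset(cdata.time, cdata.event, onehot * 0.0), times=np.full(data.n, t0)
    )[0]
    loghr = {lv: b for lv, b in zip(other, cfit.beta)}
    loghr[reference_count] = 0.0
    rows = []
    for lv in levels:
        mask = counts == lv
        s_obs = float(np.exp(-lam0 * np.exp(loghr[lv])))
        sp = float(s_pred[mask].mean())
        rows.append(
            {
                "allele_count": int(lv),
                "n_subjects": int(mask.sum()),
                "predicted_survival": sp,
                "observed_survival": s_obs,
                "predicted_loglog": float(np.log(-np.log(sp))) if 0 < sp < 1 else np.nan,
                "observed_loglog": float(np.log(-np.log(s_obs))) if 0 < s_obs < 1 else np.nan,
                "observed_loghr": float(loghr[lv]),
                "is_reference": lv == reference_count,
                "sparse": bool(mask.sum() < min_group_size),
            }
        )
    return pd.DataFrame(rows)
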