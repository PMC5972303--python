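"""Weibull cohort simulator for calibration-test studies.

Generates synthetic cohorts of SNP genotypes (Binomial(2, MAF) under
Hardy–Weinberg equilibrium), an optional Bernoulli environmental exposure
or standard-Gaussian covariates, and event times from the Weibull hazard

    h_i(t) = lambda * alpha * t^(alpha-1) * exp(g(beta, covariates_i)),

so the survival function is S_i(t) = exp(-lambda t^alpha e^{g_i}) and
event times are drawn by inverse-CDF. The linear/log-linear predictor
``g`` comes from a small model family covering correctly specified SNP
models, omitted gene–environment interactions (single or per-SNP),
omitted Gaussian-covariate interactions, and additive (non-multiplicative)
genotype effects:

========  ==========================================================
model     g(beta, covariates)
========  ==========================================================
g01       sum_j betaG_j G_j
g02       sum_j betaG_j G_j + betaE E
gA1       sum_j betaG_j G_j + betaE E + sum_j betaGE_j G_j E
g03       betaZ_1 Z_1 + betaZ_2 Z_2
gA3       betaZ_1 Z_1 + betaZ_2 Z_2 + betaZ1Z2 Z_1 Z_2
gA4       log(1 + sum_j betaG_j G_j)      (additive hazard effects)
========  ==========================================================

The Weibull scale ``lambda`` is calibrated so the marginal probability of
an event before the 10-year horizon — in the absence of censoring —
matches a target rate; calibration enumerates the exact distribution of
``g`` when the covariate space is finite and uses quasi-Monte Carlo for
Gaussian covariates. Censoring is administrative at 10 years, optionally
plus uniform lost-to-follow-up censoring C ~ Uniform(0, tau_c) with tau_c
calibrated so the expected fraction of subjects censored before
min(T, 10) hits a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, qmc

from .data import SurvivalDataset

__all__ = [
    "SimulationConfig",
    "MODELS",
    "simulate_covariates",
    "simulate_event_times",
    "calibrate_lambda",
    "calibrate_censoring",
    "apply_censoring",
    "simulate_cohort",
]

MODELS = ("g01", "g02", "g03", "gA1", "gA3", "gA4")
_GENOTYPE_MODELS = ("g01", "g02", "gA1", "gA4")
_EXPOSURE_MODELS = ("g02", "gA1")
_GAUSSIAN_MODELS = ("g03", "gA3")


def _default_beta_g(p: int) -> float:
    # default SNP main effects: HR 1.2 per allele for 5 SNPs, HR 1.15 for
    # 10 SNPs (small effects plausible for polygenic risk scores)
    return math.log(1.2) if p <= 5 else math.log(1.15)


@dataclass
class SimulationConfig:
    """Study-condition settings for one simulated cohort scenario.

    Defaults mirror the simulation design the tests were studied under:
    MAF 0.3, exposure frequency 0.3, per-SNP log-HR log(1.2) for p=5 and
    log(1.15) for p=10 (the exposure main effect matching the SNP effect),
    a 10-year administrative horizon and alpha=1 (constant baseline
    hazard). Exactly one of ``lambda_`` / ``target_event_rate`` drives the
    Weibull scale; the latter triggers calibration.
    """

    n: int
    model: str = "g01"
    p: int = 5
    maf: float = 0.3
    alpha: float = 1.0
    lambda_: float | None = None
    target_event_rate: float | None = None
    beta_g: np.ndarray | float | None = None
    beta_e: float | None = None
    beta_ge: np.ndarray | float = 0.0
    exposure_freq: float = 0.3
    beta_z: tuple[float, float] = (math.log(1.15), math.log(1.15))
    beta_z1z2: float = 0.0
    admin_time: float = 10.0
    ltfu_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model '{self.model}'; choose from {MODELS}")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.exposure_freq < 1:
            raise ValueError("exposure_freq must lie in (0, 1)")
        if self.admin_time <= 0:
            raise ValueError("admin_time must be positive")
        if not 0 <= self.ltfu_rate < 1:
            raise ValueError("ltfu_rate must lie in [0, 1)")
        if self.lambda_ is None and self.target_event_rate is None:
            raise ValueError("specify lambda_ or target_event_rate")
        if self.lambda_ is not None and self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.target_event_rate is not None and not 0 < self.target_event_rate < 1:
            raise ValueError("target_event_rate must lie in (0, 1)")
        if self.model in _GAUSSIAN_MODELS:
            self.p = 2
        if self.beta_g is None:
            self.beta_g = _default_beta_g(self.p)
        if self.beta_e is None:
            self.beta_e = float(np.atleast_1d(np.asarray(self.beta_g, float))[0])

    # -- coefficient vectors -------------------------------------------
    def beta_g_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.beta_g, float), (self.p,)).astype(float)

    def beta_ge_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.beta_ge, float), (self.p,)).astype(float)

    def resolved(self) -> "SimulationConfig":
        """Return a copy with ``lambda_`` fixed (calibrating if needed)."""
        if self.lambda_ is not None:
            return self
        return replace(self, lambda_=calibrate_lambda(self, self.target_event_rate))


# ---------------------------------------------------------------------------
# covariates and the predictor g
# ---------------------------------------------------------------------------


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the covariate frame for one cohort.

    Genotypes ``G_j ~ Binomial(2, maf)`` i.i.d. across subjects and SNPs,
    exposure ``E ~ Bernoulli(exposure_freq)``, Gaussian covariates
    ``Z_j ~ N(0, 1)``; all mutually independent.
    """
    cols: dict[str, np.ndarray] = {}
    if config.model in _GENOTYPE_MODELS:
        G = rng.binomial(2, config.maf, size=(config.n, config.p))
        for j in range(config.p):
            cols[f"G{j + 1}"] = G[:, j].astype(float)
    if config.model in _EXPOSURE_MODELS:
        cols["E"] = (rng.random(config.n) < config.exposure_freq).astype(float)
    if config.model in _GAUSSIAN_MODELS:
        Z = rng.standard_normal((config.n, 2))
        cols["Z1"], cols["Z2"] = Z[:, 0], Z[:, 1]
    return pd.DataFrame(cols)


def _predictor(config: SimulationConfig, cov: pd.DataFrame) -> np.ndarray:
    """Evaluate g(beta, covariates) for each subject."""
    m = config.model
    if m in _GENOTYPE_MODELS:
        G = cov[[f"G{j + 1}" for j in range(config.p)]].to_numpy()
        bg = config.beta_g_vector()
        if m == "gA4":
            s = G @ bg
            if np.any(1.0 + s <= 0):
                raise ValueError("gA4 requires 1 + sum_j betaG_j G_j > 0 for every subject")
            return np.log1p(s)
        g = G @ bg
        if m in _EXPOSURE_MODELS:
            E = cov["E"].to_numpy()
            g = g + config.beta_e * E
            if m == "gA1":
                g = g + (G @ config.beta_ge_vector()) * E
        return g
    z1, z2 = cov["Z1"].to_numpy(), cov["Z2"].to_numpy()
    g = config.beta_z[0] * z1 + config.beta_z[1] * z2
    if m == "gA3":
        g = g + config.beta_z1z2 * z1 * z2
    return g


# ---------------------------------------------------------------------------
# distribution of g (for exact calibration)
# ---------------------------------------------------------------------------


def _convolve_atoms(per_term: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    vals, probs = np.array([0.0]), np.array([1.0])
    for tv, tp in per_term:
        vals = (vals[:, None] + tv[None, :]).ravel()
        probs = (probs[:, None] * tp[None, :]).ravel()
        key = np.round(vals, 12)
        uniq, inverse = np.unique(key, return_inverse=True)
        probs = np.bincount(inverse, weights=probs)
        vals = uniq
    return vals, probs


def _g_atoms(config: SimulationConfig, n_qmc: int = 2**17) -> tuple[np.ndarray, np.ndarray]:
    """Atoms (values, probabilities) of the marginal distribution of g.

    Exact for the finite genotype/exposure covariate spaces (sequential
    convolution of per-SNP three-point distributions); scrambled-Sobol
    quasi-Monte Carlo with equal weights for Gaussian covariates.
    """
    maf = config.maf
    hwe = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    gcounts = np.array([0.0, 1.0, 2.0])
    if config.model in ("g01", "gA4"):
        bg = config.beta_g_vector()
        vals, probs = _convolve_atoms([(b * gcounts, hwe) for b in bg])
        if config.model == "gA4":
            if np.any(1.0 + vals <= 0):
                raise ValueError("gA4 positivity violated on the covariate support")
            vals = np.log1p(vals)
        return vals, probs
    if config.model in _EXPOSURE_MODELS:
        bg = config.beta_g_vector()
        bge = config.beta_ge_vector() if config.model == "gA1" else np.zeros(config.p)
        v0, p0 = _convolve_atoms([(b * gcounts, hwe) for b in bg])
        v1, p1 = _convolve_atoms([(b * gcounts, hwe) for b in bg + bge])
        f = config.exposure_freq
        vals = np.concatenate([v0, v1 + config.beta_e])
        probs = np.concatenate([(1 - f) * p0, f * p1])
        return vals, probs
    # Gaussian covariates: deterministic scrambled Sobol sequence
    sob = qmc.Sobol(d=2, scramble=True, seed=1905)
    u = sob.random(n_qmc)
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    g = config.beta_z[0] * z[:, 0] + config.beta_z[1] * z[:, 1]
    if config.model == "gA3":
        g = g + config.beta_z1z2 * z[:, 0] * z[:, 1]
    return g, np.full(n_qmc, 1.0 / n_qmc)


def _event_rate(lambda_: float, config: SimulationConfig, atoms) -> float:
    vals, probs = atoms
    t_a = config.admin_time**config.alpha
    return float(probs @ -np.expm1(-lambda_ * t_a * np.exp(vals)))


def calibrate_lambda(config: SimulationConfig, target_rate: float | None = None) -> float:
    """Solve for the Weibull scale giving the target uncensored event rate.

    The event rate is P(T <= admin_time) marginally over covariates and in
    the absence of censoring; it is strictly increasing in lambda, so a
    bracketed root-finder converges to |rate error| < 1e-6.
    """
    if target_rate is None:
        target_rate = config.target_event_rate
    if target_rate is None or not 0 < target_rate < 1:
        raise ValueError("target_rate must lie in (0, 1)")
    atoms = _g_atoms(config)
    lo, hi = 1e-300, 1.0 / config.admin_time**config.alpha
    for _ in range(2000):
        if _event_rate(hi, config, atoms) >= target_rate:
            break
        hi *= 4.0
    else:
        raise RuntimeError("no bracket found for lambda calibration")
    lam = optimize.brentq(
        lambda l: _event_rate(l, config, atoms) - target_rate, lo, hi, xtol=1e-300, rtol=1e-13
    )
    if abs(_event_rate(lam, config, atoms) - target_rate) > 1e-6:
        raise RuntimeError("lambda calibration did not reach the 1e-6 rate tolerance")
    return float(lam)


# ---------------------------------------------------------------------------
# event times and censoring
# ---------------------------------------------------------------------------


def simulate_event_times(
    config: SimulationConfig, covariates: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Latent Weibull event times via the inverse CDF.

    ``T_i = (-log U_i / (lambda e^{g_i}))^{1/alpha}`` with U ~ Uniform(0,1].
    """
    if config.lambda_ is None:
        raise ValueError("lambda_ unresolved; call config.resolved() first")
    g = _predictor(config, covariates)
    u = 1.0 - rng.random(len(g))  # in (0, 1]
    return (-np.log(u) / (config.lambda_ * np.exp(g))) ** (1.0 / config.alpha)


def _mean_min_t_tau(tau: float, config: SimulationConfig, atoms, nodes=None) -> float:
    """E[min(T, admin_time, tau)] by Gauss–Legendre quadrature."""
    vals, probs = atoms
    upper = min(tau, config.admin_time)
    x, wq = np.polynomial.legendre.leggauss(128) if nodes is None else nodes
    t = 0.5 * upper * (x + 1.0)
    surv = np.exp(-config.lambda_ * np.outer(np.exp(vals), t**config.alpha))
    return float(0.5 * upper * (probs @ surv) @ wq)


def calibrate_censoring(config: SimulationConfig) -> float:
    """Upper support ``tau_c`` of the uniform lost-to-follow-up censoring.

    Every subject draws C ~ Uniform(0, tau_c); the expected fraction of
    subjects censored before min(T, admin_time) is
    ``f(tau) = E[min(T, admin_time, tau)] / tau``, strictly decreasing
    from 1 toward 0, so any target in (0, 1) has a unique tau_c.
    """
    cfg = config.resolved()
    if not 0 < cfg.ltfu_rate < 1:
        raise ValueError("ltfu_rate must lie in (0, 1) for calibration")
    atoms = _g_atoms(cfg)
    nodes = np.polynomial.legendre.leggauss(128)

    def frac(tau: float) -> float:
        return _mean_min_t_tau(tau, cfg, atoms, nodes) / tau

    lo, hi = 1e-6 * cfg.admin_time, cfg.admin_time
    for _ in range(200):
        if frac(hi) <= cfg.ltfu_rate:
            break
        hi *= 2.0
    else:
        raise RuntimeError("no bracket found for censoring calibration")
    return float(optimize.brentq(lambda t: frac(t) - cfg.ltfu_rate, lo, hi, rtol=1e-12))


def apply_censoring(
    times: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
    tau_c: float | None = None,
) -> SurvivalDataset:
    """Apply administrative (and optional uniform LTFU) censoring.

    Administrative censoring truncates follow-up at ``admin_time``; with
    ``ltfu_rate > 0`` each subject additionally draws an independent
    C ~ Uniform(0, tau_c), with tau_c from :func:`calibrate_censoring`
    unless supplied.
    """
    times = np.asarray(times, float)
    horizon = config.admin_time
    if config.ltfu_rate > 0:
        if tau_c is None:
            tau_c = calibrate_censoring(config)
        c = rng.uniform(0.0, tau_c, size=len(times))
        cens = np.minimum(c, horizon)
    else:
        cens = np.full(len(times), horizon)
    x = np.minimum(times, cens)
    delta = (times <= cens).astype(np.int8)
    return SurvivalDataset(x, delta, covariates)


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig,
    rng=None,
    tau_c: float | None = None,
) -> SurvivalDataset:
    """Simulate one full cohort under the configured scenario.

    All randomness flows from one seed through three named substreams
    (covariates, event times, censoring), so scenarios differing only in,
    say, the censoring mechanism share covariate draws. ``rng`` may be an
    int seed or a :class:`numpy.random.SeedSequence`; when omitted,
    ``config.seed`` is used.
    """
    cfg = config.resolved()
    if rng is None:
        rng = cfg.seed
    ss = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    ss_cov, ss_time, ss_cens = ss.spawn(3)
    cov = simulate_covariates(cfg, np.random.default_rng(ss_cov))
    t = simulate_event_times(cfg, cov, np.random.default_rng(ss_time))
    return apply_censoring(t, cfg, np.random.default_rng(ss_cens), covariates=cov, tau_c=tau_c)


def marginal_hr_for_additive(
    beta_g: float, config: SimulationConfig, seed: int = 0, n_pilot: int = 50_000
) -> float:
    """Mean fitted per-SNP hazard ratio when additive data meet a Cox fit.

    Helper mapping an additive-model coefficient (model ``gA4``) to the
    marginal hazard ratio a working multiplicative Cox model estimates on
    a large pilot cohort; useful for choosing additive effect sizes that
    span a desired fitted-HR range.
    """
    from .cox import fit_cox

    cfg = replace(config, model="gA4", beta_g=beta_g, n=n_pilot, lambda_=None, seed=None)
    data = simulate_cohort(cfg, rng=seed)
    fit = fit_cox(data)
    return float(np.exp(fit.beta).mean())
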