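"""Causal mediation analysis with two causally dependent mediators.

The causal graph: group status T (control = 0, ET = 1) affects a primary
mediator M (a proprioceptive discrimination threshold) and a secondary
mediator W (tremor amplitude under load), both of which affect the
functional outcome Y; T also affects Y directly; W affects M (the
mediators are causally dependent); grip strength and tactile acuity X
confound the mediator-outcome relations.

The estimator is a parametric linear structural-equation system:

    W = i_w + c_w T + g_w' X + e_w
    M = i_m + a T + d W + g_m' X + e_m
    Y = i_y + c T + b M + h (T x M) + g W + g_y' X + e_y

The average causally mediated effect through M at treatment level t is

    ACME(t) = a * (b + h t)

and the average direct effect is ADE(t) = TE - ACME(t), where the total
effect TE is the T coefficient of Y ~ T + X.  "Average" columns are the
unweighted mean of the t = 0 and t = 1 quantities.  With no interaction
(h = 0), ACME + ADE = TE exactly.  Confidence intervals come from a
nonparametric bootstrap over participants, stratified by group.

The homogeneous treatment assumption — that the mediator-outcome
relation does not differ between arms beyond the single interaction
coefficient h — is probed by a sensitivity analysis: the arm-specific
M -> Y slope is perturbed per bootstrap draw by a zero-mean normal
deviate of standard deviation sigma, and the ACME band is tracked as
sigma grows; the breakdown sigma is the smallest perturbation scale at
which the band first includes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_COVARIATES, GROUP_COLUMN, encode_group

PRIMARY_MEDIATORS = ("width_threshold", "weight_threshold")
SECONDARY_MEDIATORS = ("postural_rms_weighted", "kinetic_rms_weighted")
OUTCOMES = ("ftm_ab", "abilhand", "bbt", "nhpt")


@dataclass(frozen=True)
class MediationSpec:
    """Which columns play which causal role, plus bootstrap settings."""

    primary_mediator: str
    secondary_mediator: str
    outcome: str
    treatment: str = GROUP_COLUMN
    confounders: tuple[str, ...] = DEFAULT_COVARIATES
    n_bootstrap: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.primary_mediator == self.secondary_mediator:
            raise ValueError("primary and secondary mediators must differ")
        if self.n_bootstrap < 200:
            raise ValueError("n_bootstrap must be at least 200")

    def validate_columns(self, cohort: pd.DataFrame) -> None:
        needed = [self.treatment, self.primary_mediator,
                  self.secondary_mediator, self.outcome, *self.confounders]
        missing = [c for c in needed if c not in cohort.columns]
        if missing:
            raise KeyError(f"cohort table missing columns: {missing}")


@dataclass(frozen=True)
class StructuralFit:
    """Coefficients (and standard errors) of the three structural models
    plus the total-effect model.

    Attributes hold the causally meaningful coefficients by name; the
    full coefficient vectors are kept for bootstrap refits.
    """

    t_to_w: float            # c_w: T coefficient of W ~ T + X
    t_to_m: float            # a:   T coefficient of M ~ T + W + X
    w_to_m: float            # d
    m_to_y: float            # b:   M coefficient of Y ~ T + M + TxM + W + X
    t_to_y_direct: float     # c
    interaction: float       # h:   T x M coefficient
    w_to_y: float            # g
    total_effect: float      # T coefficient of Y ~ T + X
    interaction_se: float
    n: int


def _lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    return beta


def _lstsq_se(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta = _lstsq(X, y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def _arrays(cohort: pd.DataFrame, spec: MediationSpec,
            ) -> tuple[np.ndarray, ...]:
    spec.validate_columns(cohort)
    cols = [spec.treatment, spec.primary_mediator, spec.secondary_mediator,
            spec.outcome, *spec.confounders]
    data = cohort[cols].dropna()
    t = encode_group(data[spec.treatment].to_numpy())
    m = data[spec.primary_mediator].to_numpy(dtype=float)
    w = data[spec.secondary_mediator].to_numpy(dtype=float)
    y = data[spec.outcome].to_numpy(dtype=float)
    x = data[list(spec.confounders)].to_numpy(dtype=float)
    return t, m, w, y, x


def _fit_from_arrays(t: np.ndarray, m: np.ndarray, w: np.ndarray,
                     y: np.ndarray, x: np.ndarray,
                     with_se: bool = False) -> StructuralFit:
    ones = np.ones(len(t))
    Xw = np.column_stack([ones, t, x])
    Xm = np.column_stack([ones, t, w, x])
    Xy = np.column_stack([ones, t, m, t * m, w, x])
    Xtot = np.column_stack([ones, t, x])

    bw = _lstsq(Xw, w)
    bm = _lstsq(Xm, m)
    if with_se:
        by, se_y = _lstsq_se(Xy, y)
        interaction_se = float(se_y[3])
    else:
        by = _lstsq(Xy, y)
        interaction_se = float("nan")
    btot = _lstsq(Xtot, y)
    return StructuralFit(
        t_to_w=float(bw[1]),
        t_to_m=float(bm[1]),
        w_to_m=float(bm[2]),
        m_to_y=float(by[2]),
        t_to_y_direct=float(by[1]),
        interaction=float(by[3]),
        w_to_y=float(by[4]),
        total_effect=float(btot[1]),
        interaction_se=interaction_se,
        n=len(t),
    )


def fit_structural_models(cohort: pd.DataFrame,
                          spec: MediationSpec) -> StructuralFit:
    """Fit the three structural linear models and the total-effect model.

    Requires at least 10 complete-case rows per group.
    """
    t, m, w, y, x = _arrays(cohort, spec)
    n_et = int(t.sum())
    if n_et < 10 or len(t) - n_et < 10:
        raise ValueError(
            f"need >= 10 complete-case rows per group, have "
            f"control={len(t) - n_et}, ET={n_et}")
    return _fit_from_arrays(t, m, w, y, x, with_se=True)


def _effects_from_fit(fit: StructuralFit) -> dict[str, float]:
    acme = {t: fit.t_to_m * (fit.m_to_y + fit.interaction * t)
            for t in (0, 1)}
    te = fit.total_effect
    return {
        "acme_control": acme[0],
        "acme_treated": acme[1],
        "acme_average": 0.5 * (acme[0] + acme[1]),
        "ade_control": te - acme[0],
        "ade_treated": te - acme[1],
        "ade_average": te - 0.5 * (acme[0] + acme[1]),
        "total_effect": te,
    }


@dataclass
class MediationResult:
    """Point estimates and bootstrap 95% CIs for ACME, ADE and the total
    effect, in the outcome's natural units."""

    spec: MediationSpec
    fit: StructuralFit
    estimates: dict[str, float]
    ci: dict[str, tuple[float, float]]
    bootstrap_draws: pd.DataFrame = field(repr=False)

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]

    def summary_row(self) -> dict[str, object]:
        e, c = self.estimates, self.ci
        return {
            "outcome": self.spec.outcome,
            "primary_mediator": self.spec.primary_mediator,
            "secondary_mediator": self.spec.secondary_mediator,
            "acme_et": e["acme_treated"],
            "acme_et_ci_low": c["acme_treated"][0],
            "acme_et_ci_high": c["acme_treated"][1],
            "acme_avg": e["acme_average"],
            "acme_avg_ci_low": c["acme_average"][0],
            "acme_avg_ci_high": c["acme_average"][1],
            "ade_et": e["ade_treated"],
            "ade_et_ci_low": c["ade_treated"][0],
            "ade_et_ci_high": c["ade_treated"][1],
            "ade_avg": e["ade_average"],
            "ade_avg_ci_low": c["ade_average"][0],
            "ade_avg_ci_high": c["ade_average"][1],
            "total_effect": e["total_effect"],
            "total_ci_low": c["total_effect"][0],
            "total_ci_high": c["total_effect"][1],
        }


def _bootstrap_fits(t, m, w, y, x, n_bootstrap: int,
                    rng: np.random.Generator,
                    max_failure_rate: float = 0.05) -> list[StructuralFit]:
    """Stratified (by group) participant-level bootstrap refits."""
    idx_control = np.flatnonzero(t == 0)
    idx_et = np.flatnonzero(t == 1)
    fits: list[StructuralFit] = []
    failures = 0
    for _ in range(n_bootstrap):
        take = np.concatenate([
            rng.choice(idx_control, size=len(idx_control), replace=True),
            rng.choice(idx_et, size=len(idx_et), replace=True),
        ])
        try:
            fits.append(_fit_from_arrays(t[take], m[take], w[take],
                                         y[take], x[take]))
        except np.linalg.LinAlgError:
            failures += 1
    if failures > max_failure_rate * n_bootstrap:
        raise RuntimeError(
            f"{failures}/{n_bootstrap} bootstrap refits failed (singular "
            f"resampled designs); data too degenerate for the bootstrap")
    return fits


def estimate_effects(cohort: pd.DataFrame, spec: MediationSpec,
                     fit: StructuralFit | None = None) -> MediationResult:
    """ACME, ADE and total effect with stratified-bootstrap 95% CIs.

    Resamples participants within group, refits every structural model
    per resample, and forms percentile intervals of each effect.
    """
    t, m, w, y, x = _arrays(cohort, spec)
    if fit is None:
        fit = fit_structural_models(cohort, spec)
    estimates = _effects_from_fit(fit)

    rng = np.random.default_rng(spec.seed)
    fits = _bootstrap_fits(t, m, w, y, x, spec.n_bootstrap, rng)
    records = []
    for f in fits:
        rec = _effects_from_fit(f)
        # raw structural pieces kept for the sensitivity analysis
        rec["_a"], rec["_b"], rec["_h"] = f.t_to_m, f.m_to_y, f.interaction
        records.append(rec)
    draws = pd.DataFrame(records)
    ci = {k: (float(np.percentile(draws[k], 2.5)),
              float(np.percentile(draws[k], 97.5)))
          for k in draws.columns if not k.startswith("_")}
    return MediationResult(spec=spec, fit=fit, estimates=estimates,
                           ci=ci, bootstrap_draws=draws)


@dataclass
class SensitivityCurve:
    """ACME bands as a function of the heterogeneity SD sigma."""

    sigma_grid: np.ndarray
    curves: pd.DataFrame          # columns: sigma, group, estimate, lo, hi
    breakdown_sigma: dict[str, float]


def sensitivity(result: MediationResult,
                sigma_grid: Sequence[float] | None = None,
                seed: int | None = None) -> SensitivityCurve:
    """Sensitivity of the ACME to arm-specific mediator-outcome slope
    heterogeneity.

    For each sigma in the grid, every bootstrap draw's M -> Y slope is
    perturbed by an independent N(0, sigma) deviate before recomputing
    the arm-specific ACME; the 95% percentile band of the perturbed
    draws is reported per group.  ``breakdown_sigma`` is the smallest
    sigma at which the band first includes zero (0.0 when the baseline
    band already does).  At sigma = 0 the band equals the baseline
    bootstrap CI.
    """
    if sigma_grid is None:
        se = result.fit.interaction_se
        top = 2.0 * se if np.isfinite(se) and se > 0 else 1.0
        sigma_grid = np.linspace(0.0, top, 21)
    sigma_grid = np.asarray(list(sigma_grid), dtype=float)
    if sigma_grid.size == 0:
        raise ValueError("sigma_grid is empty")

    draws = result.bootstrap_draws
    a = draws["_a"].to_numpy()  # per-draw T -> M path
    b = draws["_b"].to_numpy()  # per-draw M -> Y slope
    h = draws["_h"].to_numpy()  # per-draw T x M interaction

    rng = np.random.default_rng(
        seed if seed is not None else result.spec.seed)
    rows = []
    breakdown: dict[str, float] = {}
    for sigma in sigma_grid:
        eps = rng.normal(0.0, sigma, size=len(a)) if sigma > 0 else \
            np.zeros(len(a))
        for group, t_level in (("control", 0), ("ET", 1)):
            acme = a * (b + h * t_level + eps)
            lo, hi = (float(np.percentile(acme, 2.5)),
                      float(np.percentile(acme, 97.5)))
            point = result.fit.t_to_m * (
                result.fit.m_to_y + result.fit.interaction * t_level)
            rows.append({"sigma": float(sigma), "group": group,
                         "estimate": point, "ci_low": lo, "ci_high": hi})
            if group not in breakdown and lo <= 0.0 <= hi:
                breakdown[group] = float(sigma)
    for group in ("control", "ET"):
        breakdown.setdefault(group, float("inf"))
    return SensitivityCurve(sigma_grid=sigma_grid,
                            curves=pd.DataFrame(rows),
                            breakdown_sigma=breakdown)


def run_all_models(cohort: pd.DataFrame, n_bootstrap: int = 1000,
                   seed: int | None = None,
                   outcomes: Sequence[str] = OUTCOMES,
                   ) -> tuple[pd.DataFrame, list[MediationResult]]:
    """The full mediation grid: every outcome x {width, weight} primary
    mediator x {postural, kinetic} secondary mediator.

    Returns the results table (one row per model, 16 rows for the
    standard four outcomes) and the underlying MediationResult objects.
    Deterministic for a fixed seed.
    """
    for col in (*outcomes, *PRIMARY_MEDIATORS, *SECONDARY_MEDIATORS,
                GROUP_COLUMN, *DEFAULT_COVARIATES):
        if col not in cohort.columns:
            raise KeyError(f"cohort table missing column {col!r}")
    seed_seq = np.random.SeedSequence(seed)
    results: list[MediationResult] = []
    rows = []
    for outcome in outcomes:
        for m_col in PRIMARY_MEDIATORS:
            for w_col in SECONDARY_MEDIATORS:
                child_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0]
                                 % (2 ** 31))
                spec = MediationSpec(
                    primary_mediator=m_col, secondary_mediator=w_col,
                    outcome=outcome, n_bootstrap=n_bootstrap,
                    seed=child_seed)
                res = estimate_effects(cohort, spec)
                results.append(res)
                rows.append(res.summary_row())
    return pd.DataFrame(rows), results
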