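"""Log-likelihood and log-prior evaluation for the hierarchical joint model.

Conditional on the subject random effects ``b_i`` and the positive
half-normal latents ``w_i`` (one per visit, shared across the K outcomes),
the longitudinal observations at a visit form a K-vector

    y_ij | b_i, w_ij ~ N( X_ij beta + Z_ij b_i
                          + delta * (w_ij - sqrt(2/pi)),  Sigma_K ),

independent across visits; ``Sigma_K`` is the K x K within-visit error
covariance and ``delta`` the skewness vector.  The survival sub-model is a
proportional-hazards model with hazard
``lambda_0(t) exp(upsilon' b_i + alpha' x_i)``, handled through the
counting-process (Poisson-increments) approximation: the baseline hazard is
a set of non-negative masses ``dLambda_g`` on the grid of observed event
times, and each subject contributes

    sum_g [ dN_i(g) log( dLambda_g e^{eta_i} ) - 1{T_i >= g} e^{eta_i} dLambda_g ].

Ties share a grid point (Breslow-style).  Priors follow the weakly
informative convention: independent normals for ``beta``, ``gamma =
(upsilon, alpha)`` and ``delta`` (a stated precision of 0.01 is read as
variance 100, the BUGS convention, switchable), inverse-Wishart for the
covariance matrices with degrees of freedom equal to the dimension, and
independent Gamma(0.01, 0.01) masses for the baseline-hazard increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import DesignMatrices, ModelSpec, SurvivalDataset, ValidationError
from .sn_dist import HALF_NORMAL_MEAN

__all__ = [
    "ParameterState",
    "PriorSpec",
    "SurvivalDesign",
    "build_survival_design",
    "loglik_long_conditional",
    "loglik_surv_counting",
    "logprior",
    "logposterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ParameterState:
    """One MCMC state of the joint model.

    ``beta`` is (K, p) with rows in outcome order; ``b`` is (n, K, q)
    (outcome-major within subject, matching the hazard loading order
    ``upsilon``); ``w`` holds one latent per longitudinal row (aligned with
    :class:`~mvjoint.data_model.DesignMatrices`); ``hazard_increments`` are
    the baseline-hazard masses on the event-time grid.
    """

    beta: np.ndarray
    b: np.ndarray
    w: np.ndarray
    Sigma_b: np.ndarray
    Sigma_K: np.ndarray
    delta: np.ndarray
    upsilon: np.ndarray
    alpha: np.ndarray
    hazard_increments: np.ndarray

    @property
    def gamma(self) -> np.ndarray:
        return np.concatenate([self.upsilon, self.alpha])

    def copy(self) -> "ParameterState":
        return ParameterState(
            beta=self.beta.copy(),
            b=self.b.copy(),
            w=self.w.copy(),
            Sigma_b=self.Sigma_b.copy(),
            Sigma_K=self.Sigma_K.copy(),
            delta=self.delta.copy(),
            upsilon=self.upsilon.copy(),
            alpha=self.alpha.copy(),
            hazard_increments=self.hazard_increments.copy(),
        )


@dataclass
class PriorSpec:
    """Hyperparameters of the weakly informative prior.

    Scalar means/variances are applied iid to every component (diagonal
    hyper-covariances).  ``Sigma_*_scale`` and ``Sigma_*_df`` parameterise
    inverse-Wishart priors ``IW(scale, df)`` with density proportional to
    ``|S|^{-(df+dim+1)/2} exp(-tr(scale S^{-1})/2)``; the degrees of freedom
    default to the matrix dimension.
    """

    beta_mean: float = 0.0
    beta_var: float = 100.0
    gamma_mean: float = 0.0
    gamma_var: float = 100.0
    delta_var: float = 100.0
    Sigma_K_scale: np.ndarray = field(default_factory=lambda: 0.01 * np.eye(2))
    Sigma_K_df: float = 2.0
    Sigma_b_scale: np.ndarray = field(default_factory=lambda: 0.01 * np.eye(4))
    Sigma_b_df: float = 4.0
    hazard_shape: float = 0.01
    hazard_rate: float = 0.01

    def __post_init__(self):
        self.Sigma_K_scale = np.asarray(self.Sigma_K_scale, float)
        self.Sigma_b_scale = np.asarray(self.Sigma_b_scale, float)
        for name in ("beta_var", "gamma_var", "delta_var", "hazard_shape", "hazard_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Sigma_K_df < self.Sigma_K_scale.shape[0]:
            raise ValueError("Sigma_K_df must be at least the matrix dimension")
        if self.Sigma_b_df < self.Sigma_b_scale.shape[0]:
            raise ValueError("Sigma_b_df must be at least the matrix dimension")

    @classmethod
    def default(cls, spec: ModelSpec, normal_precision: float = 0.01,
                precision_convention: bool = True) -> "PriorSpec":
        """Weakly informative priors sized for ``spec``.

        ``precision_convention=True`` reads the stated normal dispersion
        0.01 as a precision (variance 100); ``False`` reads it as a
        variance.
        """
        var = 1.0 / normal_precision if precision_convention else normal_precision
        K = spec.n_outcomes
        d = K * spec.n_random
        return cls(
            beta_var=var,
            gamma_var=var,
            delta_var=var,
            Sigma_K_scale=0.01 * np.eye(K),
            Sigma_K_df=float(K),
            Sigma_b_scale=0.01 * np.eye(d),
            Sigma_b_df=float(d),
        )


@dataclass
class SurvivalDesign:
    """Survival data arranged for the counting-process likelihood.

    ``grid`` holds the sorted unique observed event times; ``event_index``
    maps each subject to its grid point (-1 for censored subjects);
    ``risk[i, g] = 1`` iff subject ``i`` is still at risk at grid time ``g``
    (``T_i >= grid_g``).
    """

    x: np.ndarray  # (n, d) hazard covariates, spec order
    time: np.ndarray  # (n,)
    event: np.ndarray  # (n,) int
    grid: np.ndarray  # (G,)
    event_index: np.ndarray  # (n,)
    risk: np.ndarray  # (n, G) float
    subjects: np.ndarray
    linked: np.ndarray  # indices of the flat b vector entering the hazard

    @property
    def n_subjects(self) -> int:
        return len(self.time)

    @property
    def n_grid(self) -> int:
        return len(self.grid)

    @property
    def events_per_grid(self) -> np.ndarray:
        counts = np.zeros(self.n_grid)
        observed = self.event_index >= 0
        np.add.at(counts, self.event_index[observed], 1.0)
        return counts


def build_survival_design(
    surv: SurvivalDataset, spec: ModelSpec, grid: np.ndarray | None = None
) -> SurvivalDesign:
    """Arrange survival data on the event-time grid.

    ``grid`` defaults to the sorted unique observed event times; an explicit
    grid must contain every observed event time (extra no-event points are
    allowed and leave the likelihood untouched when their increments are
    zero).
    """
    time = surv.df["time"].to_numpy(float)
    event = surv.df["event"].to_numpy(int)
    if grid is None:
        grid = np.unique(time[event == 1])
    else:
        grid = np.unique(np.asarray(grid, float))
        missing = np.setdiff1d(time[event == 1], grid)
        if len(missing):
            raise ValidationError(
                f"event times absent from the hazard grid: {missing[:5]}"
            )
    event_index = np.full(len(time), -1, dtype=int)
    if len(grid):
        pos = np.searchsorted(grid, time)
        on_grid = (event == 1) & (pos < len(grid))
        ok = on_grid & (grid[np.minimum(pos, len(grid) - 1)] == time)
        if (event == 1).sum() != ok.sum():
            raise ValidationError("event times absent from the hazard grid")
        event_index[ok] = pos[ok]
    elif event.any():
        raise ValidationError("event times absent from the hazard grid")
    risk = (time[:, None] >= grid[None, :]).astype(float)
    return SurvivalDesign(
        x=surv.covariate_matrix(spec.survival_covariates),
        time=time,
        event=event,
        grid=grid,
        event_index=event_index,
        risk=risk,
        subjects=surv.subjects,
        linked=spec.linked_indices(),
    )


def _residual(state: ParameterState, designs: DesignMatrices) -> np.ndarray:
    """y - X beta - Z b - delta (w - sqrt(2/pi)), shape (M, K)."""
    mu = designs.x @ state.beta.T
    mu += np.einsum("mq,mkq->mk", designs.z, state.b[designs.subject_index])
    mu += (state.w - HALF_NORMAL_MEAN)[:, None] * state.delta[None, :]
    return designs.y - mu


def loglik_long_conditional(state: ParameterState, designs: DesignMatrices) -> float:
    """Longitudinal log-likelihood conditional on (b, w).

    Sum over visits of the K-variate normal log density with covariance
    ``Sigma_K`` -- the per-visit factorisation of the stacked
    ``Sigma_K (x) I_{n_i}`` model.
    """
    resid = _residual(state, designs)
    M, K = resid.shape
    if M == 0:
        return 0.0
    try:
        L = np.linalg.cholesky(state.Sigma_K)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Sigma_K is not positive definite in the longitudinal likelihood"
        ) from exc
    sol = np.linalg.solve(L, resid.T)
    quad = float(np.sum(sol * sol))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (M * K * _LOG_2PI + M * logdet + quad)


def loglik_surv_counting(state: ParameterState, sdesign: SurvivalDesign) -> float:
    """Counting-process (Poisson-increments) survival log-likelihood."""
    inc = np.asarray(state.hazard_increments, float)
    if inc.shape != (sdesign.n_grid,):
        raise ValidationError(
            f"hazard_increments has shape {inc.shape}, grid needs {(sdesign.n_grid,)}"
        )
    n = sdesign.n_subjects
    eta = state.b.reshape(n, -1)[:, sdesign.linked] @ state.upsilon + sdesign.x @ state.alpha
    cumhaz = sdesign.risk @ inc
    observed = sdesign.event_index >= 0
    with np.errstate(divide="ignore"):
        log_inc = np.log(inc)
    ll = float(np.sum(log_inc[sdesign.event_index[observed]] + eta[observed]))
    ll -= float(np.sum(np.exp(eta) * cumhaz))
    return ll


def _iw_logpdf(S: np.ndarray, scale: np.ndarray, df: float) -> float:
    return float(stats.invwishart.logpdf(S, df=df, scale=scale))


def logprior(state: ParameterState, prior: PriorSpec) -> float:
    """Log prior density including the latent layers (b and w)."""
    lp = 0.0
    for vals, mean, var in (
        (state.beta.ravel(), prior.beta_mean, prior.beta_var),
        (state.gamma, prior.gamma_mean, prior.gamma_var),
        (state.delta, 0.0, prior.delta_var),
    ):
        lp += float(
            np.sum(-0.5 * (_LOG_2PI + np.log(var)) - 0.5 * (vals - mean) ** 2 / var)
        )
    lp += _iw_logpdf(state.Sigma_b, prior.Sigma_b_scale, prior.Sigma_b_df)
    lp += _iw_logpdf(state.Sigma_K, prior.Sigma_K_scale, prior.Sigma_K_df)
    inc = state.hazard_increments
    if len(inc):
        if np.any(inc <= 0):
            return -np.inf
        lp += float(
            np.sum(stats.gamma.logpdf(inc, a=prior.hazard_shape,
                                      scale=1.0 / prior.hazard_rate))
        )
    w = state.w
    if len(w):
        if np.any(w < 0):
            return -np.inf
        lp += float(np.sum(np.log(2.0) - 0.5 * _LOG_2PI - 0.5 * w * w))
    n = state.b.shape[0]
    if n:
        b_flat = state.b.reshape(n, -1)
        L = np.linalg.cholesky(state.Sigma_b)
        sol = np.linalg.solve(L, b_flat.T)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        lp += -0.5 * (
            n * b_flat.shape[1] * _LOG_2PI + n * logdet + float(np.sum(sol * sol))
        )
    return lp


def logposterior(
    state: ParameterState,
    designs: DesignMatrices,
    sdesign: SurvivalDesign,
    prior: PriorSpec,
) -> float:
    """Unnormalised log posterior: longitudinal + survival + prior."""
    lp = logprior(state, prior)
    if not np.isfinite(lp):
        return lp
    return (
        loglik_long_conditional(state, designs)
        + loglik_surv_counting(state, sdesign)
        + lp
    )
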