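"""Gibbs sampler with Metropolis-Hastings steps for the joint model.

Update cycle per iteration (order configurable; the stationary law does not
depend on it):

1. ``w``   - truncated-normal full conditionals, one latent per visit;
2. ``delta`` - normal full conditional (the mean is linear in delta given w);
3. ``beta``  - normal full conditional (GLS-type, conjugate given b, w, Sigma_K);
4. ``b``   - per-subject M-H with the exact longitudinal-conditional normal
   as proposal, so the acceptance ratio involves only the survival factor
   (and is identically 1 when the hazard loadings are zero);
5. ``Sigma_K``, ``Sigma_b`` - conjugate inverse-Wishart full conditionals;
6. baseline-hazard increments - conjugate gamma full conditionals
   (Poisson-gamma, Breslow-style tie handling);
7. ``gamma = (upsilon, alpha)`` - component-wise adaptive random-walk M-H on
   the counting-process likelihood times the normal prior, with
   Robbins-Monro scale adaptation targeting 0.30 acceptance during burn-in
   only (scales frozen afterwards).

The normal variant (``model_variant="n"``) pins ``delta = 0`` and never
references the ``w`` latents.  Chains use independent substreams derived
from the master seed, so a run is bit-reproducible from its configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.linalg import solve_triangular

from .data_model import DesignMatrices, LongitudinalDataset, ModelSpec, SurvivalDataset, build_designs
from .likelihoods import (
    ParameterState,
    PriorSpec,
    SurvivalDesign,
    build_survival_design,
    loglik_long_conditional,
    loglik_surv_counting,
)
from .sn_dist import HALF_NORMAL_MEAN

__all__ = [
    "MCMCConfig",
    "FitData",
    "PosteriorDraws",
    "build_fit",
    "update_w",
    "update_delta",
    "update_beta",
    "update_b",
    "update_covariances",
    "update_survival_params",
    "run_mcmc",
]

logger = logging.getLogger(__name__)

_DEFAULT_ORDER = ("w", "delta", "beta", "b", "Sigma_K", "Sigma_b", "survival")


@dataclass
class MCMCConfig:
    """Sampler schedule and tuning knobs.

    The default is a desk-scale schedule (3 chains x 4,000 iterations,
    burn-in 1,000, thinning 5); :meth:`paper_schedule` returns the long
    schedule of 3 chains x 30,000 with 10,000 burn-in retaining every 20th
    draw.
    """

    n_chains: int = 3
    n_iterations: int = 4000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    proposal_scales: dict = field(default_factory=lambda: {"gamma": 0.1})
    init_strategy: str = "overdispersed"
    store_random_effects: bool = False
    update_order: tuple = _DEFAULT_ORDER

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")
        if self.init_strategy not in ("overdispersed", "prior", "fixed"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def paper_schedule(cls, **kw) -> "MCMCConfig":
        kw.setdefault("n_chains", 3)
        kw.setdefault("n_iterations", 30000)
        kw.setdefault("burn_in", 10000)
        kw.setdefault("thin", 20)
        return cls(**kw)


@dataclass
class FitData:
    """Pre-assembled arrays shared by all update steps."""

    designs: DesignMatrices
    sdesign: SurvivalDesign
    spec: ModelSpec
    row_subject: np.ndarray  # (M,) row -> survival subject index
    seg_starts: np.ndarray  # reduceat starts, subjects with rows only
    seg_subjects: np.ndarray  # survival indices of those segments
    S_xx: np.ndarray  # (p, p)
    S_zz: np.ndarray  # (n, q, q)
    linked: np.ndarray  # indices of b entering the hazard

    @property
    def n(self) -> int:
        return self.sdesign.n_subjects

    @property
    def M(self) -> int:
        return len(self.row_subject)


def build_fit(
    long_data: LongitudinalDataset,
    surv_data: SurvivalDataset,
    spec: ModelSpec,
    grid: np.ndarray | None = None,
) -> FitData:
    designs = build_designs(long_data, spec)
    sdesign = build_survival_design(surv_data, spec, grid=grid)
    if len(np.setdiff1d(designs.subjects, sdesign.subjects)):
        raise ValueError("longitudinal subjects missing from the survival file")
    pos = np.searchsorted(sdesign.subjects, designs.subjects)
    row_subject = pos[designs.subject_index] if designs.n_rows else np.empty(0, int)
    # re-key the design rows to the full survival subject list so that
    # state.b (one row per survival subject) indexes consistently everywhere,
    # including subjects whose follow-up ended before the first visit
    designs.subjects = sdesign.subjects
    designs.subject_index = row_subject
    n, q = sdesign.n_subjects, spec.n_random
    S_zz = np.zeros((n, q, q))
    if designs.n_rows:
        zz = np.einsum("mq,mr->mqr", designs.z, designs.z)
        change = np.nonzero(np.diff(row_subject))[0] + 1
        seg_starts = np.concatenate([[0], change])
        seg_subjects = row_subject[seg_starts]
        S_zz[seg_subjects] = np.add.reduceat(zz, seg_starts, axis=0)
        S_xx = designs.x.T @ designs.x
    else:
        seg_starts = np.empty(0, int)
        seg_subjects = np.empty(0, int)
        S_xx = np.zeros((spec.n_fixed, spec.n_fixed))
    return FitData(
        designs=designs,
        sdesign=sdesign,
        spec=spec,
        row_subject=row_subject,
        seg_starts=seg_starts,
        seg_subjects=seg_subjects,
        S_xx=S_xx,
        S_zz=S_zz,
        linked=spec.linked_indices(),
    )


def _segment_sum(fit: FitData, values: np.ndarray) -> np.ndarray:
    """Sum row values per subject -> (n, ...); zero for subjects w/o rows."""
    out = np.zeros((fit.n,) + values.shape[1:])
    if fit.M:
        out[fit.seg_subjects] = np.add.reduceat(values, fit.seg_starts, axis=0)
    return out


def _mu_fixed(state: ParameterState, fit: FitData) -> np.ndarray:
    return fit.designs.x @ state.beta.T


def _mu_random(state: ParameterState, fit: FitData) -> np.ndarray:
    return np.einsum(
        "mq,mkq->mk", fit.designs.z, state.b.reshape(fit.n, -1, fit.spec.n_random)[fit.row_subject]
    )


def _draw_from_precision(prec: np.ndarray, rhs: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 rhs, prec^-1)."""
    L = np.linalg.cholesky(prec)
    tmp = solve_triangular(L, rhs, lower=True)
    mean = solve_triangular(L.T, tmp, lower=False)
    noise = solve_triangular(L.T, rng.standard_normal(len(rhs)), lower=False)
    return mean + noise


def _truncnorm_positive(mean: np.ndarray, sd: float | np.ndarray, rng) -> np.ndarray:
    """Vectorised N(mean, sd^2) truncated to (0, inf) via inverse CDF."""
    p0 = special.ndtr(-mean / sd)
    u = p0 + (1.0 - p0) * rng.random(np.shape(mean))
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return np.maximum(mean + sd * special.ndtri(u), 0.0)


def update_w(state: ParameterState, fit: FitData, rng) -> ParameterState:
    """Truncated-normal full-conditional draw of every half-normal latent."""
    if fit.M == 0:
        return state
    Sinv = np.linalg.inv(state.Sigma_K)
    u = fit.designs.y - _mu_fixed(state, fit) - _mu_random(state, fit)
    u += HALF_NORMAL_MEAN * state.delta[None, :]
    v = Sinv @ state.delta
    lam = 1.0 + float(state.delta @ v)
    mean = (u @ v) / lam
    state.w = _truncnorm_positive(mean, np.sqrt(1.0 / lam), rng)
    return state


def update_delta(state: ParameterState, fit: FitData, prior: PriorSpec, rng) -> ParameterState:
    """Normal full-conditional draw of the skewness vector."""
    K = fit.spec.n_outcomes
    prec = np.eye(K) / prior.delta_var
    rhs = np.zeros(K)
    if fit.M:
        Sinv = np.linalg.inv(state.Sigma_K)
        a = state.w - HALF_NORMAL_MEAN
        u = fit.designs.y - _mu_fixed(state, fit) - _mu_random(state, fit)
        prec = prec + float(a @ a) * Sinv
        rhs = Sinv @ (a @ u)
    state.delta = _draw_from_precision(prec, rhs, rng)
    return state


def update_beta(state: ParameterState, fit: FitData, prior: PriorSpec, rng) -> ParameterState:
    """Conjugate normal draw of the stacked fixed effects (outcome-major)."""
    K, p = state.beta.shape
    prec = np.eye(K * p) / prior.beta_var
    rhs = np.full(K * p, prior.beta_mean / prior.beta_var)
    if fit.M:
        Sinv = np.linalg.inv(state.Sigma_K)
        r = fit.designs.y - _mu_random(state, fit)
        r -= (state.w - HALF_NORMAL_MEAN)[:, None] * state.delta[None, :]
        prec = prec + np.kron(Sinv, fit.S_xx)
        rhs = rhs + (Sinv @ (r.T @ fit.designs.x)).ravel()
    state.beta = _draw_from_precision(prec, rhs, rng).reshape(K, p)
    return state


def update_b(state: ParameterState, fit: FitData, rng):
    """Per-subject M-H draw of the random effects.

    The proposal is the normal conditional implied by the longitudinal part
    and the N(0, Sigma_b) prior, tilted by the gradient of the survival
    log-likelihood at the current state (a per-subject Laplace-style
    independence proposal).  The M-H correction keeps the target exact; when
    the hazard loadings are zero the tilt vanishes and the step reduces to
    an exact Gibbs draw with acceptance 1.  Returns
    ``(state, acceptance_rate)``.
    """
    n, K, q = fit.n, fit.spec.n_outcomes, fit.spec.n_random
    dim = K * q
    Sb_inv = np.linalg.inv(state.Sigma_b)
    if fit.M:
        Sinv = np.linalg.inv(state.Sigma_K)
        r = fit.designs.y - _mu_fixed(state, fit)
        r -= (state.w - HALF_NORMAL_MEAN)[:, None] * state.delta[None, :]
        contrib = np.einsum("mk,mq->mkq", r @ Sinv, fit.designs.z).reshape(fit.M, dim)
        rhs = _segment_sum(fit, contrib)
        prec = np.einsum("kl,nab->nkalb", Sinv, fit.S_zz).reshape(n, dim, dim)
        prec = prec + Sb_inv[None, :, :]
    else:
        rhs = np.zeros((n, dim))
        prec = np.broadcast_to(Sb_inv, (n, dim, dim)).copy()
    L = np.linalg.cholesky(prec)
    mean0 = np.linalg.solve(prec, rhs[..., None])[..., 0]

    ups = np.zeros(dim)
    ups[fit.linked] = state.upsilon
    xa = fit.sdesign.x @ state.alpha
    cumhaz = fit.sdesign.risk @ state.hazard_increments
    event = fit.sdesign.event
    b_flat = state.b.reshape(n, dim)
    # survival score direction: grad_b loglik_surv = s(b) * ups with
    # s(b) = event - exp(eta(b)) * Lambda(T); the proposal mean is
    # mean0 + s(b) * P^-1 ups
    pv = np.linalg.solve(prec, np.broadcast_to(ups, (n, dim))[..., None])[..., 0]
    vpv = pv @ ups  # (n,) quadratic form ups' P^-1 ups

    eta_old = b_flat @ ups + xa
    with np.errstate(over="ignore"):
        s_old = event - np.exp(eta_old) * cumhaz
    noise = np.linalg.solve(
        np.transpose(L, (0, 2, 1)), rng.standard_normal((n, dim))[..., None]
    )[..., 0]
    b_prop = mean0 + s_old[:, None] * pv + noise
    eta_new = b_prop @ ups + xa
    with np.errstate(over="ignore"):
        s_new = event - np.exp(eta_new) * cumhaz
        # survival likelihood ratio
        logr = event * (eta_new - eta_old)
        logr = logr - (np.exp(eta_new) - np.exp(eta_old)) * cumhaz
    # proposal correction for the state-dependent tilt
    du_old = ((b_flat - mean0) * ups).sum(axis=1)
    du_new = ((b_prop - mean0) * ups).sum(axis=1)
    logr = logr + du_old * s_new - du_new * s_old
    logr = logr - 0.5 * (s_new**2 - s_old**2) * vpv
    accept = np.log(rng.random(n)) < logr
    b_flat[accept] = b_prop[accept]
    state.b = b_flat.reshape(n, K, q)
    return state, float(accept.mean())


def _draw_invwishart(df: float, scale: np.ndarray, rng) -> np.ndarray:
    for attempt in range(5):
        draw = np.atleast_2d(stats.invwishart.rvs(df=df, scale=scale, random_state=rng))
        try:
            np.linalg.cholesky(draw)
            return draw
        except np.linalg.LinAlgError:
            logger.warning("non-PD inverse-Wishart draw, retrying with jitter")
            scale = scale + 1e-8 * np.eye(scale.shape[0]) * (10.0**attempt)
    raise np.linalg.LinAlgError("inverse-Wishart draw failed to be positive definite")


def update_covariances(state: ParameterState, fit: FitData, prior: PriorSpec, rng) -> ParameterState:
    """Conjugate inverse-Wishart draws of Sigma_K and Sigma_b."""
    if fit.M:
        resid = fit.designs.y - _mu_fixed(state, fit) - _mu_random(state, fit)
        resid -= (state.w - HALF_NORMAL_MEAN)[:, None] * state.delta[None, :]
        state.Sigma_K = _draw_invwishart(
            prior.Sigma_K_df + fit.M, prior.Sigma_K_scale + resid.T @ resid, rng
        )
    else:
        state.Sigma_K = _draw_invwishart(prior.Sigma_K_df, prior.Sigma_K_scale, rng)
    n = fit.n
    if n:
        b_flat = state.b.reshape(n, -1)
        state.Sigma_b = _draw_invwishart(
            prior.Sigma_b_df + n, prior.Sigma_b_scale + b_flat.T @ b_flat, rng
        )
    else:
        state.Sigma_b = _draw_invwishart(prior.Sigma_b_df, prior.Sigma_b_scale, rng)
    return state


def update_survival_params(
    state: ParameterState,
    fit: FitData,
    prior: PriorSpec,
    rng,
    scales: np.ndarray,
):
    """Gamma-conjugate hazard-increment draws, then component-wise
    random-walk M-H on ``gamma = (upsilon, alpha)``.

    Returns ``(state, accept_indicators)`` with one 0/1 entry per gamma
    component for the adaptation bookkeeping.
    """
    sd = fit.sdesign
    n, dim = fit.n, fit.spec.n_outcomes * fit.spec.n_random
    ups = np.zeros(dim)
    ups[fit.linked] = state.upsilon
    b_flat = state.b.reshape(n, dim)
    eta = b_flat @ ups + sd.x @ state.alpha
    exp_eta = np.exp(eta)
    if sd.n_grid:
        d_g = sd.events_per_grid
        S_g = sd.risk.T @ exp_eta
        state.hazard_increments = rng.gamma(
            prior.hazard_shape + d_g, 1.0 / (prior.hazard_rate + S_g)
        )
    cumhaz = sd.risk @ state.hazard_increments
    d_mat = np.column_stack([b_flat[:, fit.linked], sd.x])
    gam = np.concatenate([state.upsilon, state.alpha])
    accepts = np.zeros(len(gam))
    base = float(np.sum(exp_eta * cumhaz))
    for j in range(len(gam)):
        step = scales[j] * rng.standard_normal()
        deta = step * d_mat[:, j]
        with np.errstate(over="ignore"):
            new = float(np.sum(np.exp(eta + deta) * cumhaz))
        dll = float(sd.event @ deta) - (new - base)
        dll += (
            -0.5 * ((gam[j] + step - prior.gamma_mean) ** 2 - (gam[j] - prior.gamma_mean) ** 2)
            / prior.gamma_var
        )
        if np.isfinite(dll) and np.log(rng.random()) < dll:
            gam[j] += step
            eta = eta + deta
            base = new
            accepts[j] = 1.0
    nl = len(fit.linked)
    state.upsilon = gam[:nl]
    state.alpha = gam[nl:]
    return state, accepts


# ---------------------------------------------------------------------------
# parameter packing / draws container


class _Packer:
    """Maps a ParameterState to/from the flat retained-draw vector."""

    def __init__(self, fit: FitData):
        spec = fit.spec
        K, p, q = spec.n_outcomes, spec.n_fixed, spec.n_random
        dim = K * q
        names: list[str] = []
        for k in range(K):
            names += [f"beta{t}{k + 1}" for t in range(p)]
        names += [f"delta{k + 1}" for k in range(K)]
        self._triK = [(i, j) for i in range(K) for j in range(i, K)]
        names += [f"sigma2_{i + 1}{j + 1}" for i, j in self._triK]
        self._triB = [(i, j) for i in range(dim) for j in range(i, dim)]
        names += [f"sigmab_{i + 1}{j + 1}" for i, j in self._triB]
        names += [f"upsilon{j + 1}" for j in range(len(fit.linked))]
        names += [f"alpha{j + 1}" for j in range(fit.sdesign.x.shape[1])]
        names += ["cumhaz_total"]
        self.names = names
        self.K, self.p, self.q, self.dim = K, p, q, dim
        self.n_linked = len(fit.linked)
        self.n_alpha = fit.sdesign.x.shape[1]

    def pack(self, state: ParameterState) -> np.ndarray:
        parts = [state.beta.ravel(), state.delta]
        parts.append(np.array([state.Sigma_K[i, j] for i, j in self._triK]))
        parts.append(np.array([state.Sigma_b[i, j] for i, j in self._triB]))
        parts += [state.upsilon, state.alpha]
        parts.append(np.array([float(np.sum(state.hazard_increments))]))
        return np.concatenate(parts)

    def unpack_mean(self, vec: np.ndarray) -> dict:
        K, p, dim = self.K, self.p, self.dim
        out: dict = {}
        i = 0
        out["beta"] = vec[i : i + K * p].reshape(K, p)
        i += K * p
        out["delta"] = vec[i : i + K]
        i += K
        SK = np.zeros((K, K))
        for (a, b), v in zip(self._triK, vec[i : i + len(self._triK)]):
            SK[a, b] = SK[b, a] = v
        out["Sigma_K"] = SK
        i += len(self._triK)
        SB = np.zeros((dim, dim))
        for (a, b), v in zip(self._triB, vec[i : i + len(self._triB)]):
            SB[a, b] = SB[b, a] = v
        out["Sigma_b"] = SB
        i += len(self._triB)
        out["upsilon"] = vec[i : i + self.n_linked]
        i += self.n_linked
        out["alpha"] = vec[i : i + self.n_alpha]
        return out


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus the summaries needed downstream.

    Population parameters are always stored per retained iteration; random
    effects and latents are stored in full only under
    ``store_random_effects`` (their posterior means and the per-draw
    conditional deviance are always kept, which is what the DIC needs).
    """

    param_names: list
    chains: list  # per chain (m, P)
    deviance: list  # per chain (m,) conditional deviance
    acceptance: dict
    b_mean: np.ndarray
    w_mean: np.ndarray
    increments_mean: np.ndarray
    grid: np.ndarray
    spec: ModelSpec
    variant: str
    config: MCMCConfig
    packer: object = field(repr=False, default=None)
    b_draws: list | None = None
    w_draws: list | None = None

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_retained(self) -> int:
        return self.chains[0].shape[0] if self.chains else 0

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_retained)."""
        j = self.param_names.index(name)
        return np.stack([c[:, j] for c in self.chains])

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for c, arr in enumerate(self.chains):
            df = pd.DataFrame(arr, columns=self.param_names)
            df.insert(0, "draw", np.arange(arr.shape[0]))
            df.insert(0, "chain", c)
            df["deviance"] = self.deviance[c]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        """Rebuild a summaries-capable container from a draws CSV.

        Random-effect means are unavailable after a CSV round trip, so DIC
        recomputation requires the original in-memory object.
        """
        names = [c for c in df.columns if c not in ("chain", "draw", "deviance")]
        chains, dev = [], []
        for c in sorted(df["chain"].unique()):
            sub = df[df["chain"] == c]
            chains.append(sub[names].to_numpy(float))
            dev.append(
                sub["deviance"].to_numpy(float)
                if "deviance" in df.columns
                else np.full(len(sub), np.nan)
            )
        return cls(
            param_names=names,
            chains=chains,
            deviance=dev,
            acceptance={},
            b_mean=None,
            w_mean=None,
            increments_mean=None,
            grid=None,
            spec=None,
            variant="unknown",
            config=None,
        )

    def posterior_mean_vector(self) -> np.ndarray:
        return np.concatenate(self.chains, axis=0).mean(axis=0)


# ---------------------------------------------------------------------------
# initialisation and the main loop


def _ols_init(fit: FitData):
    p, K = fit.spec.n_fixed, fit.spec.n_outcomes
    if fit.M == 0:
        return np.zeros((K, p)), np.eye(K)
    S = fit.S_xx + 1e-8 * np.eye(p)
    beta = np.linalg.solve(S, fit.designs.x.T @ fit.designs.y).T
    resid = fit.designs.y - fit.designs.x @ beta.T
    Sigma_K = resid.T @ resid / max(fit.M - 1, 1) + 1e-6 * np.eye(K)
    return beta, Sigma_K


def _init_state(fit: FitData, prior: PriorSpec, config: MCMCConfig, chain: int,
                variant: str, rng) -> ParameterState:
    spec = fit.spec
    K, q = spec.n_outcomes, spec.n_random
    n, M = fit.n, fit.M
    beta, Sigma_K = _ols_init(fit)
    sd = fit.sdesign
    at_risk = sd.risk.sum(axis=0) if sd.n_grid else np.empty(0)
    inc = (
        (sd.events_per_grid + 0.1) / (at_risk + 1.0) if sd.n_grid else np.empty(0)
    )
    state = ParameterState(
        beta=beta,
        b=np.zeros((n, K, q)),
        w=np.full(M, HALF_NORMAL_MEAN),
        Sigma_b=np.eye(K * q),
        Sigma_K=Sigma_K,
        delta=np.zeros(K),
        upsilon=np.zeros(len(fit.linked)),
        alpha=np.zeros(sd.x.shape[1]),
        hazard_increments=inc,
    )
    if config.init_strategy == "prior":
        state.beta = prior.beta_mean + np.sqrt(prior.beta_var) * rng.standard_normal((K, spec.n_fixed))
        state.upsilon = prior.gamma_mean + np.sqrt(prior.gamma_var) * rng.standard_normal(len(fit.linked))
        state.alpha = prior.gamma_mean + np.sqrt(prior.gamma_var) * rng.standard_normal(sd.x.shape[1])
        if variant == "sn":
            state.delta = np.sqrt(prior.delta_var) * rng.standard_normal(K)
    elif config.init_strategy == "overdispersed":
        # chain-dependent offsets in posterior-scale (natural) units plus
        # variance inflation/deflation; chain 0 starts at the data-driven point
        sign = [0.0, 1.0, -1.0, 2.0, -2.0][chain % 5]
        state.beta = state.beta + sign * 2.0
        state.upsilon = state.upsilon + sign * 0.5
        state.alpha = state.alpha + sign * 0.5
        if variant == "sn":
            state.delta = state.delta + sign * 1.0
        factor = (0.5, 1.0, 2.0)[chain % 3]
        state.Sigma_K = state.Sigma_K * factor
        state.Sigma_b = state.Sigma_b * factor
    if variant == "n":
        state.delta = np.zeros(K)
        state.w = np.full(M, HALF_NORMAL_MEAN)
    return state


def _run_chain(fit: FitData, prior: PriorSpec, config: MCMCConfig, chain: int,
               variant: str):
    rng = np.random.default_rng([config.seed, chain])
    state = _init_state(fit, prior, config, chain, variant, rng)
    n_gamma = len(fit.linked) + fit.sdesign.x.shape[1]
    scales = np.full(n_gamma, float(config.proposal_scales.get("gamma", 0.1)))
    m = config.n_retained
    packer = _Packer(fit)
    samples = np.empty((m, len(packer.names)))
    deviance = np.empty(m)
    b_sum = np.zeros_like(state.b)
    w_sum = np.zeros_like(state.w)
    inc_sum = np.zeros_like(state.hazard_increments)
    b_acc = 0.0
    gamma_acc = np.zeros(n_gamma)
    b_store = [] if config.store_random_effects else None
    w_store = [] if config.store_random_effects else None
    kept = 0
    for t in range(1, config.n_iterations + 1):
        for step in config.update_order:
            if step == "w":
                if variant == "sn":
                    update_w(state, fit, rng)
            elif step == "delta":
                if variant == "sn":
                    update_delta(state, fit, prior, rng)
            elif step == "beta":
                update_beta(state, fit, prior, rng)
            elif step == "b":
                _, acc = update_b(state, fit, rng)
                b_acc += acc
            elif step == "Sigma_K":
                if fit.M:
                    resid = fit.designs.y - _mu_fixed(state, fit) - _mu_random(state, fit)
                    resid -= (state.w - HALF_NORMAL_MEAN)[:, None] * state.delta[None, :]
                    state.Sigma_K = _draw_invwishart(
                        prior.Sigma_K_df + fit.M, prior.Sigma_K_scale + resid.T @ resid, rng
                    )
                else:
                    state.Sigma_K = _draw_invwishart(prior.Sigma_K_df, prior.Sigma_K_scale, rng)
            elif step == "Sigma_b":
                b_flat = state.b.reshape(fit.n, -1)
                state.Sigma_b = _draw_invwishart(
                    prior.Sigma_b_df + fit.n, prior.Sigma_b_scale + b_flat.T @ b_flat, rng
                )
            elif step == "survival":
                _, acc_g = update_survival_params(state, fit, prior, rng, scales)
                gamma_acc += acc_g
                if t <= config.burn_in:
                    scales *= np.exp((acc_g - 0.30) * t**-0.6)
            else:
                raise ValueError(f"unknown update step {step!r}")
        if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
            vec = packer.pack(state)
            if not np.all(np.isfinite(vec)):
                bad = [nm for nm, v in zip(packer.names, vec) if not np.isfinite(v)]
                raise RuntimeError(
                    f"divergent state at iteration {t} of chain {chain}: {bad}"
                )
            samples[kept] = vec
            deviance[kept] = -2.0 * (
                loglik_long_conditional(state, fit.designs)
                + loglik_surv_counting(state, fit.sdesign)
            )
            b_sum += state.b
            w_sum += state.w
            inc_sum += state.hazard_increments
            if config.store_random_effects:
                b_store.append(state.b.copy())
                w_store.append(state.w.copy())
            kept += 1
        if t % 1000 == 0:
            logger.debug(
                "chain %d iteration %d/%d (b acc %.2f)", chain, t, config.n_iterations,
                b_acc / t,
            )
    acc = {
        "b": b_acc / config.n_iterations,
        "gamma": (gamma_acc / config.n_iterations).tolist(),
    }
    return samples, deviance, acc, b_sum, w_sum, inc_sum, b_store, w_store, packer


def run_mcmc(
    long_data: LongitudinalDataset,
    surv_data: SurvivalDataset,
    spec: ModelSpec | None = None,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    model_variant: str = "sn",
) -> PosteriorDraws:
    """Fit the joint model by MCMC and return the retained draws.

    ``model_variant`` is ``"sn"`` (skew-normal errors) or ``"n"`` (normal
    errors; the skewness vector is pinned at zero and the positive latents
    are never referenced).
    """
    if model_variant not in ("sn", "n"):
        raise ValueError("model_variant must be 'sn' or 'n'")
    spec = spec if spec is not None else ModelSpec()
    config = config if config is not None else MCMCConfig()
    prior = prior if prior is not None else PriorSpec.default(spec)
    fit = build_fit(long_data, surv_data, spec)
    chains, devs, accs = [], [], {}
    b_tot = np.zeros((fit.n, spec.n_outcomes, spec.n_random))
    w_tot = np.zeros(fit.M)
    inc_tot = np.zeros(fit.sdesign.n_grid)
    b_draws: list = []
    w_draws: list = []
    packer = None
    for c in range(config.n_chains):
        samples, dev, acc, b_sum, w_sum, inc_sum, b_st, w_st, packer = _run_chain(
            fit, prior, config, c, model_variant
        )
        chains.append(samples)
        devs.append(dev)
        accs[f"chain_{c}"] = acc
        b_tot += b_sum
        w_tot += w_sum
        inc_tot += inc_sum
        if config.store_random_effects:
            b_draws += b_st
            w_draws += w_st
    total = config.n_retained * config.n_chains
    return PosteriorDraws(
        param_names=packer.names,
        chains=chains,
        deviance=devs,
        acceptance=accs,
        b_mean=b_tot / max(total, 1),
        w_mean=w_tot / max(total, 1),
        increments_mean=inc_tot / max(total, 1),
        grid=fit.sdesign.grid,
        spec=spec,
        variant=model_variant,
        config=config,
        packer=packer,
        b_draws=b_draws if config.store_random_effects else None,
        w_draws=w_draws if config.store_random_effects else None,
    )
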