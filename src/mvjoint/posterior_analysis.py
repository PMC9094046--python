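"""Posterior summaries, convergence diagnostics, DIC and survival displays.

Summaries are the posterior mean (PM), posterior SD and the 95% equal-tail
credible interval over the pooled post-burn-in draws.  Convergence is
assessed with the original Gelman-Rubin variance-ratio diagnostic: for
chains of length m, the average within-chain variance W, the pooled
variance estimate V = ((m-1)/m) W + B/m (B being m times the variance of
the chain means) and their ratio R = V/W, which tends to 1 as the chains
mix.  Model comparison uses the deviance information criterion with the
deviance *conditional* on the random effects and latents,
D(theta) = -2 log f(Y, rho | beta, b, w, Sigma_K, delta, gamma, dLambda):
DIC = Dbar + pD with pD = Dbar - D(thetabar), lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DesignMatrices, ModelSpec, SurvivalDataset
from .likelihoods import (
    ParameterState,
    SurvivalDesign,
    loglik_long_conditional,
    loglik_surv_counting,
)
from .mcmc_engine import PosteriorDraws

__all__ = [
    "PosteriorSummary",
    "GRResult",
    "DICResult",
    "summarize",
    "gelman_rubin",
    "dic",
    "hazard_ratios",
    "fitted_trajectories",
    "kaplan_meier",
    "event_fraction",
    "plot_trace",
    "plot_gelman_rubin",
    "plot_kaplan_meier",
    "plot_observed_vs_fitted",
]


@dataclass
class GRResult:
    """Gelman-Rubin diagnostic for one parameter."""

    parameter: str
    W: float
    V: float
    R: float
    sequences: pd.DataFrame | None = None


@dataclass
class DICResult:
    mean_deviance: float  # Dbar
    deviance_at_mean: float  # D(thetabar)
    p_d: float
    dic: float


class PosteriorSummary(pd.DataFrame):
    """Per-parameter PM, SD and 95% equal-tail CI (a plain DataFrame)."""

    @property
    def _constructor(self):
        return PosteriorSummary


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior mean, SD and (2.5%, 97.5%) quantiles, pooled over chains."""
    pooled = np.concatenate(draws.chains, axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least two retained draws to summarise")
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=0)
    out = PosteriorSummary(
        {
            "PM": pooled.mean(axis=0),
            "SD": pooled.std(axis=0, ddof=1),
            "ci_low": lo,
            "ci_high": hi,
        },
        index=pd.Index(draws.param_names, name="parameter"),
    )
    return out


def gelman_rubin(
    draws: PosteriorDraws, parameter: str, sequences: bool = False
) -> GRResult:
    """Original variance-ratio Gelman-Rubin diagnostic (no rank-normalisation).

    With ``sequences=True`` the result carries W, V and R computed over
    increasing chain prefixes, the data behind the dynamic diagnostic plot.
    """
    arr = draws.get(parameter)  # (C, m)
    C, m = arr.shape
    if C < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    if m < 4:
        raise ValueError("Gelman-Rubin needs at least four draws per chain")

    def _wvr(a: np.ndarray):
        mm = a.shape[1]
        W = float(a.var(axis=1, ddof=1).mean())
        B = mm * float(a.mean(axis=1).var(ddof=1))
        V = (mm - 1) / mm * W + B / mm
        return W, V, V / W

    W, V, R = _wvr(arr)
    seq = None
    if sequences:
        lens = np.unique(np.linspace(4, m, min(m - 3, 50)).astype(int))
        rows = []
        for L in lens:
            w, v, r = _wvr(arr[:, :L])
            rows.append({"length": L, "W": w, "V": v, "R": r})
        seq = pd.DataFrame(rows)
    return GRResult(parameter=parameter, W=W, V=V, R=R, sequences=seq)


def _project_pd(S: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    if vals.min() > 0:
        return S
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def posterior_mean_state(draws: PosteriorDraws) -> ParameterState:
    """Componentwise posterior-mean state (Sigma matrices PD-projected if
    the elementwise average is numerically indefinite)."""
    if draws.packer is None or draws.b_mean is None:
        raise ValueError("posterior-mean state requires an in-memory draws object")
    parts = draws.packer.unpack_mean(draws.posterior_mean_vector())
    return ParameterState(
        beta=parts["beta"],
        b=draws.b_mean,
        w=draws.w_mean,
        Sigma_b=_project_pd(parts["Sigma_b"]),
        Sigma_K=_project_pd(parts["Sigma_K"]),
        delta=parts["delta"],
        upsilon=parts["upsilon"],
        alpha=parts["alpha"],
        hazard_increments=draws.increments_mean,
    )


def dic(
    draws: PosteriorDraws,
    designs: DesignMatrices,
    sdesign: SurvivalDesign,
) -> DICResult:
    """DIC from the conditional joint deviance.

    The per-draw deviance is recorded during sampling; the plug-in deviance
    is evaluated at the componentwise posterior means (including the
    random-effect and latent means).
    """
    dev = np.concatenate(draws.deviance)
    if not np.all(np.isfinite(dev)):
        raise ValueError("stored deviances are missing or non-finite")
    dbar = float(dev.mean())
    state = posterior_mean_state(draws)
    d_at_mean = -2.0 * (
        loglik_long_conditional(state, designs) + loglik_surv_counting(state, sdesign)
    )
    p_d = dbar - d_at_mean
    return DICResult(
        mean_deviance=dbar, deviance_at_mean=d_at_mean, p_d=p_d, dic=dbar + p_d
    )


def hazard_ratios(summary: PosteriorSummary, parameters) -> pd.DataFrame:
    """exp-transform posterior means and CI bounds of log-hazard parameters.

    Returns HR = exp(PM) with CI (exp(ci_low), exp(ci_high)), rounded to 2
    decimals for reporting (full precision is a one-liner on the summary).
    """
    missing = [p for p in parameters if p not in summary.index]
    if missing:
        raise KeyError(f"parameters not in summary: {missing}")
    rows = summary.loc[list(parameters)]
    out = pd.DataFrame(
        {
            "HR": np.exp(rows["PM"]),
            "HR_low": np.exp(rows["ci_low"]),
            "HR_high": np.exp(rows["ci_high"]),
        },
        index=rows.index,
    )
    return out.round(2)


def fitted_trajectories(
    summary: PosteriorSummary,
    spec: ModelSpec,
    times: np.ndarray,
    covariates: dict,
    draws: PosteriorDraws | None = None,
    subjects=None,
) -> pd.DataFrame:
    """Population and (optionally) subject-level fitted growth curves.

    The population curve is ``X(t) @ PM(beta)`` per outcome; subject curves
    add ``Z(t) @ PM(b_i)`` using the stored random-effect means.  Because the
    skew-normal error is centred (its location absorbs ``-sqrt(2/pi) delta``),
    the marginal error mean is zero and no additional offset enters the
    fitted curve under either variant.
    """
    times = np.asarray(times, float)
    cols = {
        "intercept": np.ones_like(times),
        "time": times,
        "time2": times**2,
    }
    for name, val in covariates.items():
        cols[name] = np.full_like(times, float(val))
    X = np.column_stack([cols[t] for t in spec.fixed_terms])
    Z = np.column_stack([cols[t] for t in spec.random_terms])
    frames = []
    for k, outcome in enumerate(spec.outcomes):
        beta_k = np.array(
            [summary.loc[f"beta{t}{k + 1}", "PM"] for t in range(spec.n_fixed)]
        )
        df = pd.DataFrame({"outcome": outcome, "time": times, "population": X @ beta_k})
        if draws is not None and subjects is not None:
            if draws.b_mean is None:
                raise ValueError("subject curves need an in-memory draws object")
            for s in subjects:
                df[f"subject_{s}"] = df["population"] + Z @ draws.b_mean[int(s), k]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def kaplan_meier(surv: SurvivalDataset):
    """Product-limit survival estimate with right censoring.

    Returns ``(times, survival)`` step-function arrays starting at
    ``(0, 1)``.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(surv.df["time"], surv.df["event"])
    sf = km.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)


def event_fraction(surv: SurvivalDataset) -> float:
    """Observed cumulative event fraction, in percent."""
    if surv.n_subjects == 0:
        raise ValueError("empty survival dataset")
    return 100.0 * surv.n_events / surv.n_subjects


# ---------------------------------------------------------------------------
# plots (data behind each plot is returned so it can also be written as CSV)


def _ensure_agg():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_trace(draws: PosteriorDraws, parameters, path) -> None:
    plt = _ensure_agg()
    parameters = list(parameters)
    fig, axes = plt.subplots(len(parameters), 1, figsize=(7, 2.2 * len(parameters)),
                             squeeze=False)
    for ax, name in zip(axes[:, 0], parameters):
        for c, chain in enumerate(draws.get(name)):
            ax.plot(chain, lw=0.6, label=f"chain {c}")
        ax.set_ylabel(name)
    axes[0, 0].legend(fontsize=7)
    axes[-1, 0].set_xlabel("retained iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gelman_rubin(draws: PosteriorDraws, parameter: str, path) -> pd.DataFrame:
    plt = _ensure_agg()
    res = gelman_rubin(draws, parameter, sequences=True)
    seq = res.sequences
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(seq["length"], seq["R"], label="R (ratio)")
    ax.plot(seq["length"], seq["V"] / seq["V"].iloc[-1], label="V (pooled, scaled)")
    ax.plot(seq["length"], seq["W"] / seq["V"].iloc[-1], label="W (within, scaled)")
    ax.axhline(1.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("chain length")
    ax.set_title(f"Gelman-Rubin diagnostic: {parameter}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return seq


def plot_observed_vs_fitted(draws: PosteriorDraws, designs: DesignMatrices, path) -> pd.DataFrame:
    """Observed against fitted values per outcome.

    Fitted values are X beta-hat + Z b-hat at the posterior means (the
    centred error contributes no offset).
    """
    plt = _ensure_agg()
    if draws.b_mean is None:
        raise ValueError("observed-vs-fitted needs an in-memory draws object")
    state = posterior_mean_state(draws)
    fitted = designs.x @ state.beta.T
    fitted += np.einsum("mq,mkq->mk", designs.z, state.b[designs.subject_index])
    spec = draws.spec
    fig, axes = plt.subplots(1, spec.n_outcomes, figsize=(4.5 * spec.n_outcomes, 4))
    frames = []
    for k, (ax, outcome) in enumerate(zip(np.atleast_1d(axes), spec.outcomes)):
        obs = designs.y[:, k]
        ax.plot(obs, fitted[:, k], ".", ms=2, alpha=0.5)
        lims = [min(obs.min(), fitted[:, k].min()), max(obs.max(), fitted[:, k].max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"observed {outcome}")
        ax.set_ylabel(f"fitted {outcome}")
        frames.append(
            pd.DataFrame({"outcome": outcome, "observed": obs, "fitted": fitted[:, k]})
        )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return pd.concat(frames, ignore_index=True)


def plot_kaplan_meier(surv: SurvivalDataset, path) -> pd.DataFrame:
    plt = _ensure_agg()
    t, s = kaplan_meier(surv)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(t, s, where="post")
    ax.set_xlabel("time (years)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return pd.DataFrame({"time": t, "survival": s})
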