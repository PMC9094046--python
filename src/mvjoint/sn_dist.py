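"""Sahu-type skew-normal (SN) distribution for longitudinal error terms.

The distribution is defined by the stochastic representation

    y = mu + delta * w + sigma * z,   w ~ N(0, 1) truncated to (0, inf),
                                      z ~ N(0, 1) independent of w,

which gives the two-factor density

    f(y) = 2 * phi(y; mu, sigma^2 + delta^2)
             * Phi( delta * (y - mu) / (sigma * sqrt(sigma^2 + delta^2)) ),

with mean ``mu + sqrt(2/pi) * delta`` and variance
``sigma^2 + delta^2 * (1 - 2/pi)``.  Setting the location to
``-sqrt(2/pi) * delta`` therefore centres the distribution at zero, which is
how the SN error enters the longitudinal mixed model: the half-normal latent
``w`` is shared across outcomes at a visit while each outcome carries its own
skewness coefficient ``delta_k``.

The density is continuous in ``delta`` and reduces *exactly* to the normal
density at ``delta = 0`` (the skewing factor becomes Phi(0) = 1/2 and cancels
the leading 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "HALF_NORMAL_MEAN",
    "SNParams",
    "sn_logpdf",
    "sn_pdf",
    "sn_mean",
    "sn_var",
    "sn_sample",
    "centered_params",
]

#: E[w] for a standard half-normal latent; also the centering constant.
HALF_NORMAL_MEAN: float = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class SNParams:
    """Parameters of a univariate Sahu-type skew normal.

    Attributes
    ----------
    location : float
        Location ``mu`` (not the mean unless ``skew == 0``).
    scale_sq : float
        Variance ``sigma^2`` of the symmetric normal component; must be > 0.
    skew : float
        Skewness coefficient ``delta``; unrestricted in sign.
    """

    location: float = 0.0
    scale_sq: float = 1.0
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale_sq > 0:
            raise ValueError(f"scale_sq must be positive, got {self.scale_sq}")

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.scale_sq))


def centered_params(scale_sq: float, skew: float) -> SNParams:
    """SN parameters with location chosen so the mean is exactly zero."""
    return SNParams(location=-HALF_NORMAL_MEAN * skew, scale_sq=scale_sq, skew=skew)


def sn_logpdf(y, params: SNParams):
    """Log density of the Sahu-type skew normal, vectorised over ``y``."""
    y = np.asarray(y, dtype=float)
    mu, s2, d = params.location, params.scale_sq, params.skew
    tot = s2 + d * d
    resid = y - mu
    log_phi = -0.5 * np.log(2.0 * np.pi * tot) - 0.5 * resid * resid / tot
    t = d * resid / (np.sqrt(s2) * np.sqrt(tot))
    out = np.log(2.0) + log_phi + special.log_ndtr(t)
    return out if out.ndim else float(out)


def sn_pdf(y, params: SNParams):
    return np.exp(sn_logpdf(y, params))


def sn_mean(params: SNParams) -> float:
    """Mean ``mu + sqrt(2/pi) * delta``."""
    return params.location + HALF_NORMAL_MEAN * params.skew


def sn_var(params: SNParams) -> float:
    """Variance ``sigma^2 + delta^2 * (1 - 2/pi)``."""
    return params.scale_sq + params.skew**2 * (1.0 - 2.0 / np.pi)


def sn_sample(params: SNParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` variates via the positive-latent representation.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  The
    half-normal latent is simulated as ``|N(0,1)|`` (equivalent to truncation
    at zero).  Reproducible: a fixed integer seed yields identical output.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.abs(rng.standard_normal(n))
    z = rng.standard_normal(n)
    return params.location + params.skew * w + params.scale * z
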