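"""Probability kernels of the nested MPRA count model.

The model assumes latent construct (DNA) abundances follow a Gamma
distribution and that transcript (RNA) counts, conditional on the construct
abundance ``x``, are Poisson with rate ``alpha * x``, where ``alpha`` is the
transcription rate.  Marginalising the latent layer yields a closed-form
negative binomial for the counts, parameterised by its mean ``mu`` and size
(dispersion) ``psi``::

    r ~ NB(mu = alpha * k / b,  psi = k)      Var(r) = mu + mu**2 / psi

with ``k``/``b`` the Gamma shape and rate.  Everything here is computed in
log space; :func:`gamma_poisson_marginal` performs the mixture integral by
quadrature and serves as the independent numerical oracle for
:func:`nb_logpmf`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "GammaParams",
    "NBParams",
    "gamma_logdensity",
    "nb_logpmf",
    "nb_logpmf_mu",
    "gamma_poisson_marginal",
]


@dataclass(frozen=True)
class GammaParams:
    """Shape/rate parameters of the latent construct-count distribution."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError(
                f"Gamma shape and rate must be positive, got "
                f"shape={self.shape}, rate={self.rate}"
            )

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class NBParams:
    """Mean/size parameterisation of the negative binomial.

    ``psi`` is the size (dispersion) parameter; the variance is
    ``mu + mu**2 / psi``, so larger ``psi`` means closer to Poisson.
    """

    mu: float
    psi: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.psi > 0):
            raise ValueError(
                f"NB mean and size must be positive, got mu={self.mu}, psi={self.psi}"
            )


def gamma_logdensity(x, p: GammaParams):
    """Log-density of Gamma(shape, rate) at ``x > 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gamma_logdensity requires x > 0")
    out = stats.gamma.logpdf(x, a=p.shape, scale=1.0 / p.rate)
    return out if out.shape else float(out)


def nb_logpmf_mu(r, mu, psi):
    """Vectorised NB log-pmf in (mean, size) form.

    Valid for any nonnegative integer array ``r`` and positive ``mu``,
    ``psi``; used in hot loops by the fitting layer (no scalar validation).
    """
    r = np.asarray(r, dtype=float)
    mu = np.asarray(mu, dtype=float)
    psi = np.asarray(psi, dtype=float)
    # log C(r+psi-1, r) + psi*log(psi/(psi+mu)) + r*log(mu/(psi+mu))
    lognorm = special.gammaln(r + psi) - special.gammaln(psi) - special.gammaln(r + 1)
    logratio = np.log(psi + mu)
    return lognorm + psi * (np.log(psi) - logratio) + r * (np.log(mu) - logratio)


def nb_logpmf(r, p: NBParams):
    """NB log-pmf at nonnegative integer ``r`` with mean ``p.mu``, size ``p.psi``."""
    arr = np.asarray(r)
    if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("nb_logpmf requires nonnegative integer r")
    out = nb_logpmf_mu(arr, p.mu, p.psi)
    return out if out.shape else float(out)


def gamma_poisson_marginal(r: int, alpha: float, p: GammaParams) -> float:
    """Log-probability of observing ``r`` counts under the two-stage process.

    Integrates ``Poisson(r; alpha*x) * Gamma(x; shape, rate)`` over the latent
    abundance ``x`` by adaptive quadrature.  Mathematically identical to
    ``nb_logpmf(r, mu=alpha*shape/rate, psi=shape)``; kept as a brute-force
    cross-check of that closed form.
    """
    if r < 0 or r != int(r):
        raise ValueError("r must be a nonnegative integer")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    r = int(r)

    lognorm_g = p.shape * np.log(p.rate) - special.gammaln(p.shape)
    logfact = special.gammaln(r + 1)

    def integrand(x: float) -> float:
        # Poisson(r; alpha x) * Gamma(x; k, b), assembled in log space
        logp = (
            r * np.log(alpha * x)
            - alpha * x
            - logfact
            + lognorm_g
            + (p.shape - 1) * np.log(x)
            - p.rate * x
        )
        return np.exp(logp)

    # the integrand is proportional to a Gamma(r+shape, alpha+rate) density:
    # integrate over that density's effective support, peaked near its mode
    post = stats.gamma(a=r + p.shape, scale=1.0 / (alpha + p.rate))
    upper = float(post.isf(1e-18))
    mode = max((r + p.shape - 1) / (alpha + p.rate), upper * 1e-6)
    val, err = integrate.quad(
        integrand,
        0.0,
        upper,
        points=[mode / 4, mode, min(mode * 4, upper)],
        limit=400,
        epsabs=0.0,
        epsrel=1e-12,
    )
    if val <= 0 or not np.isfinite(val):
        raise ArithmeticError(
            f"quadrature failed for r={r}, alpha={alpha}, params={p}: value={val}"
        )
    if err > max(abs(val), 1e-300) * 1e-6:
        raise ArithmeticError(
            f"quadrature did not converge: value={val}, abs err estimate={err}"
        )
    return float(np.log(val))
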