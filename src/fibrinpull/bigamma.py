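"""Bivariate Gamma distribution with Gamma marginals and shared-component
dependence.

The pair (F, X) of peak force and peak-to-peak distance is built by
trivariate reduction::

    F = beta_f * (Y0 + Y1),   X = beta_x * (Y0 + Y2)

with independent Y0 ~ Gamma(lambda), Y1 ~ Gamma(alpha_f), Y2 ~ Gamma(alpha_x)
(unit scale).  Both marginals are Gamma — F ~ Gamma(lambda + alpha_f,
beta_f) — and the shared component Y0 carries the dependence:

    cov(F, X) = beta_f * beta_x * lambda.

The parameter map from moments (mu_f, mu_x, sd_f, sd_x, cov_fx) is the
moment inversion

    beta_f = sd_f^2 / mu_f,  k_f = (mu_f / sd_f)^2,  lambda = cov / (beta_f beta_x),
    alpha_f = k_f - lambda   (and symmetrically for x),

which is feasible iff 0 <= lambda <= min(k_f, k_x); only non-negative
dependence is representable.

The joint density requires integrating out Y0.  With u = f/beta_f,
v = x/beta_x and m = min(u, v),

    p(u, v) = e^{-(u+v)} / (G(l) G(a) G(a'))
              * INT_0^m y^{l-1} (m-y)^{c-1} g(y) e^{y} dy

where the integrand's endpoint power singularities (y^{l-1} at 0 and
(m-y)^{c-1} at m, c being the shape paired with the smaller of u, v) are
absorbed exactly into a Gauss-Jacobi rule, leaving a smooth remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, roots_jacobi
from scipy.stats import gamma as gamma_dist

#: below this, the shared component is treated as absent (independence).
_LAMBDA_TINY = 1e-10


class ParameterizationError(ValueError):
    """Raised when a moment block cannot be realized by the shared-component
    bivariate Gamma construction."""


@dataclass(frozen=True)
class GammaShapes:
    """Shape/scale block: idiosyncratic shapes ``alpha_f``/``alpha_x``,
    scales ``beta_f``/``beta_x`` and shared shape ``lam``."""

    alpha_f: float
    alpha_x: float
    beta_f: float
    beta_x: float
    lam: float

    @property
    def shape_f(self) -> float:
        """Marginal force shape lambda + alpha_f."""
        return self.lam + self.alpha_f

    @property
    def shape_x(self) -> float:
        return self.lam + self.alpha_x


def moments_to_shapes(
    mu_f: float,
    mu_x: float,
    sd_f: float,
    sd_x: float,
    cov_fx: float = 0.0,
    label: str = "component",
) -> GammaShapes:
    """Invert (mu, sd, cov) moments to the shape/scale block.

    Raises :class:`ParameterizationError` when the required shared shape
    lambda = cov/(beta_f beta_x) is negative or exceeds a marginal shape.
    """
    if mu_f <= 0 or mu_x <= 0 or sd_f <= 0 or sd_x <= 0:
        raise ParameterizationError(f"{label}: means and SDs must be positive")
    beta_f = sd_f**2 / mu_f
    beta_x = sd_x**2 / mu_x
    k_f = (mu_f / sd_f) ** 2
    k_x = (mu_x / sd_x) ** 2
    lam = cov_fx / (beta_f * beta_x)
    if lam < -_LAMBDA_TINY:
        raise ParameterizationError(
            f"{label}: covariance {cov_fx} < 0 is not representable by the "
            "shared-component construction (lambda would be negative)"
        )
    lam = max(lam, 0.0)
    kmin = min(k_f, k_x)
    if lam > kmin * (1 + 1e-12):
        raise ParameterizationError(
            f"{label}: required shared shape lambda={lam:.4g} exceeds the "
            f"smaller marginal shape {kmin:.4g} "
            f"(covariance {cov_fx} too large for these means/SDs)"
        )
    lam = min(lam, kmin)
    return GammaShapes(k_f - lam, k_x - lam, beta_f, beta_x, lam)


def shapes_to_moments(s: GammaShapes) -> tuple[float, float, float, float, float]:
    """Inverse map: (mu_f, mu_x, sd_f, sd_x, cov_fx)."""
    mu_f = s.beta_f * s.shape_f
    mu_x = s.beta_x * s.shape_x
    sd_f = s.beta_f * np.sqrt(s.shape_f)
    sd_x = s.beta_x * np.sqrt(s.shape_x)
    cov = s.beta_f * s.beta_x * s.lam
    return mu_f, mu_x, sd_f, sd_x, cov


def sample(s: GammaShapes, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (f, x) pairs by trivariate reduction."""
    y0 = rng.gamma(s.lam, 1.0, n) if s.lam > _LAMBDA_TINY else np.zeros(n)
    y1 = rng.gamma(s.alpha_f, 1.0, n) if s.alpha_f > _LAMBDA_TINY else np.zeros(n)
    y2 = rng.gamma(s.alpha_x, 1.0, n) if s.alpha_x > _LAMBDA_TINY else np.zeros(n)
    return s.beta_f * (y0 + y1), s.beta_x * (y0 + y2)


def logpdf(
    f: np.ndarray, x: np.ndarray, s: GammaShapes, n_nodes: int = 64
) -> np.ndarray:
    """Log joint density at paired arrays (f, x); -inf off the support."""
    f = np.asarray(f, dtype=float)
    x = np.asarray(x, dtype=float)
    out = np.full(np.broadcast(f, x).shape, -np.inf)
    ok = (f > 0) & (x > 0)
    if not ok.any():
        return out
    if s.lam <= _LAMBDA_TINY:
        out[ok] = gamma_dist.logpdf(
            f[ok], s.shape_f, scale=s.beta_f
        ) + gamma_dist.logpdf(x[ok], s.shape_x, scale=s.beta_x)
        return out
    u = f[ok] / s.beta_f
    v = x[ok] / s.beta_x
    val = np.empty(u.shape)
    const = (
        -gammaln(s.lam)
        - gammaln(s.alpha_f)
        - gammaln(s.alpha_x)
        - np.log(s.beta_f * s.beta_x)
    )
    # split by which coordinate limits the shared component
    for m_is_u in (True, False):
        grp = u < v if m_is_u else u >= v
        if not grp.any():
            continue
        m = u[grp] if m_is_u else v[grp]
        other = v[grp] if m_is_u else u[grp]
        c = s.alpha_f if m_is_u else s.alpha_x  # exponent paired with m
        a_other = s.alpha_x if m_is_u else s.alpha_f
        nodes, weights = roots_jacobi(n_nodes, c - 1.0, s.lam - 1.0)
        y = 0.5 * m[:, None] * (nodes[None, :] + 1.0)  # (n_grp, K)
        with np.errstate(divide="ignore"):
            log_g = (a_other - 1.0) * np.log(other[:, None] - y) + y
        log_terms = np.log(weights)[None, :] + log_g
        tmax = log_terms.max(axis=1)
        log_sum = tmax + np.log(np.exp(log_terms - tmax[:, None]).sum(axis=1))
        log_i = (s.lam + c - 1.0) * np.log(0.5 * m) + log_sum
        val[grp] = const - (u[grp] + v[grp]) + log_i
    out[ok] = val
    return out


def marginal_force_logpdf(f: np.ndarray, s: GammaShapes) -> np.ndarray:
    """Log density of the Gamma force marginal."""
    return gamma_dist.logpdf(np.asarray(f, dtype=float), s.shape_f, scale=s.beta_f)
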