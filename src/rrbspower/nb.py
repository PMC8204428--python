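"""Negative-binomial model of sequencing read depth.

Read depth across DNAm points is over-dispersed count data and is
modelled as NB(mu, r) with variance mu + mu**2 / r.  The dispersion r is
recovered from a pooled sample of depths by the method of moments:

    r = (mu**2 / var) / (1 - mu / var)

which is exact algebra on the NB mean/variance parameterisation
(equivalently r = mu**2 / (var - mu)).  Simulated depths are drawn from
the fitted NB conditioned on exceeding a minimum (depth 0 means "no
DNAm point", so simulation always truncates at >= 1); truncation is by
rejection so the shape of the distribution above the cut is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["NBDepthModel", "DispersionError", "estimate_r", "sample_depths"]

#: acceptance probability below which truncated sampling is refused
_MIN_ACCEPTANCE = 1e-6


class DispersionError(ValueError):
    """Raised when depths are under- or equi-dispersed (variance <= mean)."""

    def __init__(self, mu: float, var: float):
        self.mu = mu
        self.var = var
        super().__init__(
            f"variance ({var:g}) does not exceed mean ({mu:g}); the "
            "negative-binomial dispersion r is undefined"
        )


@dataclass(frozen=True)
class NBDepthModel:
    """NB(mu, r): mean read depth and dispersion."""

    mu: float
    r: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.r > 0):
            raise ValueError("mu and r must be positive")

    @property
    def p(self) -> float:
        """Success probability in the (p, r) parameterisation, in (0, 1)."""
        return self.mu / (self.mu + self.r)

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 / self.r

    def _scipy_dist(self):
        # scipy's nbinom uses n = r and p = r / (r + mu)
        return stats.nbinom(self.r, self.r / (self.r + self.mu))


def estimate_r(
    depths, *, fallback_r_cap: float | None = None
) -> NBDepthModel:
    """Method-of-moments NB fit from pooled read depths.

    Computes the sample mean and unbiased (n-1) variance over the
    flattened input.  When variance <= mean the NB dispersion is
    undefined; a :class:`DispersionError` is raised unless
    ``fallback_r_cap`` is given, in which case r is capped at that value
    (1e6 is effectively Poisson) and a warning is emitted.
    """
    x = np.asarray(depths, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 depth values")
    mu = float(x.mean())
    if mu <= 0:
        raise ValueError("mean depth must be positive")
    var = float(x.var(ddof=1))
    if var <= mu:
        if fallback_r_cap is None:
            raise DispersionError(mu, var)
        warnings.warn(
            f"variance ({var:g}) <= mean ({mu:g}); capping r at "
            f"{fallback_r_cap:g} (near-Poisson)",
            stacklevel=2,
        )
        return NBDepthModel(mu=mu, r=float(fallback_r_cap))
    r = (mu**2 / var) / (1.0 - mu / var)
    if fallback_r_cap is not None and r > fallback_r_cap:
        r = float(fallback_r_cap)
    return NBDepthModel(mu=mu, r=r)


def sample_depths(
    model: NBDepthModel,
    n: int,
    min_depth: int = 1,
    rng: np.random.Generator | None = None,
    size: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Draw depths from NB(mu, r) conditioned on depth >= min_depth.

    Rejection sampling: values below the cut are redrawn, so the
    distribution is the exact truncated NB.  ``size`` overrides ``n``
    with an arbitrary output shape.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    shape = size if size is not None else (int(n),)
    if int(np.prod(shape)) < 1:
        raise ValueError("need at least one draw")

    accept = float(model._scipy_dist().sf(min_depth - 1))
    if accept < _MIN_ACCEPTANCE:
        raise ValueError(
            f"P(depth >= {min_depth}) = {accept:.2e} under NB(mu={model.mu:g}, "
            f"r={model.r:g}); min_depth is incompatible with the model"
        )

    # scipy/numpy NB draws: n = r, p = r / (r + mu)
    p = model.r / (model.r + model.mu)
    out = rng.negative_binomial(model.r, p, size=shape)
    bad = out < min_depth
    while bad.any():
        out[bad] = rng.negative_binomial(model.r, p, size=int(bad.sum()))
        bad = out < min_depth
    return out
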