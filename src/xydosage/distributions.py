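"""Small distribution-spec language used by the simulators.

A law is a tuple ``(name, *params)``; the simulators draw from it with a
shared :class:`numpy.random.Generator` so that a single seed fixes every
random choice. Supported laws:

``("point", v)``
    Degenerate distribution at ``v``.
``("normal", mu, sd)``
    Gaussian.
``("lognormal", mu, sigma)``
    ``exp(Normal(mu, sigma))``.
``("uniform", lo, hi)``
    Uniform on ``[lo, hi)``.
``("uniform_signed", lo, hi)``
    Magnitude uniform on ``[lo, hi)`` with an independent random sign;
    convenient for effect sizes that may go either way.
``("exponential", scale)``
    Exponential with the given mean.
``("gamma", shape, scale)``
    Gamma.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

Law = Sequence

_LAW_NAMES = {
    "point",
    "normal",
    "lognormal",
    "uniform",
    "uniform_signed",
    "exponential",
    "gamma",
}


def draw(law: Law, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` variates from a distribution spec."""
    if not law or law[0] not in _LAW_NAMES:
        raise ValueError(f"unknown distribution law: {law!r}")
    name, *params = law
    if name == "point":
        return np.full(size, float(params[0]))
    if name == "normal":
        mu, sd = params
        return rng.normal(mu, sd, size)
    if name == "lognormal":
        mu, sigma = params
        return rng.lognormal(mu, sigma, size)
    if name == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size)
    if name == "uniform_signed":
        lo, hi = params
        mag = rng.uniform(lo, hi, size)
        sign = rng.choice([-1.0, 1.0], size)
        return mag * sign
    if name == "exponential":
        (scale,) = params
        return rng.exponential(scale, size)
    if name == "gamma":
        shape, scale = params
        return rng.gamma(shape, scale, size)
    raise AssertionError("unreachable")
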