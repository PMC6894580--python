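"""Independent oracles used by the test suite.

These deliberately avoid the package's own simulation code paths: the
bounce-count oracle unfolds constant-speed reflections analytically, and
the chance-null oracle integrates the Rayleigh approximation to the
resultant length of uniform angles.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate


def bounce_count_1d(u0: float, v: float, length: float, t_end: float) -> int:
    """Number of boundary contacts of a 1-D reflected motion.

    ``u0`` is the start offset from the lower wall, ``v`` the signed
    constant velocity, ``length`` the distance between the walls. In the
    unfolded (mirror-image) picture the trajectory is the straight line
    u0 + v t and every boundary contact is a crossing of an integer
    multiple of ``length``.
    """
    f0 = math.floor(u0 / length)
    f1 = math.floor((u0 + v * t_end) / length)
    return abs(f1 - f0)


def bounce_count_2d(
    x0: float,
    y0: float,
    heading_x: int,
    heading_y: int,
    speed: float,
    half_extent: float,
    t_end: float,
    width: float = 700.0,
    height: float = 600.0,
) -> int:
    """Total bounce events of a constant-speed diagonal mover.

    The two axes reflect independently, so the count is the sum of two
    1-D crossing counts (a corner contact contributes two events, one
    per axis, matching the simulator's convention).
    """
    v = speed / math.sqrt(2.0)
    lx = width - 2.0 * half_extent
    ly = height - 2.0 * half_extent
    nx = bounce_count_1d(x0 - half_extent, heading_x * v, lx, t_end)
    ny = bounce_count_1d(y0 - half_extent, heading_y * v, ly, t_end)
    return nx + ny


def rayleigh_angular_deviation_mean_deg(n: int) -> float:
    """E[sqrt(2 (1 - R))] in degrees for the resultant length R of n
    uniform angles, using the Rayleigh approximation R ~ Rayleigh(sigma)
    with sigma^2 = 1 / (2 n)."""
    sigma2 = 1.0 / (2.0 * n)

    def integrand(r: float) -> float:
        pdf = (r / sigma2) * math.exp(-(r**2) / (2.0 * sigma2))
        return math.sqrt(2.0 * (1.0 - r)) * pdf

    val, _ = integrate.quad(integrand, 0.0, 1.0)
    return math.degrees(val)


def rayleigh_angular_deviation_quantile_deg(n: int, q: float) -> float:
    """Quantile of the per-batch angular deviation under the Rayleigh
    approximation (monotone decreasing in R)."""
    sigma = math.sqrt(1.0 / (2.0 * n))
    # deviation quantile q corresponds to R quantile 1 - q
    r = sigma * math.sqrt(-2.0 * math.log(q))
    return math.degrees(math.sqrt(2.0 * (1.0 - r)))
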