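"""Farnsworth D-15 colour-arrangement scoring.

Implements moment-of-inertia scoring of the D-15 panel: the subject's cap
sequence is turned into colour-difference vectors in CIELUV (u*, v*)
chromaticity space, the second-moment (inertia) ellipse of those vectors
is computed, and the confusion index is the ratio of the subject's major
radius to that of the perfectly ordered panel. A perfect arrangement
scores exactly 1.00; values above 1.78 are the conventional cut-off for a
colour-vision deficiency severe enough to compromise hue reports.

The cap chromaticities are the standard published coordinates for the
saturated D-15 panel (reference cap followed by caps 1-15) and ship as a
package constant so no external table is needed.

By default the difference vectors are formed between consecutively
*placed* caps only (14 vectors), which makes the index a pure function of
the placed sequence and exactly invariant under order reversal; the
vector from the fixed reference cap to the first placed cap can be
included with ``include_reference=True``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "D15_CAP_UV",
    "D15_THRESHOLD",
    "identity_arrangement",
    "score_d15",
    "exceeds_d15_threshold",
    "random_deficient_arrangement",
]

#: CIELUV (u*, v*) chromaticities of the D-15 caps; key 0 is the fixed
#: reference (pilot) cap, keys 1-15 the movable caps in perfect order.
D15_CAP_UV: dict[int, tuple[float, float]] = {
    0: (-21.54, -38.39),
    1: (-23.26, -25.56),
    2: (-22.41, -15.53),
    3: (-23.11, -7.45),
    4: (-22.45, 1.09),
    5: (-21.67, 7.35),
    6: (-14.08, 18.74),
    7: (-2.72, 28.13),
    8: (14.84, 31.13),
    9: (23.87, 26.35),
    10: (31.82, 14.76),
    11: (33.70, 6.99),
    12: (34.75, 0.27),
    13: (34.77, -9.36),
    14: (29.58, -22.01),
    15: (24.47, -31.22),
}

#: Confusion-index cut-off (strictly greater than) used for screening.
D15_THRESHOLD = 1.78


def identity_arrangement() -> tuple[int, ...]:
    """The perfectly ordered arrangement, caps 1 through 15."""
    return tuple(range(1, 16))


def _major_radius(
    arrangement: Sequence[int],
    cap_uv: dict[int, tuple[float, float]],
    include_reference: bool,
) -> float:
    seq = ([0] if include_reference else []) + list(arrangement)
    pts = np.array([cap_uv[c] for c in seq])
    d = np.diff(pts, axis=0)
    # second-moment (inertia) matrix of the difference vectors
    uu = float(np.sum(d[:, 0] ** 2))
    vv = float(np.sum(d[:, 1] ** 2))
    uv = float(np.sum(d[:, 0] * d[:, 1]))
    half_tr = 0.5 * (uu + vv)
    half_diff = np.hypot(0.5 * (uu - vv), uv)
    lam_major = half_tr + half_diff
    return float(np.sqrt(lam_major / len(d)))


def score_d15(
    arrangement: Sequence[int],
    cap_uv: dict[int, tuple[float, float]] | None = None,
    include_reference: bool = False,
) -> float:
    """Confusion index of a D-15 arrangement.

    ``arrangement`` must be a permutation of the caps 1-15 in placed
    order. Returns the ratio of the inertia ellipse's major radius to the
    perfect arrangement's major radius (1.00 for a perfect ordering).
    """
    cap_uv = cap_uv or D15_CAP_UV
    arr = list(arrangement)
    if sorted(arr) != list(range(1, 16)):
        raise ValueError("arrangement must be a permutation of caps 1-15")
    major = _major_radius(arr, cap_uv, include_reference)
    perfect = _major_radius(identity_arrangement(), cap_uv, include_reference)
    return major / perfect


def exceeds_d15_threshold(confusion_index: float, threshold: float = D15_THRESHOLD) -> bool:
    """Screening rule: excluded only when strictly above the threshold."""
    return confusion_index > threshold


def random_deficient_arrangement(
    severity: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Corrupt the perfect arrangement by ``severity`` random cap swaps.

    A crude generative stand-in for a colour-deficient subject: each swap
    exchanges two random positions, producing long difference vectors and
    hence a raised confusion index (severity around 4 typically crosses
    the 1.78 cut-off).
    """
    arr = np.array(identity_arrangement())
    for _ in range(max(0, int(severity))):
        i, j = rng.choice(15, size=2, replace=False)
        arr[i], arr[j] = arr[j], arr[i]
    return tuple(int(c) for c in arr)
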