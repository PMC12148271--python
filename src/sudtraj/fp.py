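"""Fractional-polynomial (FP) bases of age.

Royston-Altman convention: powers are drawn from
``{-2, -1, -0.5, 0, 0.5, 1, 2, 3}``, power 0 means ``log(x)``, and a repeated
power ``p`` contributes ``x**p * log(x)`` for each repeat.  Ages are rescaled
to decades (``age / 10``) before the powers are applied so the basis columns
stay well conditioned across the 8-70y span.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np

__all__ = ["FP_POWERS", "fp_basis", "fp_power_sets"]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

AGE_SCALE = 10.0


def fp_basis(age, powers, scale=AGE_SCALE):
    """Design columns of the FP basis at the given ages.

    Parameters
    ----------
    age : array-like
        Ages in years; must be positive after rescaling by ``scale``.
    powers : sequence of float
        Multiset of powers from :data:`FP_POWERS` (order irrelevant; repeats
        multiply by an extra log per Royston-Altman).

    Returns
    -------
    ndarray of shape (n, len(powers))
    """
    x = np.asarray(age, dtype=float) / scale
    if np.any(x <= 0):
        raise ValueError("ages must be positive after rescaling")
    powers = sorted(float(p) for p in powers)
    for p in powers:
        if p not in FP_POWERS:
            raise ValueError(f"power {p} not in the FP power set {FP_POWERS}")
    logx = np.log(x)
    cols = []
    prev = None
    prev_col = None
    for p in powers:
        base = logx if p == 0.0 else x**p
        col = prev_col * logx if p == prev else base
        cols.append(col)
        prev, prev_col = p, col
    return np.column_stack(cols)


def fp_power_sets(degree):
    """All power multisets of the given degree (with repetition)."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    return [tuple(c) for c in combinations_with_replacement(FP_POWERS, degree)]
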