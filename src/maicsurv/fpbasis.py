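"""Fractional-polynomial time transforms on the month scale.

The basis follows the usual fractional-polynomial convention: ``t^p`` for a
power ``p != 0`` and ``ln t`` for ``p = 0``; a repeated power ``(p, p)`` maps
to ``(t^p, t^p * ln t)``, so ``(0, 0)`` yields ``(ln t, (ln t)^2)``.
"""

from __future__ import annotations

import numpy as np

#: Standard candidate powers for fractional-polynomial hazard models.
POWER_GRID = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


def _single(t: np.ndarray, p: float) -> np.ndarray:
    if p == 0:
        return np.log(t)
    return t**p


def fp_basis(t, powers):
    """Evaluate the fractional-polynomial basis at times ``t`` (months).

    Parameters
    ----------
    t : array-like
        Strictly positive times in months.
    powers : sequence of 1 or 2 floats
        First- or second-order FP powers, in canonical (sorted) order.

    Returns
    -------
    tuple of ndarray
        ``(f0(t),)`` for a first-order basis, ``(f0(t), f1(t))`` for a
        second-order one.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("fp_basis requires t > 0 (hazard is evaluated at bin midpoints)")
    powers = tuple(float(p) for p in powers)
    if len(powers) == 1:
        return (_single(t, powers[0]),)
    if len(powers) != 2:
        raise ValueError("powers must have length 1 or 2")
    p0, p1 = powers
    f0 = _single(t, p0)
    if p0 == p1:
        # repeated power: second term picks up a ln t factor
        return (f0, f0 * np.log(t))
    return (f0, _single(t, p1))
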