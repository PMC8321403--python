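"""Minimum-image helpers for orthorhombic periodic boxes.

All coordinates are in nm. Only rectangular (orthorhombic) boxes are
supported; triclinic inputs are rejected at the I/O layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_coordinates",
]


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Displacement ``b - a`` mapped to the nearest periodic image.

    Parameters
    ----------
    a, b : array_like, shape (..., 3)
        Points in nm. Broadcast against each other.
    box : array_like, shape (3,)
        Orthorhombic box edge lengths in nm, all > 0.

    Returns
    -------
    ndarray
        Displacement vectors with each component in ``[-box/2, box/2)``.
    """
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be 3 positive edge lengths")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Scalar minimum-image distance(s) between points ``a`` and ``b``."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary cell ``[0, box)`` per axis.

    Values that land exactly on the upper edge after the modulo (a floating
    point artifact) are folded to 0 so the result is safe for periodic
    KD-trees, which require strict ``[0, box)`` membership.
    """
    box = np.asarray(box, dtype=float)
    wrapped = np.mod(np.asarray(coords, dtype=float), box)
    return np.where(wrapped >= box, 0.0, wrapped)
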