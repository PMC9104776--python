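"""Periodic-boundary helpers for orthorhombic boxes.

Only orthorhombic cells are supported: the minimum image is taken
independently per axis by nearest-integer division, which is exact as
long as no distance of interest exceeds half the shortest box edge.
"""

from __future__ import annotations

import numpy as np


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    d : array, shape (..., 3)
        Raw displacement vectors in nm.
    box : array, shape (3,)
        Orthorhombic box edge lengths in nm.
    """
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def wrap_positions(x: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold positions into the primary cell [0, box) per axis."""
    box = np.asarray(box, dtype=float)
    return x - box * np.floor(x / box)
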