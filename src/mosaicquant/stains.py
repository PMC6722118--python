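"""Two-stain brightfield color model (hematoxylin + DAB).

Brightfield absorbance follows Beer-Lambert: each stain contributes optical
density proportional to its local amount along a fixed unit RGB-OD vector,
and the camera sees ``rgb = 255 * 10**(-OD)``.  Unmixing ("color
deconvolution") inverts that projection with the stain matrix.  The vectors
below are the widely used Ruifrok-Johnston values for hematoxylin and DAB;
the third row is their cross product and absorbs any residual signal.

The synthetic renderer uses the forward map and the quantifier the inverse,
so a pixel rendered with DAB amount ``c`` is recovered as ``c`` up to 8-bit
quantization.
"""

from __future__ import annotations

import numpy as np

#: raw (unnormalized) stain OD direction for hematoxylin
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
#: raw stain OD direction for DAB (brown chromogen)
DAB_OD = np.array([0.268, 0.570, 0.776])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def stain_matrix() -> np.ndarray:
    """Rows: unit OD vectors for (hematoxylin, DAB, residual)."""
    h = _unit(HEMATOXYLIN_OD)
    d = _unit(DAB_OD)
    r = _unit(np.cross(h, d))
    return np.stack([h, d, r])


_M = stain_matrix()
_M_INV = np.linalg.inv(_M)


def concentrations_to_rgb(conc: np.ndarray) -> np.ndarray:
    """Render per-pixel stain amounts (..., 3) to an 8-bit RGB image.

    Amounts are in optical-density units along each unit stain vector; zero
    everywhere renders pure white (255, 255, 255).
    """
    od = np.asarray(conc, dtype=float) @ _M
    rgb = 255.0 * np.power(10.0, -od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def rgb_to_concentrations(rgb: np.ndarray) -> np.ndarray:
    """Invert :func:`concentrations_to_rgb` for an 8-bit RGB image.

    Channel values are floored at 1/255 before the log so saturated black
    pixels stay finite.  Returns per-pixel amounts for (hematoxylin, DAB,
    residual); small negative values from quantization noise are possible
    and left to the caller to clip.
    """
    v = np.maximum(np.asarray(rgb, dtype=float), 1.0) / 255.0
    od = -np.log10(v)
    return od @ _M_INV
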