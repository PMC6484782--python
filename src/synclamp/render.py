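"""Synthetic microscope: renders a cell population into a FrameStack.

Phase contrast is emulated as a bright ring (the cell-wall halo) on a dim
background; fluorescence channels carry a uniform per-cell disk intensity.
Raw GFP counts are ``gfp_norm * mcherry`` so that dividing by the
calibration mCherry recovers the normalized level, exactly as the wet-lab
normalization does.
"""

from __future__ import annotations

import numpy as np
from skimage import draw

from .imaging import FrameStack
from .plant import CellState

__all__ = ["render_frame"]

PHASE_BACKGROUND = 15.0   # a.u.
PHASE_RING = 80.0
FLUOR_BACKGROUND = 5.0    # additive background in both fluorescence channels


def render_frame(cells: list[CellState], image_shape: tuple[int, int] = (256, 256),
                 noise_level: float = 0.5,
                 rng: np.random.Generator | None = None,
                 time: float = 0.0,
                 background_region: tuple[int, int, int, int] = (0, 0, 24, 24),
                 ) -> FrameStack:
    """Render phase / GFP / RFP images for the given cells.

    ``noise_level`` is the additive Gaussian noise SD in the same arbitrary
    units as the channels.  Overlapping cells are allowed; a cell whose
    circle extends outside the image raises ``ValueError``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = image_shape
    phase = np.full(image_shape, PHASE_BACKGROUND)
    gfp = np.full(image_shape, FLUOR_BACKGROUND)
    rfp = np.full(image_shape, FLUOR_BACKGROUND)
    for c in cells:
        x, y = c.position
        r = c.radius
        if not (r <= x <= w - 1 - r and r <= y <= h - 1 - r):
            raise ValueError(f"cell {c.cell_id} at {c.position} extends out of bounds")
        rr, cc = draw.circle_perimeter(int(round(y)), int(round(x)),
                                       int(round(r)), shape=image_shape)
        phase[rr, cc] = PHASE_RING
        rr, cc = draw.disk((y, x), r, shape=image_shape)
        gfp[rr, cc] = FLUOR_BACKGROUND + c.concentration * c.mcherry
        rfp[rr, cc] = FLUOR_BACKGROUND + c.mcherry
    if noise_level > 0:
        phase = phase + rng.normal(0.0, noise_level, image_shape)
        gfp = gfp + rng.normal(0.0, noise_level, image_shape)
        rfp = rfp + rng.normal(0.0, noise_level, image_shape)
    return FrameStack(phase=phase, gfp=gfp, rfp=rfp, time=time,
                      background_region=background_region)
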