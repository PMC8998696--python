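"""SDH / COX histoenzymology: per-fiber optical densities and Int-SDH.

Densitometry channels are brightfield-like: dense enzymatic stain absorbs
light, so fibers appear darker than the unstained background.  Optical
density of a pixel is -log10(I / I_bg) with I_bg the modal gray level of the
non-tissue background; a fiber's OD is the mean over its pixels.  The
spatially integrated SDH activity (Int-SDH, OD·µm²) is the product of a
fiber's SDH OD and its CSA and tracks the fiber's total mitochondrial
volume.  SDH and COX share the same code path on different channels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

from ._util import modal_value


def background_mask(fiber_label_map: np.ndarray, clearance_px: int = 5) -> np.ndarray:
    """Non-tissue pixels: outside the (dilated) convex hull of all fibers."""
    if fiber_label_map.max() == 0:
        raise ValueError("no fibers in label map")
    hull = convex_hull_image(fiber_label_map > 0)
    bg = ~ndi.binary_dilation(hull, iterations=clearance_px)
    if not bg.any():
        raise ValueError("no background region left outside the tissue")
    return bg


def measure_optical_density(
    channel: np.ndarray,
    fiber_label_map: np.ndarray,
    background: np.ndarray | None = None,
    normalize: str | None = None,
) -> pd.DataFrame:
    """Mean optical density -log10(I/I_bg) per fiber.

    ``background`` is a boolean mask of stain-free pixels; by default the
    region outside the tissue's convex hull is used and I_bg is its modal
    gray level.  Negative per-fiber means (fiber brighter than background)
    are clipped at 0.  ``normalize="section-median"`` divides all ODs by the
    section median, an opt-in guard against staining batch effects.
    """
    if channel.shape != fiber_label_map.shape:
        raise ValueError("channel and label map must share shape")
    if background is None:
        background = background_mask(fiber_label_map)
    i_bg = modal_value(channel[background])
    if i_bg <= 0:
        raise ValueError("modal background intensity is 0; cannot form OD ratio")
    od_img = -np.log10(np.maximum(channel.astype(float), 1.0) / i_bg)
    ids = np.unique(fiber_label_map)
    ids = ids[ids > 0]
    od = np.array(ndi.mean(od_img, labels=fiber_label_map, index=ids))
    od = np.maximum(od, 0.0)
    if normalize == "section-median" and len(od):
        med = np.median(od)
        if med > 0:
            od = od / med
    return pd.DataFrame({"fiber_id": ids.astype(int), "od": od})


def int_sdh(sdh_od, csa):
    """Spatially integrated SDH activity: OD × CSA (OD·µm²)."""
    sdh_od = np.asarray(sdh_od, dtype=float)
    csa = np.asarray(csa, dtype=float)
    if (sdh_od < 0).any() or (csa < 0).any():
        raise ValueError("sdh_od and csa must be >= 0")
    out = sdh_od * csa
    return float(out) if out.ndim == 0 else out


def enzyme_table(section, fiber_label_map: np.ndarray, fibers: pd.DataFrame) -> pd.DataFrame:
    """Per-fiber SDH OD, COX OD and Int-SDH joined on fiber_id."""
    bg = background_mask(fiber_label_map)
    sdh = measure_optical_density(section["sdh"], fiber_label_map, bg).rename(columns={"od": "sdh_od"})
    cox = measure_optical_density(section["cox"], fiber_label_map, bg).rename(columns={"od": "cox_od"})
    out = fibers[["fiber_id", "csa"]].merge(sdh, on="fiber_id").merge(cox, on="fiber_id")
    out["int_sdh"] = int_sdh(out["sdh_od"], out["csa"])
    return out[["fiber_id", "sdh_od", "cox_od", "int_sdh"]]
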