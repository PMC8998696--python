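"""Capillary detection and the capillary-to-fiber interface index family.

A capillary "contacts" a fiber when it lies within a small apposition
distance (default 1.5 µm, the basal-lamina gap at light-microscopy scale) of
the fiber's boundary.  From the contacts we derive, per fiber:

``CAF``
    number of capillaries around the fiber
``C/Fi``
    capillary-to-fiber ratio; each capillary contributes 1/sharing to every
    fiber it contacts, so summed over fibers the C/Fi values add up exactly
    to the number of fiber-contacting capillaries
``CFPE``
    C/Fi per millimetre of fiber perimeter
``LC`` / ``LC/PF``
    total capillary contact length (arcs from different capillaries merged
    so the index cannot exceed the perimeter) and its percentage of PF
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import find_boundaries

from ._util import relative_histogram


def detect_capillaries(
    cd31_channel: np.ndarray,
    pixel_scale: float,
    min_area: float = 3.0,
    max_area: float = 150.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Label CD31-positive objects within [min_area, max_area] µm².

    ``max_area`` admits elongated capillary profiles hugging a fiber while
    still excluding larger vessels.
    """
    if not 0 < min_area < max_area:
        raise ValueError("need 0 < min_area < max_area")
    img = np.asarray(cd31_channel)
    if img.max() < 60:  # only noise above background
        return np.zeros(img.shape, dtype=np.int32)
    if threshold is None:
        # sparse bright objects defeat plain Otsu; floor at 40% of peak signal
        thr = max(threshold_otsu(img), 0.4 * float(img.max()))
    else:
        thr = threshold
    mask = img >= thr
    lab, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return lab.astype(np.int32)
    sizes = np.bincount(lab.ravel()) * pixel_scale**2
    bad = np.flatnonzero((sizes < min_area) | (sizes > max_area))
    lab[np.isin(lab, bad)] = 0
    ids = np.unique(lab)
    ids = ids[ids > 0]
    remap = np.zeros(lab.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[lab]


def _arc_length_px(coords: np.ndarray, center: np.ndarray, closed: bool = False) -> float:
    """Length of a pixelated arc, ordering pixels by angle around `center`."""
    if len(coords) == 1:
        return 1.0
    ang = np.arctan2(coords[:, 0] - center[0], coords[:, 1] - center[1])
    c = coords[np.argsort(ang)].astype(float)
    steps = np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1]))
    if closed:
        steps = np.append(steps, np.hypot(c[0, 0] - c[-1, 0], c[0, 1] - c[-1, 1]))
    good = steps[steps <= 2.5]  # larger jumps are gaps between separate arcs
    return float(good.sum()) + 1.0


def capillary_fiber_contacts(
    capillary_map: np.ndarray,
    fiber_map: np.ndarray,
    contact_radius: float = 1.5,
    pixel_scale: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-capillary fiber contacts and per-fiber merged contact length.

    Returns ``(contacts, fiber_lc)``: ``contacts`` has one row per
    (capillary, fiber) pair with the contact arc length LCi (µm); ``fiber_lc``
    holds the per-fiber total contact length LC (µm) with overlapping arcs
    merged, so LC never double-counts a stretch of boundary.
    """
    if capillary_map.shape != fiber_map.shape:
        raise ValueError("maps must share shape")
    radius_px = contact_radius / pixel_scale
    empty_contacts = pd.DataFrame(columns=["capillary_id", "fiber_id", "contact_len"])
    empty_lc = pd.DataFrame(columns=["fiber_id", "lc"])
    if capillary_map.max() == 0 or fiber_map.max() == 0:
        return empty_contacts, empty_lc

    boundary = find_boundaries(fiber_map, mode="inner") & (fiber_map > 0)
    dist, (ir, ic) = ndi.distance_transform_edt(capillary_map == 0, return_indices=True)
    br, bc = np.nonzero(boundary)
    near = dist[br, bc] <= radius_px
    br, bc = br[near], bc[near]
    if len(br) == 0:
        return empty_contacts, empty_lc
    cap_ids = capillary_map[ir[br, bc], ic[br, bc]]
    fib_ids = fiber_map[br, bc]

    cap_centers = ndi.center_of_mass(
        capillary_map > 0, capillary_map, np.arange(1, capillary_map.max() + 1)
    )
    fib_centers = {}
    rows = []
    df = pd.DataFrame({"cap": cap_ids, "fib": fib_ids, "r": br, "c": bc})
    for (cap, fib), grp in df.groupby(["cap", "fib"]):
        coords = grp[["r", "c"]].to_numpy()
        center = np.asarray(cap_centers[cap - 1])
        rows.append(
            {
                "capillary_id": int(cap),
                "fiber_id": int(fib),
                "contact_len": _arc_length_px(coords, center) * pixel_scale,
            }
        )
    contacts = pd.DataFrame(rows)

    lc_rows = []
    for fib, grp in df.groupby("fib"):
        coords = grp[["r", "c"]].drop_duplicates().to_numpy()
        if fib not in fib_centers:
            fib_centers[fib] = ndi.center_of_mass(fiber_map == fib)
        center = np.asarray(fib_centers[fib])
        lc_rows.append(
            {"fiber_id": int(fib), "lc": _arc_length_px(coords, center, closed=True) * pixel_scale}
        )
    return contacts, pd.DataFrame(lc_rows)


def capillary_density(capillary_map: np.ndarray, tissue_area: float) -> float:
    """Capillaries per mm² of tissue (``tissue_area`` in mm²)."""
    if tissue_area <= 0:
        raise ValueError("tissue_area must be > 0")
    return float(capillary_map.max()) / tissue_area


def fiber_capillary_indices(
    contacts: pd.DataFrame,
    fibers: pd.DataFrame,
    fiber_lc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """CAF, C/Fi, CFPE (per mm), LC (µm) and LC/PF (%) for every fiber.

    ``fibers`` must carry ``fiber_id`` and ``perimeter``; fibers with no
    contacts get zero indices, fibers with non-positive perimeter are
    excluded.  If ``fiber_lc`` (merged arcs) is given it supplies LC,
    otherwise LC is the plain sum of LCi.
    """
    fibers = fibers[fibers["perimeter"] > 0]
    base = fibers[["fiber_id", "perimeter"]].copy()
    if len(contacts):
        sharing = contacts.groupby("capillary_id")["fiber_id"].nunique().rename("sharing")
        c = contacts.merge(sharing, on="capillary_id")
        agg = c.groupby("fiber_id").agg(
            caf=("capillary_id", "nunique"),
            c_fi=("sharing", lambda s: float((1.0 / s).sum())),
            lc_sum=("contact_len", "sum"),
        )
        base = base.merge(agg, left_on="fiber_id", right_index=True, how="left")
    else:
        base["caf"] = 0.0
        base["c_fi"] = 0.0
        base["lc_sum"] = 0.0
    base[["caf", "c_fi", "lc_sum"]] = base[["caf", "c_fi", "lc_sum"]].fillna(0.0)
    if fiber_lc is not None and len(fiber_lc):
        base = base.merge(fiber_lc, on="fiber_id", how="left")
        base["lc"] = base["lc"].fillna(0.0)
    else:
        base["lc"] = base["lc_sum"]
    base["caf"] = base["caf"].astype(int)
    base["cfpe"] = base["c_fi"] / (base["perimeter"] / 1000.0)  # per mm of perimeter
    base["lc_pf"] = 100.0 * base["lc"] / base["perimeter"]
    return base[["fiber_id", "caf", "c_fi", "cfpe", "lc", "lc_pf"]].reset_index(drop=True)


def lci_histogram(contacts: pd.DataFrame, bin_width: float) -> pd.DataFrame:
    """Relative-frequency histogram of per-capillary contact lengths (LCi)."""
    return relative_histogram(contacts["contact_len"], bin_width)
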