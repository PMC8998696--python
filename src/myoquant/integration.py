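"""Serial-section fiber matching and cross-index correlations.

Serial cross-sections are thin enough that most fibers reappear in every
stain's image.  Matched fibers let us join the capillarization (LC), lipid
(∑LD area) and mitochondrial (Int-SDH) measurements into one per-fiber
table and quantify their coordination with pairwise Pearson correlations
per group × time × fiber-type cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from scipy.spatial import cKDTree

GLOBAL_INDEX_VARS = ("lc", "sum_ld_area", "int_sdh")


def _centroids(label_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = np.unique(label_map)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return ids, np.empty((0, 2))
    cents = np.asarray(ndi.center_of_mass(label_map > 0, label_map, ids))
    return ids, cents


def _iou(map_a: np.ndarray, id_a: int, map_b: np.ndarray, id_b: int) -> float:
    a = map_a == id_a
    b = map_b == id_b
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def _match_pair(map_a: np.ndarray, map_b: np.ndarray, min_iou: float = 0.5) -> pd.DataFrame:
    """Mutual-nearest-centroid matching with an IoU acceptance check."""
    ids_a, cen_a = _centroids(map_a)
    ids_b, cen_b = _centroids(map_b)
    if len(ids_a) == 0 or len(ids_b) == 0:
        return pd.DataFrame(columns=["id_a", "id_b"])
    tree_b = cKDTree(cen_b)
    tree_a = cKDTree(cen_a)
    _, nn_ab = tree_b.query(cen_a)
    _, nn_ba = tree_a.query(cen_b)
    rows = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] != i:
            continue  # not mutual
        if _iou(map_a, int(ids_a[i]), map_b, int(ids_b[j])) < min_iou:
            continue
        rows.append({"id_a": int(ids_a[i]), "id_b": int(ids_b[j])})
    return pd.DataFrame(rows, columns=["id_a", "id_b"])


def match_fibers_across_sections(
    label_maps: list[np.ndarray], min_iou: float = 0.5
) -> pd.DataFrame:
    """One-to-one fiber correspondence across ≥2 serial label maps.

    Column ``map0`` holds ids from the first map, ``map1`` … from the
    others; only fibers matched in every map are kept.
    """
    if len(label_maps) < 2:
        raise ValueError("need at least two label maps")
    shapes = {m.shape for m in label_maps}
    if len(shapes) > 1:
        raise ValueError("label maps must share shape")
    table = _match_pair(label_maps[0], label_maps[1], min_iou).rename(
        columns={"id_a": "map0", "id_b": "map1"}
    )
    for k in range(2, len(label_maps)):
        pair = _match_pair(label_maps[0], label_maps[k], min_iou).rename(
            columns={"id_a": "map0", "id_b": f"map{k}"}
        )
        table = table.merge(pair, on="map0", how="inner")
    return table.reset_index(drop=True)


def global_indices(
    fibers: pd.DataFrame,
    capillary_idx: pd.DataFrame | None,
    lipid_idx: pd.DataFrame | None,
    enzyme_idx: pd.DataFrame | None,
) -> pd.DataFrame:
    """Join per-fiber LC, ∑LD area and Int-SDH into one table.

    All component tables must be keyed by the same ``fiber_id`` space (the
    serial-section correspondence already applied).  A fiber appears only if
    present in every component.
    """
    missing = [
        name
        for name, tbl in (
            ("capillary_quant", capillary_idx),
            ("lipid_droplets", lipid_idx),
            ("histoenzymology", enzyme_idx),
        )
        if tbl is None
    ]
    if missing:
        raise ValueError(f"missing component table(s): {', '.join(missing)}")
    out = fibers[["fiber_id", "fiber_type"]].merge(
        capillary_idx[["fiber_id", "lc"]], on="fiber_id"
    )
    out = out.merge(lipid_idx[["fiber_id", "sum_ld_area"]], on="fiber_id")
    out = out.merge(enzyme_idx[["fiber_id", "int_sdh"]], on="fiber_id")
    return out.reset_index(drop=True)


def index_correlations(
    global_table: pd.DataFrame,
    by: list[str] = ("group", "time", "fiber_type"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Pearson r (with two-sided p) among LC, ∑LD and Int-SDH.

    One correlation matrix per ``by`` cell; cells with < 3 fibers are
    skipped.  Constant variables give r = NaN with ``undefined=True``.
    """
    by = [b for b in by if b in global_table.columns]
    groups = global_table.groupby(by) if by else [((), global_table)]
    rows = []
    for key, grp in groups:
        if len(grp) < 3:
            continue
        if not isinstance(key, tuple):
            key = (key,)
        for a, b in (("lc", "sum_ld_area"), ("lc", "int_sdh"), ("sum_ld_area", "int_sdh")):
            x, y = grp[a].to_numpy(float), grp[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p, undef = np.nan, np.nan, True
            else:
                r, p = sps.pearsonr(x, y)
                undef = False
            rows.append(
                dict(zip(by, key))
                | {
                    "var1": a,
                    "var2": b,
                    "n": len(grp),
                    "r": r,
                    "p": p,
                    "significant": bool(p < alpha) if not undef else False,
                    "undefined": undef,
                }
            )
    return pd.DataFrame(rows)
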