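"""Synthetic muscle cross-sections and protein tables with known ground truth.

The generator emulates the statistical structure that the measurement
pipeline assumes: a mosaic of convex-ish muscle fibers separated by a thin
endomysial ECM band (with an optional thicker perimysial band), contractile
types painted into MHC channels, intramyocellular lipid droplets as small
disks, capillaries as elongated blobs hugging fiber boundaries, and
brightfield-like SDH/COX densitometry channels.  Every planted quantity is
recorded in a :class:`GroundTruth` so that recovery tests can compare
measured values against the truth.

Geometry is built as a Poisson-disc-seeded power (Laguerre) diagram with two
Lloyd relaxation iterations — cells are convex-ish and sliver-free — and the
per-cell weights are then balanced so that realized cross-sectional areas
track the per-type targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as _draw_disk
from skimage.measure import regionprops
from skimage.segmentation import find_boundaries

from .section import LabeledSection

FIBER_TYPES = ("I", "I-IIA", "IIA", "IIA-IIX", "IIX")

#: bright-signal gray level for dark-background channels
_FG = 200
#: brightfield background gray level for SDH/COX densitometry channels
_BF_BG = 230
#: faint tissue autostain in the Sirius channel (keeps top-hat honest)
_SIRIUS_FIBER = 40
#: intermediate MHC-IIa label intensity painted for IIA-IIX hybrids
_MHC2A_INTERMEDIATE = 70


def _per_type(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to all fiber types, or validate a per-type map."""
    if isinstance(value, Mapping):
        out = {t: float(value[t]) for t in value}
    else:
        out = {t: float(value) for t in FIBER_TYPES}
    for t, v in out.items():
        if v < 0:
            raise ValueError(f"{name}[{t}] must be >= 0")
    return out


@dataclass
class SectionParams:
    """Knobs of the synthetic section generator (lengths in µm, areas µm²)."""

    n_fibers: int = 25
    pixel_scale: float = 0.5  # µm per pixel; 0.5 ≈ 20x microscopy
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.45, "I-IIA": 0.03, "IIA": 0.40, "IIA-IIX": 0.03, "IIX": 0.09}
    )
    csa_mean: Mapping[str, float] | float = field(
        default_factory=lambda: {"I": 5000.0, "I-IIA": 5200.0, "IIA": 6000.0, "IIA-IIX": 6200.0, "IIX": 6500.0}
    )
    csa_cv: float = 0.25
    droplet_rate: Mapping[str, float] | float = field(
        default_factory=lambda: {"I": 20.0, "I-IIA": 12.0, "IIA": 6.0, "IIA-IIX": 4.0, "IIX": 3.0}
    )
    droplet_area_mean: float = 3.0
    droplet_area_cv: float = 0.5
    capillary_per_fiber: float = 1.5
    contact_len_mean: float = 12.0
    contact_len_cv: float = 0.3
    capillary_diameter: tuple[float, float] = (3.0, 6.0)
    endomysium_width: float = 2.0
    perimysium_width: float = 12.0
    sdh_od_mean: Mapping[str, float] | float = field(
        default_factory=lambda: {"I": 0.70, "I-IIA": 0.60, "IIA": 0.50, "IIA-IIX": 0.42, "IIX": 0.35}
    )
    cox_od_mean: Mapping[str, float] | float = field(
        default_factory=lambda: {"I": 0.60, "I-IIA": 0.52, "IIA": 0.45, "IIA-IIX": 0.38, "IIX": 0.32}
    )
    od_cv: float = 0.15
    coupling: float = 0.0  # fiber-level latent coordination of LD / SDH / capillary contact
    noise_sd: float = 5.0
    margin: float = 20.0  # clear background margin around the tissue, µm
    seed: int = 0

    def validate(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        total = float(sum(self.type_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_proportions must sum to 1 (got {total})")
        for t in self.type_proportions:
            if t not in FIBER_TYPES:
                raise ValueError(f"unknown fiber type {t!r}")
        for nm in ("csa_mean", "sdh_od_mean", "cox_od_mean"):
            for t, v in _per_type(getattr(self, nm), nm).items():
                if v <= 0:
                    raise ValueError(f"{nm}[{t}] must be > 0")
        if self.droplet_area_mean <= 0 or self.endomysium_width <= 0:
            raise ValueError("droplet_area_mean and endomysium_width must be > 0")
        if self.noise_sd < 0 or self.coupling < 0:
            raise ValueError("noise_sd and coupling must be >= 0")


@dataclass
class GroundTruth:
    """Planted values of one synthetic section (the recovery-test oracle)."""

    fibers: pd.DataFrame       # fiber_id, fiber_type, csa, perimeter, centroid_x/y, ODs, LD truth
    droplets: pd.DataFrame     # droplet_id, fiber_id, area, centroid_x/y
    capillaries: pd.DataFrame  # capillary_id, area, centroid_x/y
    contacts: pd.DataFrame     # capillary_id, fiber_id, contact_len (clean-geometry lengths)
    label_map: np.ndarray      # true fiber interiors, 0 = non-fiber
    ecm_mask: np.ndarray
    endomysium_mask: np.ndarray
    perimysium_mask: np.ndarray
    endomysium_width: float
    params: SectionParams


# ---------------------------------------------------------------------------
# mosaic construction


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Log-normal samples parameterized by arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _type_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n fibers across types."""
    items = [(t, p) for t, p in proportions.items() if p > 0]
    raw = {t: p * n for t, p in items}
    counts = {t: int(np.floor(v)) for t, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(items, key=lambda tp: raw[tp[0]] - counts[tp[0]], reverse=True)
    for t, _ in order[:rem]:
        counts[t] += 1
    return counts


def _power_labels(shape, seeds, weights):
    """Label each pixel by its power-diagram cell (1-based)."""
    h, w = shape
    rows = np.arange(h, dtype=np.float32)[:, None]
    cols = np.arange(w, dtype=np.float32)[None, :]
    best = np.full(shape, np.inf, dtype=np.float32)
    lab = np.zeros(shape, dtype=np.int32)
    for i in range(len(seeds)):
        d = (rows - seeds[i, 0]) ** 2 + (cols - seeds[i, 1]) ** 2 - weights[i]
        closer = d < best
        best[closer] = d[closer]
        lab[closer] = i + 1
    return lab


def _place_seeds(rng, radii, lo, hi):
    """Poisson-disc-style dart throwing inside the square [lo, hi)²."""
    n = len(radii)
    pts = np.empty((n, 2))
    placed = 0
    relax = 0.78
    tries = 0
    while placed < n:
        cand = rng.uniform(lo, hi, 2)
        if placed:
            d = np.hypot(*(pts[:placed] - cand).T)
            min_d = relax * (radii[:placed] + radii[placed])
            ok = bool(np.all(d >= min_d))
        else:
            ok = True
        if ok:
            pts[placed] = cand
            placed += 1
            tries = 0
        else:
            tries += 1
            if tries > 200:  # crowded: relax the packing constraint
                relax *= 0.9
                tries = 0
    return pts


def _mosaic(rng, target_px, shape, margin_px):
    """Power-diagram mosaic with Lloyd relaxation and weight balancing."""
    n = len(target_px)
    radii = np.sqrt(target_px / np.pi)
    lo = margin_px + radii.max() * 0.5
    hi = min(shape) - margin_px - radii.max() * 0.5
    if hi <= lo:
        lo, hi = margin_px, min(shape) - margin_px
    seeds = _place_seeds(rng, radii, lo, hi)
    weights = radii**2 - np.mean(radii**2)

    tissue = np.zeros(shape, dtype=bool)
    tissue[margin_px:-margin_px, margin_px:-margin_px] = True

    lab = None
    for it in range(6):
        lab = _power_labels(shape, seeds, weights)
        lab[~tissue] = 0
        flat = lab.ravel()
        areas = np.bincount(flat, minlength=n + 1)[1:].astype(float)
        if it < 2:  # Lloyd: move seeds to cell centroids
            rsum = np.bincount(flat, weights=np.repeat(np.arange(shape[0]), shape[1]), minlength=n + 1)[1:]
            csum = np.bincount(flat, weights=np.tile(np.arange(shape[1]), shape[0]), minlength=n + 1)[1:]
            nz = areas > 0
            seeds[nz, 0] = rsum[nz] / areas[nz]
            seeds[nz, 1] = csum[nz] / areas[nz]
        else:  # balance weights toward the target areas
            weights = weights + 0.9 * (target_px - areas) / np.pi
    lab = _power_labels(shape, seeds, weights)
    lab[~tissue] = 0
    return lab, seeds


def _keep_largest(lab, label_ids):
    """Keep only the largest connected component of each labeled cell."""
    out = lab
    for i in label_ids:
        mask = lab == i
        cc, ncc = ndi.label(mask)
        if ncc > 1:
            sizes = np.bincount(cc.ravel())[1:]
            keep = 1 + int(np.argmax(sizes))
            out[mask & (cc != keep)] = 0
    return out


def _band_from(mask: np.ndarray, half_width_px: float) -> np.ndarray:
    """All pixels within half_width_px of the given mask."""
    if not mask.any():
        return np.zeros_like(mask)
    return ndi.distance_transform_edt(~mask) <= half_width_px


# ---------------------------------------------------------------------------
# section generation


def generate_section(params: SectionParams) -> tuple[LabeledSection, GroundTruth]:
    """Generate one synthetic multi-channel cross-section plus its ground truth.

    Identical ``params`` (including ``seed``) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    scale = params.pixel_scale

    csa_mean = _per_type(params.csa_mean, "csa_mean")
    droplet_rate = _per_type(params.droplet_rate, "droplet_rate")
    sdh_mean = _per_type(params.sdh_od_mean, "sdh_od_mean")
    cox_mean = _per_type(params.cox_od_mean, "cox_od_mean")

    counts = _type_counts(params.type_proportions, params.n_fibers)
    types = np.array([t for t, c in counts.items() for _ in range(c)], dtype=object)
    types = types[rng.permutation(params.n_fibers)]
    latent = rng.standard_normal(params.n_fibers)  # shared driver for coupled indices

    target_csa = np.array(
        [_lognormal(rng, csa_mean[t], params.csa_cv, 1)[0] for t in types]
    )

    endo_w_px = params.endomysium_width / scale
    peri_w_px = params.perimysium_width / scale
    margin_px = max(4, int(round(params.margin / scale)))

    # ECM-compensated cell-area targets (hexagon perimeter ≈ 3.81·√A)
    mean_target = float(np.mean(target_csa))
    for _attempt in range(3):
        csa_px = target_csa / scale**2
        cell_px = csa_px + 0.5 * 3.81 * np.sqrt(csa_px) * endo_w_px
        side = int(np.ceil(np.sqrt(cell_px.sum())))
        if params.endomysium_width >= side * scale or params.perimysium_width >= side * scale:
            raise ValueError("ECM widths exceed the tissue extent")
        shape = (side + 2 * margin_px, side + 2 * margin_px)
        lab, seeds = _mosaic(rng, cell_px, shape, margin_px)

        # ECM band: cell/cell and cell/background interfaces, dilated to width
        interface = find_boundaries(lab, mode="thick") | (
            (lab == 0)
            & (ndi.binary_dilation(lab > 0, structure=np.ones((3, 3))))
        )
        tissue = np.zeros(shape, dtype=bool)
        tissue[margin_px:-margin_px, margin_px:-margin_px] = True
        interface &= ndi.binary_dilation(tissue, iterations=1)
        # the thick interface is already ~2 px wide; dilate only the remainder
        ecm = _band_from(interface, max(0.0, (endo_w_px - 2.0) / 2.0))

        peri = np.zeros(shape, dtype=bool)
        if peri_w_px > endo_w_px:
            # thicken ECM along a chord of edges: a perimysial band between fascicles
            theta = rng.uniform(0, np.pi)
            c0 = np.array(shape) / 2.0
            rr, cc = np.nonzero(interface)
            d_line = np.abs(np.cos(theta) * (rr - c0[0]) + np.sin(theta) * (cc - c0[1]))
            corridor = 0.8 * float(np.median(np.sqrt(csa_px / np.pi)))
            sel = np.zeros(shape, dtype=bool)
            sel[rr[d_line <= corridor], cc[d_line <= corridor]] = True
            sel &= interface
            if sel.any():
                peri = _band_from(sel, max(0.0, (peri_w_px - 2.0) / 2.0)) & ndi.binary_dilation(tissue)
        ecm = ecm | peri

        lab_fib = lab.copy()
        lab_fib[ecm] = 0
        lab_fib = _keep_largest(lab_fib, range(1, params.n_fibers + 1))

        realized = np.bincount(lab_fib.ravel(), minlength=params.n_fibers + 1)[1:] * scale**2
        if realized.min() <= 0:
            target_csa = target_csa * 1.05  # a cell vanished: enlarge and retry
            continue
        if abs(realized.mean() - mean_target) / mean_target <= 0.05:
            break
        target_csa = target_csa * (mean_target / realized.mean())
    ecm_mask = ecm
    endo_mask = ecm_mask & ~peri

    # --- channels -----------------------------------------------------------
    chan = {name: np.zeros(shape, dtype=float) for name in
            ("laminin", "mhc1", "mhc2a", "oro", "sdh", "cox", "sirius", "cd31")}
    chan["laminin"][ecm_mask] = _FG
    chan["sirius"][lab_fib > 0] = _SIRIUS_FIBER
    chan["sirius"][ecm_mask] = _FG

    sdh_od = np.empty(params.n_fibers)
    cox_od = np.empty(params.n_fibers)
    couple = params.coupling
    for i in range(params.n_fibers):
        t = types[i]
        mask = lab_fib == i + 1
        if t in ("I", "I-IIA"):
            chan["mhc1"][mask] = _FG
        if t in ("IIA", "I-IIA"):
            chan["mhc2a"][mask] = _FG
        elif t == "IIA-IIX":
            chan["mhc2a"][mask] = _MHC2A_INTERMEDIATE
        sdh_od[i] = _lognormal(rng, sdh_mean[t], params.od_cv, 1)[0] * np.exp(couple * 0.3 * latent[i])
        cox_od[i] = _lognormal(rng, cox_mean[t], params.od_cv, 1)[0]
    chan["sdh"][:] = _BF_BG
    chan["cox"][:] = _BF_BG
    ecm_bf = _BF_BG * 10 ** (-0.06)
    chan["sdh"][ecm_mask] = ecm_bf
    chan["cox"][ecm_mask] = ecm_bf
    for i in range(params.n_fibers):
        mask = lab_fib == i + 1
        chan["sdh"][mask] = _BF_BG * 10 ** (-sdh_od[i])
        chan["cox"][mask] = _BF_BG * 10 ** (-cox_od[i])

    droplets = _paint_droplets(rng, lab_fib, types, latent, droplet_rate, params, chan["oro"])
    cap_lab, capillaries, contacts = _paint_capillaries(rng, lab, lab_fib, latent, params, chan["cd31"])

    # --- noise and quantization --------------------------------------------
    channels = {}
    for name, arr in chan.items():
        if params.noise_sd > 0:
            arr = arr + rng.normal(0.0, params.noise_sd, shape)
        channels[name] = np.clip(arr, 0, 255).astype(np.uint8)

    # --- ground truth -------------------------------------------------------
    from .morphometry import region_perimeter_px  # shared perimeter definition

    props = regionprops(lab_fib)
    rows = []
    by_fiber = droplets.groupby("fiber_id") if len(droplets) else None
    for p in props:
        i = p.label - 1
        nd = len(by_fiber.get_group(p.label)) if by_fiber is not None and p.label in by_fiber.groups else 0
        sum_ld = float(by_fiber.get_group(p.label)["area"].sum()) if nd else 0.0
        rows.append(
            {
                "fiber_id": p.label,
                "fiber_type": types[i],
                "csa": p.area * scale**2,
                "perimeter": region_perimeter_px(p.image) * scale,
                "centroid_x": p.centroid[1] * scale,
                "centroid_y": p.centroid[0] * scale,
                "sdh_od": sdh_od[i],
                "cox_od": cox_od[i],
                "int_sdh": sdh_od[i] * p.area * scale**2,
                "n_droplets": nd,
                "sum_ld_area": sum_ld,
                "latent": latent[i],
            }
        )
    fibers = pd.DataFrame(rows)

    section = LabeledSection(channels=channels, pixel_scale=scale)
    truth = GroundTruth(
        fibers=fibers,
        droplets=droplets,
        capillaries=capillaries,
        contacts=contacts,
        label_map=lab_fib,
        ecm_mask=ecm_mask,
        endomysium_mask=endo_mask,
        perimysium_mask=peri,
        endomysium_width=params.endomysium_width,
        params=params,
    )
    return section, truth


def _paint_droplets(rng, lab_fib, types, latent, rate_by_type, params, oro):
    """Place non-overlapping ORO-positive disks inside fibers."""
    scale = params.pixel_scale
    couple = params.coupling
    records = []
    droplet_id = 0
    objects = ndi.find_objects(lab_fib)
    for i in range(len(types)):
        base = rate_by_type[types[i]]
        if base <= 0:
            continue
        # mean-preserving log-normal modulation by the latent coordination score
        lam = base * np.exp(couple * 0.5 * latent[i] - (couple * 0.5) ** 2 / 2)
        n = rng.poisson(lam)
        if n == 0 or objects[i] is None:
            continue
        sl = objects[i]
        mask = lab_fib[sl] == i + 1
        edt = ndi.distance_transform_edt(mask)
        areas = _lognormal(rng, params.droplet_area_mean, params.droplet_area_cv, n)
        radii_px = np.maximum(1.0, np.sqrt(areas / np.pi) / scale)
        order = np.argsort(-radii_px)
        placed: list[tuple[float, float, float]] = []
        for k in order:
            r = radii_px[k]
            cand_rc = np.argwhere(edt > r + 1.0)
            if len(cand_rc) == 0:
                continue
            for _try in range(40):
                rr0, cc0 = cand_rc[rng.integers(len(cand_rc))]
                if all(
                    np.hypot(rr0 - pr, cc0 - pc) >= r + prad + 2.0
                    for pr, pc, prad in placed
                ):
                    break
            else:
                continue
            placed.append((rr0, cc0, r))
            rr, cc = _draw_disk((rr0 + sl[0].start, cc0 + sl[1].start), r + 0.5, shape=oro.shape)
            oro[rr, cc] = _FG
            droplet_id += 1
            records.append(
                {
                    "droplet_id": droplet_id,
                    "fiber_id": i + 1,
                    "area": len(rr) * scale**2,
                    "centroid_x": (cc0 + sl[1].start) * scale,
                    "centroid_y": (rr0 + sl[0].start) * scale,
                }
            )
    return pd.DataFrame(
        records, columns=["droplet_id", "fiber_id", "area", "centroid_x", "centroid_y"]
    )


def _cell_edges(lab):
    """Edge pixels between pairs of adjacent cells, grouped by cell pair."""
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for axis, (dr, dc) in (((0), (1, 0)), ((1), (0, 1))):
        a = lab[: lab.shape[0] - dr, : lab.shape[1] - dc]
        b = lab[dr:, dc:]
        sel = (a > 0) & (b > 0) & (a != b)
        rr, cc = np.nonzero(sel)
        la, lb = a[rr, cc], b[rr, cc]
        for r, c, x, y in zip(rr, cc, la, lb):
            key = (int(min(x, y)), int(max(x, y)))
            edges.setdefault(key, []).append((int(r), int(c)))
    return {k: np.array(v) for k, v in edges.items() if len(v) >= 4}


def _paint_capillaries(rng, lab, lab_fib, latent, params, cd31):
    """Elongated CD31-positive blobs hugging fiber-to-fiber boundaries.

    Each capillary is an arc of the shared edge between two cells, dilated to
    a 3–6 µm caliber, optionally offset toward one of the two fibers (which
    controls how many fibers it ends up contacting).  Truth contact lengths
    are measured afterwards on the clean painted masks.
    """
    from .capillaries import capillary_fiber_contacts  # shared clean-geometry measurement

    scale = params.pixel_scale
    n_caps = rng.poisson(params.capillary_per_fiber * len(latent))
    cap_lab = np.zeros_like(lab, dtype=np.int32)
    records = []
    edges = _cell_edges(lab)
    if n_caps == 0 or not edges:
        empty = pd.DataFrame(columns=["capillary_id", "fiber_id", "contact_len"])
        caps = pd.DataFrame(columns=["capillary_id", "area", "centroid_x", "centroid_y"])
        return cap_lab, caps, empty

    keys = list(edges)
    w = np.array([len(edges[k]) for k in keys], dtype=float)
    if params.coupling > 0:
        zmean = np.array([(latent[k[0] - 1] + latent[k[1] - 1]) / 2 for k in keys])
        w = w * np.exp(params.coupling * zmean)
    w /= w.sum()

    anchors: list[tuple[float, float]] = []
    cap_id = 0
    for _ in range(n_caps):
        key = keys[rng.choice(len(keys), p=w)]
        coords = edges[key]
        center = coords.mean(axis=0)
        centered = coords - center
        # principal direction of the edge for ordering pixels along it
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        t = centered @ vt[0]
        order = np.argsort(t)
        coords = coords[order]
        m = len(coords)

        L_um = _lognormal(rng, params.contact_len_mean, params.contact_len_cv, 1)[0]
        if params.coupling > 0:
            zm = (latent[key[0] - 1] + latent[key[1] - 1]) / 2
            L_um *= np.exp(params.coupling * 0.3 * zm)
        k_px = int(np.clip(round(L_um / scale / 1.2), 2, m))
        if rng.random() < 0.6:  # junctions live at edge ends
            ci = rng.integers(0, max(1, m // 6)) if rng.random() < 0.5 else rng.integers(max(0, m - m // 6), m)
        else:
            ci = rng.integers(0, m)
        start = int(np.clip(ci - k_px // 2, 0, m - k_px))
        arc = coords[start : start + k_px]

        a0 = arc.mean(axis=0)
        min_sep_px = (params.contact_len_mean + params.capillary_diameter[1]) / scale * 0.8
        if anchors and min(np.hypot(a0[0] - ar, a0[1] - ac) for ar, ac in anchors) < min_sep_px:
            continue
        anchors.append((a0[0], a0[1]))

        rc_px = rng.uniform(*params.capillary_diameter) / 2.0 / scale
        perp = vt[1]
        delta = rng.uniform(-0.8, 0.8) * rc_px
        cap_id += 1
        painted = 0
        for rr0, cc0 in arc[::2]:
            rr, cc = _draw_disk(
                (rr0 + delta * perp[0], cc0 + delta * perp[1]), rc_px + 0.5, shape=lab.shape
            )
            free = cap_lab[rr, cc] == 0
            cap_lab[rr[free], cc[free]] = cap_id
            painted += int(free.sum())
        if painted == 0:
            cap_id -= 1
            anchors.pop()
            continue
        cd31[cap_lab == cap_id] = _FG
        sel = np.argwhere(cap_lab == cap_id)
        records.append(
            {
                "capillary_id": cap_id,
                "area": painted * scale**2,
                "centroid_x": sel[:, 1].mean() * scale,
                "centroid_y": sel[:, 0].mean() * scale,
            }
        )

    caps = pd.DataFrame(records, columns=["capillary_id", "area", "centroid_x", "centroid_y"])
    contacts, _ = capillary_fiber_contacts(cap_lab, lab_fib, contact_radius=1.5, pixel_scale=scale)
    return cap_lab, caps, contacts


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    design: pd.DataFrame,
    params_by_cell: Mapping[tuple[str, str], SectionParams],
    base_seed: int = 0,
) -> list[tuple[LabeledSection, GroundTruth]]:
    """One synthetic section per subject×time row of the design table.

    ``design`` needs columns ``subject``, ``group`` and ``time``;
    ``params_by_cell`` maps each (group, time) cell to the generator settings
    for that cell (e.g. POST droplet rates scaled by a retention fraction).
    """
    required = {"subject", "group", "time"}
    if not design.empty and not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    if design.empty:
        return []
    if design.duplicated(subset=["subject", "time"]).any():
        raise ValueError("duplicate subject×time rows in design")
    out = []
    for idx, row in enumerate(design.itertuples(index=False)):
        cell = (row.group, row.time)
        if cell not in params_by_cell:
            raise KeyError(f"params_by_cell missing cell {cell}")
        params = params_by_cell[cell]
        seed_i = (base_seed * 1_000_003 + 7919 * idx + params.seed) % (2**31)
        sec, gt = generate_section(replace(params, seed=seed_i))
        sec.subject, sec.group, sec.time = str(row.subject), str(row.group), str(row.time)
        sec.section_id = f"{row.subject}_{row.time}"
        out.append((sec, gt))
    return out


# ---------------------------------------------------------------------------
# protein tables


@dataclass
class ProteinTableParams:
    """Knobs of the synthetic label-free protein abundance generator."""

    n_proteins: int = 419
    n_subjects_per_group: int = 6
    paired: bool = True
    n_diff: int = 4
    effect_size: float = 1.0  # log2 fold-change of truly differential proteins
    noise_sd: float = 0.5  # residual SD on the log2 scale
    planted_sets: Mapping[str, tuple[list[str], float]] = field(default_factory=dict)
    effect_on: str = "time"  # "time": shift POST of effect_group; "group": shift group 50Y
    effect_group: str = "37Y"
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_diff > self.n_proteins:
            raise ValueError("n_diff must be <= n_proteins")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_on not in ("time", "group"):
            raise ValueError("effect_on must be 'time' or 'group'")


def generate_protein_table(
    params: ProteinTableParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log2 abundance table (proteins × samples) with planted differences.

    Returns ``(table, metadata, truth)``: the abundance matrix, a sample
    metadata frame (sample, subject, group, time) and per-protein truth
    labels (``null``, ``diff`` or ``set:<name>``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    proteins = [f"P{i + 1:04d}" for i in range(params.n_proteins)]

    meta_rows = []
    for g in ("37Y", "50Y"):
        for s in range(params.n_subjects_per_group):
            subject = f"{g}_S{s + 1:02d}"
            for time in ("PRE", "POST"):
                meta_rows.append(
                    {"sample": f"{subject}_{time}", "subject": subject, "group": g, "time": time}
                )
    meta = pd.DataFrame(meta_rows)

    base = rng.normal(20.0, 2.0, params.n_proteins)
    subj_eff = {s: rng.normal(0.0, params.noise_sd / 2) for s in meta["subject"].unique()}

    diff_ids = list(rng.choice(params.n_proteins, size=params.n_diff, replace=False))
    truth = np.array(["null"] * params.n_proteins, dtype=object)
    truth[diff_ids] = "diff"
    shifts = np.zeros(params.n_proteins)
    shifts[diff_ids] = params.effect_size
    for name, (ids, set_shift) in params.planted_sets.items():
        idx = [proteins.index(p) for p in ids]
        for i in idx:
            if truth[i] == "null":
                truth[i] = f"set:{name}"
            shifts[i] += set_shift

    data = np.empty((params.n_proteins, len(meta)))
    for j, row in enumerate(meta.itertuples(index=False)):
        shifted = (
            (params.effect_on == "time" and row.time == "POST" and row.group == params.effect_group)
            or (params.effect_on == "group" and row.group == "50Y")
        )
        mu = base + subj_eff[row.subject] + (shifts if shifted else 0.0)
        data[:, j] = mu + rng.normal(0.0, params.noise_sd, params.n_proteins)

    table = pd.DataFrame(data, index=proteins, columns=meta["sample"])
    if params.missing_rate > 0:
        miss = rng.random(table.shape) < params.missing_rate
        table = table.mask(miss)
    truth_df = pd.DataFrame({"protein": proteins, "label": truth})
    return table, meta, truth_df
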