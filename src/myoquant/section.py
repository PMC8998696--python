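"""Multi-channel cross-section container and TIFF I/O.

A stained muscle cross-section is represented as a set of named, equally
shaped 2D rasters (one per stain) plus the physical pixel scale.  Channel
names follow the staining they emulate:

``laminin``
    fiber-boundary outline (basal lamina), used for segmentation
``mhc1`` / ``mhc2a``
    myosin-heavy-chain immunolabels used for contractile typing
``oro``
    Oil-red-O neutral-lipid stain (lipid droplets)
``sdh`` / ``cox``
    succinate-dehydrogenase / cytochrome-c-oxidase histoenzymology,
    brightfield-like (dense stain = dark pixel)
``sirius``
    Sirius-red-like connective-tissue (ECM) stain
``cd31``
    endothelial (capillary) immunolabel
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: canonical channel order used when writing multi-page TIFFs
CHANNEL_ORDER = ("laminin", "mhc1", "mhc2a", "oro", "sdh", "cox", "sirius", "cd31")


@dataclass
class LabeledSection:
    """One imaged cross-section with named channels and metadata."""

    channels: dict[str, np.ndarray]
    pixel_scale: float  # µm per pixel
    section_id: str = ""
    subject: str = ""
    group: str = ""
    time: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def write_section(path, section: LabeledSection) -> None:
    """Write a section as a multi-page TIFF, one page per channel.

    The channel name is stored in each page's description tag; pixel scale
    and identifiers go into the file-level metadata of the first page.
    """
    names = [c for c in CHANNEL_ORDER if c in section.channels]
    names += [c for c in section.channels if c not in names]
    with tifffile.TiffWriter(path) as tw:
        for i, name in enumerate(names):
            extra = {}
            if i == 0:
                extra["metadata"] = {
                    "pixel_scale": section.pixel_scale,
                    "section_id": section.section_id,
                    "subject": section.subject,
                    "group": section.group,
                    "time": section.time,
                }
            tw.write(section.channels[name], description=name, **extra)


def read_section(path, pixel_scale: float | None = None) -> LabeledSection:
    """Read a multi-page TIFF written by :func:`write_section`.

    ``pixel_scale`` overrides the value stored in the file (required when
    reading TIFFs produced elsewhere that carry no scale metadata).
    """
    channels: dict[str, np.ndarray] = {}
    meta: dict = {}
    with tifffile.TiffFile(path) as tf:
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
        for i, page in enumerate(tf.pages):
            name = (page.description or "").strip()
            if not name or name.startswith("{"):
                name = f"channel{i}"
            channels[name] = page.asarray()
    scale = pixel_scale if pixel_scale is not None else float(meta.get("pixel_scale", 0) or 0)
    if scale <= 0:
        raise ValueError("pixel scale missing from file; pass pixel_scale explicitly")
    return LabeledSection(
        channels=channels,
        pixel_scale=scale,
        section_id=str(meta.get("section_id", "")),
        subject=str(meta.get("subject", "")),
        group=str(meta.get("group", "")),
        time=str(meta.get("time", "")),
    )
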