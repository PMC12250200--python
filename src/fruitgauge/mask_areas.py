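"""Fruit and marker pixel areas from 3-class label masks.

This is the stand-in for the instance-segmentation output stage: masks come
in as single-channel PNG images with values {0: background, 1: fruit,
2: marker}, and what leaves is the pair of region areas whose ratio drives
diameter estimation.

Because the marker is glued to the fruit top, its pixels sit inside the
fruit outline and carry their own class label; a segmentation fruit mask
would nevertheless cover the whole fruit silhouette.  Extraction therefore
fills holes in the fruit class before measuring it, so the reported fruit
area is the full silhouette rather than silhouette-minus-marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .config import RESOLUTIONS
from .scene_sim import LabelMask

CLASS_NAMES = {1: "fruit", 2: "marker"}

#: 4-connectivity structuring element
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


class MissingClassError(ValueError):
    """A required class has zero pixels in the mask (failed detection)."""

    def __init__(self, class_name: str):
        self.class_name = class_name
        super().__init__(f"no {class_name!r} pixels found in mask")


@dataclass(frozen=True)
class AreaPair:
    """Areas of the largest fruit and marker regions plus diagnostics."""

    area_fruit_px: int
    area_marker_px: int
    n_fruit_components: int
    n_marker_components: int

    def __post_init__(self) -> None:
        if self.area_fruit_px < 0 or self.area_marker_px < 0:
            raise ValueError("areas must be non-negative")


def _largest_component(binary: np.ndarray, fill_holes: bool) -> tuple[int, int]:
    """(largest component area, component count) under 4-connectivity."""
    labels, n = ndimage.label(binary, structure=_STRUCTURE_4)
    if fill_holes:
        filled = ndimage.binary_fill_holes(binary)
        labels_f, _ = ndimage.label(filled, structure=_STRUCTURE_4)
        sizes = np.bincount(labels_f.ravel())[1:]
    else:
        sizes = np.bincount(labels.ravel())[1:]
    return int(sizes.max()), int(n)


def extract_areas(mask: LabelMask | np.ndarray, fill_fruit_holes: bool = True) -> AreaPair:
    """Measure fruit and marker areas in a label mask.

    Per class, 4-connected components are labelled and the largest
    component's pixel count is returned; component counts are reported for
    diagnostics.  The fruit class is hole-filled first (see module
    docstring) so the marker cut-out does not shrink the fruit area.

    Raises :class:`MissingClassError` if either class is absent — the
    pipeline treats such an image as a failed detection rather than
    silently zero-filling.
    """
    grid = mask.grid if isinstance(mask, LabelMask) else np.asarray(mask)
    fruit = grid == 1
    marker = grid == 2
    if not fruit.any():
        raise MissingClassError("fruit")
    if not marker.any():
        raise MissingClassError("marker")
    area_f, n_f = _largest_component(fruit, fill_holes=fill_fruit_holes)
    area_m, n_m = _largest_component(marker, fill_holes=False)
    return AreaPair(area_f, area_m, n_f, n_m)


def area_ratio(pair: AreaPair) -> float:
    """Fruit-to-marker area ratio; undefined for a zero marker area."""
    if pair.area_marker_px <= 0:
        raise ValueError("area ratio undefined: marker area is zero")
    return pair.area_fruit_px / pair.area_marker_px


# ---------------------------------------------------------------------------
# PNG interchange
# ---------------------------------------------------------------------------

def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a single-channel PNG (values 0/1/2)."""
    Image.fromarray(mask.grid.astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path) -> LabelMask:
    """Read a single-channel PNG label mask; the tier is inferred from shape."""
    with Image.open(path) as img:
        grid = np.asarray(img.convert("L"))
    for tier, shape in RESOLUTIONS.items():
        if grid.shape == tuple(shape):
            return LabelMask(grid=grid, resolution_tier=tier)
    raise ValueError(f"mask shape {grid.shape} matches no known resolution tier")


def extract_areas_batch(mask_dir: str | Path, metadata: pd.DataFrame) -> pd.DataFrame:
    """Extract areas for every mask referenced by a metadata table.

    ``metadata`` must carry ``image_id`` (PNG stem), ``fruit_id`` and
    ``date``.  Returns one row per image with the two areas and their
    ratio.  Unreadable files or missing classes raise, carrying the file
    name, so a corrupt batch cannot pass silently.
    """
    mask_dir = Path(mask_dir)
    rows = []
    for rec in metadata.itertuples(index=False):
        path = mask_dir / f"{rec.image_id}.png"
        if not path.exists():
            raise FileNotFoundError(f"expected mask file {path}")
        try:
            pair = extract_areas(read_mask(path))
        except (MissingClassError, ValueError, OSError) as exc:
            raise type(exc)(f"{path.name}: {exc}") from exc
        rows.append((rec.image_id, rec.fruit_id, rec.date,
                     pair.area_fruit_px, pair.area_marker_px, area_ratio(pair)))
    return pd.DataFrame(
        rows,
        columns=["image_id", "fruit_id", "date",
                 "area_fruit_px", "area_marker_px", "ratio"],
    )
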