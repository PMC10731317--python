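"""sRGB → CIE LAB conversion and mask-based iris/pupil contrast measurement.

Conventions
-----------
* Colour space: CIE 1976 L*a*b*, D65 reference white, 2° observer, standard
  sRGB transfer function (the default for web photographs).
* Masks: boolean rasters congruent with the image; pixel-centre, row-major,
  0-based coordinates.  Label images use 0 = background, 1 = iris,
  2 = pupil, 3 = highlight.  Polygon annotations are closed rings in
  (x, y) image coordinates.
* Contrast sign: (pupil − iris) / (pupil + iris), so a dark pupil against a
  light iris gives a negative L-channel contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon2mask

from ._exceptions import DegenerateRegionError, FormatError

__all__ = [
    "LabColor",
    "EyeAnnotation",
    "RegionColorSummary",
    "IrisPupilContrast",
    "DEFAULT_HIGHLIGHT_THRESHOLD",
    "DEFAULT_DENOM_FLOOR",
    "srgb_to_lab",
    "lab_to_srgb",
    "exclude_highlights",
    "region_mean",
    "iris_pupil_contrast",
    "measure_contrast",
    "contrast_table",
    "read_label_mask",
    "read_polygon_annotation",
    "load_image",
]

DEFAULT_HIGHLIGHT_THRESHOLD = 95.0
DEFAULT_DENOM_FLOOR = 1e-6

CHANNELS = ("L", "A", "B")


@dataclass(frozen=True)
class LabColor:
    """A colour in CIE LAB: lightness ``L`` plus opponent axes ``a`` and ``b``."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass
class EyeAnnotation:
    """Iris/pupil (and optional highlight) masks for one eye in one image."""

    image_id: str
    species: str
    iris_mask: np.ndarray
    pupil_mask: np.ndarray
    highlight_mask: np.ndarray | None = None

    def validate(self) -> None:
        shapes = {self.iris_mask.shape, self.pupil_mask.shape}
        if self.highlight_mask is not None:
            shapes.add(self.highlight_mask.shape)
        if len(shapes) != 1:
            raise FormatError(f"masks of {self.image_id!r} have mismatched shapes")
        if np.logical_and(self.iris_mask, self.pupil_mask).any():
            raise FormatError(f"iris and pupil masks of {self.image_id!r} overlap")
        for region, mask in (("iris", self.iris_mask), ("pupil", self.pupil_mask)):
            if not mask.any():
                raise DegenerateRegionError(region)


@dataclass(frozen=True)
class RegionColorSummary:
    """Mean LAB colour of one region together with the pixel count used."""

    image_id: str
    region: str
    mean_lab: LabColor
    pixel_count: int


@dataclass
class IrisPupilContrast:
    """Per-channel (pupil − iris)/(pupil + iris) contrast for one image.

    Channels whose denominator magnitude falls below the configured floor are
    stored as None and listed in ``undefined_channels`` — they propagate
    downstream as missing values, never as infinities.
    """

    image_id: str
    species: str
    c_L: float | None
    c_A: float | None
    c_B: float | None
    undefined_channels: list[str] = field(default_factory=list)

    def channel(self, name: str) -> float | None:
        return {"L": self.c_L, "A": self.c_A, "B": self.c_B}[name]


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise FormatError(
            f"expected an (H, W, 3) sRGB raster, got shape {image.shape}"
        )
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    image = image.astype(float)
    if image.min() < 0:
        raise FormatError("floating sRGB input must be non-negative")
    if image.max() > 255.0:
        raise FormatError("sRGB values exceed the 0–255 convention")
    if image.max() > 1.0:  # 0–255 float convention
        image = image / 255.0
    return image


# sRGB (IEC 61966-2-1) ↔ CIE XYZ, D65/2°.  The reference white is taken as
# the matrix row sums so that sRGB (255,255,255) maps to L=100, a=b=0 exactly.
RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
XYZ_TO_RGB = np.linalg.inv(RGB_TO_XYZ)
WHITE_XYZ = RGB_TO_XYZ.sum(axis=1)

_DELTA = 6.0 / 29.0


def _linearize(s: np.ndarray) -> np.ndarray:
    return np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)


def _delinearize(linear: np.ndarray) -> np.ndarray:
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.maximum(linear, 0.0) ** (1.0 / 2.4) - 0.055,
    )


def srgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit (or unit-float) sRGB raster to CIE L*a*b* (D65, 2°)."""
    rgb = _check_rgb(image)
    xyz = _linearize(rgb) @ RGB_TO_XYZ.T / WHITE_XYZ
    f = np.where(
        xyz > _DELTA**3, np.cbrt(xyz), xyz / (3 * _DELTA**2) + 4.0 / 29.0
    )
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_srgb(lab: np.ndarray) -> np.ndarray:
    """Inverse transform back to an 8-bit sRGB raster (gamut-clipped)."""
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    f = np.stack(
        [fy + lab[..., 1] / 500.0, fy, fy - lab[..., 2] / 200.0], axis=-1
    )
    xyz = np.where(f > _DELTA, f**3, 3 * _DELTA**2 * (f - 4.0 / 29.0))
    linear = (xyz * WHITE_XYZ) @ XYZ_TO_RGB.T
    rgb = np.clip(_delinearize(np.clip(linear, 0.0, 1.0)), 0.0, 1.0)
    return np.round(rgb * 255.0).astype(np.uint8)


def exclude_highlights(
    lab: np.ndarray,
    annotation: EyeAnnotation,
    threshold: float = DEFAULT_HIGHLIGHT_THRESHOLD,
) -> tuple[EyeAnnotation, dict[str, int]]:
    """Remove specular-highlight pixels from the iris and pupil masks.

    Pixels inside ``annotation.highlight_mask`` (when present) or with
    L* above ``threshold`` are dropped.  Returns the pruned annotation and
    the per-region removal counts; raises :class:`DegenerateRegionError`
    if a region is emptied entirely.
    """
    annotation.validate()
    bright = lab[..., 0] > threshold
    if annotation.highlight_mask is not None:
        bright = bright | annotation.highlight_mask
    removed: dict[str, int] = {}
    new_masks: dict[str, np.ndarray] = {}
    for region, mask in (
        ("iris", annotation.iris_mask),
        ("pupil", annotation.pupil_mask),
    ):
        keep = mask & ~bright
        removed[region] = int(mask.sum() - keep.sum())
        if not keep.any():
            raise DegenerateRegionError(region)
        new_masks[region] = keep
    pruned = replace(
        annotation, iris_mask=new_masks["iris"], pupil_mask=new_masks["pupil"]
    )
    return pruned, removed


def region_mean(
    lab: np.ndarray, annotation: EyeAnnotation
) -> tuple[RegionColorSummary, RegionColorSummary]:
    """Arithmetic mean L/a/b over the iris and pupil masks."""
    annotation.validate()
    summaries = []
    for region, mask in (
        ("iris", annotation.iris_mask),
        ("pupil", annotation.pupil_mask),
    ):
        if not mask.any():
            raise DegenerateRegionError(region)
        mean = lab[mask].mean(axis=0)
        summaries.append(
            RegionColorSummary(
                image_id=annotation.image_id,
                region=region,
                mean_lab=LabColor(*map(float, mean)),
                pixel_count=int(mask.sum()),
            )
        )
    return summaries[0], summaries[1]


def iris_pupil_contrast(
    pupil: LabColor,
    iris: LabColor,
    denom_floor: float = DEFAULT_DENOM_FLOOR,
    image_id: str = "",
    species: str = "",
) -> IrisPupilContrast:
    """Per-channel (pupil − iris)/(pupil + iris) of the region means.

    A channel whose |pupil + iris| is below ``denom_floor`` is flagged
    undefined instead of being returned as an overflow value.
    """
    values: dict[str, float | None] = {}
    undefined: list[str] = []
    for name, p, i in zip(CHANNELS, pupil.as_array(), iris.as_array()):
        denom = p + i
        if abs(denom) < denom_floor:
            values[name] = None
            undefined.append(name)
        else:
            values[name] = float((p - i) / denom)
    return IrisPupilContrast(
        image_id=image_id,
        species=species,
        c_L=values["L"],
        c_A=values["A"],
        c_B=values["B"],
        undefined_channels=undefined,
    )


def measure_contrast(
    image: np.ndarray,
    annotation: EyeAnnotation,
    highlight_threshold: float = DEFAULT_HIGHLIGHT_THRESHOLD,
    denom_floor: float = DEFAULT_DENOM_FLOOR,
) -> dict:
    """Full per-image measurement: LAB conversion, highlight exclusion,
    region means and the contrast statistic, as one tidy record."""
    lab = srgb_to_lab(image)
    pruned, removed = exclude_highlights(lab, annotation, highlight_threshold)
    iris, pupil = region_mean(lab, pruned)
    contrast = iris_pupil_contrast(
        pupil.mean_lab,
        iris.mean_lab,
        denom_floor=denom_floor,
        image_id=annotation.image_id,
        species=annotation.species,
    )
    return {
        "image_id": annotation.image_id,
        "species": annotation.species,
        "n_iris_px": iris.pixel_count,
        "n_pupil_px": pupil.pixel_count,
        "n_removed_iris": removed["iris"],
        "n_removed_pupil": removed["pupil"],
        "iris_L": iris.mean_lab.L,
        "iris_a": iris.mean_lab.a,
        "iris_b": iris.mean_lab.b,
        "pupil_L": pupil.mean_lab.L,
        "pupil_a": pupil.mean_lab.a,
        "pupil_b": pupil.mean_lab.b,
        "c_L": contrast.c_L,
        "c_A": contrast.c_A,
        "c_B": contrast.c_B,
        "flags": ";".join(
            f"undefined_{ch}" for ch in contrast.undefined_channels
        ),
    }


def contrast_table(
    pairs: list[tuple[np.ndarray, EyeAnnotation]],
    highlight_threshold: float = DEFAULT_HIGHLIGHT_THRESHOLD,
    denom_floor: float = DEFAULT_DENOM_FLOOR,
) -> pd.DataFrame:
    """Per-image contrast table for a batch of (image, annotation) pairs."""
    rows = [
        measure_contrast(img, ann, highlight_threshold, denom_floor)
        for img, ann in pairs
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mask readers

LABEL_BACKGROUND, LABEL_IRIS, LABEL_PUPIL, LABEL_HIGHLIGHT = 0, 1, 2, 3


def read_label_mask(
    source: str | Path | np.ndarray, image_id: str, species: str
) -> EyeAnnotation:
    """Build an annotation from a label image (PNG path or integer array)."""
    if isinstance(source, (str, Path)):
        labels = np.asarray(Image.open(source))
    else:
        labels = np.asarray(source)
    if labels.ndim != 2:
        raise FormatError("label mask must be a single-channel raster")
    highlight = labels == LABEL_HIGHLIGHT
    return EyeAnnotation(
        image_id=image_id,
        species=species,
        iris_mask=labels == LABEL_IRIS,
        pupil_mask=labels == LABEL_PUPIL,
        highlight_mask=highlight if highlight.any() else None,
    )


def read_polygon_annotation(path: str | Path) -> EyeAnnotation:
    """Read a polygon-JSON annotation and rasterize it.

    Schema::

        {"image_id": ..., "species": ..., "height": H, "width": W,
         "regions": {"iris": [[x, y], ...], "pupil": [...],
                     "highlight": [...] (optional)}}

    Rings are closed polygons in (x, y) image coordinates, rasterized at
    pixel centres.  Pupil takes precedence over iris where rings overlap
    (a pupil ring drawn inside the iris ring is the common case).
    """
    payload = json.loads(Path(path).read_text())
    shape = (int(payload["height"]), int(payload["width"]))

    def rasterize(ring) -> np.ndarray:
        # polygon2mask wants (row, col) = (y, x)
        pts = np.array([(y, x) for x, y in ring], dtype=float)
        return polygon2mask(shape, pts)

    regions = payload["regions"]
    iris = rasterize(regions["iris"])
    pupil = rasterize(regions["pupil"])
    iris &= ~pupil
    highlight = (
        rasterize(regions["highlight"]) if "highlight" in regions else None
    )
    return EyeAnnotation(
        image_id=str(payload["image_id"]),
        species=str(payload["species"]),
        iris_mask=iris,
        pupil_mask=pupil,
        highlight_mask=highlight,
    )


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as an 8-bit RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
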