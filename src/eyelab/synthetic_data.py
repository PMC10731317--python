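"""Synthetic inputs for the full pipeline.

Two generators:

* parametric eye images — concentric anti-aliased iris/pupil ellipses
  rendered from specified LAB colours, with exact label masks, an optional
  specular highlight disc, Gaussian sRGB noise, and the analytic contrast
  implied by the specified colours;
* questionnaire data — a counterbalanced four-version design over
  12 dog images × 2 eye colours, and ratings drawn from a two-factor
  latent model with eye-colour shifts, image- and participant-level
  random effects, and discretization to the 0–5 / 0–3 response scales.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import CalibrationWarning, GamutError
from .colorimetry import IrisPupilContrast, LabColor, iris_pupil_contrast
from .psychometrics import PERSONALITY_ITEMS

__all__ = [
    "SyntheticEyeSpec",
    "RatingModelSpec",
    "StudyDesign",
    "DEFAULT_LOADINGS",
    "DEFAULT_MAPPING",
    "render_eye",
    "generate_design",
    "generate_ratings",
    "in_srgb_gamut",
    "wolf_like_spec",
    "dog_like_spec",
    "generate_eye_dataset",
    "write_manifest",
]

# ---------------------------------------------------------------------------
# Eye images

def _lab_to_linear_rgb(lab: LabColor) -> np.ndarray:
    """Linear-RGB coordinates under the same constants as colorimetry."""
    from .colorimetry import WHITE_XYZ, XYZ_TO_RGB

    fy = (lab.L + 16.0) / 116.0
    fx = fy + lab.a / 500.0
    fz = fy - lab.b / 200.0

    def finv(t):
        return np.where(t > 6.0 / 29.0, t**3, 3 * (6.0 / 29.0) ** 2 * (t - 4.0 / 29.0))

    xyz = WHITE_XYZ * finv(np.array([fx, fy, fz]))
    return XYZ_TO_RGB @ xyz


def _lab_to_srgb01(lab: LabColor) -> np.ndarray:
    linear = _lab_to_linear_rgb(lab)
    for channel, value in zip("RGB", linear):
        if value < -1e-9 or value > 1.0 + 1e-9:
            raise GamutError(
                f"LAB ({lab.L}, {lab.a}, {lab.b}) is outside the sRGB gamut "
                f"(linear {channel} = {value:.4f})"
            )
    linear = np.clip(linear, 0.0, 1.0)
    return np.where(
        linear <= 0.0031308, 12.92 * linear, 1.055 * linear ** (1 / 2.4) - 0.055
    )


@dataclass
class SyntheticEyeSpec:
    """Parameters of one rendered eye image."""

    image_id: str
    species: str
    size: tuple[int, int] = (64, 64)  # (height, width)
    centre: tuple[float, float] = (31.5, 31.5)  # (row, col)
    iris_axes: tuple[float, float] = (26.0, 22.0)  # (semi-axis rows, cols)
    pupil_axes: tuple[float, float] = (10.0, 9.0)
    rotation_deg: float = 0.0
    iris_lab: LabColor = field(default_factory=lambda: LabColor(65.0, 5.0, 45.0))
    pupil_lab: LabColor = field(default_factory=lambda: LabColor(10.0, 2.0, 2.0))
    background_lab: LabColor = field(default_factory=lambda: LabColor(45.0, 0.0, 0.0))
    highlight: tuple[float, float, float] | None = None  # (row, col, radius)
    noise_sd: float = 0.0  # per-channel sRGB noise, 8-bit units
    seed: int = 0

    def validate(self) -> None:
        if min(self.iris_axes) <= 0 or min(self.pupil_axes) <= 0:
            raise ValueError("ellipse axes must be positive")
        if not (
            self.pupil_axes[0] < self.iris_axes[0]
            and self.pupil_axes[1] < self.iris_axes[1]
        ):
            raise ValueError("pupil ellipse must lie strictly inside the iris")

    def analytic_contrast(self) -> IrisPupilContrast:
        return iris_pupil_contrast(
            self.pupil_lab,
            self.iris_lab,
            image_id=self.image_id,
            species=self.species,
        )


def _ellipse_membership(
    rows: np.ndarray,
    cols: np.ndarray,
    centre: tuple[float, float],
    axes: tuple[float, float],
    rotation_deg: float,
) -> np.ndarray:
    theta = np.deg2rad(rotation_deg)
    dr = rows - centre[0]
    dc = cols - centre[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def render_eye(
    spec: SyntheticEyeSpec, supersample: int = 4
) -> tuple[np.ndarray, np.ndarray, IrisPupilContrast]:
    """Render an eye image plus its exact label mask and analytic contrast.

    Returns ``(image uint8 HxWx3, labels HxW, contrast)`` where labels use
    0 = background, 1 = iris, 2 = pupil, 3 = highlight.  Ellipse edges are
    anti-aliased by ``supersample``× area sampling.  Label masks are
    conservative: a pixel is labelled iris or pupil only when fully
    covered by that region and untouched by the highlight (mirroring an
    annotator tracing inside the boundary and avoiding reflections); the
    highlight label uses majority coverage.
    """
    spec.validate()
    h, w = spec.size
    bg = _lab_to_srgb01(spec.background_lab)
    iris = _lab_to_srgb01(spec.iris_lab)
    pupil = _lab_to_srgb01(spec.pupil_lab)
    white = np.ones(3)

    s = supersample
    sub = (np.arange(h * s) + 0.5) / s - 0.5
    rows = sub[:, None] * np.ones((1, w * s))
    cols = np.ones((h * s, 1)) * sub[None, :]

    def coverage(mask_hi: np.ndarray) -> np.ndarray:
        return mask_hi.reshape(h, s, w, s).mean(axis=(1, 3))

    iris_cov = coverage(
        _ellipse_membership(rows, cols, spec.centre, spec.iris_axes, spec.rotation_deg)
    )
    pupil_cov = coverage(
        _ellipse_membership(rows, cols, spec.centre, spec.pupil_axes, spec.rotation_deg)
    )
    image = (
        bg * (1.0 - iris_cov[..., None])
        + iris * (iris_cov - pupil_cov)[..., None]
        + pupil * pupil_cov[..., None]
    )

    hl_cov = np.zeros((h, w))
    if spec.highlight is not None:
        hr, hc, radius = spec.highlight
        hl_cov = coverage((rows - hr) ** 2 + (cols - hc) ** 2 <= radius**2)
        image = image * (1.0 - hl_cov[..., None]) + white * hl_cov[..., None]

    full = 1.0 - 1e-9
    labels = np.zeros((h, w), dtype=np.uint8)
    labels[(iris_cov >= full) & (pupil_cov <= 0.0) & (hl_cov <= 0.0)] = 1
    labels[(pupil_cov >= full) & (hl_cov <= 0.0)] = 2
    labels[hl_cov > 0.5] = 3

    rng = np.random.default_rng(spec.seed)
    image = image * 255.0
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.round(np.clip(image, 0.0, 255.0)).astype(np.uint8)
    return image, labels, spec.analytic_contrast()


def in_srgb_gamut(lab: LabColor) -> bool:
    """True when the colour is renderable without clipping."""
    linear = _lab_to_linear_rgb(lab)
    return bool((linear >= -1e-9).all() and (linear <= 1.0 + 1e-9).all())


def _sample_lab(rng, means, sds) -> LabColor:
    for _ in range(100):
        lab = LabColor(*(float(rng.normal(m, s)) for m, s in zip(means, sds)))
        if lab.L > 1.0 and in_srgb_gamut(lab):
            return lab
    raise GamutError(f"could not sample an in-gamut colour near {means}")


def wolf_like_spec(image_id: str, seed: int, **overrides) -> SyntheticEyeSpec:
    """Light yellowish iris with a dark pupil (high |L contrast|)."""
    rng = np.random.default_rng(seed)
    iris = _sample_lab(rng, (65.0, 8.0, 42.0), (4.0, 2.0, 4.0))
    pupil = _sample_lab(rng, (10.0, 2.0, 2.0), (2.0, 0.5, 0.5))
    return SyntheticEyeSpec(
        image_id=image_id,
        species="wolf",
        iris_lab=iris,
        pupil_lab=pupil,
        seed=seed,
        **overrides,
    )


def dog_like_spec(image_id: str, seed: int, **overrides) -> SyntheticEyeSpec:
    """Dark brown iris with a dark pupil (low |L contrast|)."""
    rng = np.random.default_rng(seed)
    iris = _sample_lab(rng, (27.0, 14.0, 20.0), (4.0, 2.0, 3.0))
    pupil = _sample_lab(rng, (10.0, 2.0, 2.0), (2.0, 0.5, 0.5))
    return SyntheticEyeSpec(
        image_id=image_id,
        species="dog",
        iris_lab=iris,
        pupil_lab=pupil,
        seed=seed,
        **overrides,
    )


def generate_eye_dataset(
    n_wolves: int = 22,
    n_dogs: int = 81,
    seed: int = 0,
    noise_sd: float = 2.0,
    highlight_fraction: float = 0.5,
) -> list[tuple[SyntheticEyeSpec, np.ndarray, np.ndarray, IrisPupilContrast]]:
    """Render a two-species image set; a random subset gets a highlight disc."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_wolves + n_dogs):
        maker = wolf_like_spec if i < n_wolves else dog_like_spec
        label = "wolf" if i < n_wolves else "dog"
        spec = maker(f"{label}_{i:03d}", int(rng.integers(2**31)), noise_sd=noise_sd)
        if rng.random() < highlight_fraction:
            spec.highlight = (
                spec.centre[0] - 4.0,
                spec.centre[1] + 3.0,
                2.5,
            )
        image, labels, contrast = render_eye(spec)
        out.append((spec, image, labels, contrast))
    return out


# ---------------------------------------------------------------------------
# Questionnaire design and ratings

VERSIONS = ("A", "B", "C", "D")
N_IMAGES = 12
EYE_COLOURS = ("dark", "light")

#: two-factor loading pattern used as the generator default: friendliness
#: markers on factor 1 (aggressive keyed negatively), maturity markers on
#: factor 2, zero cross-loadings.
DEFAULT_LOADINGS = pd.DataFrame(
    {
        "factor1": [-0.605, 0.779, 0.780, 0.822, 0.826, 0, 0, 0, 0, 0],
        "factor2": [0, 0, 0, 0, 0, 0.684, 0.662, 0.620, 0.506, 0.798],
    },
    index=list(PERSONALITY_ITEMS),
)

#: canonical item→scale mapping implied by the default loading pattern
DEFAULT_MAPPING = {
    "aggressive": ("friendliness", -1),
    "easygoing": ("friendliness", 1),
    "friendly": ("friendliness", 1),
    "kind": ("friendliness", 1),
    "sociable": ("friendliness", 1),
    "confident": ("maturity", 1),
    "independent": ("maturity", 1),
    "intelligent": ("maturity", 1),
    "mature": ("maturity", 1),
    "trustworthy": ("maturity", 1),
}

ITEM_ANCHOR = 2.5  # latent 0 maps to the scale midpoint; ±2.5 SD spans 0–5


@dataclass
class StudyDesign:
    """Counterbalanced assignment of 24 stimuli to four questionnaire versions."""

    version_stimuli: dict[str, list[tuple[int, str]]]
    participant_version: dict[str, str]

    def rating_rows(self) -> list[tuple[str, str, int, str]]:
        """(participant_id, version, image_id, eye_colour) per rating row."""
        rows = []
        for pid, version in self.participant_version.items():
            for image_id, colour in self.version_stimuli[version]:
                rows.append((pid, version, image_id, colour))
        return rows

    def validate(self) -> None:
        seen: list[tuple[int, str]] = []
        for version in VERSIONS:
            stimuli = self.version_stimuli[version]
            assert len(stimuli) == 6
            images = [i for i, _ in stimuli]
            assert len(set(images)) == 6, "image repeated within a version"
            colours = [c for _, c in stimuli]
            assert colours.count("dark") == 3 and colours.count("light") == 3
            seen.extend(stimuli)
        assert sorted(seen) == sorted(
            (i, c) for i in range(1, N_IMAGES + 1) for c in EYE_COLOURS
        ), "each stimulus must appear exactly once across versions"


def generate_design(n_participants: int, seed: int = 0) -> StudyDesign:
    """Build a valid four-version design and an even participant allocation.

    Images are split into four blocks of three; paired versions swap the
    eye colour of their blocks, so every version shows 3 dark + 3 light,
    never both colourings of the same dog, and the 24 stimuli are covered
    exactly once across versions.
    """
    if n_participants < 4:
        raise ValueError("need at least 4 participants (one per version)")
    rng = np.random.default_rng(seed)
    images = rng.permutation(np.arange(1, N_IMAGES + 1))
    blocks = [list(map(int, images[i : i + 3])) for i in range(0, 12, 3)]
    version_stimuli = {
        "A": [(i, "dark") for i in blocks[0]] + [(i, "light") for i in blocks[1]],
        "B": [(i, "dark") for i in blocks[1]] + [(i, "light") for i in blocks[0]],
        "C": [(i, "dark") for i in blocks[2]] + [(i, "light") for i in blocks[3]],
        "D": [(i, "dark") for i in blocks[3]] + [(i, "light") for i in blocks[2]],
    }
    for version in VERSIONS:
        order = rng.permutation(6)
        version_stimuli[version] = [version_stimuli[version][k] for k in order]

    allocation = [VERSIONS[k % 4] for k in range(n_participants)]
    rng.shuffle(allocation)  # even split, random pairing
    participant_version = {
        f"p{k + 1:03d}": allocation[k] for k in range(n_participants)
    }
    design = StudyDesign(version_stimuli, participant_version)
    design.validate()
    return design


@dataclass
class RatingModelSpec:
    """Two-factor latent model generating questionnaire responses.

    Latent friendliness/maturity per (participant, stimulus) =
    eye-colour shift (±δ/2, dark minus light = δ) + image effect +
    participant effect + latent noise.  Item responses are
    loading·latent + uniqueness noise, affinely mapped to 0–5 and
    rounded; acceptance responses are a linear model on the rater's own
    observed scale scores plus an image intercept and residual noise,
    mapped to 0–3.
    """

    loadings: pd.DataFrame = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    uniqueness: np.ndarray | None = None  # default 1 - communality
    delta_f: float = 0.5  # dark minus light, latent friendliness
    delta_m: float = -0.4  # dark minus light, latent maturity
    image_sd: float = 0.3
    participant_sd: float = 0.3
    latent_sd: float = 0.9
    accept_image_sd: float = 0.15
    residual_sd: float = 0.45
    acceptance_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "interact": {
                "intercept": 0.75,
                "eye_colour": 0.0,
                "friendliness": 0.30,
                "maturity": 0.0,
            },
            "keep": {
                "intercept": 0.65,
                "eye_colour": 0.0,
                "friendliness": 0.34,
                "maturity": 0.0,
            },
        }
    )
    discretize: bool = True
    study: int = 2
    seed: int = 0

    def resolved_uniqueness(self) -> np.ndarray:
        if self.uniqueness is not None:
            u = np.asarray(self.uniqueness, dtype=float)
        else:
            u = 1.0 - (self.loadings.to_numpy() ** 2).sum(axis=1)
        if (u < 0).any():
            raise ValueError("uniqueness must be non-negative")
        return u


def _discretize(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.clip(np.round(values), lo, hi).astype(int)


def generate_ratings(design: StudyDesign, model: RatingModelSpec) -> pd.DataFrame:
    """Draw a full rating table (one row per participant × stimulus)."""
    rng = np.random.default_rng(model.seed)
    L = model.loadings.to_numpy(dtype=float)
    uniq_sd = np.sqrt(model.resolved_uniqueness())
    items = list(model.loadings.index)

    image_ids = range(1, N_IMAGES + 1)
    img_eff = {
        i: rng.normal(0.0, model.image_sd, size=2) if model.image_sd > 0 else np.zeros(2)
        for i in image_ids
    }
    accept_img = {
        i: (
            rng.normal(0.0, model.accept_image_sd)
            if model.accept_image_sd > 0
            else 0.0
        )
        for i in image_ids
    }
    participants = sorted(design.participant_version)
    part_eff = {
        p: (
            rng.normal(0.0, model.participant_sd, size=2)
            if model.participant_sd > 0
            else np.zeros(2)
        )
        for p in participants
    }

    records = []
    for pid, version, image_id, colour in design.rating_rows():
        sign = 0.5 if colour == "dark" else -0.5
        shift = np.array([sign * model.delta_f, sign * model.delta_m])
        latent_noise = (
            rng.normal(0.0, model.latent_sd, size=2)
            if model.latent_sd > 0
            else np.zeros(2)
        )
        latent = shift + img_eff[image_id] + part_eff[pid] + latent_noise

        raw_items = L @ latent + (
            rng.normal(0.0, 1.0, size=len(items)) * uniq_sd
            if uniq_sd.any()
            else np.zeros(len(items))
        )
        scaled = raw_items + ITEM_ANCHOR
        item_values = (
            _discretize(scaled, 0, 5) if model.discretize else scaled
        )
        row = dict(zip(items, item_values))

        # rater's own observed scale scores (reverse-keyed items flipped)
        per_scale: dict[str, list[float]] = {"friendliness": [], "maturity": []}
        for item, (scale, key) in DEFAULT_MAPPING.items():
            value = row[item] if key > 0 else 5 - row[item]
            per_scale[scale].append(value)
        f_score = float(np.mean(per_scale["friendliness"]))
        m_score = float(np.mean(per_scale["maturity"]))

        accept: dict[str, float] = {}
        for response, coefs in model.acceptance_coefs.items():
            lin = (
                coefs["intercept"]
                + coefs["eye_colour"] * (1.0 if colour == "dark" else 0.0)
                + coefs["friendliness"] * f_score
                + coefs["maturity"] * m_score
                + accept_img[image_id]
                + (rng.normal(0.0, model.residual_sd) if model.residual_sd > 0 else 0.0)
            )
            accept[response] = lin

        records.append(
            {
                "participant_id": pid,
                "study": model.study,
                "version": version,
                "image_id": image_id,
                "eye_colour": colour,
                **row,
                **(
                    {k: int(_discretize(np.array([v]), 0, 3)[0]) for k, v in accept.items()}
                    if model.discretize
                    else accept
                ),
            }
        )

    table = pd.DataFrame(records)
    if model.discretize:
        for col, hi in [(i, 5) for i in items] + [("interact", 3), ("keep", 3)]:
            saturated = ((table[col] == 0) | (table[col] == hi)).mean()
            if saturated > 0.20:
                warnings.warn(
                    f"{saturated:.0%} of {col!r} responses saturate the scale",
                    CalibrationWarning,
                    stacklevel=2,
                )
    return table


def write_manifest(path: str | Path, **params) -> None:
    """Record generator parameters as JSON for provenance."""

    def default(obj):
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict()
        if hasattr(obj, "__dict__"):
            return vars(obj)
        return str(obj)

    Path(path).write_text(json.dumps(params, indent=2, default=default))
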