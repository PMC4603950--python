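"""Synthetic population of subjects, landmark configurations and rendered
face images with controllable BMI-coupled shape and color signal.

This generator is a *statistical stand-in* for an unreleased photograph
collection: it makes no attempt at photorealism, but reproduces the
structure the downstream analysis assumes —

* right-skewed BMI whose reciprocal is normal (BMI is sampled as 1/T with T
  truncated normal, moment-matched to a target mean/SD), so the raw values
  fail a normality test at study size while 1/BMI passes;
* a schematic face template (outline, hairline, brows, eyes with pupils,
  nose, lips) with a configurable point count (default 154);
* lower-face and cheek breadth increasing linearly with a latent adiposity
  score (the standardized transformed BMI) at slope ``shape_effect`` per BMI
  SD, on top of BMI-independent structural nuisance (overall width/height,
  jaw-specific variation, and smooth low-order deformation modes) plus
  landmark jitter and a random small similarity transform;
* rendered faces whose skin tone shifts along a fixed color axis with the
  latent score at slope ``color_effect``, with smooth radial shading
  (darker toward the outline) as a crude 3D cue, per-subject tone nuisance,
  and per-pixel Gaussian noise inside the face; the background is constant.

Everything is deterministic under a fixed master seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize as _optimize
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon

from .exceptions import ConfigurationError
from .io import LandmarkSet, SubjectRecord
from .metrics import TemplateRoleMap

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "FaceTemplate",
    "SyntheticDataset",
    "face_template",
    "sample_population",
    "generate_landmarks",
    "render_face",
    "generate_dataset",
    "synthetic_chart_colors",
]

# base skin tone and the (unit) color axis along which tone shifts with the
# latent adiposity score: higher score -> redder / less green-blue
BASE_SKIN = np.array([0.80, 0.62, 0.52])
_axis = np.array([0.85, -0.25, -0.45])
COLOR_AXIS = _axis / np.linalg.norm(_axis)
BASE_SHADING = 0.25

_FACE_A = 1.0  # normalized face half-width
_FACE_B = 1.3  # normalized face half-height


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_subjects: int = 526
    seed: int = 0
    bmi_target_mean: float = 23.24  # kg/m^2
    bmi_target_sd: float = 3.61  # kg/m^2
    height_mean_cm: float = 166.02
    height_sd_cm: float = 6.33
    age_mean: float = 21.3
    age_sd: float = 2.87
    shape_effect: float = 0.05  # fractional lower-face widening per BMI SD
    color_effect: float = 0.06  # intensity shift along COLOR_AXIS per BMI SD
    shape_nuisance_sd: float = 0.04  # BMI-independent structural variation
    color_nuisance_sd: float = 0.04  # BMI-independent per-channel tone jitter
    landmark_noise_sd: float = 0.3  # pixels of i.i.d. landmark jitter
    pixel_noise_sd: float = 0.05  # in-face texture/sensor noise
    image_size: int = 128
    template_points: int = 154
    apply_similarity: bool = True  # random small rotation/scale/translation
    render_color_chart: bool = False

    def validate(self) -> None:
        if self.n_subjects < 20:
            raise ConfigurationError("n_subjects must be >= 20")
        for name in (
            "bmi_target_sd", "height_sd_cm", "age_sd", "shape_nuisance_sd",
            "color_nuisance_sd", "landmark_noise_sd", "pixel_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("shape_effect", "color_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be >= 16")


@dataclass
class GroundTruth:
    """Latent per-subject adiposity scores (enables recovery tests).

    The latent score is the standardized reciprocal-scale BMI — an exact
    standard-normal, deterministic monotone function of BMI.
    """

    subject_ids: list[str]
    z: np.ndarray
    config: SyntheticConfig
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {sid: i for i, sid in enumerate(self.subject_ids)}

    def index_of(self, subject_id: str) -> int:
        return self._index[subject_id]

    def z_for(self, subject_id: str) -> float:
        return float(self.z[self.index_of(subject_id)])


# ---------------------------------------------------------------------------
# template

@dataclass
class FaceTemplate:
    """Schematic face: normalized points, image-frame points, roles, parts."""

    points_norm: np.ndarray  # (p, 2), face frame, y downward
    points_image: np.ndarray  # (p, 2), pixel frame
    roles: TemplateRoleMap
    parts: dict  # part name -> index array
    scale: float  # pixels per normalized unit
    center: np.ndarray  # (2,) pixel position of the face centre
    harmonics: dict  # fixed coefficients of the smooth nuisance modes


def _part_counts(n_points: int) -> dict:
    minimums = {
        "outline": 7, "hairline": 2, "left_pupil": 1, "right_pupil": 1,
        "left_upper_lid": 2, "right_upper_lid": 2, "left_lower_lid": 0,
        "right_lower_lid": 0, "left_brow": 0, "right_brow": 0, "nose": 0,
        "upper_lip": 3, "lower_lip": 2,
    }
    base = sum(minimums.values())
    if n_points < base:
        raise ConfigurationError(
            f"template undefined for {n_points} points (minimum {base})"
        )
    cycle = [
        "outline", "hairline", "outline", "upper_lip", "left_upper_lid",
        "right_upper_lid", "lower_lip", "outline", "hairline", "nose",
        "left_brow", "right_brow", "outline", "nose", "left_lower_lid",
        "right_lower_lid",
    ]
    counts = dict(minimums)
    for part in itertools.islice(itertools.cycle(cycle), n_points - base):
        counts[part] += 1
    return counts


def _build_part(name: str, c: int) -> np.ndarray:
    a, b = _FACE_A, _FACE_B
    eye_x, eye_y = 0.45, -0.35
    side = -1.0 if name.startswith("left") else 1.0
    if name == "outline":
        theta = np.linspace(np.pi, 2 * np.pi, c)
        return np.column_stack([a * np.cos(theta), -b * np.sin(theta)])
    if name == "hairline":
        theta = np.linspace(np.pi, 0.0, c + 2)[1:-1]
        return np.column_stack([a * np.cos(theta), -b * np.sin(theta)])
    if name.endswith("pupil"):
        return np.array([[side * eye_x, eye_y]])
    if name.endswith("upper_lid"):
        t = np.linspace(-1, 1, c)
        return np.column_stack(
            [side * eye_x + 0.18 * t, eye_y - 0.02 - 0.08 * (1 - t**2)]
        )
    if name.endswith("lower_lid"):
        t = np.linspace(-1, 1, c)
        return np.column_stack(
            [side * eye_x + 0.18 * t, eye_y + 0.02 + 0.05 * (1 - t**2)]
        )
    if name.endswith("brow"):
        t = np.linspace(-1, 1, c)
        return np.column_stack(
            [side * eye_x + 0.22 * t, eye_y - 0.20 - 0.04 * (1 - t**2)]
        )
    if name == "nose":
        s = np.linspace(0.0, 1.0, c)
        return np.column_stack([0.05 * np.sin(np.pi * s), -0.10 + 0.38 * s])
    if name == "upper_lip":
        t = np.linspace(-1, 1, c)
        return np.column_stack([0.28 * t, 0.60 - 0.05 * (1 - t**2)])
    if name == "lower_lip":
        t = np.linspace(-1, 1, c + 2)[1:-1]
        return np.column_stack([0.28 * t, 0.60 + 0.10 * (1 - t**2)])
    raise ConfigurationError(f"unknown template part {name!r}")


def face_template(n_points: int = 154, image_size: int = 128) -> FaceTemplate:
    """Build the schematic face template and its role map."""
    counts = _part_counts(n_points)
    parts, chunks, cursor = {}, [], 0
    order = [
        "outline", "hairline", "left_pupil", "right_pupil", "left_upper_lid",
        "right_upper_lid", "left_lower_lid", "right_lower_lid", "left_brow",
        "right_brow", "nose", "upper_lip", "lower_lip",
    ]
    for name in order:
        c = counts[name]
        if c == 0:
            parts[name] = np.array([], dtype=int)
            continue
        pts = _build_part(name, c)
        parts[name] = np.arange(cursor, cursor + len(pts))
        chunks.append(pts)
        cursor += len(pts)
    points = np.vstack(chunks)
    assert points.shape[0] == n_points

    roles = TemplateRoleMap(
        left_pupil=int(parts["left_pupil"][0]),
        right_pupil=int(parts["right_pupil"][0]),
        outline=parts["outline"].tolist(),
        upper_eyelids=np.concatenate(
            [parts["left_upper_lid"], parts["right_upper_lid"]]
        ).tolist(),
        upper_lip=parts["upper_lip"].tolist(),
        lip_corners=(int(parts["upper_lip"][0]), int(parts["upper_lip"][-1])),
    )

    scale = 0.33 * image_size
    center = np.array([image_size / 2.0, 0.52 * image_size])
    points_image = center + scale * points

    # fixed smooth-deformation basis (template-level constants, not per run)
    hrng = np.random.default_rng(np.random.SeedSequence(777))
    n_modes = 12
    harmonics = {
        "ax": hrng.uniform(0.5, 3.0, n_modes),
        "ay": hrng.uniform(0.5, 3.0, n_modes),
        "phx": hrng.uniform(0, 2 * np.pi, n_modes),
        "phy": hrng.uniform(0, 2 * np.pi, n_modes),
        "decay": 1.0 / np.arange(1, n_modes + 1),
    }
    return FaceTemplate(points, points_image, roles, parts, scale, center, harmonics)


# ---------------------------------------------------------------------------
# population

_BMI_LO, _BMI_HI = 12.0, 60.0  # plausible-BMI truncation of the sampler


def _reciprocal_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of T ~ Normal truncated to [1/60, 1/12] such that 1/T has
    the given mean and SD.  Solved by bounded least squares against the
    truncated-normal integral on a dense grid (the truncation matches the
    sampler exactly)."""
    lo, hi = 1.0 / _BMI_HI, 1.0 / _BMI_LO
    t = np.linspace(lo, hi, 4001)

    def moments(params):
        mu, sigma = params
        pdf = np.exp(-0.5 * ((t - mu) / sigma) ** 2)
        norm = np.trapezoid(pdf, t)
        m1 = np.trapezoid(pdf / t, t) / norm
        m2 = np.trapezoid(pdf / t**2, t) / norm
        return m1, np.sqrt(max(m2 - m1**2, 1e-18))

    def residuals(params):
        m1, s1 = moments(params)
        return [m1 - mean, s1 - sd]

    x0 = [1.0 / mean, sd / mean**2]
    sol = _optimize.least_squares(
        residuals, x0, bounds=([lo, 1e-6], [hi, 0.5 * (hi - lo)]), xtol=1e-14
    )
    return float(sol.x[0]), float(sol.x[1])


def sample_population(config: SyntheticConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Draw the subject table: skewed BMI, heights, back-solved weights, ages.

    BMI = 1/T with T normal (truncated to BMI in [12, 60] kg/m^2),
    moment-matched to the target mean/SD.  The latent adiposity score is
    z = (mu_T - T)/sigma_T, an exact standard normal increasing in BMI.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_subjects
    mu_t, sd_t = _reciprocal_normal_params(config.bmi_target_mean, config.bmi_target_sd)

    t = rng.normal(mu_t, sd_t, n)
    lo, hi = 1.0 / 60.0, 1.0 / 12.0
    bad = (t < lo) | (t > hi)
    while bad.any():  # truncation: redraw the (rare) out-of-range tails
        t[bad] = rng.normal(mu_t, sd_t, int(bad.sum()))
        bad = (t < lo) | (t > hi)
    bmi = 1.0 / t
    z = (mu_t - t) / sd_t

    heights = np.clip(
        rng.normal(config.height_mean_cm, config.height_sd_cm, n), 140.0, 200.0
    )
    weights = bmi * (heights / 100.0) ** 2
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 16.0, 45.0)
    age_missing = rng.random(n) < 2.0 / 526.0  # a few subjects decline to report

    width = max(4, len(str(n)))
    subjects = [
        SubjectRecord(
            subject_id=f"S{i + 1:0{width}d}",
            height_cm=float(heights[i]),
            weight_kg=float(weights[i]),
            age=None if age_missing[i] else float(ages[i]),
        )
        for i in range(n)
    ]
    truth = GroundTruth([s.subject_id for s in subjects], z, config)
    return subjects, truth


# ---------------------------------------------------------------------------
# landmarks

def _lower_face_weight(y_norm: np.ndarray) -> np.ndarray:
    """0 above the mid-face, growing linearly toward the chin."""
    return np.clip((y_norm / _FACE_B + 0.2) / 1.2, 0.0, 1.0)


def generate_landmarks(
    record: SubjectRecord,
    truth: GroundTruth,
    config: SyntheticConfig,
    template: Optional[FaceTemplate] = None,
) -> LandmarkSet:
    """One subject's landmark configuration.

    Lower-face and cheek x-offsets scale linearly with the latent adiposity
    score at slope ``shape_effect``; structural nuisance (global width/
    height factors, jaw-specific factor, smooth deformation modes scaled by
    ``shape_nuisance_sd``) is BMI-independent; isotropic Gaussian jitter of
    ``landmark_noise_sd`` pixels and a random small similarity transform
    (rotation <= 5 deg, scale 0.95-1.05, small translation) exercise the
    downstream alignment.
    """
    config.validate()
    if template is None:
        template = face_template(config.template_points, config.image_size)
    idx = truth.index_of(record.subject_id)
    z = float(truth.z[idx])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, idx]))

    pts = template.points_norm.copy()
    x, y = pts[:, 0], pts[:, 1]

    ns = config.shape_nuisance_sd
    fw = 1.0 + rng.normal(0.0, 0.6 * ns)
    fh = 1.0 + rng.normal(0.0, 0.6 * ns)
    jw_dev = rng.normal(0.0, ns)
    h = template.harmonics
    amps = rng.normal(0.0, 0.5 * ns, len(h["decay"])) * h["decay"]

    g = _lower_face_weight(y)
    u, v = x / _FACE_A, y / _FACE_B
    dx = np.zeros_like(x)
    dy = np.zeros_like(y)
    for m in range(len(amps)):
        dx += amps[m] * np.sin(h["ax"][m] * u + h["ay"][m] * v + h["phx"][m])
        dy += amps[m] * np.cos(h["ay"][m] * u + h["ax"][m] * v + h["phy"][m])

    x2 = x * fw * (1.0 + (config.shape_effect * z + jw_dev) * g) + dx
    y2 = y * fh + dy
    out = template.center + template.scale * np.column_stack([x2, y2])

    if config.apply_similarity:
        angle = rng.uniform(-np.deg2rad(5.0), np.deg2rad(5.0))
        s = rng.uniform(0.95, 1.05)
        trans = rng.uniform(-0.02, 0.02, 2) * config.image_size
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        out = (out - template.center) @ (s * R).T + template.center + trans
    if config.landmark_noise_sd > 0:
        out = out + rng.normal(0.0, config.landmark_noise_sd, out.shape)
    size = (config.image_size, config.image_size)
    return LandmarkSet(record.subject_id, out, size)


# ---------------------------------------------------------------------------
# rendering

def synthetic_chart_colors() -> np.ndarray:
    """24 diverse reference patch colors (a synthetic stand-in for a 24-patch
    calibration chart): all RGB triples over {0.2, 0.5, 0.8} minus the three
    grays."""
    combos = [
        c for c in itertools.product([0.2, 0.5, 0.8], repeat=3)
        if not (c[0] == c[1] == c[2])
    ]
    return np.array(combos)


def chart_patch_boxes(image_size: int) -> list[tuple[int, int, int, int]]:
    """Pixel boxes (y0, y1, x0, x1) of the 24 optional chart patches, laid
    out as two columns along the left margin."""
    ph = max(2, image_size // 28)
    boxes = []
    for i in range(24):
        col, row = divmod(i, 12)
        y0 = 2 + row * ph
        x0 = 1 + col * (ph + 1)
        boxes.append((y0, y0 + ph, x0, x0 + ph))
    return boxes


def render_face(
    landmarks: LandmarkSet,
    truth: GroundTruth,
    config: SyntheticConfig,
    template: Optional[FaceTemplate] = None,
) -> np.ndarray:
    """Render one face: skin polygon with BMI-coupled tone, radial shading,
    schematic lips and pupils, constant gray background, in-face noise."""
    config.validate()
    if template is None:
        template = face_template(config.template_points, config.image_size)
    idx = truth.index_of(landmarks.subject_id)
    z = float(truth.z[idx])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, idx]))

    dc = rng.normal(0.0, config.color_nuisance_sd, 3)
    shading = float(
        np.clip(BASE_SHADING + rng.normal(0.0, 0.5 * config.color_nuisance_sd),
                0.05, 0.6)
    )

    size = config.image_size
    img = np.full((size, size, 3), 0.5, dtype=float)
    pts = landmarks.points
    face_loop = np.vstack(
        [pts[template.parts["outline"]], pts[template.parts["hairline"]][::-1]]
    )
    rr, cc = _draw_polygon(face_loop[:, 1], face_loop[:, 0], shape=(size, size))
    if rr.size == 0:
        return img

    cx, cy = face_loop[:, 0].mean(), face_loop[:, 1].mean()
    sx = max(np.abs(face_loop[:, 0] - cx).max(), 1.0)
    sy = max(np.abs(face_loop[:, 1] - cy).max(), 1.0)
    r2 = ((cc - cx) / sx) ** 2 + ((rr - cy) / sy) ** 2
    shade = 1.0 - shading * np.clip(r2, 0.0, 1.0)

    tone = np.clip(BASE_SKIN + config.color_effect * z * COLOR_AXIS + dc, 0.0, 1.0)
    img[rr, cc] = tone[None, :] * shade[:, None]

    # schematic lips and pupils give the warped texture some structure
    if template.parts["lower_lip"].size:
        lips = np.vstack(
            [pts[template.parts["upper_lip"]], pts[template.parts["lower_lip"]][::-1]]
        )
        lr, lc = _draw_polygon(lips[:, 1], lips[:, 0], shape=(size, size))
        if lr.size:
            lshade = 1.0 - shading * np.clip(
                ((lc - cx) / sx) ** 2 + ((lr - cy) / sy) ** 2, 0.0, 1.0
            )
            img[lr, lc] = np.array([0.62, 0.33, 0.35])[None, :] * lshade[:, None]
    pupil_r = max(1.0, 0.035 * template.scale)
    for role in (template.roles.left_pupil, template.roles.right_pupil):
        pr, pc = _draw_disk((pts[role, 1], pts[role, 0]), pupil_r, shape=(size, size))
        img[pr, pc] = (0.08, 0.06, 0.06)

    if config.pixel_noise_sd > 0:
        noise = rng.normal(0.0, config.pixel_noise_sd, (rr.size, 3))
        img[rr, cc] = img[rr, cc] + noise

    if config.render_color_chart:
        for color, (y0, y1, x0, x1) in zip(
            synthetic_chart_colors(), chart_patch_boxes(size)
        ):
            img[y0:y1, x0:x1] = color

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# convenience bundle

@dataclass
class SyntheticDataset:
    subjects: list[SubjectRecord]
    truth: GroundTruth
    template: FaceTemplate
    landmarks: list[LandmarkSet]
    images: Optional[list[np.ndarray]]

    @property
    def roles(self) -> TemplateRoleMap:
        return self.template.roles

    @property
    def bmi(self) -> np.ndarray:
        return np.array([s.bmi for s in self.subjects])


def generate_dataset(config: SyntheticConfig, images: bool = True) -> SyntheticDataset:
    """Population + landmarks (+ images) in one deterministic pass."""
    subjects, truth = sample_population(config)
    template = face_template(config.template_points, config.image_size)
    landmarks = [generate_landmarks(s, truth, config, template) for s in subjects]
    imgs = (
        [render_face(lm, truth, config, template) for lm in landmarks]
        if images
        else None
    )
    return SyntheticDataset(subjects, truth, template, landmarks, imgs)
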