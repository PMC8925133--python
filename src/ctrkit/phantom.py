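"""Synthetic PA-chest-film phantom generator with analytically known CTR.

A phantom is a 2-D grayscale raster that mimics the gross intensity layout of a
posteroanterior chest radiograph — two dark lung fields inside a brighter
soft-tissue/mediastinum background — together with ground-truth binary masks
for the lung fields and the cardiac silhouette.  The geometry is parametric:
the internal thoracic diameter (ID) is a prescribed fraction of the image
width, and the cardiac horizontal extent is a prescribed fraction of the ID,
so the true cardiothoracic ratio (CTR) of every phantom is known exactly by
construction.  Lung fields are superellipses (slightly boxier than ellipses,
echoing the flattened lateral chest wall); the heart is an ellipse straddling
the mediastinal gap.

Coordinates are image coordinates: x (columns) grows rightward, y (rows) grows
downward, 0-based.  Radiographic patient-side labels are metadata only.  An
extent spanning pixel columns a..b inclusive has length b - a + 1 pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, stats

from .errors import DataError, ParameterError, ResolutionError

__all__ = [
    "ThoraxShape",
    "PhantomSpec",
    "SegmentationSample",
    "CTRComponent",
    "CTRDistribution",
    "NORMAL_CTR",
    "CARDIOMEGALY_CTR",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "load_sample",
]

# CTR regimes of the two clinical groups the generator emulates:
# normal hearts cluster near CTR 0.45, cardiomegaly (CTR > 0.5) near 0.55.
NORMAL_CTR = (0.452, 0.032)
CARDIOMEGALY_CTR = (0.549, 0.043)


@dataclass(frozen=True)
class ThoraxShape:
    """Shape parameters for the lung fields and cardiac silhouette.

    All vertical placements are fractions of the image height; widths are
    controlled by :class:`PhantomSpec` so that horizontal extents stay exact.
    """

    lung_exponent: float = 2.5      # superellipse exponent (2 = ellipse)
    lung_center_y_frac: float = 0.46
    lung_height_frac: float = 0.64  # full lung height / image height
    gap_frac: float = 0.10          # mediastinal gap width / ID
    heart_center_y_frac: float = 0.60
    heart_height_frac: float = 0.42  # full heart height / image height


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one phantom; ``cardiac_width_frac`` IS the CTR."""

    image_height: int = 256
    image_width: int = 256
    thorax_width_frac: float = 0.80
    cardiac_width_frac: float = 0.45
    heart_offset_frac: float = 0.0
    lung_shape_params: ThoraxShape = field(default_factory=ThoraxShape)
    noise_sd: float = 0.03
    texture_amplitude: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ResolutionError(
                f"raster {self.image_height}x{self.image_width} below the 32x32 minimum"
            )
        if not 0.0 < self.cardiac_width_frac < 1.0:
            raise ParameterError(
                f"cardiac_width_frac must lie in (0, 1), got {self.cardiac_width_frac}"
            )
        if not 0.0 < self.thorax_width_frac <= 1.0:
            raise ParameterError(
                f"thorax_width_frac must lie in (0, 1], got {self.thorax_width_frac}"
            )
        if abs(self.heart_offset_frac) > 0.25:
            raise ParameterError(
                f"heart_offset_frac must lie in [-0.25, 0.25], got {self.heart_offset_frac}"
            )
        sh = self.lung_shape_params
        if not 0.0 < sh.gap_frac < 0.5:
            raise ParameterError(f"gap_frac must lie in (0, 0.5), got {sh.gap_frac}")
        if sh.lung_exponent < 1.0:
            raise ParameterError("lung_exponent must be >= 1")
        id_px = round(self.thorax_width_frac * self.image_width)
        if id_px < 16:
            raise ResolutionError(
                f"internal thoracic diameter of {id_px} px cannot carry the geometry"
            )
        if self.cardiac_width_frac * id_px < 3:
            raise ResolutionError("cardiac extent below 3 px; raise resolution")


@dataclass
class SegmentationSample:
    """An intensity image with paired binary lung and heart masks.

    ``truth_ctr`` is present only for phantoms, where it is exact by
    construction.  The lung mask is the union of both lung fields.
    """

    image: np.ndarray
    lung_mask: np.ndarray
    heart_mask: np.ndarray
    truth_ctr: float | None = None
    identifier: str = ""
    spec: "PhantomSpec | None" = None  # present when generated by this module

    def __post_init__(self) -> None:
        if not (self.image.shape == self.lung_mask.shape == self.heart_mask.shape):
            raise DataError("image and masks must share identical dimensions")
        for name in ("lung_mask", "heart_mask"):
            m = getattr(self, name)
            if m.dtype != bool:
                vals = np.unique(m)
                if not np.all(np.isin(vals, (0, 1))) and not np.all(np.isin(vals, (0, 255))):
                    raise DataError(f"{name} is not binary")
                setattr(self, name, m > 0)


def _superellipse(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    a: float,
    b: float,
    exponent: float,
) -> np.ndarray:
    """Boolean raster of |(x-cx)/a|^p + |(y-cy)/b|^p <= 1 at pixel centres."""
    h, w = shape
    y = np.arange(h, dtype=float)[:, None]
    x = np.arange(w, dtype=float)[None, :]
    return (
        np.abs((x - cx) / a) ** exponent + np.abs((y - cy) / b) ** exponent
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> SegmentationSample:
    """Rasterise one phantom; identical specs yield bit-identical samples.

    The lung mask has exactly two connected components (left/right fields) and
    the heart mask one component centred on the mediastinal gap.  The sample's
    ``truth_ctr`` equals ``spec.cardiac_width_frac`` exactly; re-measuring the
    rasterised masks recovers it within the +/-2/ID quantisation bound.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    sh = spec.lung_shape_params

    id_px = round(spec.thorax_width_frac * w)
    cx = (w - 1) / 2.0
    a_t = (id_px - 1) / 2.0                       # thoracic semi-span, pixel centres
    half_gap = max(1.0, sh.gap_frac * id_px / 2.0)
    a_lung = (a_t - half_gap) / 2.0
    if a_lung < 2.0:
        raise ResolutionError("lung fields narrower than 2 px; widen the thorax")
    cy_lung = sh.lung_center_y_frac * (h - 1)
    b_lung = sh.lung_height_frac * h / 2.0

    left = _superellipse(
        (h, w), cx - half_gap - a_lung, cy_lung, a_lung, b_lung, sh.lung_exponent
    )
    right = _superellipse(
        (h, w), cx + half_gap + a_lung, cy_lung, a_lung, b_lung, sh.lung_exponent
    )
    lung = left | right

    a_heart = (spec.cardiac_width_frac * id_px - 1) / 2.0
    cx_heart = cx + spec.heart_offset_frac * id_px
    cy_heart = sh.heart_center_y_frac * (h - 1)
    b_heart = sh.heart_height_frac * h / 2.0
    heart = _superellipse((h, w), cx_heart, cy_heart, a_heart, b_heart, 2.0)

    # Intensity model: bright soft tissue, dark lung fields, bright cardiac
    # silhouette drawn over the lungs, plus smooth texture and pixel noise.
    # The masks above are purely geometric, so noise settings never touch them.
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w), 0.62, dtype=np.float64)
    thorax = _superellipse(
        (h, w), cx, cy_lung, a_t + 0.06 * w, b_lung * 1.15, sh.lung_exponent
    )
    img[thorax] = 0.70
    img[lung] = 0.25
    img[heart] = 0.78
    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=w / 10.0)
        tex_sd = tex.std()
        if tex_sd > 0:
            img += spec.texture_amplitude * tex / tex_sd
    else:
        rng.standard_normal((h, w))  # keep the noise draw aligned across settings
    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal((h, w))
    np.clip(img, 0.0, 1.0, out=img)

    return SegmentationSample(
        image=img.astype(np.float32),
        lung_mask=lung,
        heart_mask=heart,
        truth_ctr=spec.cardiac_width_frac,
        identifier=f"phantom-{spec.seed}",
        spec=spec,
    )


@dataclass(frozen=True)
class CTRComponent:
    """One truncated-normal component of a CTR population."""

    weight: float
    mean: float
    sd: float


@dataclass(frozen=True)
class CTRDistribution:
    """A (mixture of) truncated normal(s) over CTR, bounded inside (0, 1).

    The defaults mix the two clinical regimes: normal hearts
    (0.452 +/- 0.032) and cardiomegaly (0.549 +/- 0.043).
    """

    components: tuple[CTRComponent, ...] = (
        CTRComponent(0.6, *NORMAL_CTR),
        CTRComponent(0.4, *CARDIOMEGALY_CTR),
    )
    minimum: float = 0.30
    maximum: float = 0.75

    @classmethod
    def normal(
        cls, mean: float, sd: float, minimum: float = 0.30, maximum: float = 0.75
    ) -> "CTRDistribution":
        return cls((CTRComponent(1.0, mean, sd),), minimum, maximum)

    def validate(self) -> None:
        if not 0.0 < self.minimum < self.maximum < 1.0:
            raise ParameterError(
                f"bounds ({self.minimum}, {self.maximum}) must be nested inside (0, 1)"
            )
        if not self.components:
            raise ParameterError("distribution needs at least one component")
        total = sum(c.weight for c in self.components)
        if total <= 0:
            raise ParameterError("component weights must sum to a positive value")
        for c in self.components:
            if c.sd <= 0:
                raise ParameterError("component sd must be positive")
            if not self.minimum <= c.mean <= self.maximum:
                raise ParameterError(
                    f"component mean {c.mean} outside [{self.minimum}, {self.maximum}]"
                )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self.validate()
        weights = np.array([c.weight for c in self.components], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for i, comp in enumerate(self.components):
            k = int(np.sum(which == i))
            if k == 0:
                continue
            a = (self.minimum - comp.mean) / comp.sd
            b = (self.maximum - comp.mean) / comp.sd
            out[which == i] = stats.truncnorm.rvs(
                a, b, loc=comp.mean, scale=comp.sd, size=k, random_state=rng
            )
        return out


def generate_cohort(
    n: int,
    ctr_distribution: CTRDistribution | None = None,
    seed: int = 0,
    *,
    image_size: int = 256,
    shape_jitter: float = 1.0,
    noise_sd: float = 0.03,
    texture_amplitude: float = 0.05,
) -> list[SegmentationSample]:
    """Draw ``n`` phantoms whose true CTRs follow ``ctr_distribution``.

    Anatomical nuisance parameters (thorax width, lung height and placement,
    mediastinal gap, heart offset and height) are jittered around their
    defaults — scaled by ``shape_jitter`` (0 disables) — so that a cohort
    exercises segmentation models rather than a single fixed silhouette.
    Per-sample seeds derive deterministically from the cohort seed.
    """
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    dist = ctr_distribution if ctr_distribution is not None else CTRDistribution()
    rng = np.random.default_rng(seed)
    ctrs = dist.sample(n, rng)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n)

    j = shape_jitter
    samples: list[SegmentationSample] = []
    for i in range(n):
        shape = ThoraxShape(
            lung_exponent=2.5 + j * rng.uniform(-0.4, 0.4),
            lung_center_y_frac=0.46 + j * rng.uniform(-0.03, 0.03),
            lung_height_frac=0.64 + j * rng.uniform(-0.06, 0.06),
            gap_frac=0.10 + j * rng.uniform(-0.03, 0.03),
            heart_center_y_frac=0.60 + j * rng.uniform(-0.03, 0.03),
            heart_height_frac=0.42 + j * rng.uniform(-0.05, 0.05),
        )
        spec = PhantomSpec(
            image_height=image_size,
            image_width=image_size,
            thorax_width_frac=0.80 + j * rng.uniform(-0.08, 0.08),
            cardiac_width_frac=float(ctrs[i]),
            heart_offset_frac=j * rng.uniform(-0.03, 0.03),
            lung_shape_params=shape,
            noise_sd=noise_sd,
            texture_amplitude=texture_amplitude,
            seed=int(sample_seeds[i]),
        )
        sample = generate_phantom(spec)
        sample.identifier = f"phantom-{i:04d}"
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# Disk I/O: 8-bit grayscale PNGs plus a CSV manifest per cohort.

def _to_png(path: Path, arr: np.ndarray) -> None:
    if arr.dtype == bool:
        data = (arr * 255).astype(np.uint8)
    else:
        data = np.clip(np.round(arr * 255), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def save_cohort(samples: Sequence[SegmentationSample], out_dir: str | Path) -> Path:
    """Write images/masks as PNGs and a ``manifest.csv``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        _to_png(out / f"{s.identifier}_image.png", s.image)
        _to_png(out / f"{s.identifier}_lung.png", s.lung_mask)
        _to_png(out / f"{s.identifier}_heart.png", s.heart_mask)
        row = {"identifier": s.identifier, "truth_ctr": s.truth_ctr}
        if s.spec is not None:
            sp = dataclasses.asdict(s.spec)
            shape = sp.pop("lung_shape_params")
            row.update(sp)
            row.update(shape)
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_sample(directory: str | Path, identifier: str, truth_ctr: float | None = None) -> SegmentationSample:
    d = Path(directory)
    image = np.asarray(Image.open(d / f"{identifier}_image.png"), dtype=np.float32) / 255.0
    lung = np.asarray(Image.open(d / f"{identifier}_lung.png")) > 127
    heart = np.asarray(Image.open(d / f"{identifier}_heart.png")) > 127
    return SegmentationSample(image, lung, heart, truth_ctr, identifier)


def load_cohort(directory: str | Path) -> list[SegmentationSample]:
    d = Path(directory)
    manifest = d / "manifest.csv"
    if not manifest.exists():
        raise DataError(f"no manifest.csv under {d}")
    df = pd.read_csv(manifest)
    return [
        load_sample(d, row.identifier, None if pd.isna(row.truth_ctr) else float(row.truth_ctr))
        for row in df.itertuples()
    ]
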