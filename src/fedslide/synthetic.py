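"""Synthetic multi-site slide generator.

Emulates the statistical structure of a multi-hospital melanoma/nevus slide
collection without any clinical imagery: each site has its own slide count,
class imbalance, per-channel stain bias and texture statistics, a sixth
site acts as an out-of-distribution external cohort (distinct stain and
shifted covariate tables), and a configurable fraction of each slide is
degraded with Gaussian blur to exercise the quality-control path.

A slide is a small RGB canvas with an elliptical lesion ROI.  Class
identity is carried by texture frequency: invasive melanoma (IM) lesions
get high-frequency irregular texture, nevi get low-frequency regular
blobs, so that simple local-variance features — and a small patch CNN —
separate the classes, while per-site stain gains create the inter-site
distribution shift that federated/centralized comparisons hinge on.

Default site sizes and IM/nevus splits follow the six-hospital cohort this
package benchmarks against: 71/97/107/178/236/336 slides (1025 total) with
site-wise melanoma fractions 19/71 ... 142/336; covariate tables default to
that cohort's marginal age/subtype/stage distributions, with the external
site shifted.  Covariates only feed cohort-composition chi-square tests,
never the classifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, ValidationError

__all__ = [
    "SiteSpec",
    "SlideRecord",
    "TABLE1_SITES",
    "default_site_specs",
    "render_slide",
    "inject_blur",
    "generate_multisite_dataset",
    "metadata_table",
    "save_dataset",
    "load_dataset",
]

#: (site_id, n_slides, n_melanoma) for the six-hospital reference cohort.
TABLE1_SITES = (
    (1, 71, 19),
    (2, 97, 56),
    (3, 107, 59),
    (4, 178, 37),
    (5, 236, 75),
    (6, 336, 142),
)

# Marginal covariate tables: training-site hospitals vs the external site.
# Categories with probability by class; stage applies to IM only.
_TRAIN_COVARIATES = {
    "age_band": {
        "IM": {"<35": 0.024, "35-54": 0.216, "55-74": 0.404, ">74": 0.356},
        "NEVUS": {"<35": 0.199, "35-54": 0.342, "55-74": 0.329, ">74": 0.130},
    },
    "subtype": {
        "IM": {"SSM": 0.679, "NM": 0.120, "LMM": 0.139, "other": 0.062},
        "NEVUS": {"dysplastic": 0.411, "blue": 0.056, "acral": 0.019,
                  "spitz": 0.016, "other": 0.498},
    },
    "ajcc_stage": {
        "IM": {"IA": 0.547, "IB": 0.145, "IIA": 0.082, "IIB": 0.044,
               "IIC": 0.044, "III": 0.126, "IV": 0.012},
    },
}
_EXTERNAL_COVARIATES = {
    "age_band": {
        "IM": {"<35": 0.028, "35-54": 0.134, "55-74": 0.408, ">74": 0.430},
        "NEVUS": {"<35": 0.263, "35-54": 0.345, "55-74": 0.247, ">74": 0.144},
    },
    "subtype": {
        "IM": {"SSM": 0.246, "NM": 0.141, "LMM": 0.063, "other": 0.549},
        "NEVUS": {"dysplastic": 0.567, "blue": 0.031, "acral": 0.062,
                  "spitz": 0.021, "other": 0.319},
    },
    "ajcc_stage": {
        "IM": {"IA": 0.493, "IB": 0.211, "IIA": 0.042, "IIB": 0.099,
               "IIC": 0.049, "III": 0.099, "IV": 0.007},
    },
}

#: Fraction of slides whose patient already contributed another slide
#: (the reference cohort has 1025 slides from 923 patients, ~1.11 per patient).
_DUPLICATE_PATIENT_FRACTION = 0.1


@dataclass
class SiteSpec:
    """Generator settings for one site.

    ``stain_shift`` is a per-channel multiplicative colour gain (the
    simplest mechanism that yields site-separable colour statistics);
    ``texture_scale`` scales lesion texture wavelength; ``blur_fraction``
    is the fraction of each slide's area degraded with Gaussian blur.
    """

    site_id: int
    n_slides: int
    melanoma_fraction: float
    stain_shift: tuple = (1.0, 1.0, 1.0)
    texture_scale: float = 1.0
    blur_fraction: float = 0.0
    covariate_tables: dict | None = None

    def __post_init__(self):
        if self.n_slides < 1:
            raise ConfigurationError("n_slides must be >= 1")
        if not 0.0 <= self.melanoma_fraction <= 1.0:
            raise ConfigurationError("melanoma_fraction must be in [0, 1]")
        if len(self.stain_shift) != 3 or any(
            not 0.5 <= g <= 2.0 for g in self.stain_shift
        ):
            raise ConfigurationError("stain_shift components must be in [0.5, 2.0]")
        if self.texture_scale <= 0:
            raise ConfigurationError("texture_scale must be positive")
        if not 0.0 <= self.blur_fraction <= 1.0:
            raise ConfigurationError("blur_fraction must be in [0, 1]")


@dataclass
class SlideRecord:
    """One synthetic (or loaded) lesion slide."""

    slide_id: str
    patient_id: str
    site_id: int
    label: str  # "IM" or "NEVUS"
    image: np.ndarray  # (H, W, 3) uint8
    roi_mask: np.ndarray  # (H, W) bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in ("IM", "NEVUS"):
            raise ValidationError(f"label must be IM or NEVUS, got {self.label!r}")
        if self.roi_mask is not None and not self.roi_mask.any():
            raise ValidationError("roi_mask must contain at least one foreground pixel")

    @property
    def label_int(self) -> int:
        return 1 if self.label == "IM" else 0


def default_site_specs(scale: float = 1.0, blur_fraction: float = 0.05) -> list:
    """The six-site reference configuration, optionally size-scaled.

    Sites 1-5 get modest, mutually distinct stain gains; site 6 (the
    external cohort) gets a clearly distinct stain gain, a different
    texture scale and shifted covariate tables.
    """
    stain = {
        1: (1.00, 1.00, 1.00),
        2: (1.08, 0.96, 1.00),
        3: (0.94, 1.02, 1.06),
        4: (1.04, 1.06, 0.94),
        5: (0.92, 0.96, 1.04),
        6: (1.25, 0.85, 1.15),
    }
    specs = []
    for site_id, n, n_im in TABLE1_SITES:
        specs.append(
            SiteSpec(
                site_id=site_id,
                n_slides=max(1, round(n * scale)),
                melanoma_fraction=n_im / n,
                stain_shift=stain[site_id],
                texture_scale=1.2 if site_id == 6 else 1.0,
                blur_fraction=blur_fraction,
                covariate_tables=(
                    _EXTERNAL_COVARIATES if site_id == 6 else _TRAIN_COVARIATES
                ),
            )
        )
    return specs


def inject_blur(
    image: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    block_px: int | None = None,
    sigma: float = 4.0,
) -> np.ndarray:
    """Replace ~``fraction`` of the image area with a Gaussian-smoothed copy.

    The canvas is divided into square blocks and ``round(fraction *
    n_blocks)`` of them, chosen uniformly without replacement, are replaced
    by the blurred version.  ``fraction=0`` returns an unchanged copy.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must be in [0, 1]")
    out = image.copy()
    if fraction == 0.0:
        return out
    h, w = image.shape[:2]
    block = block_px or max(8, h // 4)
    ny, nx = math.ceil(h / block), math.ceil(w / block)
    n_blur = round(fraction * ny * nx)
    if n_blur == 0:
        return out
    blurred = gaussian_filter(image.astype(np.float64), (sigma, sigma, 0))
    blurred = np.clip(blurred, 0, 255).astype(image.dtype)
    chosen = rng.choice(ny * nx, size=n_blur, replace=False)
    for idx in chosen:
        by, bx = divmod(int(idx), nx)
        ys, xs = by * block, bx * block
        out[ys : ys + block, xs : xs + block] = blurred[ys : ys + block, xs : xs + block]
    return out


def render_slide(
    label: str,
    spec: SiteSpec,
    rng: np.random.Generator,
    canvas_px: int = 896,
):
    """Render one slide: elliptical lesion ROI on a tissue-tinted canvas.

    IM lesions carry high-frequency irregular texture, nevi low-frequency
    regular blobs; the whole canvas is colour-scaled by the site's stain
    gain and finally degraded by the site's blur fraction.  Deterministic
    given the RNG state.  The ellipse covers 30-70% of the canvas.
    """
    c = canvas_px
    base = np.array([235.0, 205.0, 215.0])
    img = base[None, None, :] + rng.normal(0.0, 3.0, size=(c, c, 3))

    # lesion ellipse: target area fraction uniform in [0.3, 0.7]
    area_frac = rng.uniform(0.30, 0.70)
    ratio = rng.uniform(0.65, 1.0)
    ab = area_frac * c * c / math.pi
    a = min(math.sqrt(ab / ratio), 0.48 * c)
    b = ab / a
    cx = c * (0.5 + rng.uniform(-0.015, 0.015))
    cy = c * (0.5 + rng.uniform(-0.015, 0.015))
    yy, xx = np.mgrid[0:c, 0:c]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    # class-dependent texture field
    sigma = spec.texture_scale * (1.0 if label == "IM" else 6.0)
    fld = gaussian_filter(rng.standard_normal((c, c)), sigma)
    fld /= max(fld.std(), 1e-9)
    amp = 30.0 * rng.uniform(0.85, 1.15)
    color = np.array([115.0, 76.0, 64.0]) + rng.normal(0.0, 6.0, size=3)
    chan_w = np.array([1.0, 0.85, 0.75])
    lesion = color[None, None, :] + amp * fld[:, :, None] * chan_w[None, None, :]
    img = np.where(mask[:, :, None], lesion, img)

    # fine pixel noise everywhere so sharp regions are never flat
    img += rng.normal(0.0, 2.0, size=img.shape)
    img *= np.asarray(spec.stain_shift)[None, None, :]
    img = np.clip(img, 0, 255).astype(np.uint8)

    if spec.blur_fraction > 0:
        img = inject_blur(img, spec.blur_fraction, rng)
    return img, mask


def _sample_covariates(label: str, tables: dict, rng: np.random.Generator) -> dict:
    out = {}
    for cov, per_class in tables.items():
        if label not in per_class:
            continue
        cats = list(per_class[label])
        probs = np.asarray([per_class[label][k] for k in cats], dtype=float)
        probs = probs / probs.sum()
        out[cov] = cats[rng.choice(len(cats), p=probs)]
    return out


def generate_multisite_dataset(
    specs,
    seed: int,
    canvas_px: int = 896,
    exact_counts: bool = False,
) -> list:
    """Generate a full multi-site dataset of :class:`SlideRecord`.

    Labels are drawn per site from ``melanoma_fraction`` (Bernoulli, or
    exact rounded counts with ``exact_counts``); ~10% of slides reuse an
    existing patient id, mirroring a cohort where some patients contribute
    two lesions.  A pure function of ``(specs, seed, canvas_px,
    exact_counts)``.
    """
    specs = list(specs)
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(specs))
    records = []
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        n = spec.n_slides
        if exact_counts:
            n_im = round(spec.melanoma_fraction * n)
            labels = np.array(["IM"] * n_im + ["NEVUS"] * (n - n_im))
            rng.shuffle(labels)
        else:
            labels = np.where(rng.random(n) < spec.melanoma_fraction, "IM", "NEVUS")
        # patient assignment: first slides get fresh patients, a tail share
        n_dup = min(int(round(_DUPLICATE_PATIENT_FRACTION * n)), n - 1)
        n_patients = n - n_dup
        patient_of = list(range(n_patients))
        patient_of += list(rng.integers(0, n_patients, size=n_dup))
        tables = spec.covariate_tables or _TRAIN_COVARIATES
        for i in range(n):
            label = str(labels[i])
            image, roi = render_slide(label, spec, rng, canvas_px)
            records.append(
                SlideRecord(
                    slide_id=f"s{spec.site_id}_sl{i:04d}",
                    patient_id=f"s{spec.site_id}_p{patient_of[i]:04d}",
                    site_id=spec.site_id,
                    label=label,
                    image=image,
                    roi_mask=roi,
                    covariates=_sample_covariates(label, tables, rng),
                )
            )
    return records


def metadata_table(records, splits: dict | None = None) -> pd.DataFrame:
    """Metadata DataFrame (slide_id, patient_id, site_id, label, split)."""
    splits = splits or {}
    rows = [
        {
            "slide_id": r.slide_id,
            "patient_id": r.patient_id,
            "site_id": r.site_id,
            "label": r.label,
            "split": splits.get(r.slide_id, ""),
            **{f"cov_{k}": v for k, v in sorted(r.covariates.items())},
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def save_dataset(records, out_dir, specs=None, seed: int | None = None,
                 splits: dict | None = None) -> None:
    """Write slides/masks as PNG, metadata as CSV, and a JSON sidecar."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for r in records:
        Image.fromarray(r.image).save(out / "images" / f"{r.slide_id}.png")
        Image.fromarray((r.roi_mask.astype(np.uint8)) * 255).save(
            out / "masks" / f"{r.slide_id}.png"
        )
    metadata_table(records, splits).to_csv(out / "metadata.csv", index=False)
    sidecar = {"seed": seed}
    if specs is not None:
        sidecar["site_specs"] = [
            {
                "site_id": s.site_id,
                "n_slides": s.n_slides,
                "melanoma_fraction": s.melanoma_fraction,
                "stain_shift": list(s.stain_shift),
                "texture_scale": s.texture_scale,
                "blur_fraction": s.blur_fraction,
            }
            for s in specs
        ]
    with open(out / "dataset.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_dataset(in_dir) -> list:
    """Load a dataset written by :func:`save_dataset` (real-data mode entry).

    Expects ``metadata.csv`` plus ``images/<slide_id>.png`` and
    ``masks/<slide_id>.png`` pairs.
    """
    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        image = np.asarray(Image.open(src / "images" / f"{row.slide_id}.png").convert("RGB"))
        roi = np.asarray(Image.open(src / "masks" / f"{row.slide_id}.png").convert("L")) > 127
        cov = {
            k[len("cov_"):]: row[k]
            for k in meta.columns
            if k.startswith("cov_") and pd.notna(row[k])
        }
        records.append(
            SlideRecord(
                slide_id=str(row.slide_id),
                patient_id=str(row.patient_id),
                site_id=int(row.site_id),
                label=str(row.label),
                image=image,
                roi_mask=roi,
                covariates=cov,
            )
        )
    return records
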