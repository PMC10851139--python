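"""Slide preprocessing: tessellation, blur quality control, inclusion rules.

A slide is an RGB raster with a binary region-of-interest (ROI) mask over the
epidermis.  Preprocessing downscales the pair, cuts the ROI into a
non-overlapping grid of square patches, scores every patch with a
variance-of-Laplacian sharpness measure, flags blurry patches below a
threshold, and finally applies the slide-level inclusion rule (a minimum
number of sharp patches per slide).

The defaults mirror a 0.25 um/px source scan downscaled by 1.84 so that a
224-px patch spans 224 * 0.25 * 1.84 = 103.04 um of tissue, with a sharpness
threshold of 510 on the Laplacian-variance scale of such scans.  Synthetic
desk-scale data uses smaller patches and a threshold calibrated to its own
intensity statistics (see the runner profiles).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, ValidationError

__all__ = [
    "PreprocConfig",
    "PatchSet",
    "tessellate",
    "laplacian_sharpness",
    "filter_blurry",
    "filter_slides",
    "preprocess_dataset",
    "write_manifest",
    "DEFAULT_BLUR_THRESHOLD",
]

DEFAULT_BLUR_THRESHOLD = 510.0

#: 3x3 discrete Laplacian stencil (4-neighbour).
_LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)

#: ITU-R BT.601 luma weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PreprocConfig:
    """Geometry and quality-control settings for patch extraction.

    Parameters
    ----------
    edge_px:
        Square patch edge length in pixels after downscaling.
    source_um_per_px:
        Physical resolution of the source scan (micrometres per pixel).
    downscale:
        Linear downscaling factor applied before tessellation.
    blur_threshold:
        Minimum variance-of-Laplacian for a patch to be kept.
    min_patches:
        Minimum number of kept patches for a slide to be included.
    coverage_min:
        Minimum fraction of a grid square covered by the ROI mask for the
        patch to be emitted at all.
    """

    edge_px: int = 224
    source_um_per_px: float = 0.25
    downscale: float = 1.84
    blur_threshold: float = DEFAULT_BLUR_THRESHOLD
    min_patches: int = 50
    coverage_min: float = 0.5

    def __post_init__(self):
        if self.edge_px <= 0:
            raise ConfigurationError("edge_px must be positive")
        if self.downscale < 1:
            raise ConfigurationError("downscale must be >= 1")
        if self.min_patches < 1:
            raise ConfigurationError("min_patches must be >= 1")
        if not 0 < self.coverage_min <= 1:
            raise ConfigurationError("coverage_min must be in (0, 1]")

    @property
    def physical_edge_um(self) -> float:
        """Physical patch edge in micrometres of source tissue."""
        return self.edge_px * self.source_um_per_px * self.downscale


@dataclass
class PatchSet:
    """Ordered square patches cut from one slide.

    ``origins`` are (x, y) top-left corners in the *downscaled* coordinate
    frame, listed in row-major grid order.  ``kept[i]`` is True iff
    ``sharpness[i]`` met the blur threshold when the set was built or last
    filtered.
    """

    slide_id: str
    patches: np.ndarray  # (n, edge, edge, 3) uint8
    origins: np.ndarray  # (n, 2) int
    sharpness: np.ndarray  # (n,) float
    kept: np.ndarray  # (n,) bool

    def __post_init__(self):
        n = len(self.patches)
        if not (len(self.origins) == len(self.sharpness) == len(self.kept) == n):
            raise ValidationError("patches/origins/sharpness/kept lengths differ")
        if n and self.patches.shape[1] != self.patches.shape[2]:
            raise ValidationError("patches must be square")

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_patches(self) -> np.ndarray:
        return self.patches[self.kept]


def laplacian_sharpness(patch: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian response of the grayscale patch.

    Grayscale uses ITU-R BT.601 luma; borders are reflect-padded.  A
    constant patch scores exactly 0; Gaussian smoothing strictly lowers the
    score of any textured patch.
    """
    if patch.size == 0:
        raise ValidationError("empty patch")
    gray = patch.astype(np.float64) @ _LUMA if patch.ndim == 3 else patch.astype(np.float64)
    lap = ndimage.convolve(gray, _LAPLACIAN_KERNEL, mode="reflect")
    return float(lap.var())


def _downscale_pair(image: np.ndarray, mask: np.ndarray, factor: float):
    if factor == 1.0:
        return image, mask.astype(bool)
    h, w = mask.shape
    new_w, new_h = int(w / factor), int(h / factor)
    img = np.asarray(
        Image.fromarray(image).resize((new_w, new_h), Image.BILINEAR)
    )
    msk = np.asarray(
        Image.fromarray((mask.astype(np.uint8)) * 255).resize((new_w, new_h), Image.NEAREST)
    )
    return img, msk > 127


def tessellate(image: np.ndarray, mask: np.ndarray, cfg: PreprocConfig, slide_id: str = "slide") -> PatchSet:
    """Cut the masked region of a slide into a grid of square patches.

    The image/mask pair is downscaled by ``cfg.downscale``, then scanned in
    row-major order with a non-overlapping ``edge_px`` grid anchored at
    (0, 0).  A grid square is emitted iff at least ``cfg.coverage_min`` of
    its area is ROI.  Each emitted patch gets a sharpness score and a kept
    flag (``sharpness >= cfg.blur_threshold``).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValidationError(
            f"image shape {image.shape[:2]} != mask shape {mask.shape[:2]}"
        )
    img, msk = _downscale_pair(image, mask, cfg.downscale)
    e = cfg.edge_px
    h, w = msk.shape
    patches, origins, sharp = [], [], []
    for y in range(0, h - e + 1, e):
        for x in range(0, w - e + 1, e):
            cov = msk[y : y + e, x : x + e].mean()
            if cov >= cfg.coverage_min:
                patch = img[y : y + e, x : x + e]
                patches.append(patch)
                origins.append((x, y))
                sharp.append(laplacian_sharpness(patch))
    n = len(patches)
    patches_arr = (
        np.stack(patches) if n else np.empty((0, e, e, 3), dtype=np.uint8)
    )
    sharp_arr = np.asarray(sharp, dtype=np.float64)
    return PatchSet(
        slide_id=slide_id,
        patches=patches_arr,
        origins=np.asarray(origins, dtype=np.int64).reshape(n, 2),
        sharpness=sharp_arr,
        kept=sharp_arr >= cfg.blur_threshold,
    )


def filter_blurry(ps: PatchSet, threshold: float | None = None) -> PatchSet:
    """Re-flag patches against a sharpness threshold (default 510).

    Discarded patches stay in the set with ``kept=False`` so manifests keep
    a complete record; downstream sampling only sees kept patches.  The
    operation is idempotent.
    """
    thr = DEFAULT_BLUR_THRESHOLD if threshold is None else float(threshold)
    return PatchSet(
        slide_id=ps.slide_id,
        patches=ps.patches,
        origins=ps.origins,
        sharpness=ps.sharpness,
        kept=ps.sharpness >= thr,
    )


def filter_slides(dataset, min_patches: int):
    """Apply the slide-level inclusion rule.

    Parameters
    ----------
    dataset:
        Iterable of ``(record, patch_set)`` pairs; blur filtering must have
        run already.
    min_patches:
        A slide is included iff its kept-patch count is >= this value.

    Returns
    -------
    (included, excluded):
        ``included`` is a list of the passing pairs; ``excluded`` is a list
        of ``(record, patch_set, reason)`` triples.
    """
    included, excluded = [], []
    for record, ps in dataset:
        if ps.n_kept >= min_patches:
            included.append((record, ps))
        else:
            excluded.append(
                (record, ps, f"fewer than {min_patches} kept patches (n={ps.n_kept})")
            )
    return included, excluded


def preprocess_dataset(records, cfg: PreprocConfig):
    """Tessellate + QC a list of slide records.

    Each record needs ``image``, ``roi_mask`` and ``slide_id`` attributes.
    Returns ``(included, excluded, report)`` where ``report`` is a JSON-able
    summary (per-slide patch counts and exclusion reasons).
    """
    pairs = []
    for rec in records:
        ps = tessellate(rec.image, rec.roi_mask, cfg, slide_id=rec.slide_id)
        pairs.append((rec, ps))
    included, excluded = filter_slides(pairs, cfg.min_patches)
    report = {
        "n_slides_in": len(pairs),
        "n_slides_included": len(included),
        "n_slides_excluded": len(excluded),
        "physical_edge_um": cfg.physical_edge_um,
        "blur_threshold": cfg.blur_threshold,
        "exclusions": [
            {"slide_id": rec.slide_id, "reason": reason} for rec, _, reason in excluded
        ],
        "patch_counts": {
            rec.slide_id: {"total": ps.n_patches, "kept": ps.n_kept}
            for rec, ps in pairs
        },
    }
    return included, excluded, report


def write_manifest(patchsets, out_dir, report: dict | None = None, write_patches: bool = False):
    """Write the patch manifest CSV (and optionally patch PNGs + report JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "patch_manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "patch_idx", "x", "y", "sharpness", "kept"])
        for ps in patchsets:
            for i in range(ps.n_patches):
                writer.writerow(
                    [ps.slide_id, i, ps.origins[i, 0], ps.origins[i, 1],
                     f"{ps.sharpness[i]:.6f}", bool(ps.kept[i])]
                )
            if write_patches:
                pdir = out / "patches" / ps.slide_id
                pdir.mkdir(parents=True, exist_ok=True)
                for i in range(ps.n_patches):
                    Image.fromarray(ps.patches[i]).save(pdir / f"{i:04d}.png")
    if report is not None:
        with open(out / "preprocessing_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
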