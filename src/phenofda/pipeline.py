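"""End-to-end batch pipeline: image directory + metadata CSV -> confidence bands.

Stage order: segmentation -> morphological refinement -> ROI crop -> plant
region identification -> trait extraction -> functional ANOVA -> bands.  When
``method = "both-intersect"`` the DCT and HMRF masks are intersected, keeping
only the plant area common to both methods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fanova import FanovaFit, SplineBasis, coef_covariance, fanova_fit
from .hmrf import HMRFConfig, hmrf_segment, kmeans_labels, plant_class_mask
from .image_core import SceneConfig, read_image, relative_green, synth_scene, write_image, write_mask
from .inference import ci_contrast
from .segmentation import (
    DCTParams,
    DEFAULT_REFINEMENT,
    Rect,
    ROIConfig,
    contrast_image,
    crop,
    dct_binarize,
    detect_roi,
    largest_component,
    mask_intersect,
    refine_mask,
)
from .traits import PixelScale, TraitMatrix, TraitRecord, assemble_trait_matrix, extract_pheno, records_to_frame

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "segment_image",
    "make_fixtures",
    "load_config",
    "fit_to_json",
    "fit_from_json",
    "CONTRAST_DCT_DEFAULTS",
]

log = logging.getLogger("phenofda")

#: DCT settings for the signed contrast image: threshold1 = 0.7 on the summed
#: signed contrast, threshold2 = 0 with weight (1, -2, 1).
CONTRAST_DCT_DEFAULTS = DCTParams(weight=(1.0, -2.0, 1.0), threshold1=0.7, threshold2=0.0)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    image_dir: str = "."
    metadata_csv: str = "metadata.csv"
    output_dir: str = "out"
    reference_image: str | None = None
    method: str = "dct"  # dct | hmrf | both-intersect
    dct: DCTParams = field(default_factory=DCTParams)
    contrast_dct: DCTParams = field(default_factory=lambda: CONTRAST_DCT_DEFAULTS)
    hmrf: HMRFConfig = field(default_factory=HMRFConfig)
    refine: bool = True
    refinement: tuple = DEFAULT_REFINEMENT
    roi: str = "auto"  # auto | none | manual
    roi_rect: tuple | None = None
    keep_largest: bool = True
    connectivity: int = 8
    xsize: float = 1.0
    ysize: float = 1.0
    trait: str = "size"
    formula: str = "size ~ genotype + block"
    n_interior: int | None = None
    degree: int = 3
    lam_grid: list | None = None
    level: float = 0.95
    contrasts: tuple = ()  # (j1, j2) pairs, 1-based design columns
    seed: int = 0

    def validate(self):
        if self.method not in ("dct", "hmrf", "both-intersect"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.roi not in ("auto", "none", "manual"):
            raise ValueError(f"unknown roi mode {self.roi!r}")
        if self.roi == "manual" and (self.roi_rect is None or len(self.roi_rect) != 4):
            raise ValueError("roi=manual requires roi_rect = (r0, r1, c0, c1)")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        for pair in self.contrasts:
            if len(pair) != 2:
                raise ValueError(f"contrast must be a (j1, j2) pair, got {pair}")


def load_config(path) -> PipelineConfig:
    """Read a YAML config; nested dct/contrast_dct/hmrf blocks map onto their
    parameter dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, cls in (("dct", DCTParams), ("contrast_dct", DCTParams), ("hmrf", HMRFConfig)):
        if key in raw and isinstance(raw[key], dict):
            if cls is DCTParams and "weight" in raw[key]:
                raw[key]["weight"] = tuple(raw[key]["weight"])
            raw[key] = cls(**raw[key])
    if "refinement" in raw:
        raw["refinement"] = tuple((op, int(n)) for op, n in raw["refinement"])
    if "contrasts" in raw:
        raw["contrasts"] = tuple(tuple(int(j) for j in pair) for pair in raw["contrasts"])
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def segment_image(img, cfg: PipelineConfig, reference=None) -> np.ndarray:
    """Segmentation stage: DCT (optionally intersected with contrast DCT),
    HMRF, or the intersection of both methods."""
    mask = None
    if cfg.method in ("dct", "both-intersect"):
        mask = dct_binarize(img, cfg.dct)
        if reference is not None:
            mask = mask_intersect(mask, dct_binarize(contrast_image(img, reference), cfg.contrast_dct))
    if cfg.method in ("hmrf", "both-intersect"):
        y = relative_green(img)
        labels, params, _ = hmrf_segment(y, kmeans_labels(y, cfg.hmrf.K, cfg.hmrf.seed), cfg.hmrf)
        hmask = plant_class_mask(labels, params)
        mask = hmask if mask is None else mask_intersect(mask, hmask)
    return mask


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns a manifest dict of written artifacts."""
    cfg.validate()
    out = Path(cfg.output_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    try:
        meta = pd.read_csv(cfg.metadata_csv)
    except OSError as exc:
        raise PipelineError(f"input: cannot read metadata CSV {cfg.metadata_csv}: {exc}") from exc
    required = {"plant_id", "genotype", "block", "day", "image"}
    if not required <= set(meta.columns):
        raise PipelineError(f"input: metadata CSV must have columns {sorted(required)}")

    reference = None
    if cfg.reference_image is not None:
        try:
            reference = read_image(cfg.reference_image)
        except (OSError, FileNotFoundError, ValueError) as exc:
            raise PipelineError(f"segmentation: cannot read reference image: {exc}") from exc

    roi = None
    if cfg.roi == "manual":
        roi = Rect(*cfg.roi_rect)

    scale = PixelScale(cfg.xsize, cfg.ysize)
    records = []
    # sort for order invariance: the output never depends on CSV row order
    meta_sorted = meta.sort_values(["plant_id", "day"], kind="stable")
    for row in meta_sorted.itertuples(index=False):
        img_path = Path(cfg.image_dir) / str(row.image)
        try:
            img = read_image(img_path)
        except (OSError, FileNotFoundError, ValueError) as exc:
            raise PipelineError(f"segmentation: cannot read {img_path}: {exc}") from exc
        log.info("segmenting %s (%s, day %s): %s", row.plant_id, row.genotype, row.day, img_path.name)
        try:
            mask = segment_image(img, cfg, reference)
        except Exception as exc:
            raise PipelineError(f"segmentation: {img_path.name}: {exc}") from exc
        if cfg.refine:
            mask = refine_mask(mask, cfg.refinement)
        if cfg.roi != "none":
            try:
                rect = roi if roi is not None else detect_roi(reference if reference is not None else img)
            except Exception as exc:
                raise PipelineError(f"roi: {img_path.name}: {exc}") from exc
            mask = crop(mask, rect)
        if cfg.keep_largest and mask.any():
            mask = largest_component(mask, cfg.connectivity)
        mask_path = out / "masks" / f"{row.plant_id}_day{row.day}.png"
        write_mask(mask_path, mask)
        h, w, s = extract_pheno(mask, scale)
        records.append(
            TraitRecord(str(row.plant_id), str(row.genotype), str(row.block), float(row.day), h, w, s)
        )

    traits_df = records_to_frame(records)
    traits_csv = out / "traits.csv"
    traits_df.to_csv(traits_csv, index=False)

    try:
        Y = assemble_trait_matrix(records, cfg.trait)
        fit = fanova_fit(
            Y, cfg.formula, lam_grid=cfg.lam_grid, degree=cfg.degree, n_interior=cfg.n_interior
        )
    except Exception as exc:
        raise PipelineError(f"fanova: {exc}") from exc
    fit_path = out / "fit.json"
    fit_to_json(fit, fit_path)

    band_paths = []
    for j1, j2 in cfg.contrasts:
        try:
            band = ci_contrast(fit, j1, j2, level=cfg.level)
        except Exception as exc:
            raise PipelineError(f"ci: contrast ({j1}, {j2}): {exc}") from exc
        path = out / f"band_j{j1}_j{j2}.csv"
        band.to_frame().to_csv(path, index=False)
        band_paths.append(str(path))

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "method": cfg.method,
        "formula": cfg.formula,
        "lambda": fit.lam,
        "n_images": len(records),
        "traits_csv": str(traits_csv),
        "fit_json": str(fit_path),
        "bands": band_paths,
        "mask_dir": str(out / "masks"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def fit_to_json(fit: FanovaFit, path) -> None:
    """Serialize what the band constructors need: basis, design columns,
    coefficients, lambda, coefficient covariance, and the day grid."""
    if fit.cov is None:
        coef_covariance(fit)
    payload = {
        "degree": fit.basis.degree,
        "interior": fit.basis.interior.tolist(),
        "domain": list(fit.basis.domain),
        "colnames": list(fit.colnames),
        "beta": fit.beta.tolist(),
        "lambda": fit.lam,
        "cov": fit.cov.tolist(),
        "days": fit.Y.days.tolist(),
        "level_default": 0.95,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def fit_from_json(path) -> FanovaFit:
    """Rebuild a band-capable fit object from :func:`fit_to_json` output.

    Only the fields used by ``ci``/``ci_contrast``/``predict_curve`` are
    restored; the smoother operator and stacked data are not serialized.
    """
    with open(path) as fh:
        d = json.load(fh)
    basis = SplineBasis(d["degree"], np.asarray(d["interior"]), tuple(d["domain"]))
    days = np.asarray(d["days"])
    empty_Y = TraitMatrix(
        np.zeros((0, days.size)),
        days,
        pd.DataFrame(columns=["plant_id", "genotype", "block"]),
    )
    p = len(d["colnames"])
    beta = np.asarray(d["beta"])
    return FanovaFit(
        basis=basis,
        design=np.zeros((0, p)),
        colnames=list(d["colnames"]),
        beta=beta,
        lam=float(d["lambda"]),
        lam_grid=np.asarray([d["lambda"]]),
        gcv=np.asarray([np.nan]),
        A=np.zeros((beta.size, 0)),
        y=np.zeros(0),
        fitted=np.zeros(0),
        row_plant=np.zeros(0, dtype=int),
        row_dayidx=np.zeros(0, dtype=int),
        trH=np.nan,
        Y=empty_Y,
        cov=np.asarray(d["cov"]),
    )


def make_fixtures(out_dir, n_plants: int = 3, n_days: int = 4, seed: int = 0) -> Path:
    """Write a small synthetic experiment: per-(plant, day) scene images, one
    empty-pot reference, and the metadata CSV.  Plants share one block and
    have one genotype each; the plant silhouette grows with the day index at
    a genotype-specific rate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    reference_written = False
    for p in range(1, n_plants + 1):
        for d in range(1, n_days + 1):
            growth = 3 * d + p  # genotype-specific growth rate, in pixels
            cfg = SceneConfig(
                stem_rect=(90 - (25 + 2 * growth), 90, 76, 84),
                leaf_rect=(55, 63, 80 - (10 + growth), 80 + (10 + growth)),
                noise_sd=0.005,
                seed=seed * 10_000 + p * 100 + d,
            )
            plant, empty, _ = synth_scene(cfg)
            name = f"plant{p}_day{d}.png"
            write_image(out / name, plant)
            if not reference_written:
                write_image(out / "reference.png", empty)
                reference_written = True
            rows.append((f"p{p}", f"g{p}", "b1", float(d), name))
    pd.DataFrame(rows, columns=["plant_id", "genotype", "block", "day", "image"]).to_csv(
        out / "metadata.csv", index=False
    )
    return out
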