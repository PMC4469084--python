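"""End-to-end orchestration: preprocess -> segment -> features -> LOOCV report.

The pipeline mirrors the five-step scheme the package implements:
(1) grayscale conversion, linear normalization and median filtering;
(2) multilevel Otsu quantization, skull stripping and tumor-mask
extraction, plus sampling of a same-area normal-brain region;
(3) per-region feature extraction (3-component GMM vector by default,
wavelet db1/coif1 vectors as the comparison family);
(4) optional PCA reduction (pooled, fitted per training fold);
(5) per-sequence and pooled leave-one-out evaluation with kernel NB,
RBF SVM and PNN.

Input is either a generated phantom cohort (no external data needed) or a
manifest of image files tagged with patient id and sequence.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import classify, gmm, pca, phantom, preprocess, segment, wavelet

__all__ = [
    "RunConfig",
    "PipelineResult",
    "segment_image",
    "sample_normal_region",
    "extract_region_features",
    "run_pipeline",
]

log = logging.getLogger("braingmm")

FEATURE_FAMILIES = ("gmm", "pca", "wavelet-db1", "wavelet-coif1")


@dataclass
class RunConfig:
    """Everything a run needs; hashable so outputs can be traced to a config."""

    # input: either a manifest of {path, patient, sequence} records ...
    manifest: Optional[list] = None
    # ... or phantom-cohort parameters
    n_patients: int = 17
    image_size: int = 128
    # preprocessing
    median_window: int = 3
    normalize_range: tuple = (0.0, 255.0)
    # segmentation
    n_thresholds: int = 3
    n_bins: int = 256
    erosion_radius: int = 5
    tumor_band: Optional[int] = None
    opening_radius: int = 2
    min_area: int = 30
    # features / evaluation
    feature_family: str = "gmm"
    gmm_components: int = 3
    pca_components: int = 3
    classifiers: Sequence[str] = ("nb", "svm", "pnn")
    standardize: bool = True
    group_by_patient: bool = False
    per_class_pca: bool = False
    pooled: bool = False
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.feature_family not in FEATURE_FAMILIES:
            raise ValueError(f"feature_family must be one of {FEATURE_FAMILIES}")
        if self.manifest:
            for rec in self.manifest:
                p = Path(rec["path"])
                if not p.exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    features: "gmm.FeatureMatrix"
    reports: dict  # mode -> EvalReport
    excluded: list = field(default_factory=list)
    config_hash: str = ""
    out_dir: Optional[str] = None


def segment_image(image: np.ndarray, cfg: RunConfig) -> dict:
    """Preprocess and segment one slice; returns masks, labels and thresholds."""
    img = preprocess.to_grayscale(image)
    img = preprocess.median_filter(img, window=cfg.median_window)
    img = preprocess.normalize_linear(img, out_range=cfg.normalize_range)
    hist = segment.histogram(img, n_bins=cfg.n_bins, value_range=cfg.normalize_range)
    thresholds = segment.otsu_multithreshold(hist, m=cfg.n_thresholds)
    labels = segment.quantize(img, thresholds)
    brain = segment.skull_strip(labels, erosion_radius=cfg.erosion_radius)
    # the bright skull dominates the top whole-image band, so re-threshold
    # within the brain material before picking the tumor band
    hist_brain = segment.histogram(img, mask=brain, n_bins=cfg.n_bins,
                                   value_range=cfg.normalize_range)
    thr_brain = segment.otsu_multithreshold(hist_brain, m=cfg.n_thresholds)
    labels_brain = segment.quantize(img, thr_brain)
    tumor = segment.extract_tumor_mask(
        labels_brain,
        brain,
        band=cfg.tumor_band,
        opening_radius=cfg.opening_radius,
        min_area=cfg.min_area,
    )
    normal = sample_normal_region(brain, tumor, area=int(tumor.sum()))
    return {
        "image": img,
        "thresholds": thresholds,
        "labels": labels,
        "brain_thresholds": thr_brain,
        "brain_labels": labels_brain,
        "brain_mask": brain,
        "tumor_mask": tumor,
        "normal_mask": normal,
    }


def sample_normal_region(brain, tumor, area: int, margin: int = 2) -> np.ndarray:
    """Normal-brain patch of the requested area, maximally distant from the tumor.

    The patch center is the brain-interior pixel farthest from the tumor
    mask; the patch is the ``area`` interior pixels nearest that center
    (a quasi-disk clipped to the brain).
    """
    brain = np.asarray(brain, dtype=bool)
    tumor = np.asarray(tumor, dtype=bool)
    interior = brain & ~ndimage.binary_dilation(tumor, iterations=margin)
    if interior.sum() < area:
        raise ValueError("brain interior too small for a normal region of the tumor's area")
    dist_from_tumor = ndimage.distance_transform_edt(~tumor)
    dist_from_tumor[~interior] = -1.0
    cy, cx = np.unravel_index(np.argmax(dist_from_tumor), tumor.shape)
    yy, xx = np.nonzero(interior)
    order = np.argsort((yy - cy) ** 2 + (xx - cx) ** 2, kind="stable")[:area]
    mask = np.zeros_like(brain)
    mask[yy[order], xx[order]] = True
    return mask


def extract_region_features(image, mask, cfg: RunConfig, label: str, provenance: dict):
    """One region -> one feature row of the configured family."""
    family = cfg.feature_family
    if family in ("gmm", "pca"):
        params = gmm.fit_gmm(np.asarray(image)[np.asarray(mask, dtype=bool)], K=cfg.gmm_components)
        return gmm.build_feature_vector(params, label=label, provenance=provenance)
    wavelet_name = family.split("-", 1)[1]
    wf = wavelet.extract_wavelet_features(image, mask, wavelet_name=wavelet_name)
    return gmm.FeatureVector(values=wf.vector, names=wf.names, label=label, provenance=provenance)


def _load_inputs(cfg: RunConfig):
    """Yield (patient_id, sequence, image) for manifest or phantom-cohort input."""
    if cfg.manifest:
        for rec in cfg.manifest:
            yield rec["patient"], rec["sequence"], preprocess.read_image(rec["path"])
    else:
        specs = phantom.default_sequence_specs(image_size=cfg.image_size)
        for item in phantom.generate_cohort(cfg.n_patients, specs, seed=cfg.seed):
            yield item.patient_id, item.sequence, item.truth.image


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full chain and evaluate per sequence (and pooled, if asked)."""
    rows, excluded = [], []
    seg_artifacts = []
    for patient, sequence, image in _load_inputs(cfg):
        ident = f"patient={patient} sequence={sequence}"
        try:
            seg = segment_image(image, cfg)
        except segment.NoTumorDetectedError as exc:
            log.warning("no tumor detected (%s): %s — image excluded", ident, exc)
            excluded.append({"patient": patient, "sequence": sequence, "reason": str(exc)})
            continue
        except Exception as exc:
            raise RuntimeError(f"segmentation failed for {ident}") from exc
        for region, mask in (("GBM", seg["tumor_mask"]), ("normal", seg["normal_mask"])):
            prov = {"patient": patient, "sequence": sequence, "region": region}
            try:
                rows.append(extract_region_features(seg["image"], mask, cfg, region, prov))
            except Exception as exc:
                raise RuntimeError(f"feature extraction failed for {ident} region={region}") from exc
        seg_artifacts.append((patient, sequence, seg))

    if not rows:
        raise RuntimeError("no usable images: every input was excluded")
    fm = gmm.build_feature_matrix(rows)

    sequences = sorted({p["sequence"] for p in fm.provenance})
    pca_k = cfg.pca_components if cfg.feature_family == "pca" else None
    reports: dict[str, classify.EvalReport] = {}
    modes = [(s, [i for i, p in enumerate(fm.provenance) if p["sequence"] == s]) for s in sequences]
    if cfg.pooled:
        modes.append(("pooled", list(range(fm.n))))
    for mode, idx in modes:
        sub = fm.subset(np.isin(np.arange(fm.n), idx))
        data = classify.LabeledDataset.from_feature_matrix(sub)
        if data.n < 4 or np.unique(data.labels).size < 2:
            log.warning("mode %s has too few samples (%d) for LOOCV; skipping evaluation",
                        mode, data.n)
            continue
        reports[mode] = classify.evaluate(
            data,
            classifiers=cfg.classifiers,
            standardize=cfg.standardize,
            group_by_patient=cfg.group_by_patient,
            pca_components=pca_k,
        )
        reports[mode].meta.update({"mode": mode, "feature_family": cfg.feature_family,
                                   "seed": cfg.seed, "config_hash": cfg.config_hash()})

    result = PipelineResult(
        features=fm,
        reports=reports,
        excluded=excluded,
        config_hash=cfg.config_hash(),
        out_dir=cfg.out_dir,
    )
    if cfg.out_dir:
        _write_outputs(result, cfg, seg_artifacts)
    return result


def _write_outputs(result: PipelineResult, cfg: RunConfig, seg_artifacts) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / f"features_{cfg.feature_family}.csv")
    summary_rows = []
    for mode, report in result.reports.items():
        report.to_json(out / f"report_{mode}.json")
        df = report.to_dataframe()
        df.insert(0, "mode", mode)
        summary_rows.append(df)
    if summary_rows:
        import pandas as pd

        pd.concat(summary_rows, ignore_index=True).to_csv(out / "report_summary.csv", index=False)
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    for patient, sequence, seg in seg_artifacts:
        stem = f"p{patient}_{sequence}"
        preprocess.write_image(masks_dir / f"{stem}_tumor.png", seg["tumor_mask"], binary=True)
        preprocess.write_image(masks_dir / f"{stem}_normal.png", seg["normal_mask"], binary=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump({"config": asdict(cfg), "config_hash": cfg.config_hash(),
                   "excluded": result.excluded}, fh, indent=2, default=str)


def per_class_pca_models(fm: "gmm.FeatureMatrix", n_retained: int = 3) -> dict:
    """Descriptive per-class PCA bases (one eigenbasis per label)."""
    models = {}
    for label in sorted(set(fm.labels)):
        sub = fm.subset([lab == label for lab in fm.labels])
        models[label] = pca.PCAModel.from_feature_matrix(sub, n_retained=n_retained)
    return models
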