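"""End-to-end orchestration of the profiling and imaging workflows.

``run_profiling`` composes the full profiling chain — smoothing, SNIP
baseline subtraction, lock-mass recalibration, alignment, TIC
normalization, peak detection, feature binning, replicate QC, differential
testing, annotation and (optionally) pathway enrichment — over a set of
spectra with sample metadata.  ``run_msi`` composes the imaging chain —
TIC normalization, skyline projection, ion images and bisecting-k-means
segmentation.  Both are deterministic given inputs plus seed, and write a
manifest of every parameter that affects their outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .annotate import AnnotationConfig, annotate_peaklist, annotation_table
from .enrich import PathwayDB, rank_pathways
from .msi import IonImageConfig, MsiCube, SegmentationMap, bisecting_kmeans_segment, ion_image, skyline_spectrum
from .preprocess import (
    CalibrationConfig,
    FeatureMatrix,
    LockMassError,
    Peak,
    PeakList,
    ProfileSpectrum,
    QcReport,
    align_spectra,
    detect_peaks,
    extract_feature_matrix,
    mean_spectrum,
    recalibrate_spectrum,
    replicate_cv,
    savgol_smooth,
    subtract_baseline,
    tic_normalize,
)
from .reference import LipidDB, load_default_db
from .stats import DifferentialConfig, differential_features, pca_scores

__all__ = [
    "PreprocessParams",
    "ProfilingResult",
    "MsiResult",
    "preprocess_spectra",
    "run_profiling",
    "run_msi",
]


@dataclass(frozen=True)
class PreprocessParams:
    snip_iterations: int = 100
    # 11-bin window: near the peak FWHM at the default grid and resolving
    # power, so narrow low-mass peaks survive smoothing
    savgol_half_window: int = 5
    savgol_order: int = 3
    snr_threshold: float = 3.0
    noise_window: int = 200
    n_anchor_peaks: int = 10
    match_tolerance: float = 5e-4
    # per-sample intensity readout around a consensus feature: reflects
    # post-recalibration apex accuracy, deliberately tighter than the
    # annotation tolerance so neighboring peaks do not bleed into a feature
    extraction_window: float = 1e-4
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    recalibrate: bool = True
    align: bool = True


@dataclass
class ProfilingResult:
    feature_matrix: FeatureMatrix
    qc: QcReport
    differential: pd.DataFrame
    annotations: pd.DataFrame
    pathways: pd.DataFrame | None
    pca: tuple[np.ndarray, np.ndarray, np.ndarray]
    manifest: dict


@dataclass
class MsiResult:
    segmentation: SegmentationMap
    skyline: np.ndarray
    ion_images: dict[float, np.ndarray]
    manifest: dict


def preprocess_spectra(
    spectra: Sequence[ProfileSpectrum], params: PreprocessParams = PreprocessParams()
) -> tuple[list[ProfileSpectrum], list[PeakList]]:
    """Smoothing, baseline, recalibration, alignment, TIC, peak detection.

    Spectra that miss their lock mass are left uncalibrated with a warning
    (the run continues; the flag surfaces in the manifest counts).
    """
    processed: list[ProfileSpectrum] = []
    for s in spectra:
        # baseline first: smoothing a spiky spectrum rings below the baseline,
        # which the SNIP lower envelope would lock onto
        t = subtract_baseline(s, params.snip_iterations)
        t = savgol_smooth(t, params.savgol_half_window, params.savgol_order)
        if params.recalibrate:
            try:
                t, _shift = recalibrate_spectrum(t, params.calibration)
            except LockMassError as exc:
                warnings.warn(f"{s.sample_id}: {exc}; spectrum left unchanged",
                              stacklevel=2)
        processed.append(t)
    if params.align and len(processed) >= 2:
        processed = align_spectra(processed, params.n_anchor_peaks)
    processed = [tic_normalize(s)[0] for s in processed]
    peaklists = [
        detect_peaks(s, params.snr_threshold, params.noise_window) for s in processed
    ]
    return processed, peaklists


def _manifest(params: dict, inputs: dict) -> dict:
    body = {"parameters": params, "inputs": inputs}
    digest = hashlib.sha256(
        json.dumps(body, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {**body, "manifest_sha256": digest}


def _params_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _params_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    return obj


def run_profiling(
    spectra: Sequence[ProfileSpectrum],
    samples: pd.DataFrame,
    contrast: str = "group",
    params: PreprocessParams = PreprocessParams(),
    differential: DifferentialConfig = DifferentialConfig(),
    annotation: AnnotationConfig | None = None,
    db: LipidDB | None = None,
    pathway_db: PathwayDB | None = None,
    out_dir: str | Path | None = None,
) -> ProfilingResult:
    """The profiling workflow end to end, in memory, optionally writing files.

    ``samples`` must have one row per spectrum (matching order) with columns
    ``sample_id``, ``bio_sample`` and the contrast column.  A failed
    replicate-CV gate warns and flags, it does not abort.  When a pathway
    database is supplied, the query is the set of top-ranked lipid names of
    significant features.
    """
    if len(spectra) != len(samples):
        raise ValueError("one metadata row per spectrum required")
    polarity = spectra[0].polarity
    db = db or load_default_db()
    annotation = annotation or AnnotationConfig(polarity=polarity)

    processed, _peaklists = preprocess_spectra(spectra, params)
    # features from the total average spectrum, intensities extracted per
    # sample at the consensus positions (no per-sample re-detection)
    consensus = detect_peaks(
        mean_spectrum(processed), params.snr_threshold, params.noise_window
    )
    fm = extract_feature_matrix(
        processed, consensus, params.extraction_window, samples
    )
    qc = replicate_cv(fm) if "bio_sample" in samples.columns else None
    if qc is not None and not qc.passed:
        warnings.warn(
            f"replicate QC failed: mean CV {qc.mean_cv:.2f} >= 0.50", stacklevel=2
        )
    table = differential_features(fm, contrast, differential)

    # annotate the consensus features (cohort-mean intensities drive the
    # isotope-ratio gate)
    feature_peaks = PeakList(
        [
            Peak(float(mz), float(fm.values[:, j].mean()), 0.0)
            for j, mz in enumerate(fm.feature_mz)
        ],
        polarity,
    )
    features = annotate_peaklist(feature_peaks, db, annotation)
    ann = annotation_table(features)

    pathways = None
    if pathway_db is not None and len(table):
        sig = table[table["significant"]]
        sig_mz = set(np.round(sig["mz"].to_numpy(), 6))
        query = {
            f.top.lipid.name
            for f in features
            if f.top is not None and round(f.observed_mz, 6) in sig_mz
        }
        if query:
            pathways = rank_pathways(query, pathway_db)

    scores, loadings, explained = pca_scores(fm, n_components=min(2, max(1, len(samples) - 1)))

    manifest = _manifest(
        {
            "preprocess": _params_dict(params),
            "differential": _params_dict(differential),
            "annotation": _params_dict(annotation),
            "contrast": contrast,
        },
        {
            "n_spectra": len(spectra),
            "polarity": polarity,
            "n_features": int(fm.feature_mz.size),
            "mean_cv": None if qc is None else qc.mean_cv,
            "qc_passed": None if qc is None else qc.passed,
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
        },
    )
    result = ProfilingResult(fm, qc, table, ann, pathways, (scores, loadings, explained), manifest)
    if out_dir is not None:
        _write_profiling(result, Path(out_dir))
    return result


def _write_profiling(result: ProfilingResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    mio.write_feature_matrix(result.feature_matrix, out_dir / "feature_matrix.csv")
    result.differential.to_csv(out_dir / "differential.csv", index=False,
                               float_format="%.8g")
    result.annotations.to_csv(out_dir / "annotations.csv", index=False,
                              float_format="%.8g")
    if result.pathways is not None:
        result.pathways.to_csv(out_dir / "pathways.csv", index=False,
                               float_format="%.8g")
    if result.qc is not None:
        pd.DataFrame(
            {"mz": result.qc.feature_mz, "cv": result.qc.feature_cv}
        ).to_csv(out_dir / "qc_cv.csv", index=False, float_format="%.8g")
    scores, _loadings, explained = result.pca
    pd.DataFrame(
        scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        index=result.feature_matrix.samples["sample_id"],
    ).to_csv(out_dir / "pca_scores.csv", float_format="%.8g")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_msi(
    cube: MsiCube,
    max_leaves: int = 4,
    min_split_distance: float = 0.0,
    ion_targets: Sequence[float] = (),
    ion_half_width: float = 0.2,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> MsiResult:
    """The imaging workflow: normalization, skyline, ion maps, segmentation."""
    norm = cube.tic_normalized() if len(cube) and cube.intensity.sum() > 0 else cube
    seg = bisecting_kmeans_segment(norm, max_leaves, min_split_distance, seed)
    sky = skyline_spectrum(cube)
    images = {
        float(t): ion_image(cube, IonImageConfig(t, ion_half_width)) for t in ion_targets
    }
    manifest = _manifest(
        {
            "max_leaves": max_leaves,
            "min_split_distance": min_split_distance,
            "ion_half_width": ion_half_width,
            "seed": seed,
        },
        {"n_pixels": len(cube), "n_bins": int(cube.mz.size)},
    )
    result = MsiResult(seg, sky, images, manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mio.write_segmentation(seg, out_dir / "segmentation.csv",
                               out_dir / "split_tree.json")
        np.savetxt(out_dir / "skyline.csv",
                   np.column_stack([cube.mz, sky]), fmt="%.4f,%.8g",
                   header="mz,intensity", comments="")
        for t, img in images.items():
            np.savetxt(out_dir / f"ion_{t:.1f}.csv", img, fmt="%.8g", delimiter=",")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    return result
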