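"""Reading and writing the text dialects used by the pipeline.

Profile spectra travel as two-column (m/z, intensity) text — whitespace or
comma separated — with the polarity taken from a ``_pos``/``_neg`` filename
suffix unless given explicitly; mzML input is supported through pyteomics
when available.  MSI cubes use a long-format ``x,y,mz,intensity`` CSV
dialect (imzML continuous mode is read through pyimzml when available).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .msi import MsiCube, SegmentationMap
from .preprocess import FeatureMatrix, ProfileSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_spectra_dir",
    "read_imzml",
    "read_cube_csv",
    "write_cube_csv",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_segmentation",
]

_POLARITY_SUFFIX = re.compile(r"_(pos|neg)(?:\.|_|$)")


def _polarity_from_name(path: Path) -> int | None:
    m = _POLARITY_SUFFIX.search(path.stem + ".")
    if not m:
        return None
    return +1 if m.group(1) == "pos" else -1


def read_spectrum(path: str | Path, polarity: int | None = None) -> ProfileSpectrum:
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return _read_mzml(path, polarity)
    if polarity is None:
        polarity = _polarity_from_name(path) or +1
    data = np.loadtxt(path, delimiter="," if path.suffix.lower() == ".csv" else None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    order = np.argsort(data[:, 0])
    return ProfileSpectrum(
        data[order, 0], np.clip(data[order, 1], 0, None), polarity,
        sample_id=path.stem,
    )


def _read_mzml(path: Path, polarity: int | None) -> ProfileSpectrum:
    try:
        from pyteomics import mzml as pymzml
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading mzML requires the pyteomics package") from exc
    with pymzml.read(str(path)) as reader:
        for entry in reader:
            pol = polarity
            if pol is None:
                pol = -1 if "negative scan" in entry else +1
            return ProfileSpectrum(
                np.asarray(entry["m/z array"], float),
                np.clip(np.asarray(entry["intensity array"], float), 0, None),
                pol,
                sample_id=Path(path).stem,
            )
    raise ValueError(f"{path}: no spectrum found")


def write_spectrum(spectrum: ProfileSpectrum, path: str | Path) -> None:
    arr = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, arr, fmt="%.6f %.8g")


def read_spectra_dir(
    directory: str | Path, polarity: int | None = None
) -> list[ProfileSpectrum]:
    """All two-column text spectra in a directory, sorted by filename."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".txt", ".csv", ".tsv", ".dat", ".mzml")
    )
    if not files:
        raise ValueError(f"no spectrum files found in {directory}")
    return [read_spectrum(p, polarity) for p in files]


def read_imzml(path: str | Path) -> MsiCube:
    """Continuous-mode imzML (with its binary .ibd companion) into a cube."""
    try:
        from pyimzml.ImzMLParser import ImzMLParser
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading imzML requires the pyimzml package") from exc
    parser = ImzMLParser(str(path))
    pixels, rows = [], []
    mz_axis = None
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mzs, intensities = parser.getspectrum(i)
        if mz_axis is None:
            mz_axis = np.asarray(mzs, float)
        elif not np.array_equal(mz_axis, np.asarray(mzs, float)):
            raise ValueError("imzML cube is not continuous-mode (shared m/z axis)")
        pixels.append((int(x), int(y)))
        rows.append(np.clip(np.asarray(intensities, float), 0, None))
    if not pixels:
        raise ValueError(f"{path}: empty imzML file")
    return MsiCube(np.array(pixels), mz_axis, np.vstack(rows))


def read_cube_csv(path: str | Path) -> MsiCube:
    """Long-format ``x,y,mz,intensity`` CSV into an :class:`MsiCube`."""
    df = pd.read_csv(path, comment="#")
    required = {"x", "y", "mz", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"cube CSV needs columns {sorted(required)}")
    mz_axis = np.sort(df["mz"].unique())
    pix_df = df[["x", "y"]].drop_duplicates().reset_index(drop=True)
    pix_index = {(int(r.x), int(r.y)): i for i, r in pix_df.iterrows()}
    mz_index = {m: j for j, m in enumerate(mz_axis)}
    intensity = np.zeros((len(pix_df), mz_axis.size))
    for x, y, mz, inten in df[["x", "y", "mz", "intensity"]].itertuples(index=False):
        intensity[pix_index[(int(x), int(y))], mz_index[mz]] = inten
    labels = None
    if "region" in df.columns:
        labels = (
            df.drop_duplicates(["x", "y"])["region"].to_numpy()
        )
    return MsiCube(pix_df.to_numpy(int), mz_axis, intensity, labels)


def write_cube_csv(cube: MsiCube, path: str | Path, sparse_threshold: float = 0.0) -> None:
    """Write a cube in the long CSV dialect; near-zero bins may be dropped."""
    with open(path, "w") as fh:
        cols = "x,y,mz,intensity" + (",region" if cube.region_labels is not None else "")
        fh.write(cols + "\n")
        for i, (x, y) in enumerate(cube.pixels):
            keep = np.flatnonzero(cube.intensity[i] > sparse_threshold)
            region = (
                f",{cube.region_labels[i]}" if cube.region_labels is not None else ""
            )
            for j in keep:
                fh.write(
                    f"{x},{y},{cube.mz[j]:.4f},{cube.intensity[i, j]:.6g}{region}\n"
                )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Features as rows (first column mz), one column per sample."""
    df = pd.DataFrame(
        fm.values.T, columns=fm.samples["sample_id"], index=np.round(fm.feature_mz, 4)
    )
    df.index.name = "mz"
    df.to_csv(path, float_format="%.8g")


def read_feature_matrix(
    path: str | Path, samples: pd.DataFrame | None = None
) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="mz")
    if samples is None:
        samples = pd.DataFrame({"sample_id": list(df.columns)})
    return FeatureMatrix(df.index.to_numpy(float), df.to_numpy().T, samples)


def write_segmentation(seg: SegmentationMap, raster_path: str | Path,
                       tree_path: str | Path | None = None) -> None:
    np.savetxt(raster_path, seg.raster(), fmt="%d", delimiter=",")
    if tree_path is not None:
        Path(tree_path).write_text(seg.tree_json() + "\n")
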