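"""Mass spectrometry imaging: ion-density maps, skyline projection, segmentation.

Segmentation follows the bisecting k-means scheme used for "molecular
histology": pixels (TIC-normalized spectra) are recursively split in two by
k-means under the correlation distance d(u, v) = 1 - Pearson(u, v), and each
split records the correlation distance between the two child centroids and
the number of spectra involved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "MsiCube",
    "IonImageConfig",
    "SegmentationMap",
    "ion_image",
    "skyline_spectrum",
    "bisecting_kmeans_segment",
    "correlation_distance_matrix",
]


@dataclass
class MsiCube:
    """Per-pixel spectra over integer (x, y) coordinates on a shared m/z axis."""

    pixels: np.ndarray  # (n, 2) integer coordinates
    mz: np.ndarray
    intensity: np.ndarray  # pixels x mz
    region_labels: np.ndarray | None = None  # ground truth, synthetic cubes only

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) coordinate array")
        if len({tuple(p) for p in self.pixels}) != len(self.pixels):
            raise ValueError("pixel coordinates must be unique")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be ascending")
        if self.intensity.shape != (len(self.pixels), self.mz.size):
            raise ValueError("intensity must be pixels x mz")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.pixels)

    def tic_normalized(self) -> "MsiCube":
        tic = self.intensity.sum(axis=1, keepdims=True)
        if np.any(tic <= 0):
            raise ValueError("cube contains all-zero pixels")
        return MsiCube(self.pixels.copy(), self.mz.copy(), self.intensity / tic,
                       None if self.region_labels is None else self.region_labels.copy())

    def grid_shape(self) -> tuple[int, int]:
        return int(self.pixels[:, 0].max()) + 1, int(self.pixels[:, 1].max()) + 1


@dataclass(frozen=True)
class IonImageConfig:
    target_mz: float
    half_width: float = 0.2  # Da
    denoising: str = "median3x3"  # or "none"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.denoising not in ("none", "median3x3"):
            raise ValueError(f"unknown denoising mode {self.denoising!r}")


@dataclass
class SegmentationMap:
    """Pixel partition plus the binary split tree with per-split statistics."""

    pixels: np.ndarray
    labels: np.ndarray
    tree: dict

    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))

    def raster(self) -> np.ndarray:
        nx = int(self.pixels[:, 0].max()) + 1
        ny = int(self.pixels[:, 1].max()) + 1
        img = np.full((nx, ny), -1, dtype=int)
        img[self.pixels[:, 0], self.pixels[:, 1]] = self.labels
        return img

    def tree_json(self) -> str:
        return json.dumps(self.tree, indent=2)


def ion_image(cube: MsiCube, cfg: IonImageConfig) -> np.ndarray:
    """2-D ion density map: per pixel, summed intensity within +/- half_width.

    Unobserved grid positions are 0; "median3x3" applies a 3x3 median filter
    (the medium-denoising convention for single-pixel speckle removal).
    """
    if not (cube.mz[0] <= cfg.target_mz <= cube.mz[-1]):
        raise ValueError(
            f"target m/z {cfg.target_mz} outside cube range "
            f"[{cube.mz[0]}, {cube.mz[-1]}]"
        )
    sel = np.abs(cube.mz - cfg.target_mz) <= cfg.half_width
    if not np.any(sel):
        sel = np.zeros_like(cube.mz, dtype=bool)
        sel[np.argmin(np.abs(cube.mz - cfg.target_mz))] = True  # nearest-bin limit
    per_pixel = cube.intensity[:, sel].sum(axis=1)
    nx, ny = cube.grid_shape()
    img = np.zeros((nx, ny))
    img[cube.pixels[:, 0], cube.pixels[:, 1]] = per_pixel
    if cfg.denoising == "median3x3":
        img = median_filter(img, size=3, mode="nearest")
    return img


def skyline_spectrum(cube: MsiCube) -> np.ndarray:
    """Skyline projection: per m/z bin, the maximum intensity over pixels."""
    if len(cube) == 0:
        raise ValueError("empty cube")
    return cube.intensity.max(axis=0)


# ---------------------------------------------------------------------------
# bisecting k-means under correlation distance
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center and L2-normalize rows so that 1 - z @ z.T is correlation distance."""
    z = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(z, axis=1, keepdims=True)
    degenerate = norm[:, 0] <= 0
    if np.any(degenerate):
        # constant spectra have undefined correlation; treat as orthogonal
        z[degenerate] = 0.0
        norm[degenerate] = 1.0
    return z / norm


def correlation_distance_matrix(x: np.ndarray) -> np.ndarray:
    z = _standardize_rows(np.asarray(x, float))
    return np.clip(1.0 - z @ z.T, 0.0, 2.0)


def _corr_dist(z: np.ndarray, center: np.ndarray) -> np.ndarray:
    c = center - center.mean()
    norm = np.linalg.norm(c)
    if norm <= 0:
        return np.ones(z.shape[0])
    return np.clip(1.0 - z @ (c / norm), 0.0, 2.0)


def _two_means(
    x: np.ndarray, z: np.ndarray, rng: np.random.Generator,
    n_restarts: int = 10, max_iter: int = 100,
) -> tuple[np.ndarray, float, np.ndarray]:
    """2-means under correlation distance with k-means++ init and restarts.

    Returns (assignment, within-cluster distance sum, child centroids (2, m)).
    """
    n = x.shape[0]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        # k-means++ seeding
        i0 = int(rng.integers(n))
        d0 = _corr_dist(z, x[i0])
        total = d0.sum()
        if total <= 0:
            probs = np.full(n, 1.0 / n)
        else:
            probs = d0 / total
        i1 = int(rng.choice(n, p=probs))
        centers = np.vstack([x[i0], x[i1]])
        assign: np.ndarray | None = None
        for _it in range(max_iter):
            d = np.stack([_corr_dist(z, centers[0]), _corr_dist(z, centers[1])])
            new_assign = np.argmin(d, axis=0)
            # keep both clusters non-empty: move the farthest point if needed
            for c in (0, 1):
                if not np.any(new_assign == c):
                    far = int(np.argmax(d[c]))
                    new_assign[far] = c
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            centers = np.vstack([x[assign == 0].mean(axis=0), x[assign == 1].mean(axis=0)])
        d = np.stack([_corr_dist(z, centers[0]), _corr_dist(z, centers[1])])
        within = float(d[assign, np.arange(n)].sum())
        if best is None or within < best[0]:
            best = (within, assign.copy(), centers.copy())
    assert best is not None
    return best[1], best[0], best[2]


def bisecting_kmeans_segment(
    cube: MsiCube,
    max_leaves: int = 4,
    min_split_distance: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
) -> SegmentationMap:
    """Recursive binary segmentation of TIC-normalized pixel spectra.

    At each step the leaf with the largest within-cluster distance sum (tie:
    more pixels) is split by 2-means under correlation distance — splitting
    the most heterogeneous cluster, so large homogeneous regions are not cut
    on noise before small distinct ones separate; the split
    is recorded with its inter-centroid correlation distance and the number
    of spectra involved.  Splitting stops at ``max_leaves`` leaves, when a
    candidate split's distance falls below ``min_split_distance``, or when no
    leaf has two pixels left.
    """
    if len(cube) < 2:
        labels = np.zeros(len(cube), dtype=int)
        tree = {"n_spectra": len(cube), "distance": None, "leaf": 0}
        return SegmentationMap(cube.pixels.copy(), labels, tree)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = cube.tic_normalized().intensity

    n = x.shape[0]
    labels = np.zeros(n, dtype=int)
    # leaf bookkeeping: leaf id -> (member indices, within-distance sum)
    z_all = _standardize_rows(x)
    leaves: dict[int, tuple[np.ndarray, float]] = {
        0: (np.arange(n), float(_corr_dist(z_all, x.mean(axis=0)).sum()))
    }
    nodes: dict[int, dict] = {0: {"n_spectra": n, "distance": None, "children": None}}
    next_id = 1

    if max_leaves < 2 and min_split_distance <= 0:
        max_leaves = max(max_leaves, 1)

    while len(leaves) < max_leaves:
        candidates = [lid for lid, (ix, _) in leaves.items() if ix.size >= 2]
        if not candidates:
            warnings.warn("fewer splittable pixels than requested leaves", stacklevel=2)
            break
        lid = max(candidates, key=lambda l: (leaves[l][1], leaves[l][0].size))
        ix, _ = leaves[lid]
        sub_x = x[ix]
        sub_z = _standardize_rows(sub_x)
        assign, _, centers = _two_means(sub_x, sub_z, rng, n_restarts=n_restarts)
        cz = _standardize_rows(centers)
        split_distance = float(np.clip(1.0 - cz[0] @ cz[1], 0.0, 2.0))
        if split_distance < min_split_distance:
            break
        ids = (next_id, next_id + 1)
        next_id += 2
        for child, c in zip(ids, (0, 1)):
            member = ix[assign == c]
            within = float(
                _corr_dist(_standardize_rows(x[member]), x[member].mean(axis=0)).sum()
            ) if member.size else 0.0
            leaves[child] = (member, within)
            labels[member] = child
            nodes[child] = {"n_spectra": int(member.size), "distance": None, "children": None}
        nodes[lid]["distance"] = split_distance
        nodes[lid]["children"] = list(ids)
        del leaves[lid]

    # relabel leaves densely 0..k-1, deterministic by first pixel index
    leaf_ids = sorted(leaves, key=lambda l: int(leaves[l][0].min()))
    remap = {l: i for i, l in enumerate(leaf_ids)}
    final = np.empty(n, dtype=int)
    for l, ix_w in leaves.items():
        final[ix_w[0]] = remap[l]
    tree = _render_tree(nodes, 0, remap)
    return SegmentationMap(cube.pixels.copy(), final, tree)


def _render_tree(nodes: dict[int, dict], nid: int, remap: dict[int, int]) -> dict:
    node = nodes[nid]
    out = {"n_spectra": node["n_spectra"], "distance": node["distance"]}
    if node["children"]:
        out["children"] = [_render_tree(nodes, c, remap) for c in node["children"]]
    else:
        out["leaf"] = remap.get(nid, -1)
    return out
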