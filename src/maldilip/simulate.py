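"""Ground-truthed synthetic MALDI lipid data.

Generates profile spectra, cohort designs and labeled MSI cubes with the
statistical structure the analysis pipeline assumes: Gaussian peaks at
adduct m/z with coarse isotope envelopes, an exponentially decaying chemical
baseline, an additive noise floor, multiplicative log-normal sample and
replicate effects, and a multiplicative calibration drift of the m/z axis.
Every simulated peak's provenance (lipid, adduct, isotope index, region) is
recorded so that recovery can be scored exactly.

Also houses the ultracentrifugation clearing-factor utility used by the
extracellular-vesicle fractionation protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import isotope_pattern
from .msi import MsiCube
from .preprocess import FeatureMatrix, ProfileSpectrum
from .reference import (
    ADDUCTS_BY_LABEL,
    LipidDB,
    LipidRecord,
    adduct_mz,
    lipid_formula,
)

__all__ = [
    "FractionationParams",
    "PanelEntry",
    "GroundTruthPanel",
    "SimulationDesign",
    "clearing_k_factor",
    "panel_from_db",
    "random_panel",
    "simulate_profile_spectrum",
    "simulate_cohort",
    "simulate_feature_matrix",
    "simulate_msi_cube",
    "ovary_layout",
    "design_preset",
]

# ---------------------------------------------------------------------------
# rotor clearing factor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FractionationParams:
    """Swinging-bucket rotor geometry for pelleting-efficiency calculations."""

    rmin_mm: float = 60.8
    rmax_mm: float = 108.5
    rpm: float = 30000.0
    constant: float = 2.533e11

    def __post_init__(self) -> None:
        if self.rmin_mm <= 0 or self.rpm <= 0:
            raise ValueError("rmin and RPM must be positive")
        if self.rmax_mm < self.rmin_mm:
            raise ValueError("rmax must be >= rmin")


def clearing_k_factor(params: FractionationParams = FractionationParams()) -> float:
    """k = 2.533e11 * ln(rmax/rmin) / RPM^2 (dimensionless clearing factor)."""
    return params.constant * math.log(params.rmax_mm / params.rmin_mm) / params.rpm**2


# ---------------------------------------------------------------------------
# truth panels
# ---------------------------------------------------------------------------

#: Default relative ionization weights per adduct, by polarity.
DEFAULT_ADDUCT_WEIGHTS = {
    +1: {"[M+H]+": 1.0, "[M+Na]+": 0.30, "[M+K]+": 0.15},
    -1: {"[M-H]-": 1.0, "[M+Cl]-": 0.25},
}

#: Lipid classes that ionize well per polarity in this simulation.
_POSITIVE_CLASSES = ("PC", "SM", "LPC", "CE", "Cer", "CAR")
_NEGATIVE_CLASSES = ("PE", "PS", "PI", "LPE", "LPI", "LPS", "FA")


@dataclass
class PanelEntry:
    lipid: LipidRecord
    base_abundance: float
    group_multipliers: dict[str, float] = field(default_factory=dict)
    adduct_weights: dict[str, float] | None = None

    def multiplier(self, group: str) -> float:
        return self.group_multipliers.get(group, 1.0)

    @property
    def is_differential(self) -> bool:
        return len(set(self.group_multipliers.values())) > 1


@dataclass
class GroundTruthPanel:
    entries: list[PanelEntry]
    polarity: int = +1
    isotope_depth: int = 3

    def __post_init__(self) -> None:
        if any(e.base_abundance <= 0 for e in self.entries):
            raise ValueError("abundances must be positive")
        if any(m <= 0 for e in self.entries for m in e.group_multipliers.values()):
            raise ValueError("group multipliers must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    def provenance(self) -> pd.DataFrame:
        """Theoretical peak table: (lipid, adduct, isotope k, theo m/z, weight)."""
        weights = DEFAULT_ADDUCT_WEIGHTS[self.polarity]
        rows = []
        for e in self.entries:
            w = e.adduct_weights or weights
            pattern = isotope_pattern(e.lipid.formula, self.isotope_depth)
            for label, wt in w.items():
                rule = ADDUCTS_BY_LABEL[label]
                mono = adduct_mz(e.lipid.neutral_mass, rule)
                for k, ab in pattern:
                    rows.append(
                        {
                            "lipid": e.lipid.name,
                            "class": e.lipid.lipid_class,
                            "adduct": label,
                            "isotope": k,
                            "theo_mz": mono + k * 1.003355,
                            "rel_abundance": ab * wt,
                        }
                    )
        return pd.DataFrame(rows)

    def truth_table(self, groups: list[str]) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            mult = [e.multiplier(g) for g in groups]
            fc = mult[0] / mult[1] if len(mult) > 1 else 1.0
            rows.append(
                {
                    "lipid": e.lipid.name,
                    "class": e.lipid.lipid_class,
                    "base_abundance": e.base_abundance,
                    **{f"mult_{g}": m for g, m in zip(groups, mult)},
                    "true_fc": fc,
                    "differential": len(set(mult)) > 1,
                }
            )
        return pd.DataFrame(rows)


def panel_from_db(
    db: LipidDB,
    polarity: int = +1,
    tier: str | None = "tissue_specific",
    seed: int | np.random.Generator = 0,
) -> GroundTruthPanel:
    """Panel of database lipids whose class ionizes in the chosen polarity."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = _POSITIVE_CLASSES if polarity > 0 else _NEGATIVE_CLASSES
    entries = []
    for rec in db:
        if tier is not None and rec.tier != tier:
            continue
        if rec.lipid_class not in classes:
            continue
        entries.append(PanelEntry(rec, float(rng.uniform(0.3, 3.0))))
    if not entries:
        raise ValueError("no database lipid matches the requested polarity/tier")
    return GroundTruthPanel(entries, polarity)


def random_panel(
    n_lipids: int,
    polarity: int = +1,
    seed: int | np.random.Generator = 0,
    include_lock_mass: bool = True,
) -> GroundTruthPanel:
    """Random, non-duplicated lipid species drawn from the class formula rules.

    By default the polarity's lock-mass lipid (PC(34:1) positive, PI(38:4)
    negative) is always part of the panel — a lock mass is useful precisely
    because it is present in every spectrum.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = _POSITIVE_CLASSES if polarity > 0 else _NEGATIVE_CLASSES
    seen: set[tuple[str, int, int]] = set()
    entries: list[PanelEntry] = []
    if include_lock_mass:
        cls, c, d = ("PC", 34, 1) if polarity > 0 else ("PI", 38, 4)
        seen.add((cls, c, d))
        entries.append(
            PanelEntry(
                LipidRecord(f"{cls}({c}:{d})", cls, lipid_formula(cls, c, d),
                            "tissue_specific"),
                2.0,
            )
        )
    guard = 0
    while len(entries) < n_lipids:
        guard += 1
        if guard > 100 * n_lipids:
            raise RuntimeError("cannot draw enough distinct lipid species")
        cls = classes[int(rng.integers(len(classes)))]
        if cls in ("LPC", "CAR"):
            c = int(rng.integers(10, 25))
        elif cls == "Cer":
            c = int(rng.integers(30, 45))
        else:
            c = int(rng.integers(26, 45))
        d = int(rng.integers(0, min(7, c // 4)))
        key = (cls, c, d)
        if key in seen:
            continue
        seen.add(key)
        prefix = "d" if cls in ("SM", "Cer") else ""
        rec = LipidRecord(
            f"{cls}({prefix}{c}:{d})", cls, lipid_formula(cls, c, d), "tissue_specific"
        )
        entries.append(PanelEntry(rec, float(rng.uniform(0.3, 3.0))))
    return GroundTruthPanel(entries, polarity)


def set_group_contrast(
    panel: GroundTruthPanel,
    groups: tuple[str, str],
    n_differential: int,
    fold_change: float = 2.5,
    seed: int | np.random.Generator = 0,
) -> GroundTruthPanel:
    """Plant a two-group contrast: half the differential lipids go up in each group.

    Balancing the directions keeps the two groups' total ion currents
    comparable, as in real profiling data where regulation runs both ways.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_differential > len(panel):
        raise ValueError("more differential lipids than panel entries")
    pick = rng.choice(len(panel), size=n_differential, replace=False)
    up_in_first = set(pick[: n_differential // 2])
    entries = []
    for i, e in enumerate(panel.entries):
        mult = {groups[0]: 1.0, groups[1]: 1.0}
        if i in set(pick):
            target = groups[0] if i in up_in_first else groups[1]
            mult[target] = fold_change
        entries.append(replace(e, group_multipliers=mult))
    return GroundTruthPanel(entries, panel.polarity, panel.isotope_depth)


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationDesign:
    """Cohort layout and noise model for synthetic acquisitions.

    Defaults emulate a triplicated reflectron-TOF lipid profiling run in the
    m/z 100-1200 range: technical CV 20%, between-sample biological CV 30%,
    resolving power 15,000, and a calibration drift of up to +/-100 ppm that
    the lock-mass stage must remove.
    """

    groups: tuple[tuple[str, int], ...] = (("LF", 24), ("SF", 24))
    replicates: int = 3
    technical_cv: float = 0.20
    biological_cv: float = 0.30
    noise_floor: float = 0.05
    baseline_amplitude: float = 5.0
    baseline_decay: float = 300.0  # Da
    drift_ppm: float = 100.0  # spectra drift uniformly within +/- this
    mz_min: float = 100.0
    mz_max: float = 1200.0
    mz_step: float = 0.01
    resolution: float = 15000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for _, n in self.groups):
            raise ValueError("group sizes must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def axis(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.mz_step)) + 1
        return self.mz_min + self.mz_step * np.arange(n)

    def sigma(self, mz: np.ndarray | float):
        return mz / (2.3548 * self.resolution)

    @property
    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]


def design_preset(name: str, seed: int = 0) -> SimulationDesign:
    """Named cohort presets mirroring the study contrasts.

    ``follicle-size``: vesicle preparations from large vs small follicles,
    24 biological samples per arm.  ``ff-fractions``: the four sequentially
    depleted fluid fractions.  ``ev-types``: cells, apoptotic bodies,
    microvesicles and exosomes.  ``null``: two groups with no planted
    differences, for type-I calibration.
    """
    presets = {
        "follicle-size": (("LF", 24), ("SF", 24)),
        "ff-fractions": (("FF1", 6), ("FF2", 6), ("FF3", 6), ("FF4", 6)),
        "ev-types": (("Cells", 6), ("ABs", 6), ("MVs", 6), ("Exo", 6)),
        "null": (("A", 24), ("B", 24)),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(presets)}")
    return SimulationDesign(groups=presets[name], seed=seed)


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Log-normal multiplier with unit median and the requested CV."""
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _place_peaks(
    axis: np.ndarray,
    centers: np.ndarray,
    areas: np.ndarray,
    design: SimulationDesign,
) -> np.ndarray:
    """Sum of area-normalized Gaussians on the axis (5-sigma support each)."""
    out = np.zeros_like(axis)
    step = design.mz_step
    for c, a in zip(centers, areas):
        sig = float(design.sigma(c))
        lo = max(0, int((c - 5 * sig - axis[0]) / step))
        hi = min(axis.size, int((c + 5 * sig - axis[0]) / step) + 2)
        if hi <= lo:
            continue
        window = axis[lo:hi]
        out[lo:hi] += a / (sig * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((window - c) / sig) ** 2
        )
    return out


def simulate_profile_spectrum(
    panel: GroundTruthPanel,
    design: SimulationDesign,
    group: str | None = None,
    lipid_factors: np.ndarray | None = None,
    drift_ppm: float | None = None,
    sample_id: str = "synthetic",
    replicate_id: str = "r1",
    seed: int | np.random.Generator = 0,
) -> ProfileSpectrum:
    """One synthetic profile spectrum.

    Peak areas are base abundance x group multiplier x optional per-lipid
    factors x adduct weight x isotope envelope; centers are shifted by the
    multiplicative calibration drift.  Baseline decays exponentially from the
    low-mass end and the additive noise floor is half-normal, keeping
    intensities non-negative.
    """
    if not len(panel):
        raise ValueError("empty truth panel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = design.axis()
    prov = panel.provenance()
    areas_by_lipid = {
        e.lipid.name: e.base_abundance * (e.multiplier(group) if group else 1.0)
        for e in panel.entries
    }
    if lipid_factors is not None:
        for name, f in zip(areas_by_lipid, lipid_factors):
            areas_by_lipid[name] *= f
    if drift_ppm is None:
        drift_ppm = float(rng.uniform(-design.drift_ppm, design.drift_ppm))
    centers = prov["theo_mz"].to_numpy() * (1.0 + drift_ppm * 1e-6)
    areas = prov["rel_abundance"].to_numpy() * prov["lipid"].map(areas_by_lipid).to_numpy()
    inside = (centers > axis[0]) & (centers < axis[-1])
    signal = _place_peaks(axis, centers[inside], areas[inside], design)
    baseline = design.baseline_amplitude * np.exp(-(axis - axis[0]) / design.baseline_decay)
    noise = np.abs(rng.normal(0.0, design.noise_floor, size=axis.size))
    return ProfileSpectrum(
        axis, signal + baseline + noise, panel.polarity, sample_id, replicate_id
    )


def simulate_cohort(
    panel: GroundTruthPanel,
    design: SimulationDesign,
) -> tuple[list[ProfileSpectrum], pd.DataFrame, pd.DataFrame]:
    """A full cohort of technical-replicate spectra plus truth tables.

    Returns (spectra, sample metadata, lipid truth table).  Per biological
    sample each lipid gets a log-normal factor at the biological CV; each
    technical replicate adds an independent log-normal factor at the
    technical CV and a fresh drift/noise realization.  Fixed seeds reproduce
    the cohort exactly.
    """
    if len(design.groups) < 2:
        raise ValueError("cohort needs at least two groups")
    rng = np.random.default_rng(design.seed)
    spectra: list[ProfileSpectrum] = []
    meta_rows = []
    n_lipids = len(panel)
    for group, n in design.groups:
        for i in range(n):
            bio_id = f"{group}_{i + 1:02d}"
            bio_factors = _lognormal_factor(rng, design.biological_cv, n_lipids)
            for r in range(design.replicates):
                rep_id = f"t{r + 1}"
                tech_factors = _lognormal_factor(rng, design.technical_cv, n_lipids)
                gain = float(_lognormal_factor(rng, 0.20))
                spec = simulate_profile_spectrum(
                    panel,
                    design,
                    group=group,
                    lipid_factors=bio_factors * tech_factors * gain,
                    sample_id=f"{bio_id}_{rep_id}",
                    replicate_id=rep_id,
                    seed=rng,
                )
                spectra.append(spec)
                meta_rows.append(
                    {
                        "sample_id": f"{bio_id}_{rep_id}",
                        "bio_sample": bio_id,
                        "replicate_id": rep_id,
                        "group": group,
                    }
                )
    meta = pd.DataFrame(meta_rows)
    truth = panel.truth_table(design.group_names)
    return spectra, meta, truth


def simulate_feature_matrix(
    design: SimulationDesign,
    n_features: int = 300,
    n_differential: int = 0,
    fold_change: float = 2.5,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Feature-level cohort simulation (no spectral layer), with truth table.

    Used for statistical calibration at large feature counts where the
    spectral round trip adds nothing: intensities are log-normal around a
    per-feature base level with biological and technical components, and the
    planted differential features split evenly between the two directions.
    """
    if len(design.groups) != 2:
        raise ValueError("feature-level simulation is two-group")
    rng = np.random.default_rng(design.seed)
    base = rng.uniform(0.3, 3.0, size=n_features)
    mz = np.sort(rng.uniform(design.mz_min, design.mz_max, size=n_features))
    diff_ix = rng.choice(n_features, size=n_differential, replace=False)
    up_first = set(diff_ix[: n_differential // 2])
    mult = {g: np.ones(n_features) for g, _ in design.groups}
    g1, g2 = design.group_names
    for ix in diff_ix:
        mult[g1 if ix in up_first else g2][ix] = fold_change

    rows, meta_rows = [], []
    for group, n in design.groups:
        for i in range(n):
            bio_id = f"{group}_{i + 1:02d}"
            bio = _lognormal_factor(rng, design.biological_cv, n_features)
            for r in range(design.replicates):
                tech = _lognormal_factor(rng, design.technical_cv, n_features)
                rows.append(base * mult[group] * bio * tech)
                meta_rows.append(
                    {
                        "sample_id": f"{bio_id}_t{r + 1}",
                        "bio_sample": bio_id,
                        "replicate_id": f"t{r + 1}",
                        "group": group,
                    }
                )
    fm = FeatureMatrix(mz, np.vstack(rows), pd.DataFrame(meta_rows))
    truth = pd.DataFrame(
        {
            "mz": mz,
            "differential": np.isin(np.arange(n_features), diff_ix),
            "true_fc": [
                mult[g1][j] / mult[g2][j] for j in range(n_features)
            ],
        }
    )
    return fm, truth


# ---------------------------------------------------------------------------
# MSI cubes
# ---------------------------------------------------------------------------


def ovary_layout(nx: int = 32, ny: int = 32) -> np.ndarray:
    """Region template map of an ovary section, as integer labels.

    0 = stroma, 1 = follicle wall, 2 = large-follicle lumen, 3 =
    small-follicle lumen.  One large antral follicle and two small ones are
    placed in the stroma; each lumen is wrapped by a one-to-two-pixel wall.
    """
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    layout = np.zeros((nx, ny), dtype=int)

    def disc(cx, cy, r):
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2

    follicles = [
        (nx * 0.34, ny * 0.36, min(nx, ny) * 0.26, 2),  # large dominant follicle
        (nx * 0.74, ny * 0.70, min(nx, ny) * 0.11, 3),  # small subordinate
        (nx * 0.22, ny * 0.78, min(nx, ny) * 0.09, 3),  # small subordinate
    ]
    for cx, cy, r, label in follicles:
        layout[disc(cx, cy, r + 2)] = 1  # wall annulus
    for cx, cy, r, label in follicles:
        layout[disc(cx, cy, r)] = label
    return layout


def _region_panels(
    db_panel: GroundTruthPanel, rng: np.random.Generator
) -> dict[int, GroundTruthPanel]:
    """Four region panels sharing a backbone but with region-specific lipids."""
    entries = list(db_panel.entries)
    if len(entries) < 12:
        raise ValueError("need at least 12 panel lipids for the ovary layout")
    perm = rng.permutation(len(entries))
    shared = [entries[i] for i in perm[: len(entries) // 3]]
    rest = [entries[i] for i in perm[len(entries) // 3:]]
    chunks = np.array_split(np.arange(len(rest)), 4)
    panels = {}
    for region, chunk in enumerate(chunks):
        own = [rest[i] for i in chunk]
        panels[region] = GroundTruthPanel(
            [replace(e) for e in shared + own], db_panel.polarity, db_panel.isotope_depth
        )
    return panels


def simulate_msi_cube(
    layout: np.ndarray,
    panels: dict[int, GroundTruthPanel] | None = None,
    design: SimulationDesign | None = None,
    pixel_cv: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> MsiCube:
    """Labeled MSI cube: per pixel, a spectrum drawn from its region's panel.

    Region templates are noiseless spectra of the region panel; each pixel
    multiplies every lipid's contribution by a log-normal factor at
    ``pixel_cv`` and adds the design's additive noise floor.  The true region
    label is stored on the cube.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = design or SimulationDesign(
        mz_min=400.0, mz_max=900.0, mz_step=0.1, drift_ppm=0.0,
        baseline_amplitude=0.5, noise_floor=0.02,
    )
    layout = np.asarray(layout, dtype=int)
    regions = sorted(np.unique(layout))
    if panels is None:
        from .reference import load_default_db

        base_panel = panel_from_db(load_default_db(), +1, tier=None, seed=rng)
        panels = _region_panels(base_panel, rng)
    missing = [r for r in regions if r not in panels]
    if missing:
        raise ValueError(f"no panel for region(s) {missing}")

    axis = design.axis()
    # per region: per-lipid peak profiles, so pixels can vary lipid-wise
    profiles: dict[int, np.ndarray] = {}
    for r in regions:
        panel = panels[r]
        prov = panel.provenance()
        mat = np.zeros((len(panel), axis.size))
        for li, e in enumerate(panel.entries):
            sub = prov[prov["lipid"] == e.lipid.name]
            centers = sub["theo_mz"].to_numpy()
            areas = sub["rel_abundance"].to_numpy() * e.base_abundance
            inside = (centers > axis[0]) & (centers < axis[-1])
            mat[li] = _place_peaks(axis, centers[inside], areas[inside], design)
        profiles[r] = mat

    pixels, labels, rows = [], [], []
    nx, ny = layout.shape
    baseline = design.baseline_amplitude * np.exp(-(axis - axis[0]) / design.baseline_decay)
    for x in range(nx):
        for y in range(ny):
            r = int(layout[x, y])
            mat = profiles[r]
            factors = _lognormal_factor(rng, pixel_cv, mat.shape[0])
            spec = factors @ mat + baseline + np.abs(
                rng.normal(0.0, design.noise_floor, size=axis.size)
            )
            pixels.append((x, y))
            labels.append(r)
            rows.append(spec)
    return MsiCube(
        np.array(pixels), axis, np.vstack(rows), region_labels=np.array(labels)
    )
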