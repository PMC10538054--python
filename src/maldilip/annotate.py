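"""Adduct-aware lipid annotation with isotope flagging.

Observed peaks are matched against theoretical adducted m/z of a two-tier
reference database within a relative tolerance (default 0.05%, relative to
the theoretical mass).  When candidates from both tiers match the same peak,
only the tissue-specific tier is retained, ordered by absolute mass error.
Before annotation, putative M+1/M+2 isotopologue peaks (spaced by ~1.003355
Da with a plausible intensity ratio) are flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PeakList
from .reference import (
    NEGATIVE_ADDUCTS,
    POSITIVE_ADDUCTS,
    AdductRule,
    ElementalFormula,
    LipidDB,
    LipidRecord,
)

__all__ = [
    "ISOTOPE_SPACING",
    "AnnotationConfig",
    "AnnotationCandidate",
    "AnnotatedFeature",
    "enumerate_adducts",
    "annotate_peak",
    "annotate_peaklist",
    "isotope_pattern",
    "flag_isotopes",
    "annotation_table",
]

#: Average mass shift of one 13C substitution (Da).
ISOTOPE_SPACING = 1.003355

#: Isotope distributions per element as {nucleon offset: abundance}.
_ISOTOPES: dict[str, dict[int, float]] = {
    "H": {0: 0.999885, 1: 0.000115},
    "C": {0: 0.9893, 1: 0.0107},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "P": {0: 1.0},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425},
    "Na": {0: 1.0},
    "K": {0: 0.932581, 1: 0.000117, 2: 0.067302},
    "Cl": {0: 0.7576, 2: 0.2424},
}


@dataclass(frozen=True)
class AnnotationConfig:
    rel_tolerance: float = 5e-4  # 0.05%, relative to theoretical m/z
    polarity: int = +1
    isotope_spacing: float = ISOTOPE_SPACING
    # peak-pair spacing within one spectrum is differential and therefore far
    # more accurate than the absolute calibration: absolute window in Da
    # (wide enough for apex quantization on a 0.01 Da profile grid)
    spacing_tolerance: float = 0.025
    # M+1/M ceiling for a generic lipid: crude carbon-count proxy in m/z/14
    isotope_ratio_margin: float = 0.05
    max_isotope: int = 2

    def __post_init__(self) -> None:
        if self.rel_tolerance <= 0 or self.spacing_tolerance <= 0:
            raise ValueError("tolerances must be positive")

    def isotope_ceiling(self, mz: float, k: int = 1) -> float:
        base = 0.011 * (mz / 14.0) + self.isotope_ratio_margin
        return base**k if k > 1 else base


@dataclass(frozen=True)
class AnnotationCandidate:
    lipid: LipidRecord
    adduct: str
    theoretical_mz: float
    delta_mz: float
    delta_relative: float
    tier: str


@dataclass
class AnnotatedFeature:
    observed_mz: float
    polarity: int
    candidates: list[AnnotationCandidate] = field(default_factory=list)
    isotope_flag: bool = False
    parent_mz: float | None = None

    @property
    def top(self) -> AnnotationCandidate | None:
        return self.candidates[0] if self.candidates else None


def enumerate_adducts(polarity: int) -> tuple[AdductRule, ...]:
    """The singly charged adduct set considered per polarity."""
    if polarity == +1:
        return POSITIVE_ADDUCTS
    if polarity == -1:
        return NEGATIVE_ADDUCTS
    raise ValueError("polarity must be +1 or -1")


def annotate_peak(
    mz_obs: float,
    polarity: int,
    db: LipidDB,
    cfg: AnnotationConfig | None = None,
) -> AnnotatedFeature:
    """All database candidates within tolerance, tier-filtered and ranked.

    If any tissue-specific candidate matches, only tissue-specific candidates
    are retained (the public-database match is considered superseded by the
    system-specific identification); the retained list is ordered by |delta|.
    An empty candidate list is a valid outcome.
    """
    if mz_obs <= 0:
        raise ValueError("observed m/z must be positive")
    cfg = cfg or AnnotationConfig(polarity=polarity)
    hits = db.query(mz_obs, polarity, cfg.rel_tolerance)
    candidates = [
        AnnotationCandidate(
            lipid=rec,
            adduct=rule.label,
            theoretical_mz=theo,
            delta_mz=mz_obs - theo,
            delta_relative=(mz_obs - theo) / theo,
            tier=rec.tier,
        )
        for rec, rule, theo in hits
    ]
    if any(c.tier == "tissue_specific" for c in candidates):
        candidates = [c for c in candidates if c.tier == "tissue_specific"]
    candidates.sort(key=lambda c: (abs(c.delta_mz), c.adduct, c.lipid.name))
    return AnnotatedFeature(mz_obs, polarity, candidates)


def isotope_pattern(
    formula: ElementalFormula | str, n_peaks: int = 3
) -> list[tuple[int, float]]:
    """Coarse (nucleon-aggregated) isotope envelope of a neutral formula.

    Convolves the per-element isotope distributions and normalizes to the
    monoisotopic peak.  Returns [(nominal offset, relative abundance), ...]
    for offsets 0 .. n_peaks - 1.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    if not formula:
        raise ValueError("empty formula has no isotope pattern")
    size = n_peaks
    dist = np.zeros(size)
    dist[0] = 1.0
    for elem, count in formula.counts.items():
        try:
            iso = _ISOTOPES[elem]
        except KeyError:
            raise ValueError(f"no isotope data for element {elem!r}")
        base = np.zeros(size)
        for off, ab in iso.items():
            if off < size:
                base[off] = ab
        # element contribution = base ** count under truncated convolution
        power = np.zeros(size)
        power[0] = 1.0
        b = base
        c = count
        while c:
            if c & 1:
                power = np.convolve(power, b)[:size]
            b = np.convolve(b, b)[:size]
            c >>= 1
        dist = np.convolve(dist, power)[:size]
    if dist[0] <= 0:
        raise ValueError("monoisotopic abundance vanished; formula too exotic")
    dist = dist / dist[0]
    return [(k, float(dist[k])) for k in range(size)]


def flag_isotopes(
    peaklist: PeakList, cfg: AnnotationConfig | None = None
) -> list[tuple[bool, float | None]]:
    """Flag peaks that look like +k isotopologues (k = 1 .. max_isotope).

    A peak P is flagged relative to an unflagged earlier peak Q when
    |mz_P - mz_Q - k * spacing| <= spacing_tolerance (absolute, Da) and the
    intensity ratio P/Q stays below the generic-lipid envelope ceiling at
    Q's mass.  A +2 flag additionally requires that some peak was already
    flagged as the +1 of the same parent (the +1 of a CHNOP lipid always
    dominates the +2, so an isolated +2 spacing is a distinct compound).
    Returns one (flag, parent_mz) pair per peak, in peak order.
    """
    cfg = cfg or AnnotationConfig(polarity=peaklist.polarity)
    peaks = peaklist.peaks
    flags: list[tuple[bool, float | None]] = [(False, None) for _ in peaks]
    parents_with_m1: set[int] = set()
    mzs = np.array([p.mz for p in peaks])
    for i, p in enumerate(peaks):
        for k in range(1, cfg.max_isotope + 1):
            target = p.mz - k * cfg.isotope_spacing
            j_candidates = np.flatnonzero(np.abs(mzs - target) <= cfg.spacing_tolerance)
            for j in j_candidates:
                if j >= i or flags[j][0]:
                    continue
                if k >= 2 and j not in parents_with_m1:
                    continue
                q = peaks[j]
                if q.intensity <= 0:
                    continue
                if p.intensity / q.intensity <= cfg.isotope_ceiling(q.mz, k):
                    flags[i] = (True, q.mz)
                    if k == 1:
                        parents_with_m1.add(j)
                    break
            if flags[i][0]:
                break
    return flags


def annotate_peaklist(
    peaklist: PeakList, db: LipidDB, cfg: AnnotationConfig | None = None
) -> list[AnnotatedFeature]:
    """Isotope-flag then annotate every peak of a list.

    Isotope-flagged peaks carry their parent m/z and are excluded from
    database matching.
    """
    cfg = cfg or AnnotationConfig(polarity=peaklist.polarity)
    flags = flag_isotopes(peaklist, cfg)
    out = []
    for p, (flag, parent) in zip(peaklist.peaks, flags):
        if flag:
            out.append(
                AnnotatedFeature(p.mz, peaklist.polarity, [], True, parent)
            )
        else:
            feat = annotate_peak(p.mz, peaklist.polarity, db, cfg)
            out.append(feat)
    return out


def annotation_table(features: list[AnnotatedFeature]) -> pd.DataFrame:
    """Long-format annotation report (one row per retained candidate)."""
    rows = []
    for f in features:
        if not f.candidates:
            rows.append(
                {
                    "mz": f.observed_mz,
                    "polarity": "+" if f.polarity > 0 else "-",
                    "isotope_flag": f.isotope_flag,
                    "parent_mz": f.parent_mz,
                    "rank": None,
                    "lipid_name": None,
                    "class": None,
                    "adduct": None,
                    "theo_mz": None,
                    "delta_ppm": None,
                    "tier": None,
                }
            )
            continue
        for rank, c in enumerate(f.candidates, start=1):
            rows.append(
                {
                    "mz": f.observed_mz,
                    "polarity": "+" if f.polarity > 0 else "-",
                    "isotope_flag": f.isotope_flag,
                    "parent_mz": f.parent_mz,
                    "rank": rank,
                    "lipid_name": c.lipid.name,
                    "class": c.lipid.lipid_class,
                    "adduct": c.adduct,
                    "theo_mz": c.theoretical_mz,
                    "delta_ppm": 1e6 * c.delta_relative,
                    "tier": c.tier,
                }
            )
    return pd.DataFrame(rows)
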