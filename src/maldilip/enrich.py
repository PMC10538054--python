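"""Pathway over-representation analysis for annotated lipid sets.

The enrichment factor of a pathway is the number of observed hits divided by
the expected number of hits given the query-to-universe compound ratio; the
p-value is the hypergeometric upper tail (one-sided Fisher).  The topology
"impact" column is pass-through metadata only; computing it requires a
pathway-graph analysis outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PathwayDB",
    "enrichment_factor",
    "enrichment_p",
    "rank_pathways",
    "infer_background_rate",
    "load_pathway_db",
    "default_pathway_db_path",
    "default_pathway_stats_path",
]


@dataclass
class PathwayDB:
    """Pathway name -> member compound identifiers, plus the universe size.

    ``universe_size`` is the number of compounds in the background library;
    it must cover the union of all memberships.
    """

    pathways: dict[str, frozenset[str]]
    universe_size: int
    impact: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}
        if any(len(v) == 0 for v in self.pathways.values()):
            raise ValueError("pathways must be non-empty")
        union = set().union(*self.pathways.values()) if self.pathways else set()
        if self.universe_size < max([len(union)] + [len(v) for v in self.pathways.values()]):
            raise ValueError("universe smaller than pathway memberships")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(set().union(*self.pathways.values()))


def enrichment_factor(
    hits: int, total: int, query_size: int, universe_size: int
) -> float:
    """hits / expected hits, with expected = total * query_size / universe_size."""
    if not (universe_size >= query_size >= hits >= 0 and total >= hits):
        raise ValueError("inconsistent contingency inputs")
    expected = total * query_size / universe_size
    if expected == 0:
        raise ValueError("expected hit count is zero")
    return hits / expected


def enrichment_p(
    hits: int, total: int, query_size: int, universe_size: int
) -> float:
    """Hypergeometric upper tail P(X >= hits), X ~ HG(universe, total, query)."""
    if not (universe_size >= query_size >= hits >= 0 and total >= hits):
        raise ValueError("inconsistent contingency inputs")
    if universe_size < total:
        raise ValueError("pathway larger than the universe")
    return float(sps.hypergeom.sf(hits - 1, universe_size, total, query_size))


def rank_pathways(query: Iterable[str], db: PathwayDB) -> pd.DataFrame:
    """One row per pathway, sorted by (p, -enrichment, name); deterministic.

    Query identifiers are de-duplicated; identifiers outside the universe are
    dropped with a warning column tally.
    """
    q = set(query)
    if not q:
        raise ValueError("empty query")
    known = q & set(db.universe)
    dropped = len(q) - len(known)
    if dropped:
        import warnings

        warnings.warn(f"{dropped} query identifiers outside the universe dropped",
                      stacklevel=2)
    if not known:
        raise ValueError("no query identifiers overlap the universe")
    query_size = len(known)
    rows = []
    for name, members in db.pathways.items():
        total = len(members)
        hits = len(known & members)
        enr = (
            enrichment_factor(hits, total, query_size, db.universe_size)
            if total * query_size > 0
            else 0.0
        )
        p = enrichment_p(hits, total, query_size, db.universe_size)
        rows.append(
            {
                "pathway": name,
                "total": total,
                "hits": hits,
                "enrichment": enr,
                "p_value": p,
                "impact": db.impact.get(name, np.nan),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["p_value", "enrichment", "pathway"], ascending=[True, False, True]
    ).reset_index(drop=True)


def infer_background_rate(stats: pd.DataFrame, exclude: str | None = None) -> float:
    """Shared query/universe compound ratio implied by an enrichment table.

    For rows with printed (total, hits, enrichment), the model
    enrichment = hits / (total * r) is linear in x = 1/r:
    enrichment_i = (hits_i / total_i) * x, solved by least squares.  Rows
    whose pathway name matches ``exclude`` are left out of the fit.
    """
    df = stats
    if exclude is not None:
        df = df[~df["pathway"].str.contains(exclude, case=False)]
    df = df[(df["hits"] > 0) & (df["enrichment"] > 0)]
    if df.empty:
        raise ValueError("no usable rows to infer the background rate")
    a = (df["hits"] / df["total"]).to_numpy(float)
    e = df["enrichment"].to_numpy(float)
    x = float(np.dot(a, e) / np.dot(a, a))  # x = universe/query = 1/r
    return 1.0 / x


def load_pathway_db(
    path: str | Path, universe_size: int | None = None
) -> PathwayDB:
    """Read a ``pathway,compound_id`` CSV into a :class:`PathwayDB`.

    Without an explicit ``universe_size`` the universe defaults to the
    membership union scaled to the background rate bundled with the package
    fixture (about 1 query compound per 310 background compounds) -- see the
    fixture notes; pass a value for real libraries.
    """
    df = pd.read_csv(path, comment="#")
    if not {"pathway", "compound_id"} <= set(df.columns):
        raise ValueError("pathway CSV needs columns pathway,compound_id")
    groups = {
        name: frozenset(sub["compound_id"].astype(str))
        for name, sub in df.groupby("pathway")
    }
    if universe_size is None:
        union = len(set().union(*groups.values()))
        universe_size = max(union, 310 * 10)  # default background library size
    return PathwayDB(groups, universe_size)


def default_pathway_db_path() -> Path:
    return Path(__file__).with_name("data") / "pathway_db_synthetic.csv"


def default_pathway_stats_path() -> Path:
    """Bundled enrichment summary table for the large-vs-small follicle contrast."""
    return Path(__file__).with_name("data") / "pathway_stats_lf_sf.csv"
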