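"""Gene-age (phylostratum) assignment from filtered homology-search hits.

Each gene's age is the oldest (lowest-numbered) of 13 nested taxonomic
levels at which it retains a qualifying hit; genes with no qualifying hit
default to the youngest level (PS13).  PS1-3 are "old", PS11-13 "young".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_LEVELS = 13
OLD_LEVELS = frozenset({1, 2, 3})
YOUNG_LEVELS = frozenset({11, 12, 13})

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 0.3
DEFAULT_MIN_COVERAGE = 0.8

# ordered level names (PS1 .. PS13)
DEFAULT_LEVEL_NAMES = (
    "Cellular organisms",
    "Eukaryota",
    "Viridiplantae",
    "Streptophyta",
    "Embryophyta",
    "Tracheophyta",
    "Spermatophyta",
    "Magnoliophyta",
    "Liliopsida",
    "Poaceae",
    "BOP clade",
    "Oryza",
    "O. sativa",
)

_BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    db_level: int
    evalue: float
    identity: float  # fraction, 0..1
    coverage: float  # query-coverage fraction, 0..1

    def __post_init__(self) -> None:
        if not 1 <= self.db_level <= N_LEVELS:
            raise ValueError(f"{self.query_id}: db_level {self.db_level} outside 1..{N_LEVELS}")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")


def age_class(ps: int) -> str:
    if ps in OLD_LEVELS:
        return "old"
    if ps in YOUNG_LEVELS:
        return "young"
    return "intermediate"


@dataclass(frozen=True)
class PhylostratumAssignment:
    gene_id: str
    ps: int

    def __post_init__(self) -> None:
        if not 1 <= self.ps <= N_LEVELS:
            raise ValueError(f"{self.gene_id}: ps {self.ps} outside 1..{N_LEVELS}")

    @property
    def age_class(self) -> str:
        return age_class(self.ps)


def filter_hits(
    hits: Iterable[HomologyHit],
    max_e: float = DEFAULT_MAX_EVALUE,
    min_ident: float = DEFAULT_MIN_IDENTITY,
    min_cov: float = DEFAULT_MIN_COVERAGE,
) -> list[HomologyHit]:
    """Keep hits with evalue <= max_e, identity >= min_ident and coverage >=
    min_cov (all inclusive)."""
    kept = []
    for h in hits:
        if not (0.0 <= h.identity <= 1.0) or not (0.0 <= h.coverage <= 1.0):
            raise ValueError(
                f"hit {h.query_id} level {h.db_level}: identity/coverage outside [0,1]"
            )
        if h.evalue <= max_e and h.identity >= min_ident and h.coverage >= min_cov:
            kept.append(h)
    return kept


def assign_phylostratum(
    gene_id: str, filtered: Iterable[HomologyHit]
) -> PhylostratumAssignment:
    """Oldest qualifying level wins; no qualifying hit -> PS13."""
    levels = [h.db_level for h in filtered if h.query_id == gene_id]
    ps = min(levels) if levels else N_LEVELS
    return PhylostratumAssignment(gene_id, ps)


def assign_all(
    gene_ids: Iterable[str], filtered: Iterable[HomologyHit]
) -> dict[str, PhylostratumAssignment]:
    best: dict[str, int] = {}
    for h in filtered:
        cur = best.get(h.query_id)
        if cur is None or h.db_level < cur:
            best[h.query_id] = h.db_level
        if h.db_level < N_LEVELS and h.identity >= 1.0 and h.coverage >= 1.0:
            logger.warning(
                "%s: perfect full-coverage hit at level %d — possible self-hit; "
                "exclude the query species from levels 1-12 databases",
                h.query_id,
                h.db_level,
            )
    return {
        g: PhylostratumAssignment(g, best.get(g, N_LEVELS)) for g in gene_ids
    }


def read_hits_file(path, db_level: int, query_lengths: Mapping[str, int]) -> list[HomologyHit]:
    """Read one 12-column tabular homology file for a given level.

    Identity is the percent-identity column / 100; query coverage is
    alignment length / query length.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None, names=_BLAST6_COLUMNS)
    hits = []
    for row in df.itertuples(index=False):
        q = str(row.qseqid)
        if q not in query_lengths:
            raise KeyError(f"{path.name}: query {q} missing from query-lengths table")
        hits.append(
            HomologyHit(
                query_id=q,
                db_level=db_level,
                evalue=float(row.evalue),
                identity=float(row.pident) / 100.0,
                coverage=min(1.0, int(row.length) / int(query_lengths[q])),
            )
        )
    return hits


def read_hits_dir(hits_dir, query_lengths: Mapping[str, int]) -> list[HomologyHit]:
    """Read all per-level hit files named ``*<level>.tsv`` from a directory."""
    hits: list[HomologyHit] = []
    for path in sorted(Path(hits_dir).glob("*.tsv")):
        m = re.search(r"(\d+)\.tsv$", path.name)
        if not m:
            logger.debug("no level number in %s; skipped", path.name)
            continue
        level = int(m.group(1))
        if not 1 <= level <= N_LEVELS:
            logger.warning("level %d in %s outside 1..%d; skipped", level, path.name, N_LEVELS)
            continue
        hits.extend(read_hits_file(path, level, query_lengths))
    return hits


def age_summaries(
    assignments: Mapping[str, PhylostratumAssignment],
    cds_lengths: Mapping[str, int],
    mex_lengths: Mapping[str, Sequence[int]] | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per age-class summaries of CDS length, micro-exon length, expression.

    ``expression`` is an optional gene x tissue table; genes in the
    assignments but absent from ``cds_lengths`` are warned about and
    excluded from length summaries.
    """
    rows = []
    classes = ("old", "intermediate", "young")
    by_class: dict[str, list[str]] = {c: [] for c in classes}
    for g, a in assignments.items():
        by_class[a.age_class].append(g)
    total = len(assignments)

    for cls in classes:
        genes = by_class[cls]
        known = [g for g in genes if g in cds_lengths]
        for g in set(genes) - set(known):
            logger.warning("gene %s has no CDS length in annotation; excluded", g)
        lens = np.array([cds_lengths[g] for g in known], dtype=float)
        mlens: list[int] = []
        if mex_lengths:
            for g in genes:
                mlens.extend(mex_lengths.get(g, ()))
        row = {
            "age_class": cls,
            "n_genes": len(genes),
            "fraction": len(genes) / total if total else np.nan,
            "cds_len_median": float(np.median(lens)) if lens.size else np.nan,
            "cds_len_q1": float(np.percentile(lens, 25)) if lens.size else np.nan,
            "cds_len_q3": float(np.percentile(lens, 75)) if lens.size else np.nan,
            "mex_len_median": float(np.median(mlens)) if mlens else np.nan,
        }
        if expression is not None and not expression.empty:
            sub = expression.loc[expression.index.intersection(genes)]
            for tissue in expression.columns:
                row[f"expr_median_{tissue}"] = (
                    float(sub[tissue].median()) if not sub.empty else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def write_assignments(
    assignments: Mapping[str, PhylostratumAssignment], path
) -> None:
    rows = [
        {"gene_id": g, "ps": a.ps, "age_class": a.age_class}
        for g, a in sorted(assignments.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "ps", "age_class"]).to_csv(
        path, sep="\t", index=False
    )
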