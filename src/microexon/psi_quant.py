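"""Junction libraries, junction read counting and PSI quantification.

Inclusion support for a micro-exon is R_tot = 2*min(R_L, R_R), which caps
the contribution of an alternative 5' or 3' splice site inflating only one
inclusion junction.  PSI = R_tot / (R_tot + R_skipped), missing unless
either the inclusion junctions or the skip junction reach the coverage
floor.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from microexon.genome_annotation import (
    GeneModel,
    MicroExon,
    TranscriptModel,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 100
DEFAULT_MIN_OVERHANG = 3
DEFAULT_MIN_COVERAGE = 10
DEFAULT_MERGE_DELTA = 0.10
AS_FLOOR = 0.1
CS_FLOOR = 0.9


@dataclass(frozen=True)
class JunctionReference:
    """Inclusion/exclusion reference sequences for one micro-exon."""

    mex_id: str
    inclusion_seq: str
    exclusion_seq: str
    left_junction: int  # offset of the upstream inclusion junction
    right_junction: int  # offset of the downstream inclusion junction
    skip_junction: int  # offset of the skip junction in exclusion_seq
    merged_group: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.left_junction < self.right_junction < len(self.inclusion_seq)):
            raise ValueError(f"{self.mex_id}: inclusion junction offsets out of range")
        if not (0 < self.skip_junction < len(self.exclusion_seq)):
            raise ValueError(f"{self.mex_id}: skip junction offset out of range")


@dataclass(frozen=True)
class JunctionCounts:
    mex_id: str
    sample_id: str
    r_left: int
    r_right: int
    r_skipped: int

    def __post_init__(self) -> None:
        if min(self.r_left, self.r_right, self.r_skipped) < 0:
            raise ValueError("negative junction count")

    @property
    def r_tot(self) -> int:
        return 2 * min(self.r_left, self.r_right)


@dataclass(frozen=True)
class PsiRecord:
    mex_id: str
    unit_id: str
    psi: float | None
    n_inc: int = 0
    n_skip: int = 0

    def __post_init__(self) -> None:
        if self.psi is not None and not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"{self.mex_id}: PSI {self.psi} outside [0,1]")

    @property
    def splice_class(self) -> str:
        return classify_splicing(self)


def classify_splicing(p: PsiRecord, as_floor: float = AS_FLOOR, cs_floor: float = CS_FLOOR) -> str:
    """CS when psi >= 0.9, AS in [0.1, 0.9), low below 0.1, missing propagates."""
    if p.psi is None:
        return "missing"
    if p.psi >= cs_floor:
        return "CS"
    if p.psi >= as_floor:
        return "AS"
    return "low"


# ---------------------------------------------------------------------------
# junction library construction


def spliced_sequence(tr: TranscriptModel, chrom_seq: str, strand: str) -> str:
    """Mature transcript sequence in transcription orientation."""
    parts = [str(chrom_seq[s:e]).upper() for s, e in tr.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


def spliced_interval(
    tr: TranscriptModel, interval: tuple[int, int], strand: str
) -> tuple[int, int]:
    """Position of an exon interval within the spliced transcript."""
    offset = 0
    total = tr.spliced_length()
    for s, e in tr.exons:
        if (s, e) == interval:
            if strand == "+":
                return offset, offset + (e - s)
            return total - offset - (e - s), total - offset
        offset += e - s
    raise ValueError(f"interval {interval} is not an exon of {tr.transcript_id}")


def build_junction_library(
    mexs: Iterable[MicroExon],
    genes: Iterable[GeneModel],
    genome: Mapping[str, object],
    flank: int = DEFAULT_FLANK,
) -> list[JunctionReference]:
    """Build per-micro-exon inclusion/exclusion references.

    Flanks come from the mature sequence of the longest transcript
    containing the micro-exon, truncated at transcript ends.  First/last/
    single micro-exons (no flanking exon on one side) are excluded with a
    logged reason.  Micro-exons closer than ``flank`` nt in spliced
    coordinates on the same transcript share a ``merged_group``.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    refs: list[JunctionReference] = []
    placement: dict[str, tuple[str, int, int]] = {}  # mex_id -> (tid, s, e)
    chrom_cache: dict[str, str] = {}

    for mex in mexs:
        gene = gene_by_id.get(mex.gene_id)
        if gene is None:
            logger.warning("%s: gene %s not in annotation; skipped", mex.id, mex.gene_id)
            continue
        carriers = [
            tr
            for tr in gene.transcripts
            if mex.interval in tr.exons
        ]
        internal = [
            tr
            for tr in carriers
            if tr.exons.index(mex.interval) not in (0, len(tr.exons) - 1)
        ]
        if not internal:
            logger.info("%s: no transcript flanks it on both sides; excluded", mex.id)
            continue
        tr = max(internal, key=lambda t: (t.spliced_length(), t.transcript_id))
        if mex.chrom not in chrom_cache:
            chrom_cache[mex.chrom] = str(genome[mex.chrom][:]).upper()
        chrom_seq = chrom_cache[mex.chrom]
        mature = spliced_sequence(tr, chrom_seq, gene.strand)
        ms, me = spliced_interval(tr, mex.interval, gene.strand)
        up = mature[max(0, ms - flank) : ms]
        down = mature[me : me + flank]
        if not up or not down:
            logger.info("%s: empty flank; excluded", mex.id)
            continue
        placement[mex.id] = (tr.transcript_id, ms, me)
        refs.append(
            JunctionReference(
                mex_id=mex.id,
                inclusion_seq=up + mature[ms:me] + down,
                exclusion_seq=up + down,
                left_junction=len(up),
                right_junction=len(up) + (me - ms),
                skip_junction=len(up),
            )
        )

    # group micro-exons whose spliced distance on a shared transcript < flank
    groups = _merge_groups(placement, flank)
    if groups:
        refs = [
            replace(r, merged_group=groups.get(r.mex_id)) if r.mex_id in groups else r
            for r in refs
        ]
    return refs


def _merge_groups(
    placement: Mapping[str, tuple[str, int, int]], flank: int
) -> dict[str, str]:
    by_tid: dict[str, list[tuple[int, int, str]]] = {}
    for mex_id, (tid, s, e) in placement.items():
        by_tid.setdefault(tid, []).append((s, e, mex_id))
    out: dict[str, str] = {}
    for tid, members in by_tid.items():
        members.sort()
        cluster: list[str] = []
        prev_end = None
        idx = 0
        for s, e, mex_id in members:
            if prev_end is not None and s - prev_end < flank:
                cluster.append(mex_id)
            else:
                if len(cluster) > 1:
                    idx += 1
                    for m in cluster:
                        out[m] = f"{tid}.grp{idx}"
                cluster = [mex_id]
            prev_end = e
        if len(cluster) > 1:
            idx += 1
            for m in cluster:
                out[m] = f"{tid}.grp{idx}"
    return out


def write_library_fasta(refs: Sequence[JunctionReference], path) -> None:
    """Headers: ``<mex_id>|incl L=<x> R=<y>`` and ``<mex_id>|excl S=<z>``."""
    with open(path, "w") as fh:
        for r in refs:
            grp = f" G={r.merged_group}" if r.merged_group else ""
            fh.write(f">{r.mex_id}|incl L={r.left_junction} R={r.right_junction}{grp}\n")
            fh.write(r.inclusion_seq + "\n")
            fh.write(f">{r.mex_id}|excl S={r.skip_junction}{grp}\n")
            fh.write(r.exclusion_seq + "\n")


def read_library_fasta(path) -> list[JunctionReference]:
    entries: dict[str, dict] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                header = line[1:]
                name, _, desc = header.partition(" ")
                mex_id, _, role = name.rpartition("|")
                meta = dict(kv.split("=") for kv in desc.split() if "=" in kv)
                rec = entries.setdefault(mex_id, {"merged_group": meta.get("G")})
                rec[role] = {"meta": meta, "seq": []}
            elif name:
                mex_id, _, role = name.rpartition("|")
                entries[mex_id][role]["seq"].append(line)
    refs = []
    for mex_id, rec in entries.items():
        inc, exc = rec["incl"], rec["excl"]
        refs.append(
            JunctionReference(
                mex_id=mex_id,
                inclusion_seq="".join(inc["seq"]),
                exclusion_seq="".join(exc["seq"]),
                left_junction=int(inc["meta"]["L"]),
                right_junction=int(inc["meta"]["R"]),
                skip_junction=int(exc["meta"]["S"]),
                merged_group=rec["merged_group"],
            )
        )
    return refs


# ---------------------------------------------------------------------------
# junction read counting


def _covers(start: int, end: int, junction: int, overhang: int) -> bool:
    return start <= junction - overhang and end >= junction + overhang


def count_junction_reads(
    sam_path,
    refs: Sequence[JunctionReference],
    sample_id: str | None = None,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_mismatches: int = 2,
) -> dict[str, JunctionCounts]:
    """Count junction-spanning reads aligned to the junction library.

    A read supports a junction when its aligned span extends at least
    ``min_overhang`` nt on both sides of it; one read may support both
    inclusion junctions of a short micro-exon.
    """
    if sample_id is None:
        sample_id = str(sam_path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    by_name: dict[str, tuple[str, str, JunctionReference]] = {}
    for r in refs:
        by_name[f"{r.mex_id}|incl"] = (r.mex_id, "incl", r)
        by_name[f"{r.mex_id}|excl"] = (r.mex_id, "excl", r)

    tallies: dict[str, list[int]] = {r.mex_id: [0, 0, 0] for r in refs}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            entry = by_name.get(aln.reference_name)
            if entry is None:
                logger.warning("alignment to unknown reference %s; skipped", aln.reference_name)
                continue
            try:
                if int(aln.get_tag("NM")) > max_mismatches:
                    continue
            except KeyError:
                pass
            mex_id, role, ref = entry
            start, end = aln.reference_start, aln.reference_end
            t = tallies[mex_id]
            if role == "incl":
                if _covers(start, end, ref.left_junction, min_overhang):
                    t[0] += 1
                if _covers(start, end, ref.right_junction, min_overhang):
                    t[1] += 1
            else:
                if _covers(start, end, ref.skip_junction, min_overhang):
                    t[2] += 1
    return {
        mex_id: JunctionCounts(mex_id, sample_id, rl, rr, rs)
        for mex_id, (rl, rr, rs) in tallies.items()
    }


# ---------------------------------------------------------------------------
# PSI arithmetic


def compute_psi(c: JunctionCounts, min_cov: int = DEFAULT_MIN_COVERAGE) -> PsiRecord:
    """PSI = R_tot / (R_tot + R_skipped); missing below the coverage floor.

    Coverage rule: (R_L + R_R >= min_cov) or (R_skipped >= min_cov);
    additionally missing when the denominator is zero.
    """
    covered = (c.r_left + c.r_right >= min_cov) or (c.r_skipped >= min_cov)
    denom = c.r_tot + c.r_skipped
    if not covered or denom == 0:
        return PsiRecord(c.mex_id, c.sample_id, None, c.r_tot, c.r_skipped)
    return PsiRecord(c.mex_id, c.sample_id, c.r_tot / denom, c.r_tot, c.r_skipped)


def merge_replicates(
    a: PsiRecord,
    b: PsiRecord,
    max_delta: float = DEFAULT_MERGE_DELTA,
    unit_id: str | None = None,
) -> PsiRecord:
    """Combine two biological replicates of one condition.

    Single present value is kept; two values closer than ``max_delta``
    (absolute PSI units, strict) average; otherwise missing.
    """
    if a.mex_id != b.mex_id:
        raise ValueError(f"replicate mex_id mismatch: {a.mex_id} vs {b.mex_id}")
    unit = unit_id if unit_id is not None else f"{a.unit_id}+{b.unit_id}"
    n_inc, n_skip = a.n_inc + b.n_inc, a.n_skip + b.n_skip
    if a.psi is None and b.psi is None:
        psi = None
    elif a.psi is None:
        psi = b.psi
    elif b.psi is None:
        psi = a.psi
    else:
        delta = abs(a.psi - b.psi)
        # strict <, robust to float rounding at the boundary (0.6 - 0.5 case)
        if delta < max_delta and not math.isclose(delta, max_delta, rel_tol=1e-9):
            psi = (a.psi + b.psi) / 2.0
        else:
            psi = None
    return PsiRecord(a.mex_id, unit, psi, n_inc, n_skip)


# ---------------------------------------------------------------------------
# tissue expression sets


def tissue_expression_sets(
    psi: pd.DataFrame,
    unit_to_tissue: Mapping[str, str],
    min_psi: float = AS_FLOOR,
    min_samples: int = 2,
) -> tuple[dict[str, set[str]], pd.DataFrame, dict[str, set[str]]]:
    """Per-tissue expressed sets, Venn-style overlap table, tissue-specific sets.

    ``psi`` is a micro-exon x unit matrix (NaN = missing).  A micro-exon is
    expressed in a tissue when PSI >= ``min_psi`` in >= ``min_samples`` of
    that tissue's units.
    """
    unknown = [u for u in psi.columns if u not in unit_to_tissue]
    if unknown:
        raise ValueError(f"units with unknown tissue label: {unknown}")
    tissues = sorted(set(unit_to_tissue[u] for u in psi.columns))
    expressed: dict[str, set[str]] = {}
    for tissue in tissues:
        cols = [u for u in psi.columns if unit_to_tissue[u] == tissue]
        hits = (psi[cols] >= min_psi).sum(axis=1)
        expressed[tissue] = set(psi.index[hits >= min_samples])

    membership = {
        m: frozenset(t for t in tissues if m in expressed[t]) for m in psi.index
    }
    rows = []
    for k in range(1, len(tissues) + 1):
        for combo in itertools.combinations(tissues, k):
            combo_set = frozenset(combo)
            n = sum(1 for ms in membership.values() if ms == combo_set)
            rows.append({"tissues": "+".join(combo), "n_tissues": k, "count": n})
    overlap = pd.DataFrame(rows, columns=["tissues", "n_tissues", "count"])
    specific = {
        t: {m for m, ms in membership.items() if ms == frozenset([t])} for t in tissues
    }
    return expressed, overlap, specific


# ---------------------------------------------------------------------------
# tabular output


def psi_matrix(records: Iterable[PsiRecord]) -> pd.DataFrame:
    """Long records -> micro-exon x unit matrix (NaN for missing)."""
    rows = [(r.mex_id, r.unit_id, r.psi) for r in records]
    df = pd.DataFrame(rows, columns=["mex_id", "unit_id", "psi"])
    return df.pivot(index="mex_id", columns="unit_id", values="psi")


def write_psi_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", float_format="%.6g")


def write_splice_classes(records: Iterable[PsiRecord], path) -> None:
    rows = [
        {
            "mex_id": r.mex_id,
            "unit_id": r.unit_id,
            "psi": "" if r.psi is None else f"{r.psi:.6g}",
            "n_inc": r.n_inc,
            "n_skip": r.n_skip,
            "splice_class": r.splice_class,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["mex_id", "unit_id", "psi", "n_inc", "n_skip", "splice_class"]
    ).to_csv(path, sep="\t", index=False)
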