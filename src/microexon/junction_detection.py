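"""Candidate micro-exon detection from spliced (gapped) read alignments.

A spliced alignment contributes one observation for every internal aligned
block whose length is within micro-exon bounds and whose two neighbouring
blocks (the anchors) are each long enough.  Observations pooled across
samples become candidates once their total support strictly exceeds the
support threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from microexon.genome_annotation import (
    MAX_MICROEXON_LEN,
    MIN_MICROEXON_LEN,
    GeneModel,
    MicroExon,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR = 6
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MIN_SUPPORT = 10
NEAR_MISS_TOLERANCE = 3


@dataclass
class ObservationStore:
    """Per-(chrom, interval) support counts keyed by sample."""

    counts: dict[tuple[str, int, int], dict[str, int]] = field(default_factory=dict)
    min_anchor_seen: dict[tuple[str, int, int], int] = field(default_factory=dict)
    n_alignments_used: int = 0
    n_rejected: int = 0

    def add(self, chrom: str, start: int, end: int, sample: str, anchor: int) -> None:
        key = (chrom, start, end)
        per_sample = self.counts.setdefault(key, {})
        per_sample[sample] = per_sample.get(sample, 0) + 1
        prev = self.min_anchor_seen.get(key)
        self.min_anchor_seen[key] = anchor if prev is None else min(prev, anchor)

    def total(self, key: tuple[str, int, int]) -> int:
        return sum(self.counts[key].values())

    def update(self, other: "ObservationStore") -> None:
        for key, per_sample in other.counts.items():
            mine = self.counts.setdefault(key, {})
            for sample, n in per_sample.items():
                mine[sample] = mine.get(sample, 0) + n
            prev = self.min_anchor_seen.get(key)
            oa = other.min_anchor_seen[key]
            self.min_anchor_seen[key] = oa if prev is None else min(prev, oa)
        self.n_alignments_used += other.n_alignments_used
        self.n_rejected += other.n_rejected


@dataclass(frozen=True)
class CandidateMicroExon:
    chrom: str
    start: int
    end: int
    support_total: int
    support_by_sample: Mapping[str, int]
    min_anchor: int
    annotation_status: str  # annotated | novel_in_gene | novel_intergenic
    gene_id: str = ""
    near_annotated: bool = False

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def reference_blocks(aln: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Aligned reference segments split only at skipped regions (N).

    Deletions extend the current block; insertions and clips consume no
    reference.  Returns 0-based half-open intervals.
    """
    blocks: list[tuple[int, int]] = []
    pos = aln.reference_start
    block_start = pos
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a block
            pos += length
        elif op == 3:  # N closes the block
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
        # I (1), S (4), H (5), P (6) consume no reference
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks


def _mismatches(aln: pysam.AlignedSegment) -> int:
    try:
        return int(aln.get_tag("NM"))
    except KeyError:
        logger.debug("read %s lacks NM tag; assuming 0 mismatches", aln.query_name)
        return 0


def observations_from_blocks(
    blocks: Sequence[tuple[int, int]],
    min_len: int = MIN_MICROEXON_LEN,
    max_len: int = MAX_MICROEXON_LEN,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[tuple[int, int, int]]:
    """(start, end, flanking_anchor) for each qualifying middle block."""
    out = []
    for i in range(1, len(blocks) - 1):
        s, e = blocks[i]
        if not (min_len <= e - s <= max_len):
            continue
        left = blocks[i - 1][1] - blocks[i - 1][0]
        right = blocks[i + 1][1] - blocks[i + 1][0]
        if left >= min_anchor and right >= min_anchor:
            out.append((s, e, min(left, right)))
    return out


def scan_alignments(
    sam_path,
    sample_id: str | None = None,
    min_len: int = MIN_MICROEXON_LEN,
    max_len: int = MAX_MICROEXON_LEN,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    min_mapq: int = 1,
    store: ObservationStore | None = None,
) -> ObservationStore:
    """Collect middle-block observations from one SAM/BAM file.

    Alignments that are secondary, supplementary, unmapped, below the
    mapping-quality floor, or carrying >= ``max_mismatches`` mismatches are
    discarded.  ``sample_id`` defaults to the file stem.
    """
    if sample_id is None:
        sample_id = str(sam_path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if store is None:
        store = ObservationStore()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                store.n_rejected += 1
                continue
            if aln.mapping_quality < min_mapq or _mismatches(aln) >= max_mismatches:
                store.n_rejected += 1
                continue
            blocks = reference_blocks(aln)
            store.n_alignments_used += 1
            if len(blocks) < 3:
                continue
            for s, e, anchor in observations_from_blocks(
                blocks, min_len, max_len, min_anchor
            ):
                store.add(aln.reference_name, s, e, sample_id, anchor)
    return store


def call_candidates(
    store: ObservationStore,
    genes: Iterable[GeneModel] = (),
    annotated: Iterable[MicroExon] = (),
    min_support: int = DEFAULT_MIN_SUPPORT,
    per_sample: bool = False,
) -> list[CandidateMicroExon]:
    """Intervals with support strictly greater than ``min_support`` become
    candidates, labelled against the annotation.

    ``per_sample=True`` requires every sample (rather than the pool) to
    exceed the threshold.
    """
    annotated_set = {(m.chrom, m.start, m.end): m for m in annotated}
    gene_spans = [(g.chrom, g.span[0], g.span[1], g.gene_id) for g in genes]

    out: list[CandidateMicroExon] = []
    for key in sorted(store.counts):
        chrom, start, end = key
        per = store.counts[key]
        if per_sample:
            ok = all(n > min_support for n in per.values()) and bool(per)
        else:
            ok = store.total(key) > min_support
        if not ok:
            continue
        status, gene_id, near = "novel_intergenic", "", False
        if key in annotated_set:
            status = "annotated"
            gene_id = annotated_set[key].gene_id
        else:
            for gc, gs, ge, gid in gene_spans:
                if gc == chrom and gs <= start and end <= ge:
                    status, gene_id = "novel_in_gene", gid
                    break
            near = any(
                c == chrom
                and abs(s - start) <= NEAR_MISS_TOLERANCE
                and abs(e - end) <= NEAR_MISS_TOLERANCE
                for (c, s, e) in annotated_set
            )
        out.append(
            CandidateMicroExon(
                chrom=chrom,
                start=start,
                end=end,
                support_total=store.total(key),
                support_by_sample=dict(sorted(per.items())),
                min_anchor=store.min_anchor_seen[key],
                annotation_status=status,
                gene_id=gene_id,
                near_annotated=near,
            )
        )
    return out


def write_candidates_tsv(candidates: Sequence[CandidateMicroExon], path) -> None:
    import pandas as pd

    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "length_nt": c.length_nt,
            "support_total": c.support_total,
            "min_anchor": c.min_anchor,
            "annotation_status": c.annotation_status,
            "gene_id": c.gene_id,
            "near_annotated": c.near_annotated,
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "length_nt",
            "support_total",
            "min_anchor",
            "annotation_status",
            "gene_id",
            "near_annotated",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_candidates_bed(candidates: Sequence[CandidateMicroExon], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            name = f"{c.chrom}:{c.start}-{c.end}|{c.annotation_status}"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{c.support_total}\t.\n"
            )
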