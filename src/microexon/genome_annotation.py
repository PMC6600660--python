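"""Gene models from GFF3/FASTA and annotation-based micro-exon extraction.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
BED (0-based half-open) are converted only at the I/O boundary.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

MIN_MICROEXON_LEN = 3
MAX_MICROEXON_LEN = 51

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


class AnnotationError(ValueError):
    """Raised for structurally invalid GFF3/FASTA input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus CDS intervals with phase.

    Exons and CDS intervals are stored in genomic order regardless of
    strand; transcription order is derived from the strand when needed.
    """

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        for (s, e) in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted "
                    f"([{s0},{e0}) then [{s1},{e1}))"
                )
        for (s, e, _ph) in self.cds_intervals:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS [{s},{e}) outside every exon"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        for t in self.transcripts:
            ts, te = t.span
            if ts < self.span[0] or te > self.span[1]:
                raise AnnotationError(
                    f"{self.gene_id}: transcript {t.transcript_id} outside gene span"
                )


@dataclass(frozen=True)
class MicroExon:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: tuple[str, ...]
    positional_class: str  # first | internal | last | single
    coding_status: str  # cds | utr | mixed
    sequence: str = ""

    def __post_init__(self) -> None:
        n = self.end - self.start
        if not (MIN_MICROEXON_LEN <= n <= MAX_MICROEXON_LEN):
            raise AnnotationError(f"{self.id}: length {n} outside micro-exon bounds")
        if self.sequence and len(self.sequence) != n:
            raise AnnotationError(f"{self.id}: sequence length != interval length")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def frame_class(self) -> str:
        return "in_frame" if self.length_nt % 3 == 0 else "frame_shifting"

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _feature_parents(feature) -> list[str]:
    return list(feature.attributes.get("Parent", []))


def load_annotation(gff3_path, fasta_path) -> list[GeneModel]:
    """Parse a GFF3 + genome FASTA into :class:`GeneModel` objects.

    GFF3 must carry a gene -> mRNA/transcript -> exon/CDS hierarchy.  A child
    feature whose Parent is absent, or a gene on a chromosome missing from
    the FASTA, raises :class:`AnnotationError` naming the offender.
    """
    gff3_path, fasta_path = Path(gff3_path), Path(fasta_path)
    if not gff3_path.exists():
        raise FileNotFoundError(gff3_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known_ids = {f.id for f in db.all_features()}
    for ftype in ("mRNA", "transcript", "exon", "CDS"):
        for feat in db.features_of_type(ftype):
            for parent in _feature_parents(feat):
                if parent not in known_ids:
                    raise AnnotationError(
                        f"{ftype} {feat.id or feat.attributes} at "
                        f"{feat.seqid}:{feat.start}-{feat.end} references missing "
                        f"Parent {parent!r}"
                    )

    fasta = Fasta(str(fasta_path))
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        if g.seqid not in fasta:
            raise AnnotationError(
                f"gene {g.id}: chromosome {g.seqid!r} absent from FASTA"
            )
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), level=1):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            )
            if not exons:
                continue
            cds = sorted(
                (f.start - 1, f.end, int(f.frame) if f.frame != "." else 0)
                for f in db.children(t, featuretype="CDS")
            )
            transcripts.append(
                TranscriptModel(
                    transcript_id=t.id, exons=tuple(exons), cds_intervals=tuple(cds)
                )
            )
        if not transcripts:
            continue
        span = (
            min(t.span[0] for t in transcripts),
            max(t.span[1] for t in transcripts),
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                transcripts=tuple(sorted(transcripts, key=lambda t: t.transcript_id)),
                span=span,
            )
        )
    return genes


def _positional_class(tr: TranscriptModel, interval: tuple[int, int], strand: str) -> str:
    idx = tr.exons.index(interval)
    if len(tr.exons) == 1:
        return "single"
    last = len(tr.exons) - 1
    if strand == "+":
        return "first" if idx == 0 else ("last" if idx == last else "internal")
    return "last" if idx == 0 else ("first" if idx == last else "internal")


def _resolve_positional(classes: Sequence[str]) -> str:
    # majority vote; ties resolved toward the analytically relevant class
    counts = collections.Counter(classes)
    best = max(counts.values())
    tied = {c for c, n in counts.items() if n == best}
    for preferred in ("internal", "first", "last", "single"):
        if preferred in tied:
            return preferred
    return classes[0]


def _coding_status(
    interval: tuple[int, int], transcripts: Iterable[TranscriptModel]
) -> str:
    s, e = interval
    covered = set()
    for tr in transcripts:
        for cs, ce, _ph in tr.cds_intervals:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                covered.update(range(lo, hi))
    if not covered:
        return "utr"
    return "cds" if len(covered) == e - s else "mixed"


def extract_annotated_microexons(
    genes: Iterable[GeneModel],
    genome: Mapping[str, object] | Fasta | None = None,
    min_len: int = MIN_MICROEXON_LEN,
    max_len: int = MAX_MICROEXON_LEN,
) -> list[MicroExon]:
    """Extract every exon of length ``min_len``..``max_len`` as a MicroExon.

    One MicroExon per distinct genomic interval per gene; ``transcript_ids``
    lists every transcript sharing that exact interval.  Minus-strand
    sequences are reverse-complemented.  Deterministic: output sorted by
    (chrom, start, end, gene_id).
    """
    out: list[MicroExon] = []
    for gene in genes:
        by_interval: dict[tuple[int, int], list[TranscriptModel]] = {}
        for tr in gene.transcripts:
            for iv in tr.exons:
                if min_len <= iv[1] - iv[0] <= max_len:
                    by_interval.setdefault(iv, []).append(tr)
        for iv in sorted(by_interval):
            trs = by_interval[iv]
            classes = [_positional_class(tr, iv, gene.strand) for tr in trs]
            seq = ""
            if genome is not None:
                raw = str(genome[gene.chrom][iv[0] : iv[1]]).upper()
                seq = reverse_complement(raw) if gene.strand == "-" else raw
            out.append(
                MicroExon(
                    id=f"{gene.gene_id}:{gene.chrom}:{iv[0]}-{iv[1]}",
                    chrom=gene.chrom,
                    start=iv[0],
                    end=iv[1],
                    strand=gene.strand,
                    gene_id=gene.gene_id,
                    transcript_ids=tuple(t.transcript_id for t in trs),
                    positional_class=_resolve_positional(classes),
                    coding_status=_coding_status(iv, trs),
                    sequence=seq,
                )
            )
    out.sort(key=lambda m: (m.chrom, m.start, m.end, m.gene_id))
    return out


def summarize_length_distribution(mexs: Sequence[MicroExon]) -> pd.DataFrame:
    """Counts partitioned by positional class and length (long format)."""
    if not mexs:
        return pd.DataFrame(columns=["positional_class", "length_nt", "count"])
    df = pd.DataFrame(
        {
            "positional_class": [m.positional_class for m in mexs],
            "length_nt": [m.length_nt for m in mexs],
        }
    )
    return (
        df.groupby(["positional_class", "length_nt"])
        .size()
        .rename("count")
        .reset_index()
    )


def in_frame_fraction(mexs: Sequence[MicroExon]) -> float:
    """Fraction of micro-exons whose length is a multiple of three."""
    if not mexs:
        return float("nan")
    return sum(m.frame_class == "in_frame" for m in mexs) / len(mexs)


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = [
    "id",
    "chrom",
    "start",
    "end",
    "strand",
    "length_nt",
    "gene_id",
    "transcript_ids",
    "positional_class",
    "coding_status",
    "frame_class",
    "sequence",
]


def write_bed(mexs: Sequence[MicroExon], path) -> None:
    """BED6: name = micro-exon id, score = length."""
    with open(path, "w") as fh:
        for m in mexs:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.id}\t{m.length_nt}\t{m.strand}\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Return (chrom, start, end, strand) intervals from a BED6 file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "+"))
    return rows


def write_tsv(mexs: Sequence[MicroExon], path) -> None:
    rows = [
        {
            "id": m.id,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
            "length_nt": m.length_nt,
            "gene_id": m.gene_id,
            "transcript_ids": ",".join(m.transcript_ids),
            "positional_class": m.positional_class,
            "coding_status": m.coding_status,
            "frame_class": m.frame_class,
            "sequence": m.sequence,
        }
        for m in mexs
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> list[MicroExon]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        MicroExon(
            id=r["id"],
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=r["strand"],
            gene_id=r["gene_id"],
            transcript_ids=tuple(str(r["transcript_ids"]).split(",")),
            positional_class=r["positional_class"],
            coding_status=r["coding_status"],
            sequence=str(r["sequence"]),
        )
        for _, r in df.iterrows()
    ]
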