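"""Micro-exon conservation across collinear gene pairs.

A micro-exon is located in its gene's protein, mapped through a pairwise
protein alignment into the partner gene, and the partner exon's CDS phase
and length at the mapped span decide the verdict: conserved requires the
same phase and the same CDS length; nucleotide substitutions are then
counted on the back-mapped CDS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from microexon.genome_annotation import (
    GeneModel,
    MicroExon,
    TranscriptModel,
    reverse_complement,
)

logger = logging.getLogger(__name__)

VERDICTS = ("conserved_identical", "conserved_substituted", "not_conserved", "unalignable")


@dataclass(frozen=True)
class CollinearPair:
    gene_a: str
    gene_b: str
    block_id: str = ""


@dataclass(frozen=True)
class MappedMicroExon:
    """Result of locating a micro-exon's homologous span in a partner gene."""

    mex_id: str
    pair: CollinearPair
    status: str  # ok | unalignable
    phase_a: int = 0
    phase_b: int = 0
    len_a: int = 0
    len_b: int = 0
    seq_a: str = ""
    seq_b: str = ""
    exon_merged: bool = False
    aa_span_a: tuple[int, int] = (0, 0)
    aa_span_b: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class ConservationRecord:
    mex_id: str
    pair: CollinearPair
    verdict: str
    phase_a: int = 0
    phase_b: int = 0
    len_a: int = 0
    len_b: int = 0
    n_substitutions: int = 0
    exon_merged: bool = False
    domain_consistent: bool | None = None
    domain_category: str = ""
    aa_span_a: tuple[int, int] = (0, 0)
    aa_span_b: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        conserved = self.verdict in ("conserved_identical", "conserved_substituted")
        if conserved and (self.phase_a != self.phase_b or self.len_a != self.len_b):
            raise ValueError(f"{self.mex_id}: conserved verdict with unequal phase/length")
        if self.verdict == "conserved_identical" and self.n_substitutions != 0:
            raise ValueError(f"{self.mex_id}: identical verdict with substitutions")


# ---------------------------------------------------------------------------
# CDS geometry helpers


def cds_transcript(gene: GeneModel) -> TranscriptModel:
    """Longest-CDS transcript of a gene (ties broken by id)."""
    coding = [t for t in gene.transcripts if t.cds_intervals]
    if not coding:
        raise ValueError(f"{gene.gene_id}: no coding transcript")
    return max(
        coding,
        key=lambda t: (sum(e - s for s, e, _ in t.cds_intervals), t.transcript_id),
    )


def cds_nt_sequence(tr: TranscriptModel, chrom_seq: str, strand: str) -> str:
    parts = [str(chrom_seq[s:e]).upper() for s, e, _ in tr.cds_intervals]
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


def protein_sequence(tr: TranscriptModel, chrom_seq: str, strand: str) -> str:
    nt = cds_nt_sequence(tr, chrom_seq, strand)
    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def _cds_offsets(tr: TranscriptModel, strand: str) -> list[tuple[int, int, int, int]]:
    """(cds_start_offset, genomic_start, genomic_end, phase) in transcription order."""
    ivs = list(tr.cds_intervals)
    if strand == "-":
        ivs = ivs[::-1]
    out, off = [], 0
    for s, e, ph in ivs:
        out.append((off, s, e, ph))
        off += e - s
    return out


def cds_offset_of_interval(
    tr: TranscriptModel, interval: tuple[int, int], strand: str
) -> tuple[int, int, int]:
    """(offset within spliced CDS, length, phase) of a fully coding exon.

    Raises ValueError when the interval is not covered by a single CDS
    interval of the transcript (conservation is defined on coding
    micro-exons).
    """
    s, e = interval
    for off, cs, ce, ph in _cds_offsets(tr, strand):
        if cs <= s and e <= ce:
            if (cs, ce) != (s, e):
                # partial-exon CDS: offset relative to the CDS interval
                delta = (s - cs) if strand == "+" else (ce - e)
                return off + delta, e - s, (3 - ((off + delta) % 3)) % 3
            return off, e - s, ph
    raise ValueError(f"interval {interval} not in coding region of {tr.transcript_id}")


# ---------------------------------------------------------------------------
# protein alignment (bundled global aligner for self-contained fixtures)


def align_proteins(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global Needleman-Wunsch with BLOSUM62, affine gaps 11/1."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aln = aligner.align(prot_a, prot_b)[0]
    return aln[0], aln[1]


def _column_maps(aligned_a: str, aligned_b: str) -> tuple[list[int], list[int]]:
    """For each residue index of A (resp. B), its alignment column."""
    cols_a, cols_b = [], []
    for col, (ca, cb) in enumerate(zip(aligned_a, aligned_b)):
        if ca != "-":
            cols_a.append(col)
        if cb != "-":
            cols_b.append(col)
    return cols_a, cols_b


# ---------------------------------------------------------------------------
# mapping & judging


def map_microexon_to_partner(
    mex: MicroExon,
    pair: CollinearPair,
    gene_a: GeneModel,
    genome_a: Mapping[str, object],
    gene_b: GeneModel,
    genome_b: Mapping[str, object],
    alignment: tuple[str, str] | None = None,
) -> MappedMicroExon:
    """Locate the micro-exon's homologous span in the partner gene.

    ``alignment`` is an externally computed (gapped_a, gapped_b) protein
    alignment; when omitted the bundled global aligner is used.
    """
    chrom_a = str(genome_a[gene_a.chrom][:]).upper()
    chrom_b = str(genome_b[gene_b.chrom][:]).upper()
    tr_a = _carrier_transcript(gene_a, mex)
    cds_a = cds_nt_sequence(tr_a, chrom_a, gene_a.strand)
    off_a, len_a, phase_a = cds_offset_of_interval(tr_a, mex.interval, gene_a.strand)
    seq_a = cds_a[off_a : off_a + len_a]

    aa_start = off_a // 3
    aa_end = -(-(off_a + len_a) // 3)  # ceil

    tr_b = cds_transcript(gene_b)
    cds_b = cds_nt_sequence(tr_b, chrom_b, gene_b.strand)
    if alignment is None:
        prot_a = protein_sequence(tr_a, chrom_a, gene_a.strand)
        prot_b = protein_sequence(tr_b, chrom_b, gene_b.strand)
        alignment = align_proteins(prot_a, prot_b)
    aligned_a, aligned_b = alignment
    cols_a, cols_b = _column_maps(aligned_a, aligned_b)
    col_to_b = {c: i for i, c in enumerate(cols_b)}

    b_positions = []
    for aa in range(aa_start, min(aa_end, len(cols_a))):
        col = cols_a[aa]
        if col in col_to_b:
            b_positions.append(col_to_b[col])
    if not b_positions:
        return MappedMicroExon(mex.id, pair, "unalignable")

    b_aa_start, b_aa_end = min(b_positions), max(b_positions) + 1
    nt_s, nt_e = b_aa_start * 3, b_aa_end * 3

    # partner CDS interval with the largest overlap with the mapped nt span
    best, best_overlap = None, 0
    for off, cs, ce, ph in _cds_offsets(tr_b, gene_b.strand):
        lo, hi = max(nt_s, off), min(nt_e, off + (ce - cs))
        if hi - lo > best_overlap:
            best, best_overlap = (off, cs, ce, ph), hi - lo
    if best is None:
        return MappedMicroExon(mex.id, pair, "unalignable")
    off_b, cs, ce, phase_b = best
    len_b = ce - cs
    seq_b = cds_b[off_b : off_b + len_b]
    # codon rounding can push the aa-derived nt span up to 2 nt outside
    merged = len_b > len_a and nt_s >= off_b - 2 and nt_e <= off_b + len_b + 2
    return MappedMicroExon(
        mex_id=mex.id,
        pair=pair,
        status="ok",
        phase_a=phase_a,
        phase_b=phase_b,
        len_a=len_a,
        len_b=len_b,
        seq_a=seq_a,
        seq_b=seq_b,
        exon_merged=merged,
        aa_span_a=(aa_start, aa_end),
        aa_span_b=(b_aa_start, b_aa_end),
    )


def _carrier_transcript(gene: GeneModel, mex: MicroExon) -> TranscriptModel:
    carriers = [
        t for t in gene.transcripts if mex.interval in t.exons and t.cds_intervals
    ]
    if not carriers:
        raise ValueError(f"{mex.id}: no coding transcript carries it in {gene.gene_id}")
    return max(
        carriers,
        key=lambda t: (sum(e - s for s, e, _ in t.cds_intervals), t.transcript_id),
    )


def judge_conservation(mapped: MappedMicroExon) -> ConservationRecord:
    """Same phase and same CDS length => conserved; substitutions counted by
    Hamming distance over the micro-exon span."""
    if mapped.status == "unalignable":
        return ConservationRecord(mapped.mex_id, mapped.pair, "unalignable")
    common = dict(
        phase_a=mapped.phase_a,
        phase_b=mapped.phase_b,
        len_a=mapped.len_a,
        len_b=mapped.len_b,
        exon_merged=mapped.exon_merged,
        aa_span_a=mapped.aa_span_a,
        aa_span_b=mapped.aa_span_b,
    )
    if mapped.phase_a == mapped.phase_b and mapped.len_a == mapped.len_b:
        n_sub = sum(a != b for a, b in zip(mapped.seq_a, mapped.seq_b))
        verdict = "conserved_identical" if n_sub == 0 else "conserved_substituted"
        return ConservationRecord(
            mapped.mex_id, mapped.pair, verdict, n_substitutions=n_sub, **common
        )
    return ConservationRecord(mapped.mex_id, mapped.pair, "not_conserved", **common)


# ---------------------------------------------------------------------------
# domain consistency


def _domains_at(
    domains: pd.DataFrame, protein_id: str, aa_span: tuple[int, int]
) -> set[str]:
    sub = domains[domains["protein_id"] == protein_id]
    s, e = aa_span  # 0-based half-open aa coordinates
    hit = sub[(sub["start"] - 1 < e) & (sub["end"] > s)]
    return set(hit["accession"])


def domain_consistency(
    record: ConservationRecord,
    protein_a: str,
    protein_b: str,
    domains_a: pd.DataFrame | None,
    domains_b: pd.DataFrame | None,
) -> ConservationRecord:
    """Annotate a record with whether the partner carries the same domain
    accession over the mapped span, and a four-way structural category."""
    from dataclasses import replace

    if domains_a is None or domains_b is None:
        return replace(record, domain_consistent=None, domain_category="unknown")
    acc_a = _domains_at(domains_a, protein_a, record.aa_span_a)
    acc_b = _domains_at(domains_b, protein_b, record.aa_span_b)
    consistent = bool(acc_a & acc_b)
    if record.exon_merged:
        category = (
            "merged-exon-similar-domain" if consistent else "merged-exon-different-domain"
        )
    else:
        category = (
            "same-structure-same-domain" if consistent else "different-structure-one-domain"
        )
    return replace(record, domain_consistent=consistent, domain_category=category)


# ---------------------------------------------------------------------------
# summaries & I/O


def conservation_summary(
    records_by_species: Mapping[str, Sequence[ConservationRecord]],
    total_pairs: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-species gene-pair / micro-exon conservation counts.

    Columns mirror a conservation table: total gene pairs, pairs whose
    reference gene carries a micro-exon, pairs conserving at least one, and
    the number of distinct conserved micro-exons (which may exceed the pair
    count).  Domain-consistency percentages are split by conservation
    status.
    """
    rows = []
    for species in sorted(records_by_species):
        recs = records_by_species[species]
        pair_keys = {(r.pair.gene_a, r.pair.gene_b) for r in recs}
        conserved = [
            r for r in recs if r.verdict in ("conserved_identical", "conserved_substituted")
        ]
        conserved_pairs = {(r.pair.gene_a, r.pair.gene_b) for r in conserved}
        conserved_mex = {r.mex_id for r in conserved}

        def _pct_consistent(subset: list[ConservationRecord]) -> float:
            known = [r for r in subset if r.domain_consistent is not None]
            if not known:
                return float("nan")
            return 100.0 * sum(r.domain_consistent for r in known) / len(known)

        nonconserved = [r for r in recs if r not in conserved]
        rows.append(
            {
                "species": species,
                "total_gene_pairs": (total_pairs or {}).get(species, len(pair_keys)),
                "pairs_with_mex": len(pair_keys),
                "pairs_with_conserved_mex": len(conserved_pairs),
                "conserved_mex_count": len(conserved_mex),
                "pct_domain_consistent_conserved": _pct_consistent(conserved),
                "pct_domain_consistent_nonconserved": _pct_consistent(nonconserved),
            }
        )
    columns = [
        "species",
        "total_gene_pairs",
        "pairs_with_mex",
        "pairs_with_conserved_mex",
        "conserved_mex_count",
        "pct_domain_consistent_conserved",
        "pct_domain_consistent_nonconserved",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_collinear_pairs(path) -> list[CollinearPair]:
    """Parse MCScanX collinearity output (or a plain two-column TSV)."""
    pairs: list[CollinearPair] = []
    block = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.search(r"Alignment\s+(\S+?):", line)
                if m:
                    block = m.group(1)
                continue
            fields = line.replace(":", "\t").split()
            genes = [f for f in fields if not re.fullmatch(r"[\d.eE+-]+", f)]
            if len(genes) >= 2:
                pairs.append(CollinearPair(genes[-2], genes[-1], block))
            elif len(fields) >= 2:
                pairs.append(CollinearPair(fields[-2], fields[-1], block))
    return pairs


def read_domain_table(path) -> pd.DataFrame:
    """InterProScan-style TSV -> (protein_id, accession, start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 8:
        raise ValueError(f"{path}: expected >= 8 InterProScan columns")
    out = df.iloc[:, [0, 4, 6, 7]].copy()
    out.columns = ["protein_id", "accession", "start", "end"]
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out


def write_records_tsv(records: Iterable[ConservationRecord], path) -> None:
    rows = [
        {
            "mex_id": r.mex_id,
            "gene_a": r.pair.gene_a,
            "gene_b": r.pair.gene_b,
            "block_id": r.pair.block_id,
            "verdict": r.verdict,
            "phase_a": r.phase_a,
            "phase_b": r.phase_b,
            "len_a": r.len_a,
            "len_b": r.len_b,
            "n_substitutions": r.n_substitutions,
            "exon_merged": r.exon_merged,
            "domain_consistent": "" if r.domain_consistent is None else r.domain_consistent,
            "domain_category": r.domain_category,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
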