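"""Self-contained synthetic fixtures with known ground truth.

Generates toy genomes whose genes carry planted micro-exons, matching GFF3
annotation, spliced reads at controlled inclusion levels (emitted as
already-aligned SAM against both the genome and the junction library),
homology-hit tables with planted phylostrata, and edited partner genomes
for conservation tests.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from microexon.genome_annotation import (
    GeneModel,
    MicroExon,
    TranscriptModel,
    reverse_complement,
)
from microexon.psi_quant import (
    JunctionReference,
    build_junction_library,
    spliced_interval,
    spliced_sequence,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

DEFAULT_TISSUES = ("flagleaf", "panicle", "root", "shoot")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    microexon_length_set: tuple[int, ...] = (9, 12, 15, 18, 24, 30, 45, 51)
    frame_shift_lengths: tuple[int, ...] = (10, 14, 22, 31, 46)
    frame_shift_fraction: float = 0.3
    unannotated_fraction: float = 0.0
    psi_levels: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    read_length: int = 101
    depth: int = 60
    n_tissues: int = 2
    n_replicates: int = 2
    replicate_noise_sd: float = 0.0
    min_read_overhang: int = 6
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (90, 180)
    intron_range: tuple[int, int] = (60, 500)
    intergenic_pad: int = 100
    ps_old_fraction: float = 0.542
    ps_young_fraction: float = 0.132

    def __post_init__(self) -> None:
        for name in ("frame_shift_fraction", "unannotated_fraction",
                     "ps_old_fraction", "ps_young_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if any(not 0.0 <= p <= 1.0 for p in self.psi_levels):
            raise ValueError("psi_levels outside [0,1]")
        if self.read_length <= 2 * self.min_read_overhang:
            raise ValueError("read_length must exceed twice the overhang")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not all(3 <= n <= 51 for n in self.microexon_length_set):
            raise ValueError("microexon_length_set outside [3,51]")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons to host an internal micro-exon")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES[: self.n_tissues]
        return tuple(f"tissue{i + 1}" for i in range(self.n_tissues))


@dataclass(frozen=True)
class MexTruth:
    mex_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    length: int
    exon_index_tx: int  # transcript-order exon index in the TRUE structure
    annotated: bool
    true_psi: Mapping[str, float]  # tissue -> inclusion level

    @property
    def frame_class(self) -> str:
        return "in_frame" if self.length % 3 == 0 else "frame_shifting"


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_ivs_gen: tuple[tuple[int, int], ...]  # genomic order, true structure
    mex_ids: tuple[str, ...]


@dataclass
class GroundTruth:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneTruth]
    mexs: list[MexTruth]
    ps_levels: dict[str, int] = field(default_factory=dict)

    def mex(self, mex_id: str) -> MexTruth:
        return next(m for m in self.mexs if m.mex_id == mex_id)

    def gene(self, gene_id: str) -> GeneTruth:
        return next(g for g in self.genes if g.gene_id == gene_id)


# ---------------------------------------------------------------------------
# genome + annotation simulation


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n)
    return "".join(_CODONS[i] for i in idx)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _pick_mex_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    in_frame = [n for n in cfg.microexon_length_set if n % 3 == 0]
    shifting = list(cfg.frame_shift_lengths) or [
        n for n in cfg.microexon_length_set if n % 3 != 0
    ]
    if rng.random() < cfg.frame_shift_fraction and shifting:
        return int(shifting[rng.integers(0, len(shifting))])
    pool = in_frame or list(cfg.microexon_length_set)
    return int(pool[rng.integers(0, len(pool))])


def simulate_genome_annotation(cfg: SimConfig) -> GroundTruth:
    """Build a toy genome: each gene hosts one internal planted micro-exon.

    Exon sequences form a stop-free CDS starting with ATG; introns are
    canonical GT..AG on the gene strand; half of genes sit on the minus
    strand.  A configurable fraction of micro-exons is withheld from the
    annotation (but present in the true structure) to test novel detection.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    parts: list[str] = []
    cursor = 0
    genes: list[GeneTruth] = []
    mexs: list[MexTruth] = []

    for gi in range(cfg.n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        mex_idx = int(rng.integers(1, n_exons - 1))
        exon_lens = [
            int(rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1))
            for _ in range(n_exons)
        ]
        exon_lens[mex_idx] = _pick_mex_length(cfg, rng)
        total = sum(exon_lens)
        if total % 3:
            # pad a non-micro exon so the CDS is a whole number of codons
            pad_idx = 0 if mex_idx != 0 else n_exons - 1
            exon_lens[pad_idx] += 3 - total % 3

        cds = "ATG" + _random_codons(rng, sum(exon_lens) // 3 - 1)
        chunks, off = [], 0
        for ln in exon_lens:
            chunks.append(cds[off : off + ln])
            off += ln
        introns = [
            "GT" + _random_seq(rng, int(rng.integers(*cfg.intron_range)) - 4) + "AG"
            for _ in range(n_exons - 1)
        ]
        tx_seq_parts = []
        for i, ch in enumerate(chunks):
            tx_seq_parts.append(ch)
            if i < len(introns):
                tx_seq_parts.append(introns[i])
        gene_tx_seq = "".join(tx_seq_parts)
        glen = len(gene_tx_seq)

        pad = _random_seq(rng, cfg.intergenic_pad)
        parts.append(pad)
        cursor += cfg.intergenic_pad
        g0 = cursor
        parts.append(gene_tx_seq if strand == "+" else reverse_complement(gene_tx_seq))
        cursor += glen

        # transcript-order offsets within the gene sequence
        offsets, off = [], 0
        for i, ln in enumerate(exon_lens):
            offsets.append(off)
            off += ln
            if i < len(introns):
                off += len(introns[i])
        ivs_tx = []
        for o, ln in zip(offsets, exon_lens):
            if strand == "+":
                ivs_tx.append((g0 + o, g0 + o + ln))
            else:
                ivs_tx.append((g0 + glen - o - ln, g0 + glen - o))
        ivs_gen = tuple(sorted(ivs_tx))

        ms, me = ivs_tx[mex_idx]
        annotated = bool(rng.random() >= cfg.unannotated_fraction)
        base_psi = float(cfg.psi_levels[rng.integers(0, len(cfg.psi_levels))])
        true_psi = {t: base_psi for t in cfg.tissues}
        mex_id = f"{gene_id}:{chrom}:{ms}-{me}"
        mexs.append(
            MexTruth(
                mex_id=mex_id,
                gene_id=gene_id,
                chrom=chrom,
                start=ms,
                end=me,
                strand=strand,
                length=me - ms,
                exon_index_tx=mex_idx,
                annotated=annotated,
                true_psi=true_psi,
            )
        )
        genes.append(
            GeneTruth(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=g0,
                end=g0 + glen,
                exon_ivs_gen=ivs_gen,
                mex_ids=(mex_id,),
            )
        )

    parts.append(_random_seq(rng, cfg.intergenic_pad))
    return GroundTruth(
        config=cfg, genome={chrom: "".join(parts)}, genes=genes, mexs=mexs
    )


def _phases_for(exon_ivs_gen: Sequence[tuple[int, int]], strand: str) -> list[int]:
    ivs = list(exon_ivs_gen) if strand == "+" else list(exon_ivs_gen)[::-1]
    phases_tx, off = [], 0
    for s, e in ivs:
        phases_tx.append((3 - off % 3) % 3)
        off += e - s
    return phases_tx if strand == "+" else phases_tx[::-1]


def _transcript_model(
    gene: GeneTruth, exon_ivs: Sequence[tuple[int, int]]
) -> TranscriptModel:
    phases = _phases_for(exon_ivs, gene.strand)
    return TranscriptModel(
        transcript_id=f"{gene.gene_id}t1",
        exons=tuple(exon_ivs),
        cds_intervals=tuple((s, e, ph) for (s, e), ph in zip(exon_ivs, phases)),
    )


def _gene_exons(truth: GroundTruth, gene: GeneTruth, annotated_view: bool) -> list[tuple[int, int]]:
    hidden = {
        (m.start, m.end)
        for m in truth.mexs
        if m.gene_id == gene.gene_id and not m.annotated
    }
    ivs = [iv for iv in gene.exon_ivs_gen if not (annotated_view and iv in hidden)]
    return ivs


def annotation_models(truth: GroundTruth, annotated_view: bool = True) -> list[GeneModel]:
    """Gene models as the GFF3 describes them (or the true structure)."""
    out = []
    for gene in truth.genes:
        ivs = _gene_exons(truth, gene, annotated_view)
        tr = _transcript_model(gene, ivs)
        out.append(
            GeneModel(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                transcripts=(tr,),
                span=(gene.start, gene.end),
            )
        )
    return out


def write_genome_fasta(genome: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gff3(truth: GroundTruth, path) -> None:
    """Emit the annotated view (unannotated micro-exons omitted)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in truth.genes:
            s, e = gene.start + 1, gene.end
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            tid = f"{gene.gene_id}t1"
            fh.write(
                f"{gene.chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={tid};Parent={gene.gene_id}\n"
            )
            ivs = _gene_exons(truth, gene, annotated_view=True)
            phases = _phases_for(ivs, gene.strand)
            for i, ((xs, xe), ph) in enumerate(zip(ivs, phases), 1):
                fh.write(
                    f"{gene.chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{gene.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
                fh.write(
                    f"{gene.chrom}\tsim\tCDS\t{xs + 1}\t{xe}\t.\t{gene.strand}\t{ph}\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "seed": truth.config.seed,
        "mexs": [
            {
                "mex_id": m.mex_id,
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "length": m.length,
                "frame_class": m.frame_class,
                "annotated": m.annotated,
                "true_psi": dict(m.true_psi),
            }
            for m in truth.mexs
        ],
        "ps_levels": truth.ps_levels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# read simulation


def _blocks_for_span(
    exon_ivs_gen: Sequence[tuple[int, int]], span: tuple[int, int]
) -> list[tuple[int, int]]:
    """Genomic blocks covered by a span on the genomic-orientation spliced seq."""
    blocks, off = [], 0
    s, e = span
    for xs, xe in exon_ivs_gen:
        ln = xe - xs
        lo, hi = max(s, off), min(e, off + ln)
        if lo < hi:
            blocks.append((xs + lo - off, xs + hi - off))
        off += ln
    return blocks


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    out = []
    for i, (s, e) in enumerate(blocks):
        if i:
            out.append(f"{s - blocks[i - 1][1]}N")
        out.append(f"{e - s}M")
    return "".join(out)


@dataclass
class SimulatedReads:
    genome_sams: dict[str, Path]
    library_sams: dict[str, Path]
    refs: list[JunctionReference]
    samples: list[tuple[str, str, int]]  # (sample_id, tissue, replicate)


def simulate_junction_reads(
    truth: GroundTruth,
    out_dir,
    emit_genome: bool = True,
    emit_library: bool = True,
    bad_anchor_reads: int = 0,
    flank: int = 100,
) -> SimulatedReads:
    """Draw per-read inclusion ~ Bernoulli(jittered PSI) and emit SAM files.

    One genome-aligned and one library-aligned SAM per (tissue, replicate)
    sample.  Genome-aligned inclusion reads span the whole micro-exon with
    both anchors at the configured minimum or more (what a gapped aligner
    reports for a 101-nt read over a short exon); library-aligned inclusion
    reads span exactly one inclusion junction, alternating left/right so the
    junction evidence stays balanced.  ``bad_anchor_reads`` adds, per
    micro-exon, inclusion reads with a 5-nt left anchor that detection must
    ignore.
    """
    cfg = truth.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)

    genome = truth.genome
    genes_by_id = {g.gene_id: g for g in truth.genes}
    models = annotation_models(truth, annotated_view=True)
    refs: list[JunctionReference] = []
    ref_by_mex: dict[str, JunctionReference] = {}
    if emit_library:
        annotated_mexs = [
            _mex_object(truth, m) for m in truth.mexs if m.annotated
        ]
        refs = build_junction_library(annotated_mexs, models, genome, flank=flank)
        ref_by_mex = {r.mex_id: r for r in refs}

    samples = [
        (f"{tissue}_rep{r + 1}", tissue, r + 1)
        for tissue in cfg.tissues
        for r in range(cfg.n_replicates)
    ]
    sq_genome = [
        f"@SQ\tSN:{chrom}\tLN:{len(seq)}" for chrom, seq in sorted(genome.items())
    ]
    sq_library = []
    for r in refs:
        sq_library.append(f"@SQ\tSN:{r.mex_id}|incl\tLN:{len(r.inclusion_seq)}")
        sq_library.append(f"@SQ\tSN:{r.mex_id}|excl\tLN:{len(r.exclusion_seq)}")

    genome_paths: dict[str, Path] = {}
    library_paths: dict[str, Path] = {}
    counter = 0

    for sample_id, tissue, rep in samples:
        genome_lines: list[str] = []
        library_lines: list[str] = []
        for mt in truth.mexs:
            gene = genes_by_id[mt.gene_id]
            psi = float(mt.true_psi[tissue])
            if cfg.replicate_noise_sd > 0:
                psi = float(
                    np.clip(psi + rng.normal(0.0, cfg.replicate_noise_sd), 0.0, 1.0)
                )
            ivs_true = list(gene.exon_ivs_gen)
            ivs_skip = [iv for iv in ivs_true if iv != (mt.start, mt.end)]
            mature_len = sum(e - s for s, e in ivs_true)
            skip_len = sum(e - s for s, e in ivs_skip)
            # mature (transcript-orientation) coordinates of the micro-exon
            tr_true = _transcript_model(gene, ivs_true)
            ms, me = spliced_interval(tr_true, (mt.start, mt.end), gene.strand)
            ref = ref_by_mex.get(mt.mex_id)

            includes = rng.random(cfg.depth) < psi
            toggle = False
            for inc in includes:
                counter += 1
                name = f"r{counter:07d}"
                if inc:
                    toggle = not toggle
                    g_lines, l_lines = _inclusion_read(
                        truth, gene, mt, ms, me, mature_len, rng, name, sample_id,
                        ref, cfg.min_read_overhang, junction="L" if toggle else "R",
                    )
                else:
                    g_lines, l_lines = _exclusion_read(
                        truth, gene, mt, ms, skip_len, ivs_skip, rng, name,
                        sample_id, ref, cfg.min_read_overhang,
                    )
                genome_lines.extend(g_lines)
                library_lines.extend(l_lines)
            for _ in range(bad_anchor_reads):
                counter += 1
                name = f"b{counter:07d}"
                g_lines, l_lines = _inclusion_read(
                    truth, gene, mt, ms, me, mature_len, rng, name, sample_id,
                    ref, cfg.min_read_overhang, junction="L",
                    force_left_overhang=5,
                )
                genome_lines.extend(g_lines)
                library_lines.extend(l_lines)

        if emit_genome:
            path = out_dir / f"genome_{sample_id}.sam"
            with open(path, "w") as fh:
                fh.write("@HD\tVN:1.6\tSO:unsorted\n")
                fh.write("\n".join(sq_genome) + "\n")
                fh.write("".join(genome_lines))
            genome_paths[sample_id] = path
        if emit_library:
            path = out_dir / f"library_{sample_id}.sam"
            with open(path, "w") as fh:
                fh.write("@HD\tVN:1.6\tSO:unsorted\n")
                if sq_library:
                    fh.write("\n".join(sq_library) + "\n")
                fh.write("".join(library_lines))
            library_paths[sample_id] = path

    return SimulatedReads(
        genome_sams=genome_paths,
        library_sams=library_paths,
        refs=refs,
        samples=samples,
    )


def _mex_object(truth: GroundTruth, mt: MexTruth) -> MicroExon:
    seq = truth.genome[mt.chrom][mt.start : mt.end]
    if mt.strand == "-":
        seq = reverse_complement(seq)
    return MicroExon(
        id=mt.mex_id,
        chrom=mt.chrom,
        start=mt.start,
        end=mt.end,
        strand=mt.strand,
        gene_id=mt.gene_id,
        transcript_ids=(f"{mt.gene_id}t1",),
        positional_class="internal",
        coding_status="cds",
        sequence=seq,
    )


def _mature_to_gen(span: tuple[int, int], total: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return span
    return total - span[1], total - span[0]


def _sam_line(
    name: str,
    flag: int,
    rname: str,
    pos0: int,
    cigar: str,
    seq: str,
    sample_id: str,
) -> str:
    return (
        f"{name}\t{flag}\t{rname}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\t"
        f"NM:i:0\tRG:Z:{sample_id}\n"
    )


def _genome_record(
    truth: GroundTruth,
    gene: GeneTruth,
    ivs: Sequence[tuple[int, int]],
    mature_span: tuple[int, int],
    total: int,
    name: str,
    sample_id: str,
) -> str:
    gen_span = _mature_to_gen(mature_span, total, gene.strand)
    blocks = _blocks_for_span(ivs, gen_span)
    seq = "".join(truth.genome[gene.chrom][s:e] for s, e in blocks)
    flag = 16 if gene.strand == "-" else 0
    return _sam_line(name, flag, gene.chrom, blocks[0][0], _cigar(blocks), seq, sample_id)


def _inclusion_read(
    truth: GroundTruth,
    gene: GeneTruth,
    mt: MexTruth,
    ms: int,
    me: int,
    mature_len: int,
    rng: np.random.Generator,
    name: str,
    sample_id: str,
    ref: JunctionReference | None,
    ov_min: int,
    junction: str = "L",
    force_left_overhang: int | None = None,
) -> tuple[list[str], list[str]]:
    import warnings

    rl = truth.config.read_length
    mex_len = me - ms
    ivs_true = list(gene.exon_ivs_gen)
    if rl < mex_len + 2 * ov_min:
        warnings.warn(
            f"{mt.mex_id}: read length {rl} cannot bridge both junctions; "
            "emitting reads over the left junction only"
        )
        left = int(rng.integers(ov_min, rl - ov_min))
        start = ms - left
    else:
        lo = max(ov_min, rl - mex_len - (mature_len - me))
        hi = min(rl - mex_len - ov_min, ms)
        left = (
            force_left_overhang
            if force_left_overhang is not None
            else int(rng.integers(lo, hi + 1))
        )
        start = ms - left
    span = (max(0, start), min(mature_len, max(0, start) + rl))
    genome_lines = [
        _genome_record(truth, gene, ivs_true, span, mature_len, name, sample_id)
    ]
    library_lines: list[str] = []
    if ref is not None:
        lib_span = _single_junction_span(ref, mex_len, rl, rng, junction)
        if lib_span is not None:
            s, e = lib_span
            seq = ref.inclusion_seq[s:e]
            library_lines.append(
                _sam_line(
                    name, 0, f"{ref.mex_id}|incl", s, f"{len(seq)}M", seq, sample_id
                )
            )
    return genome_lines, library_lines


def _single_junction_span(
    ref: JunctionReference,
    mex_len: int,
    rl: int,
    rng: np.random.Generator,
    junction: str,
    overhang: int = 3,
) -> tuple[int, int] | None:
    """Read span on the inclusion reference spanning exactly one junction.

    The read keeps >= ``overhang`` nt on both sides of its junction but
    stops short of granting the other inclusion junction a countable
    overhang, so each read supports exactly one of R_L / R_R.
    """
    up_len = ref.left_junction
    down_len = len(ref.inclusion_seq) - ref.right_junction
    lo = max(overhang, rl - mex_len - (overhang - 1))
    if junction == "L":
        hi = min(rl - overhang, up_len)
        if lo > hi:
            return None
        a = int(rng.integers(lo, hi + 1))  # left overhang before the L junction
        start = ref.left_junction - a
    else:
        hi = min(rl - overhang, down_len)
        if lo > hi:
            return None
        b = int(rng.integers(lo, hi + 1))  # right overhang past the R junction
        start = ref.right_junction + b - rl
    return start, start + rl


def _exclusion_read(
    truth: GroundTruth,
    gene: GeneTruth,
    mt: MexTruth,
    ms: int,
    skip_len: int,
    ivs_skip: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    name: str,
    sample_id: str,
    ref: JunctionReference | None,
    ov_min: int,
) -> tuple[list[str], list[str]]:
    rl = truth.config.read_length
    # on the skip isoform the junction sits at mature position ms
    lo = max(ov_min, rl - (skip_len - ms))
    hi = min(rl - ov_min, ms)
    left = int(rng.integers(lo, hi + 1))
    span = (ms - left, ms - left + rl)
    genome_lines = [
        _genome_record(truth, gene, ivs_skip, span, skip_len, name, sample_id)
    ]
    library_lines: list[str] = []
    if ref is not None:
        lib_pos = span[0] - (ms - ref.skip_junction)
        if 0 <= lib_pos and lib_pos + rl <= len(ref.exclusion_seq):
            seq = ref.exclusion_seq[lib_pos : lib_pos + rl]
            library_lines.append(
                _sam_line(
                    name, 0, f"{ref.mex_id}|excl", lib_pos, f"{rl}M", seq, sample_id
                )
            )
    return genome_lines, library_lines


# ---------------------------------------------------------------------------
# homology-hit tables (phylostrata)


def plant_ps_levels(truth: GroundTruth) -> dict[str, int]:
    """Assign planted phylostrata honouring the configured old/young fractions."""
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(truth.genes)
    n_old = int(round(cfg.ps_old_fraction * n))
    n_young = int(round(cfg.ps_young_fraction * n))
    levels: list[int] = []
    for i in range(n_old):
        levels.append(1 + i % 3)
    for i in range(n_young):
        levels.append(11 + i % 3)
    for i in range(n - n_old - n_young):
        levels.append(4 + i % 7)
    order = rng.permutation(n)
    ps = {truth.genes[int(j)].gene_id: levels[k] for k, j in enumerate(order)}
    truth.ps_levels = ps
    return ps


def simulate_hit_tables(truth: GroundTruth, out_dir) -> dict[str, Path]:
    """Write 12-column tabular hit files ``ps01.tsv`` .. ``ps13.tsv``.

    A gene planted at level L gets passing hits at L..12 and, at every older
    level, one decoy failing exactly one filter (cycling e-value, identity,
    coverage).  PS13 genes receive no passing hit anywhere.
    """
    if not truth.ps_levels:
        plant_ps_levels(truth)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qlens = protein_lengths(truth)
    rows_per_level: dict[int, list[str]] = {lvl: [] for lvl in range(1, 14)}

    def blast_row(q, s, pident, length, evalue):
        return (
            f"{q}\t{s}\t{pident:.1f}\t{length}\t0\t0\t1\t{length}\t1\t{length}\t"
            f"{evalue:g}\t200.0"
        )

    for gene in truth.genes:
        g = gene.gene_id
        lvl = truth.ps_levels[g]
        qlen = qlens[g]
        for l in range(lvl, 13):
            rows_per_level[l].append(blast_row(g, f"db{l}_hit", 80.0, qlen, 1e-30))
        decoy_modes = ["evalue", "identity", "coverage"]
        for i, l in enumerate(range(1, lvl)):
            mode = decoy_modes[i % 3]
            if mode == "evalue":
                rows_per_level[l].append(blast_row(g, f"db{l}_decoy", 80.0, qlen, 1e-3))
            elif mode == "identity":
                rows_per_level[l].append(blast_row(g, f"db{l}_decoy", 25.0, qlen, 1e-30))
            else:
                rows_per_level[l].append(
                    blast_row(g, f"db{l}_decoy", 80.0, max(1, qlen // 2), 1e-30)
                )

    paths = {}
    for lvl in range(1, 14):
        path = out_dir / f"ps{lvl:02d}.tsv"
        path.write_text("\n".join(rows_per_level[lvl]) + ("\n" if rows_per_level[lvl] else ""))
        paths[f"ps{lvl:02d}"] = path
    qlen_path = out_dir / "query_lengths.tsv"
    with open(qlen_path, "w") as fh:
        for g in sorted(qlens):
            fh.write(f"{g}\t{qlens[g]}\n")
    paths["query_lengths"] = qlen_path
    return paths


def protein_lengths(truth: GroundTruth) -> dict[str, int]:
    return {
        g.gene_id: sum(e - s for s, e in g.exon_ivs_gen) // 3 for g in truth.genes
    }


def cds_lengths(truth: GroundTruth) -> dict[str, int]:
    return {g.gene_id: sum(e - s for s, e in g.exon_ivs_gen) for g in truth.genes}


def simulate_expression(truth: GroundTruth) -> "pd.DataFrame":
    """Lognormal FPKM per gene x tissue; old genes drawn higher than young."""
    import pandas as pd

    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 3)
    if not truth.ps_levels:
        plant_ps_levels(truth)
    rows = {}
    for gene in truth.genes:
        lvl = truth.ps_levels[gene.gene_id]
        mu = 3.0 if lvl <= 3 else (1.0 if lvl >= 11 else 2.0)
        rows[gene.gene_id] = rng.lognormal(mu, 0.5, size=len(cfg.tissues))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(cfg.tissues)
    )


# ---------------------------------------------------------------------------
# collinear partner simulation


@dataclass(frozen=True)
class PartnerEdit:
    substitutions: int = 0
    merge: bool = False


@dataclass
class PartnerFixture:
    genome: dict[str, str]
    genes: list[GeneTruth]
    pairs: list[tuple[str, str]]  # (gene_a, gene_b)
    expected: dict[str, dict]  # mex_id -> expected verdict fields


def simulate_collinear_partner(
    truth: GroundTruth,
    edits: Mapping[str, PartnerEdit] | None = None,
) -> PartnerFixture:
    """Derive a partner genome by editing designated micro-exons.

    Substitutions replace bases inside the micro-exon (codon kept stop-free);
    a merge deletes the intron downstream of the micro-exon so its homolog
    is absorbed into a longer exon.  Untouched genes stay identical.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 4)
    edits = dict(edits or {})
    chrom = "chr1"
    parts: list[str] = []
    cursor = 0
    partner_genes: list[GeneTruth] = []
    pairs: list[tuple[str, str]] = []
    expected: dict[str, dict] = {}

    parts.append(_random_seq(rng, cfg.intergenic_pad))
    cursor += cfg.intergenic_pad

    for gene in truth.genes:
        mt = truth.mex(gene.mex_ids[0])
        edit = edits.get(mt.mex_id, PartnerEdit())
        if edit.substitutions > mt.length:
            raise ValueError(
                f"{mt.mex_id}: {edit.substitutions} substitutions exceed length {mt.length}"
            )
        # reconstruct transcript-orientation pieces
        ivs_gen = list(gene.exon_ivs_gen)
        ivs_tx = ivs_gen if gene.strand == "+" else ivs_gen[::-1]
        chrom_seq = truth.genome[gene.chrom]

        def tx_seq(s, e):
            seg = chrom_seq[s:e]
            return reverse_complement(seg) if gene.strand == "-" else seg

        exon_seqs = [tx_seq(s, e) for s, e in ivs_tx]
        intron_seqs = []
        for (a, b) in zip(ivs_tx, ivs_tx[1:]):
            if gene.strand == "+":
                intron_seqs.append(tx_seq(a[1], b[0]))
            else:
                intron_seqs.append(tx_seq(b[1], a[0]))

        mex_idx = mt.exon_index_tx
        n_sub = 0
        if edit.substitutions:
            exon_seqs, n_sub = _apply_substitutions(
                exon_seqs, mex_idx, edit.substitutions, rng
            )
        merged = False
        if edit.merge:
            exon_seqs[mex_idx] = exon_seqs[mex_idx] + exon_seqs[mex_idx + 1]
            del exon_seqs[mex_idx + 1]
            del intron_seqs[mex_idx]
            merged = True

        tx_parts = []
        for i, ex in enumerate(exon_seqs):
            tx_parts.append(ex)
            if i < len(intron_seqs):
                tx_parts.append(intron_seqs[i])
        gene_tx = "".join(tx_parts)
        glen = len(gene_tx)
        g0 = cursor
        parts.append(gene_tx if gene.strand == "+" else reverse_complement(gene_tx))
        cursor += glen
        parts.append(_random_seq(rng, cfg.intergenic_pad))
        cursor += cfg.intergenic_pad

        offsets, off = [], 0
        for i, ex in enumerate(exon_seqs):
            offsets.append(off)
            off += len(ex)
            if i < len(intron_seqs):
                off += len(intron_seqs[i])
        new_ivs_tx = []
        for o, ex in zip(offsets, exon_seqs):
            if gene.strand == "+":
                new_ivs_tx.append((g0 + o, g0 + o + len(ex)))
            else:
                new_ivs_tx.append((g0 + glen - o - len(ex), g0 + glen - o))
        gene_b_id = f"{gene.gene_id}_b"
        partner_genes.append(
            GeneTruth(
                gene_id=gene_b_id,
                chrom=chrom,
                strand=gene.strand,
                start=g0,
                end=g0 + glen,
                exon_ivs_gen=tuple(sorted(new_ivs_tx)),
                mex_ids=(),
            )
        )
        pairs.append((gene.gene_id, gene_b_id))
        if merged:
            expected[mt.mex_id] = {"verdict": "not_conserved", "exon_merged": True}
        elif n_sub:
            expected[mt.mex_id] = {
                "verdict": "conserved_substituted",
                "n_substitutions": n_sub,
            }
        else:
            expected[mt.mex_id] = {"verdict": "conserved_identical"}

    return PartnerFixture(
        genome={chrom: "".join(parts)},
        genes=partner_genes,
        pairs=pairs,
        expected=expected,
    )


def _apply_substitutions(
    exon_seqs: list[str],
    mex_idx: int,
    k: int,
    rng: np.random.Generator,
) -> tuple[list[str], int]:
    """Substitute k distinct bases in the micro-exon, avoiding stop codons."""
    cds = "".join(exon_seqs)
    offset = sum(len(e) for e in exon_seqs[:mex_idx])
    mex_len = len(exon_seqs[mex_idx])
    positions = rng.choice(mex_len, size=k, replace=False)
    cds_list = list(cds)
    n_done = 0
    for p in sorted(int(x) for x in positions):
        pos = offset + p
        old = cds_list[pos]
        for base in "ACGT":
            if base == old:
                continue
            cds_list[pos] = base
            c0 = pos - pos % 3
            if "".join(cds_list[c0 : c0 + 3]) not in _STOPS:
                n_done += 1
                break
            cds_list[pos] = old
    cds_new = "".join(cds_list)
    out, off = [], 0
    for ex in exon_seqs:
        out.append(cds_new[off : off + len(ex)])
        off += len(ex)
    return out, n_done


def partner_models(fix: PartnerFixture) -> list[GeneModel]:
    out = []
    for gene in fix.genes:
        tr = _transcript_model(gene, gene.exon_ivs_gen)
        out.append(
            GeneModel(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                transcripts=(tr,),
                span=(gene.start, gene.end),
            )
        )
    return out


def write_partner_fixture(fix: PartnerFixture, out_dir) -> dict[str, Path]:
    """Write the partner genome, annotation and pair table to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shell = GroundTruth(
        config=SimConfig(), genome=fix.genome, genes=fix.genes, mexs=[]
    )
    paths = {
        "fasta": out_dir / "partner_genome.fa",
        "gff": out_dir / "partner_annotation.gff3",
        "pairs": out_dir / "pairs.collinearity",
    }
    write_genome_fasta(fix.genome, paths["fasta"])
    write_gff3(shell, paths["gff"])
    write_pair_table(fix.pairs, paths["pairs"])
    return paths


def write_run_fixture(
    cfg: SimConfig,
    out_dir,
    with_partner: bool = True,
    with_hits: bool = True,
) -> Path:
    """Write a complete pipeline fixture plus a YAML run config; returns the
    config path."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_genome_annotation(cfg)
    write_genome_fasta(truth.genome, out_dir / "genome.fa")
    write_gff3(truth, out_dir / "annotation.gff3")
    reads = simulate_junction_reads(truth, out_dir / "reads")
    write_truth_json(truth, out_dir / "truth.json")

    design_rows = ["sample_id\ttissue\tcondition\treplicate"]
    for s, t, r in reads.samples:
        design_rows.append(f"{s}\t{t}\tbase\t{r}")
    (out_dir / "design.tsv").write_text("\n".join(design_rows) + "\n")

    inputs: dict = {
        "gff": str(out_dir / "annotation.gff3"),
        "fasta": str(out_dir / "genome.fa"),
        "genome_sams": {s: str(p) for s, p in reads.genome_sams.items()},
        "library_sams": {s: str(p) for s, p in reads.library_sams.items()},
        "design": str(out_dir / "design.tsv"),
    }
    if with_hits:
        plant_ps_levels(truth)
        simulate_hit_tables(truth, out_dir / "hits")
        inputs["hits_dir"] = str(out_dir / "hits")
        inputs["query_lengths"] = str(out_dir / "hits" / "query_lengths.tsv")
    if with_partner:
        fix = simulate_collinear_partner(truth)
        paths = write_partner_fixture(fix, out_dir / "partner")
        inputs["pairs"] = str(paths["pairs"])
        inputs["gff_b"] = str(paths["gff"])
        inputs["fasta_b"] = str(paths["fasta"])

    config = {
        "seed": cfg.seed,
        "out_dir": str(out_dir / "run"),
        "inputs": inputs,
    }
    config_path = out_dir / "run_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path


def write_pair_table(pairs: Sequence[tuple[str, str]], path) -> None:
    """MCScanX-flavoured collinearity listing."""
    with open(path, "w") as fh:
        fh.write("############### Alignment 0: score=1000 e_value=0 N=%d chr1&chr1 plus\n" % len(pairs))
        for i, (a, b) in enumerate(pairs):
            fh.write(f"  0-{i:4d}:\t{a}\t{b}\t  0\n")
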