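"""Pipeline orchestration: extract -> detect -> psi -> classify -> age -> conserve.

A YAML run config names the inputs and threshold overrides; each stage
writes its outputs into the run directory and is recorded in a JSON
manifest with SHA-256 checksums, so identical configs reproduce identical
runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from microexon import (
    conservation as cons,
    genome_annotation as ga,
    junction_detection as jd,
    phylostrata as ph,
    psi_quant as pq,
)
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: dict[str, float] = {
    "min_len": 3,
    "max_len": 51,
    "min_anchor": 6,
    "max_mismatches": 2,
    "min_support": 10,
    "flank": 100,
    "min_overhang": 3,
    "min_cov": 10,
    "as_floor": 0.1,
    "cs_floor": 0.9,
    "merge_delta": 0.10,
    "max_evalue": 1e-5,
    "min_identity": 0.3,
    "min_coverage": 0.8,
}

_THRESHOLD_DOMAINS: dict[str, tuple[float, float]] = {
    "min_len": (1, 51),
    "max_len": (3, 51),
    "min_anchor": (1, 100),
    "max_mismatches": (0, 100),
    "min_support": (0, 10**9),
    "flank": (1, 10**6),
    "min_overhang": (1, 100),
    "min_cov": (0, 10**9),
    "as_floor": (0.0, 1.0),
    "cs_floor": (0.0, 1.0),
    "merge_delta": (0.0, 1.0),
    "max_evalue": (0.0, 1.0),
    "min_identity": (0.0, 1.0),
    "min_coverage": (0.0, 1.0),
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: Path
    gff: Path
    fasta: Path
    seed: int = 0
    genome_sams: dict[str, Path] = field(default_factory=dict)
    library_sams: dict[str, Path] = field(default_factory=dict)
    design: Path | None = None
    hits_dir: Path | None = None
    query_lengths: Path | None = None
    pairs: Path | None = None
    gff_b: Path | None = None
    fasta_b: Path | None = None
    domains_a: Path | None = None
    domains_b: Path | None = None
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        for key, value in merged.items():
            if key not in _THRESHOLD_DOMAINS:
                raise ConfigError(f"unknown threshold {key!r}")
            lo, hi = _THRESHOLD_DOMAINS[key]
            if not lo <= value <= hi:
                raise ConfigError(f"threshold {key}={value} outside [{lo},{hi}]")
        if merged["min_len"] > merged["max_len"]:
            raise ConfigError("min_len exceeds max_len")
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})
        kwargs: dict[str, Any] = {
            "out_dir": Path(raw["out_dir"]),
            "gff": Path(inputs["gff"]),
            "fasta": Path(inputs["fasta"]),
            "seed": int(raw.get("seed", 0)),
            "thresholds": dict(raw.get("thresholds", {})),
        }
        for key in ("genome_sams", "library_sams"):
            val = inputs.get(key) or {}
            if isinstance(val, list):
                val = {Path(p).stem: p for p in val}
            kwargs[key] = {k: Path(v) for k, v in val.items()}
        for key in (
            "design", "hits_dir", "query_lengths", "pairs",
            "gff_b", "fasta_b", "domains_a", "domains_b",
        ):
            if inputs.get(key):
                kwargs[key] = Path(inputs[key])
        cfg = cls(**kwargs)
        if cfg.design is not None:
            design = read_design(cfg.design)
            if design.empty:
                raise ConfigError("design table has no samples")
            dup = design.duplicated(subset=["tissue", "condition", "replicate"])
            if dup.any():
                raise ConfigError("replicate labels within a condition must be unique")
        return cfg


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"design table missing columns: {sorted(missing)}")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path, cfg: RunConfig) -> None:
        self.run_dir = run_dir
        self.data: dict[str, Any] = {
            "seed": cfg.seed,
            "thresholds": cfg.thresholds,
            "stages": {},
        }

    def record(self, stage: str, outputs: list[Path], counts: Mapping[str, int]) -> None:
        self.data["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            "counts": dict(counts),
        }
        logger.info("stage %s: %s", stage, dict(counts))

    def fail(self, stage: str, err: Exception) -> None:
        self.data["stages"][stage] = {"status": "FAILED", "error": str(err)}
        (self.run_dir / "FAILED").write_text(f"{stage}: {err}\n")

    def write(self) -> Path:
        path = self.run_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir, cfg)
    th = cfg.thresholds
    state: dict[str, Any] = {}

    stages = [
        ("extract", _stage_extract),
        ("detect", _stage_detect),
        ("psi", _stage_psi),
        ("phylostrata", _stage_phylostrata),
        ("conserve", _stage_conserve),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        try:
            result = fn(cfg, th, run_dir, state)
        except Exception as err:  # noqa: BLE001 - abort with stage context
            manifest.fail(name, err)
            manifest.write()
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        if result is not None:
            outputs, counts = result
            manifest.record(name, outputs, counts)
    manifest.write()
    return run_dir


# --------------------------------------------------------------------- stages


def _stage_extract(cfg, th, run_dir, state):
    genes = ga.load_annotation(cfg.gff, cfg.fasta)
    genome = Fasta(str(cfg.fasta))
    mexs = ga.extract_annotated_microexons(
        genes, genome, min_len=int(th["min_len"]), max_len=int(th["max_len"])
    )
    state["genes"], state["genome"], state["mexs"] = genes, genome, mexs
    tsv, bed = run_dir / "microexons.tsv", run_dir / "microexons.bed"
    ga.write_tsv(mexs, tsv)
    ga.write_bed(mexs, bed)
    summary = ga.summarize_length_distribution(mexs)
    dist = run_dir / "length_distribution.tsv"
    summary.to_csv(dist, sep="\t", index=False)
    return [tsv, bed, dist], {"genes": len(genes), "microexons": len(mexs)}


def _stage_detect(cfg, th, run_dir, state):
    if not cfg.genome_sams:
        return None
    store = jd.ObservationStore()
    for sample_id, path in sorted(cfg.genome_sams.items()):
        jd.scan_alignments(
            path,
            sample_id=sample_id,
            min_len=int(th["min_len"]),
            max_len=int(th["max_len"]),
            min_anchor=int(th["min_anchor"]),
            max_mismatches=int(th["max_mismatches"]),
            store=store,
        )
    candidates = jd.call_candidates(
        store, state["genes"], state["mexs"], min_support=int(th["min_support"])
    )
    state["candidates"] = candidates
    tsv, bed = run_dir / "candidates.tsv", run_dir / "candidates.bed"
    jd.write_candidates_tsv(candidates, tsv)
    jd.write_candidates_bed(candidates, bed)
    by_status = pd.Series(
        [c.annotation_status for c in candidates]
    ).value_counts().to_dict()
    return [tsv, bed], {"candidates": len(candidates), **by_status}


def _stage_psi(cfg, th, run_dir, state):
    if not cfg.library_sams or cfg.design is None:
        return None
    refs = pq.build_junction_library(
        state["mexs"], state["genes"], state["genome"], flank=int(th["flank"])
    )
    lib_fa = run_dir / "junction_library.fa"
    pq.write_library_fasta(refs, lib_fa)
    design = read_design(cfg.design)

    per_sample: dict[str, dict[str, pq.PsiRecord]] = {}
    for sample_id, path in sorted(cfg.library_sams.items()):
        counts = pq.count_junction_reads(
            path,
            refs,
            sample_id=sample_id,
            min_overhang=int(th["min_overhang"]),
            max_mismatches=int(th["max_mismatches"]),
        )
        per_sample[sample_id] = {
            mex_id: pq.compute_psi(c, min_cov=int(th["min_cov"]))
            for mex_id, c in counts.items()
        }

    merged: list[pq.PsiRecord] = []
    unit_tissue: dict[str, str] = {}
    for (tissue, condition), grp in design.groupby(["tissue", "condition"]):
        unit = f"{tissue}.{condition}"
        unit_tissue[unit] = tissue
        sample_ids = [s for s in grp["sample_id"] if s in per_sample]
        if not sample_ids:
            continue
        for mex_id in sorted(per_sample[sample_ids[0]]):
            recs = [per_sample[s][mex_id] for s in sample_ids]
            rec = recs[0]
            for other in recs[1:]:
                rec = pq.merge_replicates(
                    rec, other, max_delta=float(th["merge_delta"]), unit_id=unit
                )
            if len(recs) == 1:
                rec = pq.PsiRecord(rec.mex_id, unit, rec.psi, rec.n_inc, rec.n_skip)
            merged.append(rec)

    mat = pq.psi_matrix(merged)
    psi_path = run_dir / "psi_matrix.tsv"
    pq.write_psi_matrix(mat, psi_path)
    cls_path = run_dir / "splice_classes.tsv"
    pq.write_splice_classes(merged, cls_path)
    expressed, overlap, specific = pq.tissue_expression_sets(
        mat, unit_tissue, min_psi=float(th["as_floor"])
    )
    tissue_path = run_dir / "tissue_sets.tsv"
    overlap.to_csv(tissue_path, sep="\t", index=False)
    spec_path = run_dir / "tissue_specific.tsv"
    rows = [
        {"tissue": t, "mex_id": m} for t in sorted(specific) for m in sorted(specific[t])
    ]
    pd.DataFrame(rows, columns=["tissue", "mex_id"]).to_csv(
        spec_path, sep="\t", index=False
    )
    state["merged_psi"] = merged
    state["psi_matrix"] = mat
    n_classes = pd.Series([r.splice_class for r in merged]).value_counts().to_dict()
    return (
        [lib_fa, psi_path, cls_path, tissue_path, spec_path],
        {"library_refs": len(refs), "merged_records": len(merged), **n_classes},
    )


def _stage_phylostrata(cfg, th, run_dir, state):
    if cfg.hits_dir is None or cfg.query_lengths is None:
        return None
    qlens = {
        str(r[0]): int(r[1])
        for r in pd.read_csv(
            cfg.query_lengths, sep="\t", header=None
        ).itertuples(index=False)
    }
    hits = ph.read_hits_dir(cfg.hits_dir, qlens)
    filtered = ph.filter_hits(
        hits,
        max_e=float(th["max_evalue"]),
        min_ident=float(th["min_identity"]),
        min_cov=float(th["min_coverage"]),
    )
    mex_genes = sorted({m.gene_id for m in state["mexs"]})
    assignments = ph.assign_all(mex_genes, filtered)
    out = run_dir / "phylostrata.tsv"
    ph.write_assignments(assignments, out)

    cds_lengths = {}
    for g in state["genes"]:
        try:
            tr = cons.cds_transcript(g)
        except ValueError:
            continue
        cds_lengths[g.gene_id] = sum(e - s for s, e, _ in tr.cds_intervals)
    mex_lengths: dict[str, list[int]] = {}
    for m in state["mexs"]:
        mex_lengths.setdefault(m.gene_id, []).append(m.length_nt)
    summary = ph.age_summaries(assignments, cds_lengths, mex_lengths)
    sum_path = run_dir / "age_summary.tsv"
    summary.to_csv(sum_path, sep="\t", index=False)
    state["assignments"] = assignments
    n_class = pd.Series([a.age_class for a in assignments.values()]).value_counts()
    return [out, sum_path], {"genes_assigned": len(assignments), **n_class.to_dict()}


def _stage_conserve(cfg, th, run_dir, state):
    if cfg.pairs is None or cfg.gff_b is None or cfg.fasta_b is None:
        return None
    pairs = cons.read_collinear_pairs(cfg.pairs)
    genes_b = {g.gene_id: g for g in ga.load_annotation(cfg.gff_b, cfg.fasta_b)}
    genome_b = Fasta(str(cfg.fasta_b))
    genes_a = {g.gene_id: g for g in state["genes"]}
    genome_a = state["genome"]
    domains_a = (
        cons.read_domain_table(cfg.domains_a) if cfg.domains_a else None
    )
    domains_b = (
        cons.read_domain_table(cfg.domains_b) if cfg.domains_b else None
    )
    mexs_by_gene: dict[str, list] = {}
    for m in state["mexs"]:
        if m.coding_status == "cds" and m.positional_class == "internal":
            mexs_by_gene.setdefault(m.gene_id, []).append(m)

    records = []
    for pair in pairs:
        gene_a, gene_b = genes_a.get(pair.gene_a), genes_b.get(pair.gene_b)
        if gene_a is None or gene_b is None:
            logger.warning("pair %s-%s: unresolvable gene id", pair.gene_a, pair.gene_b)
            continue
        for mex in mexs_by_gene.get(pair.gene_a, []):
            mapped = cons.map_microexon_to_partner(
                mex, pair, gene_a, genome_a, gene_b, genome_b
            )
            rec = cons.judge_conservation(mapped)
            if domains_a is not None and domains_b is not None:
                chrom_a = str(genome_a[gene_a.chrom][:]).upper()
                chrom_b = str(genome_b[gene_b.chrom][:]).upper()
                tr_a = cons._carrier_transcript(gene_a, mex)
                tr_b = cons.cds_transcript(gene_b)
                rec = cons.domain_consistency(
                    rec, tr_a.transcript_id, tr_b.transcript_id, domains_a, domains_b
                )
            records.append(rec)

    rec_path = run_dir / "conservation.tsv"
    cons.write_records_tsv(records, rec_path)
    summary = cons.conservation_summary({"partner": records}, {"partner": len(pairs)})
    sum_path = run_dir / "conservation_summary.tsv"
    summary.to_csv(sum_path, sep="\t", index=False)
    state["conservation"] = records
    verdicts = pd.Series([r.verdict for r in records]).value_counts().to_dict()
    return [rec_path, sum_path], {"records": len(records), **verdicts}


def _stage_report(cfg, th, run_dir, state):
    path = run_dir / "report.txt"
    outputs = [path]
    lines = []
    genes, mexs = state.get("genes"), state.get("mexs")
    if genes is not None:
        n_exons = sum(
            len({iv for tr in g.transcripts for iv in tr.exons}) for g in genes
        )
        mex_genes = {m.gene_id for m in mexs}
        lines.append(f"genes\t{len(genes)}")
        lines.append(f"exons\t{n_exons}")
        lines.append(f"microexons\t{len(mexs)}")
        frac = 100.0 * len(mexs) / n_exons if n_exons else float("nan")
        lines.append(f"microexon_fraction_of_exons_pct\t{frac:.1f}")
        gfrac = 100.0 * len(mex_genes) / len(genes) if genes else float("nan")
        lines.append(f"genes_with_microexon_pct\t{gfrac:.1f}")
        inf = ga.in_frame_fraction(mexs)
        lines.append(f"in_frame_pct\t{100.0 * inf:.1f}")
    else:
        lines.append("extraction\tunavailable")
    if "candidates" in state:
        cands = state["candidates"]
        for status in ("annotated", "novel_in_gene", "novel_intergenic"):
            n = sum(1 for c in cands if c.annotation_status == status)
            lines.append(f"candidates_{status}\t{n}")
    else:
        lines.append("detection\tunavailable")
    if "merged_psi" in state:
        merged = [r for r in state["merged_psi"] if r.psi is not None]
        n_cs = sum(1 for r in merged if r.splice_class == "CS")
        n_as = sum(1 for r in merged if r.splice_class == "AS")
        if merged:
            lines.append(f"cs_pct\t{100.0 * n_cs / len(merged):.1f}")
            lines.append(f"as_pct\t{100.0 * n_as / len(merged):.1f}")
    else:
        lines.append("psi\tunavailable")
    if "assignments" in state:
        assigns = state["assignments"]
        for cls in ("old", "intermediate", "young"):
            n = sum(1 for a in assigns.values() if a.age_class == cls)
            pct = 100.0 * n / len(assigns) if assigns else float("nan")
            lines.append(f"age_{cls}_pct\t{pct:.1f}")
    else:
        lines.append("phylostrata\tunavailable")
    if "conservation" not in state:
        lines.append("conservation\tunavailable")
    path.write_text("\n".join(lines) + "\n")
    return outputs, {"lines": len(lines)}
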