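import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microexon import genome_annotation as ga
from microexon import psi_quant as pq
from microexon import synthetic_data as sim


def oracle_psi(rl, rr, rs, min_cov=10):
    """Independent brute-force restatement of the PSI rules."""
    if not (rl + rr >= min_cov or rs >= min_cov):
        return None
    rtot = 2 * min(rl, rr)
    if rtot + rs == 0:
        return None
    return Fraction(rtot, rtot + rs)


class TestComputePsi:
    def test_worked_example(self):
        rec = pq.compute_psi(pq.JunctionCounts("m", "s", 30, 20, 10))
        assert rec.psi == pytest.approx(0.8)

    def test_full_inclusion(self):
        rec = pq.compute_psi(pq.JunctionCounts("m", "s", 10, 10, 0))
        assert rec.psi == 1.0

    def test_below_coverage_missing(self):
        rec = pq.compute_psi(pq.JunctionCounts("m", "s", 4, 3, 2))
        assert rec.psi is None

    def test_rtot_arithmetic(self):
        assert pq.JunctionCounts("m", "s", 30, 20, 0).r_tot == 40

    def test_high_skip_retained_by_disjunction(self):
        rec = pq.compute_psi(pq.JunctionCounts("m", "s", 1, 1, 40))
        assert rec.psi == pytest.approx(2 / 42)

    def test_zero_denominator_missing(self):
        rec = pq.compute_psi(pq.JunctionCounts("m", "s", 20, 0, 0))
        assert rec.psi is None

    def test_exhaustive_grid_against_oracle(self):
        for rl, rr, rs in itertools.product(range(0, 51), repeat=3):
            got = pq.compute_psi(pq.JunctionCounts("m", "s", rl, rr, rs)).psi
            exp = oracle_psi(rl, rr, rs)
            if exp is None:
                assert got is None, (rl, rr, rs)
            else:
                assert got == pytest.approx(float(exp)), (rl, rr, rs)

    @given(
        rl=st.integers(0, 500), rr=st.integers(0, 500), rs=st.integers(0, 500)
    )
    def test_psi_in_unit_interval(self, rl, rr, rs):
        psi = pq.compute_psi(pq.JunctionCounts("m", "s", rl, rr, rs)).psi
        if psi is not None:
            assert 0.0 <= psi <= 1.0
            assert (psi == 1.0) == (rs == 0)

    @given(
        lo=st.integers(5, 200), hi=st.integers(0, 200), rs=st.integers(10, 200)
    )
    def test_monotone_in_min_inclusion(self, lo, hi, rs):
        a = pq.compute_psi(pq.JunctionCounts("m", "s", lo, lo, rs)).psi
        b = pq.compute_psi(pq.JunctionCounts("m", "s", lo + hi, lo + hi, rs)).psi
        assert a is not None and b is not None and b >= a

    def test_two_min_rule_caps_alt_splice_site_inflation(self):
        base = pq.compute_psi(pq.JunctionCounts("m", "s", 20, 20, 20)).psi
        inflated = pq.compute_psi(pq.JunctionCounts("m", "s", 200, 20, 20)).psi
        assert inflated == pytest.approx(base)


class TestMergeReplicates:
    def _rec(self, psi, unit="u1"):
        return pq.PsiRecord("m", unit, psi, 20, 20)

    def test_single_value_used(self):
        merged = pq.merge_replicates(self._rec(0.8), self._rec(None, "u2"))
        assert merged.psi == pytest.approx(0.8)

    def test_close_values_averaged(self):
        merged = pq.merge_replicates(self._rec(0.80), self._rec(0.85, "u2"))
        assert merged.psi == pytest.approx(0.825)

    def test_far_values_missing(self):
        merged = pq.merge_replicates(self._rec(0.50), self._rec(0.70, "u2"))
        assert merged.psi is None

    def test_both_missing(self):
        merged = pq.merge_replicates(self._rec(None), self._rec(None, "u2"))
        assert merged.psi is None

    def test_boundary_delta_exactly_010_missing(self):
        merged = pq.merge_replicates(self._rec(0.50), self._rec(0.60, "u2"))
        assert merged.psi is None

    def test_mex_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            pq.merge_replicates(
                pq.PsiRecord("m1", "u1", 0.5), pq.PsiRecord("m2", "u2", 0.5)
            )

    @given(
        a=st.one_of(st.none(), st.floats(0, 1)),
        b=st.one_of(st.none(), st.floats(0, 1)),
    )
    def test_symmetric(self, a, b):
        x = pq.merge_replicates(self._rec(a), self._rec(b, "u2"), unit_id="u")
        y = pq.merge_replicates(self._rec(b), self._rec(a, "u2"), unit_id="u")
        assert (x.psi is None) == (y.psi is None)
        if x.psi is not None:
            assert x.psi == pytest.approx(y.psi)

    def test_exhaustive_grid(self):
        grid = [None] + [round(0.05 * i, 2) for i in range(21)]
        for a, b in itertools.product(grid, repeat=2):
            merged = pq.merge_replicates(self._rec(a), self._rec(b, "u2"))
            if a is None and b is None:
                assert merged.psi is None
            elif a is None:
                assert merged.psi == pytest.approx(b)
            elif b is None:
                assert merged.psi == pytest.approx(a)
            elif abs(a - b) < 0.10 - 1e-12:
                assert merged.psi == pytest.approx((a + b) / 2)
            elif abs(a - b) > 0.10 + 1e-12:
                assert merged.psi is None


class TestClassify:
    @pytest.mark.parametrize(
        "psi,expected",
        [
            (0.95, "CS"),
            (0.90, "CS"),
            (0.50, "AS"),
            (0.10, "AS"),
            (0.05, "low"),
            (None, "missing"),
        ],
    )
    def test_thresholds(self, psi, expected):
        assert pq.PsiRecord("m", "u", psi).splice_class == expected


class TestJunctionLibrary:
    def _gene(self, exons, strand="+", gene_id="g1"):
        phases = []
        off = 0
        order = exons if strand == "+" else exons[::-1]
        ph_map = {}
        for s, e in order:
            ph_map[(s, e)] = (3 - off % 3) % 3
            off += e - s
        tr = ga.TranscriptModel(
            "t1", tuple(exons), tuple((s, e, ph_map[(s, e)]) for s, e in exons)
        )
        return ga.GeneModel(gene_id, "c", strand, (tr,), (exons[0][0], exons[-1][1]))

    def _genome(self, n=2000):
        rng = np.random.default_rng(0)
        return {"c": "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))}

    def test_flank_lengths(self):
        gene = self._gene([(0, 200), (400, 412), (600, 800)])
        genome = self._genome()
        mexs = ga.extract_annotated_microexons([gene], genome)
        (ref,) = pq.build_junction_library(mexs, [gene], genome)
        assert len(ref.inclusion_seq) == 212
        assert len(ref.exclusion_seq) == 200
        assert (ref.left_junction, ref.right_junction, ref.skip_junction) == (100, 112, 100)

    def test_truncated_flank_near_transcript_end(self):
        gene = self._gene([(0, 40), (400, 412), (600, 800)])
        genome = self._genome()
        mexs = ga.extract_annotated_microexons([gene], genome)
        (ref,) = pq.build_junction_library(mexs, [gene], genome)
        assert ref.left_junction == 40
        assert len(ref.inclusion_seq) == 40 + 12 + 100

    def test_first_exon_microexon_excluded(self):
        gene = self._gene([(0, 12), (400, 500), (600, 800)])
        genome = self._genome()
        mexs = ga.extract_annotated_microexons([gene], genome)
        assert pq.build_junction_library(mexs, [gene], genome) == []

    def test_nearby_microexons_share_merged_group(self):
        # two micro-exons 60 nt apart in spliced coordinates
        gene = self._gene([(0, 200), (300, 312), (400, 460), (500, 512), (600, 800)])
        genome = self._genome()
        mexs = ga.extract_annotated_microexons([gene], genome)
        refs = pq.build_junction_library(mexs, [gene], genome)
        groups = {r.mex_id: r.merged_group for r in refs}
        assert len(refs) == 2
        assert len(set(groups.values())) == 1
        assert all(g is not None for g in groups.values())

    def test_inclusion_sequence_content(self):
        gene = self._gene([(0, 200), (400, 412), (600, 800)])
        genome = self._genome()
        mexs = ga.extract_annotated_microexons([gene], genome)
        (ref,) = pq.build_junction_library(mexs, [gene], genome)
        seq = genome["c"]
        assert ref.inclusion_seq == seq[100:200] + seq[400:412] + seq[600:700]
        assert ref.exclusion_seq == seq[100:200] + seq[600:700]

    def test_minus_strand_mature_orientation(self):
        gene = self._gene([(0, 200), (400, 412), (600, 800)], strand="-")
        genome = self._genome()
        mexs = ga.extract_annotated_microexons([gene], genome)
        (ref,) = pq.build_junction_library(mexs, [gene], genome)
        seq = genome["c"]
        mature = ga.reverse_complement(seq[0:200] + seq[400:412] + seq[600:800])
        ms = 200  # micro-exon sits 200 nt into the mature transcript
        assert ref.inclusion_seq == mature[ms - 100 : ms + 12 + 100]

    def test_fasta_round_trip(self, tmp_path):
        gene = self._gene([(0, 200), (400, 412), (600, 800)])
        genome = self._genome()
        mexs = ga.extract_annotated_microexons([gene], genome)
        refs = pq.build_junction_library(mexs, [gene], genome)
        path = tmp_path / "lib.fa"
        pq.write_library_fasta(refs, path)
        assert pq.read_library_fasta(path) == refs


class TestCountJunctionReads:
    def _ref(self):
        return pq.JunctionReference(
            mex_id="m1",
            inclusion_seq="A" * 212,
            exclusion_seq="A" * 200,
            left_junction=100,
            right_junction=112,
            skip_junction=100,
        )

    def _sam(self, tmp_path, rows):
        ref = self._ref()
        lines = [
            "@HD\tVN:1.6",
            f"@SQ\tSN:m1|incl\tLN:{len(ref.inclusion_seq)}",
            f"@SQ\tSN:m1|excl\tLN:{len(ref.exclusion_seq)}",
        ]
        for name, rname, pos0, ln in rows:
            lines.append(
                f"{name}\t0\t{rname}\t{pos0 + 1}\t60\t{ln}M\t*\t0\t0\t{'A' * ln}\t*\tNM:i:0"
            )
        path = tmp_path / "x.sam"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_overhang_five_counts_left(self, tmp_path):
        sam = self._sam(tmp_path, [("r1", "m1|incl", 60, 45)])  # ends 5 past L junction
        counts = pq.count_junction_reads(sam, [self._ref()])
        assert counts["m1"].r_left == 1
        assert counts["m1"].r_right == 0

    def test_two_nt_past_skip_junction_not_counted(self, tmp_path):
        sam = self._sam(tmp_path, [("r1", "m1|excl", 52, 50)])  # ends at 102: 2 past skip
        counts = pq.count_junction_reads(sam, [self._ref()])
        assert counts["m1"].r_skipped == 0

    def test_three_nt_past_skip_junction_counted(self, tmp_path):
        sam = self._sam(tmp_path, [("r1", "m1|excl", 53, 50)])
        counts = pq.count_junction_reads(sam, [self._ref()])
        assert counts["m1"].r_skipped == 1

    def test_short_microexon_read_supports_both_junctions(self, tmp_path):
        sam = self._sam(tmp_path, [("r1", "m1|incl", 50, 101)])  # covers 50..151
        counts = pq.count_junction_reads(sam, [self._ref()])
        assert counts["m1"].r_left == 1
        assert counts["m1"].r_right == 1
        assert counts["m1"].r_tot == 2

    def test_unknown_reference_skipped(self, tmp_path):
        ref = self._ref()
        lines = [
            "@HD\tVN:1.6",
            "@SQ\tSN:ghost\tLN:500",
            f"r1\t0\tghost\t1\t60\t50M\t*\t0\t0\t{'A' * 50}\t*\tNM:i:0",
        ]
        path = tmp_path / "x.sam"
        path.write_text("\n".join(lines) + "\n")
        counts = pq.count_junction_reads(path, [ref])
        assert counts["m1"].r_left == 0


class TestParameterRecovery:
    def test_psi_recovery_simulated(self, tmp_path):
        cfg = sim.SimConfig(
            seed=21,
            n_genes=60,
            depth=200,
            n_tissues=1,
            n_replicates=1,
            psi_levels=(0.1, 0.3, 0.5, 0.7, 0.9),
        )
        truth = sim.simulate_genome_annotation(cfg)
        reads = sim.simulate_junction_reads(truth, tmp_path, emit_genome=False)
        (sid, path), = reads.library_sams.items()
        counts = pq.count_junction_reads(path, reads.refs, sample_id=sid)
        errors = []
        for mex_id, c in counts.items():
            rec = pq.compute_psi(c)
            true = truth.mex(mex_id).true_psi[cfg.tissues[0]]
            assert rec.psi is not None
            errors.append(rec.psi - true)
        assert np.mean(np.abs(errors)) <= 0.05
        assert abs(np.mean(errors)) <= 0.02


class TestTissueSets:
    def _matrix(self):
        units = ["leaf.a", "leaf.b", "root.a", "root.b", "shoot.a", "shoot.b"]
        data = {
            "m_leaf": [0.4, 0.5, 0.0, 0.0, 0.05, np.nan],
            "m_all": [0.3, 0.3, 0.4, 0.2, 0.6, 0.5],
            "m_single_sample": [0.4, np.nan, 0.0, 0.0, 0.0, 0.0],
        }
        mat = pd.DataFrame.from_dict(data, orient="index", columns=units)
        tissue_of = {u: u.split(".")[0] for u in units}
        return mat, tissue_of

    def test_tissue_specific(self):
        mat, tissue_of = self._matrix()
        expressed, overlap, specific = pq.tissue_expression_sets(mat, tissue_of)
        assert specific["leaf"] == {"m_leaf"}
        assert "m_all" in expressed["root"]

    def test_full_intersection(self):
        mat, tissue_of = self._matrix()
        _, overlap, _ = pq.tissue_expression_sets(mat, tissue_of)
        row = overlap[overlap.tissues == "leaf+root+shoot"]
        assert row["count"].iloc[0] == 1  # m_all

    def test_one_sample_insufficient(self):
        mat, tissue_of = self._matrix()
        expressed, _, _ = pq.tissue_expression_sets(mat, tissue_of)
        assert "m_single_sample" not in expressed["leaf"]

    def test_unknown_unit_raises(self):
        mat, tissue_of = self._matrix()
        del tissue_of["leaf.a"]
        with pytest.raises(ValueError, match="unknown tissue"):
            pq.tissue_expression_sets(mat, tissue_of)
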