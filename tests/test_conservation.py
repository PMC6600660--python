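import numpy as np
import pandas as pd
import pytest

from microexon import conservation as cons
from microexon import synthetic_data as sim


@pytest.fixture(scope="module")
def truth():
    cfg = sim.SimConfig(seed=31, n_genes=12)
    return sim.simulate_genome_annotation(cfg)


def judge_pair(truth, fix, gene_a_id, gene_b_id):
    models_a = {g.gene_id: g for g in sim.annotation_models(truth)}
    models_b = {g.gene_id: g for g in sim.partner_models(fix)}
    mt = truth.mex(truth.gene(gene_a_id).mex_ids[0])
    mex = sim._mex_object(truth, mt)
    pair = cons.CollinearPair(gene_a_id, gene_b_id)
    mapped = cons.map_microexon_to_partner(
        mex, pair, models_a[gene_a_id], truth.genome, models_b[gene_b_id], fix.genome
    )
    return mt, cons.judge_conservation(mapped)


class TestSelfPair:
    def test_self_pair_all_identical(self, truth):
        fix = sim.simulate_collinear_partner(truth)
        for gene_a, gene_b in fix.pairs:
            _, rec = judge_pair(truth, fix, gene_a, gene_b)
            assert rec.verdict == "conserved_identical"
            assert rec.n_substitutions == 0
            assert rec.phase_a == rec.phase_b
            assert rec.len_a == rec.len_b


class TestSubstitutions:
    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_planted_substitution_count(self, truth, k):
        target = truth.mexs[0].mex_id
        fix = sim.simulate_collinear_partner(
            truth, {target: sim.PartnerEdit(substitutions=k)}
        )
        gene_a, gene_b = fix.pairs[0]
        _, rec = judge_pair(truth, fix, gene_a, gene_b)
        assert rec.verdict == "conserved_substituted"
        assert rec.n_substitutions == k

    def test_excess_substitutions_rejected(self, truth):
        target = truth.mexs[0]
        with pytest.raises(ValueError, match="exceed"):
            sim.simulate_collinear_partner(
                truth, {target.mex_id: sim.PartnerEdit(substitutions=target.length + 1)}
            )

    def test_monotone_degradation(self, truth):
        # n_substitutions tracks k exactly until a merge flips the verdict
        target = truth.mexs[1].mex_id
        for k in (1, 3, 4):
            fix = sim.simulate_collinear_partner(
                truth, {target: sim.PartnerEdit(substitutions=k)}
            )
            gene_a, gene_b = fix.pairs[1]
            _, rec = judge_pair(truth, fix, gene_a, gene_b)
            assert rec.n_substitutions == k
        fix = sim.simulate_collinear_partner(truth, {target: sim.PartnerEdit(merge=True)})
        gene_a, gene_b = fix.pairs[1]
        _, rec = judge_pair(truth, fix, gene_a, gene_b)
        assert rec.verdict == "not_conserved"


class TestExonMerge:
    def test_merged_partner_exon(self, truth):
        target = truth.mexs[2]
        fix = sim.simulate_collinear_partner(
            truth, {target.mex_id: sim.PartnerEdit(merge=True)}
        )
        gene_a, gene_b = fix.pairs[2]
        mt, rec = judge_pair(truth, fix, gene_a, gene_b)
        assert rec.verdict == "not_conserved"
        assert rec.exon_merged
        assert rec.len_b > rec.len_a
        assert rec.len_a == mt.length


class TestJudgeRules:
    def _mapped(self, **kw):
        defaults = dict(
            mex_id="m",
            pair=cons.CollinearPair("a", "b"),
            status="ok",
            phase_a=0,
            phase_b=0,
            len_a=45,
            len_b=45,
            seq_a="A" * 45,
            seq_b="A" * 45,
        )
        defaults.update(kw)
        return cons.MappedMicroExon(**defaults)

    def test_identical(self):
        rec = cons.judge_conservation(self._mapped())
        assert rec.verdict == "conserved_identical"

    def test_two_mismatches(self):
        rec = cons.judge_conservation(self._mapped(seq_b="C" * 2 + "A" * 43))
        assert rec.verdict == "conserved_substituted"
        assert rec.n_substitutions == 2

    def test_phase_mismatch_not_conserved(self):
        rec = cons.judge_conservation(self._mapped(phase_b=2))
        assert rec.verdict == "not_conserved"

    def test_length_mismatch_not_conserved(self):
        rec = cons.judge_conservation(
            self._mapped(len_b=120, seq_b="A" * 120, exon_merged=True)
        )
        assert rec.verdict == "not_conserved"
        assert rec.exon_merged

    def test_unalignable_propagates(self):
        mapped = cons.MappedMicroExon("m", cons.CollinearPair("a", "b"), "unalignable")
        assert cons.judge_conservation(mapped).verdict == "unalignable"

    def test_gap_in_alignment_is_unalignable(self, truth):
        models = {g.gene_id: g for g in sim.annotation_models(truth)}
        fix = sim.simulate_collinear_partner(truth)
        models_b = {g.gene_id: g for g in sim.partner_models(fix)}
        gene_a, gene_b = fix.pairs[0]
        mt = truth.mex(truth.gene(gene_a).mex_ids[0])
        mex = sim._mex_object(truth, mt)
        tr = cons.cds_transcript(models[gene_a])
        prot = cons.protein_sequence(tr, truth.genome[mt.chrom], mt.strand)
        aa_start, _, _ = cons.cds_offset_of_interval(tr, mex.interval, mt.strand)
        s, e = aa_start // 3, -(-(aa_start + mt.length) // 3)
        # partner alignment with the micro-exon span deleted (gaps in B)
        aligned_a = prot
        aligned_b = prot[:s] + "-" * (e - s) + prot[e:]
        mapped = cons.map_microexon_to_partner(
            mex,
            cons.CollinearPair(gene_a, gene_b),
            models[gene_a],
            truth.genome,
            models_b[gene_b],
            fix.genome,
            alignment=(aligned_a, aligned_b),
        )
        assert mapped.status == "unalignable"


class TestDomainConsistency:
    def _record(self, merged=False):
        return cons.ConservationRecord(
            "m",
            cons.CollinearPair("a", "b"),
            "not_conserved" if merged else "conserved_identical",
            len_a=45,
            len_b=120 if merged else 45,
            exon_merged=merged,
            aa_span_a=(10, 25),
            aa_span_b=(10, 25),
        )

    def _domains(self, protein, acc, start, end):
        return pd.DataFrame(
            {"protein_id": [protein], "accession": [acc], "start": [start], "end": [end]}
        )

    def test_same_domain_both_sides(self):
        rec = cons.domain_consistency(
            self._record(),
            "pA",
            "pB",
            self._domains("pA", "PF00847", 5, 40),
            self._domains("pB", "PF00847", 5, 40),
        )
        assert rec.domain_consistent is True
        assert rec.domain_category == "same-structure-same-domain"

    def test_domain_only_on_one_side(self):
        rec = cons.domain_consistency(
            self._record(),
            "pA",
            "pB",
            self._domains("pA", "PF00847", 5, 40),
            self._domains("pB", "PF99999", 200, 250),
        )
        assert rec.domain_consistent is False
        assert rec.domain_category == "different-structure-one-domain"

    def test_merged_exon_similar_domain(self):
        rec = cons.domain_consistency(
            self._record(merged=True),
            "pA",
            "pB",
            self._domains("pA", "PF00847", 5, 40),
            self._domains("pB", "PF00847", 5, 40),
        )
        assert rec.domain_category == "merged-exon-similar-domain"

    def test_merged_exon_different_domain(self):
        rec = cons.domain_consistency(
            self._record(merged=True),
            "pA",
            "pB",
            self._domains("pA", "PF00847", 5, 40),
            self._domains("pB", "PF11111", 5, 40),
        )
        assert rec.domain_category == "merged-exon-different-domain"

    def test_missing_table_unknown(self):
        rec = cons.domain_consistency(self._record(), "pA", "pB", None, None)
        assert rec.domain_consistent is None
        assert rec.domain_category == "unknown"


class TestSummary:
    def _records(self):
        out = []
        for i in range(10):
            pair = cons.CollinearPair(f"a{i}", f"b{i}")
            if i < 3:  # three conserving pairs, two micro-exons each
                for j in range(2):
                    out.append(
                        cons.ConservationRecord(
                            f"m{i}_{j}", pair, "conserved_identical", len_a=9, len_b=9
                        )
                    )
            elif i < 4:
                out.append(
                    cons.ConservationRecord(
                        f"m{i}", pair, "not_conserved", len_a=9, len_b=30
                    )
                )
        return out

    def test_counts(self):
        table = cons.conservation_summary(
            {"sp": self._records()}, {"sp": 10}
        ).set_index("species")
        row = table.loc["sp"]
        assert row["total_gene_pairs"] == 10
        assert row["pairs_with_mex"] == 4
        assert row["pairs_with_conserved_mex"] == 3
        assert row["conserved_mex_count"] == 6

    def test_conserved_mex_count_at_least_pairs(self):
        table = cons.conservation_summary({"sp": self._records()})
        assert (
            table["conserved_mex_count"] >= table["pairs_with_conserved_mex"]
        ).all()

    def test_empty_records(self):
        table = cons.conservation_summary({"sp": []}, {"sp": 0}).set_index("species")
        assert table.loc["sp", "pairs_with_mex"] == 0


class TestParsers:
    def test_mcscanx_collinearity(self, tmp_path):
        text = (
            "############### Parameters ###############\n"
            "# MATCH_SCORE: 50\n"
            "## Alignment 0: score=500.0 e_value=0 N=2 chr1&chr2 plus\n"
            "  0-  0:\tGENE001\tPARTNER001\t  0\n"
            "  0-  1:\tGENE002\tPARTNER002\t1e-50\n"
        )
        path = tmp_path / "pairs.collinearity"
        path.write_text(text)
        pairs = cons.read_collinear_pairs(path)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [
            ("GENE001", "PARTNER001"),
            ("GENE002", "PARTNER002"),
        ]
        assert pairs[0].block_id == "0"

    def test_two_column_tsv(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("GA1\tGB1\nGA2\tGB2\n")
        pairs = cons.read_collinear_pairs(path)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("GA1", "GB1"), ("GA2", "GB2")]

    def test_interproscan_tsv(self, tmp_path):
        row = (
            "prot1\tmd5\t500\tPfam\tPF00847\tAP2 domain\t120\t180\t"
            "1e-20\tT\t01-01-2020"
        )
        path = tmp_path / "domains.tsv"
        path.write_text(row + "\n")
        df = cons.read_domain_table(path)
        assert df.iloc[0]["protein_id"] == "prot1"
        assert df.iloc[0]["accession"] == "PF00847"
        assert (df.iloc[0]["start"], df.iloc[0]["end"]) == (120, 180)

    def test_records_tsv(self, tmp_path, truth):
        fix = sim.simulate_collinear_partner(truth)
        gene_a, gene_b = fix.pairs[0]
        _, rec = judge_pair(truth, fix, gene_a, gene_b)
        path = tmp_path / "records.tsv"
        cons.write_records_tsv([rec], path)
        df = pd.read_csv(path, sep="\t")
        assert df.iloc[0]["verdict"] == "conserved_identical"


class TestAligner:
    def test_identity_alignment(self):
        a, b = cons.align_proteins("MKLSRV", "MKLSRV")
        assert a == b == "MKLSRV"

    def test_gap_placement(self):
        a, b = cons.align_proteins("MKLSRVWY", "MKLWY")
        assert a.replace("-", "") == "MKLSRVWY"
        assert b.replace("-", "") == "MKLWY"
        assert len(a) == len(b)
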