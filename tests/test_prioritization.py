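import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvarnet.errors import InputError
from famvarnet.family_filter import carrier_matrix
from famvarnet.prioritization import (
    DEFAULT_TOOLS,
    Category,
    PredictionMatrix,
    Status,
    ToolCutoff,
    categorize_scores,
    damaging_vote_count,
    export_heatmap_matrix,
    prioritize,
    rank_by_revel,
)
from famvarnet.variant_io import (
    Consequence,
    Genotype,
    Member,
    Pedigree,
    VariantRecord,
)


def mkvar(gene, pos, conseq=Consequence.MISSENSE, clinvar=None):
    kwargs = {}
    if clinvar:
        from famvarnet.variant_io import ClinVarCategory

        kwargs["clinvar"] = frozenset(ClinVarCategory(c) for c in clinvar)
    return VariantRecord(
        chrom="1", pos=pos, ref="A", alt="T", gene=gene, rsid=f"rs{pos}",
        consequence=conseq, **kwargs,
    )


class TestCategorize:
    def test_revel_090_damaging(self):
        m = PredictionMatrix(cutoffs={"REVEL": ToolCutoff(damaging_min=0.5)})
        m.set_score("v1", "REVEL", 0.90)
        assert categorize_scores(m)[("v1", "REVEL")] == Category.DAMAGING

    def test_boundary_score_is_damaging(self):
        m = PredictionMatrix()
        m.set_score("v1", "SIFT", 0.5)
        assert categorize_scores(m)[("v1", "SIFT")] == Category.DAMAGING

    def test_neutral_boundary_is_neutral(self):
        m = PredictionMatrix()
        m.set_score("v1", "SIFT", 0.25)
        assert categorize_scores(m)[("v1", "SIFT")] == Category.NEUTRAL

    def test_out_of_range_score_fatal_names_tool_and_variant(self):
        m = PredictionMatrix()
        m.set_score("v1", "SIFT", 1.2)
        with pytest.raises(InputError, match="SIFT.*v1"):
            categorize_scores(m)

    def test_random_matrix_matches_per_cell_oracle(self):
        rng = np.random.default_rng(42)
        m = PredictionMatrix()
        for i in range(10):
            for tool in DEFAULT_TOOLS:
                m.set_score(f"v{i}", tool, float(rng.uniform()))
        cats = categorize_scores(m)
        for (key, tool), score in m.scores.items():
            cut = m.cutoffs[tool]
            if score >= cut.damaging_min:
                expected = Category.DAMAGING
            elif score <= cut.neutral_max:
                expected = Category.NEUTRAL
            else:
                expected = Category.MODERATE
            assert cats[(key, tool)] == expected


class TestVotes:
    def test_all_fifteen_damaging(self):
        m = PredictionMatrix()
        for tool in DEFAULT_TOOLS:
            m.set_score("v1", tool, 0.9)
        assert damaging_vote_count(categorize_scores(m), "v1") == 15

    def test_fixture_ugt1a3_two_votes(self, bundle):
        cats = categorize_scores(bundle.prediction_matrix)
        assert damaging_vote_count(cats, "rs146461519") == 2

    def test_fixture_excluded_variants_two_votes(self, bundle):
        cats = categorize_scores(bundle.prediction_matrix)
        for key in ("rs146461519", "rs2230723", "rs138605229", "PSG8:Cys9Ser"):
            assert damaging_vote_count(cats, key) == 2

    def test_empty_row_zero(self):
        assert damaging_vote_count({}, "nothing") == 0


class TestRankByRevel:
    def test_fixture_klk13_nqo1_last_quartile(self, ranked_decisions):
        by_gene = {d.record.gene: d for d in ranked_decisions}
        assert by_gene["KLK13"].quartile == 4
        assert by_gene["NQO1"].quartile == 4

    def test_quartiles_balanced_for_16(self, ranked_decisions):
        sizes = [sum(1 for d in ranked_decisions if d.quartile == q) for q in (1, 2, 3, 4)]
        assert sizes == [4, 4, 4, 4]

    def test_quartiles_match_bruteforce_assignment(self, ranked_decisions):
        ranked = [d for d in ranked_decisions if d.rank is not None]
        n = len(ranked)
        for d in ranked:
            assert d.quartile == (d.rank - 1) * 4 // n + 1

    def test_rank_bijection(self, ranked_decisions):
        ranks = [d.rank for d in ranked_decisions if d.rank is not None]
        assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_tie_broken_by_votes(self):
        m = PredictionMatrix()
        for key, votes in (("rsA", 5), ("rsB", 2)):
            m.set_score(key, "REVEL", 0.7)
            for tool in DEFAULT_TOOLS[:votes]:
                if tool != "REVEL":
                    m.set_score(key, tool, 0.9)
        recs = [mkvar("GB", 2), mkvar("GA", 1)]
        recs[0].rsid, recs[1].rsid = "rsB", "rsA"
        decisions = rank_by_revel(m, recs)
        assert decisions[0].key == "rsA" and decisions[0].rank == 1

    def test_missing_revel_placed_last_unranked(self):
        m = PredictionMatrix()
        m.set_score("rs1", "REVEL", 0.9)
        recs = [mkvar("G1", 1), mkvar("G2", 2)]
        decisions = rank_by_revel(m, recs)
        assert decisions[0].rank == 1
        assert decisions[1].rank is None and decisions[1].quartile is None

    def test_non_missense_fatal(self):
        with pytest.raises(InputError):
            rank_by_revel(PredictionMatrix(), [mkvar("G1", 1, Consequence.SYNONYMOUS)])


class TestPrioritize:
    def test_fixture_twelve_prioritized(self, final_decisions):
        assert sum(1 for d in final_decisions if d.status == Status.PRIORITIZED) == 12

    def test_fixture_not_prioritized_set(self, final_decisions):
        out = {d.record.gene for d in final_decisions
               if d.status == Status.NOT_PRIORITIZED}
        assert out == {"UGT1A3", "JAK2", "SAA2", "PSG8"}

    def test_fixture_prioritized_shared_intersection(self, bundle, missense,
                                                     final_decisions):
        from famvarnet.family_filter import shared_in_affected

        m = carrier_matrix(missense, bundle.pedigree)
        shared = {r.key for r in shared_in_affected(m, bundle.pedigree)}
        inter = {
            d.record.label
            for d in final_decisions
            if d.status == Status.PRIORITIZED and d.key in shared
        }
        assert inter == {"CRP Leu61Pro", "F2 Asn514Lys", "NQO1 Arg139Trp"}

    def test_low_evidence_variant_not_prioritized(self):
        m = PredictionMatrix()
        m.set_score("rs1", "REVEL", 0.4)
        for tool in ("SIFT", "LRT", "PROVEAN"):
            m.set_score("rs1", tool, 0.9)
        decisions = rank_by_revel(m, [mkvar("G1", 1)], {"rs1": 1})
        # votes=3 < 4, one affected carrier, no QTL, NR ClinVar, rank tail
        final = prioritize(decisions, protected_rank_max=0)
        assert final[0].status == Status.NOT_PRIORITIZED
        assert final[0].damaging_votes == 3

    def test_flag_invariants_hold_exhaustively(self, bundle, final_decisions):
        for d in final_decisions:
            reg = bundle.annotations.regulatory(d.key)
            expect_plus = d.affected_carriers >= 2 and d.damaging_votes >= 4
            expect_star = d.damaging_votes >= 4 and (
                reg.has_qtl or d.record.clinvar_annotated
            )
            assert d.flag_plus == expect_plus
            assert d.flag_star == expect_star

    def test_strict_flag_rule_available(self, bundle, ranked_decisions):
        final = prioritize(
            ranked_decisions, regulatory=bundle.annotations, protected_rank_max=None
        )
        pri = {d.record.gene for d in final if d.status == Status.PRIORITIZED}
        assert pri == {"CRP", "F2", "SERPINA1", "THBS1", "VWF", "KLK13",
                       "NQO1", "PEAR1", "PLAT"}

    def test_order_independent_and_idempotent(self, bundle, ranked_decisions):
        final = prioritize(ranked_decisions, regulatory=bundle.annotations)
        shuffled = list(reversed(ranked_decisions))
        final_rev = prioritize(shuffled, regulatory=bundle.annotations)
        status = {d.key: d.status for d in final}
        assert {d.key: d.status for d in final_rev} == status
        again = prioritize(final, regulatory=bundle.annotations)
        assert {d.key: d.status for d in again} == status

    def test_manual_include_status_and_missing_fatal(self, bundle, ranked_decisions):
        final = prioritize(
            ranked_decisions,
            regulatory=bundle.annotations,
            manual_includes=["rs1131341"],
        )
        by_key = {d.key: d for d in final}
        assert by_key["rs1131341"].status == Status.MANUAL_INCLUDE
        with pytest.raises(InputError, match="rs_ghost"):
            prioritize(ranked_decisions, manual_includes=["rs_ghost"])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_planted_strong_variants_always_prioritized(self, seed):
        rng = np.random.default_rng(seed)
        m = PredictionMatrix()
        recs, counts = [], {}
        for i in range(8):
            key = f"rs{i}"
            strong = i < 3
            rec = mkvar(f"G{i}", i + 1)
            recs.append(rec)
            votes = int(rng.integers(10, 16)) if strong else int(rng.integers(0, 3))
            tools = [t for t in DEFAULT_TOOLS if t != "REVEL"][: max(votes - 1, 0)]
            if strong:
                m.set_score(key, "REVEL", float(rng.uniform(0.6, 1.0)))
            else:
                m.set_score(key, "REVEL", float(rng.uniform(0.0, 0.45)))
            for t in tools:
                m.set_score(key, t, float(rng.uniform(0.55, 1.0)))
            counts[key] = 3 if strong else 1
        final = prioritize(rank_by_revel(m, recs, counts), protected_rank_max=None)
        for d in final:
            if d.affected_carriers == 3 and d.damaging_votes >= 10:
                assert d.status == Status.PRIORITIZED


class TestHeatmapExport:
    def test_sixteen_rows_and_all_tool_columns(self, bundle, final_decisions, tmp_path):
        scores, cats = export_heatmap_matrix(
            bundle.prediction_matrix, final_decisions, tmp_path,
            network_eligible=set(bundle.network_eligible),
        )
        lines = scores.read_text().splitlines()
        assert len(lines) == 17  # header + 16 variants
        header = lines[0].split("\t")
        for tool in DEFAULT_TOOLS:
            assert tool in header

    def test_empty_decisions_header_only(self, bundle, tmp_path):
        scores, cats = export_heatmap_matrix(bundle.prediction_matrix, [], tmp_path)
        assert len(scores.read_text().splitlines()) == 1
        assert len(cats.read_text().splitlines()) == 1

    def test_re_export_byte_identical(self, bundle, final_decisions, tmp_path):
        s1, c1 = export_heatmap_matrix(
            bundle.prediction_matrix, final_decisions, tmp_path / "a"
        )
        s2, c2 = export_heatmap_matrix(
            bundle.prediction_matrix, final_decisions, tmp_path / "b"
        )
        assert s1.read_bytes() == s2.read_bytes()
        assert c1.read_bytes() == c2.read_bytes()

    def test_delta_flag_marks_prioritized_network_excluded(self, bundle,
                                                           final_decisions, tmp_path):
        _, cats = export_heatmap_matrix(
            bundle.prediction_matrix, final_decisions, tmp_path,
            network_eligible=set(bundle.network_eligible),
        )
        rows = [l.split("\t") for l in cats.read_text().splitlines()]
        header = rows[0]
        delta_idx, gene_idx = header.index("delta"), header.index("gene")
        flagged = {r[gene_idx] for r in rows[1:] if r[delta_idx] == "D"}
        assert flagged == {"ARID4A", "NCOA1", "NQO1", "PEAR1", "KLK13"}
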