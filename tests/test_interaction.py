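import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvarnet.errors import InputError
from famvarnet.family_filter import carrier_matrix
from famvarnet.interaction import (
    EdgeDB,
    EdgeEvidence,
    Term,
    TermDB,
    Tier,
    build_patient_network,
    build_patient_sets,
    classify_tier,
    combine_channel_scores,
    enrich_terms,
)


def noisy_or_oracle(scores, p):
    """Independent re-implementation of the prior-corrected combination."""
    corrected = [(s - p) / (1 - p) for s in scores]
    keep = 1.0
    for s in corrected:
        keep *= 1 - s
    return (1 - keep) * (1 - p) + p


class TestCombine:
    def test_single_channel_at_prior_collapses_to_prior(self):
        ev = EdgeEvidence.make("A", "B", {"experimental": 0.041}, prior=0.041)
        assert combine_channel_scores(ev) == pytest.approx(0.041)

    def test_single_channel_identity(self):
        ev = EdgeEvidence.make("A", "B", {"experimental": 0.9}, prior=0.041)
        assert combine_channel_scores(ev) == pytest.approx(0.9, abs=1e-12)

    def test_two_channels_match_oracle(self):
        ev = EdgeEvidence.make(
            "A", "B", {"experimental": 0.7, "database": 0.7}, prior=0.041
        )
        assert combine_channel_scores(ev) == pytest.approx(
            noisy_or_oracle([0.7, 0.7], 0.041), abs=1e-12
        )

    def test_no_channels_returns_prior(self):
        ev = EdgeEvidence.make("A", "B", {}, prior=0.1)
        assert combine_channel_scores(ev) == pytest.approx(0.1)

    def test_below_prior_channel_dropped_with_warning(self):
        ev = EdgeEvidence.make(
            "A", "B", {"experimental": 0.01, "database": 0.5}, prior=0.041
        )
        with pytest.warns(UserWarning, match="dropped"):
            combined = combine_channel_scores(ev)
        assert combined == pytest.approx(0.5, abs=1e-12)

    def test_score_out_of_range_fatal(self):
        with pytest.raises(InputError):
            EdgeEvidence.make("A", "B", {"experimental": 1.2})

    @settings(max_examples=100, deadline=None)
    @given(
        scores=st.lists(st.floats(0.05, 0.999), min_size=1, max_size=6),
        prior=st.floats(0.0, 0.049),
    )
    def test_symmetric_bounded_and_monotone(self, scores, prior):
        channels = ["neighborhood", "fusion", "cooccurrence", "experimental",
                    "database", "coexpression"]
        ev = EdgeEvidence.make(
            "A", "B", dict(zip(channels, scores)), prior=prior
        )
        combined = combine_channel_scores(ev)
        # symmetric in channel order
        ev_rev = EdgeEvidence.make(
            "A", "B", dict(zip(reversed(channels[: len(scores)]), scores)),
            prior=prior,
        )
        assert combine_channel_scores(ev_rev) == pytest.approx(combined, abs=1e-12)
        assert prior <= combined < 1.0
        # adding a channel never lowers the combined score
        ev_more = EdgeEvidence.make(
            "A", "B",
            dict(zip(channels, list(scores[:5]) + [0.5])),
            prior=prior,
        )
        if len(scores) >= 5:
            base = EdgeEvidence.make(
                "A", "B", dict(zip(channels, scores[:5])), prior=prior
            )
            assert combine_channel_scores(ev_more) >= combine_channel_scores(base) - 1e-12


class TestTier:
    @pytest.mark.parametrize(
        "score,tier",
        [
            (0.92, Tier.HIGHEST),
            (0.9, Tier.HIGHEST),
            (0.7, Tier.HIGH),
            (0.4, Tier.MEDIUM),
            (0.15, Tier.LOW),
            (0.05, Tier.BELOW_LOW),
            (0.3999, Tier.LOW),
        ],
    )
    def test_bins(self, score, tier):
        assert classify_tier(score) == tier


class TestPatientSets:
    def test_fixture_node_sets(self, bundle, final_decisions, full_matrix):
        sets = build_patient_sets(
            final_decisions, full_matrix, bundle.pedigree,
            set(bundle.network_eligible), bundle.extra_includes,
        )
        assert sets["III2"] == frozenset(
            {"THBS1", "F2", "SERPINA1", "CRP", "FGB", "IL1A"}
        )
        assert sets["II2"] == frozenset({"THBS1", "F2", "SERPINA1", "CRP", "FGB"})
        assert sets["II3"] == frozenset({"F2", "CRP", "VWF", "PLAT", "FGB"})

    def test_patient_without_eligible_variants_empty(self, bundle, final_decisions,
                                                     full_matrix):
        sets = build_patient_sets(
            final_decisions, full_matrix, bundle.pedigree, {"PLAT"}, {}
        )
        assert sets["III2"] == frozenset()  # III2 does not carry PLAT

    def test_eligible_gene_missing_from_decisions_fatal(self, bundle,
                                                        final_decisions, full_matrix):
        with pytest.raises(InputError, match="GHOSTGENE"):
            build_patient_sets(
                final_decisions, full_matrix, bundle.pedigree,
                {"GHOSTGENE"}, {},
            )


class TestPatientNetwork:
    def test_f2_vwf_highest_tier_for_ii3(self, bundle, final_decisions, full_matrix):
        sets = build_patient_sets(
            final_decisions, full_matrix, bundle.pedigree,
            set(bundle.network_eligible), bundle.extra_includes,
        )
        net = build_patient_network("II3", sets["II3"], bundle.edge_db)
        score, tier = net.edge("F2", "VWF")
        assert tier == Tier.HIGHEST

    def test_documented_tiers(self, bundle):
        nodes = {"CRP", "F2", "SERPINA1", "THBS1", "VWF", "PLAT", "FGB", "IL1A"}
        net = build_patient_network("x", nodes, bundle.edge_db)
        highest = {p for p, _s, t in net.edges if t == Tier.HIGHEST}
        high = {p for p, _s, t in net.edges if t == Tier.HIGH}
        assert highest == {("CRP", "F2"), ("F2", "FGB"), ("F2", "VWF"),
                           ("PLAT", "VWF")}
        for pair in (("FGB", "THBS1"), ("FGB", "SERPINA1"), ("FGB", "VWF"),
                     ("CRP", "FGB"), ("F2", "SERPINA1"), ("CRP", "VWF"),
                     ("CRP", "IL1A")):
            assert pair in high

    def test_nodes_without_db_pairs_edgeless(self, bundle):
        net = build_patient_network("x", {"MTHFR", "ABO"}, bundle.edge_db)
        assert net.edges == []

    def test_random_db_matches_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(8)]
        db = EdgeDB(prior=0.041)
        present = set()
        for a, b in itertools.combinations(genes, 2):
            if rng.uniform() < 0.5:
                db.add(a, b, "experimental", float(rng.uniform(0.1, 0.9)))
                present.add((a, b))
        nodes = set(genes[:6])
        net = build_patient_network("x", nodes, db)
        expected = {
            tuple(sorted((a, b)))
            for a, b in itertools.combinations(sorted(nodes), 2)
            if tuple(sorted((a, b))) in present
        }
        assert {p for p, _s, _t in net.edges} == expected


class TestEnrichment:
    def test_term_covering_background_p_one(self):
        bg = {f"G{i}" for i in range(10)}
        db = TermDB([Term("GO:1", "all", "GO-BP", frozenset(bg))], bg)
        (res,) = enrich_terms({"G0", "G1"}, db)
        assert res.p_value == pytest.approx(1.0)

    def test_two_gene_toy_closed_form(self):
        bg = {f"G{i}" for i in range(10)}
        db = TermDB([Term("GO:1", "t", "GO-BP", frozenset({"G0", "G1"}))], bg)
        (res,) = enrich_terms({"G0", "G1"}, db)
        # C(2,2)*C(8,0)/C(10,2) = 1/45
        expected = math.comb(2, 2) * math.comb(8, 0) / math.comb(10, 2)
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.k == 2 and res.K == 2 and res.n == 2 and res.N == 10

    def test_fixture_fibrinogen_complex_overlap_for_iii2(self, bundle,
                                                         final_decisions, full_matrix):
        sets = build_patient_sets(
            final_decisions, full_matrix, bundle.pedigree,
            set(bundle.network_eligible), bundle.extra_includes,
        )
        results = enrich_terms(sets["III2"], bundle.term_db)
        fib = next(r for r in results if r.term_id == "GOCC:0005577")
        # III2 nodes {CRP,F2,SERPINA1,THBS1,FGB,IL1A} overlap the term
        # {CRP,F2,PLAT,THBS1,VWF,FGB} in exactly 4 genes
        assert fib.k == 4
        assert fib.category == "GO-CC"
        assert fib.fdr < 1e-4

    def test_fixture_acute_phase_and_fibrinogen_top_terms(self, bundle,
                                                          final_decisions,
                                                          full_matrix):
        sets = build_patient_sets(
            final_decisions, full_matrix, bundle.pedigree,
            set(bundle.network_eligible), bundle.extra_includes,
        )
        for patient in ("II2", "II3", "III2"):
            results = enrich_terms(sets[patient], bundle.term_db)
            top_ids = {r.term_id for r in results[:3]}
            assert "GOCC:0005577" in top_ids

    def test_node_outside_background_fatal(self, bundle):
        with pytest.raises(InputError, match="NOT_A_GENE"):
            enrich_terms({"NOT_A_GENE"}, bundle.term_db)

    def test_bh_fdr_monotone_and_matches_stepup_oracle(self):
        rng = np.random.default_rng(11)
        bg = {f"G{i}" for i in range(40)}
        terms = []
        for t in range(12):
            genes = frozenset(
                str(g) for g in rng.choice(sorted(bg), size=6, replace=False)
            )
            terms.append(Term(f"GO:{t:07d}", f"t{t}", "GO-BP", genes))
        db = TermDB(terms, bg)
        nodes = set(sorted(bg)[:8])
        results = [r for r in enrich_terms(nodes, db) if r.category == "GO-BP"]
        ordered = sorted(results, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in ordered]
        assert fdrs == sorted(fdrs)  # monotone along sorted p-values
        # independent step-up oracle
        m = len(ordered)
        raw = [r.p_value for r in ordered]
        adj = [min(1.0, p * m / (i + 1)) for i, p in enumerate(raw)]
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        for r, expected in zip(ordered, adj):
            assert r.fdr == pytest.approx(expected, rel=1e-9)
        for r in results:
            assert r.fdr >= r.p_value - 1e-12
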