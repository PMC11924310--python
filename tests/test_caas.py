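"""Convergent amino-acid substitution screen: scan, filters, parsimony, summary."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from polartrait import caas, synthetic
from polartrait.errors import (
    ClassificationError,
    ConfigurationError,
    EmptyAlignmentError,
    LabelingError,
)
from polartrait.io import load_reference_candidates


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _cluster(members, habitats, sources=None, focal=(), tree=None, cid="c1"):
    sources = sources or {}
    labels = {
        t: caas.HabitatLabel(
            taxon=t, habitat=habitats[t], source=sources.get(t, "culture"),
            is_focal=t in focal,
        )
        for t in members
    }
    return caas.HomologCluster(cluster_id=cid, members=dict(members), labels=labels, tree=tree)


HAB8 = {"A1": "arctic", "A2": "arctic", "A3": "arctic",
        "T1": "temperate", "T2": "temperate", "T3": "temperate"}


class TestScan:
    def test_arctic_fixed_versus_variable_temperate(self):
        # arctic side fixed on S, temperate side a spread of residues
        m = {"A1": "MSK", "A2": "MSK", "A3": "MSK",
             "T1": "MAK", "T2": "MEK", "T3": "MHK"}
        recs = caas.scan_caas(_cluster(m, HAB8))
        assert len(recs) == 1
        r = recs[0]
        assert r.column == 1
        assert r.arctic_residues == {"S"}
        assert r.temperate_residues == {"A", "E", "H"}
        assert r.specificity == "arctic"

    def test_temperate_fixed_side(self):
        m = {"A1": "MAK", "A2": "MIK", "A3": "MAK",
             "T1": "MVK", "T2": "MVK", "T3": "MVK"}
        recs = caas.scan_caas(_cluster(m, HAB8))
        assert len(recs) == 1
        assert recs[0].specificity == "temperate"
        assert recs[0].temperate_residues == {"V"}

    def test_both_sides_fixed(self):
        m = {"A1": "MLK", "A2": "MLK", "A3": "MLK",
             "T1": "MVK", "T2": "MVK", "T3": "MVK"}
        recs = caas.scan_caas(_cluster(m, HAB8))
        assert recs[0].specificity == "both"

    def test_invariant_and_overlapping_columns_skipped(self):
        m = {"A1": "MAK", "A2": "MAK", "A3": "MEK",
             "T1": "MAK", "T2": "MEK", "T3": "MAK"}
        assert caas.scan_caas(_cluster(m, HAB8)) == []

    def test_gapped_columns_skipped_by_default(self):
        m = {"A1": "MSK", "A2": "MSK", "A3": "M-K",
             "T1": "MAK", "T2": "MEK", "T3": "MHK"}
        assert caas.scan_caas(_cluster(m, HAB8)) == []
        recs = caas.scan_caas(_cluster(m, HAB8), allow_gaps=True)
        assert len(recs) == 1 and recs[0].arctic_residues == {"S"}

    def test_member_order_invariance(self):
        m = {"A1": "MSK", "A2": "MSK", "A3": "MSK",
             "T1": "MAK", "T2": "MEK", "T3": "MHK"}
        r1 = caas.scan_caas(_cluster(m, HAB8))
        r2 = caas.scan_caas(_cluster(dict(reversed(list(m.items()))), HAB8))
        assert [(x.column, x.arctic_residues) for x in r1] == [
            (x.column, x.arctic_residues) for x in r2
        ]

    def test_reported_sets_disjoint_against_brute_force(self, caas_dataset):
        clusters, _ = caas_dataset
        for cl in clusters:
            for rec in caas.scan_caas(cl):
                arctic = {cl.members[t][rec.column] for t in cl.taxa_by_habitat("arctic")}
                temperate = {cl.members[t][rec.column] for t in cl.taxa_by_habitat("temperate")}
                arctic.discard("-"); temperate.discard("-")
                assert rec.arctic_residues == arctic
                assert rec.temperate_residues == temperate
                assert not (arctic & temperate)

    def test_single_member_habitat_rejected(self):
        m = {"A1": "MSK", "T1": "MAK", "T2": "MEK"}
        hab = {"A1": "arctic", "T1": "temperate", "T2": "temperate"}
        with pytest.raises(LabelingError):
            caas.scan_caas(_cluster(m, hab))


class TestClassify:
    @pytest.mark.parametrize(
        "arctic,temperate,expected",
        [
            ({"V"}, {"E", "G", "S", "T"}, "arctic"),
            ({"D", "F", "T"}, {"S"}, "temperate"),
            ({"L"}, {"V"}, "both"),
        ],
    )
    def test_published_patterns(self, arctic, temperate, expected):
        assert caas.classify_origin_specificity(arctic, temperate) == expected

    def test_overlap_and_no_singleton_rejected(self):
        with pytest.raises(ClassificationError):
            caas.classify_origin_specificity({"A", "V"}, {"V"})
        with pytest.raises(ClassificationError):
            caas.classify_origin_specificity({"A", "V"}, {"E", "G"})


class TestTrim:
    def test_gapless_alignment_unchanged(self):
        m = {"A1": "MSKL", "A2": "MSKL", "A3": "MSKL",
             "T1": "MAKL", "T2": "MEKL", "T3": "MHKL"}
        cl = caas.trim_alignment(_cluster(m, HAB8))
        assert cl.members == m
        assert cl.column_map == [0, 1, 2, 3]

    def test_all_gap_column_removed(self):
        m = {"A1": "MS-L", "A2": "MS-L", "A3": "MS-L",
             "T1": "MA-L", "T2": "ME-L", "T3": "MH-L"}
        cl = caas.trim_alignment(_cluster(m, HAB8))
        assert cl.length == 3
        assert cl.column_map == [0, 1, 3]

    def test_matches_brute_force_breakpoint_rule(self, rng):
        # random gap pattern; oracle recomputes gap fractions and the
        # largest-jump cutoff independently
        n, length = 6, 40
        taxa = list(HAB8)
        arr = rng.choice(list("ACDEF"), size=(n, length))
        gap_mask = rng.random((n, length)) < rng.uniform(0, 0.6, size=length)
        arr[gap_mask] = "-"
        members = {t: "".join(row) for t, row in zip(taxa, arr)}
        cl = _cluster(members, HAB8)
        trimmed = caas.trim_alignment(cl, gap_fraction_max=0.5)

        fractions = (arr == "-").mean(axis=0)
        uniq = np.unique(fractions)
        if uniq.size == 1:
            cutoff = uniq[0] if uniq[0] <= 0.5 else 0.5
        else:
            jumps = np.diff(uniq)
            cutoff = uniq[int(np.argmax(jumps))]
        expected = [i for i in range(length) if fractions[i] <= cutoff]
        assert trimmed.column_map == expected

    def test_all_columns_removed_is_error(self):
        m = {t: "--" for t in HAB8}
        with pytest.raises(EmptyAlignmentError):
            caas.trim_alignment(_cluster(m, HAB8))


class TestConservedContext:
    def _block_cluster(self, focal_col_content, flank="K", n_flank=6):
        m = {}
        for t in HAB8:
            m[t] = flank * n_flank + focal_col_content[t] + flank * n_flank
        return _cluster(m, HAB8)

    def test_conserved_gapless_flank_passes(self):
        cl = self._block_cluster({"A1": "S", "A2": "S", "A3": "S",
                                  "T1": "A", "T2": "E", "T3": "H"})
        assert caas.check_conserved_context(cl, 6, window=5).passed

    def test_gap_in_window_fails(self):
        m = {t: "KKKKKK" + ("S" if t.startswith("A") else "A") + "KKKKKK" for t in HAB8}
        m["T3"] = "KKKK-K" + "A" + "KKKKKK"
        cl = _cluster(m, HAB8)
        check = caas.check_conserved_context(cl, 6, window=5)
        assert not check.passed and not check.gap_free

    def test_edge_window_fails_with_flag(self):
        cl = self._block_cluster({t: "S" if t.startswith("A") else "A" for t in HAB8})
        check = caas.check_conserved_context(cl, 2, window=5)
        assert not check.passed and check.edge

    def test_variable_flank_fails_on_diversity(self, rng):
        m = {}
        for t in HAB8:
            flank = "".join(rng.choice(list("ACDEFGHIKL"), size=12))
            m[t] = flank[:6] + ("S" if t.startswith("A") else "A") + flank[6:]
        cl = _cluster(m, HAB8)
        check = caas.check_conserved_context(cl, 6, window=5, max_other_variability=0.3)
        assert not check.passed
        assert check.mean_other_variability > 0.3

    def test_planted_site_passes_decoy_near_gap_fails(self):
        clusters, truth = synthetic.simulate_caas_dataset(
            n_clusters=1, length=150, n_planted=2, seed=13
        )
        cl = clusters[0]
        for cid, col, _res in truth.planted_caas:
            assert caas.check_conserved_context(cl, col).passed
        # a column adjacent to a gap run always fails
        gap_cols = [i for i in range(cl.length)
                    if any(s[i] == "-" for s in cl.members.values())]
        assert gap_cols, "generator should have inserted gap runs"
        assert not caas.check_conserved_context(cl, gap_cols[0]).passed


class TestFilters:
    def _record(self, cluster):
        recs = caas.scan_caas(cluster)
        assert recs
        return recs[0]

    def test_additional_species_passes_with_nonfocal_carriers(self):
        m = {"A1": "S", "A2": "S", "A3": "S", "T1": "A", "T2": "E", "T3": "H"}
        cl = _cluster(m, HAB8, focal=("A1", "T1"))
        assert caas.filter_additional_species(self._record(cl), cl.labels)

    def test_focal_only_carrier_fails(self):
        # only the focal arctic species carries the convergent residue
        m = {"A1": "S", "A2": "-", "A3": "-", "T1": "A", "T2": "E", "T3": "H"}
        cl = _cluster(m, HAB8, focal=("A1", "T1"))
        recs = caas.scan_caas(cl, allow_gaps=True)
        assert not caas.filter_additional_species(recs[0], cl.labels)

    def test_no_focal_flag_is_configuration_error(self):
        m = {"A1": "S", "A2": "S", "A3": "S", "T1": "A", "T2": "E", "T3": "H"}
        cl = _cluster(m, HAB8)
        with pytest.raises(ConfigurationError):
            caas.filter_additional_species(self._record(cl), cl.labels)

    def test_member_order_does_not_change_decision(self):
        m = {"A1": "S", "A2": "S", "A3": "S", "T1": "A", "T2": "E", "T3": "H"}
        cl1 = _cluster(m, HAB8, focal=("A1", "T1"))
        cl2 = _cluster(dict(reversed(list(m.items()))), HAB8, focal=("A1", "T1"))
        assert caas.filter_additional_species(
            self._record(cl1), cl1.labels
        ) == caas.filter_additional_species(self._record(cl2), cl2.labels)

    def test_expression_requires_metatranscriptomes_from_both_habitats(self):
        m = {"A1": "S", "A2": "S", "A3": "S", "T1": "A", "T2": "E", "T3": "H"}
        both = _cluster(m, HAB8, sources={"A2": "metatranscriptome", "T2": "metatranscriptome"})
        assert caas.filter_expression_evidence(both)
        culture_only = _cluster(m, HAB8)
        assert not caas.filter_expression_evidence(culture_only)
        one_side = _cluster(m, HAB8, sources={"A2": "metatranscriptome"})
        assert not caas.filter_expression_evidence(one_side)


def _oracle_origins(tree, tip_states, target):
    """Exhaustive minimum over internal labelings: #(0->1 edges) + [root=1],
    with 1->0 reversals forbidden (the derived residue is irreversible)."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, states))
        ok = True
        origins = assign[tree.seed_node]
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            s_par = assign[nd.parent_node]
            s = (1 if tip_states[nd.taxon.label] == target else 0) if nd.is_leaf() else assign[nd]
            if s_par == 1 and s == 0:
                ok = False
                break
            origins += int(s_par == 0 and s == 1)
        if ok and (best is None or origins < best):
            best = origins
    return best


class TestFitchOrigins:
    def test_sister_pair_is_single_origin(self):
        t = _tree("((A1,A2),(T1,T2));")
        states = {"A1": "W", "A2": "W", "T1": "X", "T2": "X"}
        assert caas.count_origins_fitch(t, states, "W") == 1

    def test_scattered_carriers_are_independent(self):
        t = _tree("((A1,T1),(A2,T2));")
        states = {"A1": "W", "A2": "W", "T1": "X", "T2": "X"}
        assert caas.count_origins_fitch(t, states, "W") == 2

    def test_all_tips_carrying_is_root_state(self):
        t = _tree("((A1,A2),(T1,T2));")
        states = {k: "W" for k in ("A1", "A2", "T1", "T2")}
        assert caas.count_origins_fitch(t, states, "W") == 1

    def test_absent_residue_has_zero_origins(self):
        t = _tree("((A1,A2),(T1,T2));")
        states = {k: "X" for k in ("A1", "A2", "T1", "T2")}
        assert caas.count_origins_fitch(t, states, "W") == 0

    def test_missing_tip_state_rejected(self):
        t = _tree("((A1,A2),(T1,T2));")
        with pytest.raises(Exception):
            caas.count_origins_fitch(t, {"A1": "W"}, "W")

    def test_matches_exhaustive_enumeration_on_random_trees(self, rng):
        newicks = [
            "((a,b),(c,d));",
            "(((a,b),c),(d,(e,f)));",
            "((a,(b,c)),((d,e),f));",
            "(a,(b,(c,(d,(e,f)))));",
        ]
        for nwk in newicks:
            t = _tree(nwk)
            tips = [leaf.taxon.label for leaf in t.leaf_node_iter()]
            for _ in range(20):
                states = {tip: rng.choice(["W", "X"]) for tip in tips}
                mine = caas.count_origins_fitch(t, states, "W")
                oracle = _oracle_origins(t, states, "W")
                if all(v != "W" for v in states.values()):
                    assert mine == 0
                else:
                    assert mine == oracle, (nwk, states)


class TestClustering:
    def test_identical_sequences_cluster_together(self):
        groups = caas.cluster_homologs({"a": "MKLV" * 10, "b": "MKLV" * 10})
        assert groups == [["a", "b"]]

    def test_distant_sequences_stay_apart(self):
        a = "MKLVASDFGH" * 4
        b = "WWCCPPYYRR" * 4
        groups = caas.cluster_homologs({"a": a, "b": b}, identity_threshold=0.75)
        assert sorted(map(sorted, groups)) == [["a"], ["b"]]

    def test_single_linkage_transitivity_against_oracle(self, rng):
        # A~B and B~C above threshold, A~C below: one cluster by transitivity
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        def mutate(s, k, seed):
            r = np.random.default_rng(seed)
            pos = r.choice(len(s), size=k, replace=False)
            out = list(s)
            for p in pos:
                out[p] = "W" if out[p] != "W" else "Y"
            return "".join(out)

        a = base
        b = mutate(base, 9, 1)   # ~85% identity with a
        c = mutate(b, 9, 2)      # ~85% with b, ~72% with a (mutations disjointish)
        ident_ab = caas.pairwise_identity(a, b)
        ident_bc = caas.pairwise_identity(b, c)
        ident_ac = caas.pairwise_identity(a, c)
        assert ident_ab >= 0.75 and ident_bc >= 0.75
        if ident_ac < 0.75:  # expected with high probability
            groups = caas.cluster_homologs({"a": a, "b": b, "c": c}, 0.75)
            assert sorted(map(sorted, groups)) == [["a", "b", "c"]]

    def test_empty_input_gives_empty_output(self):
        assert caas.cluster_homologs({}) == []


class TestSummary:
    def test_reference_table_tallies(self):
        records, annotations = load_reference_candidates()
        s = caas.summarize_candidates(records, annotations)
        assert s.n_candidates == 26
        assert s.by_specificity == {"arctic": 22, "temperate": 3, "both": 1}
        assert s.n_annotated == 12
        assert s.n_central_dogma == 6
        assert s.n_metabolic == 5

    def test_multi_position_id_counts_once(self):
        records, annotations = load_reference_candidates()
        ids = [r.cluster_id for r in records]
        assert ids.count("8045") == 3  # three positions, one ID
        s = caas.summarize_candidates(records, annotations)
        assert s.by_specificity["arctic"] + s.by_specificity["temperate"] + s.by_specificity[
            "both"
        ] == s.n_candidates

    def test_id_level_specificity_rules(self):
        assert caas.id_level_specificity(["arctic", "arctic"]) == "arctic"
        assert caas.id_level_specificity(["temperate"]) == "temperate"
        assert caas.id_level_specificity(["arctic", "temperate"]) == "both"
        assert caas.id_level_specificity(["both"]) == "both"

    def test_empty_records_all_zero(self):
        s = caas.summarize_candidates([], None)
        assert s.n_candidates == 0
        assert s.n_annotated == 0
        assert sum(s.by_specificity.values()) == 0


class TestEndToEnd:
    def test_zero_noise_recovery_is_exact(self):
        clusters, truth = synthetic.simulate_caas_dataset(
            n_clusters=5, length=200, n_planted=5, substitution_prob=0.0,
            n_gap_runs=0, seed=3,
        )
        records = []
        for cl in clusters:
            records.extend(caas.screen_cluster(cl))
        sens, prec = synthetic.score_caas_recovery(records, truth)
        assert sens == 1.0
        assert prec == 1.0

    def test_null_dataset_mostly_clean(self):
        clean = total = 0
        for seed in range(5):
            clusters, _ = synthetic.simulate_caas_dataset(
                n_clusters=10, length=300, n_planted=0, seed=100 + seed
            )
            for cl in clusters:
                total += 1
                clean += not caas.screen_cluster(cl)
        assert clean / total >= 0.95
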