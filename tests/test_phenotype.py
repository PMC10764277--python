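"""Three-strategy phenotype prediction: rules, random forest, neighbour
groups, and their consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from magpheno import phenotype as ph, synthdata as sd
from magpheno.errors import InvalidInputError, InvalidParameterError, UndefinedCallError


def _and_training_data():
    """All four patterns of {0,1}^2; phenotype = role1 AND role2."""
    roles = pd.DataFrame(
        [[0, 0], [0, 1], [1, 0], [1, 1]] * 2,
        columns=["r1", "r2"],
        index=[f"g{i}" for i in range(8)],
    )
    bpm = pd.DataFrame({"P": (roles["r1"] & roles["r2"]).astype(int)})
    return roles, bpm


class TestPathwayRules:
    def test_learns_and_rule_exactly(self):
        roles, bpm = _and_training_data()
        rules = ph.train_pathway_rules(roles, bpm)
        # evaluate against the exhaustive truth table
        grid = pd.DataFrame([[0, 0], [0, 1], [1, 0], [1, 1]], columns=["r1", "r2"],
                            index=list("abcd"))
        preds = ph.predict_rules(grid, rules)
        assert preds["P"].tolist() == [0, 0, 0, 1]

    def test_noiseless_resubstitution_is_perfect(self, pangenome, role_matrix):
        rules = ph.train_pathway_rules(
            role_matrix, pangenome.truth_bpm, pangenome.pathway_definitions
        )
        preds = ph.predict_rules(role_matrix, rules)
        assert preds.loc[pangenome.truth_bpm.index].equals(pangenome.truth_bpm)
        assert all(r.training_accuracy == 1.0 for r in rules.values())

    def test_constant_phenotype_flagged(self):
        roles, _ = _and_training_data()
        bpm = pd.DataFrame({"P": [1] * 8}, index=roles.index)
        rules = ph.train_pathway_rules(roles, bpm)
        assert rules["P"].constant == 1
        preds = ph.predict_rules(pd.DataFrame(0, index=["m"], columns=["r1", "r2"]), rules)
        assert preds.loc["m", "P"] == 1

    def test_missing_role_column_treated_as_absent(self):
        roles, bpm = _and_training_data()
        rules = ph.train_pathway_rules(roles, bpm)
        mag = pd.DataFrame({"r1": [1]}, index=["m"])  # r2 column missing -> 0
        assert ph.predict_rules(mag, rules).loc["m", "P"] == 0


class TestPredictMl:
    def test_noiseless_separable_loo_accuracy_perfect(self):
        # every pattern appears twice, so each held-out genome remains
        # represented: LOO must be exact
        roles, bpm = _and_training_data()
        preds, report = ph.predict_ml(roles, bpm, roles, n_trees=60, seed=1, loo=True)
        assert report["P"]["loo_accuracy"] == 1.0
        assert preds["P"].equals(bpm["P"])

    def test_noiseless_resubstitution_recovers_truth(self, pangenome, role_matrix):
        preds, _ = ph.predict_ml(
            role_matrix, pangenome.truth_bpm, role_matrix, n_trees=60, seed=1
        )
        assert preds.loc[pangenome.truth_bpm.index].equals(pangenome.truth_bpm)

    def test_same_seed_identical(self, pangenome, role_matrix):
        a, _ = ph.predict_ml(role_matrix, pangenome.truth_bpm, role_matrix, n_trees=40, seed=7)
        b, _ = ph.predict_ml(role_matrix, pangenome.truth_bpm, role_matrix, n_trees=40, seed=7)
        assert a.equals(b)

    def test_report_records_chosen_hyperparameters(self, pangenome, role_matrix):
        _, report = ph.predict_ml(role_matrix, pangenome.truth_bpm, role_matrix,
                                  n_trees=40, seed=2)
        for entry in report.values():
            assert entry["constant"] or "params" in entry

    def test_too_few_references_rejected(self):
        roles = pd.DataFrame([[1], [0]], columns=["r"], index=["a", "b"])
        bpm = pd.DataFrame({"P": [1, 0]}, index=["a", "b"])
        with pytest.raises(InvalidInputError):
            ph.predict_ml(roles, bpm, roles)


def _sketch(ids, k=5, size=8):
    return ph.MinHashSketch("g", k, size, np.array(sorted(ids), dtype=np.uint64))


class TestMashDistance:
    def test_identical_sketches_distance_zero(self):
        s = _sketch([1, 2, 3, 4])
        assert ph.mash_distance(s, s) == 0.0

    def test_disjoint_sketches_capped_at_one(self):
        assert ph.mash_distance(_sketch([1, 2, 3]), _sketch([7, 8, 9])) == 1.0

    def test_formula_value(self):
        # j = 0.9 at k = 21: d = -(1/21) ln(1.8/1.9) ~ 0.002573
        # merged bottom sketch of size 10 with 9 shared values gives j = 0.9
        a = _sketch(range(10), k=21, size=10)
        b = _sketch(list(range(9)) + [50], k=21, size=10)
        d = ph.mash_distance(a, b)
        assert d == pytest.approx(-np.log(1.8 / 1.9) / 21, rel=1e-12)
        assert d == pytest.approx(0.00257, abs=5e-5)

    def test_mismatched_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            ph.mash_distance(_sketch([1], k=5), _sketch([1], k=7))

    @given(st.sets(st.integers(0, 200), min_size=1, max_size=30),
           st.sets(st.integers(0, 200), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_nonnegativity(self, a, b):
        sa, sb = _sketch(a, size=20), _sketch(b, size=20)
        assert ph.mash_distance(sa, sb) == ph.mash_distance(sb, sa) >= 0.0


class TestNeighborGroups:
    def test_close_mag_grouped_far_mag_ungrouped(self, pangenome):
        # MAG degraded from G0000 sits in G0000's clade; a genome of novel
        # sequence shares no k-mers with anything and stays ungrouped
        mag = sd.degrade_genome_to_mag(pangenome.genomes["G0000"], 0.9, 0.0, 0.0, seed=3)
        rng = np.random.default_rng(5)
        alien = ["".join(rng.choice(sd.AMINO_ACIDS, size=200)) for _ in range(40)]
        mag_sk = [
            ph.sketch_sequences(mag.genome_id, [p.sequence for p in mag.proteins]),
            ph.sketch_sequences("alien", alien),
        ]
        ref_sk = [
            ph.sketch_sequences(g, [p.sequence for p in pangenome.genomes[g].proteins])
            for g in sorted(pangenome.genomes)
        ]
        groups = ph.assign_neighbor_groups(mag_sk, ref_sk)
        grouped = {m for g in groups for m in g.members}
        assert mag.genome_id in grouped and "alien" not in grouped

    def test_groups_respect_distance_cap_pairwise_linkage(self, pangenome):
        ref_sk = [
            ph.sketch_sequences(g, [p.sequence for p in pangenome.genomes[g].proteins])
            for g in sorted(pangenome.genomes)
        ]
        groups = ph.assign_neighbor_groups([], ref_sk, min_size=4)
        # single linkage: every member has some other member within the cap
        for grp in groups:
            d = grp.distances.to_numpy()
            np.fill_diagonal(d, np.inf)
            assert (d.min(axis=1) <= 0.1).all()
            assert len(grp.members) >= 4

    def test_small_groups_dissolved(self):
        # three mutually close sketches, nothing else: below min_size -> no group
        base = list(range(100))
        sks = [_sketch(base[:90] + [200 + i], size=50) for i in range(3)]
        assert ph.assign_neighbor_groups(sks, [], min_size=4) == []


class TestPredictNeighbor:
    def _setup(self):
        pathway_defs = {"P": [{"a", "b"}], "Q": [{"c"}]}
        ref_roles = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], columns=["a", "b", "c"], index=["r1", "r2"]
        )
        ref_bpm = pd.DataFrame({"P": [1, 0], "Q": [0, 1]}, index=["r1", "r2"])
        group = ph.NeighborGroup(["m", "r1", "r2"], ["r1", "r2"],
                                 pd.DataFrame(np.zeros((3, 3)),
                                              index=["m", "r1", "r2"],
                                              columns=["m", "r1", "r2"]))
        return pathway_defs, ref_roles, ref_bpm, group

    def test_adopts_closest_pattern(self):
        defs, ref_roles, ref_bpm, group = self._setup()
        # on P's roles {a, b}: mag (1, 0) is Hamming 1 from r1 (1, 1) and
        # Hamming 2 from r2 (0, 1) -> adopts r1's phenotype despite the
        # missing 'b' gene
        mag = pd.Series({"a": 1, "b": 0, "c": 0})
        votes = ph.predict_neighbor(mag, group, ref_bpm, defs, ref_roles)
        assert votes["P"] == 1

    def test_comparison_restricted_to_required_roles(self):
        defs, ref_roles, ref_bpm, group = self._setup()
        # same P-pattern as r1 but swamped with c: P must still follow r1
        mag = pd.Series({"a": 1, "b": 1, "c": 1})
        votes = ph.predict_neighbor(mag, group, ref_bpm, defs, ref_roles)
        assert votes["P"] == 1 and votes["Q"] == 1

    def test_equidistant_conflict_abstains(self):
        defs = {"P": [{"a", "b"}]}
        ref_roles = pd.DataFrame([[1, 0], [0, 1]], columns=["a", "b"], index=["r1", "r2"])
        ref_bpm = pd.DataFrame({"P": [1, 0]}, index=["r1", "r2"])
        group = ph.NeighborGroup(["m", "r1", "r2"], ["r1", "r2"],
                                 pd.DataFrame(np.zeros((3, 3))))
        votes = ph.predict_neighbor(pd.Series({"a": 0, "b": 0}), group, ref_bpm, defs, ref_roles)
        assert votes["P"] == ph.ABSTAIN

    def test_no_reference_in_group_abstains(self):
        defs, ref_roles, ref_bpm, _ = self._setup()
        group = ph.NeighborGroup(["m1", "m2", "m3", "m4"], [], pd.DataFrame())
        votes = ph.predict_neighbor(pd.Series({"a": 1}), group, ref_bpm, defs, ref_roles)
        assert (votes == ph.ABSTAIN).all()


class TestConsensus:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ((1, 1, 1), (1, "high")),
            ((0, 0, 0), (0, "high")),
            ((0, 1, ph.ABSTAIN), (1, "low")),  # irreconcilable -> ML default
            ((1, 0, ph.ABSTAIN), (0, "low")),
            ((0, 1, 0), (0, "medium")),  # majority with ng participating
            ((1, 0, 1), (1, "medium")),
            ((1, 1, 0), (1, "medium")),
            ((1, 1, ph.ABSTAIN), (1, "medium")),
            ((0, 0, 1), (1, "low")),  # neighbour rescue of joint false negative
        ],
    )
    def test_vote_table(self, votes, expected):
        assert ph.consensus(*votes) == expected

    def test_rescue_can_be_disabled(self):
        assert ph.consensus(0, 0, 1, ng_rescue=False) == (0, "medium")

    def test_all_abstain_is_an_error(self):
        with pytest.raises(UndefinedCallError):
            ph.consensus(ph.ABSTAIN, ph.ABSTAIN, ph.ABSTAIN)

    def test_invalid_vote_rejected(self):
        with pytest.raises(InvalidParameterError):
            ph.consensus(2, 0, 1)

    @given(st.sampled_from([0, 1, ph.ABSTAIN]), st.sampled_from([0, 1, ph.ABSTAIN]),
           st.sampled_from([0, 1, ph.ABSTAIN]))
    @settings(max_examples=30, deadline=None)
    def test_consensus_total_and_binary(self, r, m, n):
        if (r, m, n) == (ph.ABSTAIN,) * 3:
            return
        value, conf = ph.consensus(r, m, n)
        assert value in (0, 1) and conf in ("high", "medium", "low")
        if r == m == n:
            assert value == r and conf == "high"


class TestEndToEndRecovery:
    def test_complete_mags_recover_truth_exactly(self, pangenome, role_matrix):
        """At completeness 1.0 every strategy and the consensus equal the
        planted BPM."""
        picks = sorted(pangenome.genomes)[:6]
        mags = {g: sd.degrade_genome_to_mag(pangenome.genomes[g], 1.0, 0.0, 0.0, seed=1,
                                            mag_id=f"{g}.mag")
                for g in picks}
        roles = list(role_matrix.columns)
        mag_roles = pd.DataFrame(
            [[int(r in m.role_set()) for r in roles] for m in mags.values()],
            index=[m.genome_id for m in mags.values()], columns=roles,
        )
        mag_seqs = {m.genome_id: [p.sequence for p in m.proteins] for m in mags.values()}
        ref_seqs = {g: [p.sequence for p in pangenome.genomes[g].proteins]
                    for g in sorted(pangenome.genomes)}
        bpm, calls, rep = ph.predict_phenotypes(
            role_matrix, pangenome.truth_bpm, mag_roles, pangenome.pathway_definitions,
            mag_sequences=mag_seqs, ref_sequences=ref_seqs, seed=3, n_trees=60,
        )
        truth = pangenome.truth_bpm.loc[picks].set_axis(bpm.index)
        assert bpm.equals(truth)
        assert rep["rule_preds"].equals(truth)
        assert rep["ml_preds"].equals(truth)


class TestFilterGenes:
    def test_filtering_rules(self):
        defs = {"P": [{"a", "b"}], "Q": [{"c"}]}
        bpm = pd.DataFrame({"P": [1], "Q": [0]}, index=["g"])
        annotations = pd.DataFrame(
            {
                "genome": ["g", "g", "g", "g"],
                "gene": ["x1", "x2", "x3", "x4"],
                "role": ["a", "c", None, "zz"],
            }
        )
        kept = ph.filter_genes_to_intact_pathways(annotations, bpm, defs)
        # 'a' in intact P -> kept; 'c' only in phenotype-0 Q -> dropped;
        # unannotated and out-of-pathway genes -> dropped
        assert kept["gene"].tolist() == ["x1"]
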