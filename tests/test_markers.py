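"""Clade calling, ROC calibration, hit assignment, benchmarking, modules."""

import numpy as np
import pytest

from misokit import markers as mk
from misokit import synthdata as sd


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive check of every internal node against the
# three clade criteria, followed by maximality filtering.

def exhaustive_clades(tree, evidence, min_support=70.0, min_frac=0.8):
    passing = []
    for _, members, support in tree.internal_clades():
        if support is None or support <= min_support:
            continue
        ev = [evidence[t] for t in members]
        ingroup = [e for e in ev if e.status == "ingroup_verified"]
        if not ingroup or any(e.status == "outgroup_verified" for e in ev):
            continue
        nbr = frozenset().union(*(e.neighbourhood_labels for e in ingroup))
        if nbr:
            tagged = [e for e in ev if e.neighbourhood_labels]
            if tagged and sum(bool(e.neighbourhood_labels & nbr)
                              for e in tagged) / len(tagged) < min_frac:
                continue
        traits = frozenset().union(*(e.trait_labels for e in ingroup))
        if traits and any(e.trait_labels and not (e.trait_labels & traits)
                          for e in ev):
            continue
        passing.append(members)
    return {m for m in passing
            if not any(m < other for other in passing)}


TOY_NEWICK = "(((in1,(u1,u2)92)90,(og1,u3)85)50,bg1)30;"
TOY_EVIDENCE = {
    "in1": mk.TipEvidence("ingroup_verified", frozenset({"nbrA"}), frozenset({"t"})),
    "u1": mk.TipEvidence("uncharacterized", frozenset({"nbrA"}), frozenset()),
    "u2": mk.TipEvidence("uncharacterized", frozenset({"nbrA"}), frozenset()),
    "og1": mk.TipEvidence("outgroup_verified", frozenset({"og"}), frozenset()),
    "u3": mk.TipEvidence("uncharacterized", frozenset({"nbrA"}), frozenset()),
    "bg1": mk.TipEvidence("uncharacterized", frozenset(), frozenset()),
}


class TestCladeCalling:
    def test_toy_tree_single_supported_clade(self):
        """A 6-tip tree with one supported ingroup subtree (support 90)
        yields exactly that subtree; the oracle agrees."""
        tree = mk.AnnotatedTree.from_newick(TOY_NEWICK)
        clades = mk.find_ortholog_clades(tree, TOY_EVIDENCE)
        assert [c.members for c in clades] == [frozenset({"in1", "u1", "u2"})]
        assert {c.members for c in clades} == exhaustive_clades(tree, TOY_EVIDENCE)

    def test_low_support_not_called(self):
        """Support 60 fails the strict >70 criterion even when the
        membership criteria pass."""
        newick = "((in1,(u1,u2)92)60,og1)30;"
        tree = mk.AnnotatedTree.from_newick(newick)
        ev = {k: TOY_EVIDENCE[k] for k in ("in1", "u1", "u2", "og1")}
        assert mk.find_ortholog_clades(tree, ev) == []

    def test_support_exactly_70_not_called(self):
        newick = "((in1,(u1,u2)92)70,og1)30;"
        tree = mk.AnnotatedTree.from_newick(newick)
        ev = {k: TOY_EVIDENCE[k] for k in ("in1", "u1", "u2", "og1")}
        assert mk.find_ortholog_clades(tree, ev) == []

    def test_outgroup_member_excludes_node_but_not_descendants(self):
        """A node polluted by a verified outgroup tip is skipped; the largest
        outgroup-free supported descendant is returned instead."""
        newick = "(((in1,u1)95,og1)96,bg1)40;"
        tree = mk.AnnotatedTree.from_newick(newick)
        ev = {k: TOY_EVIDENCE[k] for k in ("in1", "u1", "og1", "bg1")}
        clades = mk.find_ortholog_clades(tree, ev)
        assert [c.members for c in clades] == [frozenset({"in1", "u1"})]

    def test_missing_evidence_listed(self):
        tree = mk.AnnotatedTree.from_newick("((a,b)90,c)50;")
        with pytest.raises(ValueError, match="b"):
            mk.find_ortholog_clades(tree, {"a": TOY_EVIDENCE["in1"],
                                           "c": TOY_EVIDENCE["bg1"]})

    def test_inconsistent_neighbourhood_blocks_call(self):
        """Criterion 3: a clade whose tagged members mostly lack the ingroup
        neighbourhood label is rejected."""
        newick = "((in1,(x1,(x2,x3)93)94)95,og1)40;"
        ev = {
            "in1": mk.TipEvidence("ingroup_verified", frozenset({"nbrA"}), frozenset()),
            "x1": mk.TipEvidence("uncharacterized", frozenset({"other"}), frozenset()),
            "x2": mk.TipEvidence("uncharacterized", frozenset({"other"}), frozenset()),
            "x3": mk.TipEvidence("uncharacterized", frozenset({"other"}), frozenset()),
            "og1": mk.TipEvidence("outgroup_verified", frozenset(), frozenset()),
        }
        tree = mk.AnnotatedTree.from_newick(newick)
        assert mk.find_ortholog_clades(tree, ev) == []
        assert exhaustive_clades(tree, ev) == set()

    def test_contradictory_trait_blocks_call(self):
        newick = "((in1,z1)95,og1)40;"
        ev = {
            "in1": mk.TipEvidence("ingroup_verified", frozenset({"n"}),
                                  frozenset({"cys_pair"})),
            "z1": mk.TipEvidence("uncharacterized", frozenset({"n"}),
                                 frozenset({"his_pair"})),
            "og1": mk.TipEvidence("outgroup_verified", frozenset(), frozenset()),
        }
        tree = mk.AnnotatedTree.from_newick(newick)
        assert mk.find_ortholog_clades(tree, ev) == []

    def test_tip_order_permutation_invariance(self):
        rotated = "(bg1,((og1,u3)85,((u2,u1)92,in1)90)50)30;"
        a = mk.find_ortholog_clades(mk.AnnotatedTree.from_newick(TOY_NEWICK),
                                    TOY_EVIDENCE)
        b = mk.find_ortholog_clades(mk.AnnotatedTree.from_newick(rotated),
                                    TOY_EVIDENCE)
        assert {c.members for c in a} == {c.members for c in b}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_on_random_trees(self, seed):
        """On random planted trees of <= 12 tips the implementation equals
        the brute-force criterion check at every internal node."""
        rng = np.random.default_rng(seed)
        sizes = tuple(rng.integers(2, 5, size=rng.integers(1, 3)))
        res = sd.gen_tree_with_clades(seed, clade_sizes=sizes,
                                      n_background=int(rng.integers(1, 4)),
                                      n_outgroup=int(rng.integers(1, 3)))
        called = {c.members for c in
                  mk.find_ortholog_clades(res.tree, res.evidence)}
        assert called == exhaustive_clades(res.tree, res.evidence)
        assert called == set(res.clades)


# ---------------------------------------------------------------------------
# ROC calibration


def brute_force_best(scores, labels):
    """Exhaustive Youden-J sweep over all candidate cut-points (oracle)."""
    distinct = np.unique(scores)
    candidates = np.concatenate([[distinct[0] - 1],
                                 (distinct[:-1] + distinct[1:]) / 2,
                                 [distinct[-1] + 1]])
    pos, neg = scores[labels], scores[~labels]
    best = None
    for t in candidates:
        j = np.mean(pos >= t) + np.mean(neg < t) - 1.0
        if best is None or (j, t) > best[:2]:
            best = (j, t)
    return best


class TestCalibration:
    def test_perfect_separation(self):
        ss = mk.ScoreSet(ids=("a", "b", "c", "d"),
                         scores=np.array([100.0, 90.0, 10.0, 20.0]),
                         labels=np.array([True, True, False, False]))
        th = mk.calibrate_threshold(ss)
        assert 20.0 < th.threshold < 90.0
        assert th.sensitivity == 1.0 and th.specificity == 1.0

    def test_inseparable_input_yields_zero_j(self):
        ss = mk.ScoreSet(ids=("a", "b"), scores=np.array([50.0, 50.0]),
                         labels=np.array([True, False]))
        th = mk.calibrate_threshold(ss)
        assert th.youden_j == pytest.approx(0.0)

    def test_single_label_rejected(self):
        ss = mk.ScoreSet(ids=("a", "b"), scores=np.array([1.0, 2.0]),
                         labels=np.array([True, True]))
        with pytest.raises(ValueError):
            mk.calibrate_threshold(ss)

    @pytest.mark.parametrize("seed", range(8))
    def test_interleaved_gaussians_match_brute_force(self, seed):
        """With overlapping classes the chosen cut equals the exhaustive
        J-maximisation over every midpoint."""
        rng = np.random.default_rng(seed)
        scores = np.concatenate([rng.normal(55, 12, 20), rng.normal(45, 12, 20)])
        labels = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        ss = mk.ScoreSet(ids=tuple(map(str, range(40))), scores=scores,
                         labels=labels)
        th = mk.calibrate_threshold(ss)
        j_best, t_best = brute_force_best(scores, labels)
        assert th.youden_j == pytest.approx(j_best, abs=1e-12)
        assert th.threshold == pytest.approx(t_best)

    def test_sklearn_roc_cross_check(self):
        """Independent route: best J from scikit-learn's ROC curve equals the
        calibrated operating point."""
        from sklearn.metrics import roc_curve
        ss = sd.gen_scoreset(11, mu_pos=80, mu_neg=60, sd_pos=15, sd_neg=15)
        th = mk.calibrate_threshold(ss)
        fpr, tpr, _ = roc_curve(ss.labels.astype(int), ss.scores)
        assert th.youden_j == pytest.approx(np.max(tpr - fpr), abs=1e-12)

    def test_planted_separation_recovers_clean_cut(self):
        """Well-separated planted classes (d' = 4) yield sensitivity and
        specificity >= 0.95 (seeded)."""
        for seed in range(5):
            ss = sd.gen_scoreset(seed, mu_pos=100, mu_neg=40, sd_pos=15, sd_neg=15)
            th = mk.calibrate_threshold(ss)
            assert th.sensitivity >= 0.95 and th.specificity >= 0.95


# ---------------------------------------------------------------------------
# Hit assignment


class TestAssignHits:
    THRESH = {"mA": 50.0, "mB": 50.0}

    def test_single_passing_model(self):
        ann = mk.assign_hits({"g1": {"mA": 80.0, "mB": 20.0}}, self.THRESH)
        assert ann.hits["g1"] == ("mA", 80.0)

    def test_argmax_of_two_passing(self):
        ann = mk.assign_hits({"g1": {"mA": 120.0, "mB": 80.0}}, self.THRESH)
        assert ann.hits["g1"][0] == "mA"

    def test_below_threshold_unannotated(self):
        ann = mk.assign_hits({"g1": {"mA": 30.0, "mB": 10.0}}, self.THRESH)
        assert "g1" not in ann.hits

    def test_tie_breaks_to_lexicographically_first_model(self):
        ann = mk.assign_hits({"g1": {"mB": 90.0, "mA": 90.0}}, self.THRESH)
        assert ann.hits["g1"][0] == "mA"

    def test_random_table_matches_per_row_maximum(self):
        """Oracle: independent per-row argmax over passing models."""
        rng = np.random.default_rng(42)
        models = [f"m{i}" for i in range(5)]
        thresholds = {m: 40.0 for m in models}
        table = {f"g{i}": {m: float(rng.uniform(0, 100)) for m in models}
                 for i in range(50)}
        ann = mk.assign_hits(table, thresholds)
        for gene, row in table.items():
            passing = {m: s for m, s in row.items() if s >= 40.0}
            if not passing:
                assert gene not in ann.hits
            else:
                best = max(passing.values())
                assert ann.hits[gene][1] == best

    def test_stable_under_row_shuffling(self):
        rng = np.random.default_rng(0)
        table = {f"g{i}": {"mA": float(rng.uniform(0, 100)),
                           "mB": float(rng.uniform(0, 100))} for i in range(20)}
        shuffled = dict(reversed(list(table.items())))
        assert mk.assign_hits(table, self.THRESH).hits == \
            mk.assign_hits(shuffled, self.THRESH).hits


# ---------------------------------------------------------------------------
# Benchmarking


class TestBenchmark:
    def test_perfect_predictions(self):
        truth = {f"s{i}": i < 5 for i in range(10)}
        rep = mk.benchmark(truth, truth)
        assert rep.precision == rep.recall == rep.f_score == 1.0

    def test_f_is_harmonic_mean(self):
        # precision 0.5, recall 1 -> F = 2/3
        truth = {"a": True, "b": False}
        preds = {"a": True, "b": True}
        rep = mk.benchmark(preds, truth)
        assert rep.precision == 0.5 and rep.recall == 1.0
        assert rep.f_score == pytest.approx(2 / 3)

    def test_counts_match_hand_computation(self):
        """TP=7 FP=3 FN=1 TN=9 -> metrics by direct arithmetic."""
        rep = mk.BenchmarkReport(tp=7, fp=3, fn=1, tn=9)
        assert rep.precision == pytest.approx(7 / 10)
        assert rep.recall == pytest.approx(7 / 8)
        assert rep.specificity == pytest.approx(9 / 12)
        assert rep.f_score == pytest.approx(2 * 0.7 * 0.875 / (0.7 + 0.875))
        assert rep.f_score <= max(rep.precision, rep.recall)

    def test_unannotated_positive_counts_as_false_negative(self):
        rep = mk.benchmark({}, {"a": True, "b": False})
        assert rep.fn == 1 and rep.tn == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mk.benchmark({}, {})


# ---------------------------------------------------------------------------
# Module evaluation


class TestModules:
    def test_ten_step_module(self):
        mod = mk.ModuleDefinition("M1", " ".join(f"K{i}" for i in range(10)),
                                  frozenset({"K0"}))
        genes = {f"K{i}" for i in range(8)}
        res = mk.evaluate_module(genes, mod)
        assert res.completeness == pytest.approx(0.8)
        assert res.present

    def test_diagnostic_gate_is_conjunctive(self):
        """Full completeness does not rescue a module whose diagnostic gene
        is missing."""
        mod = mk.ModuleDefinition("M2", "K1 K2", frozenset({"K9"}))
        res = mk.evaluate_module({"K1", "K2"}, mod)
        assert res.completeness == 1.0
        assert not res.present

    def test_completeness_at_threshold_not_present(self):
        mod = mk.ModuleDefinition("M3", " ".join(f"K{i}" for i in range(10)),
                                  frozenset({"K0"}))
        res = mk.evaluate_module({f"K{i}" for i in range(7)}, mod)
        assert res.completeness == pytest.approx(0.7)
        assert not res.present  # strict > 0.70

    def test_nested_expression_matches_truth_table(self):
        """'A (B,C) D' with hits {A, C}: steps A and (B OR C) satisfied, D
        not -> completeness 2/3."""
        mod = mk.ModuleDefinition("M4", "A (B,C) D", frozenset({"A"}))
        res = mk.evaluate_module({"A", "C"}, mod)
        assert res.n_steps == 3
        assert res.steps_satisfied == 2
        assert res.completeness == pytest.approx(2 / 3)

    def test_complex_and_optional_components(self):
        mod = mk.ModuleDefinition("M5", "A+B C-D", frozenset({"A"}))
        res = mk.evaluate_module({"A", "C"}, mod)  # A+B fails, C-D passes
        assert res.steps_satisfied == 1
        res2 = mk.evaluate_module({"A", "B", "C"}, mod)
        assert res2.steps_satisfied == 2

    def test_malformed_expression_reports_position(self):
        with pytest.raises(ValueError, match="position"):
            mk.parse_module_expression("A (B,C D")

    def test_empty_diagnostic_rejected(self):
        with pytest.raises(ValueError):
            mk.ModuleDefinition("M6", "A", frozenset())
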