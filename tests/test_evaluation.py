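"""Modified F1, Jaccard semantic similarity, confusion matrices, error
breakdown and frequency-binned diagnostics, each checked against an
independent brute-force oracle."""

import numpy as np
import pytest

from ontogru import evaluation as ev
from ontogru.datatypes import OntologyGraph, is_go_tag
from tests.conftest import brute_force_ancestors

CONCEPTS = ["GO:2", "GO:3", "GO:4", "GO:5", "GO:6"]
TAGS = (
    ["O", "EOS"]
    + [f"B-{c}" for c in CONCEPTS]
    + [f"I-{c}" for c in CONCEPTS]
)


def random_tag_seqs(rng, n_seqs=5, max_len=60):
    gold, pred = [], []
    for _ in range(n_seqs):
        n = int(rng.integers(1, max_len + 1))
        gold.append([TAGS[i] for i in rng.integers(0, len(TAGS), n)])
        pred.append([TAGS[i] for i in rng.integers(0, len(TAGS), n)])
    return gold, pred


def oracle_prf(gold, pred):
    """Independent positional tally of the modified F1."""
    tp = fp = fn = 0
    for g_seq, p_seq in zip(gold, pred):
        for g, p in zip(g_seq, p_seq):
            if g == p and g in ("O", "EOS"):
                continue
            if is_go_tag(p) and g == p:
                tp += 1
            if is_go_tag(p) and g != p:
                fp += 1
            if is_go_tag(g) and g != p:
                fn += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


# -- modified F1 ------------------------------------------------------------


def test_modified_f1_perfect():
    seqs = [["O", "B-GO:2", "I-GO:2", "EOS"]]
    assert ev.modified_f1(seqs, seqs) == (1.0, 1.0, 1.0)


def test_modified_f1_all_o_predictions():
    gold = [["B-GO:2", "O", "EOS"]]
    pred = [["O", "O", "EOS"]]
    assert ev.modified_f1(gold, pred) == (0.0, 0.0, 0.0)


def test_modified_f1_length_mismatch_rejected():
    with pytest.raises(ValueError):
        ev.modified_f1([["O", "O"]], [["O"]])


def test_modified_f1_matches_oracle_on_100_random_cases():
    rng = np.random.default_rng(7)
    for _ in range(100):
        gold, pred = random_tag_seqs(rng)
        assert ev.modified_f1(gold, pred) == pytest.approx(oracle_prf(gold, pred))


def test_prefix_must_match_for_exact_credit():
    gold = [["B-GO:2", "EOS"]]
    pred = [["I-GO:2", "EOS"]]
    p, r, f = ev.modified_f1(gold, pred)
    assert f == 0.0  # B-/I- prefix identity is part of an exact prediction


# -- Jaccard ----------------------------------------------------------------


def test_jaccard_identity(toy_ontology):
    assert ev.jaccard_similarity("GO:4", "GO:4", toy_ontology) == 1.0


def test_jaccard_chain_two_thirds(toy_ontology):
    # chain root(1) -> 2 -> 4: anc(4)={4,2,1}, anc(2)={2,1}
    assert ev.jaccard_similarity("GO:4", "GO:2", toy_ontology) == pytest.approx(2 / 3)


def test_jaccard_siblings_half():
    ids = ["GO:r", "GO:p", "GO:s1", "GO:s2"]
    onto = OntologyGraph(
        ids,
        {c: c for c in ids},
        {"GO:r": set(), "GO:p": {"GO:r"}, "GO:s1": {"GO:p"}, "GO:s2": {"GO:p"}},
        {c: "biological_process" for c in ids},
    )
    # anc(s1)={s1,p,r}, anc(s2)={s2,p,r}: 2 shared of 4 total
    assert ev.jaccard_similarity("GO:s1", "GO:s2", onto) == pytest.approx(0.5)


def test_jaccard_multi_parent_dag(toy_ontology):
    # anc(4)={4,2,1}, anc(5)={5,2,3,1} -> 2/5
    assert ev.jaccard_similarity("GO:4", "GO:5", toy_ontology) == pytest.approx(2 / 5)


def test_jaccard_unknown_concept_zero(toy_ontology):
    assert ev.jaccard_similarity("GO:4", "GO:999", toy_ontology) == 0.0


def random_dag(rng, n_nodes):
    concepts = [f"GO:{i}" for i in range(n_nodes)]
    parents = {concepts[0]: set()}
    for i in range(1, n_nodes):
        k = int(rng.integers(1, min(i, 3) + 1))
        parents[concepts[i]] = {
            concepts[int(j)] for j in rng.choice(i, size=k, replace=False)
        }
    return OntologyGraph(
        concepts, {c: c for c in concepts}, parents,
        {c: "biological_process" for c in concepts},
    )


def test_jaccard_matches_closure_oracle_on_random_dags():
    rng = np.random.default_rng(11)
    for n_nodes in (5, 17, 50):
        onto = random_dag(rng, n_nodes)
        ids = sorted(onto.concepts)
        for a in ids:
            for b in ids:
                anc_a = brute_force_ancestors(onto.parents, a)
                anc_b = brute_force_ancestors(onto.parents, b)
                expected = len(anc_a & anc_b) / len(anc_a | anc_b)
                got = ev.jaccard_similarity(a, b, onto)
                assert got == pytest.approx(expected)
                assert got == ev.jaccard_similarity(b, a, onto)  # symmetry
                assert 0.0 <= got <= 1.0


# -- semantic F1 ------------------------------------------------------------


def test_semantic_equals_modified_when_exact(toy_ontology):
    seqs = [["B-GO:4", "I-GO:4", "O", "EOS"]]
    assert ev.semantic_f1(seqs, seqs, toy_ontology) == (1.0, 1.0, 1.0)


def test_semantic_partial_credit_child_parent(toy_ontology):
    gold = [["B-GO:4", "EOS"]]
    pred = [["B-GO:2", "EOS"]]  # parent predicted for child: credit 2/3
    sp, sr, sf = ev.semantic_f1(gold, pred, toy_ontology)
    mp, mr, mf = ev.modified_f1(gold, pred)
    assert sp == sr == pytest.approx(2 / 3)
    assert sf == pytest.approx(2 / 3)
    assert mf == 0.0
    assert sf > mf


def test_semantic_zero_when_no_go_predictions(toy_ontology):
    gold = [["B-GO:4", "O", "EOS"]]
    pred = [["O", "O", "EOS"]]
    assert ev.semantic_f1(gold, pred, toy_ontology) == (0.0, 0.0, 0.0)


def test_semantic_bounds_dominate_modified_on_random_cases(toy_ontology):
    rng = np.random.default_rng(23)
    for _ in range(50):
        gold, pred = random_tag_seqs(rng, n_seqs=3, max_len=30)
        mp, mr, _ = ev.modified_f1(gold, pred)
        sp, sr, _ = ev.semantic_f1(gold, pred, toy_ontology)
        assert sp >= mp - 1e-12
        assert sr >= mr - 1e-12


# -- confusion matrix -------------------------------------------------------


def test_confusion_all_correct_mf(toy_ontology):
    onto = OntologyGraph(
        ["GO:9"], {"GO:9": "x"}, {"GO:9": set()}, {"GO:9": "molecular_function"}
    )
    seqs = [["B-GO:9", "I-GO:9", "EOS"], ["B-GO:9", "O", "EOS"]]
    cm = ev.confusion_by_namespace(seqs, seqs, onto)
    assert cm.counts["GO_MF"]["GO_MF"] == 3
    assert cm.total == 3
    assert cm.excluded == 3  # one O and two EOS predicted correctly


def test_confusion_bp_predicted_as_o(toy_ontology):
    gold = [["B-GO:4", "EOS"]]
    pred = [["O", "EOS"]]
    cm = ev.confusion_by_namespace(gold, pred, toy_ontology)
    assert cm.counts["GO_BP"]["O"] == 1
    assert cm.total == 1


def test_confusion_totals_match_tally_oracle(toy_ontology):
    rng = np.random.default_rng(3)
    gold, pred = random_tag_seqs(rng, n_seqs=4, max_len=40)
    cm = ev.confusion_by_namespace(gold, pred, toy_ontology)
    non_excluded = sum(
        1
        for g_seq, p_seq in zip(gold, pred)
        for g, p in zip(g_seq, p_seq)
        if not (g == p and g in ("O", "EOS"))
    )
    assert cm.total == non_excluded
    assert cm.excluded + cm.total == sum(len(s) for s in gold)


# -- error breakdown --------------------------------------------------------


def test_error_breakdown_perfect():
    seqs = [["B-GO:2", "O", "EOS"]]
    out = ev.error_breakdown(seqs, seqs)
    assert out == {"correct": 1.0, "go_to_o": 0.0, "o_to_go": 0.0, "go_to_wrong_go": 0.0}


def test_error_breakdown_constructed_counts():
    # 8 non-excluded positions: 2 of each outcome
    gold = [["B-GO:2"] * 2 + ["B-GO:3"] * 2 + ["O"] * 2 + ["B-GO:4"] * 2]
    pred = [["B-GO:2"] * 2 + ["O"] * 2 + ["B-GO:5"] * 2 + ["B-GO:6"] * 2]
    out = ev.error_breakdown(gold, pred)
    assert out == {
        "correct": 0.25,
        "go_to_o": 0.25,
        "o_to_go": 0.25,
        "go_to_wrong_go": 0.25,
    }
    assert sum(out.values()) == pytest.approx(1.0)


def test_error_breakdown_degenerate_all_o():
    seqs = [["O", "O", "EOS"]]
    out = ev.error_breakdown(seqs, seqs)
    assert out["correct"] == 1.0


# -- frequency bins ---------------------------------------------------------


def test_frequency_bin_assignment():
    gold = [["B-GO:2"] * 4 + ["EOS"]]
    pred = [["B-GO:2"] * 4 + ["EOS"]]
    bins = ev.frequency_binned_f1(gold, pred, {"GO:2": 15})
    assert bins["10-20"] == [1.0]
    assert bins["1-10"] == []


def test_frequency_bin_zero_tp_and_unseen():
    gold = [["B-GO:2", "B-GO:3", "EOS"]]
    pred = [["O", "B-GO:3", "EOS"]]
    bins = ev.frequency_binned_f1(gold, pred, {"GO:2": 3, "GO:3": 150})
    assert bins["1-10"] == [0.0]
    assert bins["100+"] == [1.0]
    bins2 = ev.frequency_binned_f1(gold, pred, {})
    assert sorted(bins2["unseen"]) == [0.0, 1.0]


def test_low_frequency_concepts_score_lower_in_constructed_corpus():
    """Mislabelled rare concepts drag the 1-10 bin below the 20+ bins."""
    gold, pred = [], []
    counts = {}
    rare = [f"GO:r{i}" for i in range(4)]
    frequent = [f"GO:f{i}" for i in range(4)]
    for c in rare:
        counts[c] = 4
        gold.append([f"B-{c}", "EOS"])
        pred.append(["O", "EOS"])  # rare concepts missed
    for c in frequent:
        counts[c] = 60
        gold.append([f"B-{c}", f"B-{c}", "EOS"])
        pred.append([f"B-{c}", f"B-{c}", "EOS"])
    bins = ev.frequency_binned_f1(gold, pred, counts)
    assert np.mean(bins["1-10"]) < np.mean(bins["50-100"])


# -- confidence table -------------------------------------------------------


class FakePred:
    def __init__(self, probs):
        self.probabilities = np.asarray(probs)
        p = self.probabilities
        self.entropy = float(-(p * np.log(np.clip(p, 1e-12, 1))).sum() / np.log(len(p)))


def test_confidence_table_rows_and_entropy():
    gold = [["B-GO:2", "O", "B-GO:3", "EOS"]]
    pred = [["B-GO:2", "B-GO:5", "O", "EOS"]]
    preds = [[
        FakePred([0.25, 0.25, 0.25, 0.25]),
        FakePred([0.997, 0.001, 0.001, 0.001]),
        FakePred([0.7, 0.1, 0.1, 0.1]),
        FakePred([0.4, 0.2, 0.2, 0.2]),
    ]]
    rows = ev.confidence_table(gold, pred, preds, {"GO:2": 9}, None)
    # three positions involve a GO tag on either side
    assert len(rows) == 3
    assert rows[0]["entropy"] == pytest.approx(1.0)
    assert rows[0]["correct"] is True
    assert rows[0]["frequency"] == 9
    assert rows[1]["entropy"] < 0.1
    assert rows[1]["correct"] is False


def test_confidence_row_count_matches_f1_denominators(toy_ontology):
    rng = np.random.default_rng(5)
    gold, pred = random_tag_seqs(rng, n_seqs=3, max_len=25)
    preds = [
        [FakePred([0.5, 0.3, 0.1, 0.1]) for _ in seq] for seq in gold
    ]
    rows = ev.confidence_table(gold, pred, preds, {}, None)
    n_go_positions = sum(
        1
        for g_seq, p_seq in zip(gold, pred)
        for g, p in zip(g_seq, p_seq)
        if is_go_tag(g) or is_go_tag(p)
    )
    assert len(rows) == n_go_positions
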