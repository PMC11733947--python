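"""Synthetic generator and evaluation metrics against independent oracles."""

import math

import numpy as np
import pytest

from pkasense.asa import STATUS_SCORED, AsaProfile, AtomScore
from pkasense.benchlab import (
    DEFAULT_ACID_RULES,
    DEFAULT_BASE_RULES,
    DEFAULT_RULES,
    ACID_SENTINEL,
    BASE_SENTINEL,
    asa_site_metrics,
    bin_width_sweep,
    brier,
    evaluate,
    generate_synthetic_set,
    lco_split,
    mae,
    pair_direction_accuracy,
    pathological_confidence,
    records_to_frame,
)
from pkasense.chemgraph import parse_smiles
from pkasense.pka_mtc import BinScheme, TrainingConfig, encode_label, expected_pka


def _random_distributions(n, k, seed):
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(k), size=n)


class TestGenerator:
    def test_counts_and_determinism(self):
        records = generate_synthetic_set(DEFAULT_ACID_RULES, n=100, negative_fraction=0.2, seed=7)
        assert len(records) == 100
        assert sum(r.group == "negative" for r in records) == 20
        again = generate_synthetic_set(DEFAULT_ACID_RULES, n=100, negative_fraction=0.2, seed=7)
        assert records_to_frame(records).equals(records_to_frame(again))

    def test_labels_within_four_sd_of_group_mean(self):
        records = generate_synthetic_set(DEFAULT_ACID_RULES, n=200, negative_fraction=0.0, seed=1)
        means = {r.name: (r.pka_mean, r.pka_sd) for r in DEFAULT_ACID_RULES}
        for rec in records:
            mean, sd = means[rec.group]
            assert abs(rec.pka - mean) <= 4 * sd

    def test_negatives_carry_task_sentinels(self):
        acid = generate_synthetic_set(DEFAULT_ACID_RULES, n=50, negative_fraction=0.5, seed=2)
        base = generate_synthetic_set(DEFAULT_BASE_RULES, n=50, negative_fraction=0.5, seed=2)
        assert {r.pka for r in acid if r.group == "negative"} == {ACID_SENTINEL}
        assert {r.pka for r in base if r.group == "negative"} == {BASE_SENTINEL}

    def test_annotated_atom_matched_by_group_pattern(self):
        rules = {r.name: r for r in DEFAULT_RULES}
        for rec in generate_synthetic_set(DEFAULT_RULES, n=120, negative_fraction=0.0, seed=3):
            matches = rec.graph.substruct_matches(rules[rec.group].smarts)
            assert len(matches) == 1
            assert rec.site_atom in matches[0]
            assert set(rec.site_atoms) <= set(matches[0])
            assert rec.site_atom in rec.graph.heteroatom_indices()

    def test_molecule_sizes_in_druglike_window(self):
        for rec in generate_synthetic_set(DEFAULT_RULES, n=150, seed=4):
            assert 3 <= rec.graph.n_heavy_atoms <= 12

    def test_each_rule_matches_its_own_exemplar(self):
        for rule in DEFAULT_RULES:
            exemplar = parse_smiles(rule.exemplar)
            assert exemplar.matches(rule.smarts), rule.name

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            generate_synthetic_set(DEFAULT_ACID_RULES, n=0)
        with pytest.raises(ValueError):
            generate_synthetic_set([], n=10)
        with pytest.raises(ValueError):
            generate_synthetic_set(DEFAULT_ACID_RULES, n=10, negative_fraction=1.0)


class TestMae:
    def test_one_hot_at_true_median_is_zero(self):
        scheme = BinScheme(1.0)
        records = [(encode_label(4.5, scheme), 4.5), (encode_label(9.5, scheme), 9.5)]
        assert mae(records, scheme) == 0.0

    def test_single_record_offset(self):
        scheme = BinScheme(1.0)
        assert mae([(encode_label(4.2, scheme), 6.5)], scheme) == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        scheme = BinScheme(1.0)
        dists = _random_distributions(10, scheme.n_bins, seed=5)
        trues = np.random.default_rng(6).uniform(-1, 13, size=10)
        records = [(dists[i], trues[i]) for i in range(10)]
        oracle = sum(
            abs(sum(m * p for m, p in zip(scheme.medians, d)) - t) for d, t in records
        ) / len(records)
        assert mae(records, scheme) == pytest.approx(oracle, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mae([], BinScheme(1.0))


class TestBrier:
    def test_perfect_one_hot_is_zero(self):
        scheme = BinScheme(1.0)
        label = encode_label(4.2, scheme)
        assert brier([(label.copy(), label)]) == 0.0

    def test_uniform_prediction_analytic_value(self):
        k = 14
        dist = np.full(k, 1 / k)
        label = np.zeros(k)
        label[3] = 1.0
        assert brier([(dist, label)]) == pytest.approx(1 - 1 / k, abs=1e-12)

    def test_maximally_wrong_one_hot_is_two(self):
        k = 14
        pred, label = np.zeros(k), np.zeros(k)
        pred[0], label[5] = 1.0, 1.0
        assert brier([(pred, label)]) == 2.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        scheme = BinScheme(1.0)
        dists = _random_distributions(10, scheme.n_bins, seed=9)
        records = [
            (dists[i], encode_label(rng.uniform(-1, 13), scheme)) for i in range(10)
        ]
        oracle = sum(
            sum((p - r) ** 2 for p, r in zip(dist, label)) for dist, label in records
        ) / len(records)
        assert brier(records) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            brier([(np.ones(3) / 3, np.zeros(4))])


class TestPathologicalConfidence:
    def test_rule_on_constructed_fixture(self):
        scheme = BinScheme(1.0)
        broad = np.zeros(scheme.n_bins)
        broad[[2, 3, 10, 11]] = 0.25  # sigma ~ 3.9
        records = [
            (encode_label(4.2, scheme), 4.5),   # confident, correct
            (encode_label(4.2, scheme), 8.0),   # confident, err 3.5 -> flagged
            (broad, 3.0),                        # high error but low confidence
            (encode_label(11.0, scheme), 9.0),  # confident, err 2.5 -> flagged
            (encode_label(2.2, scheme), 2.4),   # confident, small error
            (broad, 7.0),                        # low confidence, near mean
        ]
        assert pathological_confidence(records, scheme) == [1, 3]

    def test_thresholds_are_parameters(self):
        scheme = BinScheme(1.0)
        records = [(encode_label(4.2, scheme), 5.2)]  # err 0.7
        assert pathological_confidence(records, scheme) == []
        assert pathological_confidence(records, scheme, err_min=0.5) == [0]


class TestLcoSplit:
    def test_one_fold_per_pattern(self):
        records = generate_synthetic_set(DEFAULT_RULES, n=60, negative_fraction=0.0, seed=10)
        patterns = ["[CX3](=[OX1])[OX2H1]", "[NX3H2]"]
        folds = lco_split(records, patterns)
        assert [f.pattern for f in folds] == patterns
        for fold in folds:
            assert len(fold.held_out) + len(fold.training) == len(records)
            assert all(r.graph.matches(fold.pattern) for r in fold.held_out)
            assert not any(r.graph.matches(fold.pattern) for r in fold.training)

    def test_record_matching_two_patterns_held_out_twice(self):
        class Rec:
            def __init__(self, smiles):
                self.graph = parse_smiles(smiles)

        rec = Rec("OC(=O)c1ccc(O)cc1")  # both carboxylic acid and phenol
        folds = lco_split([rec], ["[CX3](=[OX1])[OX2H1]", "[OX2H1][c]"])
        assert all(len(f.held_out) == 1 for f in folds)

    def test_unmatched_pattern_warns_not_errors(self, caplog):
        records = generate_synthetic_set(DEFAULT_ACID_RULES, n=10, seed=11)
        with caplog.at_level("WARNING"):
            folds = lco_split(records, ["[Po]"])
        assert folds[0].held_out == []
        assert "matches no record" in caplog.text

    def test_empty_pattern_list_raises(self):
        with pytest.raises(ValueError):
            lco_split([], [])


class TestPairDirectionAccuracy:
    PAIRS = [
        (parse_smiles("CC(=O)O"), parse_smiles("Oc1ccccc1"), 4.2, 9.9),
        (parse_smiles("CS"), parse_smiles("CC(=O)O"), 10.5, 4.2),
        (parse_smiles("CCO"), parse_smiles("CC(=O)O"), 16.0, 4.2),
    ]

    def test_oracle_predictor_scores_one(self):
        truth = {p[0].canonical_smiles: p[2] for p in self.PAIRS}
        truth.update({p[1].canonical_smiles: p[3] for p in self.PAIRS})
        assert pair_direction_accuracy(lambda m: truth[m.canonical_smiles], self.PAIRS) == 1.0

    def test_constant_predictor_scores_zero(self):
        assert pair_direction_accuracy(lambda m: 7.0, self.PAIRS) == 0.0

    def test_partial_concordance(self):
        # flip the phenol prediction (appears in the first pair only) -> 2/3
        truth = {p[0].canonical_smiles: p[2] for p in self.PAIRS}
        truth.update({p[1].canonical_smiles: p[3] for p in self.PAIRS})
        flipped = dict(truth)
        flipped[self.PAIRS[0][1].canonical_smiles] = 0.0
        assert pair_direction_accuracy(
            lambda m: flipped[m.canonical_smiles], self.PAIRS
        ) == pytest.approx(2 / 3)

    def test_equal_true_values_raise(self):
        bad = [(parse_smiles("C"), parse_smiles("CC"), 5.0, 5.0)]
        with pytest.raises(ValueError):
            pair_direction_accuracy(lambda m: 1.0, bad)


def _profile(scores):
    return AsaProfile(
        name="p",
        entries=[
            AtomScore(i, "O", math.log(s / 5 + 1) if s else 0.0, s, STATUS_SCORED)
            for i, s in scores.items()
        ],
    )


class TestAsaSiteMetrics:
    def test_perfect_separation(self):
        profiles = [
            (_profile({0: 100.0, 1: 0.0}), {0}),
            (_profile({2: 80.0, 3: 0.0, 4: 0.0}), {2}),
        ]
        m = asa_site_metrics(profiles)
        assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.top1_accuracy == 1.0

    def test_all_zero_scores(self):
        m = asa_site_metrics([(_profile({0: 0.0, 1: 0.0}), {0})])
        assert m.sensitivity == 0.0 and m.specificity == 1.0 and m.top1_accuracy == 0.0

    def test_hand_tabulated_confusion_counts(self):
        # molecule A: true site 0 scored low (FN), decoy 1 scored high (FP)
        # molecule B: true site 2 scored high (TP), decoy 3 low (TN)
        profiles = [
            (_profile({0: 0.5, 1: 3.0}), {0}),
            (_profile({2: 9.0, 3: 0.0}), {2}),
        ]
        m = asa_site_metrics(profiles, cutoff=1.5)
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 1, 1, 1)
        assert m.sensitivity == 0.5 and m.specificity == 0.5 and m.npv == 0.5
        assert m.top1_accuracy == 0.5

    def test_unannotated_profile_raises(self):
        with pytest.raises(ValueError):
            asa_site_metrics([(_profile({0: 1.0}), None)])


class TestEndToEndEvaluation:
    def test_report_fields(self, acid_predictor, acid_records):
        positives = [r for r in acid_records if r.group != "negative"][:50]
        report = evaluate(
            acid_predictor, [r.graph for r in positives], [r.pka for r in positives]
        )
        assert report.n == 50
        assert report.mae >= 0 and 0 <= report.brier <= 2
        assert set(report.records.columns) >= {"expected_pka", "sigma", "abs_error"}
        assert all(0 <= i < 50 for i in report.pathological)

    def test_bin_width_sweep_runs_all_widths(self):
        train = generate_synthetic_set(DEFAULT_ACID_RULES, n=80, seed=14)
        test = generate_synthetic_set(DEFAULT_ACID_RULES, n=30, negative_fraction=0.0, seed=15)
        cfg = TrainingConfig(epochs=5, hidden_units=32, seed=14)
        maes = bin_width_sweep(train, test, widths=(0.5, 1.0, 2.0, 3.0), base_config=cfg)
        assert set(maes) == {0.5, 1.0, 2.0, 3.0}
        assert all(v >= 0 for v in maes.values())
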