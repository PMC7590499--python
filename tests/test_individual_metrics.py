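"""Confusion counts, binary metrics, kappa and chance-corrected concordance."""

from fractions import Fraction

import numpy as np
import pytest

from vaval.data_model import NON_CONCLUSIVE, StudyGroup, VAOutput
from vaval.individual_metrics import (
    AgreementSummary,
    ConfusionCounts,
    agreement_summary,
    binary_metrics,
    ccc_per_cause,
    ccc_from_labels,
    cohen_kappa,
    confusion_by_cause,
    confusion_matrix,
    counts_from_matrix,
    overall_ccc,
    top_cause,
)
from vaval.study_tables import load_study_confusion_counts

from conftest import hard_output, make_record, toy_dictionary


def exact_percentage(num: int, den: int):
    """Oracle: exact rational percentage with round-half-to-even display."""
    if den == 0:
        return None, "N/A"
    frac = Fraction(100 * num, den)
    floor, rem = divmod(frac, 1)
    if rem > Fraction(1, 2):
        disp = int(floor) + 1
    elif rem < Fraction(1, 2):
        disp = int(floor)
    else:
        disp = int(floor) + (int(floor) % 2)
    return float(frac), disp


class TestTopCause:
    def test_first_assigned(self):
        assert top_cause(VAOutput(assigned=(("A", 0.9),), nonconclusive_mass=0.1)) == "A"
        assert (
            top_cause(VAOutput(assigned=(("A", 0.5), ("B", 0.3)), nonconclusive_mass=0.2))
            == "A"
        )

    def test_empty_report_is_nonconclusive(self):
        assert top_cause(VAOutput(assigned=(), nonconclusive_mass=1.0)) == NON_CONCLUSIVE


class TestConfusionCounts:
    def test_published_neonatal_infection_counts_reconstructed(self, dictionary):
        # 41 neonates: 27 gold infections of which 25 predicted infections,
        # 2 predicted elsewhere; 12 non-infection deaths predicted infections.
        records, outputs = [], []
        for i in range(25):
            records.append(make_record(i, "infections", StudyGroup.NEONATE))
            outputs.append(hard_output("infections"))
        for i in range(2):
            records.append(make_record(25 + i, "infections", StudyGroup.NEONATE))
            outputs.append(hard_output("preterm_complications"))
        for i in range(12):
            records.append(make_record(27 + i, "congenital_malformations", StudyGroup.NEONATE))
            outputs.append(hard_output("infections"))
        for i in range(2):
            records.append(make_record(39 + i, "other_diseases", StudyGroup.NEONATE))
            outputs.append(hard_output("other_diseases"))
        counts = {c.cause: c for c in confusion_by_cause(records, outputs, dictionary)}
        inf = counts["infections"]
        assert (inf.tp, inf.tn, inf.fp, inf.fn) == (25, 2, 12, 2)
        disp = binary_metrics(inf).display()
        assert disp == {"sensitivity": 93, "specificity": 14, "ppv": 68, "npv": 50}

    def test_perfect_predictor_no_errors(self, dictionary):
        causes = dictionary.substantive(StudyGroup.CHILD)
        records = [make_record(i, c, StudyGroup.CHILD) for i, c in enumerate(causes)]
        outputs = [hard_output(c) for c in causes]
        for c in confusion_by_cause(records, outputs, dictionary):
            assert c.fp == 0 and c.fn == 0

    def test_counts_consistency_random_cohorts(self, dictionary):
        # brute-force recount oracle on random gold/predicted labels
        rng = np.random.default_rng(13)
        causes = dictionary.for_group(StudyGroup.MATERNAL)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            gold = rng.choice(causes[:-1], size=n)
            pred = rng.choice(causes, size=n)
            records = [make_record(i, g, StudyGroup.MATERNAL) for i, g in enumerate(gold)]
            outputs = [hard_output(p) for p in pred]
            matrix = confusion_matrix(records, outputs, dictionary)
            for c in counts_from_matrix(matrix):
                assert c.total == n
                assert c.tp == sum(1 for g, p in zip(gold, pred) if g == p == c.cause)
                assert c.n == sum(1 for g in gold if g == c.cause)
            assert sum(
                cc.tp for cc in counts_from_matrix(matrix)
            ) == np.trace(matrix.to_numpy())


class TestBinaryMetrics:
    @pytest.mark.parametrize(
        "row", load_study_confusion_counts().to_dict("records"),
        ids=lambda r: f"{r['group']}-{r['cause']}",
    )
    def test_reproduces_published_percentages(self, row):
        m = binary_metrics(
            ConfusionCounts(row["cause"], row["tp"], row["tn"], row["fp"], row["fn"])
        )
        disp = m.display()
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            expected = row[name]
            assert str(disp[name]) == str(expected)

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(1000):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 60, size=4))
            m = binary_metrics(ConfusionCounts("x", tp, tn, fp, fn))
            disp = m.display()
            for (num, den), name in (
                ((tp, tp + fn), "sensitivity"),
                ((tn, tn + fp), "specificity"),
                ((tp, tp + fp), "ppv"),
                ((tn, tn + fn), "npv"),
            ):
                exact, exact_disp = exact_percentage(num, den)
                value = getattr(m, name)
                if exact is None:
                    assert value is None and disp[name] == "N/A"
                else:
                    assert value == pytest.approx(exact, abs=1e-9)
                    assert disp[name] == exact_disp


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([5, 3, 2])) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # rows proportional to column margins
        m = np.outer([10, 20, 30], [0.5, 0.3, 0.2])
        assert cohen_kappa(m) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        # p_o = 27/41, p_e = (27*37 + 14*4)/41^2
        m = np.array([[25, 2], [12, 2]])
        p_o = Fraction(27, 41)
        p_e = Fraction(27 * 37 + 14 * 4, 41**2)
        expected = float((p_o - p_e) / (1 - p_e))
        assert cohen_kappa(m) == pytest.approx(expected, abs=1e-15)
        assert cohen_kappa(m) == pytest.approx(0.083, abs=5e-4)

    def test_degenerate_single_category_is_nan(self):
        m = np.zeros((3, 3))
        m[1, 1] = 10
        assert np.isnan(cohen_kappa(m))

    def test_matches_sklearn_on_random_matrices(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(15)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 200))
            y1 = rng.integers(0, k, size=n)
            y2 = rng.integers(0, k, size=n)
            m = np.zeros((k, k), dtype=int)
            np.add.at(m, (y1, y2), 1)
            ref = cohen_kappa_score(y1, y2, labels=list(range(k)))
            assert cohen_kappa(m) == pytest.approx(ref, abs=1e-12)


class TestCcc:
    def test_formula_endpoints(self):
        assert ccc_per_cause(1.0, 6) == pytest.approx(1.0)
        assert ccc_per_cause(1.0 / 6.0, 6) == pytest.approx(0.0, abs=1e-12)
        assert ccc_per_cause(0.0, 6) == pytest.approx(-0.2)

    def test_requires_two_causes(self):
        from vaval.data_model import DataValidationError

        with pytest.raises(DataValidationError):
            ccc_per_cause(0.5, 1)

    def test_identity_predictor_scores_one(self, dictionary):
        rng = np.random.default_rng(16)
        causes = dictionary.substantive(StudyGroup.MATERNAL)
        gold = rng.choice(causes, size=80)
        records = [make_record(i, g, StudyGroup.MATERNAL) for i, g in enumerate(gold)]
        outputs = [hard_output(g) for g in gold]
        assert overall_ccc(records, outputs, dictionary) == pytest.approx(1.0)

    def test_single_cause_half_sensitivity(self):
        # one eligible cause, sensitivity 0.5, K=4 -> (0.5 - 0.25)/0.75
        gold = ["a"] * 4
        pred = ["a", "a", "b", "b"]
        assert ccc_from_labels(gold, pred, ["a", "b", "c", "d"], 4) == pytest.approx(1 / 3)

    def test_uniform_random_predictor_is_chance_level(self):
        rng = np.random.default_rng(17)
        causes = [f"c{i}" for i in range(5)]
        gold = rng.choice(causes, size=10_000)
        pred = rng.choice(causes, size=10_000)
        assert abs(ccc_from_labels(gold, pred, causes, 5)) < 0.02


class TestAgreement:
    def test_all_first_match(self):
        records = [make_record(i, "infections") for i in range(5)]
        outputs = [hard_output("infections", 0.9)] * 5
        s = agreement_summary(records, outputs)
        assert (s.n_first_match, s.n_second_match) == (5, 0)
        assert np.isnan(s.mean_second_likelihood)

    def test_second_cause_match_counted_with_likelihood(self):
        records = [make_record(0, "other_diseases")]
        outputs = [
            VAOutput(
                assigned=(("infections", 0.5), ("other_diseases", 0.4)),
                nonconclusive_mass=0.1,
            )
        ]
        s = agreement_summary(records, outputs)
        assert (s.n_first_match, s.n_second_match) == (0, 1)
        assert s.mean_second_likelihood == pytest.approx(0.4)

    def test_record_contributes_to_at_most_one_counter(self):
        # exhaustive over toy outputs with both positions matching
        records = [make_record(0, "a")]
        outputs = [
            VAOutput(assigned=(("a", 0.5), ("a", 0.3)), nonconclusive_mass=0.2)
        ]
        s = agreement_summary(records, outputs)
        assert s.n_first_match + s.n_second_match == 1
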