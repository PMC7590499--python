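"""Posterior arithmetic, prevalence adjustment and cause reporting."""

import numpy as np
import pytest

from vaval.bayes_engine import (
    PrevalenceSetting,
    ProbBase,
    ReportingRule,
    apply_prevalence,
    code_cohort,
    compute_posterior,
    load_probbase,
    report_causes,
    write_probbase,
)
from vaval.data_model import DeathRecord, StudyGroup, DataValidationError

from conftest import make_record


def probbase_2x1(p1=0.8, p2=0.2):
    return ProbBase(
        causes=("c1", "c2"),
        indicators=("i_0001",),
        prior=np.array([0.5, 0.5]),
        conditional=np.array([[p1], [p2]]),
    )


def random_probbase(rng, k=4, n_ind=12):
    return ProbBase(
        causes=tuple(f"c{j}" for j in range(k)),
        indicators=tuple(f"i_{i}" for i in range(n_ind)),
        prior=rng.dirichlet(np.ones(k)),
        conditional=rng.uniform(0.05, 0.95, size=(k, n_ind)),
    )


def random_record(rng, rid, n_ind=12):
    return make_record(
        rid, "infections", indicators=rng.choice([1, 0, -1], size=n_ind).astype(np.int8)
    )


class TestPosterior:
    def test_single_yes_indicator_bayes_rule(self):
        rec = make_record("r", "infections", indicators=np.array([1], dtype=np.int8))
        post = compute_posterior(rec, probbase_2x1())
        np.testing.assert_allclose(post, [0.8, 0.2], atol=1e-12)

    def test_no_yes_answers_returns_prior(self):
        rng = np.random.default_rng(0)
        pb = random_probbase(rng)
        rec = make_record("r", "infections", indicators=np.zeros(12, dtype=np.int8))
        np.testing.assert_allclose(compute_posterior(rec, pb), pb.prior, atol=1e-12)

    def test_constant_conditionals_return_prior(self):
        pb = ProbBase(
            causes=("a", "b", "c"),
            indicators=tuple(f"i{j}" for j in range(6)),
            prior=np.array([0.5, 0.3, 0.2]),
            conditional=np.full((3, 6), 0.37),
        )
        rec = make_record("r", "infections", indicators=np.ones(6, dtype=np.int8))
        np.testing.assert_allclose(compute_posterior(rec, pb), pb.prior, atol=1e-12)

    def test_missing_and_no_are_equivalent(self):
        rng = np.random.default_rng(1)
        pb = random_probbase(rng)
        yes = (rng.random(12) < 0.3).astype(np.int8)
        a = make_record("a", "infections", indicators=yes)
        b_ind = yes.copy()
        b_ind[yes == 0] = -1
        b = make_record("b", "infections", indicators=b_ind)
        np.testing.assert_allclose(
            compute_posterior(a, pb), compute_posterior(b, pb), atol=1e-12
        )

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        for i in range(50):
            pb = random_probbase(rng)
            post = compute_posterior(random_record(rng, i), pb)
            assert abs(post.sum() - 1.0) < 1e-12

    def test_log_domain_matches_direct_product(self):
        # independent oracle: direct-product Bayes on small instances
        rng = np.random.default_rng(3)
        for i in range(100):
            pb = random_probbase(rng, k=3, n_ind=8)
            rec = random_record(rng, i, n_ind=8)
            yes = rec.indicators == 1
            direct = pb.prior * np.prod(pb.conditional[:, yes], axis=1)
            direct = direct / direct.sum()
            np.testing.assert_allclose(
                compute_posterior(rec, pb), direct, atol=1e-9
            )

    def test_invariant_to_indicator_permutation(self):
        rng = np.random.default_rng(4)
        pb = random_probbase(rng)
        rec = random_record(rng, "r")
        perm = rng.permutation(12)
        pb_perm = ProbBase(
            causes=pb.causes,
            indicators=tuple(pb.indicators[i] for i in perm),
            prior=pb.prior,
            conditional=pb.conditional[:, perm],
        )
        rec_perm = make_record("r", "infections", indicators=rec.indicators[perm])
        np.testing.assert_allclose(
            compute_posterior(rec, pb), compute_posterior(rec_perm, pb_perm), atol=1e-12
        )

    def test_indicator_length_mismatch_raises(self):
        pb = probbase_2x1()
        rec = make_record("r", "infections", indicators=np.zeros(3, dtype=np.int8))
        with pytest.raises(DataValidationError, match="indicator"):
            compute_posterior(rec, pb)


class TestPrevalence:
    def tagged_probbase(self, priors):
        k = len(priors)
        return ProbBase(
            causes=tuple(f"c{j}" for j in range(k)),
            indicators=("i",),
            prior=np.array(priors, dtype=float),
            conditional=np.full((k, 1), 0.5),
            prevalence_tags={"malaria": frozenset({"c0"})},
        )

    def test_high_levels_leave_probbase_unchanged(self):
        pb = self.tagged_probbase([0.2, 0.2, 0.2, 0.2, 0.2])
        out = apply_prevalence(pb, PrevalenceSetting(malaria="high", hiv="high"))
        np.testing.assert_allclose(out.prior, pb.prior, atol=1e-15)

    def test_low_malaria_rescales_and_renormalises(self):
        pb = self.tagged_probbase([0.2, 0.2, 0.2, 0.2, 0.2])
        out = apply_prevalence(pb, PrevalenceSetting(malaria="low", hiv="high"))
        # weight 0.02 against four 0.2s
        expected = np.array([0.02, 0.2, 0.2, 0.2, 0.2])
        np.testing.assert_allclose(out.prior, expected / expected.sum(), atol=1e-12)

    def test_very_low_never_beats_low_for_tagged_cause(self):
        rng = np.random.default_rng(5)
        pb = ProbBase(
            causes=("malaria_cause", "other1", "other2"),
            indicators=tuple(f"i{j}" for j in range(10)),
            prior=np.array([0.4, 0.3, 0.3]),
            conditional=rng.uniform(0.1, 0.9, size=(3, 10)),
            prevalence_tags={"malaria": frozenset({"malaria_cause"})},
        )
        low = apply_prevalence(pb, PrevalenceSetting(malaria="low"))
        very_low = apply_prevalence(pb, PrevalenceSetting(malaria="very_low"))
        for i in range(50):
            rec = random_record(rng, i, n_ind=10)
            p_low = compute_posterior(rec, low)[0]
            p_very_low = compute_posterior(rec, very_low)[0]
            assert p_very_low <= p_low + 1e-12


class TestReporting:
    causes = ("c1", "c2", "c3", "c4")

    def test_only_top_clears_relative_threshold(self):
        out = report_causes(
            np.array([0.9, 0.05, 0.03, 0.02]), ReportingRule(), self.causes
        )
        assert out.assigned == (("c1", 0.9),)
        assert out.nonconclusive_mass == pytest.approx(0.1)

    def test_below_top_threshold_gives_empty_report(self):
        out = report_causes(
            np.array([0.3, 0.3, 0.2, 0.2]), ReportingRule(), self.causes
        )
        assert out.assigned == ()
        assert out.nonconclusive_mass == 1.0

    def test_second_cause_reported_when_it_clears_half_of_top(self):
        out = report_causes(
            np.array([0.5, 0.3, 0.1, 0.1]), ReportingRule(), self.causes
        )
        assert out.assigned == (("c1", 0.5), ("c2", 0.3))
        assert out.nonconclusive_mass == pytest.approx(0.2)

    def test_mass_conservation_random_posteriors(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            post = rng.dirichlet(np.ones(4))
            out = report_causes(post, ReportingRule(), self.causes)
            total = sum(l for _, l in out.assigned) + out.nonconclusive_mass
            assert abs(total - 1.0) < 1e-9

    def test_ties_broken_by_dictionary_order(self):
        out = report_causes(
            np.array([0.45, 0.45, 0.05, 0.05]), ReportingRule(), self.causes
        )
        assert out.assigned[0][0] == "c1"


class TestCohort:
    def test_empty_cohort(self):
        assert code_cohort([], probbase_2x1()) == []

    def test_pathognomonic_probbase_recovers_gold(self, toy_dict5):
        from vaval.synthetic_data import make_probbase, simulate_cohort, SimulationSpec

        pb = make_probbase(toy_dict5, 50, 1.0, seed=7)
        spec = SimulationSpec(
            group_sizes={StudyGroup.OTHER_ADULT: 60},
            true_csmf={
                StudyGroup.OTHER_ADULT: {c: 0.2 for c in toy_dict5.substantive(StudyGroup.OTHER_ADULT)}
            },
            n_indicators=50,
            n_unobservable=0,
            n_unobservable_secondary=0,
            seed=7,
        )
        records = simulate_cohort(spec, pb, toy_dict5)
        outputs = code_cohort(records, pb)
        for rec, out in zip(records, outputs):
            assert out.assigned and out.assigned[0][0] == rec.cda_cause

    def test_order_equivariance(self):
        rng = np.random.default_rng(8)
        pb = random_probbase(rng)
        records = [random_record(rng, i) for i in range(20)]
        outputs = code_cohort(records, pb)
        perm = list(rng.permutation(20))
        outputs_perm = code_cohort([records[i] for i in perm], pb)
        assert outputs_perm == [outputs[i] for i in perm]


class TestProbbaseCsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        pb = random_probbase(rng)
        path = tmp_path / "probbase.csv"
        write_probbase(pb, path)
        back = load_probbase(path)
        assert back.causes == pb.causes
        assert back.indicators == pb.indicators
        np.testing.assert_allclose(back.prior, pb.prior, rtol=1e-10)
        np.testing.assert_allclose(back.conditional, pb.conditional, rtol=1e-10)

    def test_conditionals_clamped_at_load(self, tmp_path):
        pb = ProbBase(
            causes=("a", "b"),
            indicators=("i",),
            prior=np.array([0.5, 0.5]),
            conditional=np.array([[0.0], [1.0]]),
        )
        assert pb.conditional[0, 0] > 0.0
        assert pb.conditional[1, 0] < 1.0
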