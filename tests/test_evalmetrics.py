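
import numpy as np
import pytest

from protfun.evalmetrics import (TAU_GRID, PrCurve, auprc, auprc_points,
                                 evaluate, fmax, frequency_restricted_iauprc,
                                 iauprc, iauprc_points, pr_rc_curve, smin)
from protfun.ontology import IcTable, propagate_scores

from conftest import random_dag
from oracle import (brute_auprc, brute_curve, brute_fmax, brute_iauprc,
                    brute_smin)


def random_instance(rng, n_proteins=4, n_terms=10):
    """A toy DAG, propagated truth, and score-propagated predictions."""
    dag = random_dag(rng, n_terms)
    terms = sorted(dag.terms)
    truth = {}
    for i in range(n_proteins):
        t = terms[int(rng.integers(len(terms)))]
        truth[f"p{i}"] = set(dag.ancestors(t))
    preds = {
        p: {t: float(np.round(rng.random(), 2)) for t in terms
            if rng.random() < 0.7}
        for p in truth
    }
    preds = propagate_scores(dag, preds)
    return dag, truth, preds


def curve_of(pr, rc):
    n = len(pr)
    return PrCurve(taus=TAU_GRID[:n], pr=np.array(pr), rc=np.array(rc),
                   m=np.ones(n, dtype=int), n_e=1)


class TestPrRcCurve:
    def test_perfect_predictor_flat_ones(self, chain_dag):
        truth = {"p1": {"root", "A", "B"}, "p2": {"root", "A"}}
        preds = {"p1": {"A": 1.0, "B": 1.0}, "p2": {"A": 1.0}}
        curve = pr_rc_curve(preds, truth, dag=chain_dag)
        # tau = 0 predicts the whole vocabulary, so precision dips there
        assert np.allclose(curve.pr[1:], 1.0)
        assert np.allclose(curve.rc, 1.0)
        assert curve.n_e == 2

    def test_empty_predictions_degenerate(self, chain_dag):
        truth = {"p1": {"root", "A"}}
        curve = pr_rc_curve({}, truth, dag=chain_dag)
        assert np.allclose(curve.rc[1:], 0.0)
        assert (curve.m[1:] == 0).all()
        assert np.allclose(curve.pr[1:], 0.0)
        assert curve.rc[0] == 1.0  # tau=0 predicts everything

    def test_protein_with_empty_truth_excluded(self, chain_dag, caplog):
        truth = {"p1": {"root", "A"}, "weird": {"root"}}  # root-only = empty
        with caplog.at_level("WARNING"):
            curve = pr_rc_curve({}, truth, dag=chain_dag)
        assert curve.n_e == 1
        assert "weird" in caplog.text

    def test_matches_brute_force_on_handcrafted_instance(self, diamond_dag):
        truth = {"p1": {"root", "A", "C", "B"}, "p2": {"root", "A"}}
        preds = propagate_scores(diamond_dag, {
            "p1": {"B": 0.9, "C": 0.4},
            "p2": {"A": 0.6, "B": 0.3},
        })
        curve = pr_rc_curve(preds, truth, dag=diamond_dag)
        bpr, brc, bm, bn = brute_curve(preds, truth, diamond_dag.terms,
                                       diamond_dag.root)
        assert np.allclose(curve.pr, bpr)
        assert np.allclose(curve.rc, brc)
        assert np.array_equal(curve.m, bm)
        assert curve.n_e == bn

    def test_recall_non_increasing(self, rng):
        dag, truth, preds = random_instance(rng)
        curve = pr_rc_curve(preds, truth, dag=dag)
        assert (np.diff(curve.rc) <= 1e-12).all()


class TestFmax:
    def test_perfect_curve(self, chain_dag):
        truth = {"p1": {"root", "A", "B"}}
        preds = {"p1": {"A": 1.0, "B": 1.0}}
        f, tau = fmax(pr_rc_curve(preds, truth, dag=chain_dag))
        assert f == pytest.approx(1.0)

    def test_harmonic_mean_of_equal_halves(self):
        curve = curve_of([0.5, 0.5], [0.5, 0.5])
        f, tau = fmax(curve)
        assert f == pytest.approx(0.5)
        assert tau == 0.0  # tie broken toward the smallest threshold

    def test_degenerate_curve_gives_zero(self):
        curve = PrCurve(taus=TAU_GRID, pr=np.zeros(101), rc=np.zeros(101),
                        m=np.zeros(101, dtype=int), n_e=1)
        assert fmax(curve) == (0.0, 0.0)


class TestAuprc:
    def test_unit_square(self):
        assert auprc_points([0.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_constant_half(self):
        assert auprc_points([0.0, 0.5, 1.0], [0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_sawtooth_hand_trapezoid(self):
        rc = [0.0, 0.25, 0.5, 0.75, 1.0]
        pr = [1.0, 0.4, 0.8, 0.2, 0.6]
        expected = (0.25 * (1.0 + 0.4) / 2 + 0.25 * (0.4 + 0.8) / 2
                    + 0.25 * (0.8 + 0.2) / 2 + 0.25 * (0.2 + 0.6) / 2)
        assert auprc_points(rc, pr) == pytest.approx(expected)

    def test_single_recall_value_gives_zero(self):
        assert auprc_points([0.5, 0.5], [0.9, 0.8]) == 0.0

    def test_duplicate_recall_collapsed_by_max_precision(self):
        assert auprc_points([0.0, 0.5, 0.5, 1.0],
                            [1.0, 0.2, 0.8, 0.6]) == pytest.approx(
            0.5 * (1.0 + 0.8) / 2 + 0.5 * (0.8 + 0.6) / 2
        )


class TestIauprc:
    def test_monotone_curve_unchanged(self):
        rc = [0.0, 0.5, 1.0]
        pr = [0.9, 0.7, 0.3]
        assert iauprc_points(rc, pr) == pytest.approx(auprc_points(rc, pr))

    def test_hand_example_interpolation_raises_area(self):
        """Points (0.5, 0.6), (1.0, 0.8): interpolation lifts the first
        precision to 0.8, area 0.40 vs 0.35 raw."""
        rc, pr = [0.5, 1.0], [0.6, 0.8]
        assert auprc_points(rc, pr) == pytest.approx(0.35)
        assert iauprc_points(rc, pr) == pytest.approx(0.40)

    def test_single_point_unchanged(self):
        assert iauprc_points([0.5], [0.9]) == 0.0

    def test_dominates_auprc_on_random_curves(self, rng):
        """Interpolation only raises precision, so IAuPRC >= AuPRC always,
        with equality for non-increasing curves."""
        for _ in range(300):
            n = int(rng.integers(2, 40))
            rc = np.sort(rng.random(n))
            pr = rng.random(n)
            a, ia = auprc_points(rc, pr), iauprc_points(rc, pr)
            assert ia >= a - 1e-12
        for _ in range(50):
            n = int(rng.integers(2, 40))
            rc = np.sort(rng.random(n))
            pr = np.sort(rng.random(n))[::-1]
            assert iauprc_points(rc, pr) == pytest.approx(
                auprc_points(rc, pr), abs=1e-12
            )


class TestSmin:
    def test_perfect_predictor_zero(self, chain_dag):
        truth = {"p1": {"root", "A", "B"}}
        preds = {"p1": {"root": 1.0, "A": 1.0, "B": 1.0}}
        ic = IcTable(ic={"root": 0.0, "A": 1.0, "B": 2.0})
        s, tau, ru, mi = smin(preds, truth, ic, dag=chain_dag)
        assert s == pytest.approx(0.0)

    def test_missed_term_contributes_its_ic(self, chain_dag):
        """One protein, truth {A} (IC 2), empty predictions: at tau > 0
        ru = 2 and mi = 0, and tau = 0 over-predicts, so smin = 2."""
        truth = {"p1": {"root", "A"}}
        ic = IcTable(ic={"root": 0.0, "A": 2.0, "B": 5.0})
        s, tau, ru, mi = smin({}, truth, ic, dag=chain_dag)
        assert ru[1] == pytest.approx(2.0)
        assert mi[1] == pytest.approx(0.0)
        assert s == pytest.approx(2.0)

    def test_missing_ic_names_term(self, chain_dag):
        truth = {"p1": {"root", "A", "B"}}
        with pytest.raises(KeyError, match="B"):
            smin({}, truth, IcTable(ic={"root": 0.0, "A": 1.0}), dag=chain_dag)


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_random_instances(self):
        """Fmax, AuPRC, IAuPRC and Smin agree exactly with an independent
        set-arithmetic implementation over the 101-threshold grid."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            dag, truth, preds = random_instance(
                rng, n_proteins=int(rng.integers(2, 6)),
                n_terms=int(rng.integers(4, 13)),
            )
            curve = pr_rc_curve(preds, truth, dag=dag)
            bpr, brc, bm, bn = brute_curve(preds, truth, dag.terms, dag.root)
            assert np.allclose(curve.pr, bpr, atol=1e-12)
            assert np.allclose(curve.rc, brc, atol=1e-12)

            f, tau = fmax(curve)
            bf, btau = brute_fmax(bpr, brc, bm)
            assert f == pytest.approx(bf, abs=1e-12)
            assert tau == pytest.approx(btau)

            assert auprc(curve) == pytest.approx(brute_auprc(bpr, brc), abs=1e-12)
            assert iauprc(curve) == pytest.approx(brute_iauprc(bpr, brc), abs=1e-12)

            ic = {t: float(rng.random() * 3) for t in dag.terms}
            ic[dag.root] = 0.0
            s, stau, _, _ = smin(preds, truth, IcTable(ic=ic), dag=dag)
            bs, bstau = brute_smin(preds, truth, ic, dag.terms, dag.root)
            assert s == pytest.approx(bs, abs=1e-12)
            assert stau == pytest.approx(bstau)


class TestFrequencyRestricted:
    def _setup(self, chain_dag):
        # A in every train protein, B in 20%
        train = {f"t{i}": ({"root", "A", "B"} if i < 2 else {"root", "A"})
                 for i in range(10)}
        truth = {"p1": {"root", "A", "B"}}
        preds = propagate_scores(chain_dag, {"p1": {"A": 0.9, "B": 0.7}})
        return train, truth, preds

    def test_full_percentile_equals_unrestricted(self, chain_dag):
        train, truth, preds = self._setup(chain_dag)
        full = frequency_restricted_iauprc(preds, truth, chain_dag, train, 100)
        unrestricted = iauprc(pr_rc_curve(preds, truth, dag=chain_dag))
        assert full == pytest.approx(unrestricted)

    def test_restriction_drops_common_terms(self, chain_dag):
        train, truth, preds = self._setup(chain_dag)
        # at 50%: only B (freq 0.2) qualifies
        restricted = frequency_restricted_iauprc(preds, truth, chain_dag, train, 50)
        only_b = iauprc(pr_rc_curve(preds, truth, dag=chain_dag,
                                    vocabulary={"B"}))
        assert restricted == pytest.approx(only_b)

    def test_percentile_below_rarest_term_gives_none(self, chain_dag):
        train, truth, preds = self._setup(chain_dag)
        assert frequency_restricted_iauprc(preds, truth, chain_dag, train, 1) is None

    def test_invalid_percentile_rejected(self, chain_dag):
        train, truth, preds = self._setup(chain_dag)
        with pytest.raises(ValueError):
            frequency_restricted_iauprc(preds, truth, chain_dag, train, 0)


class TestEvaluate:
    def test_truth_as_predictions_is_perfect(self, rng):
        dag, truth, _ = random_instance(rng, n_proteins=5, n_terms=10)
        preds = {p: {t: 1.0 for t in ts} for p, ts in truth.items()}
        ic = {t: float(rng.random()) for t in dag.terms}
        ic[dag.root] = 0.0
        result = evaluate(preds, truth, dag, ic=IcTable(ic=ic))
        assert result.fmax == pytest.approx(1.0)
        assert result.smin == pytest.approx(0.0)
        assert result.iauprc >= result.auprc - 1e-12

    def test_score_noise_below_half_grid_step_is_invisible(self, rng):
        """Scores perturbed by < 0.005 toward the grid midpoints cross no
        threshold, so Fmax is bit-identical."""
        dag, truth, preds = random_instance(rng)
        jittered = {
            p: {t: min(1.0, s + 0.004) if s < 1 else s
                for t, s in ts.items()}
            for p, ts in preds.items()
        }
        f0, _ = fmax(pr_rc_curve(preds, truth, dag=dag))
        f1, _ = fmax(pr_rc_curve(jittered, truth, dag=dag))
        assert f0 == pytest.approx(f1, abs=1e-12)
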