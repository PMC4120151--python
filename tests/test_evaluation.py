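"""Q8 / SOV8 scoring, cross-validation folds, similarity binning."""

import numpy as np
import pytest
from oracles import sov99_score

from ss8pred.alphabets import SS8_INDEX, SS8_ORDER
from ss8pred.evaluation import (
    EvalReport,
    evaluate_predictions,
    make_cv_folds,
    q8_score,
    similarity_binned_eval,
    sov8_score,
)


class TestQ8:
    def test_identity_is_100(self):
        rep = q8_score(["GHIEBTSC"], ["GHIEBTSC"])
        assert rep.overall_q8 == pytest.approx(100.0)
        assert np.nanmin(rep.per_state_q) == pytest.approx(100.0)
        assert rep.overall_sov8 == pytest.approx(100.0)

    def test_hand_counted_example(self):
        rep = q8_score(["HHEH"], ["HHEE"])
        assert rep.per_state_q[SS8_INDEX["H"]] == pytest.approx(100.0)
        assert rep.per_state_q[SS8_INDEX["E"]] == pytest.approx(50.0)
        assert rep.overall_q8 == pytest.approx(75.0)

    def test_absent_state_undefined_but_displayed_zero(self):
        rep = q8_score(["HHHH"], ["HHHH"])  # only H present in truth
        assert np.isnan(rep.per_state_q[SS8_INDEX["I"]])
        table = rep.to_table()
        assert table.loc["Q8", "I"] == 0.0
        assert table.loc["Q8", "H"] == 100.0

    def test_equals_confusion_trace_ratio(self):
        rng = np.random.default_rng(0)
        preds, truths = [], []
        for _ in range(5):
            L = int(rng.integers(5, 30))
            preds.append("".join(rng.choice(list(SS8_ORDER), size=L)))
            truths.append("".join(rng.choice(list(SS8_ORDER), size=L)))
        rep = q8_score(preds, truths)
        trace_ratio = 100.0 * np.trace(rep.confusion) / rep.confusion.sum()
        assert rep.overall_q8 == pytest.approx(trace_ratio, abs=1e-9)

    def test_permutation_invariant_over_chains(self):
        preds = ["HHEE", "CCTT", "GGSS"]
        truths = ["HHEH", "CCTC", "GGSB"]
        a = q8_score(preds, truths)
        order = [2, 0, 1]
        b = q8_score([preds[i] for i in order], [truths[i] for i in order])
        assert a.overall_q8 == pytest.approx(b.overall_q8)
        np.testing.assert_allclose(a.confusion, b.confusion)

    def test_masked_positions_excluded(self):
        mask = np.array([True, True, False, True])
        rep = q8_score(["HHEE"], ["HHCE"], [mask])
        assert rep.n_residues == 3
        assert rep.overall_q8 == pytest.approx(100.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            q8_score(["HH"], ["HHH"])


class TestSov8:
    def test_identity_is_100(self):
        rep = sov8_score(["GHHHEECC"], ["GHHHEECC"])
        assert rep.overall_sov8 == pytest.approx(100.0)

    def test_eight_residue_example_matches_oracle(self):
        pred, truth = "HHHCCCCC", "HHHHCCCC"
        rep = sov8_score([pred], [truth])
        oracle_overall, oracle_per_state = sov99_score([(pred, truth)])
        assert rep.overall_sov8 == pytest.approx(oracle_overall, abs=1e-9)
        np.testing.assert_allclose(
            rep.per_state_sov, oracle_per_state, atol=1e-9, equal_nan=True
        )

    def test_random_strings_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            L = int(rng.integers(4, 40))
            # few states and longer runs so segments are nontrivial
            states = rng.choice(list("HEC"), size=L)
            truth = "".join(np.repeat(states, 2))[:L]
            pred = list(truth)
            for i in range(L):
                if rng.random() < 0.3:
                    pred[i] = rng.choice(list("HEC"))
            pred = "".join(pred)
            rep = sov8_score([pred], [truth])
            oracle_overall, _ = sov99_score([(pred, truth)])
            assert rep.overall_sov8 == pytest.approx(oracle_overall, abs=1e-9)

    def test_unmatched_truth_segment_contributes_zero_score(self):
        # truth has an H segment the prediction misses entirely
        rep = sov8_score(["CCCC"], ["HHCC"])
        # H: unmatched 2-residue segment -> 0/2.
        # C: truth segment (2,4) vs pred segment (0,4): minov=2, maxov=4,
        #    delta=min(2,2,1,2)=1 -> 2*(2+1)/4 = 1.5 of 2 -> 75.
        assert rep.per_state_sov[SS8_INDEX["H"]] == pytest.approx(0.0)
        assert rep.per_state_sov[SS8_INDEX["C"]] == pytest.approx(75.0)
        assert rep.overall_sov8 == pytest.approx(100.0 * 1.5 / 4)

    def test_single_segment_zero_delta_closed_form(self):
        """With delta forced off, a single overlapping pair scores
        100 * minov / maxov (oracle self-check against the closed form)."""
        pred, truth = "HHHHCC", "CHHHHH"
        overall, _ = sov99_score([(pred[:6], truth[:6])], delta_on=False)
        # H truth segment 1..6 (len 5), pred segment 0..4 (len 4):
        # minov = 3, maxov = 6 -> H part 5*(3/6)/5; C truth seg len 1 unmatched
        expected = 100.0 * (5 * 3 / 6) / (5 + 1)
        assert overall == pytest.approx(expected, abs=1e-9)

    def test_bounded_and_100_only_for_identical_segmentation(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            L = int(rng.integers(3, 25))
            truth = "".join(np.repeat(rng.choice(list("HEC"), size=L), 3))[:L]
            pred = "".join(np.repeat(rng.choice(list("HEC"), size=L), 3))[:L]
            rep = sov8_score([pred], [truth])
            assert 0.0 <= rep.overall_sov8 <= 100.0 + 1e-9
            if pred != truth and rep.overall_sov8 == pytest.approx(100.0):
                # 100 requires every state's segmentation to coincide
                assert all(
                    p == t for p, t in zip(pred, truth)
                ), "SOV8 of 100 with differing segmentations"


class TestCvFolds:
    def test_divisible_fold_sizes(self):
        folds = make_cv_folds([f"c{i}" for i in range(14)], 7, seed=0)
        sizes = [len(folds.chains_in_fold(f)) for f in range(7)]
        assert sizes == [2] * 7

    def test_near_equal_fold_sizes(self):
        folds = make_cv_folds([f"c{i}" for i in range(15)], 7, seed=0)
        sizes = [len(folds.chains_in_fold(f)) for f in range(7)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 15

    def test_seeded_determinism(self):
        ids = [f"c{i}" for i in range(20)]
        a = make_cv_folds(ids, 7, seed=3)
        b = make_cv_folds(ids, 7, seed=3)
        assert a.fold_of_chain == b.fold_of_chain

    def test_too_few_chains_errors(self):
        with pytest.raises(ValueError):
            make_cv_folds(["a", "b"], 7)

    def test_roles_partition_chains(self):
        ids = [f"c{i}" for i in range(21)]
        folds = make_cv_folds(ids, 7, seed=1)
        for held in range(7):
            train, val, test = folds.roles(held)
            assert sorted(train + val + test) == sorted(ids)
            assert not (set(train) & set(test))
            assert not (set(val) & set(test))


def _report(q8):
    rep = EvalReport()
    rep.overall_q8 = q8
    return rep


class TestSimilarityBins:
    def test_all_templateless_single_bin(self):
        reports = {f"c{i}": _report(70.0 + i) for i in range(3)}
        sims = {cid: 0.0 for cid in reports}
        table = similarity_binned_eval(reports, sims)
        populated = table[table.n_chains > 0]
        assert list(populated["bin"]) == ["none"]
        assert populated.iloc[0]["n_chains"] == 3

    def test_binning_boundaries(self):
        reports = {"a": _report(60.0), "b": _report(80.0)}
        sims = {"a": 0.05, "b": 0.15}
        table = similarity_binned_eval(
            reports, sims, bins=[(0.0, 0.10), (0.10, 0.20)]
        )
        by_bin = dict(zip(table["bin"], table["n_chains"]))
        assert by_bin["(0, 10]"] == 1 and by_bin["(10, 20]"] == 1

    def test_means_match_brute_force(self):
        rng = np.random.default_rng(2)
        reports = {f"c{i}": _report(float(rng.uniform(50, 95))) for i in range(40)}
        sims = {cid: float(rng.uniform(0, 0.95)) for cid in reports}
        bins = [(0.0, 0.3), (0.3, 0.6), (0.6, 0.95)]
        table = similarity_binned_eval(reports, sims, bins=bins)
        for lo, hi in bins:
            members = [
                reports[c].overall_q8 for c, s in sims.items() if lo < s <= hi
            ]
            row = table[table["bin"] == f"({lo * 100:g}, {hi * 100:g}]"].iloc[0]
            assert row["q8"] == pytest.approx(np.mean(members))

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            similarity_binned_eval({}, {}, bins=[(0.0, 0.5), (0.4, 0.9)])
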