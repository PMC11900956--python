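"""Ranking, outlier flagging, swap suggestion and missing-shift prediction."""

import itertools

import numpy as np
import pytest

from shiftjudge import (
    ExperimentalTable,
    InsufficientDataError,
    Nucleus,
    apply_swap,
    boltzmann_average,
    cmae,
    fit_scaling,
    flag_outliers,
    generate_dataset,
    make_decoy,
    matched_pairs,
    predict_missing_shifts,
    rank_candidates,
    score_candidate,
    suggest_reassignments,
)
from shiftjudge.synthetic import SyntheticSpec
from conftest import make_candidate


class TestRanking:
    def test_single_candidate_wins(self, linear_system, config):
        candidate, table, _ = linear_system
        report = rank_candidates([candidate], table, config)
        assert report.winner == candidate.candidate_id
        assert len(report.ranked) == 1

    def test_true_structure_beats_decoy(self, config):
        spec = SyntheticSpec(n_H=14, n_C=20, noise_sd_C=1.5, seed=5)
        candidate, table, truth = generate_dataset(spec)
        decoy = make_decoy(candidate, truth, k_nuclei=3, magnitude=8.0, seed=99)
        report = rank_candidates([decoy, candidate], table, config)
        assert report.winner == candidate.candidate_id

    def test_ranking_invariant_to_input_order(self, config):
        spec = SyntheticSpec(seed=8, noise_sd_C=1.5)
        candidate, table, truth = generate_dataset(spec)
        decoy = make_decoy(candidate, truth, k_nuclei=3, magnitude=8.0, seed=17)
        order_a = rank_candidates([candidate, decoy], table, config)
        order_b = rank_candidates([decoy, candidate], table, config)
        assert [e.candidate_id for e in order_a.ranked] == [
            e.candidate_id for e in order_b.ranked
        ]

    def test_ranking_invariant_to_affine_shielding_transform(self, config):
        """Per-candidate scaling absorbs any affine map of a candidate's shieldings."""
        spec = SyntheticSpec(seed=21, noise_sd_C=1.5)
        candidate, table, truth = generate_dataset(spec)
        decoy = make_decoy(candidate, truth, k_nuclei=3, magnitude=8.0, seed=22)
        import copy

        warped = copy.deepcopy(candidate)
        warped.candidate_id = "warped"
        for conf in warped.conformers:
            for nucleus in list(conf.shieldings):
                conf.shieldings[nucleus] = 1.7 * conf.shieldings[nucleus] - 40.0
        base = rank_candidates([candidate, decoy], table, config)
        alt = rank_candidates([warped, decoy], table, config)
        assert base.winner == candidate.candidate_id
        assert alt.winner == "warped"
        winner_base = base.ranked[0]
        winner_alt = alt.ranked[0]
        assert winner_alt.combined_score == pytest.approx(
            winner_base.combined_score, abs=1e-9
        )

    def test_no_scoreable_candidate_rejected(self, config):
        shifts = {Nucleus("C", "C-1"): 100.0}
        candidate = make_candidate(shifts, a=-1.0)
        table = ExperimentalTable("cmpd", dict(shifts))
        with pytest.raises(InsufficientDataError):
            rank_candidates([candidate], table, config)


class TestOutliers:
    def test_perfect_data_has_no_flags(self, linear_system, config):
        candidate, table, _ = linear_system
        report = score_candidate(candidate, table, config)["C"]
        flags = flag_outliers(report, config.outlier_k)
        assert flags == [] or not any(f.flagged for f in flags)

    def test_forced_outlier_flagged_first(self, config):
        spec = SyntheticSpec(n_H=0, n_C=20, noise_sd_C=1.5, seed=31)
        candidate, table, truth = generate_dataset(spec)
        decoy = make_decoy(candidate, truth, k_nuclei=1, magnitude=15.0, seed=32)
        perturbed = next(iter(truth.decoy_perturbations))
        report = score_candidate(decoy, table, config)["C"]
        flags = flag_outliers(report, config.outlier_k)
        assert flags[0].nucleus == perturbed
        assert flags[0].flagged

    def test_flag_criterion_matches_threshold(self, config):
        spec = SyntheticSpec(n_H=0, n_C=25, noise_sd_C=1.5, seed=33)
        candidate, table, _ = generate_dataset(spec)
        report = score_candidate(candidate, table, config)["C"]
        for flag in flag_outliers(report, outlier_k=1.0):
            assert flag.flagged == (abs(flag.z) > 1.0)
            assert flag.z == pytest.approx(flag.residual / report.rmsd)

    def test_small_report_rejected(self, config):
        shifts = {Nucleus("C", "C-1"): 20.0, Nucleus("C", "C-2"): 90.0}
        candidate = make_candidate(shifts, a=-1.0)
        table = ExperimentalTable("cmpd", dict(shifts))
        report = score_candidate(candidate, table, config)["C"]
        with pytest.raises(InsufficientDataError):
            flag_outliers(report, 2.0)


def _self_fit_cmae(d, s):
    import warnings

    from shiftjudge import PositiveSlopeWarning

    with warnings.catch_warnings():
        # the brute-force oracle visits deliberately scrambled assignments
        warnings.simplefilter("ignore", PositiveSlopeWarning)
        fit = fit_scaling(d, s, "C")
        return cmae(d, s, fit)


def _exhaustive_best_two_transpositions(d, s):
    """Oracle: minimum CMAE over identity, single and disjoint double swaps."""
    n = len(d)
    best = _self_fit_cmae(d, s)
    pairs = list(itertools.combinations(range(n), 2))
    for i, j in pairs:
        d1 = d.copy()
        d1[i], d1[j] = d1[j], d1[i]
        best = min(best, _self_fit_cmae(d1, s))
        for k, l in pairs:
            if {k, l} & {i, j}:
                continue
            d2 = d1.copy()
            d2[k], d2[l] = d2[l], d2[k]
            best = min(best, _self_fit_cmae(d2, s))
    return best


class TestSwapSuggestions:
    def test_perfect_data_yields_no_suggestions(self, linear_system, config):
        candidate, table, _ = linear_system
        report = score_candidate(candidate, table, config)["C"]
        sigma = boltzmann_average(candidate, config)
        assert suggest_reassignments(report, sigma, table, config) == []

    def test_injected_swap_recovered_and_cmae_restored(self, config):
        spec = SyntheticSpec(n_H=0, n_C=20, noise_sd_C=1.5, seed=51)
        candidate, table, truth = generate_dataset(spec)
        carbons = sorted(table.assigned("C"), key=lambda n: table.shifts[n])
        low, high = carbons[0], carbons[-1]  # far apart: > 30 ppm in this range
        swapped = apply_swap(table, (low, high), truth)
        clean_cmae = score_candidate(candidate, table, config)["C"].cmae
        report = score_candidate(candidate, swapped, config)["C"]
        sigma = boltzmann_average(candidate, config)
        suggestions = suggest_reassignments(report, sigma, swapped, config)
        top = suggestions[0]
        assert top.accepted
        assert set(top.labels) == {low, high}
        assert report.cmae + top.delta_cmae == pytest.approx(clean_cmae, rel=0.25)

    def test_greedy_matches_exhaustive_two_transposition_oracle(self, config):
        """Two disjoint injected swaps on 12 carbons: greedy equals brute force."""
        spec = SyntheticSpec(n_H=0, n_C=12, noise_sd_C=1.0, seed=77)
        candidate, table, truth = generate_dataset(spec)
        carbons = sorted(table.assigned("C"), key=lambda n: table.shifts[n])
        table2 = apply_swap(table, (carbons[1], carbons[4]), truth)
        table2 = apply_swap(table2, (carbons[7], carbons[10]), truth)
        report = score_candidate(candidate, table2, config)["C"]
        sigma = boltzmann_average(candidate, config)
        suggestions = suggest_reassignments(report, sigma, table2, config)
        accepted = [s for s in suggestions if s.accepted]
        labels, d, s = matched_pairs(sigma, table2, "C")
        index = {lab: i for i, lab in enumerate(labels)}
        d_after = d.copy()
        for swap in accepted:
            i, j = index[swap.labels[0]], index[swap.labels[1]]
            d_after[i], d_after[j] = d_after[j], d_after[i]
        assert _self_fit_cmae(d_after, s) == pytest.approx(
            _exhaustive_best_two_transpositions(d, s), abs=1e-9
        )

    def test_swapping_equal_shifts_changes_nothing(self, config):
        shifts = {Nucleus("C", f"C-{i}"): 20.0 * i for i in range(1, 7)}
        shifts[Nucleus("C", "C-7")] = shifts[Nucleus("C", "C-2")]
        candidate = make_candidate(shifts, a=-1.0)
        table = ExperimentalTable("cmpd", dict(shifts))
        swapped = apply_swap(table, (Nucleus("C", "C-2"), Nucleus("C", "C-7")))
        base = score_candidate(candidate, table, config)["C"]
        after = score_candidate(candidate, swapped, config)["C"]
        assert after.cmae == pytest.approx(base.cmae, abs=1e-12)

    def test_too_few_nuclei_rejected(self, config):
        shifts = {Nucleus("C", f"C-{i}"): 30.0 * i for i in range(1, 4)}
        candidate = make_candidate(shifts, a=-1.0)
        table = ExperimentalTable("cmpd", dict(shifts))
        report = score_candidate(candidate, table, config)["C"]
        sigma = boltzmann_average(candidate, config)
        with pytest.raises(InsufficientDataError):
            suggest_reassignments(report, sigma, table, config)


class TestMissingShiftPrediction:
    def test_nothing_missing_nothing_predicted(self, linear_system, config):
        candidate, table, _ = linear_system
        report = score_candidate(candidate, table, config)["C"]
        sigma = boltzmann_average(candidate, config)
        assert predict_missing_shifts(sigma, table, report.fit) == []

    def test_masked_truth_recovered_within_noise(self, config):
        spec = SyntheticSpec(
            n_H=0, n_C=60, noise_sd_C=1.5, mask_fraction=0.1, seed=61
        )
        candidate, table, truth = generate_dataset(spec)
        assert truth.masked, "masking must have occurred"
        report = score_candidate(candidate, table, config)["C"]
        sigma = boltzmann_average(candidate, config)
        predictions = predict_missing_shifts(sigma, table, report.fit)
        assert {p.nucleus for p in predictions} == set(truth.masked)
        errors = [p.predicted_shift - truth.true_shifts[p.nucleus] for p in predictions]
        assert np.mean(np.abs(errors)) <= 2 * spec.noise_sd_C

    def test_prediction_unbiased_at_large_n(self, config):
        spec = SyntheticSpec(
            n_H=0, n_C=1000, noise_sd_C=1.5, mask_fraction=0.1, seed=62,
            n_conformers=1, conformer_sigma_spread=0.0,
        )
        candidate, table, truth = generate_dataset(spec)
        report = score_candidate(candidate, table, config)["C"]
        sigma = boltzmann_average(candidate, config)
        predictions = predict_missing_shifts(sigma, table, report.fit)
        signed = [p.predicted_shift - truth.true_shifts[p.nucleus] for p in predictions]
        assert abs(np.mean(signed)) < 0.5

    def test_sigma_at_intercept_predicts_zero(self):
        from shiftjudge import ScalingFit

        fit = ScalingFit("C", "x", a=-1.2, b=188.0, n=5)
        table = ExperimentalTable("cmpd", {Nucleus("C", "C-1"): None})
        from shiftjudge import AveragedShieldings

        sigma = AveragedShieldings("cand", {Nucleus("C", "C-1"): 188.0})
        predictions = predict_missing_shifts(sigma, table, fit)
        assert predictions[0].predicted_shift == 0.0
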