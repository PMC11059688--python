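"""Agreement coefficients, PPV, I-CVI and frequency reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emstrigger import (
    UNDEFINED,
    ConfusionMatrix2x2,
    LikertRatingSet,
    agreement_report,
    build_confusion_matrix,
    cohens_kappa,
    frequency_report,
    grid_from_frame,
    icvi,
    interpret_kappa,
    observed_agreement,
    pabak,
    trigger_ppv,
    truncate,
)

counts = st.integers(min_value=0, max_value=2000)


def nonempty_matrix(a, b, c, d):
    return ConfusionMatrix2x2(a, b, c, d) if a + b + c + d > 0 else None


class TestConfusionMatrix:
    def test_builder_counts_each_cell_once(self):
        grid1 = {("r1", "t1"): True, ("r1", "t2"): False,
                 ("r2", "t1"): True, ("r2", "t2"): False}
        grid2 = {("r1", "t1"): True, ("r1", "t2"): True,
                 ("r2", "t1"): False, ("r2", "t2"): False}
        cm = build_confusion_matrix(grid1, grid2)
        assert (cm.a, cm.b, cm.c, cm.d) == (1, 1, 1, 1)

    def test_identical_all_negative_grid(self):
        grid = {(f"r{i}", f"t{j}"): False for i in range(90) for j in range(22)}
        cm = build_confusion_matrix(grid, dict(grid))
        assert (cm.a, cm.d) == (0, 1980)
        assert observed_agreement(cm) == 1.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            build_confusion_matrix({("r1", "t1"): True}, {("r2", "t1"): True})

    def test_grid_from_frame(self):
        frame = pd.DataFrame(
            [[True, False], [False, False]], index=["r1", "r2"], columns=["t1", "t2"]
        )
        cells = grid_from_frame(frame)
        assert cells[("r1", "t1")] is True and cells[("r2", "t2")] is False

    def test_counts_tally_to_grid_size(self):
        rng = np.random.default_rng(4)
        frame1 = pd.DataFrame(rng.random((30, 22)) < 0.1)
        frame2 = pd.DataFrame(rng.random((30, 22)) < 0.1)
        cm = build_confusion_matrix(grid_from_frame(frame1), grid_from_frame(frame2))
        assert cm.n == 30 * 22


class TestAgreementCoefficients:
    def test_session_one_published_matrix(self):
        cm = ConfusionMatrix2x2(59, 69, 34, 1818)
        assert cm.n == 1980
        assert round(observed_agreement(cm), 2) == 0.95
        assert round(cohens_kappa(cm), 1) == 0.5
        assert truncate(pabak(cm), 2) == 0.89

    def test_session_two_published_matrix(self):
        cm = ConfusionMatrix2x2(31, 53, 60, 1836)
        assert round(observed_agreement(cm), 2) == 0.94
        assert round(cohens_kappa(cm), 1) == 0.3
        assert truncate(pabak(cm), 2) == 0.88

    def test_kappa_matches_independent_implementation(self):
        """Cross-check against scikit-learn on label vectors."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            y1 = rng.random(500) < 0.15
            y2 = np.where(rng.random(500) < 0.8, y1, ~y1)
            a = int(np.sum(y1 & y2))
            b = int(np.sum(~y1 & y2))
            c = int(np.sum(y1 & ~y2))
            d = int(np.sum(~y1 & ~y2))
            ours = cohens_kappa(ConfusionMatrix2x2(a, b, c, d))
            theirs = cohen_kappa_score(y1, y2)
            assert ours == pytest.approx(theirs, abs=1e-12)

    @pytest.mark.parametrize(
        "cells, expected",
        [((0, 0, 0, 10), 1.0), ((5, 5, 5, 5), 0.5), ((10, 0, 0, 10), 1.0)],
    )
    def test_observed_agreement_simple_cases(self, cells, expected):
        assert observed_agreement(ConfusionMatrix2x2(*cells)) == expected

    def test_perfect_agreement_mixed_marginals(self):
        assert cohens_kappa(ConfusionMatrix2x2(10, 0, 0, 30)) == pytest.approx(1.0)

    def test_degenerate_marginals_yield_undefined(self):
        assert cohens_kappa(ConfusionMatrix2x2(0, 0, 0, 10)) is UNDEFINED
        assert cohens_kappa(ConfusionMatrix2x2(12, 0, 0, 0)) is UNDEFINED

    @pytest.mark.parametrize(
        "p_o_cells, expected", [((0, 0, 0, 10), 1.0), ((5, 5, 0, 0), 0.0)]
    )
    def test_pabak_extremes(self, p_o_cells, expected):
        assert pabak(ConfusionMatrix2x2(*p_o_cells)) == pytest.approx(expected)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(max_examples=200, deadline=None)
    def test_rater_swap_symmetry_and_bounds(self, a, b, c, d):
        cm = nonempty_matrix(a, b, c, d)
        if cm is None:
            return
        swapped = ConfusionMatrix2x2(a, c, b, d)
        assert observed_agreement(cm) == observed_agreement(swapped)
        assert pabak(cm) == pabak(swapped)
        assert -1.0 <= pabak(cm) <= 1.0
        kappa = cohens_kappa(cm)
        if kappa is not UNDEFINED:
            assert kappa == pytest.approx(cohens_kappa(swapped))
            assert -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9

    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_kappa_equals_pabak_at_balanced_marginals(self, a, b):
        if a + b == 0:
            return
        cm = ConfusionMatrix2x2(a, b, b, a)  # both marginals exactly 0.5
        kappa = cohens_kappa(cm)
        if kappa is not UNDEFINED:
            assert kappa == pytest.approx(pabak(cm))

    def test_kappa_not_above_pabak_under_prevalence_imbalance(self):
        # negative-dominated grids, small bias: PABAK should not fall below kappa
        rng = np.random.default_rng(11)
        for _ in range(50):
            d = int(rng.integers(500, 3000))
            a = int(rng.integers(0, 40))
            b = int(rng.integers(0, 40))
            c = int(rng.integers(0, 40))
            cm = ConfusionMatrix2x2(a, b, c, d)
            kappa = cohens_kappa(cm)
            if kappa is not UNDEFINED:
                assert kappa <= pabak(cm) + 1e-9


class TestKappaInterpretation:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.5, "moderate"),
            (0.89, "almost_perfect"),
            (0.10, "below_fair"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost_perfect"),
            (1.0, "almost_perfect"),
            (-0.3, "below_fair"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_kappa(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)

    def test_agreement_report_bundle(self):
        report = agreement_report(ConfusionMatrix2x2(59, 69, 34, 1818))
        assert report["matrix"]["n"] == 1980
        assert report["kappa_band"] == "moderate"
        assert report["pabak_band"] == "almost_perfect"


class TestTriggerPPV:
    @pytest.mark.parametrize(
        "positives, nm, expected",
        [(271, 238, 87.8), (19, 16, 84.2), (185, 102, 55.1)],
    )
    def test_published_near_miss_cells(self, positives, nm, expected):
        perf = trigger_ppv("T", positives, nm, 0, 0)
        assert perf.ppv_near_miss == expected

    def test_zero_positives_undefined_not_zero(self):
        perf = trigger_ppv("T", 0, 0, 0, 0)
        assert perf.ppv_near_miss is UNDEFINED
        assert perf.ppv_harmful is UNDEFINED

    def test_all_positives_harmful(self):
        assert trigger_ppv("T", 7, 0, 0, 7).ppv_harmful == 100.0

    def test_class_counts_cannot_exceed_positives(self):
        with pytest.raises(ValueError, match="exceed"):
            trigger_ppv("T", 5, 4, 2, 0)

    def test_class_percentages_sum_at_most_100(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pos = int(rng.integers(1, 400))
            nm = int(rng.integers(0, pos + 1))
            nh = int(rng.integers(0, pos - nm + 1))
            hi = int(rng.integers(0, pos - nm - nh + 1))
            perf = trigger_ppv("T", pos, nm, nh, hi)
            total = perf.ppv_near_miss + perf.ppv_no_harm + perf.ppv_harmful
            assert total <= 100.0 + 0.3  # three one-decimal roundings


class TestICVI:
    def test_five_of_six_raters(self):
        result = icvi(LikertRatingSet("A2", "utility", (4, 3, 4, 3, 4, 2)))
        assert result.value == 0.83
        assert result.highly_relevant is True

    def test_extremes(self):
        assert icvi(LikertRatingSet("T", "clinical_relevance", (3, 4, 3, 4))).value == 1.0
        low = icvi(LikertRatingSet("T", "utility", (1, 2, 2, 1)))
        assert low.value == 0.0 and low.highly_relevant is False

    def test_invalid_ratings_rejected(self):
        with pytest.raises(ValueError):
            LikertRatingSet("T", "utility", (5, 3))
        with pytest.raises(ValueError):
            LikertRatingSet("T", "utility", ())

    def test_matches_brute_force_over_all_six_rater_vectors(self):
        for ratings in itertools.product((1, 2, 3, 4), repeat=6):
            expected = sum(1 for r in ratings if r in (3, 4)) / 6
            result = icvi(LikertRatingSet("T", "utility", ratings))
            assert result.value == round(expected, 2)
            assert result.highly_relevant == (round(expected, 2) >= 0.80)


class TestPresentation:
    @pytest.mark.parametrize(
        "value, decimals, expected",
        [(0.8959, 2, 0.89), (0.8859, 2, 0.88), (5.47, 1, 5.4), (92.19, 1, 92.1)],
    )
    def test_truncate_toward_zero(self, value, decimals, expected):
        assert truncate(value, decimals) == expected


@pytest.fixture(scope="module")
def reviewed_cohort():
    from emstrigger import (
        apply_inclusion_criteria,
        classify_cohort,
        load_registry,
        screen_cohort,
    )
    from emstrigger.synthetic import (
        CohortSpec,
        generate_cohort,
        simulate_judgements,
    )

    records, manifest = generate_cohort(
        CohortSpec(n_records=400, n_ineligible=4, seed=29)
    )
    eligible = [r for r in records if apply_inclusion_criteria(r)]
    screenings = screen_cohort(eligible, load_registry(), linkage_records=records)
    cohort = classify_cohort(screenings, simulate_judgements(manifest))
    return manifest, eligible, screenings, cohort


class TestFrequencyReport:
    def test_percentages_sum_to_100(self, reviewed_cohort):
        _, eligible, screenings, cohort = reviewed_cohort
        report = frequency_report(cohort.classifications, screenings, eligible)
        assert report.who_summary["count"].sum() == report.n
        assert report.who_summary["percent"].sum() == pytest.approx(100.0, abs=0.3)
        assert report.merp_summary["count"].sum() == report.n

    def test_report_matches_manifest_tallies(self, reviewed_cohort):
        manifest, eligible, screenings, cohort = reviewed_cohort
        report = frequency_report(cohort.classifications, screenings, eligible)
        planted = manifest.planted_counts()
        for trigger_id, row in report.trigger_summary.iterrows():
            assert row["positives"] == planted.get(trigger_id, 0), trigger_id
        who = manifest.who_counts()
        for who_class, count in who.items():
            assert report.who_summary.loc[who_class.value, "count"] == count

    def test_missing_classification_rejected(self, reviewed_cohort):
        _, eligible, screenings, cohort = reviewed_cohort
        with pytest.raises(ValueError, match="missing"):
            frequency_report(cohort.classifications[:-1], screenings, eligible)
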