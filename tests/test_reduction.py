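"""Dimension-reduction methods: oracles, hand computations, properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meatspec.containers import QualityTable, SpectraSet
from meatspec.exceptions import EmptySelectionError, NoStructureError
from meatspec.reduction import (
    CorrelationProfile,
    CorrelationSelector,
    ExtremaProfile,
    IntervalDecimator,
    JFPTExtractor,
    StepwiseSelector,
    WavelengthSelection,
    correlation_profile,
    decimate,
    detect_extrema,
    extract_jfpt,
    select_by_correlation,
    stepwise_select,
)


def _quality(protein=None, fat=None, moisture=None, n=None):
    n = n or len(next(v for v in (protein, fat, moisture) if v is not None))
    zeros = np.zeros(n)
    return QualityTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i + 1}" for i in range(n)],
                "protein": zeros if protein is None else protein,
                "fat": zeros if fat is None else fat,
                "moisture": zeros if moisture is None else moisture,
            }
        )
    )


class TestCorrelationProfile:
    def test_perfect_linear_cases(self):
        wl = np.array([1.0, 2.0, 3.0])
        X = np.array([[1.0, 9, 5], [2, 7, 5.5], [3, 8, 6]])
        s = SpectraSet(wl, X)
        up = correlation_profile(s, _quality(moisture=[2.0, 4.0, 6.0]), "moisture")
        assert up.r[0] == pytest.approx(1.0)
        down = correlation_profile(s, _quality(moisture=[3.0, 2.0, 1.0]), "moisture")
        assert down.r[0] == pytest.approx(-1.0)

    def test_column_equal_to_target(self):
        wl = np.arange(4.0)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        q = _quality(protein=X[:, 2] + 10.0)
        prof = correlation_profile(SpectraSet(wl, X + 10.0), q, "protein")
        assert prof.r[2] == pytest.approx(1.0)

    def test_null_simulation_correlations_small(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 200))
        q = _quality(fat=np.abs(rng.normal(size=1000)) + 1.0)
        prof = correlation_profile(SpectraSet(np.arange(200.0) + 400, X + 5), q, "fat")
        assert np.nanmax(np.abs(prof.r)) < 0.15

    def test_constant_parameter_rejected(self):
        s = SpectraSet(np.arange(3.0), np.random.default_rng(2).normal(size=(5, 3)))
        with pytest.raises(ValueError, match="constant"):
            correlation_profile(s, _quality(moisture=np.full(5, 50.0)), "moisture")

    def test_constant_column_marked_undefined(self):
        X = np.random.default_rng(3).normal(size=(6, 3))
        X[:, 1] = 2.0
        s = SpectraSet(np.arange(3.0), X)
        prof = correlation_profile(s, _quality(fat=np.arange(6.0) + 1), "fat")
        assert np.isnan(prof.r[1])
        sel = select_by_correlation(prof, 0.01)
        assert 1 not in sel.indices


class TestSelectByCorrelation:
    def test_hand_filter(self):
        prof = CorrelationProfile(np.array([1.0, 2, 3]), [0.2, -0.5, 0.45], "fat")
        sel = select_by_correlation(prof, 0.4)
        assert list(sel.indices) == [1, 2]
        assert sel.params["threshold"] == 0.4

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        r = rng.uniform(-1, 1, size=10)
        prof = CorrelationProfile(np.arange(10.0), r, "protein")
        sel = select_by_correlation(prof, 0.35)
        expected = [i for i in range(10) if abs(r[i]) >= 0.35]
        assert list(sel.indices) == expected

    def test_antitone_nesting(self):
        rng = np.random.default_rng(5)
        prof = CorrelationProfile(
            np.arange(50.0), rng.uniform(-1, 1, size=50), "moisture"
        )
        loose = set(select_by_correlation(prof, 0.2).indices)
        tight = set(select_by_correlation(prof, 0.6).indices)
        assert tight <= loose

    def test_empty_selection_names_threshold(self):
        prof = CorrelationProfile(np.arange(3.0), [0.1, 0.0, -0.2], "fat")
        with pytest.raises(EmptySelectionError, match="0.9"):
            select_by_correlation(prof, 0.9)


class TestDecimate:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(1130, 2, 565), (1130, 3, 376), (1130, 4, 282), (1130, 10, 113),
         (1130, 12, 94), (1130, 20, 56), (125, 2, 62), (125, 3, 41), (125, 24, 5)],
    )
    def test_printed_point_counts(self, n, k, expected):
        s = SpectraSet(np.arange(n, dtype=float), np.zeros((2, n)))
        reduced, sel = decimate(s, k)
        assert reduced.n_wavelengths == expected == len(sel)

    def test_hand_enumeration_n7_k3(self):
        s = SpectraSet(np.arange(7.0), np.arange(14.0).reshape(2, 7))
        reduced, sel = decimate(s, 3)
        assert list(sel.indices) == [2, 5]
        assert np.array_equal(reduced.reflectance, s.reflectance[:, [2, 5]])

    def test_identity_at_k1(self, toy_spectra):
        reduced, sel = decimate(toy_spectra, 1)
        assert np.array_equal(reduced.reflectance, toy_spectra.reflectance)
        assert len(sel) == toy_spectra.n_wavelengths

    def test_k_exceeding_grid_rejected(self, toy_spectra):
        with pytest.raises(ValueError):
            decimate(toy_spectra, toy_spectra.n_wavelengths + 1)

    @given(n=st.integers(2, 400), data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_count_law_floor_n_over_k(self, n, data):
        k = data.draw(st.integers(1, n))
        dec = IntervalDecimator(k=k).fit(np.zeros((2, n)))
        assert dec.indices_.size == n // k


class TestStepwise:
    def test_recovers_planted_sparse_truth(self):
        rng = np.random.default_rng(6)
        X, _ = np.linalg.qr(rng.normal(size=(60, 8)))
        y = 2.0 * X[:, 2] - X[:, 5]
        est = StepwiseSelector().fit(X, y)
        assert list(est.selected_indices_) == [2, 5]

    def test_pure_noise_nothing_enters(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 20))
        y = rng.normal(size=150)
        with pytest.raises(EmptySelectionError):
            StepwiseSelector(alpha_enter=1e-6, alpha_remove=1e-6).fit(X, y)

    def test_duplicated_column_selected_once(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        X = np.column_stack([x, x, rng.normal(size=40)])
        y = 3.0 * x + 0.01 * rng.normal(size=40)
        est = StepwiseSelector().fit(X, y)
        assert not {0, 1} <= set(est.selected_indices_)

    def test_matches_exhaustive_best_subset(self):
        """Oracle: among all 2^5 subsets, the stepwise F criteria admit a
        unique stable subset; stepwise must find it."""
        rng = np.random.default_rng(9)
        n, p, ae, ar = 20, 5, 0.05, 0.10
        X = rng.normal(size=(n, p))
        y = 1.5 * X[:, 1] - 2.0 * X[:, 3] + 0.15 * rng.normal(size=n)

        def rss_of(subset):
            D = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
            beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
            r = y - D @ beta
            return float(r @ r), D, beta

        def stable(subset):
            rss, D, beta = rss_of(subset)
            dfres = n - len(subset) - 1
            # every included variable significant at alpha_remove
            cov = rss / dfres * np.linalg.pinv(D.T @ D)
            t2 = beta[1:] ** 2 / np.maximum(np.diag(cov)[1:], 1e-300)
            if np.any(stats.f.sf(t2, 1, dfres) > ar):
                return False
            # no excluded variable admissible at alpha_enter
            for j in set(range(p)) - set(subset):
                rss_j, _, _ = rss_of(list(subset) + [j])
                df = n - len(subset) - 2
                F = (rss - rss_j) / (rss_j / df)
                if stats.f.sf(F, 1, df) < ae:
                    return False
            return True

        stable_subsets = [
            s
            for r in range(1, p + 1)
            for s in itertools.combinations(range(p), r)
            if stable(list(s))
        ]
        best = min(stable_subsets, key=lambda s: rss_of(list(s))[0])
        est = StepwiseSelector(alpha_enter=ae, alpha_remove=ar).fit(X, y)
        assert tuple(est.selected_indices_) == best == (1, 3)

    def test_spectra_wrapper_reports_nm(self, dataset150):
        sel = stepwise_select(dataset150.region2, dataset150.quality, "fat")
        assert sel.method == "stepwise"
        assert np.all(np.diff(sel.indices) > 0)
        assert np.allclose(
            sel.wavelengths, dataset150.region2.wavelengths[sel.indices]
        )


class TestExtrema:
    def test_constructed_waveform_exact_extrema(self):
        x = np.linspace(0.0, 3.0, 301)
        y = np.sin(2 * np.pi * x)  # maxima at 0.25/1.25/2.25, minima at 0.75/...
        s = SpectraSet(np.arange(301.0), y[None, :] + 2.0)
        prof = detect_extrema(s, min_prominence=0.5)
        got = np.round(x[prof.positions], 2)
        assert list(got) == [0.25, 0.75, 1.25, 1.75, 2.25, 2.75]
        assert prof.kinds == ["peak", "trough"] * 3

    def test_monotone_spectrum_has_no_structure(self):
        s = SpectraSet(np.arange(50.0), np.linspace(1, 2, 50)[None, :])
        with pytest.raises(NoStructureError):
            detect_extrema(s)

    def test_alternation_keeps_more_extreme_of_same_kind(self):
        # Two maxima separated by a shallow dip below prominence: the taller
        # peak must survive.
        y = np.array([0.0, 1.0, 0.95, 1.4, 0.0, -1.0, 0.0], dtype=float)
        s = SpectraSet(np.arange(7.0), y[None, :])
        prof = detect_extrema(s, min_prominence=0.3)
        assert 3 in prof.positions and 1 not in prof.positions
        for a, b in zip(prof.kinds, prof.kinds[1:]):
            assert a != b

    def test_region1_trough_near_980(self, dataset150):
        prof = detect_extrema(dataset150.region1)
        wl = dataset150.region1.wavelengths[prof.positions]
        troughs = wl[[k == "trough" for k in prof.kinds]]
        assert np.min(np.abs(troughs - 980.0)) <= 10.0


class TestJFPT:
    @staticmethod
    def _alternating(positions, first="trough"):
        kinds = [first if i % 2 == 0 else ("peak" if first == "trough" else "trough")
                 for i in range(len(positions))]
        return ExtremaProfile(np.asarray(positions), kinds)

    def test_four_peaks_five_troughs_give_eight_jumps(self):
        prof = self._alternating(np.arange(0, 90, 10), first="trough")
        assert prof.n_peaks == 4 and prof.n_troughs == 5
        rng = np.random.default_rng(10)
        s = SpectraSet(np.arange(100.0), rng.uniform(0.1, 1, size=(3, 100)))
        feats = extract_jfpt(s, prof)
        assert feats.n_jumps == 8

    def test_single_peak_two_troughs(self):
        prof = self._alternating([2, 5, 8], first="trough")
        s = SpectraSet(np.arange(10.0), np.random.default_rng(11).uniform(0.1, 1, (2, 10)))
        assert extract_jfpt(s, prof).n_jumps == 2

    def test_constant_spectrum_gives_zero_features(self):
        prof = self._alternating([1, 4, 7, 9], first="peak")
        s = SpectraSet(np.arange(12.0), np.full((4, 12), 0.6))
        assert np.allclose(extract_jfpt(s, prof).values, 0.0)

    def test_manual_subtraction_table(self):
        # 9 alternating extrema on a 3-sample toy matrix, checked by hand.
        positions = np.arange(9)
        prof = self._alternating(positions, first="trough")
        X = np.arange(27.0).reshape(3, 9)
        X[1] = X[1][::-1]
        s = SpectraSet(np.arange(9.0), X)
        feats = extract_jfpt(s, prof)
        assert feats.n_jumps == 8
        # jump j pairs positions (j, j+1); the peak is whichever of the two
        # carries the 'peak' label, and the value is peak minus trough
        for j in range(8):
            a, b = positions[j], positions[j + 1]
            peak, trough = (a, b) if prof.kinds[j] == "peak" else (b, a)
            assert np.allclose(feats.values[:, j], X[:, peak] - X[:, trough])

    def test_non_alternating_profile_rejected(self):
        with pytest.raises(ValueError, match="alternate"):
            ExtremaProfile(np.array([1, 3, 5]), ["peak", "peak", "trough"])

    @given(offset=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_additive_offset_invariance(self, offset):
        prof = self._alternating([1, 3, 6, 8], first="peak")
        rng = np.random.default_rng(12)
        X = rng.uniform(0.2, 0.9, size=(3, 10))
        s = SpectraSet(np.arange(10.0), X)
        shifted = SpectraSet(np.arange(10.0), X + offset)
        assert np.allclose(
            extract_jfpt(s, prof).values, extract_jfpt(shifted, prof).values, atol=1e-9
        )

    def test_transformer_matches_function(self, dataset150):
        X = dataset150.region2.reflectance
        est = JFPTExtractor(presmooth_window=5).fit(X)
        feats = est.transform(X)
        assert feats.shape == (150, len(est.extrema_) - 1)


class TestSelectorEstimators:
    def test_correlation_selector_support(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(100, 10))
        y = X[:, 4] + 0.1 * rng.normal(size=100)
        est = CorrelationSelector(threshold=0.5).fit(X, y)
        assert 4 in est.get_support(indices=True)
        assert est.transform(X).shape[1] == est.support_.sum()

    def test_selection_roundtrip_through_serialization(self, tmp_path):
        from meatspec.io import read_selection_csv, write_selection_csv

        sel = WavelengthSelection(
            np.array([2, 5, 9]),
            method="correlation",
            params={"threshold": 0.4},
            wavelengths=np.array([410.5, 422.25, 451.0]),
        )
        path = tmp_path / "sel.csv"
        write_selection_csv(sel, path)
        back = read_selection_csv(path)
        assert list(back.indices) == [2, 5, 9]
        assert back.method == "correlation"
        assert back.params["threshold"] == 0.4
        assert np.allclose(back.wavelengths, sel.wavelengths)
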