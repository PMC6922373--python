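"""Triage rules, spectrum aggregation, replicate comparison, T7 formula."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracedecomp import (
    T7Bands,
    TriageSettings,
    aggregate_spectrum,
    classify_well,
    compare_spectra,
    frameshift_class,
    screen_plate,
    t7_indel_fraction,
)


def fake_result(variants, r2=0.99, status="ok"):
    """Stand-in decomposition result: the triage contract needs only the
    frequency table, R^2 and status."""
    table = pd.Series({s: f for s, f in variants}, dtype=float)
    return SimpleNamespace(
        status=status,
        r_squared=r2,
        frequency_table=lambda table=table: table,
    )


class TestClassifyWell:
    @pytest.mark.parametrize(
        "variants, verdict",
        [
            ([(-7, 100.0)], "retain_homozygous"),
            ([(-7, 90.0), (-2, 10.0)], "discard_nonclonal"),  # 10% ally is real but off-pattern
            ([(0, 48.0), (-2, 52.0)], "discard_wildtype"),
            ([(-1, 30.0), (-4, 35.0), (1, 35.0)], "discard_nonclonal"),
            ([(-7, 80.0), (1, 20.0)], "discard_nonclonal"),  # outside 50±15 band
            ([(-7, 52.0), (-3, 48.0)], "retain_compound_het"),
            ([(-7, 60.0), (-3, 40.0)], "retain_compound_het"),  # inside band edge
            ([(0, 3.0), (-7, 97.0)], "retain_homozygous"),  # trace WT below threshold
            ([(-7, 70.0), (-3, 30.0)], "discard_nonclonal"),
        ],
    )
    def test_rule_table(self, variants, verdict):
        assert classify_well(fake_result(variants)).verdict == verdict

    def test_eliminated_fit_is_indeterminate(self):
        res = fake_result([(-7, 100.0)], r2=0.8, status="eliminated_low_fit")
        assert classify_well(res).verdict == "indeterminate"

    def test_subthreshold_variants_dropped(self):
        res = fake_result([(-7, 96.0), (3, 4.0)])
        d = classify_well(res)
        assert d.verdict == "retain_homozygous"
        assert all(s != 3 for s, _ in d.variants_considered)

    def test_wt_threshold_is_configurable(self):
        res = fake_result([(0, 8.0), (-7, 92.0)])
        assert classify_well(res).verdict == "retain_homozygous"
        strict = TriageSettings(wt_min_freq=5.0)
        assert classify_well(res, strict).verdict == "discard_wildtype"

    def test_variant_cutoff_three_follows_caption_reading(self):
        """With max_variants=3 a three-variant well is not discarded for count."""
        res = fake_result([(-1, 34.0), (-4, 33.0), (1, 33.0)])
        assert classify_well(res).verdict == "discard_nonclonal"
        relaxed = TriageSettings(max_variants=3)
        # still discarded, but for the frequency-pattern rule, not the count
        d = classify_well(res, relaxed)
        assert d.verdict == "discard_nonclonal"
        assert "pattern" in d.reason

    def test_pure_function_of_inputs(self):
        a = fake_result([(-7, 52.0), (-3, 48.0)])
        b = fake_result([(-3, 48.0), (-7, 52.0)])  # permuted
        assert classify_well(a) == classify_well(b)


class TestScreenPlate:
    def test_counts_and_order(self):
        wells = [
            ("B2", fake_result([(0, 50.0), (-2, 50.0)])),
            ("A1", fake_result([(-7, 100.0)])),
            ("C3", fake_result([(-1, 30.0), (-4, 35.0), (1, 35.0)])),
            ("D4", fake_result([(-7, 52.0), (-3, 48.0)])),
        ]
        report = screen_plate(wells)
        assert list(report.wells.well) == ["A1", "B2", "C3", "D4"]
        assert report.counts == {
            "retain_homozygous": 1,
            "discard_wildtype": 1,
            "discard_nonclonal": 1,
            "retain_compound_het": 1,
        }
        retained = report.wells[report.wells.verdict.str.startswith("retain")]
        assert retained.confirm_by_imaging.all()

    def test_empty_plate_raises(self):
        with pytest.raises(ValueError):
            screen_plate([])

    def test_duplicate_ids_raise(self):
        r = fake_result([(-7, 100.0)])
        with pytest.raises(ValueError, match="duplicate"):
            screen_plate([("A1", r), ("A1", r)])

    def test_identical_wells_get_identical_verdicts(self):
        r = fake_result([(-7, 100.0)])
        report = screen_plate([("A1", r), ("A2", r)])
        assert report.wells.verdict.nunique() == 1


class TestFrameshift:
    @pytest.mark.parametrize(
        "size, cls",
        [(-3, "in_frame"), (6, "in_frame"), (1, "frameshift"), (-7, "frameshift"),
         (0, "wild_type"), (-15, "in_frame")],
    )
    def test_classification(self, size, cls):
        assert frameshift_class(size) == cls


class TestAggregateSpectrum:
    def test_single_table(self):
        spec = aggregate_spectrum([pd.Series({-2: 100.0})])
        assert spec.deletion_freq[1] == pytest.approx(100.0)
        assert spec.total == pytest.approx(100.0, abs=0.1)

    def test_pooling_arithmetic(self):
        spec = aggregate_spectrum([pd.Series({-2: 100.0}), pd.Series({1: 100.0})])
        assert spec.deletion_freq[1] == pytest.approx(50.0)
        assert spec.insertion_freq[0] == pytest.approx(50.0)

    def test_wild_type_excluded_from_denominator(self):
        spec = aggregate_spectrum([pd.Series({0: 40.0, -2: 60.0})])
        assert spec.deletion_freq[1] == pytest.approx(100.0)

    def test_large_indels_pool_into_other(self):
        spec = aggregate_spectrum([pd.Series({-20: 50.0, -2: 50.0})])
        assert spec.other_freq == pytest.approx(50.0)
        assert spec.total == pytest.approx(100.0, abs=0.1)

    def test_frameshift_fraction(self):
        spec = aggregate_spectrum([pd.Series({-3: 50.0, -2: 25.0, 1: 25.0})])
        assert spec.frameshift_fraction == pytest.approx(50.0)

    def test_pure_wt_tables_raise(self):
        with pytest.raises(ValueError, match="wild type"):
            aggregate_spectrum([pd.Series({0: 100.0})])

    def test_conservation_property(self, rng):
        """Across random tables, bins always sum to 100."""
        for _ in range(20):
            sizes = rng.choice(np.r_[-30:0, 1:31], size=5, replace=False)
            freqs = rng.dirichlet(np.ones(5)) * 100
            spec = aggregate_spectrum([pd.Series(dict(zip(sizes, freqs)))])
            assert spec.total == pytest.approx(100.0, abs=0.1)


def multinomial_spectra(rng, probs, sizes, n_reps, depth=1000):
    """Replicate spectra from multinomial read sampling of a fixed truth."""
    out = []
    for _ in range(n_reps):
        counts = rng.multinomial(depth, probs)
        table = pd.Series({s: 100.0 * c / depth for s, c in zip(sizes, counts) if c})
        out.append(aggregate_spectrum([table]))
    return out


class TestCompareSpectra:
    SIZES = [-1, -2, -3, -5, -8, 1, 2]
    PROBS = np.array([0.25, 0.2, 0.15, 0.15, 0.1, 0.1, 0.05])

    def test_identical_replicates_nothing_significant(self, rng):
        reps = multinomial_spectra(rng, self.PROBS, self.SIZES, 4)
        table = compare_spectra(reps, reps)
        assert not table.significant.any()
        assert (table.effect_pp == 0).all()

    def test_shifted_distribution_detected(self, rng):
        """Short-indel-heavy vs long-indel-heavy profiles flag the moved bins."""
        probs_b = np.array([0.02, 0.03, 0.05, 0.2, 0.5, 0.1, 0.1])
        a = multinomial_spectra(rng, self.PROBS, self.SIZES, 4, depth=2000)
        b = multinomial_spectra(rng, probs_b, self.SIZES, 4, depth=2000)
        table = compare_spectra(a, b).set_index("bin")
        # bins differing by >= 20 pp in truth must be flagged
        assert table.loc["del1", "significant"]
        assert table.loc["del8", "significant"]

    def test_single_replicate_raises(self, rng):
        reps = multinomial_spectra(rng, self.PROBS, self.SIZES, 2)
        with pytest.raises(ValueError):
            compare_spectra(reps[:1], reps)

    def test_type_one_error_controlled(self):
        """Family-wise false-positive rate under the null stays below 7%."""
        rng = np.random.default_rng(777)
        n_false = 0
        n_sims = 200
        for _ in range(n_sims):
            a = multinomial_spectra(rng, self.PROBS, self.SIZES, 4)
            b = multinomial_spectra(rng, self.PROBS, self.SIZES, 4)
            if compare_spectra(a, b).significant.any():
                n_false += 1
        assert n_false / n_sims <= 0.07


class TestT7:
    def test_uncut_is_zero(self):
        assert t7_indel_fraction(T7Bands(parent=1000, frag1=0, frag2=0)) == 0.0

    def test_closed_form_at_36_percent_cut(self):
        # f_cut = 0.36 -> 100 * (1 - sqrt(0.64)) = 20.0
        bands = T7Bands(parent=640, frag1=180, frag2=180)
        assert bands.cut_fraction == pytest.approx(0.36)
        assert t7_indel_fraction(bands) == pytest.approx(20.0)

    def test_fully_cut_limit(self):
        assert t7_indel_fraction(T7Bands(parent=0, frag1=500, frag2=500)) == pytest.approx(100.0)

    def test_all_zero_bands_rejected(self):
        with pytest.raises(ValueError):
            T7Bands(parent=0, frag1=0, frag2=0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(min_value=0, max_value=1, exclude_max=False))
    def test_monotone_and_bounded(self, f):
        """Estimate is monotone in the cut fraction and stays in [0, 100]."""
        total = 1000.0
        frag = total * f / 2
        bands = T7Bands(parent=total * (1 - f), frag1=frag, frag2=frag)
        pct = t7_indel_fraction(bands)
        assert 0.0 <= pct <= 100.0
        eps = 0.01
        if f + eps <= 1:
            frag2 = total * (f + eps) / 2
            higher = T7Bands(parent=total * (1 - f - eps), frag1=frag2, frag2=frag2)
            assert t7_indel_fraction(higher) >= pct

    def test_monotone_over_grid(self):
        grid = np.linspace(0, 1, 100)
        vals = [
            t7_indel_fraction(T7Bands(parent=1 - f, frag1=f / 2, frag2=f / 2))
            if f < 1
            else 100.0
            for f in grid
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
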