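"""Trace decomposition: registration, component building, NNLS estimates.

The independent oracle for small mixtures is an exhaustive grid search
over component weights minimizing the same least-squares residual the
model minimizes — it shares nothing with the NNLS solution path.
"""

import numpy as np
import pytest

from tracedecomp import (
    Chromatogram,
    DecompositionSettings,
    Mixture,
    TraceDecomposition,
    TraceNoiseModel,
    align_control,
    apply_indel,
    build_components,
    decompose,
    overall_efficiency,
    simulate_trace,
)
from tracedecomp.decompose import RegistrationError, UnderdeterminedError


def grid_oracle(sample, control, reference, sizes, step=0.001):
    """Exhaustive grid search over mixture fractions of the given components.

    For each fraction vector on the grid, the overall scale is profiled out
    analytically (1-D least squares); returns frequencies (percent) of the
    best grid point under the same windowed residual as the model.
    """
    model = TraceDecomposition(sample, control, reference)
    X, y, all_sizes = model._design(0)
    cols = [int(np.where(all_sizes == s)[0][0]) for s in sizes]
    P = X[:, cols]
    if len(sizes) == 1:
        return {sizes[0]: 100.0}
    fracs = np.arange(0.0, 1.0 + step / 2, step)
    if len(sizes) == 2:
        W = np.stack([fracs, 1.0 - fracs], axis=1)
    elif len(sizes) == 3:
        W = np.array(
            [
                (f1, f2, 1.0 - f1 - f2)
                for f1 in fracs
                for f2 in np.arange(0.0, 1.0 - f1 + step / 2, step)
            ]
        )
    else:
        raise ValueError("oracle handles <= 3 components")
    M = P @ W.T  # (cells, grid)
    denom = np.einsum("ij,ij->j", M, M)
    scale = np.where(denom > 0, (y @ M) / np.maximum(denom, 1e-300), 0.0)
    rss = np.sum(y**2) - 2 * scale * (y @ M) + scale**2 * denom
    best = W[int(np.argmin(rss))]
    return {s: 100.0 * f for s, f in zip(sizes, best)}


class TestAlignControl:
    def test_identity_offset_zero(self, control_trace):
        assert align_control(control_trace, control_trace) == 0

    def test_prepended_baseline_detected(self, control_trace):
        pad = np.full((3, 4), 1e-3)
        padded = Chromatogram(channels=np.vstack([pad, control_trace.channels]))
        assert align_control(control_trace, padded) == 3
        assert align_control(padded, control_trace) == -3

    def test_unrelated_reference_fails_registration(self, control_trace, reference):
        from tracedecomp import example_reference

        other = example_reference(seed=777, guide="ACGT" * 5)
        other_trace = simulate_trace(
            Mixture(components=((apply_indel(other, 0), 1.0),)),
            other,
            TraceNoiseModel(noise_sd=0.0, crosstalk=0.0),
        )
        with pytest.raises(RegistrationError):
            align_control(other_trace, control_trace)


class TestBuildComponents:
    def test_zero_shift_equals_control(self, control_trace, reference):
        comps = {c.indel_size: c for c in build_components(control_trace, reference.cut_site)}
        c0 = comps[0]
        assert np.array_equal(c0.profile, control_trace.channels[c0.positions])
        assert not c0.masked_positions

    def test_deletion_shift_definition(self, control_trace, reference):
        comps = {c.indel_size: c for c in build_components(control_trace, reference.cut_site)}
        c = comps[-2]
        assert np.array_equal(c.profile, control_trace.channels[c.positions + 2])

    def test_insertion_masks_cut_positions(self, control_trace, reference):
        comps = {c.indel_size: c for c in build_components(control_trace, reference.cut_site)}
        c = comps[3]
        cut = reference.cut_site
        assert c.masked_positions == frozenset(range(cut, cut + 3))
        assert np.array_equal(c.profile, control_trace.channels[c.positions - 3])

    def test_window_past_trace_raises(self, control_trace, reference):
        st = DecompositionSettings(decomposition_window=(115, 1000))
        with pytest.raises(ValueError, match="past"):
            build_components(control_trace, reference.cut_site, st)


class TestDecompose:
    def test_pure_wild_type(self, control_trace, reference):
        res = decompose(control_trace, control_trace, reference)
        assert res.status == "ok"
        assert res.r_squared == pytest.approx(1.0)
        table = res.frequency_table()
        assert list(table.index) == [0]
        assert table[0] == pytest.approx(100.0)
        assert overall_efficiency(res) == pytest.approx(0.0)

    @pytest.mark.parametrize("sizes,props", [
        ((0, -7), (0.5, 0.5)),
        ((-3, -11), (0.25, 0.75)),
        ((0, 2), (0.9, 0.1)),
    ])
    def test_noiseless_mixture_matches_grid_oracle(
        self, reference, wt_allele, noiseless, control_trace, sizes, props
    ):
        alleles = [
            apply_indel(reference, s, "G" * max(s, 0)) for s in sizes
        ]
        mix = Mixture(components=tuple(zip(alleles, props)))
        sample = simulate_trace(mix, reference, noiseless)
        res = decompose(sample, control_trace, reference)
        oracle = grid_oracle(sample, control_trace, reference, list(sizes))
        for s, p in zip(sizes, props):
            assert res.frequency(s) == pytest.approx(100 * p, abs=0.5)
            assert res.frequency(s) == pytest.approx(oracle[s], abs=0.5)

    def test_shuffled_control_eliminated_by_r2(self, reference, noisy_control, rng):
        mix = Mixture(
            components=(
                (apply_indel(reference, -7), 0.5),
                (apply_indel(reference, -11), 0.5),
            )
        )
        sample = simulate_trace(mix, reference, TraceNoiseModel(seed=5))
        perm = rng.permutation(len(noisy_control))
        shuffled = Chromatogram(channels=noisy_control.channels[perm])
        res = decompose(sample, shuffled, reference)
        assert res.r_squared < 0.95
        assert res.status == "eliminated_low_fit"
        with pytest.raises(ValueError):
            overall_efficiency(res)

    def test_frequencies_sum_to_100(self, reference, noisy_control):
        mix = Mixture(
            components=(
                (apply_indel(reference, -2), 0.4),
                (apply_indel(reference, -9), 0.6),
            )
        )
        sample = simulate_trace(mix, reference, TraceNoiseModel(seed=17))
        res = decompose(sample, noisy_control, reference)
        assert res.variants.frequency.sum() == pytest.approx(100.0, abs=0.1)
        assert (res.variants.frequency >= 0).all()

    def test_shift_equivariance(self, reference, noisy_control):
        """A registration offset applied to the sample leaves the table unchanged."""
        mix = Mixture(
            components=(
                (apply_indel(reference, -5), 0.5),
                (apply_indel(reference, -12), 0.5),
            )
        )
        sample = simulate_trace(mix, reference, TraceNoiseModel(seed=23))
        res0 = decompose(sample, noisy_control, reference)
        pad = np.full((4, 4), 1e-3)
        shifted = Chromatogram(channels=np.vstack([pad, sample.channels]))
        res1 = decompose(shifted, noisy_control, reference)
        assert res1.offset == -4
        t0, t1 = res0.frequency_table(), res1.frequency_table()
        assert set(t0.index) == set(t1.index)
        for s in t0.index:
            assert t1[s] == pytest.approx(t0[s], abs=0.5)

    def test_r2_monotone_in_candidate_set(self, reference, noisy_control):
        """Nesting: a candidate set containing the true sizes fits no worse."""
        mix = Mixture(
            components=(
                (apply_indel(reference, -20), 0.5),
                (apply_indel(reference, -25), 0.5),
            )
        )
        sample = simulate_trace(mix, reference, TraceNoiseModel(seed=31))
        narrow = DecompositionSettings(max_indel=10)
        wide = DecompositionSettings(max_indel=30)
        r2_narrow = decompose(sample, noisy_control, reference, narrow).r_squared
        r2_wide = decompose(sample, noisy_control, reference, wide).r_squared
        assert r2_wide >= r2_narrow - 1e-12

    def test_efficiency_definition(self, reference, noiseless, control_trace, wt_allele):
        mix = Mixture(components=((wt_allele, 0.25), (apply_indel(reference, -7), 0.75)))
        sample = simulate_trace(mix, reference, noiseless)
        res = decompose(sample, control_trace, reference)
        assert overall_efficiency(res) == pytest.approx(75.0, abs=0.5)

    def test_underdetermined_window_raises(self, reference, control_trace):
        st = DecompositionSettings(decomposition_window=(115, 290), max_indel=30)
        with pytest.raises(UnderdeterminedError):
            TraceDecomposition(control_trace, control_trace, reference, st).fit()

    def test_summary_renders(self, control_trace, reference):
        res = decompose(control_trace, control_trace, reference)
        s = res.summary()
        assert "R-squared" in s and "status" in s


class TestParameterRecovery:
    def test_two_allele_recovery_under_default_noise(self, reference, wt_allele):
        """90:10 / 75:25 / 50:50 two-allele mixes recover within 3 pp on average."""
        from dataclasses import replace

        props = [(0.9, 0.1), (0.75, 0.25), (0.5, 0.5)]
        errors, all_detected = [], True
        rng = np.random.default_rng(1234)
        for i in range(18):
            p = props[i % 3]
            sizes = rng.choice(np.r_[-15:0, 1:4], size=2, replace=False)
            alleles = [
                apply_indel(reference, int(s), "".join(rng.choice(list("ACGT"), max(int(s), 0))))
                for s in sizes
            ]
            mix = Mixture(components=tuple(zip(alleles, p)))
            noise = TraceNoiseModel(seed=100 + i)
            sample = simulate_trace(mix, reference, noise)
            control = simulate_trace(
                Mixture(components=((wt_allele, 1.0),)),
                reference,
                replace(noise, seed=500 + i),
            )
            res = decompose(sample, control, reference)
            tbl = res.frequency_table()
            for s, true_p in zip(sizes, p):
                errors.append(abs(tbl.get(int(s), 0.0) - 100 * true_p))
                pv = res.variants.set_index("indel_size").p_value.get(int(s), 1.0)
                all_detected &= pv < 1e-4
        assert np.mean(errors) <= 3.0
        assert all_detected
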