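"""Compartment pipeline: smoothing, correlation, contrast enhancement,
eigenvector modes, and recovery of generator compartments under Rabl."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rablhic.compartments import (
    compartment_track_correlations,
    compute_compartments,
    contrast_enhance,
    correlation_map,
    label_accuracy,
    pc1,
    smooth_oe,
)
from rablhic.genome import Binning
from rablhic.hic_core import balance_matrix
from rablhic.synthetic import (
    SyntheticGenomeConfig,
    simulate_contact_map,
    simulate_tracks,
    simulate_truth,
    _centromere_distance,
)
from rablhic.tracks import GenomicTrack


class TestSmoothOE:
    def test_window_zero_is_identity(self):
        m = np.random.default_rng(0).uniform(size=(10, 10))
        m = 0.5 * (m + m.T)
        assert np.array_equal(smooth_oe(m, 0), m)

    def test_constant_matrix_unchanged(self):
        m = np.full((12, 12), 3.0)
        assert np.allclose(smooth_oe(m, 2), m)

    def test_single_spike_averages_with_neighborhood(self):
        b = 1.0
        v = 10.0
        m = np.full((15, 15), b)
        m[7, 3] = v
        m[3, 7] = v
        sm = smooth_oe(m, 1)
        assert sm[7, 3] == pytest.approx((v + 8 * b) / 9)

    def test_missing_entries_ignored_not_poisoned(self):
        m = np.full((10, 10), 2.0)
        m[4, 5] = m[5, 4] = np.nan
        sm = smooth_oe(m, 1)
        assert np.isnan(sm[4, 5])
        assert sm[4, 4] == pytest.approx(2.0)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_oe(np.ones((4, 4)), 3)


class TestCorrelationMap:
    def test_two_group_checkerboard_gives_plus_minus_one(self):
        sign = np.array([1, 1, -1, -1, 1, -1] * 4, dtype=float)
        oe = 1.0 + 0.5 * np.outer(sign, sign)
        c = correlation_map(oe)
        like = sign[:, None] == sign[None, :]
        assert np.allclose(c[like], 1.0)
        assert np.allclose(c[~like], -1.0)

    def test_duplicated_row_correlates_at_one(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(8, 8))
        m = 0.5 * (m + m.T)
        m[3] = m[5]
        m[:, 3] = m[:, 5]
        c = correlation_map(m)
        assert c[3, 5] == pytest.approx(1.0)

    def test_independent_rows_have_small_mean_absolute_correlation(self):
        rng = np.random.default_rng(2)
        n = 200
        m = rng.normal(size=(n, n))  # not symmetric; rows independent
        c = correlation_map(m)
        off = ~np.eye(n, dtype=bool)
        assert np.nanmean(np.abs(c[off])) < 0.2

    def test_too_few_good_bins_rejected(self):
        m = np.full((5, 5), np.nan)
        m[0, 0] = 1.0
        with pytest.raises(ValueError, match="3 good bins"):
            correlation_map(m)


class TestContrastEnhance:
    def test_block_spanning_half_range_stretched_to_full(self):
        m = np.array([[0.5, -0.5], [-0.5, 0.5]])
        out = contrast_enhance(m, 2)
        assert out.min() == pytest.approx(-1.0)
        assert out.max() == pytest.approx(1.0)

    def test_constant_block_maps_to_zero(self):
        out = contrast_enhance(np.full((4, 4), 0.7), 2)
        assert np.allclose(out, 0.0)

    def test_full_range_blocks_unchanged_after_symmetrization(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(-1, 1, (8, 8))
        m = 0.5 * (m + m.T)
        # force each 4x4 block to attain both extremes
        for i0 in (0, 4):
            for j0 in (0, 4):
                m[i0, j0] = -1.0
                m[i0 + 1, j0 + 1] = 1.0
        m = np.maximum(m, m.T) if False else 0.5 * (m + m.T)
        for i0 in (0, 4):
            for j0 in (0, 4):
                m[i0, j0] = -1.0
                m[i0 + 1, j0 + 1] = 1.0
        sym = 0.5 * (m + m.T)
        out = contrast_enhance(m, 4)
        assert np.allclose(out, sym, atol=1e-12)

    def test_output_bounded_and_affine_invariant_per_block(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(-0.3, 0.9, (9, 9))
        m = 0.5 * (m + m.T)
        out1 = contrast_enhance(m, 3)
        assert np.nanmax(np.abs(out1)) <= 1.0 + 1e-12
        # affine rescale of every block leaves the result unchanged
        out2 = contrast_enhance(0.25 * m + 3.0, 3)
        assert np.allclose(out1, out2)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10_000))
    def test_property_bounded_for_random_matrices(self, block, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(12, 12))
        m = 0.5 * (m + m.T)
        out = contrast_enhance(m, block)
        assert np.nanmax(np.abs(out)) <= 1.0 + 1e-12

    def test_small_block_rejected(self):
        with pytest.raises(ValueError):
            contrast_enhance(np.ones((4, 4)), 1)


class TestPC1:
    def test_rank_one_matrix_recovers_generating_vector(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=30)
        m = np.outer(v, v)
        binning = Binning(("c",), (30 * 10_000,), 10_000)
        e1, _ = pc1(m, binning, "c", mode="default")
        cos = abs(e1 @ v) / (np.linalg.norm(e1) * np.linalg.norm(v))
        assert cos > 0.999

    def test_checkerboard_correlation_partitions_groups_by_sign(self):
        sign = np.array([1, -1, 1, 1, -1, -1] * 5, dtype=float)
        c = np.outer(sign, sign)
        binning = Binning(("c",), (30 * 10_000,), 10_000)
        e1, _ = pc1(c, binning, "c", mode="default")
        called = np.sign(e1)
        agree = max(np.mean(called == sign), np.mean(called == -sign))
        assert agree == 1.0

    def test_framed_mode_computes_frames_independently(self):
        n = 40
        sign = np.ones(n)
        sign[10:20] = -1  # structure only in the first half
        c = np.outer(sign, sign)
        binning = Binning(("c",), (n * 10_000,), 10_000)
        e1, _ = pc1(c, binning, "c", mode="framed", frame_bp=20 * 10_000)
        assert np.isfinite(e1).all()
        first = np.sign(e1[:20])
        agree = max(np.mean(first == sign[:20]), np.mean(first == -sign[:20]))
        assert agree == 1.0

    def test_cropped_mode_masks_regions(self):
        import pandas as pd

        n = 30
        rng = np.random.default_rng(6)
        m = rng.normal(size=(n, n))
        m = 0.5 * (m + m.T)
        binning = Binning(("c",), (n * 10_000,), 10_000)
        crop = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [50_000]})
        e1, _ = pc1(m, binning, "c", mode="cropped", crop_regions=crop)
        assert np.isnan(e1[:5]).all()
        assert np.isfinite(e1[5:]).all()


class TestCePC1Pipeline:
    def test_rabl_map_cepc1_recovers_compartments_where_default_pc1_fails(self, rabl_map):
        bal, truth, tracks = rabl_map
        orient = tracks["gene_density"]
        ce = compute_compartments(bal, "contrast_enhanced", orientation_track=orient)
        de = compute_compartments(bal, "default", orientation_track=orient)
        acc_ce = label_accuracy(ce.ab_labels, truth.labels)
        acc_de = label_accuracy(de.ab_labels, truth.labels)
        assert acc_ce >= 0.9
        assert acc_ce > acc_de
        # Pearson with signed truth labels is strong for cePC1
        fin = np.isfinite(ce.cepc1.values)
        r = np.corrcoef(ce.cepc1.values[fin], truth.labels_signed()[fin])[0, 1]
        assert abs(r) >= 0.8

    def test_default_pc1_tracks_positional_structure_more_than_truth(self, rabl_map):
        bal, truth, tracks = rabl_map
        de = compute_compartments(bal, "default", orientation_track=tracks["gene_density"])
        fin = np.isfinite(de.cepc1.values)
        sgn = truth.labels_signed()
        # positional structure: distance to centromere (the Rabl axis)
        dcen = _centromere_distance(truth)
        r_pos = max(
            abs(np.corrcoef(de.cepc1.values[fin], dcen[fin])[0, 1]),
            abs(np.corrcoef(np.abs(de.cepc1.values[fin]), dcen[fin])[0, 1]),
        )
        r_truth = abs(np.corrcoef(de.cepc1.values[fin], sgn[fin])[0, 1])
        ce = compute_compartments(bal, "contrast_enhanced", orientation_track=tracks["gene_density"])
        finc = np.isfinite(ce.cepc1.values)
        r_truth_ce = abs(np.corrcoef(ce.cepc1.values[finc], sgn[finc])[0, 1])
        assert r_truth_ce > r_truth  # enhancement shifts PC1 toward compartments

    def test_without_rabl_default_and_cepc1_agree(self):
        cfg = SyntheticGenomeConfig(rabl_strength=1.0, cen_tel_multiplier=1.0)
        truth = simulate_truth(cfg, 31)
        bal = balance_matrix(simulate_contact_map(cfg, truth, 32), bad_bin_cov_frac=0)
        tracks = simulate_tracks(cfg, truth, 33)
        ce = compute_compartments(bal, "contrast_enhanced", orientation_track=tracks["gene_density"])
        de = compute_compartments(bal, "default", orientation_track=tracks["gene_density"])
        fin = np.isfinite(ce.cepc1.values) & np.isfinite(de.cepc1.values)
        r = np.corrcoef(ce.cepc1.values[fin], de.cepc1.values[fin])[0, 1]
        assert abs(r) >= 0.9

    def test_same_seed_and_parameters_identical_output(self, rabl_map):
        bal, truth, tracks = rabl_map
        a = compute_compartments(bal, "contrast_enhanced", orientation_track=tracks["gene_density"])
        b = compute_compartments(bal, "contrast_enhanced", orientation_track=tracks["gene_density"])
        assert np.array_equal(a.cepc1.values, b.cepc1.values, equal_nan=True)

    def test_sign_convention_a_bins_positive_on_every_chromosome(self, rabl_map):
        bal, truth, tracks = rabl_map
        ce = compute_compartments(bal, "contrast_enhanced", orientation_track=tracks["gene_density"])
        for chrom in bal.binning.chrom_names:
            s = bal.binning.chrom_slice(chrom)
            vals = ce.cepc1.values[s]
            labs = ce.ab_labels[s]
            a_vals = vals[(labs == "A") & np.isfinite(vals)]
            if a_vals.size:
                assert a_vals.mean() > 0


class TestTrackCorrelations:
    def _track(self, values, name="t"):
        binning = Binning(("c",), (len(values) * 10_000,), 10_000)
        return GenomicTrack(binning, np.asarray(values, dtype=float), name)

    def test_self_correlation_is_one(self):
        v = np.random.default_rng(7).normal(size=100)
        t = self._track(v)
        df = compartment_track_correlations(t, {"same": self._track(v)})
        assert df.loc[0, "pearson_r"] == pytest.approx(1.0)

    def test_independent_tracks_have_small_correlation(self):
        rng = np.random.default_rng(8)
        t = self._track(rng.normal(size=1000))
        df = compartment_track_correlations(t, {"other": self._track(rng.normal(size=1000))})
        assert abs(df.loc[0, "pearson_r"]) < 0.1

    def test_generator_effect_direction_recovered(self, rabl_map):
        bal, truth, tracks = rabl_map
        ce = compute_compartments(bal, "contrast_enhanced", orientation_track=tracks["gene_density"])
        df = compartment_track_correlations(ce.cepc1, tracks).set_index("track")
        assert df.loc["gene_density", "pearson_r"] > 0.3
        assert df.loc["expression", "pearson_r"] > 0.3

    def test_too_few_shared_bins_rejected(self):
        t = self._track(np.arange(12.0))
        other = self._track(np.full(12, np.nan))
        with pytest.raises(ValueError, match="10 shared"):
            compartment_track_correlations(t, {"o": other})
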