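import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcdose import ArrayTruth, generate_microarray_set
from gcdose.microarray import (
    TwoChannelArray,
    average_replicates,
    loop_consistency,
    mbc_correct,
    mean_log_ratio,
    normalize,
    read_spot_table,
)


def simple_array(f_r, b_r, f_g, b_g, **kw):
    n = len(np.atleast_1d(f_r))
    return TwoChannelArray(
        probe_id=[f"P{i}" for i in range(n)], f_r=f_r, b_r=b_r, f_g=f_g, b_g=b_g, **kw
    )


class TestMBC:
    def test_unit_background_leaves_foreground_unchanged(self):
        a = simple_array([100.0, 200.0], 1.0, [50.0, 80.0], 1.0)
        c = mbc_correct(a)
        assert np.allclose(c.f_r, [100.0, 200.0])
        assert np.allclose(c.f_g, [50.0, 80.0])

    def test_hand_value_1024_over_16(self):
        a = simple_array([1024.0, 1024.0, 1024.0], 16.0, [1024.0] * 3, 16.0)
        c = mbc_correct(a)
        assert np.allclose(c.f_r, 64.0)  # 2^(10-4)

    def test_constant_background_divides_out(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(10, 1e4, 50)
        a = simple_array(f, 8.0, f[::-1].copy(), 8.0)
        c = mbc_correct(a)
        assert np.allclose(c.f_r, f / 8.0, rtol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        f=st.lists(st.floats(1.0, 1e6), min_size=3, max_size=20),
        bl=st.floats(0.5, 1e3),
    )
    def test_log_subtraction_equals_division(self, f, bl):
        """2^(log2 F - log2 Bl) == F / Bl to machine precision."""
        f = np.asarray(f)
        a = simple_array(f, bl, f, bl)
        c = mbc_correct(a)
        assert np.allclose(c.f_r, f / np.median(np.full_like(f, bl)), rtol=1e-10)

    def test_quantile_estimator_option(self):
        bg = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        a = simple_array(np.full(5, 100.0), bg, np.full(5, 100.0), bg)
        c = mbc_correct(a, background_estimator="quantile", quantile=0.25)
        assert np.allclose(c.f_r, 100.0 / 2.0)

    def test_per_spot_background_option(self):
        bg = np.array([2.0, 4.0])
        a = simple_array([8.0, 8.0], bg, [8.0, 8.0], bg)
        c = mbc_correct(a, per_spot=True)
        assert np.allclose(c.f_r, [4.0, 2.0])

    def test_nonpositive_foreground_masked_or_rejected(self):
        a = simple_array([-1.0, -2.0], 1.0, [-1.0, -2.0], 1.0)
        with pytest.raises(ValueError):
            mbc_correct(a)


class TestReplicateAveraging:
    def _triplicate(self, values):
        out = []
        for rep, v in enumerate(values, start=1):
            a = simple_array(v, 1.0, v, 1.0, replicate=rep, design="0v1")
            a.corrected = True
            out.append(a)
        return out

    def test_geometric_mean_2_4_8_is_4(self):
        m = average_replicates(self._triplicate([[2.0], [4.0], [8.0]]))
        assert m.intensities["0v1"]["Fa_R"].iloc[0] == pytest.approx(4.0, rel=1e-12)

    def test_idempotent_on_identical_replicates(self):
        m = average_replicates(self._triplicate([[7.5], [7.5], [7.5]]))
        assert m.intensities["0v1"]["Fa_R"].iloc[0] == pytest.approx(7.5, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(v=st.lists(st.floats(0.1, 1e5), min_size=3, max_size=3))
    def test_log_of_geometric_mean_is_mean_of_logs(self, v):
        m = average_replicates(self._triplicate([[x] for x in v]))
        assert np.log2(m.intensities["0v1"]["Fa_R"].iloc[0]) == pytest.approx(
            np.mean(np.log2(v)), rel=1e-9
        )

    def test_masked_replicate_reduces_n(self):
        reps = self._triplicate([[2.0], [4.0], [8.0]])
        reps[2].mask = np.array([True])
        m = average_replicates(reps)
        assert m.n_replicates["0v1"].iloc[0] == 2
        assert m.intensities["0v1"]["Fa_R"].iloc[0] == pytest.approx(np.sqrt(8.0))

    def test_uncorrected_arrays_rejected(self):
        a = simple_array([2.0], 1.0, [2.0], 1.0)
        with pytest.raises(ValueError, match="corrected"):
            average_replicates([a])


class TestMeanLogRatio:
    @pytest.mark.parametrize(
        "ratios, expected", [((2, 2, 2), 1.0), ((1, 2, 4), 1.0), ((1, 1, 1), 0.0)]
    )
    def test_hand_values(self, ratios, expected):
        assert mean_log_ratio(ratios) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            mean_log_ratio([1.0, -2.0, 4.0])

    @settings(max_examples=30, deadline=None)
    @given(v=st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=6))
    def test_equals_log2_geometric_mean(self, v):
        gm = np.prod(v) ** (1.0 / len(v))
        assert mean_log_ratio(v) == pytest.approx(np.log2(gm), rel=1e-6, abs=1e-9)


class TestNormalization:
    def _matrix_from_channels(self, channels):
        from gcdose.microarray import ExpressionMatrix

        m = ExpressionMatrix()
        for lab, (r, g) in channels.items():
            idx = pd.Index([f"P{i}" for i in range(len(r))], name="probe_id")
            m.intensities[lab] = pd.DataFrame({"Fa_R": r, "Fa_G": g}, index=idx)
            m.replicate_ratios[lab] = pd.DataFrame(index=idx)
            m.n_replicates[lab] = pd.Series(1, index=idx)
        return m

    def test_quantile_hand_example(self):
        m = self._matrix_from_channels({"0v1": ([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])})
        out = normalize(m, method="quantile")
        assert np.allclose(sorted(out.intensities["0v1"]["Fa_R"]), [1.5, 3.0, 4.5])
        assert np.allclose(sorted(out.intensities["0v1"]["Fa_G"]), [1.5, 3.0, 4.5])

    def test_quantile_equalizes_sorted_values_across_arrays(self, noisy_arrays):
        arrays, _ = noisy_arrays
        m = average_replicates([mbc_correct(a) for a in arrays])
        out = normalize(m, method="quantile")
        ref = None
        for lab, df in out.intensities.items():
            for ch in ("Fa_R", "Fa_G"):
                v = np.sort(df[ch].to_numpy())
                if ref is None:
                    ref = v
                assert np.allclose(v, ref, rtol=1e-9)

    def test_loess_leaves_zero_signal_alone(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(50, 5000, 200)
        m = self._matrix_from_channels({"0v1": (g.copy(), g.copy())})
        out = normalize(m, method="loess")
        ratios = out.log_ratios()["0v1"].to_numpy()
        assert np.max(np.abs(ratios)) < 1e-8

    def test_loess_removes_injected_intensity_bias(self):
        # oracle: re-subtract the known injected bias curve
        rng = np.random.default_rng(2)
        n = 600
        a_vals = rng.uniform(5, 13, n)  # log2 mean intensity
        m_true = rng.normal(0.0, 0.05, n)
        bias = 0.4 * np.sin(a_vals / 2.0) + 0.1 * (a_vals - 9.0)
        m_obs = m_true + bias
        fa_r = 2.0 ** (a_vals + m_obs / 2.0)
        fa_g = 2.0 ** (a_vals - m_obs / 2.0)
        mat = self._matrix_from_channels({"0v1": (fa_r, fa_g)})
        out = normalize(mat, method="loess")
        m_norm = out.log_ratios()["0v1"].to_numpy()
        # bias amplitude ~0.5; after removal the residual must be noise-like
        assert np.mean(np.abs(m_norm - (m_true - m_true.mean()))) < 0.05

    def test_rank_invariant_removes_constant_offset(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(50, 5000, 400)
        offset = 0.8  # log2 dye bias
        mat = self._matrix_from_channels({"0v1": (g * 2**offset, g.copy())})
        out = normalize(mat, method="rank_invariant")
        ratios = out.log_ratios()["0v1"].to_numpy()
        assert np.median(np.abs(ratios)) < 0.05

    def test_too_few_probes_rejected(self):
        m = self._matrix_from_channels({"0v1": ([1.0] * 5, [1.0] * 5)})
        with pytest.raises(ValueError):
            normalize(m, method="loess")

    def test_unknown_method_rejected(self):
        m = self._matrix_from_channels({"0v1": ([1.0] * 30, [1.0] * 30)})
        with pytest.raises(ValueError):
            normalize(m, method="median")


class TestLoopConsistency:
    def test_hand_residual(self):
        idx = pd.Index(["a"])
        out = loop_consistency(
            pd.Series([1.0], index=idx), pd.Series([0.5], index=idx), pd.Series([2.0], index=idx)
        )
        assert out["residual"].iloc[0] == pytest.approx(-0.5)

    def test_zero_at_zero_noise_end_to_end(self, noiseless_arrays):
        arrays, _ = noiseless_arrays
        m = average_replicates([mbc_correct(a) for a in arrays])
        r = m.log_ratios()
        out = loop_consistency(r["0v1"], r["1v3"], r["0v3"])
        assert out.attrs["median_abs_residual"] < 1e-9

    def test_noisy_residual_scales_with_contrast_noise(self):
        # each contrast ratio has sd s = 2*sigma/sqrt(3) (four log2-noise
        # terms per replicate ratio, averaged over 3 replicates), so the
        # residual is N(0, sqrt(3) s) and median|residual| = 0.6745*sqrt(3)*s
        sigma = 0.15
        arrays, _ = generate_microarray_set(
            design_labels=["0v1", "1v3", "0v3"],
            truth=ArrayTruth(spot_noise_sd=sigma, de_fraction=0.0),
            seed=29,
        )
        m = average_replicates([mbc_correct(a) for a in arrays])
        r = m.log_ratios()
        out = loop_consistency(r["0v1"], r["1v3"], r["0v3"])
        s_contrast = 2.0 * sigma / np.sqrt(3.0)
        predicted = 0.6745 * np.sqrt(3.0) * s_contrast
        assert out.attrs["median_abs_residual"] == pytest.approx(predicted, rel=0.2)

    def test_disjoint_probe_sets_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError):
            loop_consistency(a, a, b)


class TestEndToEndRecovery:
    def test_preprocessing_recovers_true_ratios_within_noise_tolerance(self):
        # noise model: per-replicate ratio sd = 2*sigma; contrast sd
        # 2*sigma/sqrt(n_rep); with sigma=0.15 the mixed triplicate/single
        # RMSE bound is sqrt((3*(0.173)^2 + 2*(0.3)^2)/5) = 0.232, padded
        # x1.75 for normalization edge effects at the DE tails -> 0.40
        arrays, truth = generate_microarray_set(seed=11)
        m = average_replicates([mbc_correct(a) for a in arrays])
        for method in ("loess", "rank_invariant", "quantile"):
            out = normalize(m, method=method)
            ratios = out.log_ratios()
            err = (ratios - truth[ratios.columns]).to_numpy()
            rmse = float(np.sqrt(np.nanmean(err**2)))
            assert rmse < 0.40, f"{method}: RMSE {rmse:.3f}"


class TestSpotTableIO:
    def test_native_round_trip(self, tmp_path):
        a = simple_array([10.0, 20.0], [1.0, 2.0], [30.0, 40.0], [3.0, 4.0], design="1v3", replicate=2)
        path = tmp_path / "spots.tsv"
        a.write(path)
        back = read_spot_table(path)
        assert back.design == "1v3"
        assert back.replicate == 2
        assert np.allclose(back.f_r, a.f_r)
        assert np.allclose(back.b_g, a.b_g)

    def test_gpr_dialect(self, tmp_path):
        content = (
            "ATF\t1.0\n"
            "2\t4\n"
            '"Type=GenePix Results 3"\n'
            '"Wavelengths=635\t532"\n'
            "ID\tF635 Median\tB635 Median\tF532 Median\tB532 Median\n"
            "geneA\t1000\t50\t900\t40\n"
            "geneB\t800\t45\t850\t42\n"
        )
        path = tmp_path / "array.gpr"
        path.write_text(content)
        a = read_spot_table(path, replicate=1, design="0v1")
        assert a.probe_id == ["geneA", "geneB"]
        assert np.allclose(a.f_r, [1000.0, 800.0])
        assert np.allclose(a.b_g, [40.0, 42.0])

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\tF_R\n.p\t1\n")
        with pytest.raises(ValueError, match="lacks columns"):
            read_spot_table(path)
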