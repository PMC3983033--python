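"""Scale-resolved association statistic, macro/micro labels, Hi-C alpha."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intbias.controls import sample_matched_controls
from intbias.datasets import ContactMatrix, ControlSet, IntegrationSet
from intbias.scales import (
    adjusted_T,
    classify_macro_micro,
    hic_alpha,
    null_calibration,
    orientation_bias,
    rank_normalize,
    scale_association,
    score_at_scales,
    tscore,
)
from intbias.simulate import (
    BiasModel,
    FeatureCoupling,
    FeatureSpec,
    make_feature_tracks,
    simulate_integrations,
)
from intbias.tracks import FeatureTrack


class TestScoreAtScales:
    def test_constant_track_all_scores_equal(self):
        tr = FeatureTrack("c", 100, {"chr1": np.full(1000, 3.5)})
        ssm = score_at_scales(np.array(["chr1"] * 5),
                              np.array([10_000, 20_000, 30_000, 40_000, 50_000]),
                              tr, np.array([400, 1600, 6400]))
        np.testing.assert_allclose(ssm.scores, 3.5)

    def test_linear_ramp_up_down_cancel(self):
        # on a linear track the mean of the +s and -s windows equals the
        # at-site window mean
        tr = FeatureTrack("ramp", 100, {"chr1": np.arange(1000, dtype=float)})
        ssm = score_at_scales(np.array(["chr1"] * 3),
                              np.array([30_000, 50_000, 70_000]),
                              tr, np.array([1000, 4000]))
        for k in range(1, ssm.scores.shape[1]):
            np.testing.assert_allclose(ssm.scores[:, k], ssm.scores[:, 0])

    def test_matches_naive_per_locus_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=2000)
        tr = FeatureTrack("r", 50, {"chr1": vals})
        loci = rng.integers(5000, 95_000, size=200)
        scales = np.array([200, 800, 3200])
        ssm = score_at_scales(np.array(["chr1"] * 200), loci, tr, scales,
                              window=200)
        for i, p in enumerate(loci):
            def wmean(center):
                lo = (center - 100) // 50
                hi = (center + 99) // 50 + 1
                lo, hi = max(lo, 0), min(hi, 2000)
                return vals[lo:hi].mean() if hi > lo else np.nan
            assert np.isclose(ssm.scores[i, 0], wmean(p))
            for k, s in enumerate(scales):
                expect = np.nanmean([wmean(p - s), wmean(p + s)])
                assert np.isclose(ssm.scores[i, k + 1], expect)


class TestTScore:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(1).normal(size=50)
        assert tscore(x, x) == 0.0

    def test_degenerate_zero_variance(self):
        a, b = np.full(10, 2.0), np.full(10, 1.0)
        assert np.isinf(tscore(a, b)) and tscore(a, b) > 0
        assert tscore(a, a) == 0.0

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=200), rng.normal(0.3, 1.2, size=200)
        # independent recomputation of the equal-n two-sample statistic
        n = len(a)
        expect = (a.mean() - b.mean()) / np.sqrt(
            (a.var(ddof=1) + b.var(ddof=1)) / n)
        assert tscore(a, b) == pytest.approx(expect, rel=1e-12)

    def test_vectorized_matches_loop(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(7, 40))
        B = rng.normal(size=(7, 40))
        vec = tscore(A, B)
        loop = np.array([tscore(A[i], B[i]) for i in range(7)])
        np.testing.assert_allclose(vec, loop)


class TestAdjustedT:
    def test_all_zero_inputs(self):
        T, p = adjusted_T(0.0, np.zeros(10))
        assert T == 0.0 and p == 1.0

    def test_null_variance_one_plus_inv_m(self):
        rng = np.random.default_rng(4)
        m = 10
        z_i = rng.standard_normal(100_000)
        z_c = rng.standard_normal((100_000, m))
        T, _ = adjusted_T(z_i, z_c)
        assert np.var(T) == pytest.approx(1 + 1 / m, abs=0.02)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(5)
        m = 10
        T, p = adjusted_T(rng.standard_normal(50_000),
                          rng.standard_normal((50_000, m)))
        rate = np.mean(p < 0.05)
        se = np.sqrt(0.05 * 0.95 / 50_000)
        assert abs(rate - 0.05) < 3 * se


@pytest.fixture(scope="module")
def null_pair(assembly, ta_sites, gatc_map):
    ints = simulate_integrations(assembly, BiasModel(motif="TA"), n=1500,
                                 restriction_map=gatc_map, seed=90)
    cs = sample_matched_controls(ints, ta_sites, gatc_map, m=5, seed=91)
    return ints, cs


class TestScaleAssociation:

    def test_feature_identical_everywhere_small_T(self, assembly, annotation,
                                                  null_pair):
        ints, cs = null_pair
        tracks, _ = make_feature_tracks(
            assembly, annotation,
            [FeatureSpec(name="noise", noise_sd=1.0, autocorr_length=500)],
            bin_size=100, seed=92)
        res = scale_association(ints, cs, tracks,
                                scales=np.array([400, 3200, 25_600]))
        assert (res.q.to_numpy() > 0.05).all()

    def test_positive_coupling_recovered_with_sign(self, assembly, annotation,
                                                   ta_sites, gatc_map):
        tracks, _ = make_feature_tracks(
            assembly, annotation,
            [FeatureSpec(name="target", noise_sd=1.0, autocorr_length=2000)],
            bin_size=100, seed=93)
        model = BiasModel(motif="TA",
                          coefficients=[FeatureCoupling("target", 1.5, 0)])
        ints = simulate_integrations(assembly, model, n=2000,
                                     tracks={"target": tracks[0]},
                                     restriction_map=gatc_map, seed=94)
        cs = sample_matched_controls(ints, ta_sites, gatc_map, m=5, seed=95)
        res = scale_association(ints, cs, tracks,
                                scales=np.array([400, 1600, 25_600]))
        # at-site signal exceeds distant neighborhoods: positive T at the
        # largest scale, significant
        assert res.T.loc["target"].iloc[-1] > 0
        assert res.q.loc["target"].iloc[-1] < 0.05

    def test_rank_normalize_range_and_ties(self):
        r = rank_normalize(np.array([3.0, 1.0, 2.0, np.nan]))
        assert np.nanmax(r) == 1.0 and np.nanmin(r) > 0
        assert np.isnan(r[3])


class TestMacroMicro:
    def test_hand_worked_toy_table(self):
        sA = pd.Series({"f1": 100.0, "f2": 200.0, "f3": 400.0,
                        "f4": 800.0, "f5": 1600.0, "f6": np.nan})
        sB = pd.Series({"f1": 200.0, "f2": 100.0, "f3": 800.0,
                        "f4": 400.0, "f5": 1600.0, "f6": np.nan})
        out = classify_macro_micro({"A": sA, "B": sB})
        # ranks (of 5 finite): f1,f2 small; f5 largest; mean rank = 0.6
        assert out.loc["f1", "label"] == "microfeature"
        assert out.loc["f2", "label"] == "microfeature"
        assert out.loc["f5", "label"] == "macrofeature"
        assert out.loc["f6", "label"] == "none"

    def test_largest_scale_only_in_both_is_macro(self):
        s = pd.Series({"f1": 100.0, "f2": 100.0, "f3": 6400.0})
        out = classify_macro_micro({"A": s, "B": s})
        assert out.loc["f3", "label"] == "macrofeature"
        assert out.loc["f1", "label"] == "microfeature"


class TestOrientationBias:
    def test_symmetric_track_zero_t(self):
        tr = FeatureTrack("sym", 100, {"chr1": np.full(1000, 1.0)})
        ints = IntegrationSet("x", pd.DataFrame({
            "chrom": ["chr1"] * 50,
            "position": np.arange(10_000, 60_000, 1000),
            "orientation": ["+", "-"] * 25,
        }))
        df, summary = orientation_bias(ints, [tr])
        assert df.loc["sym", "t"] == 0.0

    def test_planted_upstream_step_sign(self):
        # signal high on the left of every '+' event: upstream mean larger
        vals = np.zeros(2000)
        centers = np.arange(20_000, 180_000, 2000)
        for c in centers:
            vals[(c - 600) // 100:(c) // 100] = 5.0
        tr = FeatureTrack("step", 100, {"chr1": vals})
        ints = IntegrationSet("x", pd.DataFrame({
            "chrom": "chr1", "position": centers, "orientation": "+"}))
        df, summary = orientation_bias(ints, [tr])
        assert df.loc["step", "t"] > 0  # positive = higher signal upstream

    def test_summary_closed_form_binomial(self):
        rng = np.random.default_rng(7)
        tracks = []
        vals_template = np.zeros(2000)
        centers = np.arange(20_000, 60_000, 2000)
        for k in range(12):
            vals = vals_template.copy()
            for c in centers:
                vals[(c - 600) // 100: c // 100] = 1.0 + 0.1 * k
            tracks.append(FeatureTrack(f"f{k}", 100, {"chr1": vals}))
        ints = IntegrationSet("x", pd.DataFrame({
            "chrom": "chr1", "position": centers, "orientation": "+"}))
        df, summary = orientation_bias(ints, tracks)
        assert (df["t"] > 0).all()
        assert summary["fraction_positive_minus_half"] == pytest.approx(0.5)
        assert summary["p"] == pytest.approx(2 * 0.5**12)


class TestOrientationStrata:
    def test_strata_partition_and_match_manual_split(self, annotation):
        from intbias.scales import orientation_bias_strata

        rng = np.random.default_rng(17)
        vals = rng.normal(size=10_000)
        tr = FeatureTrack("f", 100, {"chr1": vals})
        pos = rng.integers(20_000, 980_000, size=400)
        oris = np.where(rng.random(400) < 0.5, "+", "-")
        ints = IntegrationSet("x", pd.DataFrame({
            "chrom": "chr1", "position": pos, "orientation": oris,
        }).drop_duplicates(["chrom", "position", "orientation"]))
        out = orientation_bias_strata(ints, [tr], annotation.genes)
        assert set(out) == {"all", "sense_tss", "antisense_tss"}
        # strata are a partition of the events
        n_all = len(ints)
        # recompute sizes from the nearest-TSS strand assignment
        tss = sorted((g.tss, g.strand) for g in annotation.genes)
        import numpy as _np
        pos_arr = _np.array([p for p, _ in tss])
        strands = _np.array([s for _, s in tss])
        ev = ints.events
        idx = _np.searchsorted(pos_arr, ev["position"].to_numpy())
        left = _np.clip(idx - 1, 0, len(pos_arr) - 1)
        right = _np.clip(idx, 0, len(pos_arr) - 1)
        pick = _np.where(
            _np.abs(pos_arr[left] - ev["position"].to_numpy())
            <= _np.abs(pos_arr[right] - ev["position"].to_numpy()),
            left, right)
        sense = strands[pick] == ev["orientation"].to_numpy()
        t_sense = orientation_bias(
            IntegrationSet("s", ev.loc[sense].reset_index(drop=True)), [tr]
        )[0].loc["f", "t"]
        assert out["sense_tss"][0].loc["f", "t"] == pytest.approx(t_sense)

    def test_cluster_profiles_linkage_shape(self):
        from intbias.scales import cluster_profiles

        rng = np.random.default_rng(18)
        T = pd.DataFrame(rng.normal(size=(6, 4)),
                         index=[f"f{i}" for i in range(6)])
        Z = cluster_profiles(T)
        assert Z.shape == (5, 4)


def test_swap_exchangeability_of_adjusted_statistic(assembly, annotation,
                                                    null_pair):
    """Swapping the integration set with one control pseudo-dataset leaves
    T centered at zero under the null (permutation symmetry of the
    statistic)."""
    from intbias.datasets import ControlSet

    ints, cs = null_pair
    tracks, _ = make_feature_tracks(
        assembly, annotation,
        [FeatureSpec(name="noise", noise_sd=1.0, autocorr_length=500)],
        bin_size=100, seed=77)
    Ts = []
    scales = np.array([800, 6400])
    for j in [None, 0, 1, 2]:
        if j is None:
            res = scale_association(ints, cs, tracks, scales=scales)
        else:
            # promote control set j to 'integrations', demote the events
            ev = ints.events.loc[cs.kept].reset_index(drop=True)
            swapped = ev.copy()
            swapped["position"] = cs.positions[cs.kept, j]
            swapped = swapped.drop_duplicates(
                ["chrom", "position", "orientation"])
            keep_idx = swapped.index.to_numpy()
            positions = cs.positions[cs.kept][keep_idx].copy()
            positions[:, j] = ev["position"].to_numpy()[keep_idx]
            sw_set = IntegrationSet("swap", swapped.reset_index(drop=True))
            sw_cs = ControlSet(
                parent=sw_set, m=cs.m, positions=positions,
                kept=np.ones(len(sw_set), dtype=bool),
                eligible_sizes=np.ones(len(sw_set), dtype=np.int64))
            res = scale_association(sw_set, sw_cs, tracks, scales=scales)
        Ts.extend(res.T.to_numpy().ravel())
    Ts = np.array(Ts)
    # all variants are null: centered near 0 on the sqrt(1+1/m) scale
    assert np.abs(np.mean(Ts)) < 1.0
    assert np.all(np.abs(Ts) < 5.0)


class TestHicAlpha:
    def _power_law_matrix(self, exponent, n=200, bin_size=20_000, noise=None,
                          seed=0):
        rng = np.random.default_rng(seed)
        i, j = np.indices((n, n))
        d = np.abs(i - j) * bin_size
        with np.errstate(divide="ignore"):
            m = np.where(d > 0, (d / bin_size) ** exponent, 10.0)
        if noise is not None:
            ln = rng.lognormal(0, noise, size=(n, n))
            ln = (ln + ln.T) / 2
            m = m * ln
        return ContactMatrix("chr1", bin_size, (m + m.T) / 2)

    @pytest.mark.parametrize("exponent", [-1.0, -0.5])
    def test_noise_free_exact(self, exponent):
        cm = self._power_law_matrix(exponent)
        alpha = hic_alpha(cm, locus=100 * 20_000, window=400_000)
        assert alpha == pytest.approx(exponent, abs=1e-9)

    def test_noisy_recovery_averaged_over_loci(self):
        cm = self._power_law_matrix(-1.0, n=600, noise=0.5, seed=1)
        rng = np.random.default_rng(2)
        loci = rng.integers(40, 560, size=500) * 20_000
        alphas = np.array([hic_alpha(cm, int(l), window=400_000) for l in loci])
        assert np.nanmean(alphas) == pytest.approx(-1.0, abs=0.05)

    def test_zero_contacts_excluded(self):
        cm = self._power_law_matrix(-1.0)
        m = cm.matrix.copy()
        m[100, 103] = m[103, 100] = 0.0
        cm2 = ContactMatrix("chr1", 20_000, m)
        alpha = hic_alpha(cm2, locus=100 * 20_000, window=400_000)
        assert np.isfinite(alpha)


def test_null_calibration_small():
    """The vectorized null MC reproduces Var(T)=1+1/m and the alpha-level."""
    out = null_calibration(n=400, m=10, n_cells=4000, seed=0)
    assert out["var_T"] == pytest.approx(1.1, abs=0.08)
    se = np.sqrt(0.05 * 0.95 / 4000)
    assert abs(out["rejection_rate"] - 0.05) < 4 * se
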