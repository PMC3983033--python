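"""Gene/transcript/expression/TAD bias statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intbias.annotation import (
    cmh_interface_test,
    cochran_armitage_trend,
    expression_quantile_bias,
    filter_overlapping_genes,
    gene_alignment_profile,
    interface_signed_distances,
    motif_fraction,
    region_bias,
    tad_interface_profile,
)
from intbias.controls import sample_matched_controls
from intbias.datasets import GeneModel, IntegrationSet
from intbias.genome import GenomicInterval
from intbias.simulate import (
    BiasModel,
    FeatureCoupling,
    FeatureSpec,
    make_feature_tracks,
    simulate_integrations,
)


def _gene(gid, start, end, strand="+", chrom="chr1"):
    iv = GenomicInterval(chrom, start, end, strand)
    tss, tts = (start, end) if strand == "+" else (end, start)
    return GeneModel(gene_id=gid, interval=iv, tss=tss, tts=tts)


class TestFilterOverlappingGenes:
    def test_disjoint_unchanged(self):
        genes = [_gene("a", 0, 100), _gene("b", 200, 300)]
        assert filter_overlapping_genes(genes) == genes

    def test_nested_keeps_larger(self):
        genes = [_gene("small", 20, 80), _gene("big", 0, 100)]
        kept = filter_overlapping_genes(genes)
        assert [g.gene_id for g in kept] == ["big"]

    def test_partial_overlap_removes_both(self):
        genes = [_gene("a", 0, 100), _gene("b", 50, 200), _gene("c", 500, 600)]
        kept = filter_overlapping_genes(genes)
        assert [g.gene_id for g in kept] == ["c"]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(60):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(10, 800))
            genes.append(_gene(f"g{i:02d}", s, e))

        # independent quadratic-time pairwise classification
        removed = set()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i].interval, genes[j].interval
                if not a.overlaps(b):
                    continue
                a_in_b = b.start <= a.start and a.end <= b.end
                b_in_a = a.start <= b.start and b.end <= a.end
                if a_in_b and b_in_a:
                    removed.add(max(i, j, key=lambda k: genes[k].gene_id))
                elif a_in_b:
                    removed.add(i)
                elif b_in_a:
                    removed.add(j)
                else:
                    removed.add(i)
                    removed.add(j)
        expected = [g.gene_id for k, g in enumerate(genes) if k not in removed]
        got = [g.gene_id for g in filter_overlapping_genes(genes)]
        assert got == expected


class TestCochranArmitage:
    def test_symmetric_table_zero(self):
        z, p = cochran_armitage_trend(np.array([[10, 10, 10], [10, 10, 10]]))
        assert z == 0.0 and p == 1.0

    def test_zero_column_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            z, p = cochran_armitage_trend(
                np.array([[5, 0, 10], [5, 0, 10]]))
        assert z == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(30, 300, size=(2, 5))
        z, p = cochran_armitage_trend(table)
        # permutation oracle: shuffle row labels, recompute the raw score U
        scores = np.arange(1, 6, dtype=float)
        labels = np.repeat([0, 1], table.sum(axis=1)[[0, 1]])
        cols = np.concatenate([
            np.repeat(np.arange(5), table[r]) for r in (0, 1)
        ])
        n1 = table[0].sum()
        obs_u = float(np.sum(scores * table[0]))
        B = 20_000
        perm_u = np.empty(B)
        for b in range(B):
            sel = rng.permutation(len(cols))[:n1]
            perm_u[b] = np.sum(scores[cols[sel]])
        p_perm = np.mean(np.abs(perm_u - perm_u.mean())
                         >= abs(obs_u - perm_u.mean()) - 1e-9)
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(p - p_perm) < max(3 * se, 0.02)

    def test_strong_trend_detected(self):
        z, p = cochran_armitage_trend(
            np.array([[10, 20, 30, 40, 50], [50, 40, 30, 20, 10]]))
        assert z > 0 and p < 1e-6


@pytest.fixture(scope="module")
def uniform_setup(assembly, annotation, ta_sites, gatc_map):
    ints = simulate_integrations(
        assembly, BiasModel(motif="TA"), n=3000,
        restriction_map=gatc_map, seed=21)
    cs = sample_matched_controls(ints, ta_sites, gatc_map, m=5, seed=22)
    genes = filter_overlapping_genes(annotation.genes)
    return ints, cs, genes


class TestRegionBias:

    def test_binomial_p_matches_exact_tail(self):
        # two-sided exact binomial: 8 of 100 at p0=0.05
        p = stats.binomtest(8, 100, 0.05).pvalue
        k, n, p0 = 8, 100, 0.05
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        oracle = pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_counts_conserved(self, uniform_setup):
        ints, cs, genes = uniform_setup
        df = region_bias(ints, cs, genes)
        assert (df["n_obs"] == cs.n_kept).all()
        assert (df["n_ctrl"] == cs.n_kept * cs.m).all()

    def test_uniform_data_mostly_null(self, uniform_setup):
        ints, cs, genes = uniform_setup
        df = region_bias(ints, cs, genes)
        assert (df["q"].dropna() < 0.05).sum() == 0

    def test_antisymmetry_under_swap(self, uniform_setup):
        """log2 ratios flip sign when integrations and controls swap roles."""
        from intbias.datasets import ControlSet

        _, _, genes = uniform_setup
        rng = np.random.default_rng(99)
        pos_a = np.sort(rng.choice(900_000, size=800, replace=False))
        pos_b = np.sort(rng.choice(900_000, size=800, replace=False)) + 17

        def as_set(pos, name):
            return IntegrationSet(name, pd.DataFrame({
                "chrom": "chr1", "position": pos, "orientation": "+"}))

        def as_controls(parent, pos):
            n = len(parent)
            return ControlSet(parent=parent, m=1, positions=pos[:, None],
                              kept=np.ones(n, dtype=bool),
                              eligible_sizes=np.ones(n, dtype=np.int64))

        A, B = as_set(pos_a, "A"), as_set(pos_b, "B")
        fwd = region_bias(A, as_controls(A, pos_b), genes)
        rev = region_bias(B, as_controls(B, pos_a), genes)
        a = fwd.set_index("region_class")["log2_ratio"]
        b = rev.set_index("region_class")["log2_ratio"]
        ok = a.notna() & b.notna()
        assert ok.any()
        np.testing.assert_allclose(a[ok], -b[ok], atol=1e-12)

    def test_planted_tss_bias_detected(self, assembly, annotation, ta_sites,
                                       gatc_map):
        tracks, _ = make_feature_tracks(
            assembly, annotation,
            [FeatureSpec(name="tssness", noise_sd=0.0, bumps=[("tss", 1.0, 400)])],
            bin_size=100, seed=30)
        model = BiasModel(motif="TA",
                          coefficients=[FeatureCoupling("tssness", 2.0, 0)])
        ints = simulate_integrations(assembly, model, n=4000,
                                     tracks={"tssness": tracks[0]},
                                     restriction_map=gatc_map, seed=31)
        cs = sample_matched_controls(ints, ta_sites, gatc_map, m=5, seed=32)
        genes = filter_overlapping_genes(annotation.genes)
        df = region_bias(ints, cs, genes).set_index("region_class")
        for cls in ("TSS_upstream", "TSS_downstream"):
            assert df.loc[cls, "log2_ratio"] > 0.3
            assert df.loc[cls, "q"] < 0.05


def test_region_bias_null_calibration_over_replicates(
        assembly, annotation, ta_sites, gatc_map):
    """With uniform integrations the FDR-corrected region/transcript calls
    stay at or below the nominal 5% across simulation replicates."""
    genes = filter_overlapping_genes(annotation.genes)
    rng = np.random.default_rng(123)
    n_reps, sig, cells = 50, 0, 0
    for _ in range(n_reps):
        ints = simulate_integrations(
            assembly, BiasModel(motif="TA"), n=400,
            restriction_map=gatc_map, seed=int(rng.integers(2**31)))
        cs = sample_matched_controls(ints, ta_sites, gatc_map, m=3,
                                     seed=int(rng.integers(2**31)))
        df = region_bias(ints, cs, genes)
        q = df["q"].dropna()
        sig += int((q < 0.05).sum())
        cells += len(q)
    rate = sig / cells
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / cells)


class TestGeneAlignmentProfile:
    def test_controls_equal_integrations_gives_zero(self, assembly, annotation,
                                                    ta_sites, gatc_map):
        ints = simulate_integrations(assembly, BiasModel(motif="TA"), n=2000,
                                     restriction_map=gatc_map, seed=41)
        # controls identical to the integrations themselves
        n = len(ints)
        from intbias.datasets import ControlSet
        cs = ControlSet(parent=ints, m=1,
                        positions=ints.events["position"].to_numpy()[:, None],
                        kept=np.ones(n, dtype=bool),
                        eligible_sizes=np.ones(n, dtype=np.int64))
        genes = filter_overlapping_genes(annotation.genes)
        prof = gene_alignment_profile(ints, cs, genes)
        for col in ("log2_ratio_sense", "log2_ratio_antisense"):
            vals = prof[col].dropna()
            np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_uniform_profile_near_zero(self, assembly, annotation, ta_sites,
                                       gatc_map):
        ints = simulate_integrations(assembly, BiasModel(motif="TA"), n=20_000,
                                     restriction_map=gatc_map, seed=42)
        cs = sample_matched_controls(ints, ta_sites, gatc_map, m=10, seed=43)
        genes = filter_overlapping_genes(annotation.genes)
        prof = gene_alignment_profile(ints, cs, genes, n_flank_bins=5,
                                      n_body_bins=10)
        vals = pd.concat([prof["log2_ratio_sense"],
                          prof["log2_ratio_antisense"]]).dropna()
        assert np.abs(vals.mean()) < 0.1


class TestExpressionBias:
    def test_trend_recovered_for_expression_coupled_bias(
            self, assembly, annotation, ta_sites, gatc_map):
        genes = filter_overlapping_genes(annotation.genes)
        rng = np.random.default_rng(50)
        expr = pd.Series(rng.lognormal(1, 1, size=len(genes)),
                         index=[g.gene_id for g in genes])
        expr.iloc[: len(genes) // 5] = 0.0
        # expression-weighted gene-body track
        from intbias.tracks import FeatureTrack
        import math
        nb = math.ceil(assembly.chrom_lengths["chr1"] / 100)
        arr = np.zeros(nb)
        for g in genes:
            val = np.log1p(expr[g.gene_id])
            arr[g.interval.start // 100:(g.interval.end - 1) // 100 + 1] = val
        tr = FeatureTrack("exprtrack", 100, {"chr1": arr})
        model = BiasModel(motif="TA",
                          coefficients=[FeatureCoupling("exprtrack", 1.0, 0)])
        ints = simulate_integrations(assembly, model, n=5000,
                                     tracks={"exprtrack": tr},
                                     restriction_map=gatc_map, seed=51)
        cs = sample_matched_controls(ints, ta_sites, gatc_map, m=5, seed=52)
        cells, trends = expression_quantile_bias(ints, cs, genes, expr)
        genic = trends.set_index("region_class").loc["genic"]
        assert genic["trend_z"] > 0
        assert genic["trend_p"] < 0.01


class TestTADInterface:
    def test_truncation_at_element_midpoint(self):
        tads = [GenomicInterval("chr1", 100, 300)]
        boundaries = [GenomicInterval("chr1", 0, 100)]
        pos = np.array([150, 250, 50, 10, 199, 201])
        d = interface_signed_distances(np.array(["chr1"] * 6), pos, tads,
                                       boundaries)
        # TAD of length 200: left half -> +offset from start, right half ->
        # +offset from end; boundary mirrored negative
        np.testing.assert_allclose(d, [50, 50, -50, -10, 99, 99])

    def test_uniform_profile_within_band(self, assembly, annotation, ta_sites,
                                         gatc_map, uniform_ta_integrations):
        cs = sample_matched_controls(uniform_ta_integrations, ta_sites,
                                     gatc_map, m=10, seed=61)
        prof = tad_interface_profile(uniform_ta_integrations, cs,
                                     annotation.tads, annotation.boundaries,
                                     bin=5000)
        vals = prof["log2_ratio"].dropna()
        # Monte-Carlo band: mean near zero
        assert np.abs(vals.mean()) < 0.15

    def test_planted_interface_enrichment_recovered(self, assembly, annotation,
                                                    ta_sites, gatc_map):
        tracks, _ = make_feature_tracks(
            assembly, annotation,
            [FeatureSpec(name="iface", noise_sd=0.0,
                         bumps=[("interface", 1.0, 3000)])],
            bin_size=100, seed=62)
        model = BiasModel(motif="TA",
                          coefficients=[FeatureCoupling("iface", 2.0, 0)])
        ints = simulate_integrations(assembly, model, n=5000,
                                     tracks={"iface": tracks[0]},
                                     restriction_map=gatc_map, seed=63)
        cs = sample_matched_controls(ints, ta_sites, gatc_map, m=5, seed=64)
        prof = tad_interface_profile(ints, cs, annotation.tads,
                                     annotation.boundaries, bin=4000)
        prof = prof.dropna(subset=["log2_ratio"])
        near = prof[np.abs(prof["distance"]) <= 6000]
        far = prof[np.abs(prof["distance"]) > 20_000]
        assert near["log2_ratio"].mean() > far["log2_ratio"].mean() + 0.2
        assert near["log2_ratio"].mean() > 0.2

    def test_cmh_identical_systems_null(self, assembly, annotation, ta_sites,
                                        gatc_map, uniform_ta_integrations):
        cs1 = sample_matched_controls(uniform_ta_integrations, ta_sites,
                                      gatc_map, m=5, seed=71)
        cs2 = sample_matched_controls(uniform_ta_integrations, ta_sites,
                                      gatc_map, m=5, seed=72)
        stat, p = cmh_interface_test(
            uniform_ta_integrations, cs1, uniform_ta_integrations, cs2,
            annotation.tads, annotation.boundaries)
        assert p > 0.05

    def test_cmh_single_stratum_equals_chi2(self):
        """One stratum reduces to the plain 2x2 chi-square (no continuity)."""
        from statsmodels.stats.contingency_tables import StratifiedTable
        t = np.array([[30, 70], [55, 45]], dtype=float)
        st_res = StratifiedTable(t[:, :, None]).test_null_odds(correction=False)
        chi2, _, _, _ = stats.chi2_contingency(t, correction=False)
        # the CMH variance uses N-1 where Pearson uses N
        N = t.sum()
        expect = chi2 * (N - 1) / N
        assert st_res.statistic == pytest.approx(expect, rel=1e-9)
        assert st_res.pvalue == pytest.approx(
            stats.chi2.sf(expect, 1), rel=1e-9)

    def test_cmh_detects_differential_interface_bias(
            self, assembly, annotation, ta_sites, gatc_map,
            uniform_ta_integrations):
        tracks, _ = make_feature_tracks(
            assembly, annotation,
            [FeatureSpec(name="iface", noise_sd=0.0,
                         bumps=[("interface", 1.0, 3000)])],
            bin_size=100, seed=73)
        model = BiasModel(motif="TA",
                          coefficients=[FeatureCoupling("iface", 2.0, 0)])
        biased = simulate_integrations(assembly, model, n=4000,
                                       tracks={"iface": tracks[0]},
                                       restriction_map=gatc_map, seed=74)
        cs_b = sample_matched_controls(biased, ta_sites, gatc_map, m=5, seed=75)
        cs_u = sample_matched_controls(uniform_ta_integrations, ta_sites,
                                       gatc_map, m=5, seed=76)
        stat, p = cmh_interface_test(biased, cs_b, uniform_ta_integrations,
                                     cs_u, annotation.tads,
                                     annotation.boundaries)
        assert p < 0.05


class TestMotifFraction:
    def test_constrained_simulator_is_one(self, assembly,
                                           uniform_ta_integrations):
        frac, rest = motif_fraction(uniform_ta_integrations, assembly, "TA")
        assert frac == 1.0
        assert rest.empty

    def test_contaminated_fraction(self, assembly, ta_sites):
        rng = np.random.default_rng(80)
        n = 4000
        n_off = int(0.07 * n)
        on = rng.choice(ta_sites["chr1"], size=n - n_off, replace=False)
        seq = assembly.sequence["chr1"]
        off_pool = np.array([p for p in rng.integers(0, 999_000, size=2000)
                             if seq[p:p + 2] != "TA"])
        off = off_pool[:n_off]
        df = pd.DataFrame({
            "chrom": "chr1",
            "position": np.concatenate([on, off]),
            "orientation": "+",
        }).drop_duplicates(["chrom", "position", "orientation"])
        ints = IntegrationSet("mix", df)
        frac, _ = motif_fraction(ints, assembly, "TA")
        assert frac == pytest.approx(1 - n_off / len(df), abs=0.01)

    def test_empty_set_errors(self, assembly):
        ints = IntegrationSet("e", pd.DataFrame(
            {"chrom": [], "position": [], "orientation": []}))
        with pytest.raises(ValueError):
            motif_fraction(ints, assembly, "TA")
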