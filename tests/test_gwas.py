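"""GWAS integration: regions, filtering, posteriors, Blockshifter, COGS."""

import numpy as np
import pandas as pd
import pytest

from captor.gwas import (
    blockshifter,
    cogs_scores,
    define_ld_regions,
    distance_summary,
    preprocess_gwas,
    snp_posteriors,
)
from captor.simulate import simulate_gwas


def _linear_map(chrom="1", length=10_000_000, cm_per_mb=1.0):
    return pd.DataFrame({
        "chrom": chrom, "pos": [0, length],
        "cM": [0.0, length / 1e6 * cm_per_mb],
    })


class TestLDRegions:
    def test_linear_map_regular_regions(self):
        regions = define_ld_regions(_linear_map())
        assert len(regions) == 10
        assert (regions["end"] - regions["start"] == 1_000_000).all()

    def test_hotspot_short_region(self):
        gmap = pd.DataFrame({
            "chrom": "1",
            "pos": [0, 4_000_000, 4_100_000, 10_000_000],
            "cM": [0.0, 4.0, 6.0, 12.0],
        })
        regions = define_ld_regions(gmap)
        widths = regions["end"] - regions["start"]
        # the two hotspot-internal regions are ~50 kb each
        assert widths.min() < 100_000
        assert len(regions) == 12

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(0, 10_000_000, 50))
        cm = np.cumsum(rng.random(50))
        gmap = pd.DataFrame({"chrom": "1", "pos": pos, "cM": cm})
        regions = define_ld_regions(gmap)
        # oracle: walk the map and record a boundary at each whole cM
        bounds = [pos[0]]
        for target in np.arange(cm[0] + 1.0, cm[-1], 1.0):
            bounds.append(np.interp(target, cm, pos))
        bounds.append(pos[-1])
        assert len(regions) == len(bounds) - 1
        assert np.allclose(regions["start"].to_numpy()[1:],
                           np.array(bounds[1:-1]), atol=1.0)

    def test_non_monotone_errors(self):
        gmap = pd.DataFrame({"chrom": "1", "pos": [0, 1, 2], "cM": [0, 2, 1]})
        with pytest.raises(ValueError, match="monotone"):
            define_ld_regions(gmap)


class TestPreprocess:
    REGIONS = define_ld_regions(
        pd.DataFrame({"chrom": ["1", "1", "6", "6"],
                      "pos": [0, 10_000_000, 0, 40_000_000],
                      "cM": [0.0, 10.0, 0.0, 40.0]})
    )

    def test_lone_significant_snp_dropped(self):
        rec = pd.DataFrame({
            "snp": ["lone", "far"], "chrom": ["1", "1"],
            "pos": [1_000_000, 1_080_000], "p": [1e-9, 0.3],
        })
        out = preprocess_gwas(rec, ld=pd.DataFrame(columns=["snp1", "snp2", "r2"]),
                              regions=self.REGIONS)
        assert "lone" not in set(out["snp"])

    def test_supported_significant_snp_kept(self):
        rec = pd.DataFrame({
            "snp": ["hit", "support"], "chrom": ["1", "1"],
            "pos": [1_000_000, 1_030_000], "p": [1e-9, 1e-6],
        })
        out = preprocess_gwas(rec, ld=pd.DataFrame(columns=["snp1", "snp2", "r2"]),
                              regions=self.REGIONS)
        assert "hit" in set(out["snp"])

    def test_ld_partner_counts_as_support(self):
        rec = pd.DataFrame({
            "snp": ["hit"], "chrom": ["1"], "pos": [1_000_000], "p": [1e-9],
        })
        ld = pd.DataFrame({"snp1": ["hit"], "snp2": ["x"], "r2": [0.9]})
        out = preprocess_gwas(rec, ld=ld, regions=self.REGIONS)
        assert "hit" in set(out["snp"])

    def test_mhc_excluded(self):
        rec = pd.DataFrame({
            "snp": ["mhc", "keep"], "chrom": ["6", "6"],
            "pos": [30_000_000, 36_000_000], "p": [1e-4, 1e-4],
        })
        out = preprocess_gwas(rec, regions=self.REGIONS)
        assert set(out["snp"]) == {"keep"}

    def test_perfect_proxy_inherits_p(self):
        rec = pd.DataFrame({
            "snp": ["typed"], "chrom": ["1"], "pos": [2_000_000], "p": [1e-6],
        })
        ld = pd.DataFrame({"snp1": ["typed"], "snp2": ["untyped"], "r2": [1.0]})
        ref = pd.DataFrame({"snp": ["untyped"], "chrom": ["1"],
                            "pos": [2_010_000]})
        out = preprocess_gwas(rec, ld=ld, regions=self.REGIONS,
                              reference_snps=ref)
        imp = out[out["imputed"]]
        assert list(imp["snp"]) == ["untyped"]
        assert imp["p"].iloc[0] == pytest.approx(1e-6)

    def test_missing_map_errors(self):
        with pytest.raises(ValueError):
            preprocess_gwas(pd.DataFrame({"snp": [], "chrom": [], "pos": [],
                                          "p": []}))


class TestPosteriors:
    def test_single_snp_strong_signal_near_one(self):
        rec = pd.DataFrame({
            "snp": ["s"], "chrom": ["1"], "pos": [500_000],
            "beta": [0.5], "se": [0.02], "p": [1e-100],
        })
        post = snp_posteriors(rec, define_ld_regions(_linear_map()))
        assert post["ppi"].iloc[0] > 0.99

    def test_equal_stats_equal_ppi(self):
        rec = pd.DataFrame({
            "snp": ["a", "b"], "chrom": ["1", "1"],
            "pos": [400_000, 500_000], "beta": [0.3, 0.3], "se": [0.05, 0.05],
            "p": [1e-9, 1e-9],
        })
        post = snp_posteriors(rec, define_ld_regions(_linear_map()))
        assert post["ppi"].iloc[0] == pytest.approx(post["ppi"].iloc[1])

    def test_region_posteriors_sum_below_one(self):
        gwas, _, gmap, _ = simulate_gwas(n_blocks=10, causal=[(3, 5, 0.1)],
                                         seed=2)
        post = snp_posteriors(gwas, define_ld_regions(gmap))
        sums = post.groupby("region_id")["ppi"].sum()
        assert (sums <= 1.0 + 1e-9).all()

    def test_planted_causal_attains_max_ppi(self):
        hits = 0
        for seed in range(25):
            gwas, _, gmap, truth = simulate_gwas(
                n_blocks=10, causal=[(4, 10, 0.15)], seed=100 + seed)
            post = snp_posteriors(gwas, define_ld_regions(gmap))
            reg = post[post["region_id"] == 4]
            hits += reg.loc[reg["ppi"].idxmax(), "snp"] == truth.causal_snps[0][0]
        assert hits >= 20  # >= 80% of replicates


def _rand_pirs(rng, n=60, span=3_000_000, width=5_000):
    starts = rng.integers(0, span - width, size=n)
    return pd.DataFrame({"chrom": "1", "start": starts, "end": starts + width})


class TestBlockshifter:
    def test_identical_sets_zero(self):
        gwas, _, gmap, _ = simulate_gwas(n_blocks=10, seed=3)
        regions = define_ld_regions(gmap)
        post = snp_posteriors(gwas, regions)
        pirs = _rand_pirs(np.random.default_rng(1), span=1_000_000)
        res = blockshifter(post, pirs, pirs, regions, n_rot=100, seed=0)
        assert res.statistic == 0.0 and res.z == 0.0

    def test_null_calibration(self):
        zs = []
        for i in range(60):
            gwas, _, gmap, _ = simulate_gwas(n_blocks=30, seed=400 + i)
            regions = define_ld_regions(gmap)
            post = snp_posteriors(gwas, regions)
            res = blockshifter(
                post, _rand_pirs(np.random.default_rng(1000 + i)),
                _rand_pirs(np.random.default_rng(2000 + i)),
                regions, n_rot=200, seed=i,
            )
            zs.append(res.z)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.35  # N(0,1/sqrt(60)) scale
        assert 0.75 <= zs.std() <= 1.25

    def test_planted_enrichment_detected(self):
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(900 + i)
            causal = [(int(b), int(rng.integers(3, 17)), 0.15)
                      for b in rng.choice(30, 5, replace=False)]
            gwas, _, gmap, truth = simulate_gwas(n_blocks=30, causal=causal,
                                                 seed=900 + i)
            regions = define_ld_regions(gmap)
            post = snp_posteriors(gwas, regions)
            cpos = gwas.set_index("snp").loc[
                [c[0] for c in truth.causal_snps], "pos"].to_numpy()
            extra = rng.integers(0, 3_000_000 - 5_000, size=40)
            starts1 = np.concatenate([cpos - 2_000, extra])
            pir1 = pd.DataFrame({"chrom": "1", "start": starts1,
                                 "end": starts1 + 5_000})
            res = blockshifter(post, pir1, _rand_pirs(rng, n=45), regions,
                               n_rot=200, seed=i)
            hits += res.z > 2
        assert hits >= 18

    def test_scale_invariance(self):
        gwas, _, gmap, _ = simulate_gwas(n_blocks=20, causal=[(3, 5, 0.1)],
                                         seed=5)
        regions = define_ld_regions(gmap)
        post = snp_posteriors(gwas, regions)
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        p1, p2 = _rand_pirs(rng1, span=2_000_000), _rand_pirs(rng2, span=2_000_000)
        a = blockshifter(post, p1, p2, regions, n_rot=150, seed=3)
        post2 = post.assign(ppi=post["ppi"] * 37.0)
        b = blockshifter(post2, p1, p2, regions, n_rot=150, seed=3)
        assert a.z == pytest.approx(b.z, rel=1e-9)


class TestCogs:
    POST = pd.DataFrame({
        "snp": ["a", "b", "c"], "chrom": ["1", "1", "1"],
        "pos": [100_000, 1_500_000, 2_500_000],
        "region_id": [0, 1, 2], "ppi": [0.5, 0.5, 0.99],
    })

    def _links(self, gene, intervals):
        return pd.DataFrame(
            [(gene, "1", s, e) for s, e in intervals],
            columns=["gene", "chrom", "start", "end"],
        )

    def test_two_region_composition(self):
        links = self._links("G", [(0, 200_000), (1_400_000, 1_600_000)])
        out = cogs_scores(self.POST, pir_links=links)
        assert out.loc[out["gene"] == "G", "score"].iloc[0] \
            == pytest.approx(1 - 0.5 * 0.5)

    def test_all_mass_on_one_pir(self):
        links = self._links("G", [(2_400_000, 2_600_000)])
        out = cogs_scores(self.POST, pir_links=links)
        assert out["score"].iloc[0] == pytest.approx(0.99)

    def test_no_overlap_zero(self):
        links = self._links("G", [(5_000_000, 5_100_000)])
        out = cogs_scores(self.POST, pir_links=links)
        assert out["score"].iloc[0] == 0.0

    def test_no_double_counting_across_annotations(self):
        links = self._links("G", [(2_400_000, 2_600_000)])
        coding = self._links("G", [(2_450_000, 2_550_000)])
        out = cogs_scores(self.POST, coding=coding, pir_links=links)
        assert out["score"].iloc[0] == pytest.approx(0.99)  # union, not sum

    def test_region_order_invariance_and_monotonicity(self):
        links = self._links("G", [(0, 200_000), (1_400_000, 1_600_000)])
        out1 = cogs_scores(self.POST, pir_links=links)
        shuffled = self.POST.iloc[::-1].reset_index(drop=True)
        out2 = cogs_scores(shuffled, pir_links=links)
        assert out1["score"].iloc[0] == pytest.approx(out2["score"].iloc[0])
        bigger = self._links(
            "G", [(0, 200_000), (1_400_000, 1_600_000), (2_400_000, 2_600_000)])
        out3 = cogs_scores(self.POST, pir_links=bigger)
        assert out3["score"].iloc[0] >= out1["score"].iloc[0]

    def test_causal_gene_prioritized_in_power_sims(self):
        """The gene owning the causal-SNP PIR ranks first with score >= 0.5."""
        hits = 0
        n = 25
        for i in range(n):
            rng = np.random.default_rng(700 + i)
            gwas, _, gmap, truth = simulate_gwas(
                n_blocks=20, causal=[(8, 10, 0.15)], seed=700 + i)
            regions = define_ld_regions(gmap)
            post = snp_posteriors(gwas, regions)
            cpos = int(gwas.set_index("snp").loc[truth.causal_snps[0][0], "pos"])
            links = pd.concat([
                self._links("CAUSAL", [(cpos - 2_000, cpos + 3_000)]),
                self._links("DECOY1", [(cpos + 120_000, cpos + 125_000)]),
                self._links("DECOY2", [(205_000, 230_000)]),
            ])
            out = cogs_scores(post, pir_links=links)
            top = out.iloc[0]
            hits += (top["gene"] == "CAUSAL") and (top["score"] >= 0.5)
        assert hits >= 0.9 * n


class TestDistanceSummary:
    def test_distal_regulation_beats_proximity(self):
        """Causal PIR 200 kb from its target with a nearer decoy gene: the
        nearest-gene heuristic misses the prioritized target."""
        rng = np.random.default_rng(0)
        frac = []
        for i in range(10):
            gwas, _, gmap, truth = simulate_gwas(
                n_blocks=20, causal=[(8, 10, 0.2)], seed=800 + i)
            regions = define_ld_regions(gmap)
            post = snp_posteriors(gwas, regions)
            cpos = int(gwas.set_index("snp").loc[truth.causal_snps[0][0], "pos"])
            links = pd.DataFrame(
                [("TARGET", "1", cpos - 2_000, cpos + 3_000)],
                columns=["gene", "chrom", "start", "end"],
            )
            scores = cogs_scores(post, pir_links=links)
            tss = pd.DataFrame({
                "gene": ["TARGET", "DECOY"], "chrom": ["1", "1"],
                "pos": [cpos + 200_000, cpos + 20_000],
            })
            res = distance_summary(scores, gwas, tss, links)
            frac.append(res["frac_nearest"])
        assert np.mean(frac) < 0.5

    def test_snp_inside_prioritized_promoter_distance_zero(self):
        scores = pd.DataFrame({"gene": ["G"], "score": [0.9]})
        snps = pd.DataFrame({"snp": ["s"], "chrom": ["1"], "pos": [1_000],
                             "p": [1e-10]})
        links = pd.DataFrame([("G", "1", 0, 5_000)],
                             columns=["gene", "chrom", "start", "end"])
        tss = pd.DataFrame({"gene": ["G"], "chrom": ["1"], "pos": [1_000]})
        res = distance_summary(scores, snps, tss, links)
        assert res["median_d_prioritized"] == 0.0
        assert res["frac_nearest"] == 1.0

    def test_empty_prioritization_errors(self):
        with pytest.raises(ValueError):
            distance_summary(pd.DataFrame({"gene": [], "score": []}),
                             pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
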