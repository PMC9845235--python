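"""Structural variants: translocation detection, breakpoints, derivatives, CNVs."""

import numpy as np
import pandas as pd
import pytest

from captor.matrix import BinnedMatrix, bin_pairs
from captor.pairs import run_qc
from captor.simulate import simulate_library, simulate_rearrangement
from captor.svs import (
    Breakpoint,
    DegenerateSignalError,
    DerivativeMap,
    _corner_fit,
    classify_pattern,
    detect_cnv,
    detect_translocations,
    reconstruct_derivative,
    refine_breakpoint,
    remap_interactions,
)

TL = {"chromA": "chr1", "posA": 4_000_000, "chromB": "chr2", "posB": 6_000_000}


@pytest.fixture(scope="module")
def rearranged(medium_ref):
    """Reciprocal t(chr1;chr2) tumor library plus a matched control."""
    df, truth = simulate_rearrangement(
        medium_ref, n_pairs=1_000_000, translocation={**TL, "reciprocal": True},
        seed=77,
    )
    cap, _ = run_qc(df, medium_ref.fmap, medium_ref.baitmap)
    ctrl, _ = simulate_library(medium_ref, n_pairs=1_000_000, seed=78)
    cap_ctrl, _ = run_qc(ctrl, medium_ref.fmap, medium_ref.baitmap)
    return {"captured": cap, "control": cap_ctrl, "truth": truth}


class TestDetect:
    def test_reciprocal_found_null_clean(self, medium_ref, rearranged):
        m = bin_pairs(rearranged["captured"], medium_ref.fmap.chrom_sizes,
                      500_000)
        calls = detect_translocations(m, n_perm=150, seed=0)
        assert len(calls) >= 1
        assert {(c.chrom_a, c.chrom_b) for c in calls} == {("chr1", "chr2")}
        m0 = bin_pairs(rearranged["control"], medium_ref.fmap.chrom_sizes,
                       500_000)
        assert detect_translocations(m0, n_perm=150, seed=0) == []

    def test_min_permutations_enforced(self, medium_ref, rearranged):
        m = bin_pairs(rearranged["captured"], medium_ref.fmap.chrom_sizes,
                      500_000)
        with pytest.raises(ValueError):
            detect_translocations(m, n_perm=10)

    def test_null_window_zscores_standard_normal(self, medium_ref, rearranged):
        """z-scores computed on permuted (null) planes are ~N(0,1): a
        permutation draw is exchangeable with the permutation ensemble."""
        m0 = bin_pairs(rearranged["control"], medium_ref.fmap.chrom_sizes,
                       250_000)
        from scipy import ndimage

        rng = np.random.default_rng(0)
        cov = m0.marginals().astype(float)
        cov[cov == 0] = np.nan
        zs = []
        for ia, ca in enumerate(m0.chroms):
            for cb in m0.chroms[ia + 1:]:
                T = m0.trans_dense(ca, cb).astype(float)
                oa, ob = m0.bin_offset[ca], m0.bin_offset[cb]
                na, nb = T.shape
                norm = np.nan_to_num(
                    T / np.outer(cov[oa:oa + na], cov[ob:ob + nb]))
                # the "observed" plane is itself a random permutation
                obs_perm = norm[np.ix_(rng.permutation(na),
                                       rng.permutation(nb))]
                obs = ndimage.uniform_filter(obs_perm, size=3, mode="nearest")
                null = np.empty((150, na, nb))
                for k in range(150):
                    null[k] = ndimage.uniform_filter(
                        norm[np.ix_(rng.permutation(na), rng.permutation(nb))],
                        size=3, mode="nearest")
                zs.append(((obs - null.mean()) / null.std()).ravel())
        z = np.concatenate(zs)
        assert len(z) >= 500
        assert abs(z.mean()) < 0.1
        assert 0.85 <= z.std() <= 1.15


class TestRefine:
    def test_constant_rate_junction_recovered(self):
        """Piecewise-constant plane with a 10:0.1 hot quadrant: the split is
        found within one fragment in nearly every replicate."""
        good = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            H = rng.poisson(0.1, size=(300, 300)).astype(float)
            H[:120, 180:] += rng.poisson(10.0, size=(120, 120))
            ba, bb, hot, rates, gain = _corner_fit(H, 30.0)
            good += abs(ba - 120) <= 1 and abs(bb - 180) <= 1 and hot == 1
        assert good >= 19

    def test_one_sided_orientation(self):
        rng = np.random.default_rng(1)
        H = rng.poisson(0.05, size=(200, 200)).astype(float)
        H[140:, :60] += rng.poisson(8.0, size=(60, 60))  # (R, L) hot
        ba, bb, hot, rates, gain = _corner_fit(H, 30.0)
        assert hot == 2
        assert abs(ba - 140) <= 1 and abs(bb - 60) <= 1

    def test_uniform_signal_raises(self):
        rng = np.random.default_rng(2)
        H = rng.poisson(0.5, size=(300, 300)).astype(float)
        with pytest.raises(DegenerateSignalError):
            _corner_fit(H, 30.0)

    def test_tumor_breakpoints_exact(self, medium_ref, rearranged):
        bpa, bpb = refine_breakpoint(rearranged["captured"], medium_ref.fmap,
                                     "chr1", "chr2")
        truth = rearranged["truth"].translocation
        fa = medium_ref.fmap.locate("chr1", truth["posA"])
        fb = medium_ref.fmap.locate("chr2", truth["posB"])
        assert abs(bpa.fragment_id - fa) <= 1
        assert abs(bpb.fragment_id - fb) <= 1

    def test_pattern_classification(self, medium_ref, rearranged):
        assert classify_pattern(rearranged["captured"], medium_ref.fmap,
                                "chr1", "chr2") == "balanced"
        df, _ = simulate_rearrangement(
            medium_ref, n_pairs=1_000_000,
            translocation={**TL, "reciprocal": False}, seed=79,
        )
        cap, _ = run_qc(df, medium_ref.fmap, medium_ref.baitmap)
        assert classify_pattern(cap, medium_ref.fmap, "chr1", "chr2") \
            == "unbalanced"

    def test_too_few_pairs_errors(self, medium_ref):
        few = pd.DataFrame({
            "chrom1": ["chr1"] * 5, "pos1": [1000] * 5,
            "chrom2": ["chr2"] * 5, "pos2": [2000] * 5,
        })
        with pytest.raises(ValueError, match="trans pairs"):
            refine_breakpoint(few, medium_ref.fmap, "chr1", "chr2")


class TestDerivative:
    def test_round_trip_identity(self, medium_ref):
        fmap = medium_ref.fmap
        bpa = Breakpoint("chr1", fmap.locate("chr1", 4_000_000),
                         4_000_000, "left")
        bpb = Breakpoint("chr2", fmap.locate("chr2", 6_000_000),
                         6_000_000, "right")
        der = reconstruct_derivative(bpa, bpb, fmap)
        rng = np.random.default_rng(3)
        for dpos in rng.integers(0, der.length, size=200):
            c, p = der.from_derivative(int(dpos))
            assert der.to_derivative(c, p) == dpos

    def test_junction_spanning_distance_arithmetic(self, medium_ref):
        fmap = medium_ref.fmap
        bpa = Breakpoint("chr1", fmap.locate("chr1", 4_000_000),
                         4_000_000, "left")
        bpb = Breakpoint("chr2", fmap.locate("chr2", 6_000_000),
                         6_000_000, "right")
        der = reconstruct_derivative(bpa, bpb, fmap)
        # a contact spanning the junction becomes cis on the derivative
        d1 = der.to_derivative("chr1", 3_900_000)
        d2 = der.to_derivative("chr2", 6_050_000)
        want = (4_000_000 - 3_900_000) + (6_050_000 - 6_000_000)
        assert abs(d2 - d1) == want

    def test_inversion_join_reverses_segment(self, medium_ref):
        fmap = medium_ref.fmap
        bpa = Breakpoint("chr1", fmap.locate("chr1", 4_000_000),
                         4_000_000, "left")
        bpb = Breakpoint("chr2", fmap.locate("chr2", 6_000_000),
                         6_000_000, "left")
        der = reconstruct_derivative(bpa, bpb, fmap)
        assert der.segments[1][3] == "-"
        c, p = der.from_derivative(4_000_000)  # first base after junction
        assert c == "chr2" and p == 6_000_000 - 1

    def test_invalid_segments_error(self):
        with pytest.raises(ValueError):
            DerivativeMap("bad", [("chr1", 10, 10, "+")])

    def test_remapped_junction_contacts_follow_cis_decay(self, medium_ref):
        """Trans contacts across a real junction, re-projected onto the
        derivative, decay with derivative distance like cis contacts do.
        (A library without trans ligation noise isolates junction reads.)"""
        fmap = medium_ref.fmap
        df, _ = simulate_rearrangement(
            medium_ref, n_pairs=800_000, trans_rate=0.0,
            translocation={**TL, "reciprocal": True}, seed=83,
        )
        cap, _ = run_qc(df, medium_ref.fmap, medium_ref.baitmap)
        bpa, bpb = refine_breakpoint(cap, fmap, "chr1", "chr2")
        if bpa.orientation != "left":  # use the left-A derivative view
            bpa = Breakpoint(bpa.chrom, bpa.fragment_id, bpa.position, "left")
            bpb = Breakpoint(bpb.chrom, bpb.fragment_id, bpb.position, "right")
        der = reconstruct_derivative(bpa, bpb, fmap)
        spanning = cap[(cap["chrom1"] == "chr1") & (cap["chrom2"] == "chr2")]
        calls = pd.DataFrame({
            "bait_id": spanning["frag1"].to_numpy(),
            "otherend_id": spanning["frag2"].to_numpy(),
            "N": 1, "score": 0.0,
        })
        remapped = remap_interactions(calls, fmap, der)
        d = remapped["der_dist"].to_numpy()
        d = d[(d > 10_000) & (d < 3_000_000)]
        # decay per possible locus pair: the number of junction-spanning
        # locus pairs at separation s grows linearly with s, so the raw
        # histogram is divided by s before reading off the exponent
        bins = np.geomspace(10_000, 3_000_000, 15)
        hist, _ = np.histogram(d, bins=bins)
        centers = np.sqrt(bins[:-1] * bins[1:])
        widths = np.diff(bins)
        ok = hist > 0
        freq = hist[ok] / widths[ok] / centers[ok]
        slope = np.polyfit(np.log(centers[ok]), np.log(freq), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.35)


class TestCNV:
    def test_identical_samples_no_segments(self, medium_ref, rearranged):
        segs, _ = detect_cnv(rearranged["control"], rearranged["control"],
                             medium_ref.fmap.chrom_sizes)
        assert segs == []

    def test_trisomy_and_monosomy_recovered(self, medium_ref, rearranged):
        tri, _ = simulate_rearrangement(
            medium_ref, n_pairs=1_000_000,
            cnvs=[("chr3", 0, 10_000_000, 3.0)], seed=80,
        )
        cap_tri, _ = run_qc(tri, medium_ref.fmap, medium_ref.baitmap)
        segs, _ = detect_cnv(cap_tri, rearranged["control"],
                             medium_ref.fmap.chrom_sizes)
        gains = [s for s in segs if s.call == "gain"]
        assert len(gains) == 1 and gains[0].chrom == "chr3"
        assert gains[0].mean_log2 == pytest.approx(np.log2(1.5), abs=0.1)

        mono, _ = simulate_rearrangement(
            medium_ref, n_pairs=1_000_000,
            cnvs=[("chr2", 0, 10_000_000, 1.0)], seed=81,
        )
        cap_mono, _ = run_qc(mono, medium_ref.fmap, medium_ref.baitmap)
        segs, _ = detect_cnv(cap_mono, rearranged["control"],
                             medium_ref.fmap.chrom_sizes)
        losses = [s for s in segs if s.call == "loss"]
        assert len(losses) == 1 and losses[0].chrom == "chr2"
        assert losses[0].mean_log2 == pytest.approx(-1.0, abs=0.1)

    def test_swap_flips_calls(self, medium_ref, rearranged):
        tri, _ = simulate_rearrangement(
            medium_ref, n_pairs=600_000, cnvs=[("chr3", 0, 10_000_000, 3.0)],
            seed=82,
        )
        cap_tri, _ = run_qc(tri, medium_ref.fmap, medium_ref.baitmap)
        fwd, _ = detect_cnv(cap_tri, rearranged["control"],
                            medium_ref.fmap.chrom_sizes)
        rev, _ = detect_cnv(rearranged["control"], cap_tri,
                            medium_ref.fmap.chrom_sizes)
        assert {(s.chrom, s.call) for s in fwd} == {("chr3", "gain")}
        assert {(s.chrom, s.call) for s in rev} == {("chr3", "loss")}
        f = next(s for s in fwd if s.chrom == "chr3")
        r = next(s for s in rev if s.chrom == "chr3")
        assert f.mean_log2 == pytest.approx(-r.mean_log2, abs=0.05)

    def test_zero_control_errors(self, medium_ref, rearranged):
        empty = rearranged["control"].iloc[:0]
        with pytest.raises(ValueError):
            detect_cnv(rearranged["captured"], empty,
                       medium_ref.fmap.chrom_sizes)
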