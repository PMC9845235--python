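"""Shared fixtures: small simulated references and libraries.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pytest

from captor.calling import counts_from_pairs, fit_background
from captor.pairs import run_qc
from captor.simulate import simulate_library, simulate_reference


@pytest.fixture(scope="session")
def small_ref():
    """Two 2-Mb chromosomes, HindIII-digested, 5% baited."""
    return simulate_reference(n_chroms=2, chrom_length=2_000_000, seed=11)


@pytest.fixture(scope="session")
def small_library(small_ref):
    df, truth = simulate_library(small_ref, n_pairs=150_000, seed=12)
    return df, truth


@pytest.fixture(scope="session")
def small_captured(small_ref, small_library):
    df, _ = small_library
    captured, report = run_qc(df, small_ref.fmap, small_ref.baitmap)
    return captured, report


@pytest.fixture(scope="session")
def medium_ref():
    """Three 10-Mb chromosomes: the default toy scale for calling and SVs."""
    return simulate_reference(n_chroms=3, chrom_length=10_000_000, seed=1)


@pytest.fixture(scope="session")
def spiked_loops(medium_ref):
    """Twenty 8-fold loops on baits of near-typical fragment size ~80 kb away."""
    ref = medium_ref
    rng = np.random.default_rng(5)
    loops = []
    for b in rng.permutation(ref.baitmap.fragment_ids):
        c, s, e = ref.fmap.fragment(int(b))
        if e - s < 2_000:  # tiny baits carry too few reads to spike meaningfully
            continue
        tgt = (s + e) // 2 + 80_000
        if tgt >= ref.fmap.chrom_sizes[c]:
            tgt = (s + e) // 2 - 80_000
        o = ref.fmap.locate(c, int(tgt))
        oc, os_, oe_ = ref.fmap.fragment(o)
        if o == b or abs(o - b) == 1 or oe_ - os_ < 2_000:
            continue
        loops.append((int(b), int(o), 8.0))
        if len(loops) == 20:
            break
    return loops


@pytest.fixture(scope="session")
def called_library(medium_ref, spiked_loops):
    """Default-depth library with spiked loops, fitted background and counts."""
    ref = medium_ref
    df, truth = simulate_library(ref, n_pairs=2_000_000, loops=spiked_loops, seed=7)
    captured, report = run_qc(df, ref.fmap, ref.baitmap)
    counts = counts_from_pairs(captured, ref.fmap, ref.baitmap)
    model = fit_background(counts, ref.fmap, ref.baitmap)
    return {
        "truth": truth,
        "captured": captured,
        "report": report,
        "counts": counts,
        "model": model,
    }
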