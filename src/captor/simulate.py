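"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a promoter capture
Hi-C experiment rather than its sequence content: cis contacts decay as a
power law of genomic distance, baited (promoter) fragments are enriched by
capture, enhancer-promoter loops are spiked multiplicatively on top of the
decay background, trans ligation noise is uniform, and PCR duplicates
re-emit existing ligation products.  Rearranged tumor libraries are drawn
on explicit derivative haplotypes and mapped back to reference
coordinates, so junction-spanning contacts appear as trans signal exactly
as they do in real data.  GWAS panels are drawn blockwise from an AR(1)
LD correlation with optional causal non-centrality.

Every generator is deterministic given its seed and returns the ground
truth (``SimTruth``) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import BaitMap, FragmentMap, digest_genome, get_enzyme

__all__ = [
    "SimTruth",
    "SimulatedReference",
    "simulate_reference",
    "simulate_library",
    "simulate_rearrangement",
    "simulate_gwas",
]

PAIR_COLS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


@dataclass
class SimTruth:
    """Ground truth recorded by the generators."""

    loops: list = field(default_factory=list)  # (bait_frag, other_frag, fold, base_mu)
    dup_rate: float = 0.0
    trans_rate: float = 0.0
    capture_prob: float = 1.0
    artifact_rate: float = 0.0
    alpha: float = 1.0
    translocation: dict | None = None
    cnvs: list = field(default_factory=list)  # (chrom, start, end, copy_number)
    causal_snps: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass
class SimulatedReference:
    sequences: dict[str, str]
    fmap: FragmentMap
    baitmap: BaitMap

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.fmap.chrom_sizes)


def simulate_reference(
    n_chroms: int = 3,
    chrom_length: int = 10_000_000,
    enzyme: str = "HindIII",
    bait_fraction: float = 0.05,
    seed: int = 0,
) -> SimulatedReference:
    """Random i.i.d. genome, digested, with a random 5% of fragments baited."""
    rng = np.random.default_rng(seed)
    lengths = (
        chrom_length if np.iterable(chrom_length) else [chrom_length] * n_chroms
    )
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        f"chr{i + 1}": rng.choice(bases, size=int(L)).tobytes().decode()
        for i, L in enumerate(lengths)
    }
    fmap = digest_genome(seqs, get_enzyme(enzyme))
    n_baits = max(2, int(round(bait_fraction * len(fmap))))
    bait_ids = np.sort(rng.choice(len(fmap), size=n_baits, replace=False))
    baitmap = BaitMap({int(f): f"GENE{k:05d}" for k, f in enumerate(bait_ids)})
    return SimulatedReference(seqs, fmap, baitmap)


# ---------------------------------------------------------------------------
# haplotype machinery (shared by plain and rearranged libraries)


@dataclass
class Haplotype:
    """A linear chromosome copy built from reference segments."""

    name: str
    segments: list[tuple[str, int, int, str]]  # (chrom, start, end, strand)
    copies: float = 1.0  # dosage multiplier (a normal diploid chromosome is 2)

    def __post_init__(self) -> None:
        self.seg_lengths = np.array([e - s for _, s, e, _ in self.segments])
        self.offsets = np.concatenate([[0], np.cumsum(self.seg_lengths)])
        self.length = int(self.offsets[-1])

    def to_ref(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map haplotype coordinates to reference (chrom array, pos array)."""
        pos = np.asarray(pos)
        seg = np.searchsorted(self.offsets, pos, side="right") - 1
        chroms = np.empty(len(pos), dtype=object)
        refpos = np.empty(len(pos), dtype=np.int64)
        for i, (c, s, e, strand) in enumerate(self.segments):
            m = seg == i
            if not m.any():
                continue
            local = pos[m] - self.offsets[i]
            chroms[m] = c
            refpos[m] = s + local if strand == "+" else e - 1 - local
        return chroms, refpos

    def from_ref(self, chrom: str, pos: int) -> int | None:
        for i, (c, s, e, strand) in enumerate(self.segments):
            if c == chrom and s <= pos < e:
                local = pos - s if strand == "+" else e - 1 - pos
                return int(self.offsets[i] + local)
        return None

    def bait_intervals(self, fmap: FragmentMap, baitmap: BaitMap
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of baited-fragment pieces in haplotype coordinates."""
        starts, ends = [], []
        for i, (c, s, e, strand) in enumerate(self.segments):
            off = self.offsets[i]
            fs, fe = fmap.starts[c], fmap.ends[c]
            fid0 = fmap.id_offset[c]
            lo = np.searchsorted(fe, s, side="right")
            hi = np.searchsorted(fs, e, side="left")
            for k in range(lo, hi):
                if fid0 + k in baitmap:
                    a, b = max(fs[k], s), min(fe[k], e)
                    if strand == "+":
                        starts.append(off + a - s)
                        ends.append(off + b - s)
                    else:
                        starts.append(off + e - b)
                        ends.append(off + e - a)
        if not starts:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        order = np.argsort(starts)
        return np.asarray(starts)[order], np.asarray(ends)[order]


def _powerlaw_sample(rng, n, alpha, d_min, d_max):
    """Draw distances with density proportional to d**-alpha on [d_min, d_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return d_min * (d_max / d_min) ** u
    a1 = 1.0 - alpha
    return (d_min**a1 + u * (d_max**a1 - d_min**a1)) ** (1.0 / a1)


def _powerlaw_density(d, alpha, d_min, d_max):
    """Normalized density of the sampler above, per bp."""
    if abs(alpha - 1.0) < 1e-12:
        z = np.log(d_max / d_min)
    else:
        a1 = 1.0 - alpha
        z = (d_max**a1 - d_min**a1) / a1
    return d ** (-alpha) / z


def _sample_bait_positions(rng, n, bstarts, bends):
    """Uniform positions within the union of bait intervals."""
    lens = bends - bstarts
    cum = np.concatenate([[0], np.cumsum(lens)])
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return bstarts[idx] + (u - cum[idx])


def _simulate_core(
    ref: SimulatedReference,
    haplotypes: list[Haplotype],
    n_pairs: int,
    alpha: float,
    loops,
    dup_rate: float,
    trans_rate: float,
    capture_prob: float,
    artifact_rate: float,
    d_min: float,
    cnv_weight=None,
    rng=None,
):
    fmap = ref.fmap
    n_dup = int(round(n_pairs * dup_rate))
    n_unique = n_pairs - n_dup
    # decay range fixed by the reference so rearranged and plain libraries
    # share the same distance law (resampling handles short haplotypes)
    d_max = min(fmap.chrom_sizes.values()) / 2.0

    hap_baits = [h.bait_intervals(fmap, ref.baitmap) for h in haplotypes]
    bait_mass = np.array(
        [h.copies * float((be - bs).sum()) for h, (bs, be) in zip(haplotypes, hap_baits)]
    )
    if bait_mass.sum() == 0:
        raise ValueError("no baited fragments on any haplotype")
    hap_w = bait_mass / bait_mass.sum()

    chrom_names = list(fmap.chroms)
    sizes = np.array([fmap.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    chrom_arr = np.array(chrom_names, dtype=object)
    # flat per-fragment lookup tables for vectorized artifact/trans generation
    frag_df = fmap.to_dataframe()
    f_start = frag_df["start"].to_numpy()
    f_end = frag_df["end"].to_numpy()
    f_cidx = fmap.chrom_index(frag_df["fragment_id"].to_numpy())
    f_is_last = f_end == sizes[f_cidx]
    f_is_bait = np.zeros(len(fmap), dtype=bool)
    f_is_bait[ref.baitmap.fragment_ids] = True
    chrom_offsets = np.array([fmap.id_offset[c] for c in chrom_names])
    chrom_nfrags = np.array([fmap.n_fragments(c) for c in chrom_names])

    def _uniform_in(fid):
        span = f_end[fid] - f_start[fid]
        return f_start[fid] + (rng.random(len(fid)) * span).astype(np.int64)

    def gen_batch(m):
        """Generate m unique ligation events (ref coordinates)."""
        c1 = np.empty(m, dtype=object)
        p1 = np.empty(m, dtype=np.int64)
        c2 = np.empty(m, dtype=object)
        p2 = np.empty(m, dtype=np.int64)
        kind = rng.random(m)
        is_art = kind < artifact_rate
        rest = ~is_art
        # artifacts: same-fragment / adjacent re-ligation on random fragments
        na = int(is_art.sum())
        if na:
            fid = rng.integers(0, len(fmap), size=na)
            same = rng.random(na) < 0.7
            nxt = np.where(f_is_last[fid], fid - 1, fid + 1)
            fid2 = np.where(same, fid, nxt)
            c1[is_art] = chrom_arr[f_cidx[fid]]
            p1[is_art] = _uniform_in(fid)
            c2[is_art] = chrom_arr[f_cidx[fid2]]
            p2[is_art] = _uniform_in(fid2)
        # informative pairs: captured (bait-anchored) w.p. capture_prob, of
        # which trans_rate are trans background; uncaptured pairs are cis
        # ligation noise away from baits
        ni = int(rest.sum())
        if ni:
            cap = rng.random(ni) < capture_prob
            tr = cap & (rng.random(ni) < trans_rate)
            hidx = rng.choice(len(haplotypes), size=ni, p=hap_w)
            ic1 = np.empty(ni, dtype=object)
            ip1 = np.empty(ni, dtype=np.int64)
            ic2 = np.empty(ni, dtype=object)
            ip2 = np.empty(ni, dtype=np.int64)
            for hi, hap in enumerate(haplotypes):
                m_h = hidx == hi
                k = int(m_h.sum())
                if k == 0:
                    continue
                bs, be = hap_baits[hi]
                a1 = _sample_bait_positions(rng, k, bs, be)
                # uncaptured pairs: replace the bait anchor by a uniform position
                unc = ~cap[m_h]
                if unc.any():
                    a1[unc] = rng.integers(0, hap.length, size=int(unc.sum()))
                d = _powerlaw_sample(rng, k, alpha, d_min, d_max)
                sign = rng.choice([-1, 1], size=k)
                a2 = a1 + (sign * d).astype(np.int64)
                bad = (a2 < 0) | (a2 >= hap.length)
                tries = 0
                while bad.any() and tries < 50:
                    nb = int(bad.sum())
                    d2 = _powerlaw_sample(rng, nb, alpha, d_min, d_max)
                    s2 = rng.choice([-1, 1], size=nb)
                    a2[bad] = a1[bad] + (s2 * d2).astype(np.int64)
                    bad = (a2 < 0) | (a2 >= hap.length)
                    tries += 1
                a2 = np.clip(a2, 0, hap.length - 1)
                cc1, pp1 = hap.to_ref(a1)
                cc2, pp2 = hap.to_ref(a2)
                ic1[m_h], ip1[m_h], ic2[m_h], ip2[m_h] = cc1, pp1, cc2, pp2
            # trans background: keep the bait anchor, replace the partner by
            # a uniform position on a dosage-weighted random haplotype (so
            # random ligation scales with local DNA amount) on another
            # reference chromosome
            if tr.any() and len(chrom_names) > 1:
                nt = int(tr.sum())
                lw = np.array([h.copies * h.length for h in haplotypes], dtype=float)
                lw /= lw.sum()
                oc = np.empty(nt, dtype=object)
                op = np.empty(nt, dtype=np.int64)
                todo = np.ones(nt, dtype=bool)
                anchor_chrom = ic1[tr]
                for _ in range(30):
                    k = int(todo.sum())
                    if k == 0:
                        break
                    hsel = rng.choice(len(haplotypes), size=k, p=lw)
                    upos = (rng.random(k) * np.array(
                        [haplotypes[h].length for h in hsel])).astype(np.int64)
                    cc = np.empty(k, dtype=object)
                    pp = np.empty(k, dtype=np.int64)
                    for h in np.unique(hsel):
                        mh = hsel == h
                        cc[mh], pp[mh] = haplotypes[h].to_ref(upos[mh])
                    idx = np.where(todo)[0]
                    ok = cc != anchor_chrom[idx]
                    oc[idx[ok]] = cc[ok]
                    op[idx[ok]] = pp[ok]
                    todo[idx[ok]] = False
                if todo.any():  # fallback: flat draw on another chromosome
                    idx = np.where(todo)[0]
                    bc = np.array([chrom_names.index(c) for c in anchor_chrom[idx]])
                    occ = rng.integers(0, len(chrom_names) - 1, size=len(idx))
                    occ = occ + (occ >= bc)
                    oc[idx] = chrom_arr[occ]
                    op[idx] = (rng.random(len(idx)) * sizes[occ]).astype(np.int64)
                ic2[tr] = oc
                ip2[tr] = op
            # uncaptured pairs must not touch bait fragments: nudge offending
            # ends to the nearest non-bait neighbor fragment
            unc = ~cap
            if unc.any():
                for cc, pp in ((ic1, ip1), (ic2, ip2)):
                    fid = fmap.locate_many(cc[unc], pp[unc])
                    for _ in range(10):
                        on_bait = f_is_bait[fid]
                        if not on_bait.any():
                            break
                        fid[on_bait] = np.where(
                            f_is_last[fid[on_bait]], fid[on_bait] - 1,
                            fid[on_bait] + 1,
                        )
                    pp[unc] = _uniform_in(fid)
                    cc[unc] = chrom_arr[f_cidx[fid]]
            # informative cis pairs are meant to survive artifact filtering:
            # partners that land in the anchor's own or adjacent fragment by
            # chance are pushed one fragment further out
            cis_inf = ~tr
            if cis_inf.any():
                fa = fmap.locate_many(ic1[cis_inf], ip1[cis_inf])
                fb = fmap.locate_many(ic2[cis_inf], ip2[cis_inf])
                same_c = f_cidx[fa] == f_cidx[fb]
                bad = same_c & (np.abs(fa - fb) <= 1)
                if bad.any():
                    direction = np.where(fb >= fa, 1, -1)[bad]
                    tgt = fa[bad] + direction * 2
                    off = chrom_offsets[f_cidx[fa[bad]]]
                    n_c = chrom_nfrags[f_cidx[fa[bad]]]
                    tgt = np.clip(tgt, off, off + n_c - 1)
                    flip = np.abs(tgt - fa[bad]) <= 1
                    tgt[flip] = np.clip(fa[bad][flip] - 2 * direction[flip],
                                        off[flip], off[flip] + n_c[flip] - 1)
                    idx = np.flatnonzero(cis_inf)[bad]
                    ip2[idx] = _uniform_in(tgt)
                    ic2[idx] = chrom_arr[f_cidx[tgt]]
            c1[rest], p1[rest], c2[rest], p2[rest] = ic1, ip1, ic2, ip2
        return c1, p1, c2, p2, is_art

    # copy-number rejection: accept pairs with probability w/wmax
    if cnv_weight is None:
        c1, p1, c2, p2, art = gen_batch(n_unique)
    else:
        parts = []
        got = 0
        while got < n_unique:
            need = n_unique - got
            m = int(need * 1.3) + 10
            b = gen_batch(m)
            w = cnv_weight(b[0], b[1]) * cnv_weight(b[2], b[3])
            wmax = w.max() if len(w) else 1.0
            keep = rng.random(m) < w / max(wmax, 1.0)
            parts.append(tuple(x[keep] for x in b))
            got += int(keep.sum())
        c1 = np.concatenate([p[0] for p in parts])[:n_unique]
        p1 = np.concatenate([p[1] for p in parts])[:n_unique]
        c2 = np.concatenate([p[2] for p in parts])[:n_unique]
        p2 = np.concatenate([p[3] for p in parts])[:n_unique]
        art = np.concatenate([p[4] for p in parts])[:n_unique]

    # spiked loops: extra reads on specific bait-other fragment pairs
    truth_loops = []
    extra = []
    if loops:
        n_cis_capt = n_unique * (1 - artifact_rate) * capture_prob * (1 - trans_rate)
        total_bait_len = float(
            sum(fmap.fragment(int(f))[2] - fmap.fragment(int(f))[1]
                for f in ref.baitmap.fragment_ids)
        )
        for bait_fid, other_fid, fold in loops:
            cb, sb_, eb = fmap.fragment(int(bait_fid))
            co, so, eo = fmap.fragment(int(other_fid))
            if cb != co:
                raise ValueError("spiked loops must be cis")
            d = abs((sb_ + eb) / 2 - (so + eo) / 2)
            if not (d_min <= d <= d_max):
                raise ValueError(
                    f"spiked loop distance {d:.0f} outside simulable range"
                )
            n_b = n_cis_capt * (eb - sb_) / total_bait_len
            mu = n_b * 0.5 * _powerlaw_density(d, alpha, d_min, d_max) * (eo - so)
            k = rng.poisson((fold - 1) * mu)
            if k:
                e1 = rng.integers(sb_, eb, size=k)
                e2 = rng.integers(so, eo, size=k)
                extra.append((np.full(k, cb, dtype=object), e1,
                              np.full(k, co, dtype=object), e2))
            truth_loops.append((int(bait_fid), int(other_fid), float(fold), float(mu)))
    if extra:
        c1 = np.concatenate([c1] + [x[0] for x in extra])
        p1 = np.concatenate([p1] + [x[1] for x in extra])
        c2 = np.concatenate([c2] + [x[2] for x in extra])
        p2 = np.concatenate([p2] + [x[3] for x in extra])
        art = np.concatenate([art, np.zeros(len(c1) - len(art), dtype=bool)])

    n_all = len(c1)
    s1 = rng.choice(["+", "-"], size=n_all)
    s2 = rng.choice(["+", "-"], size=n_all)

    # duplicates re-emit existing records that will classify as valid (short
    # cis pairs can land in the same or adjacent fragments by chance and be
    # removed as artifacts), so the planted rate is what deduplication sees
    if n_dup:
        f1 = fmap.locate_many(c1, p1)
        f2 = fmap.locate_many(c2, p2)
        same_chrom = np.array([a == b for a, b in zip(c1, c2)])
        art_eff = art | (f1 == f2) | (same_chrom & (np.abs(f1 - f2) == 1))
        didx = rng.choice(np.where(~art_eff)[0], size=n_dup)
        c1 = np.concatenate([c1, c1[didx]])
        p1 = np.concatenate([p1, p1[didx]])
        c2 = np.concatenate([c2, c2[didx]])
        p2 = np.concatenate([p2, p2[didx]])
        s1 = np.concatenate([s1, s1[didx]])
        s2 = np.concatenate([s2, s2[didx]])

    order = rng.permutation(len(c1))
    df = pd.DataFrame(
        {
            "read_id": [f"r{i:08d}" for i in range(len(c1))],
            "chrom1": c1[order],
            "pos1": p1[order],
            "chrom2": c2[order],
            "pos2": p2[order],
            "strand1": s1[order],
            "strand2": s2[order],
        }
    )
    return df, truth_loops


def simulate_library(
    ref: SimulatedReference,
    n_pairs: int = 2_000_000,
    alpha: float = 1.0,
    loops=None,
    dup_rate: float = 0.12,
    trans_rate: float = 0.24,
    capture_prob: float = 0.61,
    artifact_rate: float = 0.40,
    d_min: float = 5_000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a capture Hi-C library on the (unrearranged) reference.

    Defaults mirror a typical library: ~24% of captured contacts in trans,
    ~61% capture efficiency, power-law cis decay with exponent 1.
    """
    rng = np.random.default_rng(seed)
    haps = [
        Haplotype(c, [(c, 0, ref.fmap.chrom_sizes[c], "+")]) for c in ref.fmap.chroms
    ]
    df, truth_loops = _simulate_core(
        ref, haps, n_pairs, alpha, loops, dup_rate, trans_rate,
        capture_prob, artifact_rate, d_min, rng=rng,
    )
    truth = SimTruth(
        loops=truth_loops, dup_rate=dup_rate, trans_rate=trans_rate,
        capture_prob=capture_prob, artifact_rate=artifact_rate, alpha=alpha,
    )
    return df, truth


def _snap_to_boundary(fmap: FragmentMap, chrom: str, pos: int) -> int:
    bounds = np.concatenate([fmap.starts[chrom], [fmap.chrom_sizes[chrom]]])
    return int(bounds[np.argmin(np.abs(bounds - pos))])


def simulate_rearrangement(
    ref: SimulatedReference,
    n_pairs: int = 2_000_000,
    translocation: dict | None = None,
    cnvs=(),
    alpha: float = 1.0,
    loops=None,
    dup_rate: float = 0.12,
    trans_rate: float = 0.24,
    capture_prob: float = 0.61,
    artifact_rate: float = 0.40,
    d_min: float = 5_000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a rearranged (tumor-like) library in reference coordinates.

    ``translocation`` is ``{"chromA", "posA", "chromB", "posB", "reciprocal"}``;
    breakpoints are snapped to restriction-fragment boundaries.  Pairs are
    drawn on derivative haplotypes, so junction-spanning cis contacts of the
    derivative map back as trans contacts between the two partner
    chromosomes.  ``cnvs`` is a list of ``(chrom, start, end, copy_number)``;
    regions emit reads at copy/2 relative rate (diploid baseline).
    """
    rng = np.random.default_rng(seed)
    fmap = ref.fmap
    haps = [
        Haplotype(c, [(c, 0, fmap.chrom_sizes[c], "+")], copies=2.0)
        for c in fmap.chroms
    ]
    truth_tl = None
    if translocation is not None:
        ca, cb = translocation["chromA"], translocation["chromB"]
        pa = _snap_to_boundary(fmap, ca, int(translocation["posA"]))
        pb = _snap_to_boundary(fmap, cb, int(translocation["posB"]))
        reciprocal = bool(translocation.get("reciprocal", True))
        la, lb = fmap.chrom_sizes[ca], fmap.chrom_sizes[cb]
        # heterozygous event: one normal copy of each partner remains
        for h in haps:
            if h.name in (ca, cb):
                h.copies = 1.0
        haps.append(
            Haplotype(f"der({ca})", [(ca, 0, pa, "+"), (cb, pb, lb, "+")])
        )
        if reciprocal:
            haps.append(
                Haplotype(f"der({cb})", [(cb, 0, pb, "+"), (ca, pa, la, "+")])
            )
        truth_tl = {"chromA": ca, "posA": pa, "chromB": cb, "posB": pb,
                    "reciprocal": reciprocal}

    cnvs = [(c, int(s), int(e), float(cn)) for c, s, e, cn in cnvs]
    for i, (c, s, e, _) in enumerate(cnvs):
        for c2, s2, e2, _ in cnvs[i + 1:]:
            if c == c2 and s < e2 and s2 < e:
                raise ValueError("overlapping CNV regions")
    # copy-number changes are modeled as real haplotype dosage: a gain adds
    # a free-standing duplicated segment (cn-2 extra copies); a loss
    # replaces one full copy with a copy lacking the region
    seen_loss: set[str] = set()
    for c, s, e, cn in cnvs:
        base = next(h for h in haps if h.name == c)
        L = fmap.chrom_sizes[c]
        if cn >= 2.0:
            if cn > 2.0:
                haps.append(
                    Haplotype(f"dup({c}:{s}-{e})", [(c, s, e, "+")], copies=cn - 2.0)
                )
        else:
            if c in seen_loss:
                raise ValueError(f"multiple sub-diploid CNVs on {c} unsupported")
            seen_loss.add(c)
            segs = [seg for seg in ((c, 0, s, "+"), (c, e, L, "+")) if seg[2] > seg[1]]
            base.copies = cn
            if segs:
                haps.append(Haplotype(f"del({c}:{s}-{e})", segs, copies=2.0 - cn))

    df, truth_loops = _simulate_core(
        ref, haps, n_pairs, alpha, loops, dup_rate, trans_rate,
        capture_prob, artifact_rate, d_min, rng=rng,
    )
    truth = SimTruth(
        loops=truth_loops, dup_rate=dup_rate, trans_rate=trans_rate,
        capture_prob=capture_prob, artifact_rate=artifact_rate, alpha=alpha,
        translocation=truth_tl, cnvs=cnvs,
    )
    return df, truth


def simulate_gwas(
    n_blocks: int = 40,
    snps_per_block: int = 20,
    block_size: int = 100_000,
    rho: float = 0.9,
    n: int = 50_000,
    causal=None,
    chrom: str = "1",
    maf_range: tuple[float, float] = (0.05, 0.5),
    r2_min: float = 0.1,
    seed: int = 0,
):
    """Blockwise GWAS summary statistics with AR(1) LD.

    Within each block, z-scores are multivariate normal with correlation
    rho**|i-j|; a causal SNP ``(block, index, effect)`` adds non-centrality
    effect * sqrt(n * 2 f (1-f)) propagated through the LD correlation.
    The genetic map is linear with 1 cM per block, so the blocks are
    exactly the 1-cM fine-mapping regions.

    Returns (gwas DataFrame, LD r2 DataFrame, genetic map DataFrame, SimTruth).
    """
    rng = np.random.default_rng(seed)
    causal = list(causal or [])
    k = snps_per_block
    corr = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))

    rows = []
    ld_rows = []
    truth_snps = []
    spacing = block_size // (k + 1)
    for b in range(n_blocks):
        pos = b * block_size + spacing * (1 + np.arange(k))
        maf = rng.uniform(*maf_range, size=k)
        z = chol @ rng.standard_normal(k)
        for cb, ci, eff in causal:
            if cb == b:
                lam = eff * np.sqrt(n * 2 * maf[ci] * (1 - maf[ci]))
                z = z + corr[:, ci] * lam
                truth_snps.append((f"rs{b}_{ci}", float(eff), b))
        se = 1.0 / np.sqrt(n * 2 * maf * (1 - maf))
        from scipy.stats import norm

        p = np.clip(2 * norm.sf(np.abs(z)), 1e-320, 1.0)
        rows.append(pd.DataFrame({
            "snp": [f"rs{b}_{i}" for i in range(k)],
            "chrom": chrom, "pos": pos, "p": p,
            "beta": z * se, "se": se, "maf": maf, "n": n,
        }))
        r2 = corr**2
        ii, jj = np.where(np.triu(r2, k=1) >= r2_min)
        ld_rows.append(pd.DataFrame({
            "snp1": [f"rs{b}_{i}" for i in ii],
            "snp2": [f"rs{b}_{j}" for j in jj],
            "r2": r2[ii, jj],
        }))
    gwas = pd.concat(rows, ignore_index=True)
    ld = pd.concat(ld_rows, ignore_index=True)
    gmap = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(n_blocks + 1) * block_size,
        "cM": np.arange(n_blocks + 1, dtype=float),
    })
    truth = SimTruth(causal_snps=truth_snps,
                     extra={"n_blocks": n_blocks, "rho": rho, "n": n})
    return gwas, ld, gmap, truth
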