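"""Structural-variant discovery from capture Hi-C contact maps.

A translocation juxtaposes two chromosomes, so ligation events between
them are locally enriched far beyond the flat trans background.
Detection scans each chromosome pair's coverage-normalized trans plane
with a sliding window and scores windows against a permutation null
(random relabeling of bins within each chromosome); maximal blocks of
extreme z-scores are the calls.  A reciprocal (balanced) translocation
produces two blocks in opposite quadrants around the junction — the
"butterfly" pattern — one derivative each; an unbalanced event produces
a single block.

Breakpoints are refined at restriction-fragment resolution by fitting a
two-dimensional step model: the fragment-level trans count plane is split
at a candidate (a, b) into four quadrants with constant Poisson rates,
and the split maximizing the likelihood locates both breakpoints at once.
Derivative chromosomes are reconstructed by joining the kept segments,
with an invertible coordinate transform that re-projects junction-spanning
contacts as cis contacts on the derivative.

CNVs are called from case/control end-coverage log2 ratios in sliding
windows (gain/loss runs of at least ``min_len`` windows beyond a
threshold), mirroring read-depth CNV callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .digest import FragmentMap
from .matrix import BinnedMatrix

__all__ = [
    "TranslocationCall",
    "Breakpoint",
    "DerivativeMap",
    "CNVSegment",
    "detect_translocations",
    "refine_breakpoint",
    "reconstruct_derivative",
    "detect_cnv",
    "DegenerateSignalError",
]


class DegenerateSignalError(ValueError):
    """Raised when the trans signal carries no localizable breakpoint."""


@dataclass
class TranslocationCall:
    chrom_a: str
    chrom_b: str
    z: float
    pattern: str  # "balanced" | "unbalanced"
    blocks: list  # [(a_start, a_end, b_start, b_end)] in bp, one per derivative
    resolution: int

    def __post_init__(self) -> None:
        if self.chrom_a == self.chrom_b:
            raise ValueError("translocation requires two distinct chromosomes")
        if not np.isfinite(self.z):
            raise ValueError("non-finite z-score")
        if not self.blocks:
            raise ValueError("empty call block")
        if self.pattern not in ("balanced", "unbalanced"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class Breakpoint:
    chrom: str
    fragment_id: int
    position: int  # fragment start, bp
    orientation: str  # "left" | "right": which side joins the partner

    def __post_init__(self) -> None:
        if self.orientation not in ("left", "right"):
            raise ValueError(f"orientation must be left/right, got {self.orientation!r}")


def detect_translocations(
    case: BinnedMatrix,
    n_perm: int = 200,
    seed: int = 0,
    z_min: float = 8.0,
    window: int = 3,
    corner_tol: int = 2,
) -> list[TranslocationCall]:
    """Scan all chromosome pairs for translocation-like trans enrichment.

    Trans counts are normalized by the product of genome-wide bin
    coverages, window-averaged, and compared against ``n_perm`` random
    within-chromosome bin permutations (pooled null mean/sd).  Connected
    blocks of bins with z >= z_min become calls; two blocks meeting at a
    shared corner in opposite quadrants are merged into one balanced
    ("butterfly") call.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    cov = case.marginals().astype(float)
    cov[cov == 0] = np.nan
    calls: list[TranslocationCall] = []
    for ia, ca in enumerate(case.chroms):
        for cb in case.chroms[ia + 1 :]:
            T = case.trans_dense(ca, cb).astype(float)
            if T.sum() == 0:
                continue
            oa, ob = case.bin_offset[ca], case.bin_offset[cb]
            na, nb = T.shape
            norm = T / np.outer(cov[oa : oa + na], cov[ob : ob + nb])
            norm = np.nan_to_num(norm)
            obs = ndimage.uniform_filter(norm, size=window, mode="nearest")
            null_vals = np.empty((n_perm, na, nb))
            for k in range(n_perm):
                pa = rng.permutation(na)
                pb = rng.permutation(nb)
                null_vals[k] = ndimage.uniform_filter(
                    norm[np.ix_(pa, pb)], size=window, mode="nearest"
                )
            mu, sd = null_vals.mean(), null_vals.std()
            if sd == 0:
                continue
            z = (obs - mu) / sd
            lab, nlab = ndimage.label(z >= z_min)
            if nlab == 0:
                continue
            blocks = []
            for l in range(1, nlab + 1):
                rows, cols = np.where(lab == l)
                blocks.append(
                    {
                        "rows": (rows.min(), rows.max()),
                        "cols": (cols.min(), cols.max()),
                        "z": float(z[rows, cols].max()),
                    }
                )
            calls.extend(
                _assemble_calls(blocks, ca, cb, case.resolution, na, nb, corner_tol)
            )
    return calls


def _assemble_calls(blocks, ca, cb, res, na, nb, tol):
    """Pair opposite-quadrant blocks into balanced calls; rest unbalanced."""
    used = set()
    calls = []
    for i, b1 in enumerate(blocks):
        if i in used:
            continue
        partner = None
        for j in range(i + 1, len(blocks)):
            if j in used:
                continue
            b2 = blocks[j]
            # shared corner: the upper block's row-range abuts the lower
            # block's, and their column ranges abut on either side
            for x, y in ((b1, b2), (b2, b1)):
                r_meet = abs(x["rows"][1] + 1 - y["rows"][0]) <= tol
                c_meet = (
                    abs(y["cols"][1] + 1 - x["cols"][0]) <= tol
                    or abs(x["cols"][1] + 1 - y["cols"][0]) <= tol
                )
                if r_meet and c_meet:
                    partner = j
                    break
            if partner is not None:
                break
        members = [b1] if partner is None else [b1, blocks[partner]]
        if partner is not None:
            used.add(partner)
        bp_blocks = [
            (
                b["rows"][0] * res,
                (b["rows"][1] + 1) * res,
                b["cols"][0] * res,
                (b["cols"][1] + 1) * res,
            )
            for b in members
        ]
        calls.append(
            TranslocationCall(
                chrom_a=ca,
                chrom_b=cb,
                z=max(b["z"] for b in members),
                pattern="balanced" if partner is not None else "unbalanced",
                blocks=bp_blocks,
                resolution=res,
            )
        )
    return calls


def refine_breakpoint(
    pairs: pd.DataFrame,
    fmap: FragmentMap,
    chrom_a: str,
    chrom_b: str,
    min_pairs: int = 50,
    min_gain: float = 30.0,
) -> tuple[Breakpoint, Breakpoint]:
    """Locate both breakpoints at fragment resolution from trans pairs.

    Fits a four-quadrant constant-rate Poisson step model over the
    fragment-level count plane of the two chromosomes and maximizes the
    likelihood over the split (a, b).  Orientation is the side of each
    breakpoint carrying the elevated rate (toward the junction).  Raises
    :class:`DegenerateSignalError` when no split improves on a uniform
    rate by at least ``min_gain`` log-likelihood units.
    """
    H = _fragment_plane(pairs, fmap, chrom_a, chrom_b, min_pairs)
    ba, bb, hot, rates, _ = _corner_fit(H, min_gain)
    na, nb = H.shape
    orient_a = "left" if hot in (0, 1) else "right"
    orient_b = "left" if hot in (0, 2) else "right"

    bp_a = Breakpoint(
        chrom_a,
        fmap.id_offset[chrom_a] + min(ba, na - 1),
        int(fmap.starts[chrom_a][min(ba, na - 1)]),
        orient_a,
    )
    bp_b = Breakpoint(
        chrom_b,
        fmap.id_offset[chrom_b] + min(bb, nb - 1),
        int(fmap.starts[chrom_b][min(bb, nb - 1)]),
        orient_b,
    )
    return bp_a, bp_b


def classify_pattern(
    pairs: pd.DataFrame,
    fmap: FragmentMap,
    chrom_a: str,
    chrom_b: str,
    hot_factor: float = 5.0,
    min_pairs: int = 50,
    min_gain: float = 30.0,
) -> str:
    """Classify a translocation as balanced or unbalanced.

    Uses the same local four-quadrant rate fit as breakpoint refinement:
    a reciprocal event leaves both derivatives, so the two quadrants
    diagonally opposite across the junction are both elevated at least
    ``hot_factor`` times over the remaining background quadrants (the
    fragment-scale view of the "butterfly"); a one-derivative event
    elevates a single quadrant.
    """
    H = _fragment_plane(pairs, fmap, chrom_a, chrom_b, min_pairs)
    _, _, hot, rates, _ = _corner_fit(H, min_gain)
    opposite = {0: 3, 1: 2, 2: 1, 3: 0}[hot]
    others = [k for k in range(4) if k not in (hot, opposite)]
    background = max(max(rates[k] for k in others), 1e-300)
    return "balanced" if rates[opposite] >= hot_factor * background else "unbalanced"


def _fragment_plane(pairs, fmap, chrom_a, chrom_b, min_pairs):
    m = ((pairs["chrom1"] == chrom_a) & (pairs["chrom2"] == chrom_b)) | (
        (pairs["chrom1"] == chrom_b) & (pairs["chrom2"] == chrom_a)
    )
    sub = pairs[m]
    if len(sub) < min_pairs:
        raise ValueError(
            f"only {len(sub)} trans pairs between {chrom_a} and {chrom_b}; "
            f"need >= {min_pairs} (consider calling at coarser resolution)"
        )
    swap = sub["chrom1"] == chrom_b
    pa = np.where(swap, sub["pos2"], sub["pos1"]).astype(np.int64)
    pb = np.where(swap, sub["pos1"], sub["pos2"]).astype(np.int64)
    fa = fmap.locate_many(np.full(len(sub), chrom_a, dtype=object), pa)
    fb = fmap.locate_many(np.full(len(sub), chrom_b, dtype=object), pb)
    ia = fa - fmap.id_offset[chrom_a]
    ib = fb - fmap.id_offset[chrom_b]
    na, nb = fmap.n_fragments(chrom_a), fmap.n_fragments(chrom_b)
    H = np.zeros((na, nb))
    np.add.at(H, (ia, ib), 1.0)
    return H


def _corner_fit(H, min_gain, window=50):
    """Locate the junction corner (ba, bb), hot quadrant and quadrant rates.

    The junction contact blob is found by a smoothed argmax; for each of
    the four hot-quadrant orientations the corner is polished by
    alternating windowed one-dimensional change points on marginals over
    the partner's hot half-plane.  Each change point uses the distal cold
    half-plane (beyond a one-window guard band, which may hold the
    opposite derivative's signal or blob tails) as per-bin exposure, so
    capture-driven bait spikes cancel instead of attracting the split.
    Hypotheses whose polished corner shows a four-quadrant likelihood
    gain >= ``min_gain`` vote; the largest cluster of agreeing corners
    wins, with hot-quadrant contrast as tie-break.
    """
    na, nb = H.shape
    if H.sum() == 0:
        raise DegenerateSignalError("empty trans plane")
    smooth = ndimage.uniform_filter(H, size=21, mode="constant")
    a0, b0 = (int(x) for x in np.unravel_index(np.argmax(smooth), H.shape))

    row_cum = H.cumsum(axis=1)  # row totals over cols < b
    col_cum = H.cumsum(axis=0)  # col totals over rows < a
    row_tot = row_cum[:, -1]
    col_tot = col_cum[-1, :]

    candidates = []
    for hot in range(4):
        ba, bb = a0, b0
        for it in range(6):
            # first pass scans the whole axis (the smoothed argmax may sit
            # deep inside a flat blob); later passes refine locally
            if it == 0:
                alo, ahi = 0, na
            else:
                alo, ahi = max(ba - window, 0), min(ba + window, na)
            if hot in (1, 3):  # hot cols right of bb
                g = max(bb - window, 0)
                m = row_tot - (row_cum[:, bb - 1] if bb > 0 else 0.0)
                e = row_cum[:, g - 1] if g > 0 else np.ones(na)
            else:
                g = min(bb + window, nb)
                m = row_cum[:, bb - 1] if bb > 0 else np.zeros(na)
                e = row_tot - (row_cum[:, g - 1] if g > 0 else 0.0)
            if np.all(e[alo:ahi] <= 0):
                e = np.ones(na)
            ba = alo + _change_point(m[alo:ahi], e[alo:ahi] + 1.0)
            if it == 0:
                blo, bhi = 0, nb
            else:
                blo, bhi = max(bb - window, 0), min(bb + window, nb)
            if hot in (0, 1):  # hot rows above ba
                g = min(ba + window, na)
                m2 = col_cum[ba - 1, :] if ba > 0 else np.zeros(nb)
                e2 = col_tot - (col_cum[g - 1, :] if g > 0 else 0.0)
            else:
                g = max(ba - window, 0)
                m2 = col_tot - (col_cum[ba - 1, :] if ba > 0 else 0.0)
                e2 = col_cum[g - 1, :] if g > 0 else np.ones(nb)
            if np.all(e2[blo:bhi] <= 0):
                e2 = np.ones(nb)
            bb = blo + _change_point(m2[blo:bhi], e2[blo:bhi] + 1.0)
        rates, gain = _quadrant_stats(H, ba, bb, window)
        adjacent = [k for k in range(4) if k not in (hot, 3 - hot)]
        contrast = rates[hot] / (max(rates[k] for k in adjacent) + 1e-12)
        candidates.append((ba, bb, hot, rates, gain, contrast))

    passing = [c for c in candidates if np.isfinite(c[4]) and c[4] >= min_gain]
    if not passing:
        gmax = max(c[4] for c in candidates)
        raise DegenerateSignalError(
            f"no breakpoint: best split improves log-likelihood by "
            f"{gmax:.1f} < {min_gain}"
        )
    clusters: list[list] = []
    for c in passing:
        for cl in clusters:
            if abs(cl[0][0] - c[0]) <= 2 and abs(cl[0][1] - c[1]) <= 2:
                cl.append(c)
                break
        else:
            clusters.append([c])
    group = max(clusters, key=lambda g: (len(g), max(c[5] for c in g)))
    ba, bb, hot, rates, gain, _ = max(group, key=lambda c: c[5])

    # final consensus: per dimension, sum the step-likelihood curves of the
    # two opposing views (a reciprocal event has a derivative on each side
    # of the junction, so both curves peak at the same split; for a
    # one-sided event the cold view's curve is flat and harmless)
    for _ in range(2):
        alo, ahi = max(ba - window, 0), min(ba + window, na)
        g_r, g_l = max(bb - window, 0), min(bb + window, nb)
        m_r = row_tot - (row_cum[:, bb - 1] if bb > 0 else 0.0)
        e_r = row_cum[:, g_r - 1] if g_r > 0 else np.ones(na)
        m_l = row_cum[:, bb - 1] if bb > 0 else np.zeros(na)
        e_l = row_tot - (row_cum[:, g_l - 1] if g_l > 0 else 0.0)
        c = _ll_curve(m_r[alo:ahi], e_r[alo:ahi] + 1.0) + _ll_curve(
            m_l[alo:ahi], e_l[alo:ahi] + 1.0
        )
        ba = alo + 1 + int(np.argmax(c))
        blo, bhi = max(bb - window, 0), min(bb + window, nb)
        g_t, g_b = min(ba + window, na), max(ba - window, 0)
        m_t = col_cum[ba - 1, :] if ba > 0 else np.zeros(nb)
        e_t = col_tot - (col_cum[g_t - 1, :] if g_t > 0 else 0.0)
        m_b = col_tot - (col_cum[ba - 1, :] if ba > 0 else 0.0)
        e_b = col_cum[g_b - 1, :] if g_b > 0 else np.ones(nb)
        c2 = _ll_curve(m_t[blo:bhi], e_t[blo:bhi] + 1.0) + _ll_curve(
            m_b[blo:bhi], e_b[blo:bhi] + 1.0
        )
        bb = blo + 1 + int(np.argmax(c2))
    rates, gain = _quadrant_stats(H, ba, bb, window)
    return ba, bb, hot, rates, gain


def _ll_curve(m: np.ndarray, exposure: np.ndarray) -> np.ndarray:
    """Two-segment exposure-offset Poisson log-likelihood gain per split."""
    n = len(m)
    cm = np.cumsum(m)
    ce = np.cumsum(exposure)
    tot, tote = cm[-1], ce[-1]
    s = np.arange(1, n)
    n1, e1 = cm[s - 1], ce[s - 1]
    n2, e2 = tot - n1, tote - e1

    def t(k, E):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = k * np.log(k / np.maximum(E, 1e-300))
        return np.where(k > 0, v, 0.0)

    ll = t(n1, e1) + t(n2, e2)
    ll0 = tot * np.log(tot / max(tote, 1e-300)) if tot > 0 else 0.0
    ll = ll - ll0
    ll[(e1 <= 0) | (e2 <= 0)] = -np.inf
    return ll


def _quadrant_stats(H, ba, bb, window):
    """Quadrant rates and log-likelihood gain of the four-quadrant split
    at (ba, bb) over a uniform rate, within the local window."""
    na, nb = H.shape
    alo, ahi = max(ba - window, 0), min(ba + window, na)
    blo, bhi = max(bb - window, 0), min(bb + window, nb)
    ca, cb = ba - alo, bb - blo
    sub = H[alo:ahi, blo:bhi]
    ma, mb = sub.shape
    n = np.array([
        sub[:ca, :cb].sum(), sub[:ca, cb:].sum(),
        sub[ca:, :cb].sum(), sub[ca:, cb:].sum(),
    ])
    area = np.array([
        ca * cb, ca * (mb - cb), (ma - ca) * cb, (ma - ca) * (mb - cb)
    ], dtype=float)
    ok = area > 0
    rates = np.zeros(4)
    rates[ok] = n[ok] / area[ok]
    tot = n.sum()
    if tot == 0:
        return rates, -np.inf
    ll = sum(
        ni * np.log(ni / ai) for ni, ai in zip(n[ok], area[ok]) if ni > 0
    )
    ll0 = tot * np.log(tot / (ma * mb))
    return rates, ll - ll0


def _change_point(m: np.ndarray, exposure: np.ndarray | None = None) -> int:
    """Two-segment constant-rate Poisson change point with optional per-bin
    exposure offsets; returns the split index (size of the left segment)."""
    n = len(m)
    e = np.ones(n) if exposure is None else np.asarray(exposure, dtype=float)
    cm = np.cumsum(m)
    ce = np.cumsum(e)
    tot, tote = cm[-1], ce[-1]
    s = np.arange(1, n)
    n1, e1 = cm[s - 1], ce[s - 1]
    n2, e2 = tot - n1, tote - e1

    def t(k, E):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = k * np.log(k / np.maximum(E, 1e-300))
        return np.where(k > 0, v, 0.0)

    ll = t(n1, e1) + t(n2, e2)
    ll[(e1 <= 0) | (e2 <= 0)] = -np.inf
    return int(s[np.argmax(ll)])


@dataclass
class DerivativeMap:
    """Ordered reference segments composing a derivative chromosome."""

    name: str
    segments: list  # (chrom, start, end, strand)
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for c, s, e, strand in self.segments:
            if e <= s:
                raise ValueError(f"empty segment on {c}")
            if strand not in ("+", "-"):
                raise ValueError("segment strand must be +/-")
        lens = np.array([e - s for _, s, e, _ in self.segments])
        self.offsets = np.concatenate([[0], np.cumsum(lens)])

    @property
    def length(self) -> int:
        return int(self.offsets[-1])

    def to_derivative(self, chrom: str, pos: int) -> int:
        for i, (c, s, e, strand) in enumerate(self.segments):
            if c == chrom and s <= pos < e:
                local = pos - s if strand == "+" else e - 1 - pos
                return int(self.offsets[i] + local)
        raise ValueError(f"{chrom}:{pos} not on derivative {self.name}")

    def from_derivative(self, dpos: int) -> tuple[str, int]:
        if not 0 <= dpos < self.length:
            raise ValueError(f"position {dpos} outside derivative")
        i = int(np.searchsorted(self.offsets, dpos, side="right")) - 1
        c, s, e, strand = self.segments[i]
        local = dpos - self.offsets[i]
        return c, int(s + local if strand == "+" else e - 1 - local)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.segments, columns=["chrom", "start", "end", "strand"]
        ).to_csv(path, sep="\t", index=False)


def reconstruct_derivative(bp_a: Breakpoint, bp_b: Breakpoint,
                           fmap: FragmentMap) -> DerivativeMap:
    """Join the kept segments of the two partner chromosomes.

    Each breakpoint's ``orientation`` names the side kept on this
    derivative.  A left/left or right/right join reverses the second
    segment (inversion-type junction).
    """
    la = fmap.chrom_sizes[bp_a.chrom]
    lb = fmap.chrom_sizes[bp_b.chrom]
    seg_a = (
        (bp_a.chrom, 0, bp_a.position, "+")
        if bp_a.orientation == "left"
        else (bp_a.chrom, bp_a.position, la, "+")
    )
    seg_b = (
        (bp_b.chrom, bp_b.position, lb, "+")
        if bp_b.orientation == "right"
        else (bp_b.chrom, 0, bp_b.position, "+")
    )
    segments = [seg_a, seg_b]
    # keep the junction adjacent: a kept-left A segment must be followed by
    # B starting at its junction edge; flip B when both kept sides face away
    if bp_a.orientation == "left" and bp_b.orientation == "left":
        segments = [seg_a, (seg_b[0], seg_b[1], seg_b[2], "-")]
    if bp_a.orientation == "right" and bp_b.orientation == "right":
        segments = [(seg_b[0], seg_b[1], seg_b[2], "-"), seg_a]
    if bp_a.orientation == "right" and bp_b.orientation == "left":
        segments = [seg_b, seg_a]
    name = f"der({bp_a.chrom};{bp_b.chrom})"
    return DerivativeMap(name, segments)


def remap_interactions(calls: pd.DataFrame, fmap: FragmentMap,
                       der: DerivativeMap) -> pd.DataFrame:
    """Re-project interaction calls onto a derivative chromosome.

    Junction-spanning trans contacts become cis on the derivative with
    distance equal to the sum of the two ends' distances to the junction.
    Calls with an end outside the derivative are dropped.
    """
    rows = []
    for row in calls.itertuples():
        cb, sb_, _ = fmap.fragment(int(row.bait_id))
        co, so, _ = fmap.fragment(int(row.otherend_id))
        try:
            d1 = der.to_derivative(cb, sb_)
            d2 = der.to_derivative(co, so)
        except ValueError:
            continue
        rows.append((row.bait_id, row.otherend_id, d1, d2, abs(d2 - d1),
                     row.N, row.score))
    return pd.DataFrame(
        rows,
        columns=["bait_id", "otherend_id", "der_pos1", "der_pos2",
                 "der_dist", "N", "score"],
    )


@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    call: str  # gain | loss
    n_windows: int

    def __post_init__(self) -> None:
        if self.call not in ("gain", "loss"):
            raise ValueError("call must be gain or loss")


def _end_coverage(pairs: pd.DataFrame, chrom_sizes: dict[str, int],
                  window: int) -> dict[str, np.ndarray]:
    cov = {}
    for c, L in chrom_sizes.items():
        n = -(-L // window)
        h = np.zeros(n)
        for pc, pp in (("chrom1", "pos1"), ("chrom2", "pos2")):
            m = pairs[pc] == c
            np.add.at(h, pairs.loc[m, pp].to_numpy() // window, 1.0)
        cov[c] = h
    return cov


def detect_cnv(
    case_pairs: pd.DataFrame,
    control_pairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window: int = 200_000,
    min_len: int = 3,
    threshold: float = 0.3,
    pseudocount: float = 1.0,
    cis_only: bool = True,
) -> tuple[list[CNVSegment], pd.DataFrame]:
    """Call copy-number segments from case/control end-coverage ratios.

    By default only cis pair ends are counted: a trans ligation scales
    with the dosage of *both* endpoints, which dilutes the copy-ratio
    signal, whereas cis coverage tracks the local copy number directly.

    Per window, log2((case + eps) / (control + eps)) of library-size
    normalized read-end coverage; segments are maximal runs of at least
    ``min_len`` windows beyond +/- ``threshold``.  Ratios are centered on
    their genome-wide median so that the diploid baseline sits at zero
    even when large aberrations shift the library totals.  Returns the
    segments and the per-window ratio table.
    """
    if cis_only:
        case_pairs = case_pairs[case_pairs["chrom1"] == case_pairs["chrom2"]]
        control_pairs = control_pairs[
            control_pairs["chrom1"] == control_pairs["chrom2"]
        ]
    cov_case = _end_coverage(case_pairs, chrom_sizes, window)
    cov_ctrl = _end_coverage(control_pairs, chrom_sizes, window)
    tot_case = sum(v.sum() for v in cov_case.values())
    tot_ctrl = sum(v.sum() for v in cov_ctrl.values())
    if tot_ctrl == 0:
        raise ValueError("control sample has zero coverage")
    tables = []
    for c in chrom_sizes:
        a = cov_case[c] / (tot_case * 1e-6)
        b = cov_ctrl[c] / (tot_ctrl * 1e-6)
        eps_a = pseudocount / (tot_case * 1e-6)
        eps_b = pseudocount / (tot_ctrl * 1e-6)
        ratio = np.log2((a + eps_a) / (b + eps_b))
        tables.append(pd.DataFrame({
            "chrom": c,
            "start": np.arange(len(ratio)) * window,
            "end": np.minimum((np.arange(len(ratio)) + 1) * window,
                               chrom_sizes[c]),
            "log2_ratio": ratio,
        }))
    table = pd.concat(tables, ignore_index=True)
    table["log2_ratio"] -= table["log2_ratio"].median()
    segments = []
    for c in chrom_sizes:
        ratio = table.loc[table["chrom"] == c, "log2_ratio"].to_numpy()
        state = np.where(ratio > threshold, 1, np.where(ratio < -threshold, -1, 0))
        i = 0
        while i < len(state):
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j < len(state) and state[j] == state[i]:
                j += 1
            if j - i >= min_len:
                segments.append(CNVSegment(
                    chrom=c,
                    start=i * window,
                    end=min(j * window, chrom_sizes[c]),
                    mean_log2=float(ratio[i:j].mean()),
                    call="gain" if state[i] > 0 else "loss",
                    n_windows=j - i,
                ))
            i = j
    return segments, table
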