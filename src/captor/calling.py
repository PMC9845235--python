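"""Fragment-resolution interaction calling against a two-component background.

The background expected count for a bait-other-end fragment pair combines
a *biological* component — a monotone-decreasing function f(d) of genomic
distance, scaled by per-bait and per-other-end activity factors — and a
*technical* component estimated from trans (inter-chromosomal) contacts,
which measures distance-independent ligation noise:

    mu(b, e, d) = f(d) * s_b * o_e + lambda_tech

Observed counts are tested against a negative-binomial upper tail at this
mean (dispersion pooled by method of moments, falling back to Poisson when
no overdispersion is detected).  P-values are reweighted by a decreasing
function of distance w(d) — long-range contacts are sparse, so an
unweighted genome-wide test would be dominated by them — and the final
score is -log(weighted p), floored at zero.  Scores at or above 5 mark
high-confidence interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson
from sklearn.isotonic import IsotonicRegression

from .digest import BaitMap, FragmentMap

__all__ = [
    "BackgroundModel",
    "fit_background",
    "call_interactions",
    "counts_from_pairs",
    "merge_replicates",
    "write_ibed",
    "write_washu",
]

SCORE_THRESHOLD = 5.0


def counts_from_pairs(captured: pd.DataFrame, fmap: FragmentMap,
                      baitmap: BaitMap) -> pd.DataFrame:
    """Aggregate captured valid pairs into per-fragment-pair counts.

    Each pair is keyed (bait_frag, other_frag); bait-to-bait pairs appear
    once from each bait's perspective.  Distance is the fragment midpoint
    distance (NaN for trans).
    """
    f1 = captured["frag1"].to_numpy()
    f2 = captured["frag2"].to_numpy()
    b1 = baitmap.is_bait(f1)
    b2 = baitmap.is_bait(f2)
    bait = np.concatenate([f1[b1], f2[b2]])
    other = np.concatenate([f2[b1], f1[b2]])
    df = pd.DataFrame({"bait_id": bait, "otherend_id": other})
    # drop self-views of bait-to-bait pairs seen from the same side twice
    df = df[df["bait_id"] != df["otherend_id"]]
    counts = (
        df.groupby(["bait_id", "otherend_id"]).size().rename("N").reset_index()
    )
    same_chrom = fmap.chrom_index(counts["bait_id"].to_numpy()) == fmap.chrom_index(
        counts["otherend_id"].to_numpy()
    )
    mid_b = fmap.midpoint_of(counts["bait_id"].to_numpy())
    mid_o = fmap.midpoint_of(counts["otherend_id"].to_numpy())
    counts["dist"] = np.where(same_chrom, np.abs(mid_b - mid_o), np.nan)
    counts["bait2bait"] = baitmap.is_bait(counts["otherend_id"].to_numpy())
    return counts


@dataclass
class BackgroundModel:
    """Fitted two-component background for one library."""

    bin_edges: np.ndarray          # geometric distance-bin edges
    f_bin: np.ndarray              # isotonic expected count per possible pair
    s_b: "pd.Series"               # per-bait scaling factor
    o_e: "pd.Series"               # per-other-end scaling factor
    lambda_tech: float             # technical (trans) expected count
    r: float                       # NB dispersion (inf => Poisson)
    w_d_mid: float                 # weight-function midpoint (bp)
    w_k: float                     # weight-function shape
    max_dist: float                # largest modeled cis distance
    len_prior: "pd.Series | None" = None  # fragment length / mean length

    def f(self, dist) -> np.ndarray:
        """Monotone non-increasing expected count at distance(s) ``dist``."""
        dist = np.asarray(dist, dtype=float)
        mids = np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])
        return np.interp(dist, mids, self.f_bin)

    def weight(self, dist) -> np.ndarray:
        """Distance weight w(d) in (0, 1], logistic in log distance."""
        dist = np.asarray(dist, dtype=float)
        return 1.0 / (1.0 + (np.maximum(dist, 1.0) / self.w_d_mid) ** self.w_k)

    def scale(self, bait_id, otherend_id) -> np.ndarray:
        """Combined activity factor; fragments unseen in the cis fit fall
        back to their fragment-length prior (capture activity scales with
        fragment size)."""
        bait_id = np.asarray(bait_id)
        otherend_id = np.asarray(otherend_id)
        if self.len_prior is not None:
            fb = self.len_prior.reindex(bait_id).fillna(1.0).to_numpy()
            fe = self.len_prior.reindex(otherend_id).fillna(1.0).to_numpy()
        else:
            fb = fe = 1.0
        s = self.s_b.reindex(bait_id).to_numpy()
        s = np.where(np.isnan(s), fb, s)
        o = self.o_e.reindex(otherend_id).to_numpy()
        o = np.where(np.isnan(o), fe, o)
        return s * o

    def expected(self, bait_id, otherend_id, dist) -> np.ndarray:
        """mu = (f(d) + lambda_tech) * s_b * o_e for cis pairs; trans pairs
        use lambda_tech alone, scaled by the same per-fragment activity."""
        dist = np.asarray(dist, dtype=float)
        sc = self.scale(bait_id, otherend_id)
        base = np.where(np.isfinite(dist), self.f(dist), 0.0)
        return (base + self.lambda_tech) * sc


def _possible_pairs_per_bin(fmap: FragmentMap, baitmap: BaitMap,
                            edges: np.ndarray) -> np.ndarray:
    """Number of bait x fragment pairs whose midpoint distance falls per bin."""
    out = np.zeros(len(edges) - 1)
    bait_ids = baitmap.fragment_ids
    ci = fmap.chrom_index(bait_ids)
    for k, c in enumerate(fmap.chroms):
        mids = np.sort(fmap.midpoints(c))
        bm = fmap.midpoint_of(bait_ids[ci == k])
        for m in bm:
            right = np.searchsorted(mids, m + edges)
            left = np.searchsorted(mids, m - edges)
            out += (right[1:] - right[:-1]) + (left[:-1] - left[1:])
    return out


def fit_background(
    counts: pd.DataFrame,
    fmap: FragmentMap,
    baitmap: BaitMap,
    n_bins: int = 20,
    d_min: float = 1_000.0,
    s_window: float = 1_500_000.0,
    s_range: tuple[float, float] = (0.1, 10.0),
    shrink: float = 5.0,
    w_min: float = 0.01,
) -> BackgroundModel:
    """Fit the two-component background model from fragment-pair counts.

    f(d) is the mean count per *possible* bait-other-end pair in geometric
    distance bins, made monotone non-increasing by isotonic regression.
    Bait factors s_b compare each bait's observed cis total within
    ``s_window`` to its expectation under f (truncated to ``s_range`` and
    renormalized to mean 1); other-end factors o_e are estimated
    symmetrically with shrinkage toward 1 (they rest on few observations).
    lambda_tech is the mean trans count per possible bait x trans-fragment
    pair; the NB dispersion r comes from pooled method of moments on
    counts stratified by expected mean.
    """
    cis = counts[np.isfinite(counts["dist"])]
    if len(cis) < 1000:
        raise ValueError(
            f"insufficient data: {len(cis)} cis fragment-pair counts < 1000"
        )
    d = cis["dist"].to_numpy()
    d_lo = max(d_min, d.min() * 0.999)
    d_hi = d.max() * 1.001
    edges = np.geomspace(d_lo, d_hi, n_bins + 1)
    which = np.digitize(d, edges) - 1
    occupied = np.unique(which[(which >= 0) & (which < n_bins)])
    if len(occupied) < 10:
        raise ValueError(
            f"insufficient data: cis counts span {len(occupied)} distance bins < 10"
        )

    possible = _possible_pairs_per_bin(fmap, baitmap, edges)
    obs_per_bin = np.bincount(
        which[(which >= 0) & (which < n_bins)],
        weights=cis["N"].to_numpy()[(which >= 0) & (which < n_bins)],
        minlength=n_bins,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_f = np.where(possible > 0, obs_per_bin / possible, np.nan)
    mids = np.sqrt(edges[:-1] * edges[1:])
    ok = np.isfinite(raw_f)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    f_bin = np.interp(
        np.log(mids), np.log(mids[ok]),
        iso.fit_transform(np.log(mids[ok]), raw_f[ok], sample_weight=possible[ok]),
    )

    model = BackgroundModel(
        bin_edges=edges, f_bin=f_bin,
        s_b=pd.Series(dtype=float), o_e=pd.Series(dtype=float),
        lambda_tech=0.0, r=np.inf,
        w_d_mid=d_hi / 10.0, w_k=np.log(1 / w_min - 1) / np.log(10.0),
        max_dist=d_hi,
    )

    # per-bait factors within s_window.  Fragment length is a strong known
    # covariate of capture activity, so the raw observed/expected ratio is
    # shrunk toward a length-proportional prior rather than toward 1.
    frag_len = pd.Series(
        np.concatenate([fmap.ends[c] - fmap.starts[c] for c in fmap.chroms]),
        index=np.arange(len(fmap)),
    ).astype(float)
    near = cis[cis["dist"] <= s_window]
    obs_b = near.groupby("bait_id")["N"].sum()
    exp_b = _expected_cis_total(fmap, baitmap, model, s_window)
    prior_b = frag_len.reindex(exp_b.index)
    prior_b /= prior_b.mean()
    obs_al = obs_b.reindex(exp_b.index).fillna(0.0)
    s = prior_b * (obs_al / prior_b + shrink) / (exp_b + shrink)
    s = s.clip(*s_range)
    s /= s.mean()
    model.s_b = s

    # per-other-end factors, symmetric, with the same length prior
    obs_e = cis.groupby("otherend_id")["N"].sum()
    exp_e = _expected_otherend_total(fmap, baitmap, model, obs_e.index.to_numpy())
    prior_e = frag_len.reindex(obs_e.index)
    prior_e /= prior_e.mean()
    o = prior_e * (obs_e / prior_e + shrink) / (exp_e + shrink)
    o = o.clip(*s_range)
    o /= o.mean()
    model.o_e = o
    model.len_prior = frag_len / frag_len.mean()

    # technical component from trans counts
    trans = counts[~np.isfinite(counts["dist"])]
    n_frag_per_chrom = np.array([fmap.n_fragments(c) for c in fmap.chroms])
    bait_ci = fmap.chrom_index(baitmap.fragment_ids)
    possible_trans = sum(
        int(n_frag_per_chrom[np.arange(len(n_frag_per_chrom)) != k].sum())
        * int((bait_ci == k).sum())
        for k in range(len(n_frag_per_chrom))
    )
    model.lambda_tech = (
        float(trans["N"].sum()) / possible_trans if possible_trans else 0.0
    )

    # dispersion by pooled method of moments on mu-stratified counts,
    # including the unobserved (zero-count) pairs in each stratum
    mu_obs = model.expected(
        cis["bait_id"].to_numpy(), cis["otherend_id"].to_numpy(), d
    )
    n_possible = possible.sum()
    n_zero = max(n_possible - len(cis), 0)
    mu_all_mean = (mu_obs.sum() + n_zero * np.median(mu_obs)) / max(n_possible, 1)
    # moment matching on observed strata only (zeros enter through f itself)
    strata = np.digitize(mu_obs, np.quantile(mu_obs, np.linspace(0, 1, 6)[1:-1]))
    num = 0.0
    den = 0.0
    for sidx in np.unique(strata):
        m = strata == sidx
        if m.sum() < 20:
            continue
        x = cis["N"].to_numpy()[m]
        mu = mu_obs[m]
        # Var(N) = E Var(N|mu) + Var(mu_hat); use residual moments vs model mu
        resid_var = np.mean((x - mu) ** 2)
        num += np.mean(mu**2) * m.sum()
        den += (resid_var - np.mean(mu)) * m.sum()
    if den > 0:
        model.r = max(num / den, 1e-2)
    else:
        model.r = np.inf  # no overdispersion: Poisson
    return model


def _expected_cis_total(fmap: FragmentMap, baitmap: BaitMap,
                        model: BackgroundModel, window: float) -> pd.Series:
    """Per-bait expected cis count total within ``window`` under f(d)."""
    edges = model.bin_edges[model.bin_edges <= window]
    if len(edges) < 2 or edges[-1] < window:
        edges = np.append(edges, window)
    mids = np.sqrt(edges[:-1] * edges[1:])
    fvals = model.f(mids)
    bait_ids = baitmap.fragment_ids
    ci = fmap.chrom_index(bait_ids)
    out = np.zeros(len(bait_ids))
    for k, c in enumerate(fmap.chroms):
        mids_c = np.sort(fmap.midpoints(c))
        sel = np.where(ci == k)[0]
        for idx in sel:
            m = fmap.midpoint_of(np.array([bait_ids[idx]]))[0]
            right = np.searchsorted(mids_c, m + edges)
            left = np.searchsorted(mids_c, m - edges)
            npairs = (right[1:] - right[:-1]) + (left[:-1] - left[1:])
            out[idx] = float((npairs * fvals).sum())
    return pd.Series(out, index=bait_ids)


def _expected_otherend_total(fmap: FragmentMap, baitmap: BaitMap,
                             model: BackgroundModel,
                             otherend_ids: np.ndarray) -> pd.Series:
    """Expected cis total per other end, summed over baits under f and s_b."""
    bait_ids = baitmap.fragment_ids
    bait_mid = fmap.midpoint_of(bait_ids)
    bait_ci = fmap.chrom_index(bait_ids)
    s = model.s_b.reindex(bait_ids).fillna(1.0).to_numpy()
    oe_mid = fmap.midpoint_of(otherend_ids)
    oe_ci = fmap.chrom_index(otherend_ids)
    out = np.zeros(len(otherend_ids))
    for k in np.unique(oe_ci):
        bm = bait_mid[bait_ci == k]
        bs = s[bait_ci == k]
        om = oe_mid[oe_ci == k]
        if len(bm) == 0 or len(om) == 0:
            continue
        dist = np.abs(om[:, None] - bm[None, :])
        fv = model.f(dist.ravel()).reshape(dist.shape)
        fv[dist > model.max_dist] = 0.0
        out[oe_ci == k] = (fv * bs[None, :]).sum(axis=1)
    return pd.Series(out, index=otherend_ids)


def call_interactions(
    counts: pd.DataFrame,
    model: BackgroundModel,
    score_threshold: float = SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Score fragment-pair counts against the fitted background.

    Returns the counts table with ``mu``, ``p``, ``score`` and
    ``significant`` columns.  p is the NB (or Poisson) upper-tail
    P(X >= N) at mu; the weighted p is min(1, p / w(d)); score is
    -log(weighted p), floored at 0.  Trans pairs use mu = lambda_tech and
    the maximum-distance weight.
    """
    out = counts.copy()
    d = out["dist"].to_numpy(dtype=float)
    mu = model.expected(out["bait_id"].to_numpy(), out["otherend_id"].to_numpy(), d)
    n_obs = out["N"].to_numpy()
    bad = (mu <= 0) & (n_obs > 0)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} pairs with zero expected count; clamped to machine-min"
        )
        mu = np.maximum(mu, np.finfo(float).tiny)
    if np.isfinite(model.r):
        pr = model.r / (model.r + mu)
        p = nbinom.sf(n_obs - 1, model.r, pr)
    else:
        p = poisson.sf(n_obs - 1, mu)
    p = np.clip(p, 1e-320, 1.0)
    w = np.where(np.isfinite(d), model.weight(d), model.weight(model.max_dist))
    wp = np.minimum(1.0, p / w)
    out["mu"] = mu
    out["p"] = p
    out["score"] = np.maximum(0.0, -np.log(wp))
    out["significant"] = out["score"] >= score_threshold
    return out


def merge_replicates(
    count_tables: list[pd.DataFrame],
    matrices=None,
    min_scc: float = 0.75,
    force: bool = False,
) -> pd.DataFrame:
    """Sum fragment-pair counts across replicate libraries.

    If binned matrices are supplied, all pairwise stratum-adjusted
    correlations must reach ``min_scc`` (default 0.75 at 100 kb) unless
    ``force`` is set; offending pairings are listed in the error.
    """
    from .matrix import scc as _scc

    if matrices is not None and len(matrices) > 1:
        bad = []
        for i in range(len(matrices)):
            for j in range(i + 1, len(matrices)):
                v = _scc(matrices[i], matrices[j]).genome
                if v < min_scc:
                    bad.append((i, j, v))
        if bad and not force:
            raise ValueError(
                "replicates below reproducibility threshold "
                + ", ".join(f"({i},{j}): SCC={v:.3f}" for i, j, v in bad)
            )
    merged = pd.concat(count_tables, ignore_index=True)
    keys = ["bait_id", "otherend_id"]
    agg = {"N": "sum", "dist": "first"}
    if "bait2bait" in merged:
        agg["bait2bait"] = "first"
    return merged.groupby(keys, as_index=False).agg(agg)


def write_ibed(calls: pd.DataFrame, fmap: FragmentMap, baitmap: BaitMap,
               path, significant_only: bool = True) -> None:
    """Write calls in ibed layout (bait locus, other-end locus, N, score)."""
    df = calls[calls["significant"]] if significant_only else calls
    with open(path, "w") as fh:
        fh.write("bait_chr\tbait_start\tbait_end\tbait_name\t"
                 "otherEnd_chr\totherEnd_start\totherEnd_end\tN_reads\tscore\n")
        for row in df.itertuples():
            bc, bs, be = fmap.fragment(int(row.bait_id))
            oc, os_, oe_ = fmap.fragment(int(row.otherend_id))
            name = baitmap.annotations.get(int(row.bait_id), ".")
            fh.write(f"{bc}\t{bs}\t{be}\t{name}\t{oc}\t{os_}\t{oe_}\t"
                     f"{int(row.N)}\t{row.score:.3f}\n")


def write_washu(calls: pd.DataFrame, fmap: FragmentMap, path,
                significant_only: bool = True) -> None:
    """Write calls as washU long-range text (chr:start-end<TAB>chr:start-end<TAB>score)."""
    df = calls[calls["significant"]] if significant_only else calls
    with open(path, "w") as fh:
        for row in df.itertuples():
            bc, bs, be = fmap.fragment(int(row.bait_id))
            oc, os_, oe_ = fmap.fragment(int(row.otherend_id))
            fh.write(f"{bc}:{bs}-{be}\t{oc}:{os_}-{oe_}\t{row.score:.3f}\n")
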