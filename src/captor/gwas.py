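"""GWAS integration: preprocessing, fine-mapping posteriors, Blockshifter
enrichment at promoter-interacting regions, and COGS gene prioritization.

The chain is: filter and impute summary statistics; partition the genome
into 1-cM recombination regions; convert per-SNP statistics into
approximate posterior probabilities of causality (Wakefield approximate
Bayes factors under a single-causal-variant-per-region model); test
whether that posterior mass concentrates in the promoter-interacting
regions (PIRs) of one tissue group versus another with a competitive,
LD-block-preserving rotation null (Blockshifter); and accumulate the
posterior mass falling in each gene's coding, promoter and PIR SNP sets
into a per-gene causality score (COGS), combining regions as
1 - prod(1 - region score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "define_ld_regions",
    "preprocess_gwas",
    "snp_posteriors",
    "blockshifter",
    "BlockshifterResult",
    "cogs_scores",
    "distance_summary",
]

GWS_P = 5e-8  # genome-wide significance
MHC_REGION = ("6", 25_000_000, 35_000_000)


def define_ld_regions(genetic_map: pd.DataFrame, width_cm: float = 1.0
                      ) -> pd.DataFrame:
    """Cut the mapped genome into regions of ``width_cm`` centimorgans.

    ``genetic_map`` has columns chrom, pos, cM (monotone within chrom).
    Returns a DataFrame (chrom, start, end, region_id) tiling each
    chromosome's mapped extent.
    """
    rows = []
    rid = 0
    for chrom, sub in genetic_map.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"genetic map not monotone on chromosome {chrom}")
        lo, hi = cm[0], cm[-1]
        cuts_cm = np.arange(lo, hi, width_cm)[1:]
        cuts = np.interp(cuts_cm, cm, pos)
        bounds = np.concatenate([[pos[0]], cuts, [pos[-1]]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e > s:
                rows.append((chrom, int(s), int(np.ceil(e)), rid))
                rid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])


def assign_regions(snps: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Region id per SNP (NaN outside the mapped genome)."""
    out = np.full(len(snps), np.nan)
    for chrom, sub in regions.groupby("chrom", sort=False):
        m = (snps["chrom"].astype(str) == str(chrom)).to_numpy()
        if not m.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["region_id"].to_numpy()
        idx = np.searchsorted(starts, snps.loc[m, "pos"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (snps.loc[m, "pos"].to_numpy() < ends[np.clip(idx, 0, None)])
        vals = np.full(m.sum(), np.nan)
        vals[ok] = ids[idx[ok]]
        out[m] = vals
    return pd.Series(out, index=snps.index)


def preprocess_gwas(
    records: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    regions: pd.DataFrame | None = None,
    genetic_map: pd.DataFrame | None = None,
    reference_snps: pd.DataFrame | None = None,
    mhc: tuple | None = MHC_REGION,
    r2_support: float = 0.6,
    support_window: int = 50_000,
    support_p: float = 1e-5,
) -> pd.DataFrame:
    """Filter and impute GWAS summary statistics.

    Steps: (i) drop genome-wide-significant SNPs (p < 5e-8) with no
    support — no LD partner at r² > 0.6 and no neighbor within 50 kb at
    p < 1e-5; (ii) exclude the MHC interval; (iii) poor-man's imputation:
    each untyped reference SNP inherits the p-value of its best typed
    proxy at r² >= 0.6 in the same 1-cM region, flagged ``imputed``.

    ``ld`` is a pairwise table (snp1, snp2, r2); ``reference_snps`` has
    columns snp, chrom, pos for the untyped panel.
    """
    if regions is None:
        if genetic_map is None:
            raise ValueError("need LD regions or a genetic map to define them")
        regions = define_ld_regions(genetic_map)
    df = records.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["imputed"] = False

    # (i) support filter for genome-wide significant SNPs
    partners: dict[str, float] = {}
    if ld is not None and len(ld):
        best1 = ld.groupby("snp1")["r2"].max()
        best2 = ld.groupby("snp2")["r2"].max()
        partners = pd.concat([best1, best2]).groupby(level=0).max().to_dict()
    drop = np.zeros(len(df), dtype=bool)
    sig = df["p"].to_numpy() < GWS_P
    if sig.any():
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            order = np.argsort(pos)
            pos_s = pos[order]
            p_s = sub["p"].to_numpy()[order]
            for i in np.where(sub["p"].to_numpy() < GWS_P)[0]:
                snp = sub["snp"].iloc[i]
                if partners.get(snp, 0.0) > r2_support:
                    continue
                lo = np.searchsorted(pos_s, pos[i] - support_window, side="left")
                hi = np.searchsorted(pos_s, pos[i] + support_window, side="right")
                neigh = p_s[lo:hi]
                npos = pos_s[lo:hi]
                if ((neigh < support_p) & (npos != pos[i])).any():
                    continue
                drop[df.index.get_loc(sub.index[i])] = True
    df = df[~drop]

    # (ii) MHC exclusion
    if mhc is not None:
        c, s, e = mhc
        df = df[~((df["chrom"] == str(c)) & (df["pos"] >= s) & (df["pos"] < e))]

    # (iii) poor-man's imputation
    if reference_snps is not None and ld is not None and len(ld):
        typed = set(df["snp"])
        untyped = reference_snps[~reference_snps["snp"].isin(typed)]
        pairs = pd.concat([
            ld.rename(columns={"snp1": "target", "snp2": "proxy"}),
            ld.rename(columns={"snp2": "target", "snp1": "proxy"}),
        ])
        pairs = pairs[
            pairs["target"].isin(untyped["snp"]) & pairs["proxy"].isin(typed)
            & (pairs["r2"] >= r2_support)
        ]
        if len(pairs):
            best = pairs.sort_values("r2", ascending=False).drop_duplicates("target")
            proxy_stats = df.set_index("snp")
            reg_u = assign_regions(untyped.set_index("snp"), regions)
            reg_t = assign_regions(
                df.set_index("snp")[["chrom", "pos"]].assign(), regions
            )
            rows = []
            for t, proxy, r2 in best[["target", "proxy", "r2"]].itertuples(index=False):
                if reg_u.get(t) != reg_t.get(proxy) or np.isnan(reg_u.get(t, np.nan)):
                    continue
                u = untyped.set_index("snp").loc[t]
                rows.append({
                    "snp": t, "chrom": str(u["chrom"]), "pos": int(u["pos"]),
                    "p": float(proxy_stats.loc[proxy, "p"]), "imputed": True,
                })
            if rows:
                df = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    return df.reset_index(drop=True)


def snp_posteriors(
    records: pd.DataFrame,
    regions: pd.DataFrame,
    W: float = 0.04,
    null_weight: float = 1.0,
) -> pd.DataFrame:
    """Per-SNP posterior probability of causality within its 1-cM region.

    Wakefield approximate Bayes factors with prior effect variance ``W``
    under a single causal variant per region; ppi_i = ABF_i /
    (sum_j ABF_j + null_weight), so posteriors sum to <= 1 per region and
    the remainder is the no-causal-variant share.

    Requires (beta, se) or (p, maf, n) to reconstruct the z-score and its
    standard error; SNPs with neither are skipped with a warning.
    """
    df = records.copy()
    df["region_id"] = assign_regions(df, regions)
    have_beta = ("beta" in df) and ("se" in df)
    if have_beta and df[["beta", "se"]].notna().all(axis=None):
        z = df["beta"].to_numpy() / df["se"].to_numpy()
        V = df["se"].to_numpy() ** 2
    elif {"p", "maf", "n"} <= set(df.columns):
        z = -norm.ppf(np.clip(df["p"].to_numpy() / 2, 1e-320, 1.0))
        maf = df["maf"].to_numpy()
        V = 1.0 / (df["n"].to_numpy() * 2 * maf * (1 - maf))
    else:
        raise ValueError("need (beta, se) or (p, maf, n) to compute Bayes factors")
    # log Wakefield ABF for H1 over H0
    r = W / (V + W)
    labf = 0.5 * (np.log(1 - r) + r * z**2)
    df["log_abf"] = labf
    out = []
    for rid, sub in df.groupby("region_id", sort=False):
        if np.isnan(rid):
            continue
        if len(sub) == 0:
            warnings.warn(f"region {rid} has no scorable SNPs")
            continue
        denom = logsumexp(np.append(sub["log_abf"].to_numpy(), np.log(null_weight)))
        ppi = np.exp(sub["log_abf"].to_numpy() - denom)
        out.append(pd.DataFrame({
            "snp": sub["snp"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "region_id": int(rid),
            "ppi": ppi,
        }))
    if not out:
        return pd.DataFrame(columns=["snp", "chrom", "pos", "region_id", "ppi"])
    return pd.concat(out, ignore_index=True)


def _in_intervals(snps: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean: SNP position falls inside any interval (chrom, start, end)."""
    hit = np.zeros(len(snps), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    for chrom, sub in intervals.groupby("chrom", sort=False):
        m = (snps["chrom"].astype(str) == str(chrom)).to_numpy()
        if not m.any():
            continue
        iv = sub.sort_values("start")
        starts = iv["start"].to_numpy()
        ends = np.maximum.accumulate(iv["end"].to_numpy())
        pos = snps.loc[m, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hit[m] = ok
    return hit


@dataclass
class BlockshifterResult:
    statistic: float
    null_mean: float
    null_sd: float
    z: float
    n_rotations: int
    n_snps_group1: int
    n_snps_group2: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.z):
            raise ValueError("non-finite Blockshifter z")


def blockshifter(
    scores: pd.DataFrame,
    pirs_group1: pd.DataFrame,
    pirs_group2: pd.DataFrame,
    regions: pd.DataFrame,
    n_rot: int = 1000,
    seed: int = 0,
) -> BlockshifterResult:
    """Competitive test of GWAS signal at group-1 vs group-2 exclusive PIRs.

    ``scores`` carries snp, chrom, pos and a ``ppi`` (or ``score``)
    column.  The statistic is the mean score of SNPs in group-1-exclusive
    PIRs minus the mean in group-2-exclusive PIRs.  The null preserves LD
    block structure: within each 1-cM region the PIR annotation vector is
    circularly rotated (SNPs ordered by position) by a random offset,
    jointly for both groups, ``n_rot`` times.
    """
    df = scores.copy()
    col = "ppi" if "ppi" in df else "score"
    df["region_id"] = assign_regions(df, regions)
    df = df[~df["region_id"].isna()].sort_values(["region_id", "pos"])
    in1 = _in_intervals(df, pirs_group1)
    in2 = _in_intervals(df, pirs_group2)
    s = df[col].to_numpy(dtype=float)

    def stat(a1, a2):
        e1 = a1 & ~a2
        e2 = a2 & ~a1
        if e1.sum() == 0 or e2.sum() == 0:
            return np.nan
        return s[e1].mean() - s[e2].mean()

    if not (in1 & ~in2).any() and not (in2 & ~in1).any():
        # identical annotations: nothing to compare, trivially no enrichment
        return BlockshifterResult(0.0, 0.0, 1.0, 0.0, 0, 0, 0)
    obs = stat(in1, in2)
    if np.isnan(obs):
        raise ValueError("a tissue group has no exclusive-PIR SNPs")

    rng = np.random.default_rng(seed)
    reg = df["region_id"].to_numpy()
    bounds = np.flatnonzero(np.r_[True, reg[1:] != reg[:-1], True])
    # per-rotation sums, accumulated region by region (vectorized over rotations)
    sum1 = np.zeros(n_rot)
    cnt1 = np.zeros(n_rot)
    sum2 = np.zeros(n_rot)
    cnt2 = np.zeros(n_rot)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        k = b1 - b0
        a1 = in1[b0:b1]
        a2 = in2[b0:b1]
        sr = s[b0:b1]
        if not (a1.any() or a2.any()):
            continue
        offs = rng.integers(0, k, size=n_rot)
        idx = (np.arange(k)[None, :] - offs[:, None]) % k
        r1 = a1[idx]
        r2 = a2[idx]
        e1 = r1 & ~r2
        e2 = r2 & ~r1
        sum1 += e1 @ sr
        cnt1 += e1.sum(axis=1)
        sum2 += e2 @ sr
        cnt2 += e2.sum(axis=1)
    ok = (cnt1 > 0) & (cnt2 > 0)
    null = sum1[ok] / cnt1[ok] - sum2[ok] / cnt2[ok]
    mu, sd = null.mean(), null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate rotation null (zero variance)")
    return BlockshifterResult(
        statistic=float(obs), null_mean=float(mu), null_sd=float(sd),
        z=float((obs - mu) / sd), n_rotations=int(ok.sum()),
        n_snps_group1=int((in1 & ~in2).sum()), n_snps_group2=int((in2 & ~in1).sum()),
    )


def cogs_scores(
    posteriors: pd.DataFrame,
    coding: pd.DataFrame | None = None,
    promoters: pd.DataFrame | None = None,
    pir_links: "pd.DataFrame | dict[str, pd.DataFrame] | None" = None,
    threshold: float = 0.5,
    mode: str = "union",
) -> pd.DataFrame:
    """COGS gene scores from SNP causality posteriors and gene annotations.

    Each annotation table carries (gene, chrom, start, end); ``pir_links``
    may be one table or a per-cell-type dict.  Per region, a gene's block
    score is the summed ppi of SNPs in the union of its coding, promoter
    and PIR intervals (no double counting); the overall score combines
    regions as 1 - prod(1 - block).  ``mode`` "union" pools PIR links
    across cell types before scoring; "max" scores each cell type
    separately and keeps the maximum.  Genes scoring >= ``threshold`` are
    flagged prioritized.
    """
    if isinstance(pir_links, dict):
        if mode == "max":
            parts = [
                cogs_scores(posteriors, coding, promoters, links, threshold, "union")
                .assign(cell_type=ct)
                for ct, links in pir_links.items()
            ]
            allscores = pd.concat(parts, ignore_index=True)
            idx = allscores.groupby("gene")["score"].idxmax()
            return allscores.loc[idx].reset_index(drop=True)
        pir_links = pd.concat(pir_links.values(), ignore_index=True)

    genes: dict[str, dict[str, pd.DataFrame]] = {}
    for name, table in (("coding", coding), ("promoter", promoters),
                        ("pir", pir_links)):
        if table is None or len(table) == 0:
            continue
        for gene, sub in table.groupby("gene", sort=False):
            genes.setdefault(gene, {})[name] = sub

    rows = []
    for gene, parts in genes.items():
        comp = {}
        union_hits = np.zeros(len(posteriors), dtype=bool)
        for name, sub in parts.items():
            hits = _in_intervals(posteriors, sub)
            comp[name] = float(posteriors.loc[hits, "ppi"].sum())
            union_hits |= hits
        hit_df = posteriors[union_hits]
        block = hit_df.groupby("region_id")["ppi"].sum().clip(upper=1.0)
        score = 1.0 - float(np.prod(1.0 - block.to_numpy()))
        rows.append({
            "gene": gene,
            "score": score,
            "coding_ppi": comp.get("coding", 0.0),
            "promoter_ppi": comp.get("promoter", 0.0),
            "pir_ppi": comp.get("pir", 0.0),
            "n_regions": int((block > 0).sum()),
            "prioritized": score >= threshold,
        })
    return (
        pd.DataFrame(rows, columns=["gene", "score", "coding_ppi", "promoter_ppi",
                                    "pir_ppi", "n_regions", "prioritized"])
        .sort_values("score", ascending=False)
        .reset_index(drop=True)
    )


def distance_summary(
    gene_scores: pd.DataFrame,
    snps: pd.DataFrame,
    tss: pd.DataFrame,
    pir_links: pd.DataFrame,
    p_threshold: float = GWS_P,
    score_threshold: float = 0.5,
) -> dict:
    """Distances between trait-associated SNPs and their COGS target genes.

    For each significant SNP lying in a PIR linked to at least one
    prioritized gene: the distance to the nearest TSS and to the
    prioritized gene's TSS, the fraction of SNPs whose prioritized gene is
    the nearest one, and the fraction linked to more than one gene.
    ``tss`` has columns (gene, chrom, pos).
    """
    prio = set(gene_scores.loc[gene_scores["score"] >= score_threshold, "gene"])
    if not prio:
        raise ValueError("no prioritized genes")
    sig = snps[snps["p"] < p_threshold]
    tss_by_chrom = {
        str(c): sub.sort_values("pos") for c, sub in tss.groupby("chrom", sort=False)
    }
    rows = []
    links = pir_links[pir_links["gene"].isin(prio)]
    for row in sig.itertuples():
        m = (links["chrom"].astype(str) == str(row.chrom)) & \
            (links["start"] <= row.pos) & (row.pos < links["end"])
        targets = sorted(set(links.loc[m, "gene"]))
        if not targets:
            continue
        sub = tss_by_chrom.get(str(row.chrom))
        if sub is None or len(sub) == 0:
            continue
        d_all = np.abs(sub["pos"].to_numpy() - row.pos)
        nearest_gene = sub["gene"].iloc[int(np.argmin(d_all))]
        d_nearest = float(d_all.min())
        d_prior = min(
            float(np.abs(sub.loc[sub["gene"] == g, "pos"].to_numpy() - row.pos).min())
            for g in targets
            if (sub["gene"] == g).any()
        )
        rows.append({
            "snp": row.snp,
            "d_nearest": d_nearest,
            "d_prioritized": d_prior,
            "nearest_is_target": nearest_gene in targets,
            "multi_gene": len(targets) > 1,
        })
    if not rows:
        raise ValueError("no significant SNPs in prioritized-gene PIRs")
    df = pd.DataFrame(rows)
    return {
        "per_snp": df,
        "median_d_nearest": float(df["d_nearest"].median()),
        "median_d_prioritized": float(df["d_prioritized"].median()),
        "frac_nearest": float(df["nearest_is_target"].mean()),
        "frac_multi_gene": float(df["multi_gene"].mean()),
    }
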