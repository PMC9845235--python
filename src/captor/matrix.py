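"""Binned contact matrices, normalization, ratio maps and reproducibility.

Contact matrices are stored genome-wide as a sparse upper-triangular
matrix over fixed-size bins (1 Mb / 250 kb / 100 kb are the conventional
resolutions).  Reproducibility between two libraries is measured with the
stratum-adjusted correlation coefficient (SCC): Pearson correlations are
computed separately within each genomic-distance stratum of the (optionally
mean-filter smoothed) cis matrices and combined with weights proportional
to the stratum size and the two stratum standard deviations, so that the
strong distance decay shared by any two Hi-C maps does not inflate the
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import uniform_filter

__all__ = ["BinnedMatrix", "SCCResult", "bin_pairs", "ratio_matrix", "scc"]


class BinnedMatrix:
    """Genome-wide symmetric contact matrix at fixed bin size.

    Only the upper triangle (bin_i <= bin_j) is stored.
    """

    def __init__(self, chrom_sizes: dict[str, int], resolution: int,
                 data: sp.spmatrix | None = None):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = int(resolution)
        self.chroms = list(chrom_sizes)
        self.chrom_sizes = dict(chrom_sizes)
        self.n_bins_per_chrom = {
            c: -(-chrom_sizes[c] // resolution) for c in self.chroms
        }
        offs = np.cumsum([0] + [self.n_bins_per_chrom[c] for c in self.chroms])
        self.bin_offset = {c: int(o) for c, o in zip(self.chroms, offs)}
        self.n_bins = int(offs[-1])
        if data is None:
            data = sp.csr_matrix((self.n_bins, self.n_bins))
        self.data = sp.triu(data).tocsr()

    # -- construction -------------------------------------------------
    @classmethod
    def from_pairs(cls, df: pd.DataFrame, chrom_sizes: dict[str, int],
                   resolution: int) -> "BinnedMatrix":
        m = cls(chrom_sizes, resolution)
        i = m.bin_index(df["chrom1"].to_numpy(), df["pos1"].to_numpy())
        j = m.bin_index(df["chrom2"].to_numpy(), df["pos2"].to_numpy())
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        m.data = sp.coo_matrix(
            (np.ones(len(df)), (lo, hi)), shape=(m.n_bins, m.n_bins)
        ).tocsr()
        return m

    def bin_index(self, chroms, pos) -> np.ndarray:
        chroms = np.asarray(chroms)
        pos = np.asarray(pos)
        out = np.empty(len(pos), dtype=np.int64)
        seen = np.zeros(len(pos), dtype=bool)
        for c in self.chroms:
            m = chroms == c
            if not m.any():
                continue
            p = pos[m]
            if p.size and (p.min() < 0 or p.max() >= self.chrom_sizes[c]):
                raise ValueError(f"position outside chromosome {c}")
            out[m] = p // self.resolution + self.bin_offset[c]
            seen |= m
        if not seen.all():
            raise ValueError("pair on chromosome absent from matrix")
        return out

    def bin_to_coord(self, b: int) -> tuple[str, int]:
        for c in reversed(self.chroms):
            if b >= self.bin_offset[c]:
                return c, (b - self.bin_offset[c]) * self.resolution
        raise ValueError(f"bin {b} out of range")

    # -- views ---------------------------------------------------------
    @property
    def total_count(self) -> float:
        return float(self.data.sum())

    def symmetric(self) -> sp.csr_matrix:
        u = self.data
        return u + sp.triu(u, k=1).T

    def cis_dense(self, chrom: str) -> np.ndarray:
        o, n = self.bin_offset[chrom], self.n_bins_per_chrom[chrom]
        sub = self.data[o : o + n, o : o + n].toarray()
        return sub + np.triu(sub, k=1).T

    def trans_dense(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        """Dense (bins_a x bins_b) trans block for an ordered chromosome pair."""
        oa, na = self.bin_offset[chrom_a], self.n_bins_per_chrom[chrom_a]
        ob, nb = self.bin_offset[chrom_b], self.n_bins_per_chrom[chrom_b]
        if oa <= ob:
            return self.data[oa : oa + na, ob : ob + nb].toarray()
        return self.data[ob : ob + nb, oa : oa + na].toarray().T

    def marginals(self) -> np.ndarray:
        s = self.symmetric()
        return np.asarray(s.sum(axis=1)).ravel() + self.data.diagonal()

    def coarsen(self, factor: int) -> "BinnedMatrix":
        """Re-bin to a coarser resolution (integer multiple)."""
        out = BinnedMatrix(self.chrom_sizes, self.resolution * factor)
        coo = self.data.tocoo()
        ci = self.chrom_of_bins(coo.row)
        cj = self.chrom_of_bins(coo.col)
        offs_old = np.array([self.bin_offset[c] for c in self.chroms])
        offs_new = np.array([out.bin_offset[c] for c in self.chroms])
        i = (coo.row - offs_old[ci]) // factor + offs_new[ci]
        j = (coo.col - offs_old[cj]) // factor + offs_new[cj]
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        out.data = sp.coo_matrix(
            (coo.data, (lo, hi)), shape=(out.n_bins, out.n_bins)
        ).tocsr()
        return out

    def chrom_of_bins(self, bins: np.ndarray) -> np.ndarray:
        offs = np.array([self.bin_offset[c] for c in self.chroms])
        return np.searchsorted(offs, np.asarray(bins), side="right") - 1

    def same_binning(self, other: "BinnedMatrix") -> bool:
        return (
            self.resolution == other.resolution
            and self.chroms == other.chroms
            and self.chrom_sizes == other.chrom_sizes
        )

    # -- normalization -------------------------------------------------
    def normalize(self, method: str = "library_size", tol: float = 1e-5,
                  max_iter: int = 200) -> "BinnedMatrix":
        if self.total_count == 0:
            raise ValueError("cannot normalize an all-zero matrix")
        out = BinnedMatrix(self.chrom_sizes, self.resolution)
        if method == "library_size":
            out.data = (self.data / (self.total_count * 1e-6)).tocsr()
        elif method == "iterative_balance":
            out.data = self._balance(tol, max_iter)
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        return out

    def _balance(self, tol: float, max_iter: int) -> sp.csr_matrix:
        # balance the full symmetric matrix so marginals are ~equal
        s = self.symmetric().toarray().astype(float)
        mask = s.sum(axis=1) > 0
        b = np.ones(self.n_bins)
        for _ in range(max_iter):
            marg = (s * b).sum(axis=1) * b
            m = marg[mask]
            target = m.mean()
            if m.std() / target < tol:
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                adj = np.where(marg > 0, np.sqrt(marg / target), 1.0)
            b /= adj
        balanced = s * np.outer(b, b)
        return sp.csr_matrix(np.triu(balanced))

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path) -> None:
        coo = self.data.tocoo()
        pd.DataFrame({"bin1": coo.row, "bin2": coo.col, "value": coo.data}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, chrom_sizes: dict[str, int], resolution: int
                 ) -> "BinnedMatrix":
        df = pd.read_csv(path, sep="\t")
        m = cls(chrom_sizes, resolution)
        m.data = sp.coo_matrix(
            (df["value"], (df["bin1"], df["bin2"])), shape=(m.n_bins, m.n_bins)
        ).tocsr()
        return m


def bin_pairs(df: pd.DataFrame, chrom_sizes: dict[str, int], resolution: int
              ) -> BinnedMatrix:
    """Bin a pairs DataFrame into a :class:`BinnedMatrix`."""
    return BinnedMatrix.from_pairs(df, chrom_sizes, resolution)


def ratio_matrix(case: BinnedMatrix, control: BinnedMatrix,
                 pseudocount: float = 1.0) -> np.ndarray:
    """Dense genome-wide log2 case/control ratio of library-size-normalized maps.

    ``pseudocount`` is expressed in raw counts of the case library and is
    scaled through the per-million normalization, avoiding log of zero.
    """
    if not case.same_binning(control):
        raise ValueError("case and control matrices are binned differently")
    eps_case = pseudocount / (case.total_count * 1e-6)
    eps_ctrl = pseudocount / (control.total_count * 1e-6)
    a = case.normalize("library_size").symmetric().toarray()
    b = control.normalize("library_size").symmetric().toarray()
    return np.log2((a + eps_case) / (b + eps_ctrl))


@dataclass
class SCCResult:
    """Stratum-adjusted correlation per chromosome and its genome average."""

    per_chrom: dict[str, float]
    genome: float
    resolution: int
    max_dist: int
    h: int
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [v for v in self.per_chrom.values() if np.isfinite(v)]
        if any(abs(v) > 1 + 1e-9 for v in vals):
            raise ValueError("SCC outside [-1, 1]")


def _smooth(m: np.ndarray, h: int) -> np.ndarray:
    if h <= 0:
        return m
    return uniform_filter(m, size=2 * h + 1, mode="constant")


def scc(a: BinnedMatrix, b: BinnedMatrix, max_dist: int = 5_000_000,
        h: int | None = None) -> SCCResult:
    """Stratum-adjusted correlation between two contact maps.

    Strata are cis diagonals k = 0..max_dist/resolution.  Matrices are
    smoothed with a (2h+1)^2 mean filter first (h defaults to 1 below 1 Mb
    resolution, else 0).  Stratum correlations are combined with weights
    N_k * sd_a,k * sd_b,k; chromosomes are averaged weighted by bin count.
    """
    if not a.same_binning(b):
        raise ValueError("matrices are binned differently")
    if h is None:
        h = 1 if a.resolution < 1_000_000 else 0
    kmax = max(1, max_dist // a.resolution)
    per_chrom: dict[str, float] = {}
    nbins: dict[str, float] = {}
    for c in a.chroms:
        da = _smooth(a.cis_dense(c), h)
        db = _smooth(b.cis_dense(c), h)
        n = da.shape[0]
        num = 0.0
        den = 0.0
        for k in range(0, min(kmax + 1, n)):
            va = np.diagonal(da, k)
            vb = np.diagonal(db, k)
            sa, sb_ = va.std(), vb.std()
            if sa == 0 or sb_ == 0 or len(va) < 2:
                continue
            rho = float(np.corrcoef(va, vb)[0, 1])
            w = len(va) * sa * sb_
            num += w * rho
            den += w
        if den > 0:
            per_chrom[c] = num / den
            nbins[c] = n
    if not per_chrom:
        raise ValueError("no informative strata shared by the two matrices")
    tot = sum(nbins.values())
    genome = sum(per_chrom[c] * nbins[c] for c in per_chrom) / tot
    return SCCResult(per_chrom, genome, a.resolution, max_dist, h, nbins)
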