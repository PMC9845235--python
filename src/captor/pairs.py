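"""Valid-pair QC: artifact classification, deduplication, capture filtering.

A mapped di-tag (read pair) represents one ligation event between two
restriction fragments.  Before interaction calling, pairs are classified
into experimental-artifact categories (re-ligation of the same or adjacent
fragments), PCR duplicates are removed, and pairs are restricted to those
with at least one captured (baited) end.  The resulting library statistics
(valid %, duplicate %, capture efficiency, trans fraction) summarize
library quality.

Pairs are held in a pandas DataFrame with columns
``read_id chrom1 pos1 strand1 chrom2 pos2 strand2`` plus, after fragment
assignment, ``frag1 frag2`` and after classification ``pair_class``.
Input/output uses the 4DN ``.pairs`` text format.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .digest import BaitMap, FragmentMap

__all__ = [
    "PairClass",
    "QCReport",
    "read_pairs",
    "write_pairs",
    "canonicalize",
    "assign_fragments",
    "classify_pairs",
    "classify_pair",
    "deduplicate",
    "capture_filter",
    "compute_qc",
    "run_qc",
]

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


class PairClass(str, Enum):
    VALID = "valid"
    SAME_FRAGMENT = "same_fragment"
    ADJACENT_RELIGATION = "adjacent_religation"
    DUPLICATE = "duplicate"
    UNCAPTURED = "uncaptured"


@dataclass
class QCReport:
    """Library-level QC summary; percentages are in [0, 100]."""

    total_pairs: int
    pct_valid: float
    pct_duplicates: float
    capture_efficiency: float
    pct_trans: float
    n_unique_valid: int
    n_captured: int

    def __post_init__(self) -> None:
        for f in ("pct_valid", "pct_duplicates", "capture_efficiency", "pct_trans"):
            v = getattr(self, f)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{f}={v} outside [0, 100]")
        if not self.n_captured <= self.n_unique_valid <= self.total_pairs:
            raise ValueError("inconsistent counts: captured <= unique valid <= total")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def to_tsv(self, path=None) -> str:
        d = asdict(self)
        s = "\t".join(d) + "\n" + "\t".join(str(v) for v in d.values()) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def read_pairs(path) -> pd.DataFrame:
    """Read a 4DN ``.pairs`` text file (header lines start with ``#``)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=PAIRS_COLUMNS,
        dtype={"chrom1": str, "chrom2": str},
    )
    return df


def write_pairs(df: pd.DataFrame, path, chrom_sizes: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
        if chrom_sizes:
            for c, n in chrom_sizes.items():
                fh.write(f"#chromsize: {c} {n}\n")
        df[PAIRS_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def canonicalize(df: pd.DataFrame, chrom_order: list[str]) -> pd.DataFrame:
    """Order each pair's ends by (chromosome rank, position)."""
    rank = {c: i for i, c in enumerate(chrom_order)}
    r1 = df["chrom1"].map(rank)
    r2 = df["chrom2"].map(rank)
    if r1.isna().any() or r2.isna().any():
        raise ValueError("pair chromosome not in chromosome order")
    swap = (r2 < r1) | ((r2 == r1) & (df["pos2"] < df["pos1"]))
    out = df.copy()
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        out.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return out


def assign_fragments(df: pd.DataFrame, fmap: FragmentMap) -> pd.DataFrame:
    out = df.copy()
    out["frag1"] = fmap.locate_many(df["chrom1"].to_numpy(), df["pos1"].to_numpy())
    out["frag2"] = fmap.locate_many(df["chrom2"].to_numpy(), df["pos2"].to_numpy())
    return out


def classify_pairs(df: pd.DataFrame, fmap: FragmentMap) -> pd.DataFrame:
    """Vectorized artifact classification on fragment-assigned pairs."""
    if "frag1" not in df or "frag2" not in df:
        raise ValueError("pairs must have fragment assignments; run assign_fragments")
    f1 = df["frag1"].to_numpy()
    f2 = df["frag2"].to_numpy()
    same_chrom = (df["chrom1"] == df["chrom2"]).to_numpy()
    cls = np.full(len(df), PairClass.VALID.value, dtype=object)
    cls[same_chrom & (np.abs(f1 - f2) == 1)] = PairClass.ADJACENT_RELIGATION.value
    cls[f1 == f2] = PairClass.SAME_FRAGMENT.value
    out = df.copy()
    out["pair_class"] = cls
    return out


def classify_pair(chrom1, frag1, chrom2, frag2) -> PairClass:
    """Classify a single di-tag from its fragment assignments."""
    if frag1 is None or frag2 is None:
        raise ValueError("both ends must be assigned to fragments")
    if frag1 == frag2:
        return PairClass.SAME_FRAGMENT
    if chrom1 == chrom2 and abs(frag1 - frag2) == 1:
        return PairClass.ADJACENT_RELIGATION
    return PairClass.VALID


_DUP_KEY = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def deduplicate(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse records sharing both ends and strands; keep first occurrence.

    Returns (unique records, number of duplicates removed).
    """
    keep = ~df.duplicated(subset=_DUP_KEY, keep="first")
    return df[keep].copy(), int((~keep).sum())


def capture_filter(
    df: pd.DataFrame, baitmap: BaitMap
) -> tuple[pd.DataFrame, float]:
    """Keep pairs with >=1 baited end; returns (kept, capture efficiency %).

    Bait-to-bait pairs are flagged in a ``bait2bait`` column.
    """
    if len(baitmap) == 0:
        raise ValueError("empty bait map")
    b1 = baitmap.is_bait(df["frag1"].to_numpy())
    b2 = baitmap.is_bait(df["frag2"].to_numpy())
    kept = df[b1 | b2].copy()
    kept["bait2bait"] = (b1 & b2)[b1 | b2]
    eff = 100.0 * len(kept) / len(df) if len(df) else 0.0
    return kept, eff


def compute_qc(
    total: int, n_dup: int, n_unique_valid: int, captured: pd.DataFrame
) -> QCReport:
    if total == 0:
        raise ValueError("zero input pairs")
    n_captured = len(captured)
    n_trans = int((captured["chrom1"] != captured["chrom2"]).sum()) if n_captured else 0
    return QCReport(
        total_pairs=total,
        pct_valid=100.0 * n_unique_valid / total,
        pct_duplicates=100.0 * n_dup / total,
        capture_efficiency=100.0 * n_captured / n_unique_valid if n_unique_valid else 0.0,
        pct_trans=100.0 * n_trans / n_captured if n_captured else 0.0,
        n_unique_valid=n_unique_valid,
        n_captured=n_captured,
    )


def run_qc(
    df: pd.DataFrame, fmap: FragmentMap, baitmap: BaitMap
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pipeline: canonicalize, classify, deduplicate, capture-filter.

    Returns the captured unique valid pairs plus the library QC report.
    Deduplication is applied among otherwise-valid pairs only (artifact
    classes are removed first, so a duplicated artifact counts as artifact).
    Capture efficiency uses the post-deduplication denominator.
    """
    df = canonicalize(df, fmap.chroms)
    df = assign_fragments(df, fmap)
    df = classify_pairs(df, fmap)
    valid = df[df["pair_class"] == PairClass.VALID.value]
    unique_valid, n_dup = deduplicate(valid)
    captured, _ = capture_filter(unique_valid, baitmap)
    report = compute_qc(len(df), n_dup, len(unique_valid), captured)
    return captured, report
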