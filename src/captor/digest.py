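"""In-silico restriction digestion and fragment/bait map handling.

Capture Hi-C works at restriction-fragment resolution: the genome is cut
in silico with the library enzyme and every downstream unit of analysis
(valid pair, interaction, breakpoint) is a fragment pair.  This module
produces and queries that coordinate backbone.

All coordinates are 0-based, half-open.  Files that use other conventions
are converted at their I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "RestrictionEnzyme",
    "FragmentMap",
    "BaitMap",
    "ENZYMES",
    "digest_genome",
    "expected_fragment_length",
    "read_fasta",
    "write_fasta",
]

_DNA = frozenset("ACGT")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by its recognition site and cut offset.

    ``cut_offset`` is the distance in bp from the start of the recognition
    site at which both strands are treated as cut for fragment bookkeeping
    (e.g. HindIII A^AGCTT has offset 1; MboI ^GATC has offset 0).
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.site or not set(self.site) <= _DNA:
            raise ValueError(
                f"recognition site must be a non-empty A/C/G/T string, got {self.site!r}"
            )
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut_offset must lie within the recognition site")
        # Sites are scanned on the forward strand only; demand palindromes so
        # this is lossless (both common capture Hi-C enzymes qualify).
        if self.site != _revcomp(self.site):
            raise ValueError(
                f"non-palindromic site {self.site!r}: forward-strand scanning "
                "would miss reverse-strand cuts"
            )


ENZYMES: dict[str, RestrictionEnzyme] = {
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
    "MboI": RestrictionEnzyme("MboI", "GATC", 0),
    "DpnII": RestrictionEnzyme("DpnII", "GATC", 0),
}


def get_enzyme(name_or_enzyme: "str | RestrictionEnzyme") -> RestrictionEnzyme:
    if isinstance(name_or_enzyme, RestrictionEnzyme):
        return name_or_enzyme
    try:
        return ENZYMES[name_or_enzyme]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name_or_enzyme!r}; known: {sorted(ENZYMES)}"
        ) from None


def expected_fragment_length(site_length: int) -> int:
    """Expected spacing of a fixed k-mer in i.i.d. uniform DNA: 4**k.

    For a six-cutter this is 4096 bp, the fragment-level resolution of a
    HindIII capture Hi-C library; for a four-cutter, 256 bp.
    """
    if site_length < 1:
        raise ValueError("site_length must be >= 1")
    return 4**site_length


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each chromosome.

    Fragment ids are integers, unique genome-wide and increasing along
    coordinates (chromosomes in insertion order).
    """

    chroms: list[str]
    chrom_sizes: dict[str, int]
    starts: dict[str, np.ndarray]  # per-chrom fragment start coords
    ends: dict[str, np.ndarray]
    id_offset: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        off = 0
        self.id_offset = {}
        for c in self.chroms:
            s, e = self.starts[c], self.ends[c]
            if len(s) == 0:
                raise ValueError(f"chromosome {c} has no fragments")
            if s[0] != 0 or e[-1] != self.chrom_sizes[c]:
                raise ValueError(f"fragments do not tile chromosome {c}")
            if np.any(s[1:] != e[:-1]) or np.any(e <= s):
                raise ValueError(f"fragment gaps/overlaps on chromosome {c}")
            self.id_offset[c] = off
            off += len(s)
        self._n = off

    def __len__(self) -> int:
        return self._n

    def n_fragments(self, chrom: str) -> int:
        return len(self.starts[chrom])

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment id containing ``pos`` (0-based), by binary search."""
        if chrom not in self.starts:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        i = int(np.searchsorted(self.starts[chrom], pos, side="right")) - 1
        return self.id_offset[chrom] + i

    def locate_many(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`locate` over parallel chrom/pos arrays."""
        out = np.empty(len(pos), dtype=np.int64)
        chroms = np.asarray(chroms)
        pos = np.asarray(pos)
        for c in np.unique(chroms):
            m = chroms == c
            p = pos[m]
            if p.size and (p.min() < 0 or p.max() >= self.chrom_sizes[c]):
                raise ValueError(f"position outside chromosome {c}")
            idx = np.searchsorted(self.starts[c], p, side="right") - 1
            out[m] = idx + self.id_offset[c]
        return out

    def fragment(self, fid: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a genome-wide fragment id."""
        c = self.chrom_of(fid)
        i = fid - self.id_offset[c]
        return c, int(self.starts[c][i]), int(self.ends[c][i])

    def chrom_of(self, fid: int) -> str:
        if not 0 <= fid < self._n:
            raise ValueError(f"fragment id {fid} out of range")
        for c in reversed(self.chroms):
            if fid >= self.id_offset[c]:
                return c
        raise AssertionError

    def chrom_index(self, fid: np.ndarray) -> np.ndarray:
        """Vectorized chromosome ordinal for fragment ids."""
        offs = np.array([self.id_offset[c] for c in self.chroms])
        return np.searchsorted(offs, np.asarray(fid), side="right") - 1

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts[chrom] + self.ends[chrom]) / 2.0

    def midpoint_of(self, fid: np.ndarray) -> np.ndarray:
        """Vectorized fragment midpoint (within-chromosome coordinate)."""
        fid = np.asarray(fid)
        out = np.empty(len(fid), dtype=float)
        ci = self.chrom_index(fid)
        for k, c in enumerate(self.chroms):
            m = ci == k
            if m.any():
                local = fid[m] - self.id_offset[c]
                out[m] = (self.starts[c][local] + self.ends[c][local]) / 2.0
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            n = len(self.starts[c])
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": self.starts[c],
                        "end": self.ends[c],
                        "fragment_id": np.arange(n) + self.id_offset[c],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_rmap(self, path) -> None:
        """Tab-separated rmap: chrom, start, end, fragment_id (0-based half-open)."""
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FragmentMap":
        chroms = list(dict.fromkeys(df["chrom"]))
        starts = {}
        ends = {}
        sizes = {}
        for c in chroms:
            sub = df[df["chrom"] == c].sort_values("start")
            starts[c] = sub["start"].to_numpy(dtype=np.int64)
            ends[c] = sub["end"].to_numpy(dtype=np.int64)
            sizes[c] = int(ends[c][-1])
        return cls(chroms, sizes, starts, ends)

    @classmethod
    def read_rmap(cls, path) -> "FragmentMap":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "fragment_id"],
            dtype={"chrom": str},
        )
        return cls.from_dataframe(df)


@dataclass
class BaitMap:
    """Annotation of captured (baited) fragments: fragment_id -> gene names."""

    annotations: dict[int, str]

    def __post_init__(self) -> None:
        for fid, ann in self.annotations.items():
            if not ann:
                raise ValueError(f"empty annotation for baited fragment {fid}")

    @property
    def fragment_ids(self) -> np.ndarray:
        return np.array(sorted(self.annotations), dtype=np.int64)

    def __contains__(self, fid: int) -> bool:
        return int(fid) in self.annotations

    def __len__(self) -> int:
        return len(self.annotations)

    def is_bait(self, fid: np.ndarray) -> np.ndarray:
        return np.isin(np.asarray(fid), self.fragment_ids)

    def validate(self, fmap: FragmentMap) -> None:
        bad = [f for f in self.annotations if not 0 <= f < len(fmap)]
        if bad:
            raise ValueError(f"baited fragments missing from fragment map: {bad[:5]}")

    def write_baitmap(self, path, fmap: FragmentMap) -> None:
        with open(path, "w") as fh:
            for fid in sorted(self.annotations):
                c, s, e = fmap.fragment(fid)
                fh.write(f"{c}\t{s}\t{e}\t{fid}\t{self.annotations[fid]}\n")

    @classmethod
    def read_baitmap(cls, path) -> "BaitMap":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "fragment_id", "annotation"],
            dtype={"chrom": str},
        )
        return cls(dict(zip(df["fragment_id"].astype(int), df["annotation"].astype(str))))


def digest_genome(
    sequences: "dict[str, str] | str", enzyme: "str | RestrictionEnzyme"
) -> FragmentMap:
    """Digest genome sequences into a :class:`FragmentMap`.

    Cut positions are every forward-strand occurrence of the recognition
    site, offset by the enzyme's cut offset; overlapping occurrences count.
    A chromosome with no site yields a single fragment spanning it.

    ``sequences`` is a ``{name: sequence}`` dict or a FASTA path.
    """
    enz = get_enzyme(enzyme)
    if isinstance(sequences, (str, bytes)) or hasattr(sequences, "read"):
        sequences = read_fasta(sequences)
    if not sequences:
        raise ValueError("no sequences to digest")
    pat = re.compile(f"(?={enz.site})")  # lookahead: overlapping matches
    chroms, sizes, starts, ends = [], {}, {}, {}
    for name, seq in sequences.items():
        seq = str(seq).upper()
        L = len(seq)
        if L == 0:
            raise ValueError(f"empty sequence for {name}")
        cuts = np.fromiter(
            (m.start() + enz.cut_offset for m in pat.finditer(seq)), dtype=np.int64
        )
        cuts = cuts[(cuts > 0) & (cuts < L)]
        bounds = np.unique(np.concatenate([[0], cuts, [L]]))
        chroms.append(name)
        sizes[name] = L
        starts[name] = bounds[:-1]
        ends[name] = bounds[1:]
    return FragmentMap(chroms, sizes, starts, ends)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
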