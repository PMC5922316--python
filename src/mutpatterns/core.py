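"""Core data model: reference genomes, SNV catalogues and genomic interval sets.

All coordinates in this package are 1-based and inclusive (the VCF
convention). BED input/output is converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("mutpatterns")

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class RefMismatchError(ValueError):
    """Reference genome base disagrees with a variant's REF allele.

    Raised instead of silently skipping: a systematic mismatch almost
    always means the calls come from a different genome build.
    """


@dataclass
class ReferenceGenome:
    """An in-memory reference genome: chromosome name -> upper-case sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference genome has no sequences")
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def context(self, chrom: str, pos: int) -> str | None:
        """Plus-strand trinucleotide centred on ``pos``; None at chromosome edges."""
        seq = self.sequences[chrom]
        if pos < 2 or pos > len(seq) - 1:
            return None
        return seq[pos - 2 : pos + 1]


@dataclass(frozen=True, order=True)
class Snv:
    """A single-nucleotide somatic variant in 1-based plus-strand coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-canonical allele in {self.chrom}:{self.pos} {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class MutationCatalogue:
    """Per-sample catalogue of somatic SNVs, sorted by (chrom, pos).

    ``skipped`` tallies records excluded at import, keyed by reason
    (indel, mnv, symbolic, filtered, duplicate, ...).
    """

    sample_id: str
    snvs: list[Snv] = field(default_factory=list)
    skipped: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.snvs = sorted(self.snvs)
        seen: set[tuple[str, int, str]] = set()
        for snv in self.snvs:
            key = (snv.chrom, snv.pos, snv.alt)
            if key in seen:
                raise ValueError(f"duplicate SNV {key} in sample {self.sample_id}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.snvs)

    def __iter__(self):
        return iter(self.snvs)

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Check chromosomes, bounds and REF alleles against a genome."""
        for snv in self.snvs:
            if snv.chrom not in genome:
                raise ValueError(
                    f"sample {self.sample_id}: chromosome {snv.chrom!r} absent from genome"
                )
            if snv.pos > genome.lengths[snv.chrom]:
                raise ValueError(
                    f"sample {self.sample_id}: {snv.chrom}:{snv.pos} beyond chromosome end"
                )
            ref = genome.base(snv.chrom, snv.pos)
            if ref != snv.ref:
                raise RefMismatchError(
                    f"{snv.chrom}:{snv.pos} genome has {ref!r} but variant REF is "
                    f"{snv.ref!r} — wrong reference build?"
                )


@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start > end: {self.chrom}:{self.start}-{self.end}")
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1: {self.chrom}:{self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


class IntervalSet:
    """A labelled collection of (possibly stranded) genomic intervals."""

    def __init__(self, intervals, label: str = ""):
        self.intervals: list[Interval] = [
            iv if isinstance(iv, Interval) else Interval(*iv) for iv in intervals
        ]
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and sorted(
            self.intervals, key=_iv_key
        ) == sorted(other.intervals, key=_iv_key)

    @property
    def stranded(self) -> bool:
        return len(self) > 0 and all(iv.strand in "+-" for iv in self.intervals)

    def validate_against(self, genome: ReferenceGenome) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise ValueError(f"{self.label}: chromosome {iv.chrom!r} absent from genome")
            if iv.end > genome.lengths[iv.chrom]:
                raise ValueError(
                    f"{self.label}: {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
                )

    # ---- interval algebra (union / intersection on merged sets) ----

    def merged(self) -> "IntervalSet":
        """Union of the intervals, ignoring strand; output sorted and disjoint."""
        return IntervalSet(
            [
                Interval(chrom, s, e)
                for chrom, pairs in _merge_by_chrom(self.intervals).items()
                for s, e in pairs
            ],
            label=self.label,
        )

    def merged_by_strand(self, strand: str) -> "IntervalSet":
        """Union of the intervals on one strand only."""
        subset = [iv for iv in self.intervals if iv.strand == strand]
        return IntervalSet(
            [
                Interval(chrom, s, e, strand)
                for chrom, pairs in _merge_by_chrom(subset).items()
                for s, e in pairs
            ],
            label=f"{self.label}[{strand}]",
        )

    def total_length(self) -> int:
        """Number of distinct bases covered (overlaps counted once)."""
        return sum(len(iv) for iv in self.merged())

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-wise intersection of the two merged sets (unstranded)."""
        a = _merge_by_chrom(self.intervals)
        b = _merge_by_chrom(other.intervals)
        out = []
        for chrom in a.keys() & b.keys():
            ia = ib = 0
            pa, pb = a[chrom], b[chrom]
            while ia < len(pa) and ib < len(pb):
                s = max(pa[ia][0], pb[ib][0])
                e = min(pa[ia][1], pb[ib][1])
                if s <= e:
                    out.append(Interval(chrom, s, e))
                if pa[ia][1] < pb[ib][1]:
                    ia += 1
                else:
                    ib += 1
        out.sort(key=_iv_key)
        return IntervalSet(out, label=f"{self.label}&{other.label}")

    def point_lookup(self) -> "PointLookup":
        return PointLookup(self)


def _iv_key(iv: Interval):
    return (iv.chrom, iv.start, iv.end, iv.strand)


def _merge_by_chrom(intervals) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        acc = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s <= acc[-1][1] + 1:  # adjacent 1-based intervals merge
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = [(s, e) for s, e in acc]
    return dict(sorted(merged.items()))


class PointLookup:
    """O(log n) point-in-merged-set queries over an IntervalSet."""

    def __init__(self, iset: IntervalSet):
        self._index = {}
        for chrom, pairs in _merge_by_chrom(iset.intervals).items():
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            self._index[chrom] = (starts, ends)

    def covers(self, chrom: str, pos: int) -> bool:
        if chrom not in self._index:
            return False
        starts, ends = self._index[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos <= ends[i]

    def covers_array(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership test for many positions on one chromosome."""
        if chrom not in self._index:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = self._index[chrom]
        i = np.searchsorted(starts, positions, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] <= ends[i[ok]]
        return out
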