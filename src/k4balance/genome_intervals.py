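"""Genomic interval data model and exact overlap arithmetic.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``. Book-ended intervals
(``[0,5)`` and ``[5,10)``) merge into one but share zero overlapping bases.

The central objects are :class:`GenomeLayout` (the coordinate universe:
named chromosomes with lengths) and :class:`IntervalSet` (a list of
validated intervals tied to a layout). Everything downstream — shuffle
nulls, overlap enrichment, coverage tracks — builds on the exact base-pair
set operations defined here: :func:`merge`, :func:`overlap_bp`,
:func:`subtract`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "merge",
    "overlap_bp",
    "subtract",
    "complement",
    "total_bp",
    "fisher_overlap",
]


class BedParseError(ValueError):
    """Raised for malformed BED records (with the 1-based line number)."""


class GenomeMismatchError(ValueError):
    """Raised when interval sets on different genome layouts are combined."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the coordinate universe.

    Parameters
    ----------
    chromosomes:
        Sequence of ``(name, length)`` pairs. Names must be unique and
        lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def extend(self, extra: Iterable[tuple[str, int]]) -> "GenomeLayout":
        """New layout with additional contigs appended (e.g. spike-in barcodes)."""
        return GenomeLayout(list(self.chromosomes) + list(extra))


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand is not None and self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A list of intervals validated against one :class:`GenomeLayout`.

    Iteration order is the construction order (deterministic). Set-algebra
    helpers (:meth:`merged`, :meth:`total_bp`) treat the set as a union of
    covered bases.
    """

    def __init__(self, intervals: Iterable[Interval], genome: GenomeLayout):
        self.genome = genome
        ivs = list(intervals)
        for iv in ivs:
            if iv.chrom not in genome:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > genome.length_of(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:[{iv.start},{iv.end}) exceeds "
                    f"chromosome length {genome.length_of(iv.chrom)}"
                )
        self.intervals: list[Interval] = ivs

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def merged(self) -> "IntervalSet":
        return merge(self)

    def total_bp(self) -> int:
        return total_bp(self)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Raw ``(n, 2)`` start/end arrays per chromosome, in file order."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


# ---------------------------------------------------------------------------
# I/O

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column ``name<TAB>length`` chrom-sizes table."""
    chroms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name\\tlength'")
            chroms.append((parts[0], int(parts[1])))
    return GenomeLayout(chroms)


def _parse_bed_line(line: str, lineno: int) -> Interval:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise BedParseError(f"line {lineno}: fewer than 3 columns")
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError:
        raise BedParseError(
            f"line {lineno}: non-integer coordinates {parts[1]!r}, {parts[2]!r}"
        ) from None
    if start >= end:
        raise BedParseError(
            f"line {lineno}: start {start} >= end {end} (zero- or negative-length)"
        )
    name = parts[3] if len(parts) > 3 and parts[3] != "" else None
    score: float | None = None
    if len(parts) > 4 and parts[4] not in ("", "."):
        try:
            score = float(parts[4])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-numeric score {parts[4]!r}") from None
    strand = parts[5] if len(parts) > 5 and parts[5] != "" else None
    return Interval(chrom, start, end, name=name, score=score, strand=strand)


def read_bed(path: str | Path, genome: GenomeLayout) -> IntervalSet:
    """Read a 3-6 column BED file, validating every record against *genome*.

    ``track``/``browser``/``#`` header lines are skipped. Records on unknown
    chromosomes or out of bounds raise rather than being silently dropped —
    silent drops would corrupt downstream overlap statistics.
    """
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if (not stripped or stripped.startswith("#")
                    or stripped.startswith("track") or stripped.startswith("browser")):
                continue
            try:
                iv = _parse_bed_line(line, lineno)
            except ValueError as e:
                raise BedParseError(f"{path}: {e}") from None
            ivs.append(iv)
    return IntervalSet(ivs, genome)


def write_bed(ivset: IntervalSet, path: str | Path) -> None:
    """Write intervals as tab-separated BED (3-6 columns as available)."""
    with open(path, "w") as fh:
        for iv in ivset:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(format(iv.score, "g") if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Set arithmetic (exact, half-open)

def _merge_arrays(arr: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping [start,end) rows; book-ended rows fuse."""
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s <= cur_e:  # overlap or book-ended
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


def merge(ivset: IntervalSet) -> IntervalSet:
    """Canonical form: sorted by (chrom, start), pairwise disjoint.

    The union of covered bases is unchanged; optional BED fields are
    dropped (a merged interval has no single source record).
    """
    out: list[Interval] = []
    per = ivset.by_chrom()
    for chrom in sorted(per, key=lambda c: ivset.genome.names.index(c)):
        for s, e in _merge_arrays(per[chrom]):
            out.append(Interval(chrom, int(s), int(e)))
    return IntervalSet(out, ivset.genome)


def total_bp(ivset: IntervalSet) -> int:
    """Number of distinct bases covered by the set."""
    n = 0
    for arr in ivset.by_chrom().values():
        m = _merge_arrays(arr)
        n += int((m[:, 1] - m[:, 0]).sum())
    return n


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome.chromosomes != b.genome.chromosomes:
        raise GenomeMismatchError("interval sets are on different genome layouts")


def _intersect_bp_arrays(a: np.ndarray, b: np.ndarray) -> int:
    """Overlap bp between two *merged* [start,end) arrays (one chromosome)."""
    if a.size == 0 or b.size == 0:
        return 0
    i = j = 0
    tot = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            tot += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return int(tot)


def overlap_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Base pairs in the intersection of the two sets' covered bases.

    Symmetric; both sets are merged internally first, so duplicated or
    overlapping records never double-count.
    """
    _check_same_genome(a, b)
    pa, pb = a.by_chrom(), b.by_chrom()
    tot = 0
    for chrom in pa.keys() & pb.keys():
        tot += _intersect_bp_arrays(_merge_arrays(pa[chrom]), _merge_arrays(pb[chrom]))
    return tot


def subtract(a: IntervalSet, excluded: IntervalSet) -> IntervalSet:
    """Bases of *a* not covered by *excluded*; no zero-length survivors."""
    _check_same_genome(a, excluded)
    pex = {c: _merge_arrays(v) for c, v in excluded.by_chrom().items()}
    out: list[Interval] = []
    per = a.by_chrom()
    for chrom in sorted(per, key=lambda c: a.genome.names.index(c)):
        ex = pex.get(chrom, np.empty((0, 2), dtype=np.int64))
        for s, e in _merge_arrays(per[chrom]):
            cur = s
            for xs, xe in ex:
                if xe <= cur or xs >= e:
                    continue
                if xs > cur:
                    out.append(Interval(chrom, int(cur), int(xs)))
                cur = max(cur, xe)
                if cur >= e:
                    break
            if cur < e:
                out.append(Interval(chrom, int(cur), int(e)))
    return IntervalSet(out, a.genome)


def complement(ivset: IntervalSet) -> IntervalSet:
    """Bases of the genome not covered by the set."""
    whole = IntervalSet(
        [Interval(c, 0, l) for c, l in ivset.genome.chromosomes], ivset.genome
    )
    return subtract(whole, ivset)


# ---------------------------------------------------------------------------
# Fisher's exact test on interval co-occurrence

def _count_overlapping(a: IntervalSet, b_merged: np.ndarray | dict) -> int:
    """Number of intervals of ``a`` that overlap >=1 base of merged set b."""
    per_b = b_merged
    n = 0
    for iv in a:
        arr = per_b.get(iv.chrom)
        if arr is None or arr.size == 0:
            continue
        # first merged b interval ending after iv.start
        k = int(np.searchsorted(arr[:, 1], iv.start, side="right"))
        if k < len(arr) and arr[k, 0] < iv.end:
            n += 1
    return n


def fisher_overlap(
    a: IntervalSet, b: IntervalSet, genome: GenomeLayout
) -> tuple[np.ndarray, float]:
    """Fisher's exact test for interval-level co-occurrence of two peak sets.

    Both sets are merged, then counted: intervals of ``a`` hitting ``b``,
    ``a``-only, ``b``-only, and an estimated "neither" count. Fisher's test
    needs a finite universe of trials; the neither cell is approximated as
    ``floor(uncovered_genome_bp / mean_interval_length(a ∪ b))`` — the number
    of interval-sized slots in the untouched genome.

    Returns the 2x2 contingency table ``[[both, a_only], [b_only, neither]]``
    and the two-sided exact p-value.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("fisher_overlap requires two non-empty interval sets")
    am, bm = merge(a), merge(b)
    per_am = am.by_chrom()
    per_bm = bm.by_chrom()
    both = _count_overlapping(am, per_bm)
    a_only = len(am) - both
    b_only = len(bm) - _count_overlapping(bm, per_am)
    union = IntervalSet(list(am) + list(bm), genome)
    covered = total_bp(union)
    uncovered = genome.total_size - covered
    mean_len = covered / max(len(merge(union)), 1)  # mean length over merged a∪b
    neither = int(math.floor(uncovered / mean_len)) if mean_len > 0 else 0
    table = np.array([[both, a_only], [b_only, neither]], dtype=np.int64)
    _, p = _sps.fisher_exact(table, alternative="two-sided")
    return table, float(p)
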