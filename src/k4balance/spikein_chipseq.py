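"""Spike-in (SNAP nucleosome) normalization for ChIP-seq.

Barcoded synthetic nucleosomes are added to chromatin before
immunoprecipitation; reads mapping to the barcode contigs calibrate ChIP
signal between samples. Within a biological replicate the scale factor is

    scale = reference barcode reads / test barcode reads

(the reference sample's own factor is 1), applied multiplicatively to the
test sample's binned coverage. Coverage bins hold scaled *mean per-base
depth* (not raw read counts), which keeps partial final bins well defined;
tracks round-trip as text bedGraph. :func:`metaprofile` samples a track
over fixed windows around region centers, producing the matrix behind
peak-centered heatmaps sorted by mean occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_intervals import GenomeLayout, Interval, IntervalSet

__all__ = [
    "BarcodePanel",
    "SampleReads",
    "SpikeScale",
    "CoverageTrack",
    "count_barcode_reads",
    "scale_factor",
    "binned_coverage",
    "metaprofile",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass(frozen=True)
class BarcodePanel:
    """Contig names belonging to the spike-in barcode panel."""

    barcode_names: tuple[str, ...]

    def __init__(self, barcode_names):
        names = tuple(barcode_names)
        if not names:
            raise ValueError("barcode panel is empty")
        if len(set(names)) != len(names):
            raise ValueError("duplicate barcode names")
        object.__setattr__(self, "barcode_names", names)

    def __contains__(self, name: str) -> bool:
        return name in self.barcode_names


@dataclass
class SampleReads:
    """Mapped reads of one sample over genome + barcode contigs."""

    sample_id: str
    replicate: int
    condition: str  # "reference" | "test"
    reads: IntervalSet


@dataclass(frozen=True)
class SpikeScale:
    """Per-replicate spike-in scale factor (reference / test barcode reads)."""

    replicate: int
    ref_barcode_reads: int
    test_barcode_reads: int

    @property
    def scale_factor(self) -> float:
        return scale_factor(self.ref_barcode_reads, self.test_barcode_reads)


def count_barcode_reads(
    sample: SampleReads, panel: BarcodePanel
) -> tuple[dict[str, int], int]:
    """Reads per barcode contig and their sum; genome-mapped reads excluded."""
    counts = {name: 0 for name in panel.barcode_names}
    for iv in sample.reads:
        if iv.chrom in panel:
            counts[iv.chrom] += 1
    return counts, sum(counts.values())


def scale_factor(ref_total: int, test_total: int) -> float:
    """Reference barcode reads divided by test barcode reads."""
    if ref_total <= 0 or test_total <= 0:
        raise ValueError("no spike-in reads: both barcode totals must be > 0")
    return ref_total / test_total


@dataclass
class CoverageTrack:
    """Binned, scaled read-depth track over a genome layout.

    ``values[chrom]`` holds one float per bin of ``bin_size`` bp; the final
    bin of each chromosome may be narrower and its value is the mean depth
    over its true width.
    """

    genome: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.length_of(chrom) // self.bin_size)

    def value_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Track value at per-base positions (vectorized bin lookup)."""
        return self.values[chrom][np.asarray(pos) // self.bin_size]


def binned_coverage(
    reads: IntervalSet,
    genome: GenomeLayout,
    bin_size: int = 50,
    scale: float = 1.0,
) -> CoverageTrack:
    """Scaled mean per-base depth in fixed-width bins.

    Bin value = ``scale * (sum of read bases in bin) / bin width``; the last
    partial bin divides by its true width. Reads on contigs absent from
    *genome* (e.g. barcode contigs) are ignored.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values: dict[str, np.ndarray] = {}
    per = reads.by_chrom()
    for chrom, length in genome.chromosomes:
        nb = -(-length // bin_size)
        depth_sum = np.zeros(nb, dtype=np.float64)
        arr = per.get(chrom)
        if arr is not None:
            for s, e in arr:
                b0, b1 = s // bin_size, (e - 1) // bin_size
                if b0 == b1:
                    depth_sum[b0] += e - s
                else:
                    depth_sum[b0] += (b0 + 1) * bin_size - s
                    depth_sum[b1] += e - b1 * bin_size
                    if b1 > b0 + 1:
                        depth_sum[b0 + 1:b1] += bin_size
        widths = np.full(nb, bin_size, dtype=np.float64)
        widths[-1] = length - (nb - 1) * bin_size
        values[chrom] = scale * (depth_sum / widths)  # scale last: exact linearity
    return CoverageTrack(genome=genome, bin_size=bin_size, values=values)


def metaprofile(
    track: CoverageTrack,
    centers: IntervalSet,
    flank: int,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signal matrix over windows centered on region midpoints.

    For each region the window ``[mid - flank, mid + flank)`` is split into
    ``n_bins`` equal sub-windows and the mean track value computed per
    sub-window; bases beyond chromosome ends contribute zero and such rows
    are flagged truncated. Rows are sorted by descending row mean.

    Returns ``(matrix, order, truncated)`` where ``order[i]`` is the index
    of the i-th output row in the input region list and ``truncated`` is a
    boolean flag per output row.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    width = 2 * flank
    edges = np.linspace(0, width, n_bins + 1).astype(np.int64)
    mat = np.zeros((len(centers), n_bins), dtype=np.float64)
    trunc = np.zeros(len(centers), dtype=bool)
    for i, iv in enumerate(centers):
        if iv.chrom not in track.genome:
            raise ValueError(f"region on unknown chromosome {iv.chrom!r}")
        length = track.genome.length_of(iv.chrom)
        w0 = iv.midpoint - flank
        pos = np.arange(w0, w0 + width)
        inside = (pos >= 0) & (pos < length)
        if not inside.all():
            trunc[i] = True
        vals = np.zeros(width, dtype=np.float64)
        vals[inside] = track.value_at(iv.chrom, pos[inside])
        for k in range(n_bins):
            seg = vals[edges[k]:edges[k + 1]]
            mat[i, k] = seg.mean() if seg.size else 0.0
    order = np.argsort(-mat.mean(axis=1), kind="stable")
    return mat[order], order, trunc[order]


# ---------------------------------------------------------------------------
# bedGraph I/O (text, bit-exact, diff-able)

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """4-column bedGraph; adjacent equal-valued bins are run-length merged."""
    with open(path, "w") as fh:
        for chrom, length in track.genome.chromosomes:
            vals = track.values[chrom]
            bs = track.bin_size
            start_bin = 0
            for b in range(1, len(vals) + 1):
                if b == len(vals) or vals[b] != vals[start_bin]:
                    s = start_bin * bs
                    e = min(b * bs, length)
                    fh.write(f"{chrom}\t{s}\t{e}\t{vals[start_bin]:.10g}\n")
                    start_bin = b


def read_bedgraph(path: str | Path, genome: GenomeLayout, bin_size: int) -> CoverageTrack:
    """Read a bedGraph whose records align to ``bin_size`` boundaries."""
    values = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.float64)
        for chrom, length in genome.chromosomes
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e, v = int(s), int(e), float(v)
            if chrom not in values:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if s % bin_size:
                raise ValueError(f"{path}:{lineno}: record not aligned to {bin_size}-bp bins")
            values[chrom][s // bin_size: -(-e // bin_size)] = v
    return CoverageTrack(genome=genome, bin_size=bin_size, values=values)
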