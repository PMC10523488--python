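"""Randomized null peak sets for overlap-enrichment testing.

The null model places each annotation peak at a new, uniformly chosen
position anywhere in the genome (any chromosome), keeping its exact length
and never touching exclusion regions (assembly gaps, blacklist). For
ChIP-chip annotations, placements are additionally rejection-sampled until
the shuffled peak's microarray probe density is within a tolerance of the
original peak's density, the constraint being declared satisfied once at
least ``min_matched_fraction`` of peaks match.

Placement is sampled exactly uniformly over valid start positions: for a
peak of length L the valid starts inside an allowed (non-excluded) region
``[u, v)`` are ``u .. v-L``, so chromosomes are implicitly weighted by
their number of valid starts. Same seed, same inputs -> bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_intervals import (
    GenomeLayout,
    Interval,
    IntervalSet,
    _merge_arrays,
    complement,
)

__all__ = [
    "ProbeMap",
    "ShuffleConfig",
    "probe_density",
    "shuffle_length_matched",
    "shuffle_density_matched",
    "AllowedSpace",
]


class PlacementError(RuntimeError):
    """A peak could not be placed under the current constraints."""


@dataclass(frozen=True)
class ProbeMap:
    """Microarray probe positions; densities are counted by probe midpoint."""

    probes: IntervalSet

    def midpoints(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for iv in self.probes:
            out.setdefault(iv.chrom, []).append(iv.midpoint)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


@dataclass(frozen=True)
class ShuffleConfig:
    """Parameters of the permutation null.

    Defaults follow the published analysis: 1,000 permutations, probe-density
    tolerance 0.1 (probes/bp), and a 99% matched-peak quota.
    """

    n_permutations: int = 1000
    seed: int = 0
    density_tolerance: float = 0.1
    min_matched_fraction: float = 0.99
    max_attempts_per_peak: int = 1000

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not (0 < self.min_matched_fraction <= 1):
            raise ValueError("min_matched_fraction must be in (0, 1]")
        if self.density_tolerance < 0:
            raise ValueError("density_tolerance must be >= 0")
        if self.max_attempts_per_peak < 1:
            raise ValueError("max_attempts_per_peak must be positive")


def probe_density(iv: Interval, probes: ProbeMap) -> float:
    """Probes per base pair: midpoints falling in ``[start, end)`` / length."""
    mids = probes.midpoints().get(iv.chrom)
    if mids is None:
        return 0.0
    n = int(np.searchsorted(mids, iv.end, side="left")
            - np.searchsorted(mids, iv.start, side="left"))
    return n / iv.length


class AllowedSpace:
    """Pre-computed complement of the exclusion set, for uniform placement.

    For each chromosome holds the merged allowed regions; ``draw(length, rng)``
    picks a start uniformly among every valid start genome-wide for that
    length.
    """

    def __init__(self, genome: GenomeLayout, excluded: IntervalSet):
        self.genome = genome
        allowed = complement(excluded) if len(excluded) else IntervalSet(
            [Interval(c, 0, l) for c, l in genome.chromosomes], genome
        )
        per = allowed.by_chrom()
        self.regions: list[tuple[str, int, int]] = []
        for chrom in genome.names:
            arr = per.get(chrom)
            if arr is None:
                continue
            for s, e in _merge_arrays(arr):
                self.regions.append((chrom, int(s), int(e)))
        self._starts = np.array([s for _, s, _ in self.regions], dtype=np.int64)
        self._ends = np.array([e for _, _, e in self.regions], dtype=np.int64)

    def n_valid_starts(self, length: int) -> int:
        counts = np.maximum(self._ends - self._starts - length + 1, 0)
        return int(counts.sum())

    def draw(self, length: int, rng: np.random.Generator) -> tuple[str, int]:
        """Uniform draw of (chrom, start) over all valid placements."""
        counts = np.maximum(self._ends - self._starts - length + 1, 0)
        total = int(counts.sum())
        if total == 0:
            raise PlacementError(
                f"no valid placement for a peak of length {length}"
            )
        cum = np.cumsum(counts)
        r = int(rng.integers(total))
        k = int(np.searchsorted(cum, r, side="right"))
        chrom, u, _ = self.regions[k]
        offset = r - (int(cum[k - 1]) if k > 0 else 0)
        return chrom, u + offset


def shuffle_length_matched(
    peaks: IntervalSet,
    genome: GenomeLayout,
    excluded: IntervalSet,
    seed: int,
    space: AllowedSpace | None = None,
) -> IntervalSet:
    """One genome-wide shuffle conserving the exact multiset of peak lengths.

    Every output interval avoids ``excluded`` entirely (no partial overlap)
    and is placed uniformly over all valid start positions. Peaks are placed
    independently, so shuffled peaks may overlap one another.
    """
    out, _ = _shuffle(peaks, genome, excluded, seed, probes=None,
                      tolerance=np.inf, max_attempts=1, space=space)
    return out


def shuffle_density_matched(
    peaks: IntervalSet,
    genome: GenomeLayout,
    excluded: IntervalSet,
    probes: ProbeMap,
    cfg: ShuffleConfig,
    seed: int,
    space: AllowedSpace | None = None,
) -> tuple[IntervalSet, float]:
    """Length-matched shuffle that also preserves per-peak probe density.

    Each peak is redrawn until its shuffled probe density is within
    ``cfg.density_tolerance`` of the original, up to
    ``cfg.max_attempts_per_peak`` draws; unmatched peaks keep their final
    draw. If fewer than ``cfg.min_matched_fraction`` of peaks match, raises
    with diagnostics. Returns the shuffled set and the matched fraction.

    With an infinite tolerance this reduces exactly (same RNG stream) to
    :func:`shuffle_length_matched`.
    """
    if len(probes.probes) == 0:
        raise ValueError("density matching requested but the probe map is empty")
    out, matched = _shuffle(
        peaks, genome, excluded, seed, probes=probes,
        tolerance=cfg.density_tolerance, max_attempts=cfg.max_attempts_per_peak,
        space=space,
    )
    frac = matched / len(peaks) if len(peaks) else 1.0
    if frac < cfg.min_matched_fraction:
        raise PlacementError(
            f"only {matched}/{len(peaks)} peaks ({frac:.3f}) matched probe "
            f"density within {cfg.density_tolerance} after "
            f"{cfg.max_attempts_per_peak} attempts each "
            f"(required {cfg.min_matched_fraction})"
        )
    return out, frac


def _shuffle(peaks, genome, excluded, seed, probes, tolerance, max_attempts, space):
    if space is None:
        space = AllowedSpace(genome, excluded)
    rng = np.random.default_rng(seed)
    mids = probes.midpoints() if probes is not None else None
    out: list[Interval] = []
    matched = 0
    for iv in peaks:
        if probes is not None and np.isfinite(tolerance):
            m0 = mids.get(iv.chrom)
            n0 = 0 if m0 is None else int(
                np.searchsorted(m0, iv.end) - np.searchsorted(m0, iv.start)
            )
            target = n0 / iv.length
        placed = None
        ok = False
        for _ in range(max_attempts):
            try:
                chrom, start = space.draw(iv.length, rng)
            except PlacementError:
                raise PlacementError(
                    f"peak {iv.name or f'{iv.chrom}:{iv.start}-{iv.end}'} of "
                    f"length {iv.length} has no valid placement"
                ) from None
            placed = Interval(chrom, start, start + iv.length,
                              name=iv.name, score=iv.score, strand=iv.strand)
            if probes is None or not np.isfinite(tolerance):
                ok = True
                break
            m = mids.get(chrom)
            n = 0 if m is None else int(
                np.searchsorted(m, placed.end) - np.searchsorted(m, placed.start)
            )
            if abs(n / iv.length - target) <= tolerance:
                ok = True
                break
        matched += ok
        out.append(placed)
    return IntervalSet(out, genome), matched
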