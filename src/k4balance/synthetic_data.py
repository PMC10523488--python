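"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the structure of one experimental input — peak
sets with a planted overlap enrichment, spike-in ChIP-seq read sets with a
planted global signal change, qPCR Ct tables with a planted fold change,
TMT peptide matrices with a planted set of enriched proteins, and
two-condition nucleus-intensity tables with a planted shift — and returns
a :class:`SimTruth` record of the planted parameters and seed alongside
the data. Same parameters + same seed -> identical output.

The default toy genome is 2 chromosomes x 500 kb: large enough for stable
permutation nulls, small enough that full analyses run in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_intervals import (
    GenomeLayout,
    Interval,
    IntervalSet,
    merge,
    subtract,
    total_bp,
)
from .null_shuffle import AllowedSpace, ProbeMap
from .spikein_chipseq import BarcodePanel, SampleReads
from .tmt_hits import PeptideMatrix

__all__ = [
    "SimTruth",
    "gen_genome",
    "gen_peaks",
    "gen_enriched_query",
    "gen_probe_map",
    "gen_spikein_reads",
    "gen_ct_table",
    "gen_peptide_matrix",
    "gen_nucleus_table",
    "DEFAULT_BARCODES",
]

DEFAULT_BARCODES = tuple(f"barcode_{k:02d}" for k in range(1, 7))


@dataclass
class SimTruth:
    """Planted parameters and seed of one synthetic dataset."""

    stage: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(
            {"stage": self.stage, "seed": self.seed, "params": self.params},
            indent=2, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SimTruth":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(stage=d["stage"], seed=d["seed"], params=d["params"])


def gen_genome(
    n_chrom: int = 2,
    chrom_length: int = 500_000,
    gap_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[GenomeLayout, IntervalSet]:
    """Toy genome plus exclusion (gap/blacklist) intervals covering
    approximately ``gap_fraction`` of it."""
    if not (0 <= gap_fraction < 1):
        raise ValueError("gap_fraction must be in [0, 1)")
    genome = GenomeLayout([(f"chr{i+1}", chrom_length) for i in range(n_chrom)])
    rng = np.random.default_rng(seed)
    gaps: list[Interval] = []
    if gap_fraction > 0:
        gap_len = 2_000
        n_gaps = max(1, int(round(gap_fraction * genome.total_size / gap_len)))
        for _ in range(n_gaps):
            chrom = genome.names[rng.integers(n_chrom)]
            start = int(rng.integers(genome.length_of(chrom) - gap_len))
            gaps.append(Interval(chrom, start, start + gap_len))
    return genome, merge(IntervalSet(gaps, genome))


def gen_peaks(
    genome: GenomeLayout,
    excluded: IntervalSet,
    n_peaks: int = 50,
    length_range: tuple[int, int] = (500, 3000),
    seed: int = 0,
) -> IntervalSet:
    """Peaks placed uniformly in the non-excluded genome (may overlap)."""
    rng = np.random.default_rng(seed)
    space = AllowedSpace(genome, excluded)
    out = []
    for i in range(n_peaks):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        chrom, start = space.draw(length, rng)
        out.append(Interval(chrom, start, start + length, name=f"peak_{i}"))
    return IntervalSet(out, genome)


def gen_enriched_query(
    annotation: IntervalSet,
    genome: GenomeLayout,
    excluded: IntervalSet,
    n_peaks: int = 60,
    length_range: tuple[int, int] = (200, 500),
    enrich_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[IntervalSet, SimTruth]:
    """Query peaks whose expected annotation overlap is a planted multiple
    of the uniform expectation.

    With annotation covering fraction ``f`` of the placeable genome, a peak
    is placed fully inside the annotation with probability
    ``p_in = f (r - 1) / (1 - f)`` (enrichment, ``r > 1``), fully outside
    with probability ``1 - r`` (depletion, ``r < 1``), and uniformly
    otherwise, giving expected per-peak overlap ``r * f * length``. The
    truth records the planted ratio and the realized overlap ratio.
    """
    if enrich_ratio <= 0:
        raise ValueError("enrich_ratio must be > 0")
    rng = np.random.default_rng(seed)
    ann = merge(subtract(annotation, excluded)) if len(excluded) else merge(annotation)
    allowed_space = AllowedSpace(genome, excluded)
    allowed_bp = sum(e - s for _, s, e in allowed_space.regions)
    f = total_bp(ann) / allowed_bp
    if f <= 0:
        raise ValueError("annotation covers none of the placeable genome")
    if enrich_ratio >= 1:
        p_in = f * (enrich_ratio - 1) / (1 - f)
        p_out = 0.0
        if p_in > 1:
            raise ValueError(
                f"enrich_ratio {enrich_ratio} infeasible: annotation fraction "
                f"{f:.3f} supports at most {1 / f:.2f}x"
            )
    else:
        p_in = 0.0
        p_out = 1 - enrich_ratio
    ann_regions = [(iv.chrom, iv.start, iv.end) for iv in ann]
    out_space = AllowedSpace(
        genome, merge(IntervalSet(list(excluded) + list(ann), genome))
    )
    peaks = []
    for i in range(n_peaks):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        u = rng.random()
        if u < p_in:
            fits = [(c, s, e) for c, s, e in ann_regions if e - s >= length]
            if not fits:
                raise ValueError(
                    f"no annotation interval can contain a {length}-bp query peak"
                )
            w = np.array([e - s - length + 1 for _, s, e in fits], dtype=float)
            k = int(rng.choice(len(fits), p=w / w.sum()))
            c, s, e = fits[k]
            start = int(s + rng.integers(e - s - length + 1))
            chrom = c
        elif u < p_in + p_out:
            chrom, start = out_space.draw(length, rng)
        else:
            chrom, start = allowed_space.draw(length, rng)
        peaks.append(Interval(chrom, start, start + length, name=f"query_{i}"))
    query = IntervalSet(peaks, genome)
    from .genome_intervals import overlap_bp  # local to avoid cycle at import

    observed = overlap_bp(query, ann)
    expected_uniform = f * total_bp(merge(query))
    truth = SimTruth(
        stage="enriched_query",
        seed=seed,
        params={
            "enrich_ratio": enrich_ratio,
            "annotation_fraction": f,
            "realized_ratio": observed / expected_uniform if expected_uniform else None,
            "n_peaks": n_peaks,
        },
    )
    return query, truth


def gen_probe_map(
    genome: GenomeLayout,
    spacing: int = 300,
    dense_regions: IntervalSet | None = None,
    dense_spacing: int = 50,
    seed: int = 0,
) -> ProbeMap:
    """Regularly spaced 1-bp microarray probes, optionally denser inside
    ``dense_regions`` (a two-density genome for matching tests)."""
    probes = []
    dense = {c: arr for c, arr in dense_regions.by_chrom().items()} if dense_regions else {}
    for chrom, length in genome.chromosomes:
        pos = set(range(spacing // 2, length, spacing))
        for s, e in dense.get(chrom, []):
            pos.update(range(int(s), int(e), dense_spacing))
        for p in sorted(pos):
            if p + 1 <= length:
                probes.append(Interval(chrom, int(p), int(p) + 1))
    return ProbeMap(IntervalSet(probes, genome))


def gen_spikein_reads(
    genome: GenomeLayout,
    signal_regions: IntervalSet,
    n_reads: int = 20_000,
    global_scale: dict[str, float] | None = None,
    spike_reads: int = 2000,
    read_length: int = 50,
    n_replicates: int = 2,
    barcodes: tuple[str, ...] = DEFAULT_BARCODES,
    barcode_length: int = 200,
    seed: int = 0,
) -> tuple[dict[tuple[str, int], SampleReads], BarcodePanel, GenomeLayout, SimTruth]:
    """ChIP read sets with a planted condition-level global signal change.

    Genomic reads fall uniformly within ``signal_regions`` (regions weighted
    by length) at a Poisson rate ``n_reads * global_scale[condition]``;
    spike-in barcode reads fall on the barcode contigs at the constant rate
    ``spike_reads`` regardless of condition. Returns samples keyed by
    ``(condition, replicate)``, the barcode panel, the combined layout
    (genome + barcode contigs) and the truth.
    """
    if global_scale is None:
        global_scale = {"reference": 1.0, "test": 0.5}
    if any(g <= 0 for g in global_scale.values()):
        raise ValueError("global_scale values must be > 0")
    panel = BarcodePanel(barcodes)
    combined = genome.extend((b, barcode_length) for b in barcodes)
    regions = [(iv.chrom, iv.start, iv.end) for iv in merge(signal_regions)]
    weights = np.array([e - s for _, s, e in regions], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    samples: dict[tuple[str, int], SampleReads] = {}
    for condition, g in global_scale.items():
        for rep in range(1, n_replicates + 1):
            reads = []
            n_gen = rng.poisson(n_reads * g)
            ks = rng.choice(len(regions), size=n_gen, p=weights)
            for k in ks:
                c, s, e = regions[k]
                hi = max(e - read_length, s + 1)
                start = int(rng.integers(s, hi))
                reads.append(Interval(c, start,
                                      min(start + read_length, combined.length_of(c))))
            n_spike = rng.poisson(spike_reads)
            bs = rng.choice(len(barcodes), size=n_spike)
            for b in bs:
                start = int(rng.integers(barcode_length - read_length))
                reads.append(Interval(barcodes[b], start, start + read_length))
            samples[(condition, rep)] = SampleReads(
                sample_id=f"{condition}_rep{rep}",
                replicate=rep,
                condition=condition,
                reads=IntervalSet(reads, combined),
            )
    truth = SimTruth(
        stage="spikein_reads", seed=seed,
        params={"global_scale": dict(global_scale), "n_reads": n_reads,
                "spike_reads": spike_reads, "n_replicates": n_replicates},
    )
    return samples, panel, combined, truth


def gen_ct_table(
    fold_change: float = 0.5,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    input_percent: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """qPCR Ct table with a planted fold change on target amplicons.

    Two conditions (reference/test), four amplicons (a reference target, a
    second target, a negative-control locus, the spike amplicon). Per-
    replicate IP efficiency varies and is cancelled by spike normalization;
    targets in the test condition carry ``fold_change``; Ct noise is
    normal with SD ``noise_sd`` cycles (technical-triplicate-mean scale).
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    rng = np.random.default_rng(seed)
    amplicons = [
        ("pos_region_1", "reference-target", 8.0),
        ("pos_region_2", "target", 5.0),
        ("neg_region", "negative", 0.2),
        ("snap_spike", "spike", 10.0),
    ]
    rows = []
    for rep in range(1, n_replicates + 1):
        efficiency = float(rng.uniform(0.5, 1.5))
        for condition, fc in (("reference", 1.0), ("test", fold_change)):
            for name, role, base_pct in amplicons:
                if role == "spike":
                    pct = base_pct * efficiency  # constant across conditions
                elif role == "negative":
                    pct = base_pct * efficiency
                else:
                    pct = base_pct * efficiency * fc
                ct_input = 25.0 + rng.normal(0, noise_sd)
                # %input = 2^(ct_input - ct_ip) / input_percent * 100
                delta = np.log2(pct * input_percent / 100.0)
                ct_ip = ct_input - delta + rng.normal(0, noise_sd)
                rows.append(
                    dict(sample_id=f"{condition}_rep{rep}", condition=condition,
                         replicate=rep, amplicon=name, role=role,
                         ct_ip=ct_ip, ct_input=ct_input,
                         input_percent=input_percent)
                )
    truth = SimTruth(
        stage="ct_table", seed=seed,
        params={"fold_change": fold_change, "noise_sd": noise_sd,
                "n_replicates": n_replicates},
    )
    return pd.DataFrame(rows), truth


def gen_peptide_matrix(
    n_proteins: int = 500,
    n_enriched: int = 5,
    effect: float = 8.0,
    peptides_per_protein: int = 5,
    n_bait: int = 3,
    n_control: int = 3,
    channel_cv: float = 0.10,
    seed: int = 0,
) -> tuple[PeptideMatrix, SimTruth]:
    """TMT peptide matrix with a planted set of bait-enriched proteins.

    Peptide base abundances are lognormal; the first ``n_enriched``
    proteins are multiplied by ``effect`` in bait channels; measurement
    noise is lognormal with the given CV. Coisolation interference is
    exponential (mean 10%), so a realistic minority of peptides exceeds
    the 25% filter.
    """
    if effect <= 0 or channel_cv < 0:
        raise ValueError("effect must be > 0 and channel_cv >= 0")
    rng = np.random.default_rng(seed)
    channels = [f"bait_{i+1}" for i in range(n_bait)] + [
        f"ctrl_{i+1}" for i in range(n_control)
    ]
    groups = {c: ("bait" if c.startswith("bait") else "control") for c in channels}
    sigma = float(np.sqrt(np.log1p(channel_cv ** 2)))
    pep_ids, prot_ids, unique_flags, coiso = [], [], [], []
    base = []
    for p in range(n_proteins):
        for q in range(peptides_per_protein):
            pep_ids.append(f"P{p:04d}_pep{q}")
            prot_ids.append(f"P{p:04d}")
            unique_flags.append(bool(rng.random() < 0.95))
            coiso.append(float(min(rng.exponential(10.0), 100.0)))
            base.append(float(rng.lognormal(mean=np.log(1e5), sigma=1.0)))
    base = np.asarray(base)
    enriched = [f"P{p:04d}" for p in range(n_enriched)]
    mat = np.empty((len(base), len(channels)))
    for j, ch in enumerate(channels):
        mult = np.where(
            np.isin(prot_ids, enriched) & (groups[ch] == "bait"), effect, 1.0
        )
        noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=len(base))
        mat[:, j] = base * mult * noise
    abundance = pd.DataFrame(mat, index=pd.Index(pep_ids, name="peptide_id"),
                             columns=channels)
    meta = pd.DataFrame(
        {"protein_id": prot_ids, "is_unique_or_razor": unique_flags,
         "coisolation_pct": coiso},
        index=abundance.index,
    )
    truth = SimTruth(
        stage="peptide_matrix", seed=seed,
        params={"enriched_proteins": enriched, "effect": effect,
                "n_proteins": n_proteins, "channel_cv": channel_cv},
    )
    return PeptideMatrix(abundance, meta, groups), truth


def gen_nucleus_table(
    shift: float = 1.5,
    n_per_replicate: int = 400,
    n_replicates: int = 3,
    marker_sigma: float = 0.4,
    dapi_sigma: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-condition per-nucleus intensity table with a planted median shift.

    Marker and DAPI intensities are lognormal; the test condition's marker
    median is multiplied by ``shift`` (shift=1 is the null). Conditions are
    named ``control`` and ``treated``.
    """
    if shift <= 0:
        raise ValueError("shift must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, s in (("control", 1.0), ("treated", shift)):
        for rep in range(1, n_replicates + 1):
            marker = rng.lognormal(np.log(1000 * s), marker_sigma, n_per_replicate)
            dapi = rng.lognormal(np.log(5000), dapi_sigma, n_per_replicate)
            for i in range(n_per_replicate):
                rows.append(
                    dict(condition=condition, replicate=rep,
                         roi_id=f"{condition}_r{rep}_n{i}",
                         marker_intensity=float(marker[i]),
                         dapi_intensity=float(dapi[i]))
                )
    truth = SimTruth(
        stage="nucleus_table", seed=seed,
        params={"shift": shift, "n_per_replicate": n_per_replicate,
                "n_replicates": n_replicates},
    )
    return pd.DataFrame(rows), truth
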