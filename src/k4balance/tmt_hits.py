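"""TMT reporter-ion quantification and IP-MS hit calling.

Downstream of peptide identification: peptides with coisolation
interference above 25% are discarded, channel abundances are normalized in
two steps (equal totals, then equal medians), peptides are rolled up to
proteins over unique/razor peptides, and each protein is tested bait vs.
control with an equal-variance Student t-test on log2 abundances. A hit is
a protein with p < 0.05 and positive log2 fold change (bait over control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "PeptideMatrix",
    "ProteinResult",
    "filter_coisolation",
    "normalize_channels",
    "protein_rollup",
    "protein_test",
    "call_hits",
    "read_peptide_csv",
]

META_COLUMNS = ("protein_id", "is_unique_or_razor", "coisolation_pct")


@dataclass
class PeptideMatrix:
    """Peptide x channel reporter-ion abundances with peptide metadata.

    ``abundance`` is a DataFrame (rows = peptide_id, columns = channel_id);
    ``meta`` carries per-peptide ``protein_id``, ``is_unique_or_razor`` and
    ``coisolation_pct``; ``groups`` maps channel_id -> "bait" | "control".
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self):
        if not self.abundance.index.equals(self.meta.index):
            raise ValueError("abundance and meta must share the peptide index")
        vals = self.abundance.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("abundances must be finite and >= 0")
        gset = set(self.groups.values())
        if not {"bait", "control"} <= gset:
            raise ValueError("need at least one bait and one control channel")
        missing = set(self.abundance.columns) - set(self.groups)
        if missing:
            raise ValueError(f"channels without group assignment: {sorted(missing)}")

    def channels(self, group: str) -> list[str]:
        return [c for c in self.abundance.columns if self.groups[c] == group]


@dataclass(frozen=True)
class ProteinResult:
    protein_id: str
    mean_bait: float
    mean_control: float
    log2_fc: float
    p: float
    is_hit: bool


def filter_coisolation(m: PeptideMatrix, threshold: float = 25.0) -> PeptideMatrix:
    """Drop peptides with coisolation interference strictly above *threshold*."""
    keep = m.meta["coisolation_pct"] <= threshold
    if not keep.any():
        warnings.warn("all peptides exceed the coisolation threshold; empty matrix")
    return PeptideMatrix(m.abundance.loc[keep], m.meta.loc[keep], dict(m.groups))


def normalize_channels(m: PeptideMatrix) -> PeptideMatrix:
    """Two-step between-channel normalization.

    Step 1 scales every channel so its total equals the across-channel mean
    total (assumes comparable background between IPs). Step 2 divides each
    channel by its median peptide abundance, equalizing channel medians.
    The composed map is idempotent.
    """
    ab = m.abundance.astype(float)
    totals = ab.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero channel total in channels {bad}")
    ab = ab * (totals.mean() / totals)
    medians = ab.median(axis=0)
    if (medians <= 0).any():
        raise ValueError("non-positive channel median after total normalization")
    ab = ab / medians
    return PeptideMatrix(ab, m.meta, dict(m.groups))


def protein_rollup(m: PeptideMatrix) -> pd.DataFrame:
    """Protein x channel matrix: sum of unique/razor peptide abundances.

    Proteins with no qualifying (unique-or-razor) peptide are dropped.
    """
    qual = m.meta["is_unique_or_razor"].astype(bool)
    ab = m.abundance.loc[qual]
    prot = m.meta.loc[qual, "protein_id"]
    return ab.groupby(prot).sum()


def protein_test(
    rollup: pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 0.05,
) -> list[ProteinResult]:
    """Equal-variance Student t-test (log2 abundances), bait vs. control.

    Zero abundances are floored at the smallest positive value in the matrix
    before the log transform. ``log2_fc = mean(bait) - mean(control)`` on
    the log2 scale; a hit requires ``p < alpha`` and ``log2_fc > 0``.
    """
    bait = [c for c in rollup.columns if groups[c] == "bait"]
    ctrl = [c for c in rollup.columns if groups[c] == "control"]
    if len(bait) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 channels per group for a t-test")
    vals = rollup.to_numpy(dtype=float)
    pos = vals[vals > 0]
    floor = pos.min() if pos.size else 1.0
    logged = pd.DataFrame(
        np.log2(np.maximum(vals, floor)), index=rollup.index, columns=rollup.columns
    )
    results = []
    for pid, row in logged.iterrows():
        b, c = row[bait].to_numpy(), row[ctrl].to_numpy()
        if np.allclose(b, b[0]) and np.allclose(c, c[0]) and np.isclose(b[0], c[0]):
            t, p = 0.0, 1.0  # degenerate: all values identical
        else:
            t, p = _sps.ttest_ind(b, c, equal_var=True)
        fc = float(b.mean() - c.mean())
        p = float(p)
        results.append(
            ProteinResult(
                protein_id=str(pid),
                mean_bait=float(b.mean()),
                mean_control=float(c.mean()),
                log2_fc=fc,
                p=p,
                is_hit=bool(p < alpha and fc > 0),
            )
        )
    return results


def read_peptide_csv(matrix_path, design_path) -> PeptideMatrix:
    """Load a peptide matrix from CSV.

    ``matrix_path``: one row per peptide, indexed by ``peptide_id``, with
    the meta columns (protein_id, is_unique_or_razor, coisolation_pct)
    followed by one abundance column per channel. ``design_path``: two
    columns ``channel,group`` with group bait or control.
    """
    df = pd.read_csv(matrix_path, index_col="peptide_id")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide matrix missing columns: {missing}")
    design = pd.read_csv(design_path)
    groups = dict(zip(design["channel"], design["group"]))
    meta = df[list(META_COLUMNS)]
    abundance = df.drop(columns=list(META_COLUMNS))
    return PeptideMatrix(abundance, meta, groups)


def call_hits(
    m: PeptideMatrix,
    coisolation_threshold: float = 25.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full pipeline: filter -> normalize -> rollup -> test.

    Returns a volcano-ready DataFrame (log2_fc, p, neg_log10_p, is_hit),
    one row per protein.
    """
    filt = filter_coisolation(m, coisolation_threshold)
    norm = normalize_channels(filt)
    rollup = protein_rollup(norm)
    res = protein_test(rollup, norm.groups, alpha=alpha)
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in res],
            "mean_bait": [r.mean_bait for r in res],
            "mean_control": [r.mean_control for r in res],
            "log2_fc": [r.log2_fc for r in res],
            "p": [r.p for r in res],
            "neg_log10_p": [-np.log10(r.p) if r.p > 0 else np.inf for r in res],
            "is_hit": [r.is_hit for r in res],
        }
    ).set_index("protein_id")
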