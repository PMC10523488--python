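"""Spike-in-normalized ChIP-qPCR quantification.

Three steps, in order:

1. **Percent enrichment** (percent of input):
   ``%Enrichment = 2^(CtInput - CtIP) / input_percent * 100`` — the standard
   delta-Ct recovery of a locus in the IP relative to the chromatin input,
   corrected for the fraction of chromatin used as input.
2. **Spike normalization**: each locus's percent input divided by the
   percent input of the spike-in (SNAP nucleosome) amplicon of the same
   sample, canceling between-sample IP-efficiency differences.
3. **Reference rescaling**: within each biological replicate, all values
   divided by the spike-normalized signal of the designated reference
   target amplicon in the reference (e.g. wild-type) condition, which is
   thereby fixed at exactly 1 in every replicate.

Technical qPCR triplicates are averaged as mean Ct before the delta-Ct.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "percent_enrichment",
    "spike_normalize",
    "reference_rescale",
    "quantify",
    "read_ct_table",
]

REQUIRED_COLUMNS = (
    "sample_id", "condition", "replicate", "amplicon", "role",
    "ct_ip", "ct_input", "input_percent",
)
ROLES = {"target", "negative", "spike", "reference-target"}


def percent_enrichment(ct_input, ct_ip, input_percent):
    """``2^(ct_input - ct_ip) / input_percent * 100`` (vectorized)."""
    ct_input = np.asarray(ct_input, dtype=float)
    ct_ip = np.asarray(ct_ip, dtype=float)
    input_percent = np.asarray(input_percent, dtype=float)
    if not (np.all(np.isfinite(ct_input)) and np.all(np.isfinite(ct_ip))):
        raise ValueError("Ct values must be finite")
    if np.any(input_percent <= 0):
        raise ValueError("input_percent must be > 0")
    return 2.0 ** (ct_input - ct_ip) / input_percent * 100.0


def spike_normalize(locus_pct, spike_pct):
    """Percent input of a locus divided by that of the spike-in amplicon."""
    spike_pct = np.asarray(spike_pct, dtype=float)
    if np.any(spike_pct <= 0):
        raise ValueError("spike percent input must be > 0")
    return np.asarray(locus_pct, dtype=float) / spike_pct


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad_roles = set(table["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"unknown amplicon roles: {sorted(bad_roles)}")
    if table.groupby(["condition", "replicate"], sort=False).apply(
        lambda g: (g["role"] == "spike").sum(), include_groups=False
    ).ne(1).any():
        raise ValueError("each (condition, replicate) needs exactly one spike amplicon")
    if len(set(table.loc[table["role"] == "reference-target", "amplicon"])) != 1:
        raise ValueError("exactly one amplicon must be flagged reference-target")


def reference_rescale(
    table: pd.DataFrame,
    value_col: str = "spike_normalized",
    reference_condition: str = "reference",
) -> pd.Series:
    """Divide each replicate's values by its reference-amplicon/WT value.

    The divisor for replicate r is the ``value_col`` of the row with role
    ``reference-target`` in ``reference_condition`` for that replicate; the
    rescaled value of that row is therefore exactly 1.
    """
    out = pd.Series(np.nan, index=table.index, dtype=float)
    for rep, grp in table.groupby("replicate", sort=False):
        ref_rows = grp[(grp["role"] == "reference-target")
                       & (grp["condition"] == reference_condition)]
        if len(ref_rows) != 1:
            raise ValueError(
                f"replicate {rep}: expected exactly one reference-target "
                f"measurement in condition {reference_condition!r}, "
                f"found {len(ref_rows)}"
            )
        ref_val = float(ref_rows[value_col].iloc[0])
        if ref_val <= 0:
            raise ValueError(f"replicate {rep}: non-positive reference value")
        out.loc[grp.index] = grp[value_col] / ref_val
    return out


def quantify(table: pd.DataFrame, reference_condition: str = "reference") -> pd.DataFrame:
    """Full pipeline: percent enrichment -> spike normalization -> rescaling.

    Returns a copy of the table with ``pct_enrichment``, ``spike_normalized``
    and ``rescaled`` columns appended.
    """
    _validate(table)
    out = table.copy()
    out["pct_enrichment"] = percent_enrichment(
        out["ct_input"], out["ct_ip"], out["input_percent"]
    )
    spike_by_sample = (
        out[out["role"] == "spike"]
        .set_index(["condition", "replicate"])["pct_enrichment"]
    )
    keys = pd.MultiIndex.from_frame(out[["condition", "replicate"]])
    out["spike_normalized"] = spike_normalize(
        out["pct_enrichment"].to_numpy(),
        spike_by_sample.reindex(keys).to_numpy(),
    )
    out["rescaled"] = reference_rescale(
        out, "spike_normalized", reference_condition
    )
    return out


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table CSV and check its columns."""
    table = pd.read_csv(path)
    _validate(table)
    return table
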