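"""Per-nucleus quantitative immunofluorescence analysis.

Each nucleus (an ROI segmented on the DAPI channel) contributes one
measurement: marker intensity divided by DAPI intensity, normalizing for
per-cell DNA content. Replicates of a condition are pooled, 1,000 cells are
sampled without replacement per condition, and group differences are tested
with the Kruskal-Wallis rank test (tie-corrected H, chi-square p). Pairwise
Mann-Whitney tests with Holm correction serve as the post-hoc; a one-way
ANOVA + Tukey path is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "REQUIRED_COLUMNS",
    "normalize_to_dna",
    "sample_cells",
    "kruskal_wallis",
    "pairwise_posthoc",
    "anova_tukey",
    "compare_conditions",
]

REQUIRED_COLUMNS = ("condition", "replicate", "roi_id",
                    "marker_intensity", "dapi_intensity")


def normalize_to_dna(marker, dapi):
    """Marker intensity per unit DAPI (DNA content) — scale invariant."""
    marker = np.asarray(marker, dtype=float)
    dapi = np.asarray(dapi, dtype=float)
    if np.any(dapi <= 0):
        raise ValueError("DAPI intensity must be > 0")
    return marker / dapi


def sample_cells(
    table: pd.DataFrame,
    condition: str,
    n: int = 1000,
    seed: int = 0,
    stratify_replicates: bool = False,
) -> np.ndarray:
    """Pool a condition's replicates and sample *n* nuclei without replacement.

    Returns DAPI-normalized ratios. If the pool holds fewer than *n* nuclei
    all of them are returned (with a warning). ``stratify_replicates``
    samples n/replicate from each replicate instead of from the pool.
    """
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no nuclei for condition {condition!r}")
    rng = np.random.default_rng(seed)
    ratios = normalize_to_dna(sub["marker_intensity"], sub["dapi_intensity"])
    if stratify_replicates:
        reps = sub["replicate"].unique()
        per = n // len(reps)
        parts = []
        for rep in reps:
            r = ratios[(sub["replicate"] == rep).to_numpy()]
            take = min(per, len(r))
            parts.append(rng.choice(r, size=take, replace=False))
        return np.concatenate(parts)
    if len(ratios) < n:
        warnings.warn(
            f"condition {condition!r} has only {len(ratios)} nuclei (< {n}); "
            "using all of them"
        )
        return rng.permutation(ratios)
    return rng.choice(ratios, size=n, replace=False)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # degenerate: every observation tied
    h, p = _sps.kruskal(*arrays)
    return float(h), float(p)


def pairwise_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Holm-corrected pairwise two-sided Mann-Whitney U tests."""
    names = list(samples)
    pairs, raw_p, stat = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u, p = _sps.mannwhitneyu(
                samples[names[i]], samples[names[j]], alternative="two-sided"
            )
            pairs.append((names[i], names[j]))
            raw_p.append(p)
            stat.append(u)
    adj = multipletests(raw_p, method="holm")[1] if raw_p else []
    return pd.DataFrame(
        {"group_a": [a for a, _ in pairs], "group_b": [b for _, b in pairs],
         "U": stat, "p": raw_p, "p_holm": adj}
    )


def anova_tukey(samples: dict[str, np.ndarray]):
    """Alternative parametric path: one-way ANOVA F test + Tukey HSD."""
    groups = list(samples.values())
    f, p = _sps.f_oneway(*groups)
    tukey = _sps.tukey_hsd(*groups)
    return float(f), float(p), tukey


def compare_conditions(
    table: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    method: str = "kruskal",
) -> dict:
    """End-to-end comparison across all conditions in a nucleus table.

    Samples *n* DAPI-normalized nuclei per condition (seeded per condition)
    and tests for a group difference. Returns a dict with the sampled
    ratios, the omnibus statistic and p, and the pairwise post-hoc table.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nucleus table missing columns: {missing}")
    conditions = list(dict.fromkeys(table["condition"]))
    samples = {
        cond: sample_cells(table, cond, n=n, seed=seed + k)
        for k, cond in enumerate(conditions)
    }
    if method == "kruskal":
        stat, p = kruskal_wallis(*samples.values())
        posthoc = pairwise_posthoc(samples)
    elif method == "anova":
        stat, p, tukey = anova_tukey(samples)
        posthoc = pd.DataFrame(
            {"group_a": [], "group_b": [], "p": []}
        ) if len(samples) < 2 else _tukey_frame(list(samples), tukey)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"samples": samples, "statistic": stat, "p": p,
            "method": method, "posthoc": posthoc}


def _tukey_frame(names, tukey) -> pd.DataFrame:
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append((names[i], names[j], float(tukey.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p"])
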