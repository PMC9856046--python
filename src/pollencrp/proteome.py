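"""Post-processing of peptide-spectrum match (PSM) and protein tables.

Covers the downstream, score-level part of a target–decoy proteomics
workflow: FDR estimation against a reversed-sequence decoy database with
high/medium confidence tiers, union-merging of replicate identification
lists with relative abundance, molecular-weight profiling, and generic
set-overlap reports.  Spectral search scoring itself is out of scope.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Confidence tier boundaries on the q-value: high <= 1%, medium <= 5%.
TIER_HIGH = 0.01
TIER_MEDIUM = 0.05


@dataclass(frozen=True)
class FDRConfig:
    high: float = TIER_HIGH
    medium: float = TIER_MEDIUM
    pseudocount: bool = False  # (#decoy + 1)/#target variant


def psm_fdr(psms: pd.DataFrame, config: FDRConfig | None = None) -> pd.DataFrame:
    """Assign target–decoy FDR, q-values and confidence tiers to PSMs.

    Expects columns ``score`` (higher is better) and ``is_decoy``.  At a
    score threshold s, FDR(s) = #decoys >= s / #targets >= s (1.0 when no
    target passes); the q-value is the minimum FDR over all thresholds
    that still accept the PSM, which makes it non-increasing in score.
    Decoys are counted before targets at tied scores (conservative).
    Tiers: q <= 1% high, 1% < q <= 5% medium, else excluded; the 1%
    boundary is treated as high-confidence inclusive.
    """
    config = config or FDRConfig()
    if "score" not in psms or "is_decoy" not in psms:
        raise ValueError("PSM table needs 'score' and 'is_decoy' columns")
    if len(psms) == 0 or not (~psms.is_decoy.astype(bool)).any():
        raise ValueError("no target PSMs to estimate FDR from")

    df = psms.copy()
    # decoys first at ties: sort by score desc, then is_decoy desc
    order = df.sort_values(["score", "is_decoy"], ascending=[False, False]).index
    sorted_df = df.loc[order]
    decoy = sorted_df.is_decoy.to_numpy(dtype=bool)
    scores = sorted_df.score.to_numpy(dtype=float)
    n_decoy = np.cumsum(decoy) + (1 if config.pseudocount else 0)
    n_target = np.cumsum(~decoy)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_target > 0, n_decoy / np.maximum(n_target, 1), 1.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    # a threshold accepts whole tied-score groups: every row takes the FDR
    # at the last row of its score group
    group_end = np.searchsorted(-scores, -scores, side="right") - 1
    fdr = fdr[group_end]
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    tier = np.where(q <= config.high, "high", np.where(q <= config.medium, "medium", "excluded"))
    df.loc[order, "fdr"] = fdr
    df.loc[order, "q_value"] = q
    df.loc[order, "tier"] = tier
    return df


def merge_replicates(replicates: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union-merge per-replicate protein lists into one identification table.

    Each replicate table needs ``protein_id`` and may carry ``area`` (summed
    peptide area) and ``molecular_weight``.  Duplicate ids within one
    replicate are collapsed with summed area (and logged).  The output has
    one row per protein with ``n_replicates``, total ``area`` and
    ``rel_abundance_pct`` (percentage of total peptide area, summing to
    100).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    frames = []
    for rep_id, table in replicates.items():
        if "protein_id" not in table:
            raise ValueError(f"replicate {rep_id!r} lacks 'protein_id'")
        t = table.copy()
        if t.protein_id.duplicated().any():
            dups = t.protein_id[t.protein_id.duplicated()].unique()
            logger.warning(
                "replicate %s: %d duplicate protein ids collapsed (summed area)",
                rep_id,
                len(dups),
            )
            agg = {"area": "sum"} if "area" in t else {}
            keep = {
                c: "first" for c in t.columns if c not in ("protein_id", "area")
            }
            t = t.groupby("protein_id", as_index=False).agg({**agg, **keep})
        t["replicate"] = rep_id
        frames.append(t)
    allrows = pd.concat(frames, ignore_index=True)
    has_area = "area" in allrows
    agg = {"replicate": "nunique"}
    if has_area:
        agg["area"] = "sum"
    if "molecular_weight" in allrows:
        agg["molecular_weight"] = "first"
    merged = allrows.groupby("protein_id", as_index=False).agg(agg)
    merged = merged.rename(columns={"replicate": "n_replicates"})
    if has_area:
        total = merged.area.sum()
        merged["rel_abundance_pct"] = 100.0 * merged.area / total if total > 0 else 0.0
    return merged.sort_values("protein_id", ignore_index=True)


DEFAULT_MW_EDGES = (20.0, 40.0, 60.0)  # kDa; bins <20, 20-40, 40-60, >=60


def size_profile(weights_kda, edges=DEFAULT_MW_EDGES) -> pd.DataFrame:
    """Fraction of proteins per molecular-weight bin.

    Default bins (<20, 20-40, 40-60, >=60 kDa) follow the conventional
    presentation of pollen coat proteome size distributions.
    """
    w = np.asarray(weights_kda, dtype=float)
    if w.size == 0:
        raise ValueError("no molecular weights supplied")
    if np.any(w <= 0):
        raise ValueError("molecular weights must be positive")
    full_edges = np.concatenate([[0.0], np.asarray(edges, dtype=float), [np.inf]])
    counts, _ = np.histogram(w, bins=full_edges)
    labels = []
    for lo, hi in zip(full_edges[:-1], full_edges[1:]):
        if lo == 0:
            labels.append(f"<{hi:g}")
        elif np.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    return pd.DataFrame({"bin_kda": labels, "count": counts, "fraction": counts / w.size})


MEAN_RESIDUE_MASS_DA = 110.0  # average amino-acid residue mass


def molecular_weight_kda(sequence: str) -> float:
    """Rough molecular weight from length via the mean residue mass."""
    return len(sequence) * MEAN_RESIDUE_MASS_DA / 1000.0


def overlap_report(named_sets: dict[str, set], max_order: int | None = None) -> pd.DataFrame:
    """Pairwise and k-way intersection counts of named sets."""
    names = list(named_sets)
    max_order = max_order or len(names)
    rows = []
    for k in range(1, max_order + 1):
        for combo in itertools.combinations(names, k):
            inter = set.intersection(*(set(named_sets[n]) for n in combo))
            rows.append({"sets": "&".join(combo), "order": k, "n": len(inter)})
    return pd.DataFrame(rows)
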