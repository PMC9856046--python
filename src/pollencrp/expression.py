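"""Count normalization and tissue-specificity categorization.

RNA-seq style gene x tissue count matrices are normalized with the
median-of-ratios size-factor method, then each gene is assigned one of
four expression categories relative to three tissue roles:

* ``target`` — mature-anther tissues (opened anthers, anthers of the
  mature flower), where pollen-coat genes are expected to peak;
* ``auxiliary`` — earlier floral stages (anthers of young flowers, young
  flower buds);
* ``reference`` — vegetative and female tissues (mature leaf, root apex,
  carpels, stigmatic tissue), where "specific" genes should be silent.

A gene is mature-anther-specific when it is expressed in the target
tissues and every reference tissue shows very little to no signal —
quantified as at most 5% of the target peak and at most 5 normalized
counts (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLES = ("target", "auxiliary", "reference")

CATEGORIES = (
    "mature-anther-specific",
    "young-anther/bud-enriched",
    "broadly-expressed",
    "not-expressed",
)


def median_of_ratios(counts: pd.DataFrame, pseudo_reference: bool = False):
    """Median-of-ratios size factors and the normalized matrix.

    The per-gene reference is the geometric mean across samples, restricted
    to genes with nonzero counts in every sample; each sample's size factor
    is the median ratio of its counts to that reference, and normalized
    counts are counts divided by the factor.  With ``pseudo_reference=True``
    the geometric mean is taken over positive entries only, relaxing the
    all-nonzero requirement for sparse matrices.

    Returns ``(size_factors: Series, normalized: DataFrame)``.
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        log_ref = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_ref)
    else:
        usable = (mat > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has nonzero counts in all samples; "
                "use pseudo_reference=True"
            )
        log_ref = np.full(mat.shape[0], np.nan)
        log_ref[usable] = np.log(mat[usable]).mean(axis=1)
    factors = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        ok = usable & (col > 0)
        if not ok.any():
            raise ValueError(f"sample {counts.columns[j]!r} shares no reference gene")
        factors.append(float(np.median(col[ok] / np.exp(log_ref[ok]))))
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    return size_factors, normalized


@dataclass(frozen=True)
class SpecificityConfig:
    expressed_floor: float = 10.0  # min normalized counts to call "expressed"
    leakage_fraction: float = 0.05  # reference allowed up to 5% of target peak
    leakage_floor: float = 5.0  # ... or up to this absolute level


def classify_specificity(
    normalized: pd.DataFrame,
    roles: dict[str, str],
    config: SpecificityConfig | None = None,
) -> pd.DataFrame:
    """Assign each gene one expression category given tissue roles.

    Rules, applied in order:

    1. not-expressed — every tissue below ``expressed_floor``;
    2. mature-anther-specific — target peak >= floor and every reference
       tissue <= max(leakage_fraction * target peak, leakage_floor);
    3. young-anther/bud-enriched — auxiliary peak >= floor, exceeds the
       target peak, and references satisfy the same leakage bound relative
       to the auxiliary peak;
    4. broadly-expressed — everything else.
    """
    config = config or SpecificityConfig()
    missing = set(normalized.columns) - set(roles)
    if missing:
        raise ValueError(f"tissues without a role: {sorted(missing)}")
    bad = set(roles.values()) - set(ROLES)
    if bad:
        raise ValueError(f"unknown roles {sorted(bad)}; expected {ROLES}")
    cols = {r: [c for c in normalized.columns if roles[c] == r] for r in ROLES}
    if not cols["target"] or not cols["reference"]:
        raise ValueError("need at least one target and one reference tissue")

    tgt = normalized[cols["target"]].max(axis=1)
    aux = normalized[cols["auxiliary"]].max(axis=1) if cols["auxiliary"] else pd.Series(0.0, index=normalized.index)
    ref = normalized[cols["reference"]].max(axis=1)
    peak = normalized.max(axis=1)

    def leak_ok(peak_signal):
        bound = np.maximum(config.leakage_fraction * peak_signal, config.leakage_floor)
        return ref <= bound

    labels = np.full(len(normalized), "broadly-expressed", dtype=object)
    labels[(aux >= config.expressed_floor) & (aux > tgt) & leak_ok(aux)] = (
        "young-anther/bud-enriched"
    )
    labels[(tgt >= config.expressed_floor) & leak_ok(tgt)] = "mature-anther-specific"
    labels[peak < config.expressed_floor] = "not-expressed"

    return pd.DataFrame(
        {
            "category": labels,
            "target_peak": tgt,
            "auxiliary_peak": aux,
            "reference_peak": ref,
        },
        index=normalized.index,
    )


def read_count_matrix(path):
    """TSV count matrix with a two-row header: tissue names then roles.

    Returns ``(counts: DataFrame, roles: dict)``.
    """
    head = pd.read_csv(path, sep="\t", nrows=1, index_col=0)
    roles = {c: str(head.iloc[0][c]).strip() for c in head.columns}
    counts = pd.read_csv(path, sep="\t", skiprows=[1], index_col=0)
    return counts, roles


def write_count_matrix(path, counts: pd.DataFrame, roles: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(counts.columns) + "\n")
        fh.write("#role\t" + "\t".join(roles[c] for c in counts.columns) + "\n")
        counts.to_csv(fh, sep="\t", header=False)
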