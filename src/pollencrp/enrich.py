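"""Term over-representation statistics for annotated item sets.

Each term is tested with a one-sided Fisher's exact test (hypergeometric
upper tail) of the sample against an annotated background, fold enrichment
is reported relative to the expected count, p-values are corrected with
the Benjamini–Hochberg step-up FDR procedure, and a reporting filter keeps
terms with fold enrichment > 3 and p < 0.05.  Terms are flat labels; no
ontology-graph propagation is performed.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def read_annotation_table(path) -> pd.DataFrame:
    """Two-column TSV (item <TAB> term) into a tidy annotation frame."""
    df = pd.read_csv(path, sep="\t", header=None, names=["item", "term"], comment="#")
    return df.drop_duplicates()


def fisher_enrich(sample, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-term over-representation of *sample* against the background.

    ``annotations`` maps background items to terms (columns ``item`` and
    ``term``); the background universe is the set of annotated items.
    Sample items missing from the background are dropped with a warning.
    For each term: k = sample hits, n = sample size, K = background hits,
    N = background size; fold = (k/n)/(K/N); p is the one-sided
    hypergeometric tail P(X >= k).
    """
    if "item" not in annotations or "term" not in annotations:
        raise ValueError("annotation table needs 'item' and 'term' columns")
    background = set(annotations["item"])
    if not background:
        raise ValueError("empty background")
    sample = set(sample)
    if not sample:
        raise ValueError("empty sample")
    missing = sample - background
    if missing:
        logger.warning("%d sample items absent from background; dropped", len(missing))
        sample &= background
        if not sample:
            raise ValueError("no sample items remain within the background")

    N = len(background)
    n = len(sample)
    ann = annotations.drop_duplicates()
    rows = []
    for term, grp in ann.groupby("term", sort=True):
        members = set(grp["item"])
        K = len(members)
        k = len(members & sample)
        expected = n * K / N
        fold = (k / n) / (K / N) if K > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "expected": expected,
                "fold": fold,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(pvalues) -> "pd.Series | list":
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    import numpy as np

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def report_filter(
    results: pd.DataFrame, fold_min: float = 3.0, p_max: float = 0.05
) -> pd.DataFrame:
    """Reporting filter: strict fold > fold_min and p < p_max, sorted by p."""
    if results.empty:
        return results
    keep = results[(results["fold"] > fold_min) & (results["p"] < p_max)]
    return keep.sort_values(["p", "term"], ignore_index=True)
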