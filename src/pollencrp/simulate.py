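"""Ground-truth-labelled synthetic data for every stage of the pipeline.

Each generator emulates the statistical structure its consumer assumes:
CRP sequences drawn from (or knocked out of) the family cysteine grammars;
codon alignments evolved along a tree under site-class omega mixtures;
target/decoy PSM score tables as Gaussian mixtures; negative-binomial
gene x tissue count matrices with planted tissue-specific genes; and
annotation tables with planted enriched terms.  All generators are
deterministic under a fixed seed and emit truth tables alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grammar import CysPattern, ProteinRecord
from .selection.alignment import CodonAlignment, PhyloTree
from .selection.codon import N_CODONS
from .selection.likelihood import category_matrices

_NON_CYS = "ADEFGHIKLMNPQRSTVWY"  # 19 residues; spacers are cysteine-free
_HYDROPHOBIC = "AVLIMFW"


# ---------------------------------------------------------------------------
# CRP sequences

def _sample_from_pattern(pattern: CysPattern, rng: np.random.Generator) -> str:
    parts = ["C"]
    for lo, hi in pattern.spacers:
        k = int(rng.integers(lo, hi + 1))
        parts.append("".join(rng.choice(list(_NON_CYS), size=k)))
        parts.append("C")
    return "".join(parts)


def gen_crp_proteins(
    class_defs,
    n_per_class: int,
    seed: int = 0,
    n_prefix: tuple[int, int] = (0, 8),
    hydrophobic_prefix: bool = False,
    knockouts: bool = False,
):
    """Generate CRP sequences obeying (or violating) the family grammars.

    For each class, sequences cycle over the per-species patterns; spacer
    lengths are uniform within the pattern ranges and spacer residues
    uniform over the 19 non-cysteine amino acids.  With ``knockouts=True``
    a negative set is produced instead by substituting one conserved
    cysteine of each positive with serine.

    Returns ``(records, truth)`` where truth has columns protein_id,
    class_id, pattern_species, is_knockout.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    rows = []
    for cdef in class_defs:
        for i in range(n_per_class):
            pat = cdef.patterns[i % len(cdef.patterns)]
            core = _sample_from_pattern(pat, rng)
            alphabet = _HYDROPHOBIC if hydrophobic_prefix else _NON_CYS
            npre = int(rng.integers(n_prefix[0], n_prefix[1] + 1))
            prefix = "".join(rng.choice(list(alphabet), size=npre))
            seq = prefix + core
            if knockouts:
                cys_positions = [j for j, aa in enumerate(seq) if aa == "C"]
                hit = int(rng.choice(cys_positions))
                seq = seq[:hit] + "S" + seq[hit + 1 :]
            pid = f"{'ko' if knockouts else 'crp'}_{cdef.class_id.replace('/', '-')}_{i:04d}"
            records.append(
                ProteinRecord(id=pid, sequence=seq, species=pat.species_tag)
            )
            rows.append(
                {
                    "protein_id": pid,
                    "class_id": cdef.class_id,
                    "pattern_species": pat.species_tag,
                    "is_knockout": knockouts,
                }
            )
    return records, pd.DataFrame(rows)


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# codon alignments

def random_tree(n_taxa: int, seed: int = 0, mean_branch: float = 0.1) -> PhyloTree:
    """Random coalescent-shaped topology with exponential branch lengths."""
    rng = np.random.default_rng(seed)
    taxa = tuple(f"t{i + 1}" for i in range(n_taxa))
    # successive random joins; node ids: leaves 0..n-1, internals appended
    nodes = list(range(n_taxa))
    parent = {}
    blen = {}
    next_id = n_taxa
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent[a] = next_id
        parent[b] = next_id
        blen[a] = float(rng.exponential(mean_branch))
        blen[b] = float(rng.exponential(mean_branch))
        nodes = [n for n in nodes if n not in (a, b)] + [next_id]
        next_id += 1
    root = next_id
    for n in nodes:
        parent[n] = root
        blen[n] = float(rng.exponential(mean_branch))
    n_nodes = root + 1
    parr = np.full(n_nodes, -1, dtype=int)
    barr = np.zeros(n_nodes)
    for n, p in parent.items():
        parr[n] = p
        barr[n] = blen[n]
    return PhyloTree(taxa=taxa, parent=parr, branch_lengths=barr, root=root)


def sim_codon_alignment(
    tree: PhyloTree,
    kappa: float,
    omegas,
    class_weights,
    freqs,
    n_sites: int,
    seed: int = 0,
):
    """Evolve a gap-free codon alignment under a site-class omega mixture.

    Per site, an omega class is drawn from ``class_weights``; the root
    codon is drawn from the equilibrium frequencies and propagated along
    each branch with that class's transition matrix.  Rate scaling follows
    the mixture-average convention of the likelihood machinery, so branch
    lengths mean expected substitutions/codon averaged over classes.

    Returns ``(alignment, site_classes)``.
    """
    rng = np.random.default_rng(seed)
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    w = np.asarray(class_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w < 0):
        raise ValueError("class weights must be a probability vector")
    freqs = np.asarray(freqs, dtype=float)
    pmats = category_matrices(
        kappa, omegas, freqs, tree.branch_lengths, class_weights=w
    )
    site_class = rng.choice(len(omegas), size=n_sites, p=w)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(N_CODONS, size=n_sites, p=freqs / freqs.sum())
    # preorder: parents before children
    order = list(reversed([int(i) for i in tree.order()]))
    for node in order:
        p = int(tree.parent[node])
        for k in range(len(omegas)):
            mask = site_class == k
            if not mask.any():
                continue
            pm = pmats[k, node]
            pm = pm / pm.sum(axis=1, keepdims=True)
            src = states[p, mask]
            u = rng.random(src.size)
            cdf = np.cumsum(pm[src], axis=1)
            states[node, mask] = np.minimum(
                (u[:, None] > cdf).sum(axis=1), N_CODONS - 1
            )
    aln = CodonAlignment.from_indices(tree.taxa, states[: tree.n_leaves])
    return aln, site_class


# ---------------------------------------------------------------------------
# PSM tables

@dataclass(frozen=True)
class PSMScoreModel:
    """Gaussian-mixture score model for target and decoy PSMs.

    Targets are a mixture of true matches N(mu_true, sd) with proportion
    pi_true and null matches N(mu_null, sd); decoys are all null.
    """

    mu_true: float = 4.0
    mu_null: float = 0.0
    sd: float = 1.0
    pi_true: float = 0.6


def gen_psm_table(
    n_target: int,
    n_decoy: int,
    model: PSMScoreModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic PSM score table with truth column ``is_true_match``."""
    model = model or PSMScoreModel()
    rng = np.random.default_rng(seed)
    is_true = rng.random(n_target) < model.pi_true
    t_scores = np.where(
        is_true,
        rng.normal(model.mu_true, model.sd, n_target),
        rng.normal(model.mu_null, model.sd, n_target),
    )
    d_scores = rng.normal(model.mu_null, model.sd, n_decoy)
    df = pd.DataFrame(
        {
            "spectrum_id": [f"s{i:05d}" for i in range(n_target + n_decoy)],
            "peptide": [f"PEP{i:05d}" for i in range(n_target + n_decoy)],
            "protein_id": [f"prot{i % max((n_target + n_decoy) // 4, 1):04d}" for i in range(n_target + n_decoy)],
            "score": np.concatenate([t_scores, d_scores]),
            "is_decoy": np.concatenate(
                [np.zeros(n_target, bool), np.ones(n_decoy, bool)]
            ),
            "is_true_match": np.concatenate([is_true, np.zeros(n_decoy, bool)]),
        }
    )
    return df


# ---------------------------------------------------------------------------
# expression matrices

DEFAULT_TISSUE_ROLES = {
    "opened_anther": "target",
    "mature_anther": "target",
    "young_anther": "auxiliary",
    "young_flower": "auxiliary",
    "leaf": "reference",
    "root_apex": "reference",
    "carpel": "reference",
    "stigma": "reference",
}


def gen_expression_matrix(
    n_genes: int = 200,
    n_specific: int = 30,
    tissue_roles: dict[str, str] | None = None,
    base_mean: float = 80.0,
    specific_mean: float = 400.0,
    dispersion: float = 0.3,
    seed: int = 0,
):
    """Negative-binomial count matrix with planted mature-anther-specific genes.

    The first ``n_specific`` genes express only in target tissues (mean
    ``specific_mean``) with zero reference-tissue signal; the rest are
    broadly expressed around ``base_mean`` with log-normal gene effects.
    Library sizes vary per tissue so normalization matters.

    Returns ``(counts, roles, truth)`` with truth column ``is_specific``.
    """
    roles = dict(tissue_roles or DEFAULT_TISSUE_ROLES)
    rng = np.random.default_rng(seed)
    tissues = list(roles)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    gene_effect = rng.lognormal(0.0, 0.6, size=n_genes)
    lib = rng.uniform(0.5, 2.0, size=len(tissues))
    mean = np.zeros((n_genes, len(tissues)))
    for j, t in enumerate(tissues):
        role = roles[t]
        for i in range(n_genes):
            if i < n_specific:
                mu = specific_mean * gene_effect[i] if role == "target" else 0.0
            else:
                mu = base_mean * gene_effect[i]
            mean[i, j] = mu * lib[j]
    r = 1.0 / dispersion
    p = r / (r + np.clip(mean, 1e-9, None))
    counts = np.where(mean > 0, rng.negative_binomial(r, p), 0)
    df = pd.DataFrame(counts, index=genes, columns=tissues)
    truth = pd.DataFrame(
        {"gene": genes, "is_specific": [i < n_specific for i in range(n_genes)]}
    )
    return df, roles, truth


# ---------------------------------------------------------------------------
# annotation tables

def gen_annotation_table(
    n_items: int = 2000,
    n_terms: int = 50,
    n_sample: int = 100,
    enriched_terms: int = 5,
    base_rate: float = 0.05,
    enrichment: float = 8.0,
    seed: int = 0,
):
    """Annotation table and sample with planted over-represented terms.

    Background items carry each term with probability ``base_rate``; the
    sample is re-drawn so that for the first ``enriched_terms`` terms the
    membership probability is multiplied by ``enrichment``.

    Returns ``(annotations, sample_items, truth)``.
    """
    rng = np.random.default_rng(seed)
    items = [f"item{i:05d}" for i in range(n_items)]
    terms = [f"TERM:{j:04d}" for j in range(n_terms)]
    membership = rng.random((n_items, n_terms)) < base_rate
    sample_idx = rng.choice(n_items, size=n_sample, replace=False)
    enriched_p = min(base_rate * enrichment, 0.95)
    for j in range(enriched_terms):
        membership[sample_idx, j] = rng.random(n_sample) < enriched_p
    rows = [
        {"item": items[i], "term": terms[j]}
        for i, j in zip(*np.nonzero(membership))
    ]
    annotations = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"term": terms, "is_enriched": [j < enriched_terms for j in range(n_terms)]}
    )
    return annotations, [items[i] for i in sample_idx], truth
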