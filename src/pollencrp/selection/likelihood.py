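"""Phylogenetic likelihood for codon mixture models via Felsenstein pruning.

Site likelihoods are computed on compressed site patterns, batched over the
omega categories of a mixture, with per-pattern rescaling to avoid
underflow.  The tree is treated as rooted at an arbitrary node; under the
reversible codon model the likelihood is invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment, PhyloTree
from .codon import N_CODONS, gy94_generator, mean_rate

_TINY = 1e-300


@dataclass
class PackedData:
    """Alignment compressed to unique site patterns, aligned to a tree."""

    tree: PhyloTree
    patterns: np.ndarray  # (n_taxa, n_patterns) codon index or -1
    weights: np.ndarray  # pattern multiplicities
    site_of_pattern: np.ndarray  # pattern index per original site
    postorder_internal: list  # internal nodes, children before parents
    children: dict  # node -> list of child nodes

    @classmethod
    def build(cls, alignment: CodonAlignment, tree: PhyloTree) -> "PackedData":
        if set(alignment.taxa) != set(tree.taxa):
            raise ValueError("alignment and tree taxa differ")
        row = [alignment.taxa.index(t) for t in tree.taxa]
        mat = alignment.codon_matrix[row]
        patterns, site_of_pattern, weights = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        order = tree.order()
        children: dict[int, list[int]] = {}
        for i in order:
            children.setdefault(int(tree.parent[i]), []).append(int(i))
        internal = [int(i) for i in order if int(i) >= tree.n_leaves]
        internal.append(int(tree.root))
        return cls(tree, patterns, weights.astype(float), site_of_pattern, internal, children)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_sites(self) -> int:
        return self.site_of_pattern.size


def category_matrices(
    kappa, omegas, freqs, branch_lengths, rate_scale=None, class_weights=None
):
    """Transition matrices P_k(t_b) for each omega category and branch.

    ``rate_scale`` overrides the normalization constant; by default every
    category matrix is scaled by the class-weighted average equilibrium
    rate of the mixture, so a branch length is the expected
    substitutions/codon averaged over site classes (the same convention
    the simulator uses).  Zero-weight classes therefore do not perturb the
    scale, which keeps nested models exactly comparable.
    """
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    qs = [gy94_generator(kappa, w, freqs, scale=False) for w in omegas]
    if rate_scale is None:
        rates = np.array([mean_rate(q, freqs) for q in qs])
        if class_weights is None:
            rate_scale = float(rates.mean())
        else:
            w = np.asarray(class_weights, dtype=float)
            rate_scale = float((w * rates).sum() / w.sum())
    if rate_scale <= 0:
        rate_scale = 1.0
    bl = np.clip(np.asarray(branch_lengths, dtype=float), 0.0, None)
    freqs = np.asarray(freqs, dtype=float)
    sqrtp = np.sqrt(np.clip(freqs, 1e-300, None))
    bs = np.stack([(q / rate_scale) * sqrtp[:, None] / sqrtp[None, :] for q in qs])
    bs = 0.5 * (bs + bs.transpose(0, 2, 1))
    evals, u = np.linalg.eigh(bs)  # batched over categories
    right = u / sqrtp[None, :, None]
    left = u.transpose(0, 2, 1) * sqrtp[None, None, :]
    expvals = np.exp(evals[:, None, :] * bl[None, :, None])  # (K, B, 61)
    pmats = np.einsum("kij,kbj,kjl->kbil", right, expvals, left, optimize=True)
    return np.clip(pmats, 0.0, None)


def site_logliks_by_category(
    packed: PackedData, pmats: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """``log f(pattern | category)`` with shape (K, n_patterns).

    Pruning is batched over categories: partials have shape
    (K, n_patterns, 61); each child edge applies its category's transition
    matrix; per-pattern rescaling keeps values in range.
    """
    tree = packed.tree
    K = pmats.shape[0]
    npat = packed.n_patterns
    eye = np.eye(N_CODONS)
    partials: dict[int, np.ndarray] = {}
    for leaf in range(tree.n_leaves):
        states = packed.patterns[leaf]
        lp = np.where(states[:, None] >= 0, eye[np.clip(states, 0, None)], 1.0)
        partials[leaf] = np.broadcast_to(lp, (K, npat, N_CODONS))

    logscale = np.zeros((K, npat))
    for node in packed.postorder_internal:
        acc = None
        for child in packed.children[node]:
            contrib = np.matmul(partials.pop(child), pmats[:, child].transpose(0, 2, 1))
            acc = contrib if acc is None else acc * contrib
        m = acc.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        partials[node] = acc / m[:, :, None]
        logscale += np.log(m)

    root_partial = partials[int(tree.root)]
    site_lik = root_partial @ np.asarray(freqs)
    return np.log(np.clip(site_lik, _TINY, None)) + logscale


def mixture_loglik(
    alignment_or_packed,
    tree: PhyloTree | None,
    kappa: float,
    omegas,
    class_weights,
    freqs,
    branch_lengths=None,
) -> float:
    """Total log-likelihood of a codon mixture model.

    Per-site likelihood averages the category likelihoods with the class
    weights; the total is the weighted sum over compressed patterns.
    """
    packed = (
        alignment_or_packed
        if isinstance(alignment_or_packed, PackedData)
        else PackedData.build(alignment_or_packed, tree)
    )
    bl = packed.tree.branch_lengths if branch_lengths is None else branch_lengths
    w = np.asarray(class_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w < 0):
        raise ValueError("class weights must be a probability vector")
    pmats = category_matrices(kappa, omegas, freqs, bl, class_weights=w)
    logf = site_logliks_by_category(packed, pmats, freqs)
    logw = np.log(np.clip(w, _TINY, None))
    site_log = logsumexp(logf + logw[:, None], axis=0)
    return float(site_log @ packed.weights)


def site_logliks(
    packed: PackedData, kappa: float, omegas, class_weights, freqs, branch_lengths=None
) -> np.ndarray:
    """Per-original-site mixture log-likelihoods (uncompressed order)."""
    bl = packed.tree.branch_lengths if branch_lengths is None else branch_lengths
    w = np.asarray(class_weights, dtype=float)
    pmats = category_matrices(kappa, omegas, freqs, bl, class_weights=w)
    logf = site_logliks_by_category(packed, pmats, freqs)
    logw = np.log(np.clip(w, _TINY, None))
    per_pattern = logsumexp(logf + logw[:, None], axis=0)
    return per_pattern[packed.site_of_pattern]


def brute_force_loglik(
    alignment: CodonAlignment, tree: PhyloTree, kappa, omega, freqs
) -> np.ndarray:
    """Per-site log-likelihood by explicit summation over all internal-node
    state assignments.  Exponential in internal nodes; an oracle for tiny
    trees only (<= 4 internal nodes)."""
    pmats = category_matrices(kappa, [omega], freqs, tree.branch_lengths)[0]
    internal = [n for n in range(tree.n_nodes) if n >= tree.n_leaves]
    if len(internal) > 4:
        raise ValueError("brute-force oracle is limited to <= 4 internal nodes")
    slot = {n: i for i, n in enumerate(internal)}
    mat = alignment.codon_matrix[[alignment.taxa.index(t) for t in tree.taxa]]
    n_sites = mat.shape[1]
    freqs = np.asarray(freqs)

    assign = np.indices((N_CODONS,) * len(internal)).reshape(len(internal), -1)
    base = freqs[assign[slot[int(tree.root)]]].astype(float)
    for node in internal:
        parent = int(tree.parent[node])
        if parent >= 0:
            base = base * pmats[node][assign[slot[parent]], assign[slot[node]]]

    out = np.zeros(n_sites)
    for h in range(n_sites):
        prob = base
        for leaf in range(tree.n_leaves):
            obs = mat[leaf, h]
            if obs < 0:
                continue
            parent = int(tree.parent[leaf])
            prob = prob * pmats[leaf][assign[slot[parent]], obs]
        out[h] = np.log(max(prob.sum(), _TINY))
    return out
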