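"""Codon alignments and phylogenies: containers and FASTA/PHYLIP/Newick IO."""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

from .codon import CODON_INDEX, N_CODONS, SENSE_CODONS, STOP_CODONS


@dataclass
class CodonAlignment:
    """In-frame, gap-aware codon alignment.

    ``codon_matrix`` holds the codon index (0..60) per taxon and site, with
    -1 for missing data: gaps, ambiguity codes, and (optionally) masked
    in-frame stop codons.
    """

    taxa: tuple[str, ...]
    seqs: tuple[str, ...]
    stop_policy: str = "reject"  # or "mask"
    codon_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        if self.stop_policy not in ("reject", "mask"):
            raise ValueError("stop_policy must be 'reject' or 'mask'")
        self.codon_matrix = self._encode()

    def _encode(self) -> np.ndarray:
        n_sites = len(self.seqs[0]) // 3
        mat = np.full((len(self.taxa), n_sites), -1, dtype=np.int16)
        for i, seq in enumerate(self.seqs):
            s = seq.upper().replace("U", "T")
            for h in range(n_sites):
                codon = s[3 * h : 3 * h + 3]
                if codon in CODON_INDEX:
                    mat[i, h] = CODON_INDEX[codon]
                elif codon in STOP_CODONS:
                    if self.stop_policy == "reject":
                        raise ValueError(
                            f"in-frame stop codon {codon} in {self.taxa[i]} "
                            f"at codon {h} (use stop_policy='mask' to treat as missing)"
                        )
                # anything else (gap/ambiguity) stays missing
        return mat

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codon_matrix.shape[1]

    def codon_counts(self) -> np.ndarray:
        """Observed counts over the 61 sense codons (for F3x4)."""
        flat = self.codon_matrix[self.codon_matrix >= 0]
        return np.bincount(flat, minlength=N_CODONS).astype(float)

    def is_constant(self) -> bool:
        """True when no site shows two different observed codons."""
        for h in range(self.n_codons):
            col = self.codon_matrix[:, h]
            obs = np.unique(col[col >= 0])
            if obs.size > 1:
                return False
        return True

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.seqs):
                fh.write(f">{t}\n{s}\n")

    @classmethod
    def from_indices(cls, taxa, matrix: np.ndarray, stop_policy: str = "reject"):
        seqs = []
        for row in np.asarray(matrix):
            seqs.append("".join(SENSE_CODONS[i] if i >= 0 else "---" for i in row))
        return cls(tuple(taxa), tuple(seqs), stop_policy=stop_policy)


def read_codon_alignment(path, fmt: str | None = None, stop_policy: str = "reject") -> CodonAlignment:
    """Read a codon alignment from FASTA or sequential PHYLIP."""
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "fasta" if first.startswith(">") else "phylip-sequential"
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        taxa = tuple(r.id for r in records)
        seqs = tuple(str(r.seq) for r in records)
    else:
        aln = AlignIO.read(path, fmt)
        taxa = tuple(r.id for r in aln)
        seqs = tuple(str(r.seq) for r in aln)
    return CodonAlignment(taxa, seqs, stop_policy=stop_policy)


@dataclass
class PhyloTree:
    """Unrooted phylogeny flattened for pruning.

    Nodes are indexed 0..n_nodes-1 with leaves first (in ``taxa`` order).
    ``postorder`` lists (node, parent) pairs, children before parents,
    excluding the root; ``branch_lengths[node]`` is the length of the edge
    to the parent, in expected substitutions per codon.
    """

    taxa: tuple[str, ...]
    parent: np.ndarray  # parent[node] or -1 at root
    branch_lengths: np.ndarray
    root: int
    newick: str = ""

    def __post_init__(self):
        if np.any(self.branch_lengths[self.order()] < 0):
            raise ValueError("negative branch length")

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def order(self) -> np.ndarray:
        """Indices of non-root nodes, children before parents."""
        order = []
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        stack = [self.root]
        seen = []
        while stack:
            node = stack.pop()
            seen.append(node)
            stack.extend(children.get(node, []))
        for node in reversed(seen):
            if node != self.root:
                order.append(node)
        return np.asarray(order)

    def with_branch_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(self.taxa, self.parent, np.asarray(lengths, dtype=float), self.root, self.newick)

    def edge_nodes(self) -> np.ndarray:
        """Nodes carrying a free branch (root's edge is absorbed by children)."""
        return np.asarray([i for i in range(self.n_nodes) if self.parent[i] >= 0])

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)

        def rec(node: int) -> str:
            label = self.taxa[node] if node < self.n_leaves else ""
            if node in children:
                inner = ",".join(
                    f"{rec(c)}:{self.branch_lengths[c]:.12g}" for c in children[node]
                )
                return f"({inner}){label}"
            return label

        return rec(int(self.root)) + ";"


def _flatten(tree: dendropy.Tree, taxa_order: tuple[str, ...] | None) -> PhyloTree:
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label.replace(" ", "_") for lf in leaves]
    if taxa_order is None:
        taxa_order = tuple(labels)
    if set(labels) != set(taxa_order):
        raise ValueError("tree leaves do not match alignment taxa")
    index = {}
    for lf in leaves:
        index[id(lf)] = taxa_order.index(lf.taxon.label.replace(" ", "_"))
    next_id = len(leaves)
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            index[id(node)] = next_id
            next_id += 1
    parent = np.full(next_id, -1, dtype=int)
    blen = np.zeros(next_id)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent[index[id(node)]] = index[id(node.parent_node)]
            blen[index[id(node)]] = node.edge.length if node.edge.length is not None else 0.0
    root = index[id(tree.seed_node)]
    return PhyloTree(
        taxa=tuple(taxa_order),
        parent=parent,
        branch_lengths=blen,
        root=root,
        newick=tree.as_string(schema="newick").strip(),
    )


def read_tree(path_or_newick, taxa: tuple[str, ...] | None = None) -> PhyloTree:
    """Parse a Newick tree (file path or string) into a :class:`PhyloTree`.

    The model is time-reversible, so an input rooting is kept as an
    arbitrary pruning root; likelihoods do not depend on it.
    """
    text = str(path_or_newick)
    if "(" not in text:
        with open(text) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return _flatten(tree, taxa)
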