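"""Codon-level substitution machinery: genetic code, frequencies, rate matrix.

The substitution process is the Goldman–Yang-style codon model used for
site-specific dN/dS analysis: instantaneous change is allowed only between
codons differing at a single nucleotide, with rate proportional to the
target codon frequency, multiplied by the transition/transversion ratio
kappa for transitions and by omega (dN/dS) for amino-acid-changing moves.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _build_code(table_id: int = 1):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codons = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
    sense = [c for c in codons if c not in table.stop_codons]
    aa = {c: table.forward_table[c] for c in sense}
    return tuple(sense), aa, tuple(table.stop_codons)


#: 61 sense codons of the standard genetic code, TCAG order.
SENSE_CODONS, CODON_AA, STOP_CODONS = _build_code(1)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61
AA_OF = np.array([CODON_AA[c] for c in SENSE_CODONS])


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _single_change_tables():
    """Index arrays over codon pairs differing at exactly one position."""
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ii.append(i)
            jj.append(j)
            ts.append(_is_transition(ci[k], cj[k]))
            syn.append(CODON_AA[ci] == CODON_AA[cj])
    return (
        np.asarray(ii),
        np.asarray(jj),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _single_change_tables()


def equal_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_freqs(codon_counts: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from observed codon counts.

    Position-specific nucleotide frequencies are multiplied per codon and
    renormalized over the 61 sense codons.
    """
    counts = np.asarray(codon_counts, dtype=float)
    if counts.shape != (N_CODONS,):
        raise ValueError(f"expected counts over the {N_CODONS} sense codons")
    pos_freq = np.zeros((3, 4))
    for idx, codon in enumerate(SENSE_CODONS):
        for k in range(3):
            pos_freq[k, NUC_INDEX[codon[k]]] += counts[idx]
    tot = pos_freq.sum(axis=1, keepdims=True)
    if np.any(tot == 0):
        raise ValueError("empty alignment: cannot estimate F3x4 frequencies")
    pos_freq /= tot
    freqs = np.array(
        [
            pos_freq[0, NUC_INDEX[c[0]]]
            * pos_freq[1, NUC_INDEX[c[1]]]
            * pos_freq[2, NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    s = freqs.sum()
    if s <= 0:
        raise ValueError("degenerate F3x4 frequencies")
    return freqs / s


def _validate_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (N_CODONS,):
        raise ValueError(f"frequencies must have length {N_CODONS}")
    if np.any(freqs < 0):
        raise ValueError("negative codon frequency")
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("codon frequencies must sum to 1")
    return freqs


def gy94_generator(
    kappa: float,
    omega: float,
    freqs: np.ndarray,
    scale: bool = True,
) -> np.ndarray:
    """61x61 instantaneous rate matrix of the codon model.

    Off-diagonal rate i->j is zero for multi-nucleotide changes and
    otherwise ``freqs[j] * kappa**is_transition * omega**is_nonsynonymous``.
    Rows sum to zero.  With ``scale=True`` the matrix is normalized so the
    expected rate at equilibrium is one substitution per codon, making
    branch lengths expected substitutions/codon.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    freqs = _validate_freqs(freqs)
    q = np.zeros((N_CODONS, N_CODONS))
    rates = freqs[_PAIR_J].copy()
    rates[_PAIR_TS] *= kappa
    rates[~_PAIR_SYN] *= omega
    q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        mean_rate = -(freqs * np.diag(q)).sum()
        if mean_rate > 0:
            q /= mean_rate
    return q


def mean_rate(q: np.ndarray, freqs: np.ndarray) -> float:
    """Expected substitutions/codon/unit-time at equilibrium."""
    return float(-(np.asarray(freqs) * np.diag(q)).sum())


def eigen_decompose(q: np.ndarray, freqs: np.ndarray):
    """Symmetric eigendecomposition of a reversible generator.

    Returns (evals, left, right) with ``P(t) = right @ diag(exp(evals*t)) @ left``.
    """
    freqs = np.asarray(freqs, dtype=float)
    sqrtp = np.sqrt(np.clip(freqs, 1e-300, None))
    b = (q * sqrtp[:, None]) / sqrtp[None, :]
    b = 0.5 * (b + b.T)  # symmetrize numerical noise
    evals, u = np.linalg.eigh(b)
    right = u / sqrtp[:, None]
    left = (u * sqrtp[:, None]).T
    return evals, left, right


def transition_matrix(eig, t: float) -> np.ndarray:
    """P(t) from a cached eigendecomposition; entries clipped to [0, 1]."""
    evals, left, right = eig
    p = (right * np.exp(evals * t)) @ left
    return np.clip(p, 0.0, 1.0)
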