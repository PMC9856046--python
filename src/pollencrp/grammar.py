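"""Cysteine-spacing motif grammars for small cysteine-rich proteins (CRPs).

Pollen-coat CRP families (PCP-A/DEFL/LCR, PCP-B, SCRL, nsLTP, GASA) are
defined by the spacing of their conserved cysteine residues rather than by
overall sequence similarity.  A family pattern is written in a compact
PROSITE-like notation::

    CXXXXCX(7-8)CXCCX(6-8)CX(6)CXXXC

where ``C`` is a conserved cysteine, ``X`` any non-cysteine residue,
``X(a-b)`` between ``a`` and ``b`` arbitrary residues and ``X(a)`` exactly
``a`` residues.  This module parses that notation, matches it against
protein sequences via their cysteine skeleton, and assigns each protein to
a family.

Spacers are cysteine-free by construction: a match anchors on a run of
consecutive cysteines of the sequence skeleton, so a pattern describes a
complete local cysteine arrangement.  Matching is position-free within the
sequence (no signal-peptide model) and extra cysteines outside the matched
span do not invalidate a match.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")  # 20 residues + ambiguity X

#: Deterministic class precedence used as the final tie-break when a protein
#: satisfies several family envelopes (most-constrained families first).
CLASS_ORDER = ("PCP-B", "SCRL", "GASA", "nsLTP", "PCP-A/DEFL/LCR")


class PatternSyntaxError(ValueError):
    """Malformed cysteine-pattern notation; carries the failing offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class CysPattern:
    """Ordered cysteine-spacing grammar for one family in one species.

    ``spacers[i]`` is the inclusive (min, max) number of non-cysteine
    residues between conserved cysteines ``i`` and ``i+1``.
    """

    class_id: str
    species_tag: str
    n_cys: int
    spacers: tuple[tuple[int, int], ...]
    source_text: str = ""

    def __post_init__(self):
        if self.n_cys < 2:
            raise ValueError("a cysteine pattern needs at least 2 cysteines")
        if len(self.spacers) != self.n_cys - 1:
            raise ValueError("need exactly n_cys - 1 spacers")
        for lo, hi in self.spacers:
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid spacer range ({lo},{hi})")

    def render(self) -> str:
        """Canonical notation string; re-parsing gives an equal structure."""
        parts = ["C"]
        for lo, hi in self.spacers:
            if lo == hi:
                parts.append("X" * lo if lo <= 4 else f"X({lo})")
            else:
                parts.append(f"X({lo}-{hi})")
            parts.append("C")
        return "".join(parts)

    @property
    def span_range(self) -> tuple[int, int]:
        """(min, max) length in residues of a full match."""
        lo = self.n_cys + sum(s[0] for s in self.spacers)
        hi = self.n_cys + sum(s[1] for s in self.spacers)
        return lo, hi

    def spacer_volume(self) -> int:
        """Total slack of the spacer ranges; smaller = more specific."""
        return sum(hi - lo for lo, hi in self.spacers)


@dataclass(frozen=True)
class CRPClassDef:
    """A CRP family: one pattern per species plus their merged envelope."""

    class_id: str
    patterns: tuple[CysPattern, ...]
    envelope: CysPattern
    size_range: tuple[int, int]
    subgroup_ids: tuple[str, ...] = ()

    def __post_init__(self):
        n = {p.n_cys for p in self.patterns} | {self.envelope.n_cys}
        if len(n) != 1:
            raise ValueError(f"{self.class_id}: patterns disagree on n_cys")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range min > max")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""
    species: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass
class PatternMatch:
    class_id: str
    species_tag: str
    start: int  # 0-based, half-open span
    end: int
    gaps: tuple[int, ...]  # realised spacer lengths


@dataclass
class ClassificationResult:
    protein_id: str
    matches: list[PatternMatch] = field(default_factory=list)
    primary_class: str = "unclassified"
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(r"C|X\((\d+)(?:-(\d+))?\)|X")
_TYPO_RE = re.compile(r"C\((\d+)(?:-(\d+))?\)")


def normalize_notation(text: str) -> tuple[str, bool]:
    """Repair the known typographic variant ``C(a-b)`` -> ``CX(a-b)``.

    A bracketed range must follow an ``X``; a range directly after ``C``
    (as in the printed A. lyrata PCP-A row ending ``CXC(1-8)C``) drops the
    ``X`` and would silently lose a cysteine spacer.  The repair is logged.
    """
    fixed = _TYPO_RE.sub(lambda m: "CX" + text[m.start() + 1 : m.end()], text)
    if fixed != text:
        logger.warning("normalized pattern notation %r -> %r", text, fixed)
    return fixed, fixed != text


def parse_pattern(text: str, class_id: str = "", species_tag: str = "") -> CysPattern:
    """Parse pattern notation into a :class:`CysPattern`.

    Each inter-cysteine region accumulates its tokens: a bare ``X`` adds
    (1,1), ``X(a)`` adds (a,a) and ``X(a-b)`` adds (a,b); ``CC`` yields a
    (0,0) spacer.
    """
    if not text:
        raise PatternSyntaxError("empty pattern", 0)
    text = text.strip().upper()
    text, _ = normalize_notation(text)

    spacers: list[tuple[int, int]] = []
    cur_lo = cur_hi = 0
    n_cys = 0
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise PatternSyntaxError(f"unexpected character {text[pos]!r}", pos)
        tok = m.group(0)
        if tok == "C":
            if n_cys > 0:
                spacers.append((cur_lo, cur_hi))
            cur_lo = cur_hi = 0
            n_cys += 1
        elif tok == "X":
            cur_lo += 1
            cur_hi += 1
        else:
            a = int(m.group(1))
            b = int(m.group(2)) if m.group(2) is not None else a
            if a > b:
                raise PatternSyntaxError(f"range min {a} > max {b}", pos)
            cur_lo += a
            cur_hi += b
        pos = m.end()
    if n_cys < 2:
        raise PatternSyntaxError("pattern must contain at least 2 cysteines", len(text))
    if cur_lo or cur_hi:
        raise PatternSyntaxError("pattern must end on a cysteine", len(text))
    return CysPattern(
        class_id=class_id,
        species_tag=species_tag,
        n_cys=n_cys,
        spacers=tuple(spacers),
        source_text=text,
    )


# ---------------------------------------------------------------------------
# matching

def cys_skeleton(sequence: str) -> list[tuple[int, int]]:
    """Cysteine positions with the gap (non-C residue count) to the next one.

    The final cysteine has gap -1 (no successor).  A cysteine-free sequence
    gives an empty list.
    """
    seq = sequence.upper()
    positions = [i for i, aa in enumerate(seq) if aa == "C"]
    out = []
    for i, p in enumerate(positions):
        nxt = positions[i + 1] - p - 1 if i + 1 < len(positions) else -1
        out.append((p, nxt))
    return out


def match_pattern(pattern: CysPattern, sequence: str) -> list[PatternMatch]:
    """All maximal matches of *pattern* on the cysteine skeleton of *sequence*.

    A match anchors on ``n_cys`` consecutive skeleton cysteines whose
    successive gaps each fall inside the pattern's spacer ranges.  Spans are
    0-based half-open over the full sequence.
    """
    skel = cys_skeleton(sequence)
    k = pattern.n_cys
    matches: list[PatternMatch] = []
    for i in range(len(skel) - k + 1):
        gaps = tuple(skel[i + j][1] for j in range(k - 1))
        ok = all(lo <= g <= hi for g, (lo, hi) in zip(gaps, pattern.spacers))
        if ok:
            start = skel[i][0]
            end = skel[i + k - 1][0] + 1
            matches.append(
                PatternMatch(pattern.class_id, pattern.species_tag, start, end, gaps)
            )
    return matches


def build_envelope(patterns: Sequence[CysPattern]) -> CysPattern:
    """Per-spacer interval hull of same-arity patterns.

    The envelope accepts every sequence any of the inputs accepts.
    """
    if not patterns:
        raise ValueError("no patterns to merge")
    n = {p.n_cys for p in patterns}
    if len(n) != 1:
        raise ValueError(f"unequal cysteine counts across patterns: {sorted(n)}")
    spacers = tuple(
        (min(p.spacers[i][0] for p in patterns), max(p.spacers[i][1] for p in patterns))
        for i in range(patterns[0].n_cys - 1)
    )
    return CysPattern(
        class_id=patterns[0].class_id,
        species_tag="envelope",
        n_cys=patterns[0].n_cys,
        spacers=spacers,
        source_text="",
    )


@dataclass(frozen=True)
class ClassifierConfig:
    max_length: int = 300  # precursor size filter, residues
    use_envelope: bool = True  # match the merged envelope vs per-species rows

    def __post_init__(self):
        if self.max_length < 1:
            raise ValueError("max_length must be positive")


def classify_protein(
    protein: ProteinRecord,
    defs: Sequence[CRPClassDef],
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Assign *protein* to a CRP family by its cysteine skeleton.

    All matching classes are reported; the primary class is chosen by
    (1) most matched cysteines, (2) smallest total spacer slack (most
    specific pattern), (3) the fixed precedence :data:`CLASS_ORDER`.
    """
    if not defs:
        raise ValueError("no class definitions supplied")
    config = config or ClassifierConfig()
    result = ClassificationResult(protein_id=protein.id)

    if len(protein.sequence) > config.max_length:
        result.reasons.append(f"size-filter:{len(protein.sequence)}>{config.max_length}")
        return result
    if "C" not in protein.sequence.upper():
        result.reasons.append("no-cysteine")
        return result

    matched_defs: list[CRPClassDef] = []
    for cdef in defs:
        pats = [cdef.envelope] if config.use_envelope else list(cdef.patterns)
        hits: list[PatternMatch] = []
        for pat in pats:
            hits.extend(match_pattern(pat, protein.sequence))
        if hits:
            result.matches.extend(hits)
            matched_defs.append(cdef)

    if not matched_defs:
        result.reasons.append("no-pattern-match")
        return result

    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    best = min(
        matched_defs,
        key=lambda d: (
            -d.envelope.n_cys,
            d.envelope.spacer_volume(),
            order.get(d.class_id, len(order)),
        ),
    )
    result.primary_class = best.class_id
    return result


def classify_proteins(
    proteins: Iterable[ProteinRecord],
    defs: Sequence[CRPClassDef],
    config: ClassifierConfig | None = None,
) -> list[ClassificationResult]:
    return [classify_protein(p, defs, config) for p in proteins]


# ---------------------------------------------------------------------------
# class definitions and IO

def load_class_definitions(path=None) -> list[CRPClassDef]:
    """Load family definitions from a TSV config (bundled table by default).

    Columns: class_id, species, subgroups, size_min, size_max, pattern.
    Rows of one class are merged into a per-spacer envelope.
    """
    if path is None:
        with resources.files("pollencrp.data").joinpath("crp_classes.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    defs = []
    for class_id, grp in df.groupby("class_id", sort=False):
        pats = tuple(
            parse_pattern(r.pattern, class_id=class_id, species_tag=r.species)
            for r in grp.itertuples()
        )
        subgroups: tuple[str, ...] = ()
        if grp.subgroups.notna().any():
            subgroups = tuple(
                sorted({s for cell in grp.subgroups.dropna() for s in cell.split(",")})
            )
        defs.append(
            CRPClassDef(
                class_id=class_id,
                patterns=pats,
                envelope=build_envelope(pats),
                size_range=(int(grp.size_min.min()), int(grp.size_max.max())),
                subgroup_ids=subgroups,
            )
        )
    return defs


def read_fasta(path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Long-format classification table (1-based inclusive spans for humans)."""
    rows = []
    for r in results:
        if r.matches:
            for m in r.matches:
                rows.append(
                    {
                        "protein_id": r.protein_id,
                        "primary_class": r.primary_class,
                        "matched_class": m.class_id,
                        "pattern_species": m.species_tag,
                        "start": m.start + 1,
                        "end": m.end,
                        "skeleton": "-".join(map(str, m.gaps)),
                    }
                )
        else:
            rows.append(
                {
                    "protein_id": r.protein_id,
                    "primary_class": r.primary_class,
                    "matched_class": "",
                    "pattern_species": "",
                    "start": 0,
                    "end": 0,
                    "skeleton": ";".join(r.reasons),
                }
            )
    return pd.DataFrame(rows)


def generate_report(
    results: Sequence[ClassificationResult],
    proteins: Sequence[ProteinRecord] | None = None,
    defs: Sequence[CRPClassDef] | None = None,
) -> pd.DataFrame:
    """Per-class summary: counts of primary assignments and observed sizes."""
    lengths = {p.id: len(p.sequence) for p in proteins} if proteins else {}
    class_ids = [d.class_id for d in defs] if defs else sorted(
        {r.primary_class for r in results if r.primary_class != "unclassified"}
    )
    rows = []
    for cid in list(class_ids) + ["unclassified"]:
        members = [r for r in results if r.primary_class == cid]
        sizes = [lengths[r.protein_id] for r in members if r.protein_id in lengths]
        rows.append(
            {
                "class_id": cid,
                "n_proteins": len(members),
                "size_min": min(sizes) if sizes else 0,
                "size_max": max(sizes) if sizes else 0,
            }
        )
    return pd.DataFrame(rows)
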