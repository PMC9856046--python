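"""Cysteine-pattern parsing, matching and CRP family classification."""

import numpy as np
import pytest

from pollencrp.grammar import (
    ClassifierConfig,
    CysPattern,
    PatternSyntaxError,
    ProteinRecord,
    build_envelope,
    classify_protein,
    cys_skeleton,
    generate_report,
    load_class_definitions,
    match_pattern,
    normalize_notation,
    parse_pattern,
)
from pollencrp.simulate import gen_crp_proteins


class TestParsePattern:
    def test_pcpb_pattern_hand_parse(self):
        # hand-parsed A. thaliana PCP-B family pattern
        p = parse_pattern("CXXXXCX(7-8)CXCCX(6-8)CX(6)CXXXC")
        assert p.n_cys == 8
        assert p.spacers == ((4, 4), (7, 8), (1, 1), (0, 0), (6, 8), (6, 6), (3, 3))

    def test_gasa_pattern_cysteine_count(self):
        p = parse_pattern("CXXXCXXXCX(8)CXXXCXXCCXXCX(1-2)CX(11)CXCX(12)C")
        assert p.n_cys == 12

    def test_adjacent_cysteines(self):
        p = parse_pattern("CC")
        assert p.n_cys == 2
        assert p.spacers == ((0, 0),)

    def test_crr_motif(self):
        # the cysteine-rich repeat motif of CRRSP domains
        p = parse_pattern("CX(8)CXXC")
        assert p.n_cys == 3
        assert p.spacers == ((8, 8), (2, 2))

    def test_typo_normalization_restores_spacer(self):
        fixed, changed = normalize_notation("CXC(1-8)C")
        assert changed and fixed == "CXCX(1-8)C"
        p = parse_pattern("CXC(1-8)C")
        assert p.n_cys == 3
        assert p.spacers == ((1, 1), (1, 8))

    @pytest.mark.parametrize(
        "bad", ["", "C", "CX(3-1)C", "CX(3C", "CZ C", "CXXX", "CX(a)C"]
    )
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises((PatternSyntaxError, ValueError)):
            parse_pattern(bad)

    def test_all_printed_family_patterns_parse(self, class_defs):
        """The published family rows parse; implied cysteine counts match."""
        n_cys = {d.class_id: d.envelope.n_cys for d in class_defs}
        assert n_cys == {
            "PCP-A/DEFL/LCR": 8,
            "PCP-B": 8,
            "SCRL": 8,
            "nsLTP": 8,
            "GASA": 12,
        }
        assert sum(len(d.patterns) for d in class_defs) == 15

    def test_parse_render_roundtrip_structure(self, class_defs):
        for d in class_defs:
            for p in d.patterns:
                again = parse_pattern(p.render(), p.class_id, p.species_tag)
                assert again.n_cys == p.n_cys
                assert again.spacers == p.spacers


class TestSkeletonAndMatch:
    def test_skeleton_enumeration(self):
        assert cys_skeleton("ACAAACA") == [(1, 3), (5, -1)]
        assert cys_skeleton("AAAA") == []
        assert [g for _, g in cys_skeleton("CCC")] == [0, 0, -1]

    def test_direct_containment(self):
        pat = parse_pattern("CC")
        spans = [(m.start, m.end) for m in match_pattern(pat, "ACCA")]
        assert spans == [(1, 3)]

    def test_gap_outside_range_rejected(self):
        pat = CysPattern("t", "t", 2, ((2, 4),))
        assert match_pattern(pat, "CAAAAAC") == []  # gap 5
        assert len(match_pattern(pat, "CAAAC")) == 1  # gap 3

    def test_match_against_skeleton_scan_oracle(self):
        # exhaustive oracle: slide over every skeleton window
        rng = np.random.default_rng(1)
        pat = parse_pattern("CX(2-4)CXCC")
        for _ in range(50):
            seq = "".join(rng.choice(list("ACDEF"), size=30))
            got = {(m.start, m.end) for m in match_pattern(pat, seq)}
            skel = cys_skeleton(seq)
            expect = set()
            for i in range(len(skel) - 3):
                gaps = [skel[i + j][1] for j in range(3)]
                if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, pat.spacers)):
                    expect.add((skel[i][0], skel[i + 3][0] + 1))
            assert got == expect

    def test_extra_cysteines_outside_span_allowed(self):
        pat = parse_pattern("CXXC")
        assert len(match_pattern(pat, "CCAAAACAAC")) >= 1


class TestEnvelope:
    def test_idempotent_on_identical_inputs(self):
        p = parse_pattern("CXXC", "a", "s1")
        env = build_envelope([p, p])
        assert env.spacers == p.spacers

    def test_interval_hull(self):
        a = CysPattern("c", "s1", 2, ((4, 4),))
        b = CysPattern("c", "s2", 2, ((3, 5),))
        assert build_envelope([a, b]).spacers == ((3, 5),)

    def test_unequal_arity_rejected(self):
        a = parse_pattern("CXC")
        b = parse_pattern("CXCXC")
        with pytest.raises(ValueError):
            build_envelope([a, b])

    def test_envelope_superset_of_species_matches(self, class_defs, rng):
        """Envelope matches contain every per-species match (soundness)."""
        for d in class_defs:
            recs, _ = gen_crp_proteins([d], 20, seed=int(rng.integers(1 << 30)))
            for rec in recs:
                species_spans = set()
                for p in d.patterns:
                    species_spans |= {
                        (m.start, m.end) for m in match_pattern(p, rec.sequence)
                    }
                env_spans = {
                    (m.start, m.end) for m in match_pattern(d.envelope, rec.sequence)
                }
                assert species_spans <= env_spans


class TestClassify:
    def test_generated_pcpb_protein_is_pcpb(self, class_defs):
        pcpb = next(d for d in class_defs if d.class_id == "PCP-B")
        recs, _ = gen_crp_proteins([pcpb], 5, seed=3)
        for rec in recs:
            res = classify_protein(rec, class_defs)
            assert res.primary_class == "PCP-B"

    def test_cysteine_free_protein_unclassified(self, class_defs):
        rec = ProteinRecord(id="x", sequence="AAAAAGGGG")
        res = classify_protein(rec, class_defs)
        assert res.primary_class == "unclassified"
        assert "no-cysteine" in res.reasons

    def test_size_filter(self, class_defs):
        rec = ProteinRecord(id="big", sequence="A" * 301)
        res = classify_protein(rec, class_defs, ClassifierConfig(max_length=300))
        assert res.primary_class == "unclassified"
        assert any(r.startswith("size-filter") for r in res.reasons)

    def test_published_envelopes_pairwise_disjoint(self, class_defs):
        """No gap vector satisfies two published same-arity envelopes, which
        is why family assignment on conforming sequences is unambiguous."""
        eight = [d.envelope for d in class_defs if d.envelope.n_cys == 8]
        assert len(eight) == 4
        for i in range(len(eight)):
            for j in range(i + 1, len(eight)):
                overlap = all(
                    max(a_lo, b_lo) <= min(a_hi, b_hi)
                    for (a_lo, a_hi), (b_lo, b_hi) in zip(
                        eight[i].spacers, eight[j].spacers
                    )
                )
                assert not overlap, (eight[i].class_id, eight[j].class_id)

    def test_ambiguous_match_resolved_by_tie_rule(self):
        """A sequence inside two overlapping envelopes lists both classes;
        the more specific pattern (smaller spacer slack) wins primary."""
        from pollencrp.grammar import CRPClassDef

        loose = parse_pattern("CX(1-6)CX(1-6)C", "LOOSE", "s")
        tight = parse_pattern("CX(2-3)CX(2-3)C", "TIGHT", "s")
        defs = [
            CRPClassDef("LOOSE", (loose,), build_envelope([loose]), (3, 300)),
            CRPClassDef("TIGHT", (tight,), build_envelope([tight]), (3, 300)),
        ]
        rec = ProteinRecord(id="amb", sequence="MCAAACAAC")
        res = classify_protein(rec, defs)
        assert {m.class_id for m in res.matches} == {"LOOSE", "TIGHT"}
        assert res.primary_class == "TIGHT"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(max_length=0)


class TestReport:
    def test_counts_equal_planted_labels(self, class_defs):
        recs, truth = gen_crp_proteins(class_defs, 3, seed=5)
        results = [classify_protein(r, class_defs) for r in recs]
        rep = generate_report(results, recs, class_defs).set_index("class_id")
        planted = truth.groupby("class_id").size()
        for cid, n in planted.items():
            assert rep.loc[cid, "n_proteins"] == n

    def test_empty_input_gives_zero_table(self, class_defs):
        rep = generate_report([], None, class_defs)
        assert (rep.n_proteins == 0).all()
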