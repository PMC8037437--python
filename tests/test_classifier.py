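"""REC classifier: rule examples, invariants, and exhaustive oracle equivalence.

The oracle is a hand-written decision table over a toy transcript: it
re-derives each expected class from first principles (string-surgery
translation, flat base->exon lookup, literal window arithmetic) without
calling the classifier's own machinery.
"""

from __future__ import annotations

import pytest

from rb1rec.classifier import (
    ClassifierConfig,
    Med4Status,
    Med4Subclass,
    NmdBoundaryMode,
    NmdRuleConfig,
    RecClass,
    SpliceEffect,
    VariantRecord,
    VariantScale,
    VariantValidationError,
    classify_cohort,
    classify_variant,
    nmd_rule,
    parse_hgvs_p,
)
from rb1rec.simulate import stop_gain_sites
from rb1rec.transcript import TranscriptModel

from conftest import STOPS, brute_force_exon, hand_first_stop

# toy grid runs with NMD range 2..4 (boundary exon 4 under the 50-nt rule)
TOY_NMD = NmdRuleConfig(nmd_first_exon=2, nmd_last_exon=4)
TOY_CONFIG = ClassifierConfig(nmd=TOY_NMD)


# ---------------------------------------------------------------------------
# Decision-table oracle
# ---------------------------------------------------------------------------

def _oracle_class_for_ptc(ptc_codon, tm: TranscriptModel):
    """Class of an exonic small variant given its (possibly absent) PTC."""
    if ptc_codon is None:
        return ("REC_III", False)
    base = min(max((ptc_codon - 1) * 3 + 1, 1), tm.cds_length)
    exon = brute_force_exon(base, tm)
    if exon == 1:
        return ("REC_III", False)
    if exon < TOY_NMD.nmd_first_exon:
        return ("REC_IV", False)
    if exon < TOY_NMD.nmd_last_exon:
        return ("REC_I", False)
    if exon == TOY_NMD.nmd_last_exon:
        junction_c = tm.exons[exon - 1].cdna_end - tm.cds_start_cdna + 1
        return ("REC_I", False) if junction_c - base > 50 else ("REC_IV", False)
    return ("REC_IV", False)


def _oracle_splice(offset: int, skipped_exon: int, tm: TranscriptModel, validated=None):
    if abs(offset) <= 2:
        leaky = False
    elif (0 < offset <= 6) or (-12 <= offset < 0):
        leaky = True
    else:
        return ("UNCLASSIFIED", False)
    if validated is not None:
        has_ptc = validated
    else:
        if skipped_exon in (1, tm.n_exons):
            return ("UNCLASSIFIED", False)
        clen = tm.coding_length_of_exon(skipped_exon)
        has_ptc = clen % 3 != 0
    return ("REC_I" if has_ptc else "REC_III", leaky)


def build_grid(tm: TranscriptModel):
    """(VariantRecord, expected (main_class, leaky) or subclass) pairs covering
    every exon x consequence type, every splice offset x adjacent-exon frame,
    and all gross-deletion flag combinations."""
    cases: list[tuple[VariantRecord, tuple[str, bool] | str]] = []
    cds = tm.cds_sequence
    i = 0

    def vid():
        nonlocal i
        i += 1
        return f"G{i:04d}"

    # nonsense substitutions: every single-base stop-gain in the CDS
    for c_base, ref, alt, codon, _ in stop_gain_sites(tm):
        rec = VariantRecord(vid(), VariantScale.SMALL, hgvs_c=f"c.{c_base}{ref}>{alt}")
        cases.append((rec, _oracle_class_for_ptc(codon, tm)))

    # single-base (frameshift) deletions every 4 coding bases
    for b in range(2, tm.cds_length - 3, 4):
        mutant = cds[: b - 1] + cds[b:]
        rec = VariantRecord(vid(), VariantScale.SMALL, hgvs_c=f"c.{b}del")
        cases.append((rec, _oracle_class_for_ptc(hand_first_stop(mutant), tm)))

    # missense substitutions and codon-aligned in-frame deletions
    for codon in range(2, tm.protein_length + 1, 2):
        start = (codon - 1) * 3
        ref = cds[start]
        alt = next(
            a for a in "ACGT"
            if a != ref and (a + cds[start + 1 : start + 3]) not in STOPS
        )
        cases.append((
            VariantRecord(vid(), VariantScale.SMALL, hgvs_c=f"c.{start + 1}{ref}>{alt}"),
            ("REC_III", False),
        ))
        cases.append((
            VariantRecord(vid(), VariantScale.SMALL, hgvs_c=f"c.{start + 1}_{start + 3}del"),
            ("REC_III", False),
        ))

    # splice-region variants: every donor/acceptor x offset, incl. out-of-window
    for exon in range(1, tm.n_exons):          # donor of exon e skips exon e
        donor_c = tm.exons[exon - 1].cdna_end - tm.cds_start_cdna + 1
        for off in (1, 2, 3, 4, 5, 6, 7, 40):
            rec = VariantRecord(vid(), VariantScale.SMALL, hgvs_c=f"c.{donor_c}+{off}G>T")
            cases.append((rec, _oracle_splice(off, exon, tm)))
    for exon in range(2, tm.n_exons + 1):      # acceptor before exon e skips exon e
        acc_c = tm.exons[exon - 1].cdna_start - tm.cds_start_cdna + 1
        for off in (1, 2, 3, 8, 12, 13, 40):
            rec = VariantRecord(vid(), VariantScale.SMALL, hgvs_c=f"c.{acc_c}-{off}A>G")
            cases.append((rec, _oracle_splice(-off, exon, tm)))

    # validated splice effects override the default skip model
    donor2_c = tm.exons[1].cdna_end - tm.cds_start_cdna + 1  # exon 2 is in-frame on skip
    for off, effect, expected in [
        (5, SpliceEffect.PTC, ("REC_I", True)),
        (5, SpliceEffect.NO_PTC, ("REC_III", True)),
        (1, SpliceEffect.PTC, ("REC_I", False)),
    ]:
        rec = VariantRecord(
            vid(), VariantScale.SMALL, hgvs_c=f"c.{donor2_c}+{off}G>T",
            validated_splice_effect=effect,
        )
        cases.append((rec, expected))

    # gross deletions: all extent-flag combinations x MED4 status
    for whole in (False, True):
        for prom in (False, True):
            for tail in (False, True):
                for med4 in Med4Status:
                    rec = VariantRecord(
                        vid(), VariantScale.GROSS_DELETION, whole_gene=whole,
                        includes_promoter_5prime=prom, includes_3prime_end=tail,
                        med4_status=med4,
                    )
                    if whole or prom:
                        sub = {
                            Med4Status.INCLUDED: "REC_II_plus",
                            Med4Status.EXCLUDED: "REC_II_minus",
                        }.get(med4, "REC_II_unknown")
                        cases.append((rec, sub))
                    elif tail:
                        cases.append((rec, ("REC_IV", False)))
                    else:
                        cases.append((rec, ("UNCLASSIFIED", False)))

    # promoter-regulatory variants
    cases.append((
        VariantRecord(vid(), VariantScale.PROMOTER_REGULATORY, hgvs_c="c.-190A>T (regulatory)"),
        ("REC_V", False),
    ))

    # protein-level shortcut descriptions
    for p, expected in [
        ("p.Arg40Ter", _oracle_class_for_ptc(40, tm)),
        ("p.Gln150*", _oracle_class_for_ptc(150, tm)),
        ("p.Ser170Leu", ("REC_III", False)),
        ("p.Gly60ValfsTer8", _oracle_class_for_ptc(67, tm)),
    ]:
        cases.append((VariantRecord(vid(), VariantScale.SMALL, hgvs_p=p), expected))
    return cases


def check_against_oracle(tm, dm, config=TOY_CONFIG):
    cases = build_grid(tm)
    assert len(cases) > 400
    mismatches = []
    for rec, expected in cases:
        a = classify_variant(rec, tm, dm, config)
        got = a.subclass_label if isinstance(expected, str) else (a.main_class.value, a.leaky)
        if got != expected:
            mismatches.append((rec.variant_id, rec.hgvs_c or rec.hgvs_p, expected, got))
    return len(cases), mismatches


def test_engine_matches_decision_table_oracle(toy_transcript, toy_domain_map):
    n, mismatches = check_against_oracle(toy_transcript, toy_domain_map)
    assert mismatches == [], f"{len(mismatches)}/{n} grid cases disagree: {mismatches[:5]}"


# ---------------------------------------------------------------------------
# NMD rule
# ---------------------------------------------------------------------------

def test_nmd_rule_default_exon_ranges():
    from rb1rec.io import load_packaged_transcript

    tm = load_packaged_transcript()
    assert nmd_rule(3, tm) is True
    assert nmd_rule(27, tm) is False
    assert nmd_rule(1, tm) is False
    assert nmd_rule(26, tm) is False


def test_nmd_boundary_exon_fifty_nt_vs_hard(toy_transcript):
    tm = toy_transcript
    junction_c = tm.exons[3].cdna_end - tm.cds_start_cdna + 1   # end of exon 4
    early = junction_c - 80   # > 50 nt upstream of the junction
    late = junction_c - 10    # within 50 nt
    assert nmd_rule(4, tm, TOY_NMD, ptc_cdna_base=early) is True
    assert nmd_rule(4, tm, TOY_NMD, ptc_cdna_base=late) is False
    hard = NmdRuleConfig(nmd_first_exon=2, nmd_last_exon=4, boundary_mode=NmdBoundaryMode.EXON)
    assert nmd_rule(4, tm, hard, ptc_cdna_base=late) is True
    # without a position the boundary exon falls back to the hard rule
    assert nmd_rule(4, tm, TOY_NMD) is True


# ---------------------------------------------------------------------------
# Spot examples and invariants
# ---------------------------------------------------------------------------

def test_headline_examples(toy_transcript, toy_domain_map):
    tm, dm = toy_transcript, toy_domain_map
    sites = stop_gain_sites(tm)
    in_exon2 = next(s for s in sites if s[4] == 2)
    a = classify_variant(
        VariantRecord("v1", VariantScale.SMALL, hgvs_c=f"c.{in_exon2[0]}{in_exon2[1]}>{in_exon2[2]}"),
        tm, dm, TOY_CONFIG,
    )
    assert (a.main_class, a.leaky) == (RecClass.REC_I, False)
    assert a.ptc_codon == in_exon2[3]
    assert a.domain_bin is not None

    a = classify_variant(
        VariantRecord("v2", VariantScale.GROSS_DELETION, whole_gene=True,
                      med4_status=Med4Status.INCLUDED), tm, dm, TOY_CONFIG)
    assert (a.main_class, a.med4_subclass) == (RecClass.REC_II, Med4Subclass.PLUS)
    assert a.subclass_label == "REC_II_plus"

    in_exon1 = next(s for s in sites if s[4] == 1)
    a = classify_variant(
        VariantRecord("v3", VariantScale.SMALL, hgvs_c=f"c.{in_exon1[0]}{in_exon1[1]}>{in_exon1[2]}"),
        tm, dm, TOY_CONFIG,
    )
    assert a.main_class is RecClass.REC_III
    assert "ptc_in_exon_1_evades_nmd" in a.rationale

    # remote donor next to the in-frame exon 2 -> REC-III-leaky
    donor2 = tm.exons[1].cdna_end - tm.cds_start_cdna + 1
    a = classify_variant(
        VariantRecord("v4", VariantScale.SMALL, hgvs_c=f"c.{donor2}+5G>T"), tm, dm, TOY_CONFIG)
    assert (a.main_class, a.leaky) == (RecClass.REC_III, True)

    a = classify_variant(
        VariantRecord("v5", VariantScale.PROMOTER_REGULATORY, hgvs_c="c.-200G>A (regulatory)"),
        tm, dm, TOY_CONFIG)
    assert a.main_class is RecClass.REC_V


def test_validation_and_rationale_invariants(toy_transcript, toy_domain_map):
    with pytest.raises(VariantValidationError):
        VariantRecord("x", VariantScale.SMALL, hgvs_c="c.100C>T",
                      med4_status=Med4Status.INCLUDED).validate()
    with pytest.raises(VariantValidationError):
        VariantRecord("x", VariantScale.SMALL).validate()

    cases = build_grid(toy_transcript)
    for rec, _ in cases[::11]:
        a1 = classify_variant(rec, toy_transcript, toy_domain_map, TOY_CONFIG)
        a2 = classify_variant(rec, toy_transcript, toy_domain_map, TOY_CONFIG)
        assert a1 == a2                                     # determinism
        terminal = [r for r in a1.rationale if r.startswith("assign_")]
        assert len(terminal) == 1                           # exactly one rule fires
        if a1.leaky:
            assert any("remote" in r for r in a1.rationale)  # leaky only from remote sites
        if a1.main_class is RecClass.UNCLASSIFIED:
            assert a1.reason


def test_parse_hgvs_p_forms():
    assert parse_hgvs_p("p.Arg251Ter").ptc_codon == 251
    assert parse_hgvs_p("p.(Gln100*)").ptc_codon == 100
    assert parse_hgvs_p("p.Gly101ValfsTer5").ptc_codon == 105
    fs = parse_hgvs_p("p.Leu84fs")
    assert fs.ptc_codon == 84 and fs.approximate
    assert parse_hgvs_p("p.Ser567Leu").kind == "no_ptc"


def test_classify_cohort_counts(toy_transcript, toy_domain_map):
    sites = stop_gain_sites(toy_transcript)
    s2 = next(s for s in sites if s[4] == 2)
    s3 = next(s for s in sites if s[4] == 3)
    recs = [
        VariantRecord("a", VariantScale.SMALL, hgvs_c=f"c.{s2[0]}{s2[1]}>{s2[2]}"),
        VariantRecord("b", VariantScale.SMALL, hgvs_c=f"c.{s3[0]}{s3[1]}>{s3[2]}"),
        VariantRecord("c", VariantScale.GROSS_DELETION, whole_gene=True,
                      med4_status=Med4Status.EXCLUDED),
    ]
    _, table = classify_cohort(recs, toy_transcript, toy_domain_map, TOY_CONFIG)
    d = dict(zip(table["subclass"], table["n"]))
    assert d == {"REC_I": 2, "REC_II_minus": 1}
    pct = dict(zip(table["subclass"], table["percent"]))
    assert pct == {"REC_I": 66.7, "REC_II_minus": 33.3}

    _, table1 = classify_cohort(
        [VariantRecord("z", VariantScale.GROSS_DELETION)],  # no extent flags
        toy_transcript, toy_domain_map, TOY_CONFIG,
    )
    assert list(table1["subclass"]) == ["UNCLASSIFIED"]
    assert list(table1["percent"]) == [100.0]

    with pytest.raises(VariantValidationError):
        classify_cohort([], toy_transcript, toy_domain_map)
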