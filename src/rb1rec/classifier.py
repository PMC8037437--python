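"""Retinoblastoma variant effect classification (REC).

Maps each constitutional RB1 allele description to one of five effect
classes defined by the variant's predicted consequence for the pRB protein:

* **REC-I** — premature termination codon (PTC) in the NMD-competent part
  of the open reading frame: transcripts are largely degraded by
  nonsense-mediated decay, residual transcripts encode a C-truncated pRB.
* **REC-II** — whole-gene or 5'/promoter-including gross deletion:
  complete loss of pRB from the allele.  Subclassified by co-deletion of
  the neighbouring *MED4* gene (REC-II+ / REC-II−), a cis modifier.
* **REC-III** — missense/in-frame change, PTC in exon 1 (NMD-evading,
  N-terminally altered protein), or splice change without a PTC in the
  predicted mRNA: structurally altered pRB at normal abundance.
* **REC-IV** — 3'-end deletion or PTC in the NMD-escaping 3' exons:
  C-truncated pRB without a quantitative change.
* **REC-V** — regulatory promoter variant: reduced expression of normal pRB.

Splice-region variants at remote (non-invariant) positions are flagged
*leaky* (REC-I-leaky / REC-III-leaky): a fraction of transcripts is
expected to splice normally.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .domains import DomainMap, SegmentKind
from .transcript import (
    CdnaPosition,
    DEFAULT_SPLICE_WINDOW,
    ExonLocation,
    HgvsParseError,
    ParsedVariant,
    PtcPrediction,
    SplicePositionClass,
    SpliceWindow,
    TranscriptError,
    TranscriptModel,
    classify_splice_position,
    codon_of,
    exon_of,
    parse_hgvs_c,
    predict_ptc,
    skip_frame_effect,
)


class VariantValidationError(ValueError):
    """VariantRecord violates its own consistency rules."""


# ---------------------------------------------------------------------------
# Records and outcomes
# ---------------------------------------------------------------------------

class VariantScale(enum.Enum):
    SMALL = "small"
    GROSS_DELETION = "gross_deletion"
    PROMOTER_REGULATORY = "promoter_regulatory"


class Med4Status(enum.Enum):
    INCLUDED = "included"
    EXCLUDED = "excluded"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


class SpliceEffect(enum.Enum):
    PTC = "ptc"
    NO_PTC = "no_ptc"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantRecord:
    """One constitutional RB1 allele description."""

    variant_id: str
    scale: VariantScale
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    whole_gene: bool = False
    includes_promoter_5prime: bool = False
    includes_3prime_end: bool = False
    med4_status: Med4Status = Med4Status.NOT_APPLICABLE
    validated_splice_effect: SpliceEffect = SpliceEffect.UNKNOWN

    def validate(self) -> None:
        if self.scale is not VariantScale.GROSS_DELETION:
            if self.med4_status is not Med4Status.NOT_APPLICABLE:
                raise VariantValidationError(
                    f"{self.variant_id}: med4_status only applies to gross deletions"
                )
            if any((self.whole_gene, self.includes_promoter_5prime, self.includes_3prime_end)):
                raise VariantValidationError(
                    f"{self.variant_id}: gross-deletion flags set on a {self.scale.value} variant"
                )
            if not (self.hgvs_c or self.hgvs_p):
                raise VariantValidationError(
                    f"{self.variant_id}: small/promoter variants need hgvs_c or hgvs_p"
                )


class RecClass(enum.Enum):
    REC_I = "REC_I"
    REC_II = "REC_II"
    REC_III = "REC_III"
    REC_IV = "REC_IV"
    REC_V = "REC_V"
    UNCLASSIFIED = "UNCLASSIFIED"


class Med4Subclass(enum.Enum):
    PLUS = "plus"
    MINUS = "minus"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class RECAssignment:
    main_class: RecClass
    leaky: bool = False
    med4_subclass: Med4Subclass = Med4Subclass.NOT_APPLICABLE
    ptc_codon: Optional[int] = None
    domain_bin: Optional[tuple[str, SegmentKind]] = None
    rationale: tuple[str, ...] = ()
    reason: str = ""   # non-empty only for UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.leaky and self.main_class not in (RecClass.REC_I, RecClass.REC_III):
            raise VariantValidationError("leaky flag only valid with REC_I or REC_III")
        if (
            self.med4_subclass is not Med4Subclass.NOT_APPLICABLE
            and self.main_class is not RecClass.REC_II
        ):
            raise VariantValidationError("med4_subclass only valid with REC_II")
        if self.main_class is RecClass.UNCLASSIFIED and not self.reason:
            raise VariantValidationError("UNCLASSIFIED requires a reason")

    @property
    def subclass_label(self) -> str:
        """Reporting label: REC_I, REC_I_leaky, REC_II_plus, ... UNCLASSIFIED."""
        c = self.main_class
        if c is RecClass.REC_II:
            suffix = {
                Med4Subclass.PLUS: "_plus",
                Med4Subclass.MINUS: "_minus",
                Med4Subclass.UNKNOWN: "_unknown",
                Med4Subclass.NOT_APPLICABLE: "",
            }[self.med4_subclass]
            return c.value + suffix
        if self.leaky:
            return c.value + "_leaky"
        return c.value


# ---------------------------------------------------------------------------
# NMD rule
# ---------------------------------------------------------------------------

class NmdBoundaryMode(enum.Enum):
    FIFTY_NT = "fifty-nt"   # 50-nt junction heuristic inside the boundary exon
    EXON = "exon"           # hard exon boundary: whole boundary exon is NMD-competent


@dataclass(frozen=True)
class NmdRuleConfig:
    """NMD competence by PTC exon.

    PTCs in ``nmd_first_exon..nmd_last_exon`` elicit NMD; exon 1 PTCs evade
    it (NMD-insensitive first exon), as do PTCs downstream of
    ``nmd_last_exon``.  Inside the boundary exon itself the fifty-nt mode
    applies the canonical rule: a PTC more than ``junction_margin_nt``
    upstream of that exon's 3' junction still triggers NMD.
    """

    nmd_first_exon: int = 2
    nmd_last_exon: int = 25
    boundary_mode: NmdBoundaryMode = NmdBoundaryMode.FIFTY_NT
    junction_margin_nt: int = 50


DEFAULT_NMD_CONFIG = NmdRuleConfig()


def nmd_rule(
    ptc_exon: int,
    tm: TranscriptModel,
    config: NmdRuleConfig = DEFAULT_NMD_CONFIG,
    ptc_cdna_base: Optional[int] = None,
) -> bool:
    """Does a PTC in this exon elicit nonsense-mediated decay?

    ``ptc_cdna_base`` (HGVS c. coordinate of the stop codon's first base) is
    only consulted for the boundary exon under the fifty-nt mode; without it
    the boundary exon falls back to the hard-boundary resolution.
    """
    if not (1 <= ptc_exon <= tm.n_exons):
        raise TranscriptError(f"exon {ptc_exon}: no such exon")
    if ptc_exon < config.nmd_first_exon:
        return False
    if ptc_exon > config.nmd_last_exon:
        return False
    if ptc_exon < config.nmd_last_exon:
        return True
    # boundary exon
    if config.boundary_mode is NmdBoundaryMode.EXON or ptc_cdna_base is None:
        return True
    junction_cdna = tm.exons[ptc_exon - 1].cdna_end
    ptc_t = tm.c_to_cdna(ptc_cdna_base)
    return (junction_cdna - ptc_t) > config.junction_margin_nt


# ---------------------------------------------------------------------------
# Protein-level (hgvs_p) shortcut
# ---------------------------------------------------------------------------

_P_TER_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2}|[A-Z*])?(\d+)(\*|Ter)\)?$")
_P_FS_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])?fs(?:(\*|Ter)(\d+))?\)?$")
_P_MISSENSE_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])\)?$")
_P_INFRAME_RE = re.compile(r"^p\.\(?.+(del|dup|ins)\)?$")


@dataclass(frozen=True)
class ProteinConsequence:
    kind: str                       # "ptc" | "no_ptc"
    ptc_codon: Optional[int] = None
    approximate: bool = False       # True when only the variant codon is known


def parse_hgvs_p(s: str) -> ProteinConsequence:
    """Interpret a p. description as PTC / no-PTC.

    Handles nonsense (``p.Arg251Ter``, ``p.R251*``), frameshift with or
    without a stop distance (``p.Gly101ValfsTer5`` -> PTC at 105;
    ``p.Leu84fs`` -> PTC near codon 84, flagged approximate), missense and
    in-frame del/dup/ins (no PTC).
    """
    body = s.strip().replace(" ", "")
    m = _P_FS_RE.match(body)
    if m:
        start = int(m.group(2))
        if m.group(5):
            return ProteinConsequence("ptc", ptc_codon=start + int(m.group(5)) - 1)
        return ProteinConsequence("ptc", ptc_codon=start, approximate=True)
    m = _P_TER_RE.match(body)
    if m:
        return ProteinConsequence("ptc", ptc_codon=int(m.group(2)))
    m = _P_MISSENSE_RE.match(body)
    if m:
        return ProteinConsequence("no_ptc")
    if _P_INFRAME_RE.match(body):
        return ProteinConsequence("no_ptc")
    raise HgvsParseError(f"{s!r}: unrecognized protein-level description")


# ---------------------------------------------------------------------------
# The decision procedure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    splice_window: SpliceWindow = DEFAULT_SPLICE_WINDOW
    nmd: NmdRuleConfig = DEFAULT_NMD_CONFIG


DEFAULT_CLASSIFIER_CONFIG = ClassifierConfig()


def _domain_bin(codon: int, tm: TranscriptModel, dm: DomainMap):
    if 1 <= codon <= dm.protein_length:
        return dm.bin_of_codon(codon)
    return None


def _ptc_c_base(ptc_codon: int, tm: TranscriptModel) -> int:
    """Reference c. coordinate of a PTC codon's first base (clamped to CDS).

    For frameshifts the PTC codon lives in the mutant frame; mapping by
    codon arithmetic on the reference ignores the small indel offset, which
    is immaterial at the exon granularity the class rules need.
    """
    base = (ptc_codon - 1) * 3 + 1
    return min(max(base, 1), tm.cds_length)


def classify_variant(
    v: VariantRecord,
    tm: TranscriptModel,
    dm: DomainMap,
    config: ClassifierConfig = DEFAULT_CLASSIFIER_CONFIG,
) -> RECAssignment:
    """Assign a REC class to one variant record, with rule-level rationale.

    Deterministic and total: every record that passes validation receives
    exactly one terminal class, UNCLASSIFIED (with a reason) included.
    """
    v.validate()
    r: list[str] = []

    # (1)/(2) gross deletions, by extent flags
    if v.scale is VariantScale.GROSS_DELETION:
        r.append("gross_deletion")
        if v.whole_gene or v.includes_promoter_5prime:
            r.append("whole_gene" if v.whole_gene else "includes_promoter_5prime")
            sub = {
                Med4Status.INCLUDED: Med4Subclass.PLUS,
                Med4Status.EXCLUDED: Med4Subclass.MINUS,
                Med4Status.UNKNOWN: Med4Subclass.UNKNOWN,
                Med4Status.NOT_APPLICABLE: Med4Subclass.UNKNOWN,
            }[v.med4_status]
            r.append("assign_REC_II")
            return RECAssignment(RecClass.REC_II, med4_subclass=sub, rationale=tuple(r))
        if v.includes_3prime_end:
            r += ["includes_3prime_end_only", "assign_REC_IV"]
            return RECAssignment(RecClass.REC_IV, rationale=tuple(r))
        r.append("assign_UNCLASSIFIED")
        return RECAssignment(
            RecClass.UNCLASSIFIED, rationale=tuple(r),
            reason="gross deletion without extent flags (whole gene / 5' / 3')",
        )

    # (3) promoter regulatory variants
    if v.scale is VariantScale.PROMOTER_REGULATORY:
        r += ["promoter_regulatory", "assign_REC_V"]
        return RECAssignment(RecClass.REC_V, rationale=tuple(r))

    # small variants
    r.append("small_variant")
    parsed: Optional[ParsedVariant] = None
    if v.hgvs_c:
        try:
            parsed = parse_hgvs_c(v.hgvs_c)
        except HgvsParseError as e:
            r.append("assign_UNCLASSIFIED")
            return RECAssignment(
                RecClass.UNCLASSIFIED, rationale=tuple(r), reason=f"unparsable hgvs_c: {e}"
            )

    # (5) splice-region variants take the intronic route
    if parsed is not None and parsed.is_intronic:
        return _classify_splice(v, parsed, tm, dm, config, r)

    # (4) exonic small variants: establish PTC status
    ptc_codon: Optional[int] = None
    has_ptc: Optional[bool] = None
    if v.hgvs_p:   # protein-level call takes precedence over sequence prediction
        try:
            pc = parse_hgvs_p(v.hgvs_p)
        except HgvsParseError as e:
            r.append("assign_UNCLASSIFIED")
            return RECAssignment(
                RecClass.UNCLASSIFIED, rationale=tuple(r), reason=f"unparsable hgvs_p: {e}"
            )
        r.append("hgvs_p_consequence")
        has_ptc = pc.kind == "ptc"
        ptc_codon = pc.ptc_codon
        if pc.approximate:
            r.append("ptc_codon_approximate")
    elif parsed is not None:
        try:
            pred = predict_ptc(parsed, tm)
        except TranscriptError as e:
            r.append("assign_UNCLASSIFIED")
            return RECAssignment(
                RecClass.UNCLASSIFIED, rationale=tuple(r), reason=str(e)
            )
        r.append("ptc_predicted" if pred.ptc_codon else "no_ptc_predicted")
        has_ptc = pred.ptc_codon is not None
        ptc_codon = pred.ptc_codon
    else:
        r.append("assign_UNCLASSIFIED")
        return RECAssignment(
            RecClass.UNCLASSIFIED, rationale=tuple(r),
            reason="small variant with neither parsable hgvs_c nor hgvs_p",
        )

    if not has_ptc:
        # missense / in-frame: focal structural change
        if parsed is not None:
            loc = exon_of(parsed.start, tm)
            if loc.kind == "exon" and loc.index > config.nmd.nmd_last_exon:
                r.append("missense_in_3prime_exons")
        r.append("assign_REC_III")
        return RECAssignment(RecClass.REC_III, rationale=tuple(r))

    assert ptc_codon is not None
    ptc_base = _ptc_c_base(ptc_codon, tm)
    ptc_exon = exon_of(CdnaPosition(ptc_base), tm).index
    if ptc_exon == 1:
        r += ["ptc_in_exon_1_evades_nmd", "assign_REC_III"]
        return RECAssignment(RecClass.REC_III, rationale=tuple(r))
    if nmd_rule(ptc_exon, tm, config.nmd, ptc_cdna_base=ptc_base):
        r += ["nmd_triggered", "assign_REC_I"]
        return RECAssignment(
            RecClass.REC_I, ptc_codon=ptc_codon,
            domain_bin=_domain_bin(ptc_codon, tm, dm), rationale=tuple(r),
        )
    r += ["nmd_escaped_3prime", "assign_REC_IV"]
    return RECAssignment(RecClass.REC_IV, ptc_codon=ptc_codon, rationale=tuple(r))


def _classify_splice(
    v: VariantRecord,
    parsed: ParsedVariant,
    tm: TranscriptModel,
    dm: DomainMap,
    config: ClassifierConfig,
    r: list[str],
) -> RECAssignment:
    pos = next(p for p in parsed.positions if not p.is_exonic)
    splice_class = classify_splice_position(pos, config.splice_window)
    r.append(f"splice_position_{splice_class.value}")
    if splice_class is SplicePositionClass.NOT_SPLICE_REGION:
        r.append("assign_UNCLASSIFIED")
        return RECAssignment(
            RecClass.UNCLASSIFIED, rationale=tuple(r),
            reason=f"intronic position c.{pos} outside the configured splice window",
        )

    # predicted-mRNA PTC status: validated effect wins, else default exon skip
    if v.validated_splice_effect is not SpliceEffect.UNKNOWN:
        r.append("validated_splice_effect")
        has_ptc = v.validated_splice_effect is SpliceEffect.PTC
    else:
        intron = exon_of(pos, tm).index
        skipped_exon = intron if pos.intron_offset > 0 else intron + 1
        try:
            effect = skip_frame_effect(skipped_exon, tm)
        except TranscriptError as e:
            r.append("assign_UNCLASSIFIED")
            return RECAssignment(
                RecClass.UNCLASSIFIED, rationale=tuple(r),
                reason=f"default exon-skip consequence undefined: {e}",
            )
        r.append(f"default_skip_exon_{skipped_exon}_{effect}")
        has_ptc = effect == "frameshift"

    leaky = splice_class is SplicePositionClass.REMOTE
    if has_ptc:
        r.append("assign_REC_I_leaky" if leaky else "assign_REC_I")
        return RECAssignment(RecClass.REC_I, leaky=leaky, rationale=tuple(r))
    r.append("assign_REC_III_leaky" if leaky else "assign_REC_III")
    return RECAssignment(RecClass.REC_III, leaky=leaky, rationale=tuple(r))


# ---------------------------------------------------------------------------
# Cohort-level classification
# ---------------------------------------------------------------------------

SUBCLASS_ORDER = [
    "REC_I", "REC_I_leaky",
    "REC_II_plus", "REC_II_minus", "REC_II_unknown",
    "REC_III", "REC_III_leaky",
    "REC_IV", "REC_V", "UNCLASSIFIED",
]


def classify_cohort(
    variants: Sequence[VariantRecord],
    tm: TranscriptModel,
    dm: DomainMap,
    config: ClassifierConfig = DEFAULT_CLASSIFIER_CONFIG,
) -> tuple[dict[str, RECAssignment], pd.DataFrame]:
    """Classify every variant and tabulate subclass counts and percentages.

    Returns (assignments keyed by variant_id, count table).  The table has
    one row per observed subclass label in canonical order with columns
    ``n`` and ``percent`` (half-up, one decimal, summing to 100 up to
    rounding).
    """
    if len(variants) == 0:
        raise VariantValidationError("classify_cohort requires a non-empty variant list")
    assignments = {v.variant_id: classify_variant(v, tm, dm, config) for v in variants}
    labels = pd.Series([a.subclass_label for a in assignments.values()], dtype="object")
    counts = labels.value_counts()
    order = [s for s in SUBCLASS_ORDER if s in counts.index]
    order += [s for s in counts.index if s not in order]
    counts = counts.reindex(order)
    from .stats import round_half_up  # shared rounding convention
    table = pd.DataFrame({
        "subclass": counts.index,
        "n": counts.values,
        "percent": [round_half_up(100.0 * c / len(variants), 1) for c in counts.values],
    }).reset_index(drop=True)
    return assignments, table
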