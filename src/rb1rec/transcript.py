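"""Transcript coordinate model and small-variant interpretation.

This module resolves HGVS c.-notation variant descriptions against a
transcript model: which exon a position falls in, which codon a coding base
belongs to, whether an intronic position hits an invariant or a remote
splice signal, and — given the coding sequence — whether an edit creates a
premature termination codon (PTC).

Coordinates follow the HGVS coding-DNA convention: ``c.1`` is the first
base of the start codon; intronic positions are written as an exonic anchor
base plus a signed offset (``+k`` = k bases into the downstream intron,
``-k`` = k bases upstream of the exon).  Only coding anchor bases are
supported (no ``c.-`` / ``c.*`` UTR coordinates): promoter-level variants
are handled upstream of this module by an explicit scale flag.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

_NUC = frozenset("ACGT")


class TranscriptError(ValueError):
    """Invalid transcript model or position outside the transcript."""


class HgvsParseError(ValueError):
    """Malformed HGVS c. description; message names the offending token."""


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    index: int          # 1-based exon number
    cdna_start: int     # 1-based, transcript coordinates (5' end = 1)
    cdna_end: int


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS bounds of one transcript.

    ``cds_start_cdna``/``cds_end_cdna`` are in transcript coordinates
    (1-based from the 5' end of the mRNA), so HGVS c. position ``c`` maps to
    transcript position ``c + cds_start_cdna - 1``.
    """

    gene_symbol: str
    exons: tuple[Exon, ...]
    cds_start_cdna: int
    cds_end_cdna: int
    cds_sequence: Optional[str] = None
    version: str = "unspecified"
    promoter_note: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise TranscriptError("transcript must have at least one exon")
        prev_end = 0
        for i, ex in enumerate(self.exons, start=1):
            if ex.index != i:
                raise TranscriptError(f"exon indices must be 1..n in order, got {ex.index} at slot {i}")
            if ex.cdna_start > ex.cdna_end:
                raise TranscriptError(f"exon {ex.index}: cdna_start > cdna_end")
            if ex.cdna_start != prev_end + 1:
                raise TranscriptError(
                    f"exon {ex.index} starts at {ex.cdna_start}, expected {prev_end + 1} "
                    "(exons must tile the cDNA contiguously)"
                )
            prev_end = ex.cdna_end
        if not (1 <= self.cds_start_cdna <= self.cds_end_cdna <= prev_end):
            raise TranscriptError("CDS bounds must lie within the transcript")
        if self.cds_length % 3 != 0:
            raise TranscriptError(f"CDS length {self.cds_length} not divisible by 3")
        if self.cds_sequence is not None:
            seq = self.cds_sequence.upper()
            if len(seq) != self.cds_length:
                raise TranscriptError(
                    f"cds_sequence length {len(seq)} != CDS length {self.cds_length}"
                )
            if set(seq) - _NUC:
                raise TranscriptError("cds_sequence contains non-ACGT characters")
            if seq[:3] != "ATG":
                raise TranscriptError("cds_sequence must begin with ATG")
            if seq[-3:] not in ("TAA", "TAG", "TGA"):
                raise TranscriptError("cds_sequence must end with a stop codon")
            object.__setattr__(self, "cds_sequence", seq)

    @property
    def cds_length(self) -> int:
        return self.cds_end_cdna - self.cds_start_cdna + 1

    @property
    def protein_length(self) -> int:
        """Length of the encoded protein in amino acids (stop excluded)."""
        return self.cds_length // 3 - 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cdna_length(self) -> int:
        return self.exons[-1].cdna_end

    def c_to_cdna(self, c_base: int) -> int:
        """Map an HGVS c. coordinate (>= 1) to a transcript coordinate."""
        if c_base < 1:
            raise TranscriptError(f"c.{c_base}: only coding coordinates >= 1 are supported")
        t = c_base + self.cds_start_cdna - 1
        if t > self.cdna_length:
            raise TranscriptError(f"c.{c_base} lies beyond the transcript 3' end")
        return t

    def coding_length_of_exon(self, exon_index: int) -> int:
        ex = self.exons[exon_index - 1]
        lo = max(ex.cdna_start, self.cds_start_cdna)
        hi = min(ex.cdna_end, self.cds_end_cdna)
        return max(0, hi - lo + 1)


# ---------------------------------------------------------------------------
# Positions and parsed variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CdnaPosition:
    """One HGVS c. position: coding anchor base plus signed intron offset."""

    base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise HgvsParseError(f"coding base must be >= 1, got {self.base}")

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset == 0

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return str(self.base)
        return f"{self.base}{self.intron_offset:+d}"


class VariantKind(enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


@dataclass(frozen=True)
class ParsedVariant:
    kind: VariantKind
    positions: tuple[CdnaPosition, ...]
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    raw: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) not in (1, 2):
            raise HgvsParseError("variant must carry one or two positions")
        if len(self.positions) == 2 and self.positions[0] > self.positions[1]:
            raise HgvsParseError(f"{self.raw!r}: start position after end position")
        if self.kind is VariantKind.SUBSTITUTION:
            if len(self.positions) != 1 or not self.ref_allele or not self.alt_allele:
                raise HgvsParseError(f"{self.raw!r}: substitution needs one position, ref and alt")

    @property
    def start(self) -> CdnaPosition:
        return self.positions[0]

    @property
    def end(self) -> CdnaPosition:
        return self.positions[-1]

    @property
    def is_intronic(self) -> bool:
        return any(not p.is_exonic for p in self.positions)

    def to_hgvs(self) -> str:
        """Normalized HGVS c. serialization (lossy w.r.t. spacing only)."""
        pos = str(self.positions[0])
        if len(self.positions) == 2:
            pos = f"{pos}_{self.positions[1]}"
        k = self.kind
        if k is VariantKind.SUBSTITUTION:
            return f"c.{pos}{self.ref_allele}>{self.alt_allele}"
        if k is VariantKind.DELETION:
            return f"c.{pos}del"
        if k is VariantKind.DUPLICATION:
            return f"c.{pos}dup"
        if k is VariantKind.INSERTION:
            return f"c.{pos}ins{self.alt_allele}"
        return f"c.{pos}delins{self.alt_allele}"


_POS_RE = r"(\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^{_POS_RE}([ACGT])>([ACGT])$")
_RANGE_RE = rf"{_POS_RE}(?:_{_POS_RE})?"
_DEL_RE = re.compile(rf"^{_RANGE_RE}del([ACGT]*)$")
_DUP_RE = re.compile(rf"^{_RANGE_RE}dup([ACGT]*)$")
_INS_RE = re.compile(rf"^{_POS_RE}_{_POS_RE}ins([ACGT]+)$")
_DELINS_RE = re.compile(rf"^{_RANGE_RE}delins([ACGT]+)$")


def _pos(base: str, off: Optional[str]) -> CdnaPosition:
    return CdnaPosition(int(base), int(off) if off else 0)


def parse_hgvs_c(s: str) -> ParsedVariant:
    """Parse a c.-prefixed small-variant description.

    Supported grammar: substitution (``c.100C>T``), deletion
    (``c.99_101del``), duplication, insertion (``c.100_101insAT``) and
    deletion-insertion, with signed intronic offsets (``c.607+1G>T``).
    Raises :class:`HgvsParseError` naming the offending token otherwise.
    """
    if not isinstance(s, str):
        raise HgvsParseError(f"expected a string, got {type(s).__name__}")
    raw = s.strip()
    body = raw.replace(" ", "")
    if not body.startswith("c."):
        raise HgvsParseError(f"{raw!r}: missing 'c.' prefix")
    body = body[2:]
    if not body:
        raise HgvsParseError(f"{raw!r}: empty description after 'c.'")

    m = _SUB_RE.match(body)
    if m:
        return ParsedVariant(
            VariantKind.SUBSTITUTION, (_pos(m.group(1), m.group(2)),),
            ref_allele=m.group(3), alt_allele=m.group(4), raw=raw,
        )
    m = _INS_RE.match(body)
    if m:
        p1, p2 = _pos(m.group(1), m.group(2)), _pos(m.group(3), m.group(4))
        return ParsedVariant(VariantKind.INSERTION, (p1, p2), alt_allele=m.group(5), raw=raw)
    m = _DELINS_RE.match(body)
    if m:
        positions = _range_positions(m)
        return ParsedVariant(VariantKind.DELINS, positions, alt_allele=m.group(5), raw=raw)
    m = _DEL_RE.match(body)
    if m:
        return ParsedVariant(
            VariantKind.DELETION, _range_positions(m), ref_allele=m.group(5) or None, raw=raw
        )
    m = _DUP_RE.match(body)
    if m:
        return ParsedVariant(
            VariantKind.DUPLICATION, _range_positions(m), ref_allele=m.group(5) or None, raw=raw
        )
    raise HgvsParseError(f"{raw!r}: unrecognized variant description {body!r}")


def _range_positions(m: re.Match) -> tuple[CdnaPosition, ...]:
    p1 = _pos(m.group(1), m.group(2))
    if m.group(3) is None:
        return (p1,)
    return (p1, _pos(m.group(3), m.group(4)))


# ---------------------------------------------------------------------------
# Coordinate resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonLocation:
    """Result of exon_of: either an exon or a flanking intron."""

    kind: str    # "exon" | "intron"
    index: int   # exon number, or intron number (intron k lies between exon k and k+1)


def exon_of(pos: CdnaPosition, tm: TranscriptModel) -> ExonLocation:
    """Locate a c. position in the exon/intron structure.

    Intronic offsets are interpreted HGVS-style: a positive offset hangs off
    the donor (3') side of the anchor base's exon, a negative offset off the
    acceptor (5') side, so ``c.100+2`` with exon 1 ending at c.100 is in
    intron 1, and ``c.101-1`` is also in intron 1.
    """
    t = tm.c_to_cdna(pos.base)
    exon_idx = next(ex.index for ex in tm.exons if ex.cdna_start <= t <= ex.cdna_end)
    if pos.intron_offset == 0:
        return ExonLocation("exon", exon_idx)
    if pos.intron_offset > 0:
        if exon_idx == tm.n_exons:
            raise TranscriptError(f"c.{pos}: no intron downstream of the last exon")
        return ExonLocation("intron", exon_idx)
    if exon_idx == 1:
        raise TranscriptError(f"c.{pos}: no intron upstream of exon 1")
    return ExonLocation("intron", exon_idx - 1)


def codon_of(pos: CdnaPosition, tm: TranscriptModel) -> int:
    """1-based protein codon containing a coding base (stop = protein_length+1)."""
    if not pos.is_exonic:
        raise TranscriptError(f"c.{pos}: intronic position has no codon")
    if not (1 <= pos.base <= tm.cds_length):
        raise TranscriptError(f"c.{pos.base}: outside the CDS (1..{tm.cds_length})")
    return (pos.base + 2) // 3


class SplicePositionClass(enum.Enum):
    INVARIANT = "invariant"
    REMOTE = "remote"
    NOT_SPLICE_REGION = "not_splice_region"


@dataclass(frozen=True)
class SpliceWindow:
    """Intronic windows defining the splice region.

    Donor window covers offsets +donor_min..+donor_max downstream of an
    exon; acceptor window covers acceptor_min..acceptor_max (negative)
    upstream.  Offsets +-1/+-2 are the invariant GT/AG dinucleotides.
    """

    donor_min: int = 1
    donor_max: int = 6
    acceptor_min: int = -12
    acceptor_max: int = -1

    def __post_init__(self) -> None:
        if not (1 <= self.donor_min <= self.donor_max):
            raise ValueError("donor window must satisfy 1 <= min <= max")
        if not (self.acceptor_min <= self.acceptor_max <= -1):
            raise ValueError("acceptor window must satisfy min <= max <= -1")


DEFAULT_SPLICE_WINDOW = SpliceWindow()


def classify_splice_position(
    pos: CdnaPosition, window: SpliceWindow = DEFAULT_SPLICE_WINDOW
) -> SplicePositionClass:
    """Invariant (+-1/+-2), remote (elsewhere inside the window), or neither.

    Exonic positions are never splice-region here: their consequence is
    taken to be the coding one unless a validated splice effect overrides.
    """
    off = pos.intron_offset
    if off == 0:
        return SplicePositionClass.NOT_SPLICE_REGION
    if abs(off) <= 2:
        return SplicePositionClass.INVARIANT
    if off > 0 and window.donor_min <= off <= window.donor_max:
        return SplicePositionClass.REMOTE
    if off < 0 and window.acceptor_min <= off <= window.acceptor_max:
        return SplicePositionClass.REMOTE
    return SplicePositionClass.NOT_SPLICE_REGION


# ---------------------------------------------------------------------------
# PTC prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PtcPrediction:
    """Outcome of predict_ptc.

    ``ptc_codon`` is the 1-based stop position in the mutant reading frame;
    None with ``note`` set when the edit creates no premature stop.
    """

    ptc_codon: Optional[int]
    note: str = ""


def _apply_edit(cds: str, v: ParsedVariant) -> str:
    """Apply a small exonic edit to the CDS string (c.1 = index 0)."""
    i = v.start.base - 1
    j = v.end.base - 1
    k = v.kind
    if k is VariantKind.SUBSTITUTION:
        if cds[i] != v.ref_allele:
            raise TranscriptError(
                f"{v.raw!r}: reference allele {v.ref_allele} does not match CDS base "
                f"{cds[i]} at c.{v.start.base}"
            )
        return cds[:i] + v.alt_allele + cds[i + 1:]
    if k is VariantKind.DELETION:
        return cds[:i] + cds[j + 1:]
    if k is VariantKind.DUPLICATION:
        return cds[: j + 1] + cds[i : j + 1] + cds[j + 1:]
    if k is VariantKind.INSERTION:
        return cds[: i + 1] + v.alt_allele + cds[i + 1:]
    return cds[:i] + v.alt_allele + cds[j + 1:]  # delins


def predict_ptc(v: ParsedVariant, tm: TranscriptModel) -> PtcPrediction:
    """Predict the premature termination codon created by a small exonic edit.

    The edit is applied to the CDS, the mutant is translated from the start
    codon, and the first in-frame stop is reported if it is premature, i.e.
    not the mutant's own terminal stop after a frame-preserving edit.
    Requires ``tm.cds_sequence``.
    """
    if tm.cds_sequence is None:
        raise TranscriptError("predict_ptc requires a transcript with cds_sequence")
    if v.is_intronic:
        raise TranscriptError(f"{v.raw!r}: predict_ptc applies to exonic variants only")
    for p in v.positions:
        if not (1 <= p.base <= tm.cds_length):
            raise TranscriptError(f"{v.raw!r}: position c.{p.base} outside the CDS")

    mutant = _apply_edit(tm.cds_sequence, v)
    frame_preserved = (len(mutant) - len(tm.cds_sequence)) % 3 == 0
    n_codons = len(mutant) // 3
    protein = str(Seq(mutant[: n_codons * 3]).translate())
    stop_idx = protein.find("*")
    if stop_idx == -1:
        return PtcPrediction(None, note="no PTC: no stop codon before transcript end")
    stop_codon = stop_idx + 1
    if frame_preserved and stop_codon == n_codons:
        return PtcPrediction(None, note="no PTC: frame preserved, normal stop retained")
    return PtcPrediction(stop_codon)


def skip_frame_effect(exon_index: int, tm: TranscriptModel) -> str:
    """Frame consequence of skipping one internal coding exon.

    Returns ``"in_frame"`` when the exon's coding length is divisible by 3,
    ``"frameshift"`` otherwise.  First/last exons cannot be skipped.
    """
    if exon_index in (1, tm.n_exons):
        raise TranscriptError(
            f"exon {exon_index}: skipping the first or last exon is not a defined splice outcome"
        )
    if not (1 <= exon_index <= tm.n_exons):
        raise TranscriptError(f"exon {exon_index}: no such exon")
    clen = tm.coding_length_of_exon(exon_index)
    if clen == 0:
        raise TranscriptError(f"exon {exon_index}: contains no coding sequence")
    return "in_frame" if clen % 3 == 0 else "frameshift"
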