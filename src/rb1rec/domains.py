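"""pRB structural segmentation: named segments and the structured/linker split.

The retinoblastoma protein consists of alpha-helical structured domains
(RB-N, pocket A, pocket B, RB-C) connected by unstructured linker regions
carrying CDK phosphorylation sites.  A :class:`DomainMap` is an ordered,
gap-free, non-overlapping partition of residues 1..protein_length into
segments, each labelled ``structured`` or ``linker``; the labels are data,
not code, so alternative segmentations load from config without edits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence


class DomainMapError(ValueError):
    """Segmentation violates coverage, ordering, or uniqueness."""


class SegmentKind(enum.Enum):
    STRUCTURED = "structured"
    LINKER = "linker"


@dataclass(frozen=True)
class Segment:
    name: str
    aa_start: int
    aa_end: int
    kind: SegmentKind


@dataclass(frozen=True)
class DomainMap:
    protein_length: int
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise DomainMapError("protein_length must be positive")
        if not self.segments:
            raise DomainMapError("domain map must contain at least one segment")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DomainMapError(f"duplicate segment names: {dupes}")
        problems: list[str] = []
        expected = 1
        for s in self.segments:
            if s.aa_start > s.aa_end:
                problems.append(f"segment {s.name}: aa_start {s.aa_start} > aa_end {s.aa_end}")
            if s.aa_start > expected:
                problems.append(f"gap at position {expected} (before segment {s.name})")
            elif s.aa_start < expected:
                problems.append(f"overlap at position {s.aa_start} (segment {s.name})")
            expected = s.aa_end + 1
        if expected != self.protein_length + 1:
            if expected <= self.protein_length:
                problems.append(f"gap at position {expected} (after segment {self.segments[-1].name})")
            else:
                problems.append(
                    f"segment {self.segments[-1].name} extends beyond protein length "
                    f"{self.protein_length}"
                )
        if problems:
            raise DomainMapError("; ".join(problems))

    def bin_of_codon(self, aa: int) -> tuple[str, SegmentKind]:
        return bin_of_codon(aa, self)


def load_domain_map(config: Mapping) -> DomainMap:
    """Build and validate a DomainMap from a config mapping.

    Expected shape::

        {"protein_length": 928,
         "segments": [{"name": "RB-N", "aa_start": 53, "aa_end": 355,
                       "kind": "structured"}, ...]}
    """
    try:
        length = int(config["protein_length"])
        raw_segments: Sequence[Mapping] = config["segments"]
    except KeyError as e:
        raise DomainMapError(f"domain map config missing key {e.args[0]!r}") from None
    segments = []
    for rec in raw_segments:
        try:
            kind = SegmentKind(str(rec["kind"]).lower())
        except ValueError:
            raise DomainMapError(
                f"segment {rec.get('name', '?')}: kind must be 'structured' or 'linker', "
                f"got {rec.get('kind')!r}"
            ) from None
        segments.append(
            Segment(str(rec["name"]), int(rec["aa_start"]), int(rec["aa_end"]), kind)
        )
    segments.sort(key=lambda s: s.aa_start)
    return DomainMap(protein_length=length, segments=tuple(segments))


def bin_of_codon(aa: int, dm: DomainMap) -> tuple[str, SegmentKind]:
    """Return (segment name, kind) for a 1-based amino-acid position."""
    if not (1 <= aa <= dm.protein_length):
        raise DomainMapError(f"amino-acid position {aa} outside 1..{dm.protein_length}")
    for s in dm.segments:
        if s.aa_start <= aa <= s.aa_end:
            return s.name, s.kind
    raise AssertionError("unreachable: validated map covers every position")
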