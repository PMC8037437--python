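"""Readers and writers for the exchange formats.

Canonical exchange format is TSV (UTF-8, header row, ``.`` for missing
values, booleans as ``true``/``false``, enums as lower-case tokens); model
configurations (transcript, domain map) are JSON.  A synthetic default
transcript and domain map ship with the package for demos and simulations.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .classifier import (
    Med4Status,
    RECAssignment,
    SpliceEffect,
    VariantRecord,
    VariantScale,
    VariantValidationError,
)
from .domains import DomainMap, load_domain_map
from .stats import FamilyHistory, Laterality, PatientRecord
from .transcript import Exon, TranscriptModel

PathLike = Union[str, Path]
MISSING = "."


class TableFormatError(ValueError):
    """A table violates the documented schema."""


# ---------------------------------------------------------------------------
# JSON configs
# ---------------------------------------------------------------------------

def transcript_to_dict(tm: TranscriptModel) -> dict:
    return {
        "gene_symbol": tm.gene_symbol,
        "version": tm.version,
        "exons": [
            {"index": e.index, "cdna_start": e.cdna_start, "cdna_end": e.cdna_end}
            for e in tm.exons
        ],
        "cds_start_cdna": tm.cds_start_cdna,
        "cds_end_cdna": tm.cds_end_cdna,
        "cds_sequence": tm.cds_sequence,
        "promoter_note": tm.promoter_note,
    }


def transcript_from_dict(d: dict) -> TranscriptModel:
    return TranscriptModel(
        gene_symbol=d["gene_symbol"],
        exons=tuple(
            Exon(int(e["index"]), int(e["cdna_start"]), int(e["cdna_end"]))
            for e in d["exons"]
        ),
        cds_start_cdna=int(d["cds_start_cdna"]),
        cds_end_cdna=int(d["cds_end_cdna"]),
        cds_sequence=d.get("cds_sequence"),
        version=d.get("version", "unspecified"),
        promoter_note=d.get("promoter_note", ""),
    )


def read_transcript_model(path: PathLike) -> TranscriptModel:
    with open(path, encoding="utf-8") as fh:
        return transcript_from_dict(json.load(fh))


def write_transcript_model(tm: TranscriptModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(transcript_to_dict(tm), indent=1), encoding="utf-8")


def read_domain_map(path: PathLike) -> DomainMap:
    with open(path, encoding="utf-8") as fh:
        return load_domain_map(json.load(fh))


def write_domain_map(dm: DomainMap, path: PathLike) -> None:
    d = {
        "protein_length": dm.protein_length,
        "segments": [
            {"name": s.name, "aa_start": s.aa_start, "aa_end": s.aa_end, "kind": s.kind.value}
            for s in dm.segments
        ],
    }
    Path(path).write_text(json.dumps(d, indent=1), encoding="utf-8")


def load_packaged_transcript() -> TranscriptModel:
    """Synthetic default RB1-like transcript shipped with the package.

    27 exons, 928-aa protein, 2787-nt CDS — the exon boundaries and the
    sequence are synthetic stand-ins; load a curated transcript config for
    real variant interpretation.
    """
    text = resources.files("rb1rec.data").joinpath("rb1_transcript.synthetic.json").read_text()
    return transcript_from_dict(json.loads(text))


def load_packaged_domain_map() -> DomainMap:
    """Synthetic default pRB domain map (approximate residue boundaries)."""
    text = resources.files("rb1rec.data").joinpath("rb1_domains.synthetic.json").read_text()
    return load_domain_map(json.loads(text))


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s in ("", MISSING) else s


def _bool(value, default: bool = False) -> bool:
    s = _opt(value)
    if s is None:
        return default
    if s.lower() in ("true", "1", "yes"):
        return True
    if s.lower() in ("false", "0", "no"):
        return False
    raise TableFormatError(f"expected true/false, got {value!r}")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


VARIANT_COLUMNS = [
    "variant_id", "scale", "hgvs_c", "hgvs_p", "whole_gene",
    "includes_promoter_5prime", "includes_3prime_end", "med4_status",
    "validated_splice_effect",
]


def read_variant_table(path: PathLike, permissive: bool = False):
    """Read a variant TSV into validated VariantRecords.

    Required columns: ``variant_id`` and ``scale``; the rest default to
    missing.  In strict mode the first invalid row raises with its line
    number; in permissive mode invalid rows are skipped and reported.
    Returns (records, list of (line_number, message) for skipped rows).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant_id" not in df.columns:
        raise TableFormatError(f"{path}: missing required column 'variant_id'")
    if "scale" not in df.columns and "hgvs_c" not in df.columns:
        raise TableFormatError(f"{path}: need a 'scale' or 'hgvs_c' column")
    records: list[VariantRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            scale_s = _opt(row.get("scale")) or "small"
            rec = VariantRecord(
                variant_id=_opt(row["variant_id"]) or "",
                scale=VariantScale(scale_s),
                hgvs_c=_opt(row.get("hgvs_c")),
                hgvs_p=_opt(row.get("hgvs_p")),
                whole_gene=_bool(row.get("whole_gene")),
                includes_promoter_5prime=_bool(row.get("includes_promoter_5prime")),
                includes_3prime_end=_bool(row.get("includes_3prime_end")),
                med4_status=Med4Status(_opt(row.get("med4_status")) or "not_applicable"),
                validated_splice_effect=SpliceEffect(
                    _opt(row.get("validated_splice_effect")) or "unknown"
                ),
            )
            if not rec.variant_id:
                raise VariantValidationError("empty variant_id")
            rec.validate()
        except (ValueError, KeyError) as e:
            if permissive:
                problems.append((line_no, str(e)))
                continue
            raise TableFormatError(f"{path} line {line_no}: {e}") from e
        records.append(rec)
    return records, problems


def write_variant_table(records: Sequence[VariantRecord], path: PathLike) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "scale": v.scale.value,
            "hgvs_c": v.hgvs_c or MISSING,
            "hgvs_p": v.hgvs_p or MISSING,
            "whole_gene": _fmt_bool(v.whole_gene),
            "includes_promoter_5prime": _fmt_bool(v.includes_promoter_5prime),
            "includes_3prime_end": _fmt_bool(v.includes_3prime_end),
            "med4_status": v.med4_status.value,
            "validated_splice_effect": v.validated_splice_effect.value,
        }
        for v in records
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


COHORT_COLUMNS = [
    "patient_id", "variant_id", "laterality", "age_at_dx_months",
    "tumors_less_affected_eye", "family_history", "ip_variant",
]


def read_cohort_table(path: PathLike) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"patient_id", "laterality", "age_at_dx_months"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        line_no = i + 2
        try:
            age_s = _opt(row["age_at_dx_months"])
            if age_s is None:
                raise TableFormatError(
                    f"patient {_opt(row['patient_id'])}: missing age_at_dx_months"
                )
            tumors = _opt(row.get("tumors_less_affected_eye"))
            records.append(PatientRecord(
                patient_id=_opt(row["patient_id"]) or "",
                variant_id=_opt(row.get("variant_id")) or "",
                laterality=Laterality(_opt(row["laterality"]) or ""),
                age_at_dx=float(age_s),
                tumors_less_affected_eye=None if tumors is None else int(tumors),
                family_history=FamilyHistory(_opt(row.get("family_history")) or "unknown"),
                ip_variant=_bool(row.get("ip_variant")),
            ))
        except ValueError as e:
            raise TableFormatError(f"{path} line {line_no}: {e}") from e
    return records


def write_cohort_table(patients: Sequence[PatientRecord], path: PathLike) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "variant_id": p.variant_id,
            "laterality": p.laterality.value,
            "age_at_dx_months": f"{p.age_at_dx:g}",
            "tumors_less_affected_eye": (
                MISSING if p.tumors_less_affected_eye is None else p.tumors_less_affected_eye
            ),
            "family_history": p.family_history.value,
            "ip_variant": _fmt_bool(p.ip_variant),
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assignment output
# ---------------------------------------------------------------------------

def assignments_to_frame(assignments: dict[str, RECAssignment]) -> pd.DataFrame:
    rows = []
    for vid, a in assignments.items():
        seg, kind = (a.domain_bin if a.domain_bin else (None, None))
        rows.append({
            "variant_id": vid,
            "main_class": a.main_class.value,
            "subclass": a.subclass_label,
            "leaky": _fmt_bool(a.leaky),
            "med4_subclass": a.med4_subclass.value,
            "ptc_codon": MISSING if a.ptc_codon is None else a.ptc_codon,
            "domain_segment": seg or MISSING,
            "domain_kind": kind.value if kind else MISSING,
            "rationale": ";".join(a.rationale),
            "reason": a.reason or MISSING,
        })
    return pd.DataFrame(rows)


def write_assignments(assignments: dict[str, RECAssignment], path: PathLike) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def write_curve_points(points, path: PathLike) -> None:
    """Write (t, logS) step points as a two-column TSV for plotting."""
    pd.DataFrame(points, columns=["t_months", "log_S"]).to_csv(path, sep="\t", index=False)
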