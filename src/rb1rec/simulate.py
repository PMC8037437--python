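"""Synthetic cohorts of class-labelled RB1 variants with matched phenotypes.

Every downstream stage — classification, class summaries, exponential
onset fits — is testable without patient data: the simulator fabricates
variant descriptions *guaranteed by construction* to classify into a
requested REC class (e.g. nonsense substitutions in ORF exons 2–24 for
REC-I, whole-gene deletion flags for REC-II±) and draws the matching
phenotypes from the generating models the analyses assume: ages at
diagnosis from Exponential(λ), laterality from a per-class Bernoulli (or
from the Poisson two-eye model), tumour counts from a truncated Poisson.

The default specification mirrors the class structure of a German referral
cohort of 287 non-screened children: per-class sizes, onset rates set so
the exponential median ln2/λ matches each class's reported median age, and
per-class bilateral fractions.  Ages in the demo spec are truncated at 48
months (the cohort's observed maximum); parameter-recovery experiments run
untruncated, since truncation biases the MLE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .classifier import (
    Med4Status,
    SpliceEffect,
    VariantRecord,
    VariantScale,
)
from .domains import DomainMap, SegmentKind, Segment
from .stats import (
    FamilyHistory,
    Laterality,
    PatientRecord,
    fit_exponential,
    poisson_laterality,
)
from .transcript import Exon, TranscriptModel

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


class SimulationError(ValueError):
    """Spec requests a cohort the fabricator cannot construct."""


# ---------------------------------------------------------------------------
# Synthetic transcripts
# ---------------------------------------------------------------------------

def make_synthetic_transcript(
    seed: int = 0,
    n_exons: int = 27,
    protein_length: int = 928,
    utr5_len: int = 139,
    utr3_len: int = 180,
    gene_symbol: str = "RB1",
) -> TranscriptModel:
    """Deterministic synthetic transcript with a full CDS sequence.

    Exon coding lengths are drawn around the even split with jitter so both
    frame classes (length % 3 == 0 and != 0) occur among internal exons; the
    CDS is random sense codons (ATG ... TAA) with no internal stop.  The
    coordinates are synthetic — suitable for engine tests and simulations,
    not for interpreting real patient variants.
    """
    rng = np.random.default_rng(seed)
    cds_len = 3 * (protein_length + 1)

    # partition the CDS across exons (each exon gets >= 30 coding bases)
    base = cds_len // n_exons
    lengths = np.full(n_exons, base, dtype=int)
    lengths[: cds_len - base * n_exons] += 1
    jitter = rng.integers(-25, 26, size=n_exons)
    jitter -= jitter.sum() // n_exons  # keep total roughly fixed
    lengths = lengths + jitter
    lengths[-1] += cds_len - lengths.sum()
    if lengths.min() < 30:
        raise SimulationError("exon partition produced an implausibly short exon")

    exons = []
    pos = 1
    for i, clen in enumerate(lengths, start=1):
        length = int(clen)
        if i == 1:
            length += utr5_len
        if i == n_exons:
            length += utr3_len
        exons.append(Exon(index=i, cdna_start=pos, cdna_end=pos + length - 1))
        pos += length

    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), protein_length - 1)]
    cds = "ATG" + "".join(codons) + "TAA"
    return TranscriptModel(
        gene_symbol=gene_symbol,
        exons=tuple(exons),
        cds_start_cdna=utr5_len + 1,
        cds_end_cdna=utr5_len + cds_len,
        cds_sequence=cds,
        version=f"synthetic (seed={seed})",
    )


def default_domain_map(protein_length: int = 928) -> DomainMap:
    """Structured/linker segmentation of pRB with approximate boundaries.

    Residue bounds follow the commonly cited domain architecture (RB-N,
    pocket A, pocket-loop, pocket B, RB-C with intervening linkers) but are
    approximate; real analyses should load a curated map.  RB-C is labelled
    structured here (it forms alpha-helices); the label is data and can be
    flipped in a config.
    """
    raw = [
        ("N-terminal-linker", 1, 52, "linker"),
        ("RB-N", 53, 355, "structured"),
        ("linker-N-A", 356, 379, "linker"),
        ("pocket-A", 380, 577, "structured"),
        ("pocket-loop", 578, 644, "linker"),
        ("pocket-B", 645, 787, "structured"),
        ("linker-B-C", 788, 828, "linker"),
        ("RB-C", 829, protein_length, "structured"),
    ]
    return DomainMap(
        protein_length=protein_length,
        segments=tuple(Segment(n, s, e, SegmentKind(k)) for n, s, e, k in raw),
    )


# ---------------------------------------------------------------------------
# Variant fabrication
# ---------------------------------------------------------------------------

def stop_gain_sites(tm: TranscriptModel) -> list[tuple[int, str, str, int, int]]:
    """All single-base substitutions creating a stop codon.

    Returns (c_base, ref, alt, codon, exon_index) tuples over the CDS,
    excluding the normal stop codon itself.
    """
    if tm.cds_sequence is None:
        raise SimulationError("stop_gain_sites requires cds_sequence")
    from .transcript import CdnaPosition, exon_of

    sites = []
    cds = tm.cds_sequence
    for codon_idx in range(tm.protein_length):  # codons 1..protein_length
        start = codon_idx * 3
        codon = cds[start : start + 3]
        for offset in range(3):
            for alt in "ACGT":
                if alt == codon[offset]:
                    continue
                mutant = codon[:offset] + alt + codon[offset + 1 :]
                if mutant in _STOPS:
                    c_base = start + offset + 1
                    exon = exon_of(CdnaPosition(c_base), tm).index
                    sites.append((c_base, codon[offset], alt, codon_idx + 1, exon))
    return sites


def _internal_exons_by_frame(tm: TranscriptModel) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {"in_frame": [], "frameshift": []}
    for idx in range(2, tm.n_exons):
        clen = tm.coding_length_of_exon(idx)
        if clen == 0:
            continue
        out["in_frame" if clen % 3 == 0 else "frameshift"].append(idx)
    return out


class _Fabricator:
    """Draws variant descriptions that classify into a requested class."""

    def __init__(self, tm: TranscriptModel, rng: np.random.Generator,
                 nmd_last_exon: int = 25):
        self.tm = tm
        self.rng = rng
        self.sites = stop_gain_sites(tm)
        self.frames = _internal_exons_by_frame(tm)
        # stay clear of the ambiguous NMD boundary exon when fabricating
        self.nmd_exons = range(2, nmd_last_exon)
        self.escape_exons = range(nmd_last_exon + 1, tm.n_exons + 1)

    def _pick_stop_site(self, exon_ok) -> tuple[int, str, str, int, int]:
        pool = [s for s in self.sites if exon_ok(s[4])]
        if not pool:
            raise SimulationError("transcript offers no stop-gain site in the requested exons")
        return pool[self.rng.integers(0, len(pool))]

    def _splice_hgvs(self, exon_index: int, donor: bool, offset: int) -> str:
        ex = self.tm.exons[exon_index - 1]
        if donor:
            c = ex.cdna_end - self.tm.cds_start_cdna + 1
            return f"c.{c}+{offset}G>T"
        c = ex.cdna_start - self.tm.cds_start_cdna + 1
        return f"c.{c}-{abs(offset)}A>G"

    def rec_i(self, vid: str) -> VariantRecord:
        """Nonsense in an unambiguously NMD-competent ORF exon, or an
        invariant splice change whose default exon skip frameshifts."""
        if self.frames["frameshift"] and self.rng.random() < 0.2:
            exon = self._choose(self.frames["frameshift"], lambda e: e in self.nmd_exons)
            if exon is not None:
                return VariantRecord(
                    vid, VariantScale.SMALL,
                    hgvs_c=self._splice_hgvs(exon, donor=True, offset=int(self.rng.integers(1, 3))),
                )
        c_base, ref, alt, _, _ = self._pick_stop_site(lambda e: e in self.nmd_exons)
        return VariantRecord(vid, VariantScale.SMALL, hgvs_c=f"c.{c_base}{ref}>{alt}")

    def rec_i_leaky(self, vid: str) -> VariantRecord:
        exon = self._choose(self.frames["frameshift"], lambda e: True)
        if exon is None:
            raise SimulationError("no frameshift-on-skip internal exon for REC-I-leaky")
        return VariantRecord(
            vid, VariantScale.SMALL,
            hgvs_c=self._splice_hgvs(exon, donor=True, offset=int(self.rng.integers(3, 7))),
        )

    def rec_ii(self, vid: str, med4: Med4Status) -> VariantRecord:
        return VariantRecord(
            vid, VariantScale.GROSS_DELETION, whole_gene=True,
            includes_promoter_5prime=True, med4_status=med4,
        )

    def rec_iii(self, vid: str) -> VariantRecord:
        """Missense, codon-aligned in-frame deletion, or exon-1 nonsense."""
        u = self.rng.random()
        if u < 0.15:
            site = [s for s in self.sites if s[4] == 1]
            if site:
                c_base, ref, alt, _, _ = site[self.rng.integers(0, len(site))]
                return VariantRecord(vid, VariantScale.SMALL, hgvs_c=f"c.{c_base}{ref}>{alt}")
        if u < 0.4:
            codon = int(self.rng.integers(2, self.tm.protein_length))
            start = (codon - 1) * 3 + 1
            return VariantRecord(vid, VariantScale.SMALL, hgvs_c=f"c.{start}_{start + 2}del")
        return VariantRecord(vid, VariantScale.SMALL, hgvs_c=self._missense_hgvs())

    def _missense_hgvs(self) -> str:
        cds = self.tm.cds_sequence
        assert cds is not None
        while True:
            codon_idx = int(self.rng.integers(1, self.tm.protein_length))
            start = codon_idx * 3
            codon = cds[start : start + 3]
            offset = int(self.rng.integers(0, 3))
            alt = "ACGT"[self.rng.integers(0, 4)]
            if alt == codon[offset]:
                continue
            mutant = codon[:offset] + alt + codon[offset + 1 :]
            if mutant in _STOPS:
                continue
            return f"c.{start + offset + 1}{codon[offset]}>{alt}"

    def rec_iii_leaky(self, vid: str) -> VariantRecord:
        exon = self._choose(self.frames["in_frame"], lambda e: True)
        if exon is None:
            raise SimulationError("no in-frame-on-skip internal exon for REC-III-leaky")
        return VariantRecord(
            vid, VariantScale.SMALL,
            hgvs_c=self._splice_hgvs(exon, donor=False, offset=-int(self.rng.integers(3, 13))),
        )

    def rec_iv(self, vid: str) -> VariantRecord:
        if self.rng.random() < 0.5:
            return VariantRecord(
                vid, VariantScale.GROSS_DELETION, includes_3prime_end=True,
            )
        c_base, ref, alt, _, _ = self._pick_stop_site(lambda e: e in self.escape_exons)
        return VariantRecord(vid, VariantScale.SMALL, hgvs_c=f"c.{c_base}{ref}>{alt}")

    def rec_v(self, vid: str) -> VariantRecord:
        return VariantRecord(
            vid, VariantScale.PROMOTER_REGULATORY,
            hgvs_c="promoter regulatory SNV (descriptive)", hgvs_p=None,
        )

    def _choose(self, pool: list[int], ok) -> Optional[int]:
        good = [e for e in pool if ok(e)]
        if not good:
            return None
        return int(good[self.rng.integers(0, len(good))])

    def fabricate(self, label: str, vid: str) -> VariantRecord:
        if label == "REC_I":
            return self.rec_i(vid)
        if label == "REC_I_leaky":
            return self.rec_i_leaky(vid)
        if label == "REC_II_plus":
            return self.rec_ii(vid, Med4Status.INCLUDED)
        if label == "REC_II_minus":
            return self.rec_ii(vid, Med4Status.EXCLUDED)
        if label == "REC_II_unknown":
            return self.rec_ii(vid, Med4Status.UNKNOWN)
        if label == "REC_III":
            return self.rec_iii(vid)
        if label == "REC_III_leaky":
            return self.rec_iii_leaky(vid)
        if label == "REC_IV":
            return self.rec_iv(vid)
        if label == "REC_V":
            return self.rec_v(vid)
        raise SimulationError(f"no fabricator for class label {label!r}")


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassBlock:
    """One simulated stratum: a REC subclass with its phenotype models."""

    label: str                       # subclass label, e.g. "REC_I", "REC_II_plus"
    n: int
    onset_rate: float                # exponential λ, per month
    p_bilateral: Optional[float] = None
    poisson_m: Optional[float] = None   # alternative laterality model
    tumor_mean: float = 1.0          # mean tumours in the less-affected eye (bilateral)
    ip_count: int = 0                # patients flagged as carrying an IP-associated variant

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SimulationError(f"{self.label}: n must be >= 0")
        if self.n > 0 and not (self.onset_rate > 0):
            raise SimulationError(f"{self.label}: onset rate must be positive")
        if (self.p_bilateral is None) == (self.poisson_m is None):
            raise SimulationError(
                f"{self.label}: exactly one of p_bilateral / poisson_m must be set"
            )
        if self.p_bilateral is not None and not (0.0 <= self.p_bilateral <= 1.0):
            raise SimulationError(f"{self.label}: p_bilateral outside [0, 1]")
        if not (0 <= self.ip_count <= self.n):
            raise SimulationError(f"{self.label}: ip_count outside 0..n")

    def bilateral_probability(self) -> float:
        if self.p_bilateral is not None:
            return self.p_bilateral
        p0, p_uni, p_bi = poisson_laterality(self.poisson_m)
        if p_uni + p_bi == 0:
            raise SimulationError(f"{self.label}: Poisson mean 0 yields no affected individuals")
        return p_bi / (p_uni + p_bi)   # conditioned on being a diagnosed case


@dataclass(frozen=True)
class SimulationSpec:
    blocks: tuple[ClassBlock, ...]
    seed: int = 0
    truncate_months: Optional[float] = None
    p_familial: float = 39 / 287
    p_unknown_history: float = 3 / 287

    @property
    def n_total(self) -> int:
        return sum(b.n for b in self.blocks)


def _rate(median_months: float) -> float:
    return math.log(2.0) / median_months


def default_simulation_spec(seed: int = 0) -> SimulationSpec:
    """Demo cohort mirroring the reference class structure (n = 287).

    Block sizes and bilateral fractions follow the reported class table;
    onset rates are set so ln2/λ equals each class's reported median age at
    diagnosis (months).  Ages are truncated at 48 months, the cohort's
    observed maximum.
    """
    blocks = (
        ClassBlock("REC_I", 190, _rate(7.2), p_bilateral=179 / 190, tumor_mean=2.0),
        ClassBlock("REC_I_leaky", 9, _rate(12.0), p_bilateral=7 / 9, tumor_mean=1.0, ip_count=2),
        ClassBlock("REC_II_plus", 27, _rate(8.4), p_bilateral=19 / 27, tumor_mean=1.0, ip_count=27),
        ClassBlock("REC_II_minus", 6, _rate(11.0), p_bilateral=1.0, tumor_mean=1.0),
        ClassBlock("REC_II_unknown", 6, _rate(10.3), p_bilateral=5 / 6, tumor_mean=1.0),
        ClassBlock("REC_III", 39, _rate(12.3), p_bilateral=30 / 39, tumor_mean=1.0, ip_count=15),
        ClassBlock("REC_III_leaky", 6, _rate(8.2), p_bilateral=1.0, tumor_mean=1.0, ip_count=1),
        ClassBlock("REC_IV", 1, _rate(13.1), p_bilateral=1.0, tumor_mean=2.0),
        ClassBlock("REC_V", 3, _rate(18.4), p_bilateral=2 / 3, tumor_mean=1.0, ip_count=2),
    )
    return SimulationSpec(blocks=blocks, seed=seed, truncate_months=48.0)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedCohort:
    variants: tuple[VariantRecord, ...]
    patients: tuple[PatientRecord, ...]
    intended_class: dict[str, str]    # variant_id -> intended subclass label
    seed: int

    def __iter__(self):
        return iter((list(self.variants), list(self.patients)))


def _draw_age(rng: np.random.Generator, lam: float, truncate: Optional[float]) -> float:
    for _ in range(10_000):
        age = rng.exponential(1.0 / lam)
        if age < 0.05:   # diagnoses below ~a day are not observed
            continue
        if truncate is None or age <= truncate:
            return round(float(age), 1)
    raise SimulationError(f"truncation at {truncate} months incompatible with rate {lam}")


def simulate_cohort(
    spec: SimulationSpec,
    tm: Optional[TranscriptModel] = None,
    seed: Optional[int] = None,
) -> SimulatedCohort:
    """Generate (variants, patients) for every block of the spec.

    Fully reproducible: the same spec and seed give identical output.  One
    variant is fabricated per patient; ``intended_class`` records the
    subclass each variant was constructed for, so classifier closure can be
    asserted externally.
    """
    if tm is None:
        from .io import load_packaged_transcript

        tm = load_packaged_transcript()
    use_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    fab = _Fabricator(tm, rng)

    variants: list[VariantRecord] = []
    patients: list[PatientRecord] = []
    intended: dict[str, str] = {}
    counter = 0
    for block in spec.blocks:
        if block.n == 0:
            continue
        p_bi = block.bilateral_probability()
        ip_flags = np.zeros(block.n, dtype=bool)
        ip_flags[: block.ip_count] = True
        rng.shuffle(ip_flags)
        for i in range(block.n):
            counter += 1
            vid = f"V{counter:04d}"
            pid = f"P{counter:04d}"
            variant = fab.fabricate(block.label, vid)
            bilateral = rng.random() < p_bi
            if bilateral:
                extra = max(block.tumor_mean - 1.0, 0.05)
                tumors = 1 + int(rng.poisson(extra))
            else:
                tumors = 0
            u = rng.random()
            if u < spec.p_unknown_history:
                history = FamilyHistory.UNKNOWN
            elif u < spec.p_unknown_history + spec.p_familial:
                history = FamilyHistory.FAMILIAL
            else:
                history = FamilyHistory.ISOLATED
            patients.append(PatientRecord(
                patient_id=pid,
                variant_id=vid,
                laterality=Laterality.BILATERAL if bilateral else Laterality.UNILATERAL,
                age_at_dx=_draw_age(rng, block.onset_rate, spec.truncate_months),
                tumors_less_affected_eye=min(tumors, 8),
                family_history=history,
                ip_variant=bool(ip_flags[i]),
            ))
            variants.append(variant)
            intended[vid] = block.label
    return SimulatedCohort(tuple(variants), tuple(patients), intended, use_seed)


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------

def recovery_experiment(
    spec: SimulationSpec,
    n_replicates: int,
    tm: Optional[TranscriptModel] = None,
):
    """Simulate → fit per class, repeatedly; report mean λ̂ and relative bias.

    Runs untruncated regardless of the spec's demo truncation (truncation
    would bias the MLE).  Returns a pandas DataFrame with one row per block:
    label, true λ, mean λ̂, relative bias.
    """
    import pandas as pd

    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    spec = replace(spec, truncate_months=None)
    if tm is None:
        from .io import load_packaged_transcript

        tm = load_packaged_transcript()
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_replicates) % (2**31)
    estimates: dict[str, list[float]] = {b.label: [] for b in spec.blocks if b.n > 0}
    for rep_seed in seeds:
        cohort = simulate_cohort(spec, tm=tm, seed=int(rep_seed))
        by_label: dict[str, list[float]] = {}
        for patient in cohort.patients:
            by_label.setdefault(cohort.intended_class[patient.variant_id], []).append(
                patient.age_at_dx
            )
        for label, ages in by_label.items():
            estimates[label].append(fit_exponential(ages).rate_lambda)
    rows = []
    for block in spec.blocks:
        if block.n == 0:
            continue
        lam_hat = float(np.mean(estimates[block.label]))
        rows.append({
            "label": block.label,
            "n_per_replicate": block.n,
            "true_lambda": block.onset_rate,
            "mean_lambda_hat": lam_hat,
            "relative_bias": (lam_hat - block.onset_rate) / block.onset_rate,
        })
    return pd.DataFrame(rows)
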