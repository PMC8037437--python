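# Methods

## Scope and model

`rb1rec` classifies constitutional *RB1* alleles by their predicted effect
on the retinoblastoma protein pRB and provides the statistics used to
compare the resulting classes in cohorts of diagnosed patients. The
classification assumes pRB is the sole mediator between genotype and
phenotype: variants with the same predicted consequence for pRB amount and
structure are pooled, regardless of their DNA-level diversity.

The decision procedure is deterministic and total. Rule order:

1. gross deletion including the 5′ end/promoter or the whole gene →
   REC-II, subclassed by *MED4* co-deletion status (+ / − / unknown);
2. gross deletion of the 3′ end only → REC-IV;
3. regulatory promoter variant → REC-V;
4. small exonic variant: predict the premature termination codon (PTC);
   PTC in exon 1 → REC-III (NMD-evading, N-terminally altered protein);
   PTC in the NMD-competent region → REC-I; PTC in the 3′ escape region →
   REC-IV; no PTC (missense / in-frame) → REC-III;
5. splice-region variant: PTC status of the predicted variant mRNA decides
   REC-I vs REC-III; invariant (±1/±2) positions give the non-leaky class,
   remote in-window positions the leaky subclass;
6. anything else → UNCLASSIFIED with a machine-readable reason.

Every assignment carries the ordered list of rules fired; exactly one
terminal rule fires per variant.

## PTC prediction

For small exonic variants with a CDS sequence available, the edit is
applied to the CDS string and the mutant is translated from the start
codon (Biopython). The first stop is a PTC unless the edit preserved the
frame and the stop is the mutant's own terminal codon. The PTC codon is
reported in the mutant reading frame; when locating the PTC's exon the
codon is mapped back to a reference cDNA base by codon arithmetic,
ignoring the small indel length offset — immaterial at exon granularity,
which is all the class rules need. A protein-level description (`hgvs_p`),
when supplied, takes precedence over sequence-based prediction, so cohorts
can be classified without a CDS sequence; bare `fs` descriptions without a
stop distance use the variant's own codon as an approximate PTC location
and are flagged in the rationale.

## NMD rule

PTCs in ORF exons 2–25 are treated as NMD-competent, exon-1 PTCs as
NMD-evading, PTCs in exons 26–27 as escaping. Published class definitions
place exon 25 in both the NMD-competent and the escape bin; the default
resolution applies the canonical 50-nt junction heuristic within exon 25
(PTC more than 50 nt upstream of the exon-25/26 junction → NMD → REC-I,
otherwise REC-IV). A hard exon-boundary mode (`--nmd-boundary exon`) is
available; both the exon range and the margin are configurable.

## Splice model

Intronic offsets ±1/±2 are invariant splice positions; other offsets
inside the configured window (donor +1..+6, acceptor −12..−1 by default)
are remote, predicting leaky missplicing. Exonic positions near junctions
are classified by their coding consequence, not as splice variants, unless
a `validated_splice_effect` override is supplied. The default consequence
of a splice-site change is skipping of the adjacent exon: the skipped
exon's coding length modulo 3 decides frameshift (→ PTC → REC-I) versus
in-frame (→ REC-III). This default is deliberately simple — real splice
outcomes must be determined per variant by transcript analysis, and the
override field is the hook for that evidence. Skips of the first or last
exon have no defined outcome and yield UNCLASSIFIED.

## Domain map

pRB positions are binned into named segments labelled structured or
linker. The kind labels are data, not code: the shipped map labels RB-C
structured (it is an α-helical domain), but whether RB-C belongs with the
structured domains in the linker-vs-structured contrast is genuinely open,
and users can flip the label in the config without code changes. The
packaged map's residue boundaries are approximate and the file is named
`*.synthetic.json` accordingly; engine correctness is established on
synthetic maps, independent of those boundaries.

## Packaged transcript

The packaged transcript model matches the published anchors of *RB1* — 27
exons, a 928-amino-acid protein, a 2787-nt CDS — but its exon boundaries
and CDS sequence are synthetic stand-ins (generated deterministically, and
labelled `synthetic` in the filename and the `version` field). All unit
tests run on small toy transcripts; real analyses should supply a curated
RefSeq-derived config, recording the transcript version used, since exon
numbering conventions differ between sources.

## Cohort statistics

* **Percent rounding** is decimal half-up to one decimal place,
  reproducing clinical-table conventions.
* **Medians** use the even-n convention (mean of the central pair);
  ranges are min–max. Ages are in months throughout.
* **Exponential onset model**: all cohort members are diagnosed cases, so
  there is no censoring and the MLE is the closed form λ̂ = n/Σt; the 95%
  CI uses the normal approximation on log λ (SE = 1/√n). Group contrasts
  use the Wald statistic log(λ̂ₐ/λ̂_b)/√(1/nₐ + 1/n_b) with a two-sided
  normal p-value. p-values are descriptive; no multiple-testing correction
  is applied, mirroring the exploratory character of such analyses.
* **Empirical log-survival**: S after the i-th order statistic is
  (n−i)/n; tied ages collapse to one step; the terminal S = 0 point is
  omitted because its log is undefined.
* **Poisson laterality link**: tumour foci per carrier ~ Poisson(m) split
  independently between two eyes with per-eye mean m/2, giving
  p(unaffected) = e^(−m), p(bilateral) = (1 − e^(−m/2))², unilateral the
  remainder. The two-eye independence form is this package's modelling
  choice — the underlying two-hit literature asserts the linkage without
  printing a formula — and it is validated against its own Monte-Carlo
  oracle. The estimator maximises the multinomial likelihood of
  (unaffected, unilateral, bilateral) counts by root-finding on the score
  (relative tolerance 1e-8); all-bilateral data without unilateral or
  unaffected observations push m̂ to infinity and return a flagged
  upper-limit value.

## Synthetic cohorts

The simulator fabricates variants guaranteed *by construction* to
classify into a requested class — nonsense substitutions found by scanning
the CDS for single-base stop gains in the target exons, invariant/remote
splice changes adjacent to exons of known frame, codon-aligned in-frame
deletions, gross-deletion flag sets — and never consults the classifier,
so classifier-closure tests are a genuine cross-check. Phenotypes are
drawn from the generating models the analyses assume: Exponential(λ) ages,
Bernoulli (or conditional two-eye Poisson) laterality, truncated-Poisson
tumour counts (bilateral cases have at least one tumour in the less
affected eye; counts are capped at 8, the observed support).

The default spec mirrors the class structure of a 287-patient referral
cohort: block sizes 190/9/27/6/6/39/6/1/3 across REC-I(±leaky),
REC-II(+/−/unknown), REC-III(±leaky), REC-IV and REC-V, onset rates set so
ln 2/λ equals each class's reported median age at diagnosis (7.2, 12.0,
8.4, 11.0, 10.3, 12.3, 8.2, 13.1 and 18.4 months), bilateral fractions
from the reported splits, 47 patients flagged as carrying
incomplete-penetrance-associated variants, and family-history frequencies
39/245/3 (familial/isolated/unknown). Demo ages are truncated at 48
months, the cohort's observed maximum; parameter-recovery experiments run
untruncated because truncation biases the MLE. Ages are recorded to 0.1
month as in clinical tables, and diagnoses below ~0.05 months are
redrawn — both effects are far below the recovery tolerances tested.

What the simulator does **not** emulate: somatic mosaicism, familial
screening effects, recurrent variants shared between patients (one
variant per patient), parent-of-origin effects, and any correlation
between age and laterality within a class. Passing tests therefore show
the machinery is correct under the stated generating models, not that
real cohorts obey them.

## Problem sizes and numerical choices

Acceptance-level checks use: an exhaustive toy-variant grid (> 400 cases)
against a hand-written decision-table oracle; parameter recovery at
n = 500 per class × 100 replicates (|relative bias| < 2%); two-group
rate-ratio recovery at n = 2000 per group (within 10%); log-survival
slope at n = 5000 (within 5%); a 10⁶-draw two-eye Monte-Carlo oracle for
the laterality probabilities (within 3 standard errors); and estimator
self-consistency on exact multinomial counts (within 0.01). All
randomness flows from explicit integer seeds; identical spec + seed gives
byte-identical simulator output.

## Known limitations

* Genomic (g.) coordinates, liftover and multi-transcript support are out
  of scope; inputs are HGVS c. descriptions against one transcript model.
* The HGVS parser covers the small-variant subset (substitution, del,
  dup, ins, delins with intronic offsets), not the full grammar.
* The splice default (adjacent-exon skip) is a modelling convenience;
  validated per-variant effects should be supplied where known.
* ACMG-style pathogenicity assessment is not performed: the engine
  assumes input variants are already judged pathogenic.
* The exponential contrast is unadjusted (group factor only).
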