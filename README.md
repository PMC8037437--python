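# rb1rec

Variant effect classification and genotype–phenotype analytics for
heritable retinoblastoma.

Heritable retinoblastoma is caused by constitutional haploinsufficiency of
the *RB1* tumour-suppressor gene. Pathogenic *RB1* alleles are extremely
heterogeneous — nonsense and frameshift variants, splice-signal changes,
whole-gene deletions, missense changes, promoter variants — but their
phenotypic effect is mediated through a single channel: the amount and
structure of the retinoblastoma protein pRB. `rb1rec` implements a
five-class **retinoblastoma variant effect classification (REC)** built on
that idea, plus the statistical toolkit used to compare the classes in
clinical cohorts. It is aimed at clinical geneticists and researchers who
need to group rare *RB1* variants by predicted protein effect and relate
the groups to laterality, age at diagnosis and tumour counts.

## The classification

Each variant is mapped to one class by its predicted effect on pRB:

| Class | Predicted effect | Typical alteration |
|---|---|---|
| REC-I | PTC triggering nonsense-mediated decay (NMD): reduced amount of a C-truncated pRB | nonsense/frameshift in ORF exons 2–25; splice changes creating a PTC |
| REC-II | complete loss of pRB from the allele | whole-gene / 5′-including gross deletion; subclassed REC-II± by *MED4* co-deletion |
| REC-III | structurally altered pRB at normal amount | missense, in-frame indel, exon-1 PTC (NMD-evading), splice change without PTC |
| REC-IV | C-truncated pRB without quantitative change | 3′-end deletions; PTCs in the NMD-escaping 3′ exons |
| REC-V | reduced amount of normal pRB | regulatory promoter variants |

Splice variants at *remote* (non-invariant) positions are flagged
**leaky** (REC-I-leaky / REC-III-leaky): part of the transcripts still
splice normally, predicting a milder phenotype.

The engine resolves HGVS c.-notation against a transcript model (exon
table, CDS, optional sequence), predicts premature termination codons by
in-silico translation of the edited CDS, applies a configurable NMD rule
(default: exons 2–25 with the canonical 50-nt junction heuristic in the
boundary exon), and bins PTCs into pRB's structured domains (RB-N, pocket
A, pocket B, RB-C) versus unstructured linker regions.

## The onset model

Under Knudson's two-hit model the fraction S(t) of predisposed children
not yet diagnosed declines exponentially, log S ∝ −λt. With every cohort
member a diagnosed case (no censoring) the maximum-likelihood rate is the
closed form **λ̂ = n / Σtᵢ**; groups are compared by the Wald test on
log λ̂ₐ − log λ̂_b with variance 1/nₐ + 1/n_b. The same Poisson parameter m
(mean tumour foci per carrier) links penetrance and laterality through a
two-eye model: p(unaffected) = e^(−m), p(bilateral) = (1 − e^(−m/2))².

## Worked example

```
rb1rec simulate --seed 5 --out-dir demo
rb1rec classify --variants demo/variants.tsv --out demo/assignments.tsv
rb1rec summarize --cohort demo/cohort.tsv --assignments demo/assignments.tsv --out-dir demo/sum
rb1rec fit --cohort demo/cohort.tsv --assignments demo/assignments.tsv \
       --group-a REC_I --group-b REC_III --out-dir demo/fit
```

`simulate` writes a 287-patient demo cohort whose class structure mirrors
a published referral cohort. `classify` re-derives every variant's class
from its HGVS description; `demo/assignments.class_counts.tsv` then reads

```
subclass        n   percent
REC_I           190 66.2
REC_I_leaky     9   3.1
REC_II_plus     27  9.4
REC_II_minus    6   2.1
REC_II_unknown  6   2.1
REC_III         39  13.6
REC_III_leaky   6   2.1
REC_IV          1   0.3
REC_V           3   1.0
```

i.e. every fabricated variant classifies into the class it was constructed
for (REC-I dominates at ~69% of the cohort counting its leaky subset).
`fit` writes per-class exponential rates and `rate_comparison.json` with
the REC-I versus REC-III rate ratio — values above 1 mean REC-I children
are diagnosed earlier.

The classifier works from plain-text configs; the packaged transcript and
domain map are clearly-labelled synthetic stand-ins (27 exons, 928-aa
protein), so supply curated RefSeq-derived configs via `--transcript` /
`--domains` for real data.

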