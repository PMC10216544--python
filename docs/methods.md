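# Methods

This note documents the statistical and biochemical models implemented
in `cdr3profile`, the defaults chosen where several conventions are in
live use, and what the synthetic cohort generator does and does not
emulate.

## Input model

A rearrangement table carries one row per unique CDR3 nucleotide
junction per sample, with a template count (bias-controlled input
molecule count) as the abundance unit. Two column dialects are mapped
onto one schema: immunoSEQ-like (`rearrangement`/`amino_acid`/
`templates`/`frame_type`/`sample_name`) and the AIRR Rearrangement
subset (`junction`/`junction_aa`/`duplicate_count`/`productive`, plus
`vj_in_frame`/`stop_codon` when present, and `repertoire_id`). Duplicate
junctions within a sample are merged with summed templates, so template
totals are conserved. A missing template column downgrades every row to
one template with a logged warning. Sequences are uppercased on read;
ambiguity codes are rejected rather than silently expanded, because
downstream pI and immunogenicity need unambiguous residues. Clinical
group labels come only from a metadata file or flags, never from sample
naming conventions.

## Translation and productivity

Junctions are translated with the standard genetic code from position 1;
a trailing partial codon is dropped from the peptide and flagged through
`in_frame=False`. Productive = in frame AND stop-free. When the input
file carries a frame annotation it takes precedence over recomputation
(vendor pipelines sometimes encode decisions not recoverable from the
junction alone); disagreements are logged. The computed translation is
always the peptide used downstream, cross-checked against any input
amino acid column. Anchor conservation (first residue C, last F or W) is
reported as a flag but is not a productivity criterion — common
rearrangement-pipeline semantics, and auditable either way.

## Length distributions and moments

Lengths are reported on the nucleotide scale by default (in-frame
junctions are multiples of 3) and on the amino acid scale by flag; both
are labelled explicitly in outputs. Only productive records contribute;
each clone enters with weight templates/total-productive-templates
("sum productive frequency"), so per-sample frequencies sum to 1 and are
invariant to uniform template rescaling. Moment summaries use population
(n-denominator) central moments, standardized skewness, and *excess*
kurtosis (normal → 0). Frequency weighting is the default; an unweighted
mode counting each unique clone once is provided because summary
conventions differ between tools. A single distinct length yields
variance 0 and NaN shape moments with a warning.

## Simpson clonality

`clonality = sqrt(Σ p_i²)` over productive clone frequencies. No
unbiased-estimator correction (n(n−1) denominators) is applied: the
statistic is defined on the sample itself, which is also what makes it
comparable across samples with different input amounts. An
all-rearrangements mode is available by flag.

## Isoelectric point

Net charge at pH x:

```
q(x) = 1/(1+10^(x−pKa_Nterm)) + Σ_basic n_r/(1+10^(x−pKa_r))
     − 1/(1+10^(pKa_Cterm−x)) − Σ_acidic n_r/(1+10^(pKa_r−x))
```

with basic groups K, R, H and acidic groups D, E, C, Y. q is strictly
decreasing in x, so the root is unique; bisection on [0, 14] stops when
the bracket is below 1e−6 pH, or earlier once |q| < 1e−4 charge units
*and* the bracket is below 1e−3 pH (the charge tolerance alone does not
pin the pH where the curve is flat). Default pKa constants (N-term 8.6,
C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) are a
widely used published set; different pI tools use different constants,
so the table is a config file and every operation accepts an override.
B and Z have no defined pKa and are rejected with a clear error.

## Residue-property composition

Eight IUPAC-IUB-style groups: Aliphatic {G,A,V,L,I}, Aromatic {F,W,Y},
Sulphur {C,M}, Basic {K,R,H}, Acidic {B,D,E,N,Q,Z}, Aliphatic hydroxyl
{S,T}, tRNA synthetase class I {Z,E,Q,R,C,M,V,I,L,Y,W}, class II
{B,G,A,P,S,T,H,D,N,K,F}. The groups overlap (a residue can count toward
several); the two synthetase classes partition the alphabet, so their
percentages sum to 100 — a useful internal consistency check. The first
six groups cover everything except proline. Counts are raw "times found"
occurrences over productive peptides, unweighted by templates (a
weighted mode exists); composition is emitted both per sample and pooled
per clinical group, since published tables typically pool per group.

## Immunogenicity scoring

Score = Σ over unmasked positions of a per-residue log-enrichment weight
times a per-position importance weight; score > 0 (strictly) classifies
a peptide immunogenic. The packaged weight table is transcribed from the
published enrichment model behind the IEDB class I immunogenicity
predictor (aromatic and large residues enriched; presented-peptide
positions P4–P6 most important; anchor positions 1, 2 and the C-terminus
masked). The importance map is calibrated on 9-mers; for longer peptides
the last four positions map from the C-terminus, the first five from the
N-terminus, and extra interior positions reuse the central-position
weight — a documented extrapolation, appropriate because CDR3 peptides
are typically 7–23 residues. Whole-sequence scoring is the default; a
sliding 9-mer max mode is available. The between-group comparison of
score variances is an F-test; no canonical test exists for this
comparison, so the choice is documented and the raw scores are emitted
for any alternative.

## Clone sharing and conservation

Sharing is exact identity of productive CDR3 amino acid sequences across
samples (convergent recombination makes nucleotide-level sharing a
strictly different question; an nt mode exists). Shared sets of one
common length are annotated per column with Clustal consensus symbols
using the Clustal X strong/weak similarity groups ('*' identical, ':'
within one strong group, '.' within one weak group, space otherwise);
the scheme is configurable since the published thresholds ("roughly"
Gonnet PAM 250 > 0.5 and > 0) admit variants. Gapped alignment of
unequal-length sets is out of scope and delegated to an external
aligner.

## Dunn's test

Global midranks over the pooled observations; tie correction
T = Σ(t³−t)/(12(N−1)); z_ab = (R̄_a − R̄_b)/sqrt((N(N+1)/12 − T)(1/n_a +
1/n_b)); two-sided normal p. Unadjusted p is the default, with
Bonferroni and Holm by flag. The pipeline preset compares per-clone
productive frequency distributions across samples; this is one
operationalization of "comparing clonal frequencies between samples" and
is labelled as such — the generic interface accepts any per-sample
observable. With all pooled observations identical the statistic is
undefined and reported as NaN.

## Synthetic cohort generator

The generator produces the study conditions the analysis assumes, with
exact ground truth:

- **Shape.** 7 samples in two groups (4 + 3); unique-clone counts
  {1560, 56, 1485, 202} and {25, 118, 169} (total 3615).
- **Junctions.** In-frame lengths uniform over multiples of 3 in
  21–69 nt (30–66 for the second group), TGT/TGC first codon, TTT/TTC
  last codon, uniform stop-free interior codons.
- **Clone frequencies.** Symmetric Dirichlet with per-sample
  concentration solved from a target clonality c via
  E[Σp²] = (α+1)/(nα+1) = c²; the default targets pair each sample size
  with a clonality in 0.04–0.24 (feasibility requires c > 1/√n, which
  uniquely determines the size↔target pairing used). A power-law mode is
  available because real repertoires are heavy-tailed. Frequencies are
  realized as template counts by multinomial sampling at depth 25× the
  clone count, with one guaranteed template per clone so the unique-clone
  count is exact.
- **Nonproductive fraction.** Default 0.1, realized as round(f·n) clones
  broken by deleting one internal base (frameshift) or substituting an
  interior stop codon, 50/50.
- **Planted sharing.** Identical junctions inserted into chosen samples
  (default: four sequences across three same-group samples, one across
  groups; 42 nt so the shared set is equal-length). Planted clones are
  always productive. Non-planted clones are unique across the cohort at
  both nucleotide and amino acid level, so the recovered sharing pattern
  equals the plan exactly.
- **Determinism.** One `numpy` Generator seeded from the config; same
  seed → byte-identical output files.

What it does *not* emulate: V/D/J gene-segment structure and segment-
specific codon usage (interiors are uniform), sequencing error, real
repertoires' amino acid composition bias (synthetic interiors are
uniform over sense codons, so composition, mean pI and percent-
immunogenic of synthetic cohorts differ from clinical values), and
biological convergence between samples. Tests passing on synthetic
cohorts therefore validate the *statistical machinery* — counting,
weighting, frequency, sharing and test arithmetic — not claims about
real lung-fluid repertoires.

## Problem sizes and numerical choices

The default synthetic cohort is full study scale (3615 clones) and runs
the complete pipeline in ~1 s. Pipeline tests use a scaled-down preset
(25–140 clones per sample) to keep the suite fast. Oracle-equivalence
checks use 500 random peptides (pI), 200 random datasets plus 2000 null
replicates (Dunn's), and 1000 random junctions (translation).
Tie-breaks: percent values are rounded half-even to two decimals only in
human-readable summaries; full precision is written everywhere else.
Degenerate inputs (no productive records, single distinct length,
all-identical observations) warn and return empty/NaN results rather
than raising, except where a downstream statistic would be meaningless
(clone frequencies of a sample with zero productive templates raise).

## Known limitations

- The immunogenicity weight table is a transcription of a published
  model; scores should be compared across sequences scored with the same
  table, not mixed across tables.
- pI values depend on the pKa constant set; absolute values differ
  between tools by up to ~0.5 pH even though orderings are stable.
- Dunn's normal approximation is coarse below ~5 observations per group.
- The conservation annotator handles only gapless equal-length sets by
  design.
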