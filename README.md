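# cdr3profile

Characterization of TCRβ CDR3 immune repertoires from rearrangement
tables: junction translation and productivity filtering, length
distributions, Simpson clonality, theoretical isoelectric points,
residue-property composition, class I pMHC immunogenicity scoring,
cross-sample clone sharing with conservation annotation, and
nonparametric group comparison. It is aimed at researchers profiling
small clinical cohorts — for example lung edema fluid from ARDS (Acute
Respiratory Distress Syndrome) patients versus other lung-injury
controls — where repertoires are small (tens to ~1.5k unique clones per
sample) and per-sample summaries, not machine-learning pipelines, are
the deliverable.

## What it computes

A *rearrangement* is one unique CDR3 nucleotide junction with a template
count (number of input DNA molecules). The core per-sample statistics:

- **Productivity.** A junction is productive iff it is in frame
  (length ≡ 0 mod 3) and its standard-genetic-code translation carries
  no stop codon. Anchor conservation (C…F/W) is reported but never used
  as a filter.
- **Simpson clonality.** With productive clone frequencies
  `p_i = templates_i / Σ templates`,

  ```
  clonality = sqrt(Σ_i p_i²)
  ```

  ranging from `1/sqrt(n)` (a perfectly even n-clone sample, → 0) to 1
  (monoclonal). The plug-in form is used deliberately: it measures the
  evenness of the sample, not of the underlying T-cell pool.
- **Isoelectric point.** The pH at which the Henderson–Hasselbalch net
  charge over the termini and K/R/H/D/E/C/Y side chains crosses zero,
  found by bisection on [0, 14]; the pKa table is configurable.
- **Immunogenicity.** Per-peptide score
  `Σ_pos enrichment(residue) × importance(pos)` over unmasked positions
  (positions 1, 2 and the C-terminus are masked by default); peptides
  with score > 0 are classified immunogenic.
- **Sharing and conservation.** Exact amino acid identity across
  samples, with Clustal-style `* : . ` column symbols for equal-length
  shared sets (strong/weak similarity groups ≈ Gonnet PAM 250
  thresholds 0.5 / 0).
- **Group comparison.** Pairwise Dunn's rank test with midrank tie
  correction: `z_ab = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − T)(1/n_a + 1/n_b))`.

A seeded synthetic-cohort generator (`cdr3profile.simulate`) emulates a
seven-sample two-group study (unique-clone counts 25–1560 summing to
3615, junction lengths 21–69 nt in multiples of 3, a 10% nonproductive
fraction, planted shared clones, per-sample Dirichlet clone-frequency
skew calibrated to target clonalities of 0.04–0.24) and returns exact
ground truth for every stage.

## Worked example

```bash
cdr3profile simulate --seed 3 -o sim
cdr3profile clonality -i sim/rearrangements.tsv -m sim/metadata.tsv
```

prints (abridged):

```
sample_id  group     n_clones  simpson_index  clonality
111        ARDS      1404      0.00859...     0.09272...
176        ARDS      50        0.02435...     0.15606...
186        ARDS      1337      0.00175...     0.04190...
```

Sample 186, with 1337 productive clones and near-even frequencies, sits
close to the even-sample floor (clonality ≈ 0.042); smaller or more
skewed samples score higher. The same cohort flows through
`cdr3profile lengths | pi | composition | immunogenicity | shared |
compare`, or all at once via `cdr3profile report -i ... -o outdir`,
which writes per-stage TSVs, per-sample FASTA, figures, a combined
summary and a MANIFEST.

The numbered drivers under `analysis/` run the same stages as a
narrative: `01_simulate_cohort.py` writes the default cohort under
`results/cohort/`, and `02`–`05` produce the tables kept in `results/`
(length moments, clonality, composition, immunogenicity summaries,
shared-clone alignment, Dunn's pairs).

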