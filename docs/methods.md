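# Methods

## Expression scale

All statistics operate on lRPKM = log₂(RPKM + 1).  The +1 offset bounds the
influence of very small RPKM values and maps RPKM 0 to lRPKM 0 exactly, so
the transform is a strictly monotone bijection of [0, ∞) onto itself and
`2**l − 1` inverts it to floating precision.  Note that the commonly quoted
equivalence "3.5 lRPKM ≈ 10.35 RPKM" is slightly off under this formula:
2³·⁵ − 1 = 10.31.  The package implements the formula; the 0.04 RPKM
discrepancy is immaterial to any call the screen makes.

## Tiers, ranking, variability

Median lRPKM per gene (even-sized groups: mean of the two central order
statistics) is binned at cut points 1 / 3.5 / 6.7 lRPKM into
`not_expressed`, `expressed`, `high`, `very_high`.  Boundaries are
**lower-inclusive**: a median of exactly 3.5 is `high`.  The ≥ convention
is explicit for the 1-lRPKM cut; for 3.5 and 6.7 the inclusive reading was
adopted for consistency — a documented choice, as "above" is ambiguous at
the boundary and no observed median lands exactly on a cut in practice.
Ranking ties are broken lexicographically by gene id so output order is
reproducible.

The coefficient of variation is computed on lRPKM (the scale every other
statistic uses) with the sample (n−1) standard deviation — material for the
12-sample reference group.  CV is undefined when the mean is 0; such genes
carry a missing (NA) CV and stability flag, never a numeric stand-in.  The
stability cut-off is CV < 0.5.

## Differential screen

A gene is `up` when median(case) − median(reference) > +1 lRPKM and `down`
when < −1 (strict inequalities; configurable threshold).  The three
statuses partition the gene universe.  No multiplicity correction is
applied to the headline calls — the screen is a fixed-threshold filter, not
a hypothesis-test family.

## Subfamily enrichment

For each of the 18 receptor subfamilies and each direction the 2×2 table is

|            | in family | not in family |
|------------|-----------|---------------|
| direction set | a | b |
| background    | c | d |

where the background is the classified universe minus **both** directional
sets (not just the tested direction).  The default universe is all
classified receptors; restricting it to expressed receptors is available
as a configuration (`enrichment_universe="expressed"`), since either
convention is defensible and the choice shifts c+d by the silent fraction.

The two-tailed Fisher exact p sums hypergeometric point probabilities of
every table with the observed margins whose probability is at most that of
the observed table.  The ≤ comparison carries a 1e-7 relative tolerance so
tables that are mathematical ties but differ in floating representation
are counted as ties; terms accumulate from log factorials (finite for
totals in the hundreds).  This point-probability ordering matches the
dominant convention of exact-test implementations (scipy, R).  The
all-zero table returns p = 1 by convention.  A Benjamini–Hochberg `bh_q`
column is emitted alongside the raw p as a clearly labeled extension.

## Subgroup fingerprints

For a genetic subgroup, every gene is tested samples-with vs
samples-without the flag inside a comparison scope:

* cytogenetic subgroups (t(8;21), inv(16), *MLL* translocations) — all AML
  samples;
* mutation subgroups (*NPM1*, *FLT3*-ITD, *DNMT3A*) — normal-karyotype AML
  only, where these mutations define the recognized subgroups.

The scope is configurable and recorded in the run manifest.  Samples
outside scope are excluded entirely (the "without" group is never padded
with unknown-status samples).  A record is emitted iff |Δmean| ≥ 1.5 lRPKM
**and** p < 0.05; the magnitude gate applies to the absolute difference,
so down-regulated fingerprint genes are reported too.  The t-test is the
classical equal-variance Student test (pooled variance, n₁+n₂−2 df), since
that is the screen's stated test; Welch's form is available behind
`equal_var=False` because the group sizes are very unequal and the choice
is material in principle.  Zero pooled variance yields a flagged
degenerate result (NaN statistic and p), never a silent 0.

Cross-cohort validation marks a record `validated` when the same
(subgroup, gene) pair is flagged with the same direction in a second
cohort.  Nomination takes up-direction fingerprint genes and requires
Δ > 0 **and** p < 0.05 against *every* normal population tested — strict
positivity because the scientific goal is overexpression on leukemic
cells; a degenerate comparison fails the requirement.  BH q-values are
again extension columns only.

## Synthetic cohorts

The generator emulates the screen's data-generating assumptions, not any
particular dataset:

* **Shape** — 148 AML + 12 CD34⁺ reference samples, five normal
  populations of 3 (granulocytes, B cells, T cells, monocytes, total white
  blood cells), 772 receptors in 18 subfamilies (sizes mimic an
  IUPHAR/GRAFS-style partition: 370 olfactory, 23 chemokine, 33 adhesion,
  …).
* **Baselines** — per-gene mean μ_g ~ Normal(1.0, 2.0) truncated at 0 on
  the lRPKM scale.  This is a stand-in: no distributional description of
  real receptor RPKM exists to copy, and the truncated normal reproduces
  the qualitative picture (roughly half the repertoire silent, a long
  expressed tail) without claiming realism.  Chosen once; location/scale
  are config fields.
* **Noise** — per-sample values Normal(μ_g + effects, σ) with σ = 0.5
  lRPKM by default, truncated at 0.  Truncation (rather than resampling)
  is simple and its bias is negligible except at the floor, where a
  silent gene's sample mean rises by ≈ 0.2 lRPKM — well below every
  decision threshold.
* **Planted effects** — additive on the lRPKM scale, so a planted Δ maps
  1:1 onto the screen's Δmedian/Δmean cut-offs.  The default cohort plants
  30 up and 19 down genes at ±2 lRPKM, with 6 of the 30 up genes drawn
  from the 23-member chemokine-like subfamily (a real enrichment to
  recover), plus ±2 lRPKM subgroup shifts (8 genes for t(8;21), 8 for
  inv(16), 4 for *MLL*, 3 for *FLT3*-ITD, 1 for *NPM1*, 0 for *DNMT3A* —
  mirroring that not every subgroup need carry a fingerprint).  Planted
  down genes and down subgroup effects receive high baselines (3.5–6.5
  lRPKM) so the shift is observable above the truncation floor, mirroring
  receptors well expressed in the normal reference.
* **Annotation** — cytogenetic labels are mutually exclusive draws over
  all AML samples (8% t(8;21), 8% inv(16), 10% *MLL*); non-cytogenetic
  samples are 65% normal / 15% complex / 20% other karyotype; mutation
  flags are independent Bernoulli draws within normal-karyotype samples
  (45% *NPM1*, 35% *FLT3*-ITD, 30% *DNMT3A*, approximating reported
  normal-karyotype co-mutation rates and allowing co-occurrence).
* **Determinism** — a single root seed drives three spawned numpy
  SeedSequence streams (baselines, annotation, noise), so any stage can be
  regenerated independently and the same config + seed is bit-identical.

What passing tests on these cohorts show: the screen's thresholds, tests
and bookkeeping recover exactly the planted structure at the planted
effect sizes and control false calls under the modeled noise.  What they
do not show: robustness to count-level dispersion (negative-binomial
variance), batch effects, mixed cellularity, or annotation errors — none
of which the generator models.

## Numerical and design notes

* Validation is strict and named: duplicate ids, negative RPKM, conflicting
  subfamily assignments, flags on non-AML samples and unknown cohort or
  population labels all raise a `ValidationError` identifying the
  offender; well-formed inputs are never rejected.
* Gene ids are opaque strings; an optional exact-match synonym table
  handles aliases (e.g. two names for one receptor).  When a matrix
  contains unclassified genes the pipeline intersects on classified ids
  and writes the dropped set to `dropped_genes.tsv`.
* Result tables are TSV with a fixed column order and `%.10g` floats;
  the manifest stores input checksums and file names (not absolute paths),
  so identical inputs give byte-identical outputs wherever they live.
* Replicate-based checks in the test- and acceptance-suites use 20 seeded
  cohorts of the full default shape (148 vs 12 × 772 genes); unit tests
  use a 60-gene, 40-vs-8 scaled cohort that exercises every stage.

## Limitations

* The median-difference call has no error model; its false-call rate is
  characterized empirically on null cohorts rather than controlled
  analytically.
* Fingerprints and nominations inherit the multiple-testing exposure of
  the published procedure; the BH columns are provided but deliberately
  not used for the headline calls.
* The generator's Gaussian lRPKM noise understates the mean–variance
  coupling of real RNA-seq counts at low expression.
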