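# Methods

This note documents the models implemented in `ncaging`, the parameters
that matter, the synthetic data used to test them, and the numerical and
design choices made where more than one reasonable option existed.

## Normalization and filtering

Expression is measured in reads per mapped million (rpmm): each sample
column is scaled by 10⁶ over its in-matrix count total. Two choices are
deliberate:

* **Denominator = in-matrix total.** Whether class-share or rpmm
  denominators should include unmapped or out-of-matrix reads is
  ambiguous in practice; we use only counts present in the loaded matrix.
* **Normalize before filtering, never re-normalize.** rpmm is attached
  once; all filters subset the normalized table. Consequences: filters
  are idempotent and commute, and a feature's rpmm cannot change because
  some other feature was removed.

Filter semantics (all thresholds live in `Thresholds`):

| rule | comparison |
|---|---|
| sample QC, 2·10⁶ aligned reads | strict "fewer than" — a sample at exactly 2,000,000 is kept |
| global abundance, 1 rpmm in ≥ 1 sample | inclusive at 1.0 rpmm |
| local abundance, 10 % of a tissue's samples | exact fraction k/n ≥ 0.10, no rounding |
| circulating detection, > 10 % of a group's samples | strict, intentionally different from the local filter |
| piRNA prepachytene | piRNAs with a false or missing cluster flag are removed; other classes untouched |

Somatic piRNA annotation is noisy (piRNA-sized fragments of other ncRNAs
are frequently annotated as piRNAs), hence the cluster-membership filter
and the expectation — reproduced on synthetic data — that the abundance
filter removes ≳ 90 % of detected piRNAs.

RNA-class composition: per-sample percentage shares, averaged per
(tissue, timepoint); a tissue's temporal stability is the mean over
classes of the sample variance (ddof = 1) of the timepoint shares,
compared against 4.5 (percent² scale). Equality classifies as stable;
the published wording defines only the two open intervals, so the
boundary had to be assigned — we chose the conservative side. We follow
the word "variance" literally rather than interpreting it as a standard
deviation.

## Aging classification

Spearman correlation is Pearson on mid-ranks; two-sided p values use the
t approximation with n−2 degrees of freedom, replaced by the exact
permutation distribution for n ≤ 9 without ties (the regime where the
approximation is worst). The cutoffs are strict: |ρ| must *exceed* 0.5,
and a global call needs the same sign in *more than* five tissues —
positive and negative global sets are counted separately, matching the
practice of reporting them as separate lists. A feature exceeding the
cutoff in 1–5 tissues is local; when several tissues qualify the summary
column names the tissue of largest |ρ| and a second column keeps all of
them.

Fold-change deregulation uses group means per timepoint against the
3-month baseline; zero-baseline features are excluded, log₂FC is dropped
when FC = 0. Deregulation is the fold-change rule alone (strict at 2/3
and 3/2); the t-test/BH flags are carried separately (`significant`),
because the headline deregulation counts are defined on FC alone while
p values are only computed where both groups have ≥ 3 samples. The
t-test is Welch's by default (the safer choice under unequal variances;
the classical equal-variance test would be an easy toggle). BH
correction is applied within each (tissue, timepoint) stratum only.

## Trajectory clustering

Each (feature, tissue) trajectory is the mean rpmm per timepoint,
z-scored with ddof = 1; constant trajectories are dropped. Fuzzy c-means
uses the standard Bezdek updates (membership ∝ d^(−2/(m−1)), centroids
weighted by u^m), k-means++ initialization from the seed, best of
`n_init` restarts by objective, and an assertion that the objective is
non-increasing every iteration. A point coinciding with a centroid gets
membership 1 there (singularity rule).

* **Fuzzifier m = 2.0.** The conventional default for time-course
  clustering; a data-driven estimate would trade seed stability for
  little gain at 10 timepoints, so it is a config option conceptually,
  not the default.
* **Choice of c.** Dmin(c) — the minimum pairwise centroid distance — is
  computed for each candidate c; we select the c with the largest
  relative drop Dmin(c)/Dmin(c+1). The measure is standard; the decision
  rule on top of it is our interpretation (the alternative is visual
  inspection), and the full curve is always returned so a user can
  overrule it.

A cluster is tissue-specific when ≥ 30 % (inclusive) of its hard-labelled
members come from one tissue.

## Target inference

Candidate pairs are scored by Spearman correlation per tissue between
miRNA and gene rpmm over matched samples; an inverse target needs
ρ < −0.4 and p < 0.05 in at least two tissues. The control set mirrors
the criterion at ρ > +0.4 with the same p cutoff and tissue-support rule
(the mirrored threshold is our choice; only the inverse threshold is
standard). Enrichment counts unique (miRNA, gene) pairs — a pair counts
once regardless of how many tissues support it or how many sites of a
type it carries — and tests each site type (8mer, 7mer-m8, 7mer-1a) and
the pooled "any" with a two-sided Fisher exact test. When the control
has zero hits the fold is reported as +inf and Fisher is still computed.

## Parabiosis

REJ is oriented HA relative to IA (so "REJ up" means higher in the
heterochronic aged animal), ACC is HY relative to IY, AGE is 21 m
relative to 3 m. Deregulation requires the fold change strictly outside
(2/3, 3/2) **and** p < 0.05 (Welch); a missing p never deregulates.
Group assignment: reversal groups (REJ and AGE deregulated in opposite
directions) take precedence, then same-direction AGE+ACC, then uniquely
deregulated REJ or ACC. The reversal groups do not additionally require
ACC non-deregulation — the definitions are ambiguous on this point and
we chose the weaker reading; the exhaustive truth-table test pins down
exactly the semantics implemented. Features absent from the aging cohort
get dereg_age = false rather than being excluded.

The per-feature reversal summary z-scores the feature across all
parabiosis samples of a tissue and reports group means, the rejuvenation
effect |z(IA) − z(HA)|, the acceleration effect |z(HY) − z(IY)| and
their ratio (NaN when the acceleration effect is zero).

## Synthetic cohorts

The generator emulates the study design, not the sequencing chemistry:

* 6 tissues × timepoints {1, 3, 6, 9, 12, 15, 18, 21, 24, 27} months ×
  4 replicates (a 16-tissue layout is available by config; the 6-tissue
  default keeps the full test suite under a minute).
* Counts are gamma-Poisson (negative binomial, Var = µ + φµ²) around
  library-scaled expected rpmm with log-normal library sizes
  (µ = 15.5, σ = 0.15 on the log scale, ≈ 5.4 M reads). φ = 0.03 for the
  aging cohort — a realistic bulk small-RNA biological+technical
  dispersion at this depth — and φ = 0.01 for the parabiosis cohort,
  whose groups are age-matched inbred animals under a controlled 5-week
  intervention rather than a 27-month lifespan span.
* Planted global aging features (20) follow log-linear trends of
  1.5 log₂ units across the lifespan with a single sign per feature in
  every tissue; local features (10 per tissue) carry the trend in one
  tissue only; 95 % of piRNAs are planted near zero (≤ 0.1 rpmm) to
  mimic spurious somatic piRNA annotation.
* mRNA partner: each global miRNA gets 16 inverse and 16 positive planted
  genes whose log-means track the realized miRNA expression (β = 1), plus
  150 independent genes. Conserved sites are assigned at base probability
  0.12, multiplied by 5 for true inverse-target pairs. The base rate and
  target count were set by the prescribed multi-seed calibration so that
  the planted enrichment is reliably *detectable*: because all same-sign
  global miRNAs share the age trend, the called inverse set necessarily
  contains cross-miRNA pairs, which dilutes the observed fold well below
  the planted 5× — a real feature of correlation-based target calling,
  not a bug.
* Parabiosis: IY/IA means equal the aging model at 3/21 months; for
  reversible features (the planted global set) HA is pulled linearly
  toward IY by the reversal fraction (default 0.8) and HY toward IA by
  the acceleration fraction (default 0.2), with 6 replicates per group.
  Linear-scale interpolation makes the z-score effect ratio equal
  reversal/acceleration exactly; with `noise="none"` the normalized
  matrix holds the exact planted rpmm means (counts are rounded
  library-scaled versions — the counts↔rpmm consistency invariant is
  intentionally relaxed in this verification mode), so the 0.8/0.2
  design yields a rejuvenation-to-acceleration ratio of exactly 4.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: sequence-level read simulation, ligation and
PCR biases, RNA degradation profiles, batch structure, mixed cell-type
composition, non-monotone aging trajectories beyond what the planted
log-linear trends induce, and miRNA–target regulation that is not
expressible as a rank correlation.

## Numerical notes

* Interval coordinates are 0-based half-open everywhere; touching
  intervals merge (contiguity at a shared boundary), a stated choice
  since adjacency is otherwise undefined. Coverage statistics are
  validated against a per-position occupancy scan.
* "Covered read length" is exposed both as the union size
  (`covered_length`) and as total raw read length
  (`total_reads × mean_read_len`), since the two readings of that
  phrase differ.
* Fuzzy c-means tolerance 1e-6 on the maximum centroid shift, 300
  iterations max; distances below 1e-300 trigger the singularity rule.
* Spearman p values: t approximation two-sided, exact permutation for
  n ≤ 9 without ties; constant vectors return NaN with a warning.
* Problem sizes in the acceptance script (10 aging seeds, 20 enrichment
  seeds, 120-trajectory planted clustering) are the package's chosen
  desk-scale defaults; all quantities it reports are recomputed at run
  time from the seed given.

## Known limitations

* The headline counts of any real study (numbers of global miRNAs,
  cluster compositions, specific target lists) depend on the real
  cohorts and are out of reach of the synthetic design by construction;
  the tests certify the *machinery*, not those numbers.
* The Dmin elbow rule can select a smaller c than the visually appealing
  one when cluster shapes overlap smoothly; inspect the returned curve.
* Fold-change-based deregulation on mean rpmm is sensitive to outliers
  in small groups; the Welch p value guards the parabiosis calls but the
  aging deregulation counts are FC-only by design.
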