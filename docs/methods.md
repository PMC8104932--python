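# Methods

## Pipeline overview

The package estimates allelic imbalance (AI) from allele-specific counts in
four stages, followed by a crossing-design inference layer:

1. **Genotype-specific references** (`refbuild`). Each parental line's SNPs
   are substituted into the reference FASTA. Only biallelic single-nucleotide
   substitutions are applied, so sequence names and lengths — and therefore
   all coordinates — are preserved between the two parental references.
   Indels, multiallelic records, reference mismatches, records on unknown
   chromosomes and heterozygous calls are skipped with machine-readable
   reasons. Heterozygous calls are treated as genotyping errors because the
   method targets inbred parental lines. Soft-masked reference bases are
   matched case-insensitively; edited positions are emitted uppercase.
2. **Dual-alignment classification** (`alncount`). The same reads, aligned
   upstream against both parental references, are compared read by read.
   The comparison metric is the aligner's alignment-score tag (AS) when
   present, falling back to mapping quality; ties at the finest available
   level are AMBIGUOUS, a read mapped in only one genome is informative for
   that allele, a read mapped in neither is UNMAPPED. Every read increments
   exactly one feature's x (allele 1), y (allele 2) or z (ambiguous)
   counter — the feature containing its leftmost aligned coordinate —
   which preserves read conservation (x + y + z + unmapped = input reads).
   Overlapping BED features are refused rather than resolved silently.
   Technical replicates are summed; features with x + y below a
   user-chosen threshold are flagged, not dropped.
3. **Mapping-bias priors** (`priors`). q1 is the probability that a read
   originating from genome 1 maps better to genome 1; q2 analogously. Two
   estimators are provided. From reads of known origin (simulation):
   q_g = best-to-own / total mapped. From F1 genomic DNA, where the true
   allele ratio is 1:1: E[x] = N·q1/2 and E[y] = N·q2/2 with N = x + y + z,
   giving the moment estimators q1 = 2x/N, q2 = 2y/N. Estimates are point
   values clipped into [1e-3, 1 − 1e-3] (the model requires the open
   interval) and plugged into the model as constants. No estimator is
   offered for RNA counts: RNA confounds AI with bias, so the mode is
   reserved and refused with an explanation. Defaults are q1 = q2 = 0.5.
4. **Bayesian model** (`bayes`). Per condition c, informative counts follow
   `x_c | x_c + y_c ~ Binomial(x_c + y_c, pi_c)` with
   `pi_c = theta_c q1_c / (theta_c q1_c + (1 - theta_c) q2_c)`; conditions
   are independent a priori and delta = theta_1 - theta_2. Evidence against
   a null is the statistic ev = 2·min(F(null), 1 − F(null)) under the
   empirical posterior CDF F (convention: F(v) = #draws ≤ v / n) — the
   smallest ev whose 1 − ev equal-tailed interval excludes the null.
5. **Crossing designs** (`crossdesign`). Testcross triples (two crosses
   sharing a tester in the same parental role) are enumerated from the
   cross design; rejection of H3 (equal AI) between the two member crosses
   predicts divergent nontester alleles; rejection of H3 between reciprocal
   crosses flags parent-of-origin (POO) effects; predictions are validated
   by detecting AI (H1) in a direct cross of the two nontester lines.
   McNemar's test for paired detection calls uses the exact binomial form.

## Model assumptions and choices

- **Likelihood.** Ambiguous reads are excluded from the likelihood: under
  the generative model they carry no allelic information beyond what q1 and
  q2 already encode, and conditioning on the informative total removes the
  overall-expression nuisance parameter. This binomial-conditional form is
  a deliberate reconstruction — it is the simplest model consistent with
  the q1/q2 "maps better" semantics and the informative-count tables the
  pipeline produces.
- **Prior.** Beta(a, b) on the informative-read probability pi_c, default
  a = b = 1 (uniform, symmetric at the null); theta_c is the deterministic
  monotone transform of pi_c. Placing the prior on pi makes the posterior
  conjugate — `Beta(a + x, b + y)` — which provides an exact analytic
  oracle for validating the sampler. When q1 = q2 the induced prior on
  theta is identical to a Beta(a, b) prior on theta itself; when the biases
  differ, the two parameterisations differ slightly and the pi
  parameterisation was chosen as the one with a checkable closed form.
- **Sampler.** Independence Metropolis-Hastings on eta = logit(pi),
  vectorised across features and chains: proposals are Student-t (df 5)
  centred at the posterior mode with scale 1.2 times the Laplace
  (inverse-curvature) scale, so proposal tails dominate the target's and
  the chain is geometrically ergodic; acceptance is typically above 0.9.
  Defaults: 4 chains × 2000 iterations with 1000 warmup (4000 retained
  draws). Identical inputs and seed reproduce identical output.
  Diagnostics (split-R̂, bulk ESS, MCSE of means and interval endpoints)
  come from arviz; a fit with split-R̂ > 1.05 on any reported quantity is
  emitted with its convergence flag cleared, never suppressed.
- **Reported scale.** AI is reported as theta (share of allele 1,
  null 0.5) with 95% central credible intervals; delta = theta1 - theta2
  (null 0); the fold-ratio theta/(1 − theta) is available as a
  deterministic transform for readability.
- **Thresholds.** No ev threshold is hard-coded; every decision rule takes
  `alpha` (default 0.05) as a parameter, and coverage flags mask features
  from prediction but never remove rows from output.

## Synthetic data

`simfix` generates data at two levels.

*Count level* — each of N reads originates from allele 1 with probability
theta and is informative to its genome of origin with probability q_g, else
ambiguous, so (x, y, z) ~ Multinomial(N; theta·q1, (1−theta)·q2, rest).
Scenarios cover arbitrary cross grids, per-feature theta, conditions,
replicates, POO shifts added to one reciprocal cross, and an optional
cross-misassignment (contamination) rate that the default model assumes
absent. Defaults emulate a realistic bulk RNA-seq experiment on a 3-line
reciprocal panel: 500 reads per feature per sample, q1 = q2 = 0.9
(roughly one read in ten uninformative), cis effect sizes of 1.5-fold for
divergent alleles, POO shifts of 0.15 on the theta scale.

*Read level* — `make_toy_fixture` writes a miniature but complete data set
(two 1 kb chromosomes, one feature each, two inbred lines with disjoint
SNPs, ~60 placed reads). Alignment records are synthesized directly, not
produced by an aligner, so tests are bit-stable: reads overlapping a line's
SNPs get a higher alignment score against that line's genome, reads on
SNP-free segments get equal scores (true AMBIGUOUS), plus unmapped and
intergenic reads. Every read name carries its ground-truth label.

What the generator does **not** emulate: sequencing error and base
qualities, fragment-length and GC effects, positional coverage
heterogeneity, overdispersion across biological replicates, genuine
aligner behaviour (soft-clipping, multimapping), or trans-acting and
cis-by-trans structure. Passing calibration tests therefore demonstrates
correctness of the statistical machinery under its own assumptions — not
robustness to every artefact of real libraries.

## Verification strategy and problem sizes

The acceptance checks (mirrored in `scripts/acceptance.py`) are sized to
run in about half a minute total on one CPU while keeping every estimate's
Monte-Carlo error well inside the asserted bands:

- ev versus a brute-force equal-tailed-interval scan (grid step 1e-3) on
  1000 random draw sets.
- Sampler versus the conjugate analytic posterior on 50 random
  configurations (x + y up to 2000): the 150 standardised errors
  (mean, 2.5%, 97.5% of theta) must be unit-scaled (mean z² in
  [0.75, 1.33]) with max |z| < 4.3, the 99.73% quantile of the maximum of
  150 absolute standard normals. A per-z 3-sigma assertion would reject an
  exactly correct sampler about a third of the time, so the same
  confidence standard is applied familywise.
- Type-I error at the null (500 features, theta = 0.5, true priors):
  ev_h1 and ev_h3 rejection rates inside the 95% binomial band around 5%.
- Bias-correction necessity: at theta = 0.5 with q1 = 0.8, q2 = 0.5 a
  naive exact binomial test rejects almost always; the model with true
  priors stays in the calibration band.
- Parameter recovery over 200 features at 500 reads with theta drawn from
  the prior: |bias| < 0.01 and 95% interval coverage in [0.93, 0.97]
  (the prior draw makes nominal coverage exact by construction; a 40k-draw
  budget keeps endpoint jitter from moving borderline features).
- End-to-end: the read-level fixture through reference building,
  classification and counting reproduces the generator's truth table with
  zero mismatches.
- Testcross inference on the 3-line reciprocal design (150 null + 100
  divergent features): prediction power above the false-prediction rate,
  validation in direct crosses above the null base rate, POO detectable
  through reciprocals and invisible to testcrosses by construction.

## Allele orientation in comparisons

COUNT_G1/COUNT_G2 are defined by which genotype reference the design file
lists first for a cross, so "allele 1" is a per-cross convention. A
two-condition comparison is only meaningful if both sides label the same
thing as allele 1: for a testcross comparison that is the tester allele
(automatic when the tester is listed consistently); for a reciprocal pair
A×B vs B×A the same *line* must be listed first in both crosses, otherwise
a pure cis effect masquerades as a parent-of-origin signal. Swapping a
cross's orientation is exact — exchange x with y and q1 with q2, mapping
theta to 1 − theta — and the packaged 3-line experiment
(`simfix.three_line_experiment`) applies it automatically per comparison.

## Known limitations

- Priors are point estimates; their sampling uncertainty is not propagated
  (no hierarchical treatment of q1, q2 across features).
- No shrinkage or joint modelling across features or across the cross
  grid; every (feature, comparison) is fit independently.
- Paired-end mates are classified independently unless fragment-level
  agreement is requested; no split-read or fusion handling.
- Coordinate equivalence between parental references holds only because
  edits are SNP-only; indel-segregating lines would need liftover, which
  is out of scope.
- Sex chromosomes and organellar genomes receive no special handling;
  analyses are intended for autosomal features.
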