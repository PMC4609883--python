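# Methods

## Model and assumptions

A differential co-expression variant is a biallelic SNP whose genotype
partitions samples into two groups with different population correlation
between a pair of expression probes. The test is the classical
two-sample comparison of correlations: within-group Pearson r, Fisher's
variance-stabilizing transform z = arctanh(r) with sampling variance
approximately 1/(m − 3), and the standardized absolute difference

    Z = |z1 − z2| / sqrt(1/(m1 − 3) + 1/(m2 − 3)),

referred to the standard normal for a two-sided p-value. The transform
is applied *signed*: r = −0.9 and r = +0.9 are maximally different
correlation structures and must produce a large Z, so the absolute value
enters only in the numerator difference, and the denominator carries the
square root of the summed approximate variances, as the standard-normal
reference requires. Assumptions inherited from this machinery:
approximately bivariate-normal expression within groups (Pearson r plus
the arctanh variance formula), independent samples, and group sizes
large enough for the normal approximation (hard floor m ≥ 4, where the
variance term is defined at all; m ≳ 25 per group for the tail to be
trustworthy). The normal approximation is known to be slightly liberal
in the extreme tail at moderate group sizes; the permutation module
exists precisely to measure the realized false-positive behavior on a
given instance rather than trusting the asymptotics.

## Genotype encodings

Calls are coded as minor-allele counts {0, 1, 2} with missing calls
excluded per SNP (pairwise exclusion maximizes usable samples and keeps
each SNP's test independent of unrelated missingness). Three
dichotomizations are provided: dominant (0 vs {1,2}), recessive
({0,1} vs 2) and homozygous (0 vs 2, heterozygotes excluded). Dominant
is the default discovery model: with the default MAF window it best
balances the two group sizes, which both maximizes power and keeps the
m − 3 variance terms comparable. No additive/dosage model is offered —
the statistic compares exactly two groups; a linear model of
co-expression on allele count is a different estimator and deliberately
out of scope.

## Preprocessing

Applied in this order, mirroring a standard discovery pipeline:

1. **MAF window** (default 0.2–0.8 on allele frequency, i.e. minor
   frequency ≥ 0.2, inclusive bounds). Guarantees both genotype groups
   are populated; below 0.2 the minor-homozygote group collapses and the
   recessive/homozygous encodings become untestable.
2. **Per-transcript quantile normalization**: value at ascending rank k
   maps to Φ⁻¹((k − 0.5)/n); ties get average ranks, so a constant
   transcript maps to all zeros rather than erroring. The (k − 0.5)/n
   offset is the conventional symmetric choice and makes the transform
   exactly testable; output depends only on ranks, so any strictly
   monotone distortion of the raw intensities is removed. This also
   tames cross-population scale differences in mixed-ancestry cohorts.
3. **Top-N variance filter** (after normalization): unbiased sample
   variance (ddof = 1), ties at the cutoff broken by probe-ID
   lexicographic order so the selected set is deterministic and
   invariant to input row order.

Upstream genotype QC (call rate, Hardy–Weinberg, LD pruning) is assumed
done by dedicated genotype tooling; this package only applies the MAF
window and per-SNP missing-call exclusion.

## Multiple testing

The family is every SNP against every unordered probe pair:
S × T(T − 1)/2 designed tests. The Bonferroni threshold divides alpha by
that full designed count **including skipped trios** — a trio skipped
for a small group or a constant probe was still designed, and shrinking
the denominator after the fact would be anti-conservative. At the
reference genome scale (70,716 SNPs × 10,000 probes, alpha 0.05) the
threshold is 1.41 × 10⁻¹⁴; restricted to a single variant it is
~1 × 10⁻⁹. Benjamini–Hochberg FDR (step-up over the evaluated p-values,
via statsmodels) is available for users who accept a false-discovery
criterion instead of family-wise control; `--p-threshold` overrides
either arithmetic explicitly.

## Scan engine

Per SNP, the expression matrix is restricted to each genotype group and
the full probe × probe correlation matrix is computed per group from the
centered block (one matrix product), rather than looping over pairs; the
results equal the naive per-trio loop up to floating-point summation
order (verified to relative error 10⁻¹² in tests). Trios are skipped,
counted by reason, and never assigned a placeholder p when a group falls
below `min_group_size` or a probe is constant within a group (constancy
is detected exactly, max = min). The bookkeeping identity
evaluated + skipped = designed holds on every run. Output is
canonicalized — probe_i < probe_j lexicographically, rows sorted by
(snp, probe_i, probe_j) — so identical inputs and config produce
byte-identical files regardless of input row order. Only trios at or
below the emission threshold are materialized, which keeps genome-scale
result sets bounded.

## Permutation false-positive estimation

The null is generated by permuting each SNP's call vector across samples
(missing entries travel with the permutation) while fixing expression.
This preserves every per-SNP genotype count — hence MAF, group sizes and
the marginal distribution of the statistic — while severing any
genotype–expression link; it also destroys inter-SNP LD, which is
intentional: the estimator targets the per-trio null, not the effective
number of independent tests. Each SNP draws its permutation from a
stream keyed by (master seed, CRC-32 of the SNP ID), so results are
reproducible and independent of SNP storage order. At a Bonferroni
threshold alpha/n_tests the expected survivor count per whole-scan
replicate is alpha; the acceptance study checks the mean over 200
replicates of a 10-SNP × 50-probe null fixture (100 samples) against the
99% Monte-Carlo interval around 0.05. Overlapping probe pairs make the
per-scan counts mildly dependent, and the far-tail liberality noted
above can push the realized mean somewhat above nominal while remaining
within that interval — which is exactly the kind of deviation this
estimator is meant to surface.

## Synthetic fixtures

`dcvar.synthetic.generate` plants one ground-truth trio: a causal SNP
drawn at Hardy–Weinberg genotype frequencies for the requested MAF
(redrawn, by default, if a group comes up short of `min_group_size`),
and a probe pair drawn bivariate normal — via the 2 × 2 Cholesky
factor — with correlation rho1 in G1 and rho2 in G2 under the chosen
model. Heterozygotes excluded by the homozygous model need their own
correlation; they inherit rho1 unless `rho_het` says otherwise (a
declared, configurable convention). Null SNPs draw MAFs uniformly in
[0.2, 0.5]; null probes are i.i.d. standard normal. All margins are
standard normal, so quantile normalization is approximately an identity
on large fixtures and the statistic is tested in isolation from
normalization effects. Default study conditions: 200 samples, causal MAF
0.3, dominant model, rho1 = 0.7 vs rho2 = 0.0, 10 null SNPs, 20 null
probes — sized so a planted effect of realistic strength is clearly
separable from the null floor of ~2,500 trios on one CPU in
milliseconds. The generator does **not** emulate LD, population
stratification, microarray noise floors or RNA-Seq count distributions;
passing tests demonstrate correctness and calibration of the statistic,
not robustness to those real-data features.

## Numerical choices

- A within-group |r| = 1 (possible at tiny m) is clamped to
  ±(1 − 10⁻¹⁵) before arctanh and flagged on the result, preserving
  "extremely significant" rather than overflowing to infinity.
- p-values are floored at the smallest positive double (5 × 10⁻³²⁴)
  because 2·Φ̄(Z) underflows to exactly 0 near Z ≈ 39 and the contract
  requires p > 0; they are written in scientific notation with six
  significant digits so 10⁻¹⁴-scale thresholds survive a text round
  trip.
- Pearson r is computed with matching divisor conventions in numerator
  and denominator (the result is divisor-invariant); block results are
  clipped into [−1, 1] to absorb last-ulp excursions.
- Minor-allele designation at load time: the less frequent allele among
  non-missing calls; at an exact 50/50 tie the lexicographically smaller
  character is the major allele. "0" and "N" allele characters are
  missing; a call with ≥ 1 missing allele is missing.
- `min_group_size` defaults to the mathematical floor 4 and is
  configurable upward (10+ recommended for stable correlations).

## Known limitations

Two-group dichotomization cannot model a dose-dependent correlation
trend across the three genotypes; Pearson r is outlier-sensitive (no
Spearman/bootstrap variant is provided); the Fisher-z normal reference
is approximate in the far tail at moderate m (measure it with `dcvar
permute` on your own instance); and the scan is single-process —
genome-scale runs should shard SNPs externally.
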