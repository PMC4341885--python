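# Methods

## The statistic

For a SNP pair the 3×3 genotype table is collapsed under a dominant
(carrier = ≥1 minor allele) or recessive (carrier = homozygous minor)
assumption into four classes, each split into cases and controls:
α/β (non-carrier × non-carrier), γ/δ (non-carrier × carrier),
ε/ζ (carrier × non-carrier), η/θ (carrier × carrier).  The interaction
odds ratio is

    I_OR = OR₁*₂/(OR₁·OR₂) = αδζη/βγεθ,
    OR₁ = βε/αζ, OR₂ = βγ/αδ, OR₁*₂ = βη/αθ,

with a pseudocount (default 1) added **unconditionally** to all eight
cells, not only when a zero appears — this keeps every value finite and
makes the statistic continuous in the counts.  u(I_OR) = max(I_OR, 1/I_OR)
folds the two interaction directions onto one upper tail; exchanging the
case and control columns maps I_OR to 1/I_OR and leaves u unchanged, and
swapping the roles of the two SNPs leaves both unchanged.

Genotypes are coded as copies of the dataset-wide minor allele, defined by
pooled frequency over all retained samples (cases + controls); an exact
tie at 0.5 is broken toward the lexicographically smaller allele name.
This makes all downstream statistics invariant to how alleles are listed
in the input files.  Missing data are handled pairwise complete-case: a
sample missing either genotype of a pair is excluded from that pair's
table only.

## Scan

Each SNP is pre-encoded, separately for cases and controls, into two
packed bit strings: a carrier mask and a present (non-missing) mask.  All
eight cells of any pair's table are then AND/NOT combinations followed by
popcounts, so the exhaustive scan over n(n−1)/2 pairs is cheap.  Pairs are
excluded when

* both SNPs share a chromosome and lie < 100 kb apart (strict `<`;
  linkage-disequilibrium guard — the rule is undefined across
  chromosomes and never applied there);
* any class row total (cases + controls combined) is < 50, or any cell is
  < 5, on **raw** counts before the pseudocount — sparse tables produce
  extreme but unstable u values.  Whether the original row rule counted
  columns separately is not documented; combined totals are used and the
  thresholds are configurable.

Rejection reasons are counted with precedence distance → row → cell, so
evaluated + rejected = candidate pairs.  The top-K list (default K = 500)
is deterministic: descending u(I_OR), ties broken by the lexicographic
(snp1, snp2) id pair, each row listing the smaller id first.  The scan
streams SNP-against-block and prunes the accumulator keeping all boundary
ties, so results are independent of block size and SNP input order.

## Significance

**Empirical P** of a pair is the proportion of random case/control label
assignments (shuffles of the full phenotype vector, preserving group
sizes) whose u(I_OR) is ≥ the observed value.  Conditional on the pair's
per-class totals, a label shuffle induces a multivariate hypergeometric
draw of case counts over the classes (including a "missing" class), so
`method="table"` samples that distribution directly — the identical null,
used by the benchmark for speed; `method="permutation"` shuffles labels
explicitly.  Each pair's stream derives from (seed, snp1, snp2), making
results independent of evaluation order.  An observed P of 0 is reported
as 0 (with n_perm known from the call); the (+1)/(n+1) correction is
available but off by default, matching the plain-proportion definition.

**Exact P** enumerates all case-count tuples (α′, γ′, ε′, η′) compatible
with the class row totals and the informative case count; each tuple's
probability is ∏C(rowᵢ, countᵢ)/C(N, n_cases).  Tuple I_OR values use the
same pseudocount as the observed statistic.  The enumeration asserts that
probabilities sum to 1 before tail-summing.  Tail convention: tuples with
I_OR ≥ x are summed, the sum doubled for the reciprocal tail, and the
result capped at 1.  For balanced designs (equal cases and controls) the
case/control exchange is measure-preserving, so for x > 1 this equals
Pr(u ≥ x) exactly and matches the permutation P; for unbalanced tables it
is conservative.  Summing u ≥ x *and* doubling would double-count both
tails, which is why the one-sided-then-doubled form is used.

The genome-wide threshold helper returns 2α/n² for n independent SNPs
(10⁻¹³ at α = 0.05, n = 10⁶).

## Simulator

Six 3×3 penetrance matrices define pure two-locus epistasis.  Both loci of
a model share allele frequencies (p, q = 1−p): genotype index 0/1/2 counts
copies of the q-frequency allele, so P(0) = p², P(1) = 2pq, P(2) = q².
(p, q) is (0.5, 0.5) for models 1–2, (0.25, 0.75) for 3–4, (0.1, 0.9) for
5–6.  Models 1–2 have exactly zero marginal effects (each genotype's
marginal penetrance equals the prevalence; model 1's prevalence is 0.05);
models 3–6 come from a computational search that *minimizes* marginals,
leaving relative spreads up to ≈4.3% (model 4) — so "no main effect" holds
exactly for 1–2 and only approximately for 3–6.  Tests reflect this: a
distributional case/control test for models 1–2, a 5%-tolerance
closed-form check and a bounded empirical marginal difference for 3–6.

A dataset is 200 cases + 200 controls × 10 SNPs by default.  Individuals
are rejection-sampled (vectorized, with a configurable draw budget ~5×10⁶)
until the case and control quotas fill; SNPs 1–2 carry the interaction,
the rest are phenotype-independent HWE noise with per-SNP minor-allele
frequencies drawn once per dataset from U(0.05, 0.45) — a range chosen so
null SNPs survive a MAF filter, configurable.  All SNPs sit 1 Mb apart on
one chromosome so the distance filter never removes the planted pair.

Noise conditions:

* **MS** (missing data): each genotype set missing independently with
  probability 0.05, applied last.
* **GE** (genotyping error): each genotype replaced with probability 0.05
  by one of the other two values uniformly.  By default the corruption is
  applied *before* disease assignment (`ge_mode="causal"`): the penetrance
  is read off the corrupted genotype, so the observed genotype–phenotype
  association is not attenuated.  This choice reproduces the published
  behaviour of benchmarks of this design, where the GE condition is
  indistinguishable from no noise for every model and method; a
  post-measurement variant (`ge_mode="readout"`), which attenuates power
  noticeably (model 2 drops from ≈0.97 to ≈0.8), is available.
* **PC** (phenocopy): half of the cases are relabelled unaffected-
  population individuals — their genotypes are drawn conditional on being
  unaffected under the model, emulating disease of non-genetic origin.
* **GH** (genetic heterogeneity): two independent planted pairs (SNPs 1–2
  and 3–4, same penetrance model by default), each causal in half of the
  (non-phenocopy) cases; the other pair's SNPs are population draws in
  that half.  Controls must be unaffected under both interactions.
  Combination order is GE → MS; with PC the case quota splits
  phenocopy/genetic first, then the genetic half splits across pairs.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs, covariates or population structure, sex chromosomes, main-effect or
additive disease models, quantitative traits.  Passing benchmark tests
therefore demonstrate detection of idealized pure epistasis in unlinked
panels, not performance on structured real cohorts.

## Benchmark protocol

Per condition (model × noise × collapsing): 100 datasets; every one of the
45 pairs gets an empirical P from 1000 permutations; a pair is detected at
P < 0.001 (strict, ≈ 0.05/45 Bonferroni).  Power = fraction of datasets
whose planted pair is detected; FWER = fraction with ≥1 other detection.
Under GH, power is reported three ways: both pairs, the first pair, or
either pair detected.  The scan-time distance/row/cell filters are
disabled here — they target sparse genome-scale data and would reject
valid 400-sample tables.  Per-dataset seeds derive from (master seed,
dataset index).  With 1000 permutations, detection requires the observed u
to exceed all permuted values; a null pair does so with probability
≈ 1/1001, giving an expected FWER of ≈ 1 − (1 − 1/1001)⁴⁴ ≈ 0.04, which
the no-noise FWER estimates match.

## Numerical and interface choices

* QC order: sample missingness (> 0.05 removed) → SNP missingness
  (> 0.05) → MAF (< 0.05, strict), each recomputed on surviving data; the
  minor-allele coding is re-derived afterwards.  QC is idempotent on
  realistic data, though adversarial missingness patterns could raise a
  sample's missing rate after SNP removal; at very small SNP counts the
  sample rule is coarse (one missing call in 10 SNPs is already 10%).
* The single-SNP "main effect" test is the 1-df allelic chi-square on
  minor/major allele counts (no continuity correction); monomorphic SNPs
  get P = 1.  Any standard single-SNP test would do; this one is fixed and
  documented, with removal at P ≤ 10⁻⁵ by default.
* PLINK phenotype codes: 2 = case, 1 = control; 0/−9 samples are dropped
  (never treated as controls) with a logged count.
* u(I_OR) comparisons use a 10⁻⁹ relative tie tolerance to absorb
  floating-point noise between arithmetically identical tables.
* Exact-P enumeration cost grows with the product of row totals; it is
  intended for the top-ranked pairs, not for exhaustive use.
* Problem sizes in the test suite follow the full benchmark protocol
  (100 datasets, 1000 permutations); oracle cross-checks run at reduced
  sizes (e.g. 36-sample tables for exact-vs-permutation agreement) chosen
  so full enumeration stays exact.
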