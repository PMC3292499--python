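# Methods

## The mixture model

A di-allelic locus has a tracked allele M (by default the minor allele;
any named allele can be designated) and alternative N. Each case-parent
trio is reduced to the code *x*<sub>abc</sub> — copies of M in parent 1,
parent 2 and the affected child — with parents unordered (a ≥ b), giving
ten Mendelian-consistent trio types grouped in six mating types. Writing
*g*<sub>abc</sub>(*t*) for the probability of the child's genotype given
the mating type when every heterozygous parent transmits M independently
with probability *t*, the sample is modeled as

Pr(x_abc) = μ_i(abc) · [π₁·g_abc(t) + (1−π₁)·g_abc(½)],

a two-component mixture: a linked fraction π₁ with free transmission
probability *t*, an unlinked fraction at the Mendelian ½. Both components
share one vector μ of mating-type frequencies. Assumptions worth stating
explicitly:

- *t* is common to all linked trios (a single-locus, single-effect model);
- mating types are ancillary: μ is shared between components, so its MLE is
  the observed mating-type relative frequencies under H0 and H1 alike, and
  μ cancels from the likelihood ratio;
- one affected child per family, parents' phenotypes unmodeled;
- trio types without a heterozygous parent (000, 201, 222) carry no
  information about *t*; their posterior probability of linkage equals π₁
  identically, and the implementation preserves that identity bit-exactly.

## Estimation and the test statistic

H1 maximization is by EM over (*t*, π₁). The E-step responsibility of the
linked component for trio type *abc* is π₁g(t) / [π₁g(t) + (1−π₁)g(½)];
the M-step updates are weighted binomial MLEs with symmetric pseudo-counts
C (numerator +C, denominator +2C), i.e. MAP estimation under
Beta(1+C, 1+C) priors on *t* and π₁. The penalized objective
ll + C·[log t + log(1−t) + log π₁ + log(1−π₁)] increases at every
iteration and is what multi-start selection maximizes; at the default
C = 0.001 the penalty's effect on estimates is O(10⁻⁵) for samples in the
hundreds. Defaults (changeable via `EMSettings`): 200 random starts with
t, π₁ ~ U(0,1) independently, at most 100 EM steps per start, convergence
when the penalized log-likelihood changes by < 10⁻⁶ (absolute change: the
tolerance is specified without a metric, and absolute log-likelihood
change is the conventional reading), highest penalized log-likelihood
wins, exact ties to the lowest start index. H0 (t = ½) needs no EM: π₁ is
unidentifiable there and the profile likelihood has the closed form with
μ̂ at observed frequencies. The statistic 2·(llmax_H1 − ll_H0) is floored
at 0 (finite-precision EM can land infinitesimally below the H0 value).
A sample with no heterozygous-parent trios leaves *t* unidentified: the
statistic is defined as 0 and a warning is logged.

The EM engine runs every (dataset × start) chain of a batch as one flat
vector, dropping chains as they converge; only the seven trio types with a
heterozygous parent enter (the other three cancel). When numba is
importable the chain loop is JIT-compiled; a pure-numpy fallback gives
bit-identical selections (asserted in the suite). A unit test also checks
the maximized likelihood against a two-stage 201 × 201 grid search over
(t, π₁) on random count vectors; that comparison runs with C = 0 and an
extended step budget, since the oracle maximizes the plain likelihood and
the penalty alone shifts the optimum by about the comparison tolerance.

## Permutation significance

The statistic is not χ²₁ under the null. The permutation scheme redraws
every child genotype from the Mendelian kernel conditional on its parental
mating type — equivalently each heterozygous parent re-transmits M with
probability ½ — preserving all six mating-type totals exactly and
generating the exact conditional null that H0 specifies. P-values are
plain exceedance proportions #{perm ≥ obs}/B (ties counted, conservative);
an add-one convention (k+1)/(B+1) is available by flag. The classic TDT is
evaluated on the same permuted tables so the two tests are compared on
identical data. Multi-locus sums use permutation-index-aligned per-locus
statistics; max-T family-wise p-values use the per-permutation maximum
across loci. For genotype-level multi-locus data the same parental
re-transmission is applied jointly across loci; for count-level data
(the simulation design) loci are permuted independently and aligned by
index, which is exact under the null because children are conditionally
independent across loci given mating types.

Choice of B: the plain-proportion test rejects at level α with probability
(⌊αB⌋+1)/(B+1) for a continuous statistic. B = 199 makes this exactly α at
both 0.05 and 0.01, so the null-calibration runs use B = 199. B = 100
would inflate the 1% level to ≈ 0.02 by discreteness alone. The power
comparisons use B = 500 — the reference protocol, whose effective 1% size
is 6/501 ≈ 0.012 — because matching the protocol matters on the steep part
of the power curve. The candidate-locus analysis default is B = 100,000.

## Simulator

Single locus: mating-type frequencies are the HWE random-mating products
of the allele frequency *p* (e.g. MN × NN has frequency 4pq³). Penetrances
come from prevalence φ, *p*, mode of inheritance and homozygote relative
risk R₂ via f₀·(q² + 2pq·R₁ + p²·R₂) = φ, with R₁ = R₂ (dominant), 1
(recessive) or √R₂ (multiplicative); a configuration implying f > 1 is an
error, never clamped. Each trio is linked with probability π₁; linked
trios are drawn from the ascertained distribution
∝ μ·g(½)·f_child (Bayes through the affected child), unlinked trios from
μ·g(½). Under the multiplicative MOI the ascertained distribution
factorizes exactly as mating-type weights times g(t*) with
t* = R₁/(R₁+1).

Multi locus: the linked/unlinked label is drawn once per trio and shared
across loci — π₁ is the probability that a *family* is linked, a family
property (a per-locus redraw is available as a code path but not the
default). Mating-type rows are chained per locus as
Y[l][i] = ρ·MT[l−1][i] + (1−ρ)·X with fresh X ~ U(0,1) per cell and row
normalization; ρ = 1 copies rows, ρ = 0 gives independent random rows. A
per-cell noise draw is used (a single shared X per locus, selectable by
flag, collapses ρ = 0 rows to the uniform vector). Mating-frequency rows
are redrawn per replicate. Linked children are generated with the kernel
at t* = R₁/(R₁+1), exact for the multiplicative MOI the multi-locus design
specifies; unlinked children at ½.

Replicates are seeded by independent per-replicate streams derived from the
design seed, so experiment results are identical regardless of chunking or
execution order. Empirical rejection rates are reported with exact
Clopper–Pearson 95% intervals.

What the generator does *not* emulate: genotyping error and missingness,
ascertainment beyond a single affected child, parental phenotypes,
haplotype-level LD (the ρ construction correlates mating-type frequencies,
not haplotypes), X linkage and parent-of-origin effects. Passing tests
therefore validate the statistical machinery under the stated model, not
robustness to those real-data features.

## Scaled protocols

The reference protocol per setting is 1000 trios, 250 replicates, 500
permutations and 200 EM starts. The test suite and the acceptance script
use desk-scale versions chosen once: 50 EM starts throughout (on a
two-parameter surface the multi-start maximum is already stable), B = 199
for null calibration (exactly sized, see above) and B = 500 for the power
cells, 100 replicates per cell in the suite's 40-cell null grid and 250
replicates per cell in the acceptance script and power runs.

## Known limitations

- The boundary penalty C is a pseudo-count construction chosen for its MAP
  interpretation; it is exposed in `EMSettings` so an alternative form can
  be substituted.
- The (t, π₁) likelihood surface has a flat ridge when the signal is weak:
  t̂ and π̂₁ are then individually poorly determined (only the mixture is
  identified), EM convergence is slow there, and reported estimates should
  be read jointly, as the worked example in the README illustrates. The
  LRT statistic itself is unaffected.
- Missing-parent trios, sib-TDT generalizations, covariates and
  quantitative traits are out of scope; input is text PED/MAP only.
- The per-locus odds-ratio column is the raw b/c transmission ratio and is
  reported as infinity when c = 0.
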