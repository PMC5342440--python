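# Methods

## Scope and data model

The package pools case–control genetic association studies summarised as
genotype counts. A study record holds three ordered counts per arm —
common homozygote, heterozygote, rare homozygote — with the effect (minor)
allele declared explicitly per SNP in the input, because published tables
orient each SNP differently and an explicit declaration avoids silent
allele flips. Odds ratios are always oriented effect-vs-reference.

Three record shapes are accepted: full genotype counts; pre-collapsed 2×2
counts valid for exactly one named contrast (some publications only report
enough for a dominant collapse); and incomplete rows, which carry partial
counts and no usable complement. Incomplete rows are kept — the table
mirrors its source line-for-line and the bookkeeping is auditable — but
every analysis skips them with a note. Duplicate (study_id, snp_id) pairs
are an error rather than a silent merge; source tables that repeat an
author-year label (one publication contributing several case series
against a shared control arm) must disambiguate, as the bundled table does
with suffixed ids. Note the bundled table reuses one Norwegian control
series across four case series and one American control series across
three SNPs; pooled estimates treat studies as independent, as summary-level
meta-analysis must.

## Per-study estimation

The effect measure is the crude (unadjusted) log odds ratio with the Woolf
variance, `SE² = 1/a + 1/b + 1/c + 1/d`. Wald z tests and normal-theory
CIs follow; the confidence level is a parameter, default 95%.

Zero cells make the Woolf estimate undefined, so a policy is explicit and
selectable:

* `drop` (default): the study is excluded from that contrast and recorded
  in `excluded_ids`. The source analysis evidently did this — its
  recessive and homozygote rows count 47 studies where the allele rows
  count 51, exactly the four studies with a zero rare-homozygote case
  cell — but never states the rule, so it is implemented as an inference
  and kept switchable.
* `haldane`: 0.5 added to all four cells (Haldane–Anscombe), flagged
  `corrected`.

## Hardy–Weinberg screening

Controls are tested by the three-cell Pearson χ² against expected counts
`n·((1−q)², 2q(1−q), q²)` with q the estimated rare-allele frequency, on
1 degree of freedom (3 cells − 1 − 1 estimated parameter). No Yates
correction and no exact test: the uncorrected statistic reproduces the
printed reference values. Monomorphic arms are defined to fit exactly
(χ² = 0, p = 1). One reference cell prints 0.484 where the exact
computation gives 0.48346 (→ 0.483), an off-by-one rounding in the source;
the test suite pins every other cell at printed precision and that one to
within 0.001.

## Pooling and heterogeneity

Fixed-effect pooling is inverse-variance on Woolf log-ORs; this choice
(rather than Mantel–Haenszel, the default of some packages) reproduces the
reference two-study rows at printed precision, and MH with the
Robins–Breslow–Greenland variance is kept as an option — the two agree to
well under 0.01 on the bundled data. Heterogeneity (Q, its p-value, I²,
τ²) is always computed from fixed inverse-variance weights regardless of
the method that reports the pooled effect; with one study P_het := 1 and
I² := 0, and τ² := 0 under any fixed method. Random effects are
DerSimonian–Laird with truncation at zero; k = 1 falls back to the fixed
answer. DL is only approximately unbiased for τ² and overcovers slightly
under homogeneity (truncation can only widen the interval) — the
calibration tests assert a band around nominal coverage that reflects
this. Hartung–Knapp, meta-regression and likelihood-based τ² are out of
scope.

Model selection follows the conventional rule — random effects when
P_het < 0.1 or I² > 50%, fixed otherwise (both thresholds are
parameters). The reference text garbles this sentence (its two branches
both say "fixed"); the conventional rule matches every internally
consistent Random/Fixed label in its tables, and inconsistent cells there
(apparently row-shifted) are not used as checks. Subgroup pooling applies
the same pipeline independently per stratum; leave-one-out re-pools each
k−1 subset and requires k ≥ 2.

Report formatting copies the field's table style for diff-based testing:
OR and CI to 2 decimals as `0.95(0.75,1.20)`, p-values to 3 decimals with
`<0.001` below that, I² to 1 decimal.

Known non-reproduction: the reference rs1563828 dominant row prints
OR 0.96, p 0.814, but recomputation from its own printed counts gives
0.97, p 0.842 under both IV and MH pooling — a probable transcription
error in the source. The suite asserts the recomputed values and
documents the discrepancy rather than matching the print.

## Publication-bias tests

Egger's test is the OLS regression of the standardized effect θ̂ᵢ/SEᵢ on
precision 1/SEᵢ (equivalent to weighted regression of θ̂ on SE); the
intercept is tested two-sided against t with k−2 df, k ≥ 3 required, and
an all-equal-precision design is rejected as singular. A zero-residual
(exactly collinear) input is reported finitely: p = 0 for a nonzero
intercept, p = 1 otherwise. The unweighted variant is not offered.

Begg's test rank-correlates the variance-stabilized deviates
uᵢ = (θ̂ᵢ−θ̂)/√(SE²ᵢ − 1/Σw) with the variances SE²ᵢ; Kendall's tau is
computed from concordant/discordant pair counts, and
z = (P−Q)/√(k(k−1)(2k+5)/18) with |P−Q| reduced by 1 as a continuity
correction. At k = 2 the correction nulls the statistic (p = 1)
by construction. Ties in either ranking make tau undefined and raise.

The reference reports bias p-values over 51 studies of which 40 are
unprinted GWAS sub-studies, so those values cannot be recomputed at desk
scale; the tests are instead validated by calibration: type-I error within
[0.03, 0.08] (Egger) and [0.01, 0.08] (Begg, deliberately conservative) at
α = 0.05 over 1000 null simulations with k = 15, a shift of the mean Egger
intercept away from zero under simulated selection, and a rejection rate
under selection above the null rate. The power gain from p-and-direction
suppression is modest at k = 15: that mechanism shifts every surviving
study's standardized effect by the same constant regardless of precision,
and a pure intercept shift is what Egger's regression estimates least
precisely (it extrapolates to zero precision), a dilution worth knowing
about when interpreting a non-significant Egger test on real data.

## Synthetic data generator

Each simulated study draws a control minor-allele frequency q uniformly
from `maf_range`, sets control genotype probabilities to exact HWE
proportions, draws a per-study log-OR θᵢ ~ N(true_log_or, τ²) and tilts
the control probabilities by `exp(θᵢ·dose)` (dose 0/1/2 for allele-type
generation, indicator doses for dominant/recessive), then draws
multinomial counts per arm. Exponential tilting is the logistic disease
model under the rare-disease approximation and yields the target OR
exactly in expectation for the dose used. Defaults — k = 15 studies, q ∈
(0.05, 0.35), 200–2000 subjects per arm, τ² = 0, no selection — emulate
the shape of the bundled real table (mostly mid-size Asian and Caucasian
case-control series with minor-allele frequencies in that range).

Reproducibility: study i uses the dedicated substream
`default_rng([seed, i])`, so enlarging k extends a table without
reshuffling earlier studies. The selection rule suppresses, with given
probability, candidate studies whose crude allele-model p-value exceeds a
threshold and whose estimated effect points in a given direction
(small-study suppression); the generator then keeps drawing candidates on
successive substreams until k survive, mimicking a published literature of
fixed size, with a bounded attempt budget.

What the generator does not emulate: linkage disequilibrium between SNPs,
covariate confounding, gene–environment interaction, shared control arms,
and genotyping error. Passing calibration tests therefore demonstrates
correctness of the estimators under a clean logistic model, not robustness
to those real-data features.

## Numerical and testing choices

Simulation sizes in the suite (1000 null replicates for test calibration,
500 for effect and τ² recovery, k = 10–30, arms ≤ 2000) were chosen to
keep Monte-Carlo error well inside the asserted bands while the whole
suite runs in seconds. All simulations are seeded; hypothesis property
tests run derandomized. The inverse-variance pooling path is checked
against a brute-force weighted-mean oracle to 1e-10 relative error on 200
random estimate sets and cross-checked against R's metafor (`rma`,
method = "FE") on the bundled two-study pool; the HWE statistic against a
first-principles Pearson sum on 100 random count triples; Egger against
closed-form three-point OLS; Begg against hand-evaluated pair counts.
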