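# Methods

## Normalization and the ΔCT convention

Each sample's endogenous controls (default U6-2 and SNORD48) are summarized
by the arithmetic mean of their non-missing Ct values.  Ct is already a
log2-scale quantity, so averaging on the Ct scale equals a geometric mean of
the linear abundances; no stability weighting (geNorm-style) is applied. A
control undetermined in one sample drops out of that sample's mean with a
logged note; a sample with no usable control is an error rather than a
silent gap.

Relative expression is ΔCT = mean reference Ct − target Ct, so **larger ΔCT
means higher expression**.  The handedness matters: it makes the published
"highest expression" orderings descend in ΔCT and makes the within-pair
fold exactly 2^|ΔΔCt|.  No amplification-efficiency correction is applied;
exponentiation is base 2 throughout, per the comparative-Ct convention.
ΔCT is invariant to adding a constant to every Ct of a sample (controls and
targets alike), a property the suite checks; the reference level used when
inverting published ΔCT back to Ct (32 cycles) is therefore arbitrary.

## Detection and "not expressed"

A cell counts as undetected when its Ct is missing ("Undetermined", "NA" or
empty in input files) or above the detection limit, default 40 cycles — the
run length of the common real-time platforms; the study names no limit.  An
assay undetected in **every** sample is flagged not-expressed study-wide
(the study's miR-10b).  Flagged assays stay in the written outputs, carrying
a `not_expressed` bin and "NE" cells, but are excluded from bin counts,
group assignment and correlation.  This exclusion makes the published
counts internally consistent for the identical twins (19 printed low-list
entries including miR-10b at fold 1.00, 18 reported low); the fraternal
low count (10 printed including miR-10b, 10 reported) cannot be reconciled
the same way and is left as a documented discrepancy, not patched.

## Discordance bins and the A–D rule

Folds bin as low (< 2), moderate (2–10 inclusive) and high (> 10).  The
boundary values land in moderate because the published wording is strictly
"more than 10-fold" / "less than 2-fold".  The cross-zygosity rule is:

- **A** — fraternal high, identical low;
- **B** — both high, identical fold ≥ fraternal fold;
- **C** — both high, fraternal fold > identical fold;
- **D** — identical high, fraternal not high;
- **none** — anything else (moderate combinations), or either side
  not expressed.

A tie between two high folds goes to B: B is the "high in both" default
and C its "fraternal strictly larger" refinement.  Applied to the published
folds the rule reproduces 22 of the 23 published group labels; the
exception is miR-181d (fraternal 128.89, identical 1.33), which satisfies
the A definition verbatim but was published under C.  The rule is kept
faithful to the definitions and the disagreement is asserted explicitly in
the regression test.  The two group-D members miR-24 and miR-19b have no
printed fraternal fold — the published discordance tables list only the
high and low tails, so both are necessarily moderate there — and enter the
regression with a nominal mid-range fold (5.0) whose exact value the rule
never reads beyond its bin.

With several pairs per zygosity, per-pair folds pool by geometric mean
(equivalently the mean |ΔΔCt|) before grouping, because folds are
multiplicative; the published tables are treated as one composite pair per
zygosity.

## Co-twin correlation and heritability

Resemblance per zygosity is the Pearson correlation between the co-twins'
ΔCT vectors **across the miRNA panel**, with pairwise-complete deletion of
flagged assays, computed on the log2 (ΔCT) scale rather than on linearized
2^ΔCT values — the scale on which the expression values are tabulated.
Significance uses the exact t transform t = r√(n−2)/√(1−r²) on n−2 degrees
of freedom.  Several pairs of one zygosity pool on the Fisher z scale
weighted by n−3 (the approximate inverse variance of z); the pooled p then
refers z̄·√Σ(n−3) to a standard normal.  The original study reported one r
per zygosity from two pairs without stating its pooling; Fisher z is this
package's choice.

Falconer's estimate is H² = 2(r_MZ − r_DZ).  Both the raw value and a
[0, 1]-clamped value are reported; the environment share 1 − H² uses the
clamped value so the two shares always sum to one.  No likelihood-based
ACE/ADE structural-equation fit, intraclass-correlation variant, or
standard error on H² is provided beyond the Monte-Carlo evaluation in the
tests.

## The simulator

Per miRNA m and twin pair, true expression is

    ΔCT = μ + b_m + G + C + E

with b_m ~ N(0, σ_b²) a panel-wide per-assay baseline, G additive-genetic
with marginal SD σ_g and within-pair correlation ρ = 1 (MZ) or 0.5 (DZ)
(twin B's score is ρG + √(1−ρ²)G′ with G′ independent), C ~ N(0, σ_c²)
shared by the pair and E ~ N(0, σ_e²) unique per twin.  Emitted target
Ct = reference Ct − ΔCT; controls are emitted exactly at the reference
level; Cts beyond the detection limit become undetermined, and a configured
number of assays is forced past the limit in every sample to emulate an
absent target.  All randomness flows from one seeded `numpy` generator;
identical seeds give bit-identical studies.

Closed forms serve as oracles: across the panel,

    r(ρ) = (σ_b² + ρ·σ_g² + σ_c²) / σ_total²,    h² = σ_g² / σ_total²,

with σ_total² the sum of the four variances, so 2(r_MZ − r_DZ) = h²
exactly in expectation.

Two modelling points deserve emphasis.  First, the correlation is taken
across assays (one profile per twin), mirroring how small twin panels are
actually analyzed — not the conventional across-pairs design of large twin
registries.  Second, the between-assay variance σ_b² inflates **both**
zygosities' correlations and also sits in σ_total²: it cancels from the
difference r_MZ − r_DZ but not from the denominator, so the true h² itself
decreases as the panel's spread grows.  The parameter-recovery tests
therefore check that the estimator is unbiased for h² = σ_g²/σ_total² at
each σ_b level (bias < 0.05 over 20 seeds), not that the estimate is
numerically unchanged across σ_b levels — it provably is not.

### Defaults

| parameter | default | units | rationale |
|---|---|---|---|
| n_mirnas | 44 | assays | the published panel size |
| n_pairs_mz / n_pairs_dz | 2 / 2 | pairs | the published design |
| μ | 10 | log2 (ΔCT) | center of the published ΔCT range (≈ 5.8–17.0) |
| σ_b | 2 | log2 | spreads the panel over roughly that range |
| σ_g / σ_c / σ_e | 1.5 / 0.5 / 1.0 | log2 | within-pair noise of order the published low folds (< 2-fold ⇒ \|ΔΔCt\| < 1) with a genetic share large enough to separate zygosities |
| n_not_expressed | 1 | assays | one absent target, as in the study |
| reference Ct | 32 | cycles | typical small-RNA control level; arbitrary by shift invariance |
| detection limit | 40 | cycles | instrument run length |

The benchmark recovery configuration (σ_b², σ_g², σ_c², σ_e² = 1, 2, 0.5,
1.5 ⇒ h² = 0.4; 5000 assays; one pair per zygosity; 20 seeds) is sized so
the Monte-Carlo standard error of the mean estimate (≈ 0.006) is an order
below the ±0.05 assertion while the full suite plus recovery runs in a few
seconds on one CPU.

### What the simulator does not emulate

Per-cycle amplification noise and efficiency differences between assays,
technical-replicate structure (the study ran triplicates; the simulator
emits the consolidated Ct), dominance/epistatic genetic components,
chorionicity effects, and any correlation structure *between* miRNAs beyond
the shared baseline.  Passing recovery tests therefore show that the
computation chain is correct under the variance-component model, not that
real cord-blood panels satisfy that model.

## Numerical choices and degeneracies

- Folds are compared and pooled unrounded; file outputs round to 2
  decimals, matching the precision of the published tables.
- |r| = 1 returns p = 0 (the t statistic diverges); constant vectors raise
  an error naming the offending side rather than returning NaN.
- Falconer clamping is the only nonlinearity; h2_raw is preserved alongside
  so no information is lost.
- Zero total simulated variance yields h² = 0 by convention and an error
  for the (undefined) expected correlation.
- The group rule reads only bins plus, for the B/C refinement, the fold
  ordering; equal high folds are B.

## Known limitations

- Falconer's formula assumes equal shared environments across zygosities
  and no dominance; with two pairs per zygosity the published correlations
  carry large sampling error, and the 92%/8% split inherits it.  The
  package reports the arithmetic faithfully and leaves inference to the
  simulator-based analyses.
- The across-panel correlation conflates between-assay spread with twin
  resemblance (see above); σ_b² > 0 pushes both correlations up and the
  implied h² down.  This is a property of the published design, reproduced
  deliberately.
- The reported fraternal p-value (0.3433 at r = 0.15) is not exactly
  reproducible from a two-sided t-test at any plausible n near the panel
  size (≈ 0.33 at n = 44); the original n and test variant are unstated,
  so the package's p-values follow the exact t transform and no attempt is
  made to match that figure.
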