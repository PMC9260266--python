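# Methods

## Scoring model

MSAP scores one clear band per locus per digest as 1/0. The H digest
(EcoRI+HpaII) and M digest (EcoRI+MspI) differ only in the methylation
sensitivity of the CCGG cutter, so the (H, M) pair maps bijectively onto
four methylation patterns: (1,1)=I unmethylated, (1,0)=II hemi-methylated,
(0,1)=III internally fully methylated, (0,0)=IV hypermethylated. Pattern IV
is genuinely ambiguous in real gels (a dark locus may also be a restriction
site polymorphism); the level formulas therefore exclude it from their
denominators:

    total% = (II + III) / (I + II + III) × 100
    hemi%  =  II        / (I + II + III) × 100
    full%  =  III       / (I + II + III) × 100

`hemi% + full% = total%` holds identically; in floating point the package
guarantees it to 1e-9 and the test suite enforces it over random counts.
Percentages are carried at full precision internally and rounded to two
decimals only in reports. A group whose scored loci are all pattern IV has
an undefined level; `methylation_levels` raises an explicit error, while
the tabular report (`levels_table`) records NA for that group so one
degenerate group does not abort a multi-group run.

### Replicate consensus

Band-call noise is mitigated by collapsing replicates per (tissue, stage,
dose) cell before comparison. The default rule is strict majority per flag,
with ties resolved to 0 and a logged warning: a band call requires positive
evidence, so an evenly split call is treated as absent. `any` and `all`
rules are available for sensitivity analysis. Missing calls (`NA`) are
dropped before voting; an all-NA set stays NA, and loci with any NA in a
compared pair are excluded from transition counts and reported.

## Transition typing

The 16 (CK, treated) pattern pairs partition structurally by what the H
band does: lost ⇒ methylation gain (B1 = I→III, B2 = II→III, B3 = II→IV,
B4 = I→IV), gained ⇒ demethylation (C1 = III→I, C2 = III→II, C3 = IV→II,
C4 = IV→I), unchanged with M unchanged ⇒ UNCHANGED, unchanged with M moved
⇒ AMBIGUOUS (I↔II, III↔IV). The ambiguous pairs cannot be assigned a
direction by MSAP — a hypermethylated and an unmethylated site bracket the
same M-lane change — so they are tallied and reported but excluded from the
gain/loss totals. The test suite verifies the full mapping by exhaustive
enumeration against this structural rule.

The packaged dose-study fixture stores per-band-type site counts for six
comparisons (root/leaf × 15/50/100 μM against untreated control) together
with each type's defining H/M flags. An expander materializes one synthetic
locus per counted site, so the printed totals are always re-derived by
running the classifier end-to-end rather than read back from the table.
Only changed sites are tabulated in the source counts, so `n_loci_compared`
for those fixtures equals the number of changed sites; for user data the
report always includes the true number of compared loci.

## Supporting quantitation

**Relative expression (2^−ΔΔCt).** Per sample, ΔCt = Ct(target) −
Ct(reference); per group, ΔΔCt = mean ΔCt − mean ΔCt(control); fold =
2^−ΔΔCt. The group-mean formulation (rather than per-sample folds averaged
afterwards) is the standard Livak calculation and makes the control group
exactly 1. Any Ct shift applied uniformly to one gene across all samples
cancels in ΔΔCt; the tests check this invariance directly. No
amplification-efficiency correction is applied.

**5mC percentage.** Chromatography yields peak areas for cytosine and
5-methylcytosine; areas are converted to molar amounts with per-analyte
response factors (default 1.0, i.e. equal detector response at the
detection wavelength — override from calibration standards when available):
`5mC% = 100·(A_5mC/rf_5mC) / (A_5mC/rf_5mC + A_C/rf_C)`. This molar-fraction
convention is a documented package choice; peak integration itself is out
of scope.

**ANOVA + Duncan's multiple range test.** One-way ANOVA from sums of
squares; F tested against the F distribution. Duncan's test sorts means
descending and compares each pair spanning `p` consecutive means against
the critical range `R_p = q(1−α_p; p, df_error)·√(MS_error/n_h)`, with
Duncan's protection level `α_p = 1 − (1−α)^(p−1)` (studentized-range
quantiles from scipy). With unequal group sizes `n_h` is the harmonic mean
of the two compared groups' sizes; the balanced three-replicate design this
supports makes the choice moot there. The standard step-down protection is
applied: a range nested inside a non-significant wider range is itself
non-significant. Letters come from the insert-and-absorb compact-letter
algorithm, lettered from the largest mean, and satisfy the display
invariant (two groups share a letter iff not significantly different); the
tests compare the display against an independent brute-force
maximal-clique construction at ≤4 groups. `MS_error = 0` (all observations
identical within groups) is rejected as degenerate rather than reported as
infinite separation.

**Co-occurrence rates.** For a taxa × genes 0/1 matrix, a gene's rate is
100 × (taxa with presence)/(taxa), rounded half away from zero to one
decimal — the rounding convention required to render 22/72 as 30.6 and
28/72 as 38.9. The packaged survey covers 72 plant taxa × 5 iridoid-pathway
genes. One G10H presence (assigned to *Medicago truncatula*) reconciles an
internal inconsistency between the survey's tick marks and its printed
marginal rates; the printed rates were taken as authoritative, which leaves
that taxon's row sum at 4 rather than its block label 3.

## Synthetic data generator

The generator emulates the study design, not gel physics. Its defaults are
the package's reference conditions:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 500 | scorable MSAP loci, typical of a multi-primer plant study |
| `state_probs` | (0.45, 0.25, 0.15, 0.15) | control mix of U/HEMI/FULL/HYPER; hemi-methylation the commonest methylated state, total detectable methylation ≈47% |
| `doses` | 0, 15, 50, 100 μM | the study's 5-azaC arms |
| `kappa` | 0.007 /μM | demethylation rate constant; p(50 μM) ≈ 0.30, unsaturated at 100 μM |
| `gain_prob` | 0.01 | rare methylation gains, matching the small B-type counts |
| `call_error` | 0.02 | symmetric per-flag miscall probability |
| `n_replicates` | 3 | the study's replicate structure |

Mechanism: control states are drawn i.i.d. from `state_probs`; each dose
arm applies **one** demethylation step per locus with probability
`p(d) = 1 − exp(−κ·d)` (HYPER→HEMI or FULL with equal odds, FULL→U,
HEMI→U), and independently drawn gain events (probability `gain_prob`)
apply only where the demethylation event did not fire (U→HEMI or FULL with
equal odds, HEMI→HYPER). Demethylation takes precedence on HEMI loci where
both events could apply — this tie-break gives a closed-form one-step
kernel

    U:     [1−g,  g/2,        g/2,  0    ]
    HEMI:  [p,    (1−p)(1−g), 0,    (1−p)g]
    FULL:  [p,    0,          1−p,  0    ]
    HYPER: [0,    p/2,        p/2,  1−p  ]

used by the closure tests (simulate → score → transitions recovers the
kernel-implied transition-type proportions within multinomial bounds). The
one-step rule is the simplest mechanism that reproduces the observed IV→II
dominance among losses; it is not equilibrium methylation dynamics. Doses
are independent arms derived from the same control states, not a time
course, and replicates share an arm's true states, differing only in call
noise. All randomness flows from a single seed through numpy
`SeedSequence` spawning (separate streams for state draw, per-dose
treatment, per-dose noise), so outputs are bit-reproducible.

κ is recovered by inverting the dose response: among control loci not
already unmethylated, the fraction that changed state estimates `p`, and
`κ̂ = −ln(1−p̂)/d`. At 10,000 loci and one 50 μM arm this lands within 10%
of truth (seeded test).

**Monotonicity caveat.** With `gain_prob = 0` the expected total
methylation level is non-increasing in dose at the default state mix, and
the suite verifies this analytically and by simulation. It is *not* a
universal law: when the HYPER fraction dominates, one-step demethylation
moves invisible IV loci into detectable II/III, and the measured level can
rise with dose even as true methylation falls — the same detection artifact
that motivates excluding IV from the level denominators. The derivative of
the expected level in p at p=0 has the sign of `y·u − (h+f)·(u+h+f)` for
state fractions (u, h, f, y).

### What the generator does not emulate

No sequence-level CCGG simulation, fragment lengths, primer selectivity,
band-size co-migration artifacts, or correlated miscalls between H and M
lanes. Passing tests therefore show that scoring, consensus and transition
logic are correct under independent symmetric noise and i.i.d. loci — not
that real gels meet those assumptions.

## Problem sizes and numerical conventions

Simulation-based tests use 10,000–50,000 loci, sizes at which 3–4σ
multinomial/binomial bounds are tight enough to catch logic errors while
the full suite stays fast. Analysis drivers use 2,000 loci. Exact checks
(formula identities, round trips) use tolerances of 1e-9 or exact equality;
stochastic checks state their σ bounds in the test. Percent rounding: half
away from zero (reports), two decimals for levels, one for co-occurrence
rates. TSV cells are literal `0`/`1`/`NA`; `#` lines are comments
(provenance headers written by the CLI are re-readable by the package).

## Known limitations

- Ambiguous transitions (I↔II, III↔IV) are irrecoverable by design of the
  assay; totals here are lower bounds on methylation change.
- The level formulas condition on detectability, so level changes confound
  true methylation change with movement in and out of pattern IV.
- Duncan's test controls no familywise error rate in the modern sense; it
  is provided because it is the field's reporting convention, not as a
  recommendation.
- The 5mC% response-factor convention assumes calibrated or equal detector
  response; without calibration standards the default rf = 1 is an
  approximation.
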