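# Methods

## The problem

qPCR reports, per reaction, a quantification cycle Cq — the amplification
cycle at which fluorescence crosses a fixed threshold.  Low-abundance
targets (circulating microRNAs, viral nucleic acids in biofluids) often fail
to cross the threshold before the assay's quality cutoff C₁ (commonly 32 or
40 cycles); the instrument then reports "Undetermined".  Such reactions are
not missing at random: the true Cq is known to satisfy Cq ≥ C₁, i.e. the
observation is *right-censored* at a known point, exactly as administrative
censoring at the end of a survival study.

Common analysis strategies either discard this information (CO drops the
censored samples, CNA declines to analyze the target) or distort the data
(MC substitutes C₁ for the unknown Cq).  This package implements a
nonparametric alternative: treat "reaching the fluorescence threshold" as
the event of interest and compare the two groups' conditional
*cycle-to-threshold rates* λ(ΔY) — the hazard-rate analogue on the
normalized-cycle axis — with an exact weighted log-rank test.

## Normalization and censoring propagation

The analysis outcome is the normalized cycle ΔY = Cq(target) −
Cq(normalizer), with the event indicator φ = I(Cq < C₁) (strict: Cq = C₁ is
censored).  When φ = 0 the true ΔY is bounded below by C₁ − Cq(normalizer);
because normalizer Cq values differ by sample, censoring bounds are
observation-specific, and all downstream machinery works with per-sample
bounds rather than a single cutoff.  The normalizer itself must be well
observed (determined and < C₁); data violating this are rejected.  A sample
that simply has no record for the target is excluded with a warning —
missingness carries no bound and is not censoring.

## The test statistic

Order the distinct ΔY values among event observations ascending; call them
detection points d = 1…r.  At each d, with P_dk samples of group k still "at
risk" (event value or censoring bound ≥ d) and O_dk events at d, the
conditional null distribution of O_d1 given the margins is hypergeometric,
with

    E_d1 = O_d · P_d1 / P_d
    Var(O_d1) = O_d · (P_d1/P_d)(1 − P_d1/P_d)(P_d − O_d)/(P_d − 1)   (P_d > 1)

The weighted statistic is U = Σ_d w_d (O_d1 − E_d1) with variance
V = Σ_d w_d² Var(O_d1), and Z = U/√V.  Weights are the Fleming–Harrington
family w_d = Ŝ(d−)^p (1 − Ŝ(d−))^q built from the pooled Kaplan–Meier left
limit (0⁰ = 1); p = q = 0 gives the log-rank test, p > 0 emphasizes early
detection points, q > 0 late ones.  U > 0 means group 1 reaches the
threshold in excess of expectation: a higher cycle-to-threshold rate, lower
ΔCq, higher target level.  One-sided alternatives are named for the group-1
rate (`rate1_greater`, `rate1_less`) to avoid sign confusion.

## Exact inference

Small group sizes (n = 5 per group is typical of preclinical designs) make
the normal approximation unreliable, so the default p-value is exact: U is
rewritten as a sum of per-observation scores

    c_i = φ_i·w(y_i) − Σ_{d ≤ y_i} w_d·O_d/P_d

(the classic censored-data log-rank scores when w ≡ 1), which makes U
linear in the group labels; the permutation distribution is then the set of
subset sums over all C(n, n₁) relabelings.  The score identity
Σ_{i∈group 1} c_i = U is enforced by tests against an oracle that rebuilds
the risk table per labeling.  Two-sided extremeness is absolute deviation
of the statistic from its permutation mean (|T − μ| ≥ |T_obs − μ|), the
standard exact-conditional convention, which keeps p ≤ 1 structurally; the
observed labeling is always counted, so p > 0.  Floating-point ties are
counted as ties using an absolute tolerance of 1e-12·n·max|c_i|.

Modes: `exact` enumerates when C(n, n₁) ≤ 200,000 (the default `auto`
threshold); `montecarlo` uses (1 + #extreme)/(B + 1) over B random
relabelings; `asymptotic` uses the normal approximation.  Degenerate data —
no detection points at all, or V = 0 — return p = 1 with a flag instead of
raising, so simulation harnesses count them as non-rejections.

Because the test uses only ranks and the censoring pattern, any strictly
increasing transform applied consistently to values and bounds leaves the
p-value unchanged; this is tested.

## Comparators and summaries

MC, CO and CNA are implemented exactly as used in practice, each followed
by a two-independent-groups t-test; BFD (benchmark full data) runs the same
t-test on the uncensored simulation truth.  The default t-test is Welch
(unequal variances); the pooled-variance form is available via
`var_equal=True` and every study report records which was used.  Degenerate
comparator outcomes (CO leaving < 2 observations in a group, zero-variance
data) are recorded as non-rejections with a reason, never raised.  On
censoring-free data all four strategies coincide exactly.

Interpretable summaries mirror time-to-event reporting: per-group
proportion of uncertain quantifications, per-group Kaplan–Meier median ΔY
(smallest detection point with Ŝ ≤ 0.5; "not reached" when censoring
prevents Ŝ from getting there — no extrapolation), and the
cycle-to-threshold rate ratio.  No estimator for the ratio is standard in
this setting; we use the O/E ratio (O₁/E₁)/(O₂/E₂) from the pooled
unit-weight risk table — closed-form, no proportionality fitting, stable at
n = 5 — and label it as such.  It is undefined when a group has no events.

## The simulator

ΔCq is drawn on the cycle (log) scale with location β₀ + x·β₁ (x = 0/1 the
group indicator) and scale σ, from one of three families chosen so that
e^ΔCq follows the named distribution:

| family      | ΔCq distribution                | e^ΔCq          |
|-------------|---------------------------------|----------------|
| lognormal   | Normal(m, σ)                    | log-normal     |
| weibull     | m + σ·G, G min-Gumbel           | Weibull, shape 1/σ |
| loglogistic | Logistic(m, σ)                  | log-logistic, γ = σ |

so σ is uniformly the cycle-scale dispersion across families.  Each
sample's normalizer Cq is Normal(25, 0.45) (0.45 is a standard deviation);
the reported Cq is ΔCq + normalizer, and a reaction is "Undetermined" iff
Cq ≥ C₁.  The uncensored ΔCq truth is retained on the replicate object so
the BFD benchmark never re-derives it.

Default study conditions: n = 5 per group, C₁ = 40, α = 0.05.  Power
scenarios draw β₀ ~ N(10, 2.24) and β₁ ~ N(1, 4.47) independently, 100
scenarios per family (300 in total), 1,000 replicates each at full scale;
σ alternates 1, 2, 1, 2 … across scenario index (the split between σ values
is a design choice; `all1`, `all2` and `random` schemes are available).
Type-I studies use the four null parameter sets β₁ = 0, β₀ ∈ {5, 10},
σ ∈ {1, 2} (log-normal), 10,000 replicates each.

What the simulator does *not* emulate: pre-PCR errors (hemolysis, RNA
extraction variability), amplification-efficiency differences, technical
replicates, or plate effects.  Passing tests therefore demonstrate the
statistical behaviour of the methods under clean limit-of-detection
censoring, not robustness to assay artefacts.

## Study harness and accounting

Power studies pool decisions over scenarios × replicates and restrict to
replicates with at least one uncertain observation — the subset where the
strategies actually differ.  Since drawn β₁ ≠ 0 almost surely, a "correct
decision" is a two-sided rejection at α regardless of direction.  CO/CNA
degeneracies count as non-rejections in power (and as non-errors in type-I
accounting) with separate tallies; the accounting identity rejections +
non-rejections + degenerates + not-analyzed = n_rep holds per method.
Reports carry the Wald Monte-Carlo interval p̂ ± 1.96√(p̂(1−p̂)/n), truncated
to [0, 1] — the form conventionally printed alongside simulation rejection
rates; no continuity or exact (Clopper–Pearson) correction is applied to
the default output.

Replicate streams derive from a master seed and a (scenario, replicate)
counter via `numpy.random.SeedSequence` spawn keys: any scenario subset can
be re-run independently, and a report is bit-identical given its config.

The two-sample t-test power utility uses the noncentral t distribution with
df = 2n − 2 and noncentrality |μ₁ − μ₂|√(n/2)/σ, cross-checked against a
simulation oracle in tests.

## Numerical and design notes

* Problem sizes in the shipped tests: the type-I acceptance check runs the
  full design (4 × 10,000 replicates, ~2 minutes); the power-ordering check
  runs 10 scenarios × 200 replicates per family, enough to resolve the
  >20-percentage-point CTOT–CO gap but not the ~1-point CTOT–MC gap, which
  is left to full-scale runs.
* Exact reproduction of published *power* tables is not expected even at
  full scale: scenario parameters are random draws, so only orderings and
  magnitudes are comparable.  Type-I rates and all closed-form arithmetic
  reproduce directly.
* Censored observations tied with an event value remain in the risk set at
  that value (events precede censorings), the standard survival convention.
* The boundary Cq = C₁ is censored (φ = I(Cq < C₁) is strict).
* Worked-example fixtures (`ctot fixtures`) use illustrative (β₀, β₁) pairs
  with fixed seeds; they are synthetic and do not correspond to any
  published dataset's draws.

## Known limitations

* Two groups only; no stratification, trend tests or regression modelling.
* Relative quantification only — no standard-curve absolute quantification,
  no amplification-efficiency correction, single normalizer (no
  geometric-mean multi-reference normalization).
* The exact test is conservative at very small n because the permutation
  distribution is discrete; attainable p-values at n = 5 + 5 are multiples
  of 1/252, so the realized level at α = 0.05 is ≈ 0.048.
* The O/E rate-ratio estimate has no accompanying confidence interval.
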