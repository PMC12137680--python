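# Methods

## Forward model

The ninhydrin assay reports amine-group equivalents (µg/mL). A composition
holds the free amino-acid pool `A` (counted with exactly one amine group
each — the assumption under which the balance equations close, even though
the counting utilities also expose the raw convention in which a free
glutamine reads as 2), dipeptide classes `x1..x3` and tripeptide classes
`y1..y4`, indexed by intact amine-group count. Before hydrolysis each class
contributes its index; hydrolysis adds one amine group per peptide bond, so

    F = A + Σ i·xi + Σ i·yi,        T = F + x + 2y.

The supremum of T/F over all such compositions is 3, attained only by the
single-amine tripeptide class `y1` (verified by brute-force scan in the
tests and the acceptance script). The two-amine residue set defaults to
{Q, R, K, N, H, W} — 6/20 = 30 % of the alphabet, the standard side-chain
amine carriers — and is configurable; only the *fraction* 0.3 enters the
estimator, through the α, β bounds.

## The feasible set and its uniform average

A reading pair fixes only W = T/F. Under the structural conventions
`x1 = (1−α)x, x2 = x3` and `y1 = (1−β)y, y2 = y3 = y4`, the consistent
compositions form the set

    S(W) = {(α, β, A) : α, β ∈ [0, 0.3],
            max(1 − (1+1.5α)(W−1), 0) ≤ A ≤ 1 − (1+2β)(W−1)/2},

with `x, y ≥ 0` recovered linearly from `(α, β, A, W)`. The estimator is
the expectation of the before/after share triples under the **uniform
distribution on S(W)** — the most conservative choice when nothing beyond W
is known. Both triples sum to 1 pointwise by construction, so conservation
is exact for any averaging scheme, and `E[x] + 2E[y] = W − 1` holds because
`x + 2y = W − 1` pointwise.

Note the A-interval length varies with (α, β): uniformity on the 3-D set
implies the (α, β) marginal is proportional to that length, so quadrature
cells must be weighted by `max(A_hi − A_lo, 0)`. An unweighted (α, β)
average would target a different (box-uniform) prior.

### Integration

* **Quadrature (default).** Midpoint rule on a 400×400 (α, β) grid. Every
  share is affine in A at fixed (α, β), so the inner uniform average over
  [A_lo, A_hi] is the value at the interval midpoint — the inner integral
  is closed-form, not discretised. Shares converge to ~1e−5 already at
  resolution 100; pipeline-heavy experiments therefore use resolutions of
  150–200 where noted, far below any tolerance asserted. Near W → 3 the
  feasible β-range shrinks like (3 − W); the β grid is restricted to that
  range (the discarded region has zero weight, leaving the measure
  unchanged) so the quadrature stays resolved arbitrarily close to the
  ceiling.
* **Monte Carlo.** Rejection sampling: uniform proposals on
  [0, 0.3]² × [0, 1], accepted iff A falls inside its interval. Requires an
  explicit seed. It is the independent oracle for the quadrature: at 1e6
  proposals the two agree within 5e−4 on every share (asserted at 0.005).
* **Endpoints.** At W = 1 and W = 3 the set has zero 3-D measure (the
  A-interval collapses everywhere), so both integrators degenerate; the
  exact limit structures (1,0,0) and (0,0,1) are returned analytically.

## W policy

W < 1 can only arise from assay noise and is clamped to 1 with a warning
flag; W > 3 is clamped to 3 with a "possible longer peptides" flag — the
model deliberately excludes peptides beyond tripeptides, and a persistent
W > 3 is evidence of them, worth surfacing rather than crashing on. Flags
propagate through every pipeline table; either side can be switched to a
hard error.

## AUC pipeline

Baseline = mean of the pre-meal samples (−60 and −1 min in the canonical
schedule); post-meal F and T have it subtracted, negatives floored at 0 and
flagged (components must stay non-negative to sum to AUC_T). Integration is
the trapezoid rule over the collected post-meal window (5–120 min), with no
extrapolation to t = 0. The default **pointwise** mode splits the adjusted
T at every time by the after-hydrolysis mean shares at that point's W and
integrates each component curve — additivity `AUC_T = AUC_F + AUC_DD +
AUC_TD` is then exact because the split is convex at every point. A point
whose adjusted F is 0 has no defined W and is dropped from all four curves
with a flag. The **aggregate** mode instead forms one ratio from the
integrated curves, `W = AUC_T/AUC_F`, and applies a single split; the two
modes coincide exactly when W is constant in time, and aggregate serves as
a sensitivity check. Group summaries report mean ± SD per component (SD = 0
with a flag for n = 1); hypothesis testing is out of scope.

## Synthetic meal tests

Each pool follows `baseline + amplitude·(t/τ)·exp(1 − t/τ)` for t > 0 — a
gamma-type rise-and-fall that peaks at `amplitude` at `t = τ`. This is a
phenomenological absorption curve (the kernel is a modelling choice, not a
mechanism); it reproduces the features the estimator cares about — smooth
single-peaked responses, baselines that cancel on adjustment, a
time-varying W — but none of the physiology (transporter saturation,
recirculation, inter-subject kinetic variability). Defaults: free pool
baseline 100 µg/mL (fasting plasma is dominated by free amino acids) with
amplitude 25 and τ = 25 min; dipeptide 12/45/40; tripeptide 8/70/50 —
a postprandial influx dominated by peptide-bound amino acids, the regime
the assay was designed to resolve, giving adjusted W ≈ 1.9–2.3 over the
sampling schedule (−60, −1, 5, 15, 30, 45, 60, 120 min, the canonical
design). `α_true = β_true = 0.15`, the centre of the admissible range.
Noise is independent multiplicative lognormal per reading, parameterised to
unit mean at the requested CV; the default CV = 0.1 is a plausible
colorimetric-assay figure, not a measured one. All randomness flows from a
mandatory scenario seed.

## Recovery metrics, and what passing shows

`run_recovery` compares per-subject estimated after-hydrolysis AUC shares
with the generative truth (the noise-free baseline-adjusted component
curves, integrated). Two facts shape the metrics:

1. **Intrinsic spread.** The uniform average is an interval summary — a
   single W identifies a set, and the truth is one point of it — so even
   noise-free recovery has a bounded systematic offset. On a scenario
   sweeping W ≈ 1.3–2.5 with α = β = 0.15 the measured per-component bias
   stays within 0.12 (cross-checked against the Monte-Carlo oracle's
   pointwise prediction). Note the full nominal W-range cannot be swept at
   β = 0.15: the ceiling there is W = 3.3/1.3 ≈ 2.54 (pure tripeptide).
2. **Noise-induced offset.** Multiplicative noise pushed through the
   nonlinear map W ↦ shares leaves a small bias common to all subjects that
   no cohort size removes. `rmse_vs_cohort_size` therefore measures the
   dispersion of the cohort-mean estimate about its expectation (grand
   replicate mean), which isolates the 1/√n sampling component; accuracy
   against the truth is reported separately by `run_recovery`. References
   "noise_free" and "truth" are available to expose the offset floors.

Passing these tests shows the pipeline is self-consistent and recovers
known compositions to within the estimator's documented spread under the
simulated conditions; it does not validate the structural conventions
(`x2 = x3`, equal-probability prior) against real plasma, which would
require chromatographic ground truth.

## Numerical conventions

Feasible-set membership uses a 1e−12 absolute slack, with x, y clipped to
0; share conservation is asserted at 1e−9. `solve_xy` refuses points
outside the set, naming the violated bound. Degenerate inputs: empty or
constant series yield zero AUCs; duplicate time points and missing pre-meal
samples are errors. A legacy heuristic (`F/W` as the free-amino-acid
equivalent) is retained under an explicit name for comparison; it is not
consistent with the feasible-set machinery and no pipeline uses it.
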