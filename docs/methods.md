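# Methods

## Scope and data model

All analysis operates on voxel volumes sharing one `GridGeometry` (shape,
spacing in mm, origin in mm). Geometries must agree **exactly** for any
two volumes entering a computation; there is no implicit resampling, since
silent interpolation would corrupt overlap statistics (Dice, kappa). An
explicit nearest-neighbor `resample_nearest` is provided for callers that
must bring mismatched inputs onto a common grid, and is never invoked
internally. For file round-trips, spacing and origin are compared with a
1e-6 mm tolerance to absorb floating-point NIfTI headers. Masks serialize
as unsigned 8-bit 0/1, doses as 32-bit float Gy.

## Isodose contours

`contour_90%iso` is the set of voxels with dose ≥ 0.9 × prescription. The
threshold is inclusive: a voxel exactly at 90% belongs to the contour,
which keeps the uniform-dose edge case non-degenerate. All voxels above
threshold are retained; no connected-component cleaning is applied, since
whether disconnected isodose islands should be discarded is a reporting
choice, not a property of the dose distribution.

## EQD2 conversion

Institutions prescribe different schedules (50/25, 50.4/28, 43.2/16, …),
so organ-at-risk doses are converted to the equivalent dose in 2 Gy
fractions under the linear-quadratic model: per voxel,
`EQD2 = D (d + α/β) / (2 + α/β)` with `d = D / n_fractions` and
α/β = 3 Gy for late-responding normal tissue. The conversion is applied
**per voxel** using the plan's single fraction count. This makes V_x
thresholds well defined in EQD2 space; converting summary metrics instead
would leave V_x ambiguous. Conversion at d = 2 Gy is the identity for any
α/β, which the tests exploit as an exact invariant.

Relative nodal dose is computed on *physical* dose over the physical
prescription by default: it is a plain ratio of same-schedule quantities,
and an EQD2 ratio would mix two different nonlinear transforms of
numerator and denominator. Both choices are switchable in `RunConfig` and
recorded in every report.

## STAPLE consensus

Binary STAPLE treats the unknown reference segmentation as a latent
voxelwise indicator and each institution as a noisy channel with
sensitivity p_j and specificity q_j, estimated jointly with the truth
probabilities by EM (E-step posterior weights, M-step performance
re-estimation; spatially uniform foreground prior; no Markov-field
regularization). Numerical choices:

- probabilities (p_j, q_j, prior) clamped to [1e-6, 1−1e-6] to avoid
  degenerate log-likelihoods at finite sample size;
- initialization p_j = q_j = 0.9999, prior = mean rater foreground
  fraction inside the domain;
- convergence when max |Δp_j|, |Δq_j| < 1e-6, cap 200 iterations; the
  observed-data log-likelihood trace is retained and must be
  non-decreasing (an EM guarantee used as a runtime check in tests);
- consensus is W ≥ 0.5, ties toward foreground, false outside the domain;
- a rater set that is unanimously empty or unanimously full inside the
  domain yields the unanimous answer with clamped performances and a
  `degenerate` flag rather than an exception.

The EM runs on an explicit **analysis domain**: the union of the rater
masks dilated by 2 voxels of 6-connectivity (configurable). Including the
entire grid would let millions of unanimous background voxels pin the
prior and specificities to degenerate values while changing nothing inside
the region of interest. The same domain policy is used for Fleiss's kappa
and is stated in every report, because agreement values are only
comparable between studies if the domain convention matches — a whole-grid
domain inflates kappa via unanimous background.

## Agreement statistics

Fleiss's kappa treats domain voxels as subjects and the two categories
in-contour/out-of-contour: with n raters and n_i1 positive votes at voxel
i, `P_i = [Σ_c n_ic² − n]/[n(n−1)]`, `P̄` its mean, `P̄_e = Σ_c p_c²` from
the marginal category proportions, and `κ = (P̄ − P̄_e)/(1 − P̄_e)`. If every
rater is unanimous in one category everywhere, the formula is 0/0;
agreement is then perfect and κ is reported as 1.0 with a degeneracy flag.
Dice of two empty masks is likewise an error rather than a silent 0 or 1 —
the limit is ambiguous and the caller must decide.

## Dosimetry

Voxels are equal-volume (no partial-volume weighting; masks are already
voxelized). `V_x` uses strict "more than x Gy"; an inclusive variant
exists. Cumulative DVHs are tabulated on 0.1 Gy bins from 0 to the maximum
structure dose plus one bin; `V_x` and the DVH agree within one bin width
by construction, which the tests verify against a direct counting oracle.

## Paired statistics

The Wilcoxon signed-rank statistic W is the sum of ranks of positive
differences. Zero differences are dropped (the original convention; a
Pratt variant is available and reported as approximate). With tie-free
differences and n ≤ 25 the two-sided p-value is exact:
`p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))` under the uniform distribution on
all 2^n sign assignments, computed by dynamic programming over the integer
ranks (identical to enumeration, exact in float64 for n ≤ 25). Midranks
plus a tie-corrected, continuity-corrected normal approximation are used
otherwise, and the result records which route was taken. The IMN subgroup
contrast (6 vs 18 institutions within the WBI+RNI arm) is an unpaired
comparison, so it uses a two-sided rank-sum (Mann–Whitney) test; a
signed-rank pairing does not exist across disjoint institutions. No
multiple-testing correction is applied; p-values are reported per station
and metric as raw values.

## Synthetic cohort generator

The generator emulates the *conditions* of a 24-institution dummy run, not
treatment-planning physics. Clinical plans come from beam-transport
optimization systems that are out of scope; the downstream analysis only
needs dose fields with realistic gradients, junction behaviour, and
inter-institution variability, plus known ground truth.

**Anatomy.** Each case is a set of non-overlapping ellipsoidal structures
on a 96³ grid at 2.5 mm (240 mm cube): a lateralized hemi-ellipsoid breast,
the ALN I→II→III chain ascending to SCN, a parasternal IMN capsule, the
ipsilateral lung, and a heart placed left of midline and *not* mirrored —
so the left-sided Case S heart sits nearer the breast, reproducing the
clinically higher cardiac exposure of left-sided irradiation. Structures
are carved in a fixed order so all pairwise intersections are empty, with
seeded ±1.5 mm centroid jitter; construction fails loudly if a structure
would leave the grid.

**Dose model.** `dose = Rx · max(field, scatter) · noise`, with
`field = σ((margin − s)/w)` a sigmoid of the signed Euclidean distance s
to the target volume (negative inside), i.e. a penumbra of scale w around
a field edge `margin` millimetres outside the target. Defaults, chosen to
be clinically plausible rather than fitted: margin 12.5 ± 4 mm across
institutions (floor 5 mm) — the distance from target to the ~50% dose
point; penumbra w = 4 mm, a typical 6 MV beam-edge gradient; scatter floor
3% of Rx at the field edge decaying over 40 mm; multiplicative Gaussian
voxel noise, σ = 2%. For WBI+RNI the breast field gains 5 mm (wider "high"
tangents), a separate nodal field covers ALN I–III + SCN, the IMN-including
institutions add a deeper medial field (margin + 7.5 mm around the IMN
chain), and a junction term `bump · min(f_breast, f_nodal)` with bump
drawn uniformly in [0.05, 0.15] models the overdose where the tangential
and nodal fields meet — three-field junctions routinely overdose, which is
what drives relative nodal doses above 1.0 in the RNI arm. Enlarging the
margin is monotone: it can only increase dose everywhere, a property the
tests check on paired seeds.

**Raters.** Alongside each plan's true 90% isodose mask, a "rater" version
is produced by voxelwise corruption with configured sensitivity 0.95 and
specificity 0.98, giving the agreement and consensus modules fixtures with
known generative parameters.

**Reproducibility.** One master seed drives a `SeedSequence` tree covering
scheme assignment, the IMN-including subset, margins, junction bumps,
phantom jitter, plan noise and rater corruption; two runs from one seed are
bit-identical, through to byte-identical CSV reports.

**What the generator does not emulate — and what passing therefore does
not show.** There is no beam transport, no CT anatomy, no heterogeneity
correction, and the "institutional variability" is a scalar margin plus
noise rather than genuinely different field designs. Synthetic agreement
is consequently tighter and smoother than clinical (kappa ≈ 0.62–0.64 and
DSC ≈ 0.87 here, against ≈ 0.68–0.78 and 0.77–0.83 in clinical dummy-run
cohorts), and absolute lung volumes receiving low doses are smaller than
with real tangential beams that traverse lung. Conclusions supported by
the pipeline on this cohort are therefore *directional and structural*
(arm orderings, subgroup contrasts, statistic calibration), not absolute
dosimetric levels.

## Problem sizes used in validation

The test suite and the acceptance script exercise: the full default cohort
(24 institutions × 2 cases × 2 arms on 96³), STAPLE parameter recovery
with 24 simulated raters on 64³ domains over 10 seeds, a 2000-replicate
null calibration of the exact signed-rank test at n = 24 pairs, and
enumeration oracles at n ≤ 12. Structural and round-trip tests run on
reduced cohorts (8 institutions, 48³ at 5 mm) — the statistics are
size-invariant, so the smaller grids test the same code paths.

## Known limitations

- Single-label consensus only; no multi-label STAPLE or spatially varying
  prior.
- Kappa/DSC absolute values depend on the declared domain policy; they are
  not directly comparable to reports that used a different (or
  unstated) domain convention.
- No Hausdorff/surface distance, no kappa confidence intervals, no
  NTCP/TCP modeling, no DICOM-RT I/O (everything is NIfTI voxel data).
- The Pratt zero-handling route always uses the normal approximation; an
  exact Pratt null is not implemented.
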