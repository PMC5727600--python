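# Methods

This note records the model behind each component, the conventions and
defaults, and what the synthetic validation does and does not establish.

## Sampling model

The package implements a two-stage fractionator. Sections of nominal
thickness `t` are numbered 0-based in cutting order; section `i` owns the
half-open slab `z ∈ [i·t, (i+1)·t)`, so a boundary point belongs to
exactly one section. Systematic uniform random sampling draws a start
uniformly from `{0, …, k−1}` and takes every k-th section; the same
scheme in continuous form places the frame grid with offsets uniform in
`[0, step)` on each axis. All randomness flows through explicit
`numpy.random.Generator` objects (a study seed spawns per-stage
substreams); there is no global random state, so every sampling decision
is reproducible from the recorded seed.

A disector pair is two adjacent sampled sections mounted together
(reference = sampled index, lookup = sampled index + 1 in cutting order),
so the pair separation `h` equals `t`. Counting is bidirectional — the
two sections swap roles and the fractionator product is divided by two.

Defaults follow the design the package is dimensioned for: `k = 50`,
`a(frame) = 60,000 µm²`, steps `387.29 µm` (so `1/asf = 2.4999 ≈ 2.50`),
`t = 5 µm`. Under these conditions the default phantom (below) yields
10–15 section pairs and ~150–200 counting events per study, the workload
this class of design targets.

## Counting frame convention

The unbiased counting frame is a rectangle whose top and right edges are
inclusion lines and whose exclusion boundary is the classic polyline: an
infinite upward extension from the top-left corner, the left edge, the
bottom edge, and an infinite downward extension from the bottom-right
corner. A profile is sampled iff it intersects the closed frame and does
not touch the exclusion polyline. "Touching" means nonempty intersection
in continuous geometry; in raster mode, any 8-connected overlap with an
edge pixel. For convex profiles this rule counts each profile in exactly
one frame of a complete tiling (verified exhaustively in the tests by
brute force over random discs, including discs much larger than a
frame). The orientation of the inclusion/exclusion edges is a convention
flag, not a free parameter: published figures of such frames are often
reproduced too coarsely to fix the orientation, and any consistent
orientation yields the same statistics.

Infinite extensions are represented with a 10^7 µm surrogate in the
polygon (shapely) path; the disc path is fully analytic. Profiles are
attributed to the first frame that samples them; with frames no larger
than the grid cell (enforced by the design invariant
`a(frame) ≤ step_x · step_y`) double attribution cannot arise.

## Disector matching

Profiles are matched across a pair by particle identity when available
(simulation) and otherwise by greedy nearest-centroid matching after
alignment, accepting pairs in increasing distance within a tolerance
`r_match` (default: the mean profile radius, i.e. half the mean
diameter), ties broken by smallest distance then lowest index. The greedy
rule is deterministic and auditable; it is not a globally optimal
assignment, which is acceptable because real pairs are sparse at the
scale of `r_match`.

## Estimators and display rounding

`N = (1/ssf)(1/asf)ΣQ⁻ / 2` and `V = ΣP · step_x · step_y · t · (1/ssf)`.
All arithmetic keeps full precision; display rounding (N to the nearest
integer, half away from zero; V and CE to two decimals) is applied only
at the reporting boundary. When reproducing printed worked examples the
printed, two-decimal `1/asf` must be supplied explicitly (`inv_asf`
override in `RunConfig`/`estimate_from_table`), because published tables
are computed from the rounded fraction; pipeline computations otherwise
use the unrounded value.

One published volume row (ΣP = 190 at t = 5 µm) prints 7.13 mm³ where
the formula gives 7.12; the difference is consistent with a
block-specific caliper thickness near 5.004 µm rather than the nominal
5 µm, which cannot be resolved from the published numbers. The
`thickness` override exists for exactly this purpose; the reproduction
suite pins the two rows that are exact at the nominal thickness.

Mean section thickness is `(height_before − height_after)/sections_cut`
from the two caliper measurements; the weight-based shrinkage index is
`(formalin − paraffin)/formalin` (a plain fractional loss — the exact
normalization is a package choice, flagged, since conventions differ).

Percent reduction in paired (ipsi/contra) designs is reported under two
labelled conventions: the mean of per-animal ratios (default headline,
matching the paired design) and the ratio of group means.

## Precision prediction

`Var_SURS = (3(A − noise) − 4B + C)/240` with `noise = ΣQ⁻` for number
estimates; the B and C sums simply have fewer terms near the end of the
series. The smoothness constant 240 is a design-level default stored on
`SamplingDesign`, not hard-coded, because it is tied to the smoothness
class of the sampled quantity. Negative raw values — which occur
legitimately for short or flat series — are clamped to zero with a
warning, and both raw and clamped values are retained in results and
reports. `CE = sqrt(noise + Var_SURS)/ΣQ⁻`; the group mean CE is the
root mean square (the CEs add in variance, not in value — the typeset
form of this formula in the source literature is ambiguous, and the RMS
reading is the one consistent with the variance decomposition). The
volume estimator carries no CE: its noise term requires a different
point-counting variance model that is deliberately out of scope, so
volume precision is only assessed against the non-infused side.

`CV_obs² = CV_biol² + CE²` with `CV_biol` floored at zero (flagged when
the mean CE exceeds the observed CV); the acceptability flag tests
`CE²/CV_obs² < 0.5`.

## Alignment

Section pairs are registered by maximizing normalized cross-correlation
under a rigid transform, searched coarse-to-fine (downscale 4, 2, 1;
rotation grids 1°, 0.25°, 0.1° refined around the running best).
Translation at each candidate rotation uses masked phase correlation
(Padfield's masked NCC), with the mask excluding pixels that the
candidate rotation brought in from outside the frame and exact-zero
background; this is what makes the search robust to the empty borders
that rotation and mounting displacement produce. Candidates are scored
by NCC over the valid overlap only. Defaults: translation range ±25% of
the image size, rotation ±10°, confidence threshold NCC ≥ 0.5 — below
threshold the transform is flagged and the pipeline demands a manual
override (`apply_manual_override`, which logs the operator and
parameters) instead of proceeding silently.

Transform convention: `p' = R(θ)(p − c) + c + d`, with image coordinates
`(x, y) = (col, row)` and positive θ counter-clockwise as displayed;
`warp` applies exactly the point transform about the image centre, so
point-space and image-space uses cannot drift apart. Over 100 seeded
synthetic pairs with shifts uniform in ±50 px and rotations ±5°, the
search recovers the truth within 2 px and 1° in 100% of cases (worst
observed error ≈ 0.8 px, 0.3°).

## Phantoms and virtual sectioning

The default phantom places spheres with radii uniform in 5–10 µm (nigral
soma scale) uniformly in a 2.0 × 1.2 × 3.0 mm box (7.2 mm³ — the scale
of a rat SNc-containing sampling volume), with a 2 µm surface gap
enforced by rejection so raster profiles cannot merge. Sectioning is
along the 3 mm axis, giving ~600 sections and, at k = 50, the designed
10–15 pairs.

Virtual sectioning assigns a sphere a disc profile in every slab its
z-extent touches; the profile radius is the cross-section at the slab
midplane, clipped at 0.25 µm (midplane rather than the union over the
slab: simpler, and irrelevant for number estimation since the disector
counts presence, not size). Each sphere has exactly one top slab, so the
physical disector with identity matching counts tops, and the stack is
padded with one empty slab at each end so the census design
(`ssf = asf = 1`) recovers the true N exactly rather than losing tops in
the terminal slab. Point counting uses one test point per grid position,
counted when inside the ROI cross-section of the reference section.

The in-silico study uses an unbounded frame lattice (every frame a
profile can reach exists): all phantom particles are the population of
interest, so no ROI delineation step is simulated. What the phantom does
not emulate: staining variability, segmentation error, section
deformation, lost or folded sections, and non-spherical somata. Passing
Monte Carlo validation therefore establishes that the *sampling and
estimation* chain is unbiased, not that a particular staining/imaging
pipeline is.

Validation conditions (kept deliberately desk-sized): unbiasedness uses
one 10,000-particle phantom and 200 replicate sampling realizations
(mean within 2 Monte Carlo SE of truth for both N and V); the census
check uses 500 particles in a 0.4 mm box with a 40 µm grid so the point
count resolves the volume to well under 1%.

## Lesion cohorts

`generate_lesion_cohort` emulates a unilateral-lesion study: intact-side
numbers lognormal around 10,000 (motivated by reported contralateral
means near 10,000) with between-animal CV 0.26 (back-computed from the
reported SEM at n = 26); fractional ipsilateral loss normal around the
effect size (default 0.55; 0.85 for the severe design) with SD 0.12;
multiplicative sampling noise with CV 0.08 on the estimated numbers
(the design's own CE). Amphetamine rotations scale linearly with the
fractional loss with lognormal noise (CV 0.25); apomorphine rotations
engage only above 50% loss, mirroring their insensitivity to restricted
lesions. The loss-linked noise levels were set so the simulated
count-rotation rank correlation has the strength reported for the real
cohort (r ≈ −0.6 at n = 26); with these defaults the correlation is
negative in ≥95% of seeded replicates, which is the property the tests
assert — per-animal rotation counts are otherwise arbitrary units.

## Known limitations

* Only coronal (axis-aligned) sectioning planes; no smooth-fractionator
  sorting, no optical disector or guard zones.
* The rank-correlation permutation test enumerates exactly up to n = 8
  and falls back to seeded Monte Carlo above; p-values at large n carry
  Monte Carlo error of order `1/sqrt(n_permutations)`.
* Raster (label-mask) counting reduces objects to equivalent-area discs
  at their centroids; highly anisometric profiles near frame edges may
  be classified differently than their full outlines would be.
* Rigid alignment only; sections with nonlinear deformation should be
  handled by manual override after visual inspection.
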