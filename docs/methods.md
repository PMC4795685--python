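# Methods

## Problem setting

`contourqa` operationalizes a multi-center contouring QA protocol: several
physicians delineate the same clinical target volume (CTV) on the same image
series, in two rounds separated by a harmonization intervention (case review
and adoption of shared guidelines). The analysis asks (i) how far each
observer's contour is from a reference, summarized as mean ± SD of five
overlap indices per round, and (ii) whether the second round's indices are
significantly closer to their optima.

## Representation and indices

Contours are binary occupancy masks on a shared regular voxel grid
(`occupancy[x, y, z]`, spacing in mm, origin at the center of voxel (0,0,0)).
Volume is voxel count × voxel volume with no partial-volume weighting, so all
indices are ratios of integers and the worked cube example
(|∩| = 729, |∪| = 1271, VO = 0.57) is bit-exact. Grids must match exactly in
dimensions and to 1e-6 mm in spacing/origin; resampling between mismatched
grids is deliberately out of scope.

Index direction follows the ordered pair (test Cn, reference CR): CV is
referenced to CR, AV to Cn. These two are therefore order-sensitive, while VO
and DSC are symmetric and VR(test,ref)·VR(ref,test) = 1. An index with an
empty denominator raises an error rather than returning a sentinel, since an
empty clinical contour indicates corrupted input. Reports round to two
decimals; full precision is kept internally.

## Reference choices

* **Reference mode** elects one observer's contour as reference for every
  case and round. The reference observer is excluded from the scored panel
  (their self-comparison is identically optimal and would dilute the
  variability estimate).
* **Consensus mode** scores each observer against the common contour of
  voxels delineated by ≥ t of N observers. The default t = ⌈9/14 · N⌉
  preserves a ≈64 % vote fraction across panel sizes and equals 9 when
  N = 14. "At least" semantics are used for the threshold. By default the
  scored observer's own vote participates in the consensus; because
  self-inclusion can only raise that observer's CV (a bias the test suite
  asserts), a leave-one-out option rebuilds the consensus per observer with
  the same vote count.

## Statistics

Round-to-round change is tested per index with the two-sided Wilcoxon
signed-rank test, pairing by observer: zero differences are dropped
(Wilcoxon's convention), ties are mid-ranked, and the exact null distribution
is used when the effective n is ≤ 25 with no tied nonzero |differences|,
otherwise the normal approximation with tie correction. Between-case
comparisons of VO and DSC use the two-sided Mann-Whitney U test (exact null
for group sizes ≤ 8 without ties; tie-corrected normal approximation
otherwise, without continuity correction so that identical groups yield
p = 1). α = 0.05. No multiple-testing correction is applied across the five
indices or the case pairs, matching common practice for this kind of QA
report; `holm_adjust` is provided for users who want the step-down
adjustment. Samples that carry no information (all paired differences zero,
all values tied) are reported as degenerate instead of producing a p-value.

## Synthetic study generator

The generator stands in for clinical contour sets, which are essentially
never distributable. It emulates the features of multi-observer CTV data that
the analysis relies on — it is not an anatomical model.

**Ground truth.** An analytic shape rasterized on the grid: an ellipsoid
(compact organ) or an elliptical cross-section extruded along z with a
sinusoidal in-plane center drift (an elongated, curved "nodal-chain" target).
The default grid is 56×56×40 voxels at 2×2×2.5 mm.

**Observer model.** Each observer's contour displaces the truth boundary
radially, slice by slice:

    r_obs(θ, z) = r_truth(θ, z) + bias_o + ε(θ, z)

with `bias_o ~ N(0, σ_sys)` drawn once per (observer, case) — a systematic
over/under-contouring tendency that persists across rounds — and ε a
zero-mean Gaussian field with SD σ_rand, smoothed over angle with a Gaussian
kernel of SD 30° (and lightly across slices, SD 1 slice), normalized back to
unit marginal variance. This yields smooth, contour-like disagreement rather
than voxel noise. Craniocaudal extent disagreement — the classic apex/base
problem — is a separate channel: each end of the structure is independently
extended (copying the end-slice boundary profile) or trimmed by
`round(N(0, σ_extent))` slices. The per-slice truth boundary `r_truth(θ)` is
measured from the rasterized truth (max occupied radius per 5° bin, plus half
a voxel), so perturbation works for any star-convex-per-slice truth.

**Rounds.** Round 2 multiplies all three SDs — and each observer's bias — by
`round2_scale ∈ (0, 1]`; a value < 1 emulates post-guideline harmonization
and 1 is the null of no change. The designated reference observer reuses the
same noise substream in both rounds, so their round-2 contour differs only
through the scale factor. This models the reference participant's
reported near-identical re-delineation, and it matters statistically: if the
reference re-drew independently, its round-2 fluctuation would shift every
paired difference in the same direction, correlating the pairs and inflating
the signed-rank test's false-positive rate far above α (we measured ≈30 %
instead of ≈5 % in reference mode). With a round-consistent reference the
paired differences are independent across observers and the test holds its
nominal level (measured 4 % over 100 null replicates).

**Determinism.** One global seed; every draw comes from a substream keyed by
CRC-32 hashes of (purpose, case, observer, round), so studies are reproducible
voxel-for-voxel and adding observers does not perturb existing ones.

**Case presets.** Three presets mirror a three-case prostate QA design:

| preset | truth | σ_sys = σ_rand (mm) | σ_extent (slices) | baseline DSC |
|---|---|---|---|---|
| `lowrisk` | ellipsoid 25×22×24 mm (~55 cc) | 2.4 | 0.7 | ≈ 0.83 |
| `nodal` | curved chain, 16×13 mm section, ±34 mm, 12 mm drift | 4.0 | 1.0 | ≈ 0.59 |
| `postop` | ellipsoid 17×15×16 mm (~17 cc) | 3.0 | 1.8 | ≈ 0.63 |

The noise magnitudes are a calibration choice: no quantitative inter-observer
noise levels are available for the clinical data the presets emulate, so the
SDs were fixed once so that round-1 mean DSC versus a reference observer
lands in the ranges typically reported for easy (≈0.8+) versus difficult
(≈0.6) pelvic targets, and were not revisited. Consequently, agreements
between simulated summaries and any particular clinical table are qualitative
(directions and orderings), never numeric reproductions.

**What the simulator does not model.** Real CT/MR appearance and
image-dependent ambiguity; guideline content (it shrinks noise, it does not
encode boundary definitions); inter-center clustering of observers;
non-star-convex per-slice cross-sections (a branched truth would be filled
convexly by the radial model); intra-observer drift between rounds beyond the
scale factor. Passing tests therefore demonstrate that the pipeline measures
and detects harmonization correctly under its stated noise model, not that
any specific clinical finding is reproduced.

## Numerical and scale choices

* Exact integer arithmetic for all voxel counts; index identities hold to
  1e-12 (floating division only).
* Wilcoxon exact mode whenever valid (n ≤ 25, no tied |differences|): at the
  panel sizes involved (n = 13–14 pairs) the exact null is cheap and avoids
  approximation error in the tails.
* Shift clipping (voxels pushed off the lattice) is a logged warning, not an
  error, since the operation is diagnostic plumbing.
* Simulation-based checks in the test suite use 30–100 replicates of
  14-observer studies on the default grid; at those sizes the full pipeline
  runs in well under a minute per hundred replicates while binomial bounds on
  detection rates stay tight enough to be meaningful.
* Empty consensus at a chosen threshold and annihilating perturbations are
  errors with actionable messages (lower the threshold / reduce the SDs);
  the simulator retries an annihilating draw up to 10 times first.

## Known limitations

* No surface-distance metrics (Hausdorff, mean surface distance); the
  package's scope is volumetric indices, which are deliberately stricter.
* No resampling, registration, or DICOM-RTSTRUCT polygon rasterization;
  inputs must already be voxel masks on a common grid.
* Reference mode inherits the usual caveat that conclusions are conditional
  on the elected reference; consensus mode exists precisely to avoid that
  choice, and the two modes can disagree for individual indices.
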