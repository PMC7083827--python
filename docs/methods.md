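# Methods

`tarsomorph` implements a quantitative test of two homology hypotheses for
the archosauromorph ankle: that the centrale — a separate tarsal
ossification medial to the astragalus in early archosauromorphs — was
**fused into** the astragalus on the stem of Erythrosuchidae + Eucrocopoda,
or that it was simply **lost** while the astragalus expanded medially into
its place.  Each hypothesis corresponds to a landmark configuration of the
proximal tarsus: digitising astragalus + centrale as one unit (fusion) or
the astragalus alone (loss).  Both configurations are carried through the
same chain — Procrustes superimposition, reference-taxon alignment,
minimum-displacement ancestral reconstruction on a fixed phylogeny — and
the landmark displacement each one requires on the focal stem branch,
restricted to the five medial-margin points, is the test statistic.  The
configuration needing fewer medial "steps" on that branch is the more
parsimonious, and its hypothesis is preferred.

## Landmark data

Specimens are 2D configurations of 9 fixed landmarks and 2 sliding
semilandmarks (11 points), read and written in plain TPS records
(`LM=`, coordinate rows, `IMAGE=`/`ID=`, `SCALE=`).  `SCALE=` converts
digitising units to millimetres on read.  Curve-extension records
(`CURVES=`, `POINTS=`) are rejected loudly rather than silently ignored.
The axis convention is mathematical: y increases upward ("dorsal" = +y);
right-side specimens are mirrored about the vertical axis so every
configuration is a left tarsal and "medial" = −x.  Mirroring is an isometry
(all inter-point distances preserved) and refuses to run twice.

The landmark scheme (which points slide, along which neighbour chord, and
named subsets) ships as an editable YAML document rather than hard-coded
anatomy.  The default scheme's `medial` subset is {LM2, LM6, LM9, SL1, SL2}
(0-based indices 1, 5, 8, 9, 10), the five points sampling the medial
margin.  The generic scheme type only validates index ranges and neighbour
sanity; the presence of a medial subset is enforced where it is actually
needed, at the hypothesis-test entry point.

## Generalized Procrustes analysis

`gpa_align` iterates: centre every configuration, scale it (unit centroid
size in `unit` mode; no rescaling in `mm` mode), rotate it onto the current
consensus by the 2D SVD (Kabsch) solution with reflections excluded, slide
the semilandmarks, and update the consensus, until the consensus
root-mean-square change falls below 1e−10 or 100 iterations have run.
Non-convergence at the cap is recorded in the provenance and is not fatal.

Sliding uses the Procrustes-distance criterion: each semilandmark's tangent
is the chord between its two declared neighbours, and the point moves along
the line through its current position in that direction to the foot of the
perpendicular from the matching consensus point.  This never increases the
specimen's distance to the consensus.  With sliding enabled the iteration
has no strict fixed point at the 1e−10 tolerance — the semilandmarks keep
creeping minutely along their chords as the consensus co-adapts — so slid
alignments typically terminate at the iteration cap.  This is harmless for
the downstream statistics (the creep is orders of magnitude below any
biological signal), and two design choices keep the output well defined
anyway:

* the **initial consensus** is the mean of the individually
  principal-axis-canonicalised shapes — a symmetric function of the input
  set — so the result does not depend on specimen order;
* the **final orientation** is canonicalised (consensus rotated onto its
  principal axes, sign fixed by the largest-|x| point, determinant +1), so
  the output is invariant to arbitrary rotations, translations and (in
  unit mode) rescalings of the inputs.

The morphospace summary is a PCA of the flattened aligned coordinates
(specimens × 2p), and disparity is the Sum of Variances (SoV): the summed
per-coordinate variance across specimens.  The eigenvalue sum equals the
SoV by the trace identity under the same divisor.  The divisor is n−1 by
default with n available (`ddof=0`); no tangent-space projection is applied
before PCA (shape variation in this application is small).  SoV is computed
on the aligned coordinates with all components retained, which is identical
to computing it on the full set of PC scores.

## Reference-taxon superimposition

Before optimisation, all aligned configurations are re-superimposed onto a
reference taxon (in the original study design, the earliest-branching
outgroup) under the **minimum-distance criterion**: rotation + translation
(no reflection; no rescaling unless requested) minimising the *unsquared*
summed Euclidean landmark distances to the reference.  This is solved by
iteratively reweighted least squares — weights 1/max(d, 1e−9), each step a
weighted Kabsch fit — iterated to an objective change below 1e−12.  The
unsquared criterion is robust: it fits the concordant landmarks tightly
and concentrates genuine localised shape differences in the discrepant
landmarks instead of smearing them.

## Minimum-displacement ancestral reconstruction

Given terminal configurations in a common space and a rooted topology
(branch lengths in the input are ignored; the analysis derives lengths),
ancestral configurations minimise

    L = Σ_landmarks Σ_branches ‖x(parent) − x(child)‖ ,

the continuous analogue of minimum-steps parsimony.  The problem separates
into p independent convex multifacility Weber problems, one per landmark,
whose per-node optimality condition is that every internal node sits at the
geometric median of its tree neighbours.  Because only branch sums enter,
the optimal value is invariant to the root position.

The objective is non-smooth wherever adjacent nodes coincide — and
coincidence is *typical* at the optimum (ancestral ties, nodes pinned onto
terminals).  The solver therefore works in three stages per landmark:

1. **Smoothed Newton.**  Each edge term is smoothed to
   √(d² + ε²) and minimised over all internal positions by a damped Newton
   iteration with the exact (dense, 2m × 2m) Hessian, over the decreasing
   schedule ε = 1e−3, 1e−5, 1e−7, warm-starting each level.  Newton
   absorbs the 1/ε stiffness of near-coincident nodes that defeats
   first-order methods; steps are trust-region capped at the data diameter
   and fall back to a gradient step if a line search fails.
2. **Guarded kink resolution.**  Connected groups of near-coincident
   adjacent internal nodes are collapsed onto the geometric median of
   their outside neighbours, and internal nodes hugging an adjacent
   terminal are pinned onto it — each move accepted only if the *exact*
   objective does not increase, so a genuinely distinct optimum is never
   destroyed.
3. **Contracted Newton.**  Collapsed groups share one variable and pinned
   nodes become fixed; the contracted problem is smooth and a final Newton
   pass at ε = 1e−10 drives its gradient to ~1e−11 (the kink-detection
   radius widens and the pass repeats, up to four rounds, if a borderline
   tie was initially missed).  A residual gradient g bounds the objective
   error by roughly g × diameter; the run aborts only if g exceeds 1e−3,
   far above anything observed on non-degenerate data (generic instances
   converge to ~1e−11; rare degenerate blobs of near-coincident terminals
   can stall around 1e−4, an objective error of order 1e−6).

Tie-breaks fall out of the smoothing deterministically: a degree-2 root
whose optimum is anywhere on the segment between its children reports the
midpoint.  Note that the two branches incident to a degree-2 root are one
edge of the unrooted tree; how that edge's length divides between them is
an artefact of the root placement, so a focal branch should never be a
child of the root (in the real study design, and in the synthetic default,
it is not).

`geometric_median` itself is a damped Weiszfeld iteration with the
Vardi–Zhang vertex test (a data point is optimal iff the pull of the
remaining points does not exceed its own weight) and Newton acceleration
away from data points, to tolerance 1e−12.

The per-branch, per-landmark displacement table, per-landmark totals and
the tree length are read off the optimal positions.  The **consistency
index** is CI = Σ_l m_l / L with m_l the Euclidean minimum-spanning-tree
length over landmark l's terminal positions, capped at 1: on very small
trees the free-internal-node optimum can undercut the MST (Steiner effect),
and the cap keeps CI in (0, 1].  This is a declared package convention for
continuous landmark characters; published CI values computed by other
software need not match it.  A squared-change option (`squared=True`)
replaces the objective with summed squared displacements for comparison;
it is not the default and is not used by the hypothesis test.

## The decision rule

For one topology, the two configurations' reconstructions are compared by
their focal-branch medial-subset lengths.  The strictly smaller length
wins; ties are inconclusive.  No probabilistic test is attached to the
difference — the comparison is a parsimony argument, where any difference
counts — and the package instead quantifies the rule's operating
characteristics by simulation (below).  Reports carry the full 2 × 2
design (two configurations × two topologies), the per-topology preference,
the SoV pair, and the per-landmark displacement vectors on the focal
branch; output JSON/TSV/tables are deterministic (sorted keys, no
timestamps, repr-exact floats).

## Synthetic data generator

The generator emulates the study's inputs so that every stage is testable
without the original fossils.  Each landmark coordinate evolves down the
tree as Brownian motion with variance σ² per unit branch duration,
starting from an 11-point left-tarsus-like ancestor (~20 × 12 mm, centroid
size ≈ 28 mm); independent Gaussian digitisation noise is added at the
leaves.  Defaults: 8 taxa on ((t1,(t2,t3)),(t4,((t5,t6),(t7,t8)))) with
unit durations, focal clade {t5..t8}, σ = 0.3 mm per branch (a few percent
of bone size per split — mid-sized divergence for congeneric-to-familial
comparisons), noise 0.05 mm, seed 42.

Under the **loss + medial expansion** scenario the astragalus-only dataset
receives, on the focal branch only, an extra deterministic displacement of
the medial-margin landmarks of magnitude δ (default 1.5 mm, i.e.
δ/σ = 5), inherited by all focal-clade descendants; the combined dataset
receives none, because its medial margin is already occupied by the
centrale.  Under **fusion**, neither dataset is shifted and the two are
exchangeable draws.  The displacement field is deliberately
*heterogeneous* — LM2 ventromedial, LM6/SL1 medial, LM9 ventromedial, SL2
dorsolateral at lower magnitude — mirroring the localised margin
deformation the fossil optimisations recover.  This matters: a uniform −x
translation of the medial points is largely a similarity transform of the
whole configuration, and Procrustes superimposition absorbs ~87% of it,
whereas the heterogeneous field survives alignment about 3× better.  The
generator runs on raw coordinates, not in Procrustes tangent space, as a
transparency choice; the pipeline's own GPA removes the nuisance
similarity components.

What the generator does *not* emulate: correlated landmark covariance
(real bones deform in integrated modules), allometry, measurement error
that scales with specimen size, fossil missing data, and any rate
heterogeneity across branches or landmarks.  Passing calibration therefore
shows that the decision rule recovers a focal-branch margin displacement
against Brownian noise of the stated magnitude — not that it is robust to
every failure mode of real fossil data.

## Calibration semantics

`calibrate_decision_rule` simulates replicate dataset pairs and classifies
each by the sign of d = medial(astragalus-only) − medial(combined) on the
focal branch: d > 0 is the signature only the loss scenario generates
(the astragalus-only configuration needs extra medial steps), d < 0 points
the other way, d = 0 is inconclusive.  Note the distinction between this
*scenario-recovery* reading and the per-configuration parsimony preference:
when d > 0 the parsimony rule prefers the combined configuration (fewer
steps), while the asymmetry itself is evidence that a medial expansion —
the loss scenario's fingerprint — is present in the astragalus-only
representation.  Both readings are reported per replicate.  Under the
default conditions (δ/σ = 5, 8 taxa) the loss signature is recovered in
≈96% of replicates, rising to 100% at δ/σ = 10; under the fusion null the
fractions sit near ½, as exchangeability requires.  Per-replicate seeds
derive from the root seed by a fixed documented rule (entries of the root
`SeedSequence` state, folded below 2³¹), so any replicate can be reproduced
alone.

## Problem sizes and tolerances in the test suite

The test suite exercises the pipeline at the scale of the synthetic
default (8 taxa, 11 landmarks) with 200 calibration replicates per
scenario, the solver against a 1e−3-resolution exhaustive grid oracle on
50 random single-landmark instances of 3–5 leaves, and GPA against an
angle-grid (1e−4 rad) superimposition oracle — sizes chosen so the whole
suite completes in minutes while every claim is still checked by an
independent route.  Analytic optima (Fermat point √3; unit-square Steiner
tree 1 + √3 with internal nodes at x = 1/(2√3) and 1 − 1/(2√3)) are met to
1e−6.  Reproducing the published 42-taxon table requires the journal's
supplementary landmark coordinates and supertrees, which cannot be
redistributed here; the corresponding checks look for those inputs under
`data/study/` (see README) and report their absence explicitly.

## Known limitations

* The minimum-distance alignment precedes the optimisation; TNT-style
  joint re-alignment/optimisation is not attempted.
* CI for continuous landmark characters has no universal convention; ours
  (capped MST ratio) is documented above and not comparable across
  software.
* Branch lengths adjacent to a degree-2 root are individually arbitrary
  (only their sum is meaningful); keep focal branches away from the root.
* 2D landmarks only; curve (CURVES=) TPS records and 3D data are out of
  scope.
* The sliding-GPA iteration is capped rather than converged; tolerances
  below ~1e−6 on slid coordinates are not meaningful.
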