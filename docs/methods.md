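# Methods

This note documents the models, numerical choices and limitations behind
`limbshape`.  It is written for users who want to know exactly what each
stage computes and what a passing test suite does and does not establish.

## Shape capture and superimposition

A specimen is a labelled configuration of K 3D points partitioned into
three bones (femur, tibia, fibula).  Points are *fixed* landmarks or
*semilandmarks*; each semilandmark belongs to exactly one curve whose two
terminal anchors are fixed landmarks.  Centroid size
CS = sqrt(Σ‖xᵢ − x̄‖²), in mm, is the size variable throughout; the size
proxy for trend analyses is its natural log (any other base only shifts
intercepts).

Generalized Procrustes Analysis centres every configuration, scales it to
unit centroid size and iteratively rotates it onto the running consensus
(the mean shape rescaled to unit CS).  Rotations come from the SVD-based
orthogonal Procrustes solution with a determinant correction so that
reflections are excluded — limb bones are handed objects and any
left/right mirroring must be resolved upstream, not by the optimiser.
Convergence is declared when the consensus RMS change drops below 1e-10
(at most 100 iterations; non-convergence is an error, not a warning).
Aligned shapes are projected orthogonally onto the affine tangent plane of
the pre-shape sphere at the consensus before ordination; the projection is
a switch (`project_to_tangent`) because at small shape variation its
effect is of second order.

### Semilandmark sliding

Per cycle: GPA; per-specimen curve tangents estimated from the two points
flanking each interior semilandmark; all interior semilandmarks displaced
along their tangents by the closed-form minimiser of the chosen criterion
against the consensus; GPA re-run.  Two criteria are available:

- **Bending energy** (default, 3 cycles): thin-plate-spline energy of the
  displacement field from the consensus, with the 3D kernel U(r) = −r
  (the sign that makes the energy form positive semidefinite).  All
  sliding parameters are solved jointly from the k×k bending-energy
  matrix of the consensus.
- **Procrustes distance**: summed squared distance to the consensus; the
  joint minimiser decouples into independent orthogonal projections of
  each consensus target onto the point's tangent line.

Anchors and fixed landmarks never move.  Within a cycle the slide is an
exact quadratic minimisation, so the criterion cannot increase; across
cycles the consensus re-estimate can in principle raise the bending
energy slightly once the procedure has converged, so a cycle that would
increase the criterion is discarded and iteration stops.  The reported
criterion history is therefore non-increasing by construction.  Sliding
displaces points along tangent *lines* (no re-projection onto an
underlying curve model, which would require a curve parameterisation the
landmark data do not carry).

### Limb assembly

Each bone is rotated into its principal frame; the proximodistal axis is
the first principal axis, oriented deterministically (the
largest-magnitude projection is positive, with per-bone flip flags for
atypical elements).  The zeugopod elements are translated distally so the
stylopod–zeugopod gap equals `gap_fraction` (default 0.02) times femur
length — a constant articular-cartilage allowance — and offset to either
side of the midline so they do not interpenetrate.  The composite
proximodistal extent is femur length + gap + max(tibia, fibula length) by
construction.  Missing elements are an error: the package never imputes
morphology.

## Ordination

PCA is computed on the covariance (not correlation) of the flattened
tangent coordinates — Procrustes coordinates share a unit, so variable
rescaling would be wrong.  Eigenvalues below 1e-12 of the leading one are
treated as null; with n specimens at most n−1 (and never more than 3K−7)
components are nonzero.  Signs are fixed by making each component's
largest-magnitude loading positive, which makes regression tests and
repeated runs deterministic.

Retention uses Anderson's large-sample sphericity statistic on the
trailing q eigenvalues, (n−1)[q ln λ̄ − Σ ln λᵢ] against χ² with
q(q+1)/2 − 1 df, retaining components until the remainder is first not
rejected.  A single nonzero eigenvalue is retained by convention.  If no
trailing set is ever spherical all components are retained.

## Phylogeny

Supertrees use Baum–Ragan matrix representation with parsimony: one
binary character per non-trivial clade per source tree (members 1,
sampled non-members 0, unsampled taxa missing).  Characters are equally
weighted.  The hypothetical all-zero ancestor is an explicit leaf during
the search — its attachment point is part of the topology — and roots the
result.  Fitch lengths are computed with missing entries as wildcards.
Search is either exhaustive enumeration (≤ 9 ingroup taxa) or
hill-climbing with NNI moves refined by SPR moves from seeded random
starting trees (default 10 restarts); equally parsimonious topologies are
reduced by strict consensus, so unresolvable conflicts surface as
polytomies rather than arbitrary resolutions.

Time calibration is deliberately minimal ("conservative"): postorder,
each node's age is the maximum over children of child age + mbl, with
mbl = 1 My by default.  Every branch is therefore at least mbl long —
which also keeps the BM covariance invertible — and no node is older than
its tip ages force it to be.  Tip ages are user inputs (e.g. midpoints of
stratigraphic ranges); the packaged `tip_ages.csv` for the 17-taxon
demonstration tree contains approximate, editable stand-in values, not
measured data.

## Comparative methods

Under Brownian motion with rate σ², trait covariance between tips equals
σ² times the shared root-to-MRCA path length; Pagel's λ multiplies the
off-diagonal entries only.  λ is estimated by profile maximum likelihood:
at each λ the root state and rate are solved by GLS, and the scalar
profile is maximised over [0, 1] with bounded Brent search (tolerance
1e-6; the exact endpoints are checked explicitly because the bounded
optimiser never evaluates them).  The profile is assumed unimodal, which
holds in practice for this model; no restarts are used.  Star trees make
λ unidentifiable and are flagged rather than fitted.

The significance of λ uses a simulated null: n_sim datasets (default
1000) of independent normal tips with the GLS mean and rate of the λ = 0
model, each refitted; p is the fraction of null likelihood ratios at
least as large as the observed LR = 2(ℓ(λ̂) − ℓ(0)).  λ = 0 is the
natural "signal versus none" contrast; a white-noise permutation null
would be a one-line variant.

Ancestral states are the GLS/BLUP estimates under BM: the root is the
GLS-weighted tip mean, and every other internal node is the conditional
expectation given the tips, which coincides with the GLS root estimate of
the tree rerooted at that node (the test suite checks this equivalence
against an independent pairwise-distance construction).  Reported
variances include the propagation of root-mean uncertainty.
Phylomorphospace coordinates are these estimates per ordination axis,
with parent–child segments for plotting.

The phylogenetic ANOVA is simulation-based: the observed statistic is
the ordinary one-way F, and its null distribution comes from BM
simulations of the response on the tree at the ML rate of the observed
data.  p is the fraction of simulated F ≥ observed and Z standardises
the observed F against the simulated distribution (raw F, not log F).

## Allometry and trend tests

RMA regression: slope = sign(r)·s_y/s_x (positive at r = 0 by
convention), intercept through the means, p from the two-sided t-test on
the Pearson correlation with n−2 df (a permutation p is available), and
slope CI slope·(√(B+1) ± √B) with B = F(1−α; 1, n−2)(1−r²)/(n−2).
Subset fits (e.g. one nested clade only) are plain re-invocations on
filtered tips.  Rank tests delegate to SciPy (tie-corrected H with the χ²
approximation; exact Mann–Whitney enumeration when the pooled sample is
≤ 10 and tie-free).  Multiplicity uses Bonferroni, min(1, p·m).

Trend tests compare every node of a named clade against its parent using
the ancestral estimates (the clade's basal node is compared against its
parent outside the clade whenever one exists; node counts `n` include the
basal node).  Exactly-zero changes are non-directional and enter neither
count.  The 50:50 test is χ² = (n₊ − n₋)²/(n₊ + n₋) on 1 df without
continuity correction.  Summary means divide the change sum by the clade
node count n.  Because ancestral estimates shrink toward the root,
changes on different branches are correlated; the test suite verifies
empirically that the test still calibrates to ≈5% rejection under
driftless BM on independent replicate trees at the 17-taxon scale.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions the test suite runs
under: 17 taxa; a limb template with 28 fixed landmarks and 12
semilandmark curves (five interior points each, K = 88) assembled with
the 2% gap; tree depth 80 My; latent shape variance 4.5e-5 per My per
axis (tip score spread of a few hundredths of a Procrustes unit); log-size
variance 0.002 per My around a root of 7.44 log-mm (~1700 mm limbs, the
scale of the demonstration taxa); λ = 1; size drift −0.01 log-mm/My (a
phyletic size decrease); landmark noise SD 0.003 shape units.  Latent
deformation fields (stylopod arching, zeugopod shortening, lateromedial
widening, optional distal twist) are orthonormalised and projected free
of similarity components, so they are pure shape directions and PCA
recovery checks are well-posed.  Each specimen receives a random rigid
motion so superimposition is exercised non-trivially.  The λ transform is
realised on branch lengths (internal branches × λ, terminal branches
extended to preserve tip variance); drift acts on real time.

The template's tibia and fibula share dimensions so the assembled limb is
an exact bilateral object — useful for symmetry tests, slightly less
realistic anatomically.  The generator does not emulate bone surface
geometry, taphonomic deformation, missing elements, intraspecific
sampling imbalance, or measurement error that is correlated along curves.
Passing tests therefore demonstrate the correctness and calibration of
the estimators under a known generating model, not the robustness of the
pipeline to the messiness of real fossil data.

## Problem sizes and seeds

Statistical checks run at fixed, seeded sizes chosen to make Monte-Carlo
noise small relative to the tested tolerances: λ recovery uses 200
replicates per signal level at 64 tips; the LR-test type-I check uses 200
replicates with 199 null simulations each; RMA coverage uses 1000
datasets of n = 30; ACE oracles use 30 random 8-tip trees; drift
detection uses 100 seeds of the full landmark pipeline.  All randomness
flows from explicit integer seeds; regenerating any dataset from the same
configuration is bit-identical.

## Known limitations

- Sliding is tangent-line based; for strongly curved, sparsely sampled
  curves a curve-reprojection step would reduce drift off the curve.
- The MRP hill-climb is stochastic; with very conflicted matrices the
  strict consensus of the topologies it happens to find can differ
  between seeds even at the optimal score.  Exhaustive search is exact
  but limited to small problems.
- The λ LR test's simulated null conditions on the fitted λ = 0
  parameters rather than refitting uncertainty into the null draw; at the
  sample sizes tested this bias is within the verified type-I band.
- The phylogenetic ANOVA's Z is a plain standardisation of F against the
  simulated null; other effect-size conventions (log-F) exist.
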