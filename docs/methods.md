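# Methods

## Problem

A still (monochromatic, zero-oscillation) diffraction snapshot of a
microcrystal records only the Bragg reflections whose reciprocal-lattice
points lie close enough to the Ewald sphere to diffract. When the
pattern contains only a handful of identifiable peaks — small or weakly
diffracting crystals, small unit cells, low-resolution data —
Fourier-based auto-indexers cannot recover the lattice periodicity, and
the pattern is discarded. `snapindex` indexes such sparse patterns by
exploiting prior knowledge of the unit cell ("guiding cell"): peak
pairs are matched against a precomputed table of pair geometries of the
guiding lattice, each match yields a candidate crystal orientation, and
a solution is accepted only when one orientation is corroborated by
every peak pair and predicts every observed peak.

## Geometry and conventions

* Laboratory frame: beam along +z, a single flat detector panel
  perpendicular to the beam at `z = detector_distance`, fast pixel axis
  = +x, slow = +y (right-handed). The paper-style geometry never fixes
  detector-axis handedness; the same convention is used by the
  simulator and the indexer, which is the only requirement.
* Momentum transfer in the crystallographic convention (no 2π):
  `|q| = 2 sin θ / λ`, `d = 1/|q|`, q in Å⁻¹ throughout. A peak at
  detector position r lifts to `q = (r/|r| − ẑ)/λ`, which lies on the
  Ewald sphere of radius 1/λ centred at −ẑ/λ.
* Crystal frame: Busing–Levy setting (a* along +x, b* in the xy-plane),
  so the reciprocal basis matrix B is upper triangular and the
  orientation matrix R maps crystal-frame vectors B·h to the lab frame.
* Euler angles are reported in the intrinsic z-y-z convention.
  Orientation comparisons use the misorientation angle
  `arccos((tr(R₁ᵀR₂) − 1)/2)`, which is convention-free.

## The indexing pipeline

For each pattern:

1. **Peak selection.** The best `n_index_peaks` (default 5) peaks by
   SNR (or intensity / resolution) are chosen; all N(N−1)/2 unordered
   pairs are formed. Five peaks give ten pairs, a good compromise
   between constraint strength and cost.
2. **Pair invariants.** Each observed pair is reduced to its rotation
   invariants: the two vector lengths (sorted), their ratio, and the
   inter-vector angle.
3. **Reference-table query.** The table holds these invariants for
   every unordered pair of guiding-cell reflections to the resolution
   limit (Friedel mates as separate reflections; centering extinctions
   applied; pairs within `angle_min` = 10° of collinearity excluded as
   they cannot constrain an orientation). It is sorted by angle and
   queried by bisection; both assignments of the observed pair are
   tried. This orientation-free formulation is mathematically
   equivalent to matching against a dense set of discretized
   orientations, but exact; an explicit brute-force oracle is retained
   in the tests.
4. **Candidate orientations.** Every matching assignment is turned into
   an orientation by a closed-form two-vector Wahba fit (orthonormal
   triads from observed and reference vectors, `R = T_obs·T_refᵀ`).
   The candidates of one pair form that pair's solution pool.
   Observed pairs inside the collinearity exclusion band are skipped
   entirely — they carry no evidence either way.
5. **Pool intersection.** Candidates from all pools are clustered by
   single linkage under misorientation ≤ `pool_merge_tol` (1°),
   implemented with a KD-tree on unit quaternions (both signs inserted
   to handle the double cover). A cluster survives only with support
   from *all* pairs in sparse mode (≥ half in general mode), and the
   chosen orientation must be corroborated by every required pool
   directly within the merge tolerance (star topology), not merely
   through a linkage chain — chains of independent coincidences
   otherwise masquerade as consensus.
6. **Prediction and matching.** For each surviving cluster the member
   with the best all-peak match (most peaks matched, then lowest rms)
   represents it. Each observed q is assigned its nearest lattice node
   `h* = round((R·B)⁻¹q)` and matched iff `|q − R·B·h*|` is within the
   match threshold — by default half the shortest reciprocal-lattice
   vector of the guiding cell ("half-nearest", 0.0266 Å⁻¹ for the I3C
   cell), or a fixed value such as the 0.01 Å⁻¹ used in the
   guiding-cell scans.
7. **Accept/reject.** Sparse patterns (≤ `sparse_cutoff` = 6 usable
   peaks): the best candidate must match *all* observed peaks, its
   matched indices must be consistent with the lattice centering, and
   no inequivalent competitor may match comparably well (see
   *Ambiguity* below); otherwise the pattern is rejected with a typed
   reason (`too-few-peaks`, `no-table-match`, `no-consensus`,
   `failed-match-gate`). Patterns with more peaks are scored by
   (centering consistency, peaks matched, fraction matched, −rms) with
   a match-fraction gate that rises as the peak count falls
   (1.0 ≤ 6 peaks, 0.8 for 7–15, 0.6 above).

### Ambiguity and lattice symmetry

Orientations related by a proper rotation of the lattice point group
(for the orthorhombic I3C lattice: identity plus the three 2-folds)
predict identical patterns and are fundamentally indistinguishable in a
single snapshot; the indexer returns one representative
deterministically. A literal "unique consensus" requirement would
therefore reject everything; instead, acceptance is vetoed only when a
fully-matching competitor that is *not* a lattice-symmetry copy has an
all-peak rms within a factor `ambiguity_rms_factor` (default 2) of the
best — a genuinely ambiguous peak set. Ground-truth comparisons in the
evaluation module likewise reduce by the proper lattice rotations
(integer re-indexing operators M with B·M·B⁻¹ orthogonal, det +1): a
pattern is *correctly indexed* when accepted, the orientation is within
0.5° of the generating one modulo that group, and every matched peak's
index equals the correspondingly re-indexed ground truth. A pure
whole-pattern Friedel flip is not realizable by any proper detected
orientation (−I is improper); the realizable re-indexings are exactly
this group.

### Tolerances

The pair-search defaults (`tol_len` = 3×10⁻³ Å⁻¹ = 3×10⁷ m⁻¹ absolute
on both lengths, `tol_angle` = 3°) mirror the protein-data operating
point; the length ratio is stored for a relative-tolerance mode (useful
when the camera length needs refinement) but is off by default. In the
guiding-cell scan the search length tolerance is widened to the 0.01
Å⁻¹ match cut-off so that the search stage never prunes a pair the
acceptance stage would accept under a deliberately mis-set cell; the 3°
angle window is kept, and the scan's ±3° tolerance range for the
guiding α angle is its direct signature.

## The simulator

The simulator emulates the I3C test case: orthorhombic cell a = 9.02,
b = 15.73, c = 18.82 Å (P), 9.61 keV photons, 110 µm pixels at 0.07 m,
53.2° maximum scattering angle (d_min ≈ 1.44 Å). Per pattern:

* orientation uniform on SO(3) (uniform unit quaternions); optional
  Gaussian fluctuation of the cell lengths (0.5% s.d. in the
  lattice-inhomogeneity study), angles unchanged;
* each reflection's excitation error ζ — the beam-direction distance
  from the node to the Ewald sphere — is computed in closed form;
  nodes within `zeta_window_sigmas` (5) × `relrod_sigma` of the sphere,
  inside the acceptance cone, and projecting onto the detector are
  recordable;
* the rel-rod profile is an isotropic Gaussian of width `relrod_sigma`
  = `relrod_width_factor`/crystal size = 3×10⁻⁴ Å⁻¹ for a 1 µm
  crystal. The ideal finite-size shape transform alone gives ~1×10⁻⁴;
  the default constant absorbs beam divergence, residual bandwidth and
  mosaic broadening, and is calibrated once so that essentially every
  random orientation yields at least a handful of recordable
  reflections — the condition under which a full set of random
  orientations can carry 3–5 identifiable peaks each;
* intensities are `gain · F² · exp(−ζ²/2σ²)` with Wilson-statistics
  structure factors (F² ~ Exp(1), fixed per Miller index by an integer
  hash, Friedel-symmetric) under an `exp(−B q²/2)` envelope, B = 7 Å²
  as an effective bundle of thermal motion and the form-factor decay of
  an iodine-dominated small molecule (`structure_factors="unit"`
  restores flat intensities);
* a uniform background (100 counts per peak region) is added, counts
  are Poisson-sampled, and a peak is *identifiable* when
  `(counts − bg)/√counts ≥ 4` (the common hit-finding SNR cut);
* the per-pattern gain is calibrated so that exactly k peaks are
  identifiable, k drawn uniformly from {3..min(5, available)};
  realizations that land off-target are redrawn, and orientations with
  fewer than 3 recordable reflections are resampled (they cannot
  produce an indexable sparse pattern);
* peak centers are quantized to whole pixels (detection without
  profile centroiding), which is the dominant position noise
  (~10⁻³ Å⁻¹); the ζ-offset of off-sphere nodes contributes up to
  ~1.5×10⁻³ Å⁻¹.

What the generator does **not** model: physical count scales and
detector gain curves, non-uniform background, mosaic spread and SASE
spectral structure, multi-crystal patterns, profile-fitted (sub-pixel)
peak positions, and real I3C structure-factor amplitudes. Passing tests
therefore demonstrate the geometry and logic of the method and its
robustness under pixel-level position noise and cell inhomogeneity —
not detector-calibration effects or real-beam artifacts.

## Validation experiments and problem sizes

* **Sparse round trip** — 400 noisy 3–5-peak patterns, nominal guiding
  cell, default parameters; reports the correctly-indexed count and
  the median/90th-percentile misorientation. The test suite runs a
  50-pattern smoke version; the acceptance script runs the full 400.
* **Guiding-cell α scan** — one 400-pattern set with 0.5% lattice
  fluctuation, re-indexed with volume-preserving guiding-cell variants
  (α mis-set, b and c scaled by 1/√sin α), match cut-off 0.01 Å⁻¹;
  reports per-α indexing rates and the distribution of
  predicted-vs-found distances for matched peaks. The suite runs 200
  patterns over α ∈ {87…105}; band checks widen by twice the binomial
  standard error of the reduced sample.
* **Property checks** — exact-node round trips (orientation recovery
  < 10⁻⁶° modulo lattice symmetry), equivalence of the bisection query
  with an exhaustive linear scan, equivalence of the pipeline with an
  exhaustive Miller-assignment search on toy cubic patterns, and a
  < 2% false-positive bound on lattice-free random 5-peak patterns.

## Numerical choices and degenerate inputs

* Angles are clipped into [−1, 1] before arccos; misorientations below
  ~10⁻⁶° are at the precision floor of the trace formula (tests needing
  more use the rotation-vector norm).
* Zero-length q (a peak at the beam center, the 000 reflection) is
  legal input, excluded from selection and matching.
* Collinear pairs raise a typed `DegeneratePairError` in the two-vector
  fit; degenerate candidate fits are dropped and counted per pool.
* The reflection-list cap (200 000) converts an oversized table into an
  explicit configuration error; the pair table grows quadratically in
  the reflection count (~6.9×10⁶ entries for I3C at full resolution,
  ~10 s to build, ~150 MB).
* Ties in scoring break deterministically (stable candidate order, then
  construction index); identical inputs, parameters and seed produce
  byte-identical solution records, independent of the number of
  parallel workers.

## Known limitations

* Multi-crystal patterns index at most one lattice; peaks from a second
  lattice usually veto the single-lattice consensus.
* Merohedral/Bravais indexing ambiguity is reported modulo the proper
  lattice rotations, not resolved.
* No per-pattern cell or orientation refinement; the orientation comes
  from the best two-vector fit among the consensus candidates
  (typically ~0.05° median error under pixel-level noise).
* Very sparse (3-peak) patterns at high resolution admit coincidental
  full matches at the 0.01 Å⁻¹ cut-off with probability of order
  (4/3)π(0.01)³·V_cell per free peak; the rejection module suppresses
  but cannot eliminate these, so a mis-set guiding cell beyond the
  tolerance range retains a small (~5–8%) acceptance floor in this
  simulator's high-resolution-peak regime.
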