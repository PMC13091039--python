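# Methods

## Scope

`ensemblefp` implements ensemble conformational fingerprinting for
multi-model structure predictions of receptor–effector complexes:
domain-restricted rigid superposition, residue-pair distance observables,
2D distance maps with representative selection, two-state classification,
and AF3-style confidence aggregation. Model inference itself is out of
scope; the package consumes coordinates and confidence JSONs as input, or
generates synthetic stand-ins.

## Input model

An ensemble is a directory of mmCIF/PDB files named
`seed-SSS_sample-J_model.cif`, organized as seed batches (default scheme:
20 seeds × 5 models = 100 models), with optional per-model
`*_summary_confidences.json` (ipTM, chain-pair ipTM, chain ids) and
`*_full_data.json` (token PAE matrix, per-token pLDDT, token chain/residue
ids) in the AF3-server layout. Parsing uses gemmi. The PAE matrix is stored
exactly as read — no symmetrization or rescaling — and is interpreted
asymmetrically: entry (i, j) is the expected position error of token j when
the prediction is aligned on token i. pLDDT is accepted under the keys
`plddt` or `token_plddts` (per token); the per-atom `atom_plddts` variant
is not aggregated, since collapsing it to tokens would require an
atom-level token table the summary files do not carry.

## Atom addressing

Atoms are addressed as `[letter]resid[^BW]/atom`, e.g. `D256^45.52/cg`:
one-letter residue type (checked against the model), author residue
number, optional Ballesteros–Weinstein code (annotation only — never used
for lookup), and atom name. Alternate locations resolve by highest
occupancy, then altloc 'A', then lexical order.

## Superposition

Weighted Kabsch fit: subtract weighted centroids, form the 3×3
cross-covariance, take its SVD, and build the rotation with the smallest
singular direction sign-flipped when the determinant would be −1, so the
result is always a proper rotation (det = +1, verified to 1e-9). Degenerate
configurations (coincident or collinear points, smallest singular value ≤
1e-8 of the largest) emit a `DegenerateGeometryWarning`; fewer than 3
points is an error. The default selection is receptor CA atoms over seven
transmembrane spans; the first model (or a named model) is the reference
and all others are fitted to it. Tests cross-check against
`scipy.spatial.transform.Rotation.align_vectors` and a brute-force
rotation-grid search with local refinement.

## Observables and classification

Distances are Euclidean, in Å, computed after (but invariant to)
superposition. 2D maps use uniform bins of width 0.5 Å by default, with
edges at `floor(min)`/`ceil(max)` padded by one bin on each side; bins are
right-open except the last, and counts always sum to the number of
contributing models. The representative model is the member of the modal
bin closest to the bin centre, ties broken by model order.

Two-state classification runs k-means (k = 2, scikit-learn, fixed
`random_state`) on the distance columns of each axis; the cluster with the
smaller mean receives the "compact" label of the axis's label pair. The
separation score is |μ₁ − μ₀| / √((σ₀² + σ₁²)/2). A fixed-threshold method
is available for pre-registered cutoffs. Fewer than 4 models is an error;
zero spread yields a single state with separation 0.

## Confidence aggregation

Motif PAE is the arithmetic mean of the PAE submatrix selected by a motif
residue range (e.g. βarr2 finger loop 64–77) against a partner range or
whole chain. Three orientations are supported — motif-on-partner (rows =
partner, columns = motif), partner-on-motif (transpose selection), and
their mean (`symmetric-mean`, the default). Means are computed with
`math.fsum`, so the result is the correctly rounded mean, independent of
summation order, and matches an exhaustive double-loop oracle exactly.
Motif and partner token sets must be disjoint. Ensemble summaries report
per-model ipTM, mean pLDDT, and one column per motif spec (plus the two
oriented variants), with mean/median/quartiles per column; two ensembles
are compared by mean difference and the normalized Mann–Whitney rank
statistic U/(n₁n₂).

## Synthetic two-state generator

Chains are idealized helical point chains (rise 1.5 Å/residue, 100°/turn,
radius 2.3 Å) laid out as 7 receptor TM segments on a 10 Å circle plus an
extracellular loop, helix 8, and a partner-chain finger-loop segment.
Selected atoms (CB, CG, OH) are radial offsets from CA. Each model draws a
state (Bernoulli, mixture weight 0.5 by default); state B rigidly displaces
designated segments (TM6, TM7, H8, finger loop) by δ = 8 Å, which moves the
designated pocket/effector pairs by 6–8 Å while a control pair stays
fixed. Per-atom isotropic Gaussian noise (σ = 0.8 Å) gives a pair-distance
noise of ≈ √2·σ ≈ 1.1 Å, so the planted separation is ≈ 6σ. Confidence
JSONs mirror the geometry: interface PAE blocks are offset by −6 for
state A versus 0 for state B (plus N(0, 0.3) noise, clamped to
[0.25, 31.75], rounded to 2 decimals), ipTM is Beta-distributed (state A ≈
0.8, state B ≈ 0.5), and pLDDT means are 88 vs 78. Default generator
parameters are fixed study conditions, not tuning knobs.

All randomness uses `numpy.random.default_rng` with the spawn key
`[root_seed, seed_index, sample_index]`, so each model's stream is
independent of ensemble size and every regeneration is byte-identical.

### Generator realism limits

The toy chains are point helices, not stereochemically valid proteins: no
side-chain rotamers, no backbone beyond CA plus a few offset atoms, no
loops connecting segments, and the state change is a rigid translation
rather than a hinge or rotamer switch. PAE is a block model with
independent Gaussian noise, whereas real PAE has strong distance-dependent
structure; pLDDT is i.i.d. around a state mean. The generator is designed
to exercise the pipeline's contracts (ingestion, superposition, distance
recovery, classification, confidence aggregation) with known ground truth,
not to imitate AlphaFold output statistically.

## Numerical and determinism choices

Coordinates are handled in float64 throughout. Rotations are validated
orthonormal with det +1 to 1e-9. Motif-PAE means use `fsum` (exact);
histogram binning uses `numpy.histogram2d` on explicitly constructed
edges. Output tables are written atomically (temp file + rename) in a fixed
column order with pandas' default float formatting; `run_summary.json`
records the sha256 hash of the canonicalized config and the seed. Rerunning
an identical config produces byte-identical outputs.

## Limitations

- Two-state classification only; mixtures of more states need the fixed
  threshold method or external clustering.
- BW codes are annotations; no automatic BW assignment from structure.
- Chain-pair ipTM requires the summary JSON to carry the table; it is not
  reconstructed from PAE.
- Per-atom pLDDT (`atom_plddts`) is not aggregated (see above).
- The optional external ensemble deposit is never fetched; all tests run
  on synthetic data.
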