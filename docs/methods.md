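# Methods

## Model and procedure

All communication statistics operate on the Cα trace of a protein,
represented as an F × N × 3 coordinate ensemble. Multi-chain complexes
are concatenated into a single 0-based residue index; chain identity is
kept per residue (the neighbour window and selections respect it) and an
optional segment label preserves monomer/domain identity for intra- vs
inter-monomer analyses.

**Communication propensity.** CP_ij is the population variance (1/F
normalisation) of the Euclidean Cα–Cα distance d_ij over frames. With
F in the hundreds the 1/F vs 1/(F−1) distinction is immaterial; 1/F is
chosen because CP is defined as a mean-square fluctuation, and the same
normalisation is used for the coordinate covariance so that
PCA-projection variances equal eigenvalues exactly. CP depends only on
internal distances, so it is rigorously invariant under per-frame rigid
motion; superposition is neither required nor harmful, and the test
suite asserts the invariance numerically (≤ 1e-9 Å²).

**Efficiency threshold.** For each residue i the CP values to sequence
neighbours j ∈ {i−w, …, i+w}, j ≠ i (default w = 4) are averaged; the
window truncates at chain termini and never crosses a chain boundary.
The threshold is the unweighted mean of these per-residue averages — a
single global scalar, with the per-residue means and term counts m
retained as diagnostics. A pair is *efficient* iff CP_ij ≤ threshold;
equality counts. The threshold's absolute value depends entirely on the
fluctuation amplitude of the input ensemble, so no particular numeric
value is meaningful outside a given dataset.

**LRCC.** The density for residue i at reference distance δ is
|{j ≠ i : efficient(i,j) and ⟨d_ij⟩ > δ}| / (N−1). The denominator N−1
makes the density a true fraction in [0, 1]. Distance gating uses the
trajectory-mean distance ⟨d_ij⟩, self-consistent with CP's averaging; a
single-frame "ensemble" built from a reference structure can be passed
to gate on crystal-structure distances instead. The default δ grid is
{20, 30, 40, 50, 60, 70} Å: the lower half probes long-range
intra-domain communication, the upper half very-long-range inter-domain
communication. ΔLRCC between states A and B is the elementwise
difference A − B at equal δ; positive values mean enhanced long-range
communication in A.

**Peak clusters.** Residues with density above mean + z·SD of the
profile (default z = 1.0), grouped into maximal contiguous runs of at
least `min_run` residues (default 3). The criterion is a package choice:
any peak rule needs a scale, and the profile's own dispersion is the
only scale available without external calibration. A flat profile
yields no clusters.

**Essential dynamics.** Frames are superposed onto a reference by
least-squares (Kabsch, proper rotations only — a mirror-image frame
retains positive residual). The 3N × 3N covariance of centered
coordinates is eigendecomposed; eigenvalues are sorted descending and
each eigenvector's sign is fixed so its largest-magnitude component is
positive. The residue cross-correlation map uses the standard
trace-of-block reduction c_ij = tr(C_ij)/√(tr(C_ii) tr(C_jj));
zero-variance residues get correlation 0 with a warning. RMSF is
computed about the ensemble mean (not the reference); per-frame RMSD is
against the reference. Segment flexibility restricts to a residue
subset, by default in the global superposition frame, optionally with
local re-superposition to isolate internal segment motion. Covariance
supports evenly spaced subsampling (e.g. 500 snapshots, the
conventional count for a production trajectory) or a stride; the frame
count used is recorded.

## Synthetic ensembles

The generators emulate, with controllable and analytically known
statistics, the features of MD ensembles that the analyses consume:

- **rigid_body** — random SO(3) rotations (uniform via normalised
  quaternions) plus Gaussian translations of one structure. Internal
  distances are invariant, so CP, the threshold, and post-superposition
  RMSF are exactly zero: the null model.
- **iid_jitter** — independent isotropic Gaussian displacement, std σ
  per Cartesian component per residue per frame. Analytic limits:
  Var(d) → 2σ² for separations ≫ σ, RMSF → σ√3. At short separations
  Var(d) is slightly below 2σ² (the norm of a noncentral Gaussian has
  reduced variance), which places distal pairs near the efficiency
  threshold — an intentional stress case for the efficiency rule.
- **gnm** — displacements drawn per Cartesian component from a zero-mean
  Gaussian with covariance scale × pinv(Kirchhoff matrix) of the contact
  graph at a cutoff (default 7.5 Å); x, y, z are independent copies
  (classic isotropic GNM). The contact graph must be connected. Because
  the three components are iid, the top coordinate-covariance eigenvalue
  is triply degenerate; spectral checks therefore compare the sampled
  top mode against the three-dimensional analytic eigenspace (norm of
  the projection), not against a single arbitrary member of it.
- **hinge** — residues beyond a split index rotate rigidly per frame
  about a fixed axis through the split residue (perpendicular to the
  local chain direction; any fixed perpendicular suffices and the choice
  is deterministic) by a Gaussian angle, then iid jitter is added to all
  residues. Two states differing only in angle σ have cross-block
  distance variances of known ordering, so the sign of their ΔLRCC is
  designed in.

Frames are independent draws — the time autocorrelation of real MD is
not emulated — and each ensemble is fully determined by one integer
seed (a single numpy Generator per call; bit-identical reruns are
asserted in the tests). Passing tests on these ensembles demonstrates
the correctness of the statistics and the recoverability of designed
effects; it says nothing about force-field accuracy, sampling
convergence, or solvent effects in real trajectories.

### Two-state hinge study conditions

The designed-effect experiment uses two compact helical domains
(ideal helix, 60 residues, split at 30; each domain extends ~44 Å),
residual jitter 0.5 Å, hinge angle σ = 2° (stiff) vs 15° (floppy),
5000 frames, δ = 50 Å. The geometry is chosen so that δ *spans the two
domains*: no within-domain pair exceeds δ, hence the LRCC at this δ
counts cross-domain communication only and the floppy state can only
lose it. The designed ordering is stiff ≥ floppy per residue
(floppy-minus-stiff nonpositive); the recovery test requires ≥ 95% of
cross-domain-participating residues to match and additionally requires
a strictly positive aggregate effect, so a degenerate all-zero
comparison cannot pass. With extended (straight-chain) domains and the
same δ, within-domain pairs beyond δ sit exactly at the efficiency
threshold under iid jitter and contribute coin-flip noise that can mask
the designed signal near the hinge — the compact-domain geometry is the
configuration the hinge generator is intended for.

## Contacts

Contacts are user-declared (no automatic interface detection): two atom
groups, a kind, and cutoffs. Per-frame distance is the minimum over
cross-pair atom distances. Defaults are conventional geometric
criteria, not fitted values: hydrogen bond — donor–acceptor heavy-atom
distance ≤ 3.5 Å, with a D–H⋯A angle ≥ 120° applied only when explicit
hydrogens exist (otherwise distance-only, with a warning); salt bridge
— minimum side-chain N/O distance ≤ 4.0 Å; generic — user cutoff (e.g.
ring-centroid ≤ 5.5 Å as a stacking proxy; ring-plane angles are out of
scope). Occupancy is the fraction of frames satisfying the criterion;
it is invariant under frame permutation and rigid motion and monotone
in the cutoff.

## Numerical choices

- Distance variances below 1e-9 Å² are snapped to zero: they are
  cancellation noise, and a rigid ensemble must behave exactly
  degenerately (zero threshold, all pairs efficient).
- LRCC distance gating excludes ties at δ with a 1e-9 Å tolerance, so
  exact geometric boundaries (a partner at exactly δ) are stable
  against rounding.
- Superposition requires ≥ 3 selected residues and rejects collinear
  selections (rotation underdetermined). Only proper rotations are
  used.
- Covariance of an apparently unsuperposed ensemble (net frame-to-mean
  rotation > 5° on a 5-frame probe) triggers a warning, not an error:
  large genuine internal motion can also trip the heuristic.
- PDB B-factor annotation scales scores linearly to 0–99.99 (the
  column's range); scale and offset are recorded in REMARK lines so the
  original values are recoverable. Residues outside the annotation get
  0. PDB coordinates round-trip at the format's 3-decimal precision.
- Alternate locations: altloc '' or 'A' kept, others discarded.
  Residues lacking a Cα are skipped with a warning (the resulting index
  shift is the documented behaviour; gap modelling is out of scope).

## Pipeline

A YAML config declares states (files or synthetic specs), the δ grid,
window, peak parameters, contacts, and a master seed; synthetic states
without an explicit seed get one derived deterministically from the
master seed and their position. The pipeline writes per-state tables
(documented TSV headers), annotated PDBs, a correlation heatmap, and
for the first two states ΔLRCC and occupancy differences
(first-listed minus second), plus a manifest listing every output with
a SHA-256 checksum. The manifest contains no timestamps, and all float
formatting is fixed, so identical config + seed reruns are
byte-identical; stage wall times go to the log only.

## Problem sizes

Default test and driver sizes (N ≤ 60 residues; F = 5000 frames for
designed-effect recovery, 20000–50000 for analytic-limit and covariance
recovery, a few hundred for identities) were chosen so that Monte-Carlo
error is comfortably inside the asserted tolerances — e.g. the CP
sampling SD at F = 20000 is ~1% of the analytic value against a 5%
band, and GNM covariance entries converge as √(2/F) against a 5% band.

## Known limitations

- Frames are treated as iid; statistical errors quoted for real,
  autocorrelated MD data would need effective-sample-size corrections.
- No trajectory unwrapping or periodic-boundary imaging; inputs are
  assumed whole molecules.
- No mmCIF output; insertion codes pass through untouched.
- Stacking interactions are approximated by centroid distance only.
- The efficiency threshold is global; systems whose domains have very
  different local stiffness may warrant per-segment thresholds, which
  the per-residue diagnostics support but the pipeline does not apply.
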