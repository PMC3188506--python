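# allocomm

Allosteric communication analysis of protein conformational ensembles —
communication propensity, long-range communication capability (LRCC)
profiles, essential dynamics, and interface-contact occupancy — for
structural biologists comparing the internal dynamics of two protein
states (wild type vs mutant, monomer vs dimer, inactive vs active).

## The statistics

Given an ensemble of F snapshots of a protein's Cα trace (from MD, a
multi-model PDB, or a synthetic generator), the **communication
propensity** of a residue pair is the variance of their Cα–Cα distance:

    CP_ij = ⟨(d_ij − ⟨d_ij⟩)²⟩        [Å², population average over frames]

Pairs whose distance barely fluctuates transmit a perturbation
consistently; pairs with large, incoherent distance fluctuations do not.
Sequence neighbours are assumed to communicate well, so the **efficiency
threshold** is the mean CP between neighbours j ∈ {i−4, …, i+4} (same
chain, window truncated at termini), averaged over residues; a pair is
*efficient* iff CP_ij ≤ threshold. The **LRCC** of residue i at a
reference distance δ is the fraction of the other N−1 residues that
communicate efficiently with it from a mean distance greater than δ
(δ ∈ {20, 30, 40} Å probes intra-domain, {50, 60, 70} Å inter-domain
communication), and **ΔLRCC** is the elementwise difference of two
states' profiles — positive values mean enhanced long-range
communication in the first state.

Alongside, the package provides **essential dynamics** (3N×3N coordinate
covariance after Kabsch superposition, dynamic cross-correlation maps,
PCA modes and projections, RMSD/RMSF flexibility profiles) and
**contact occupancy** (fraction of frames in which a declared salt
bridge / hydrogen bond satisfies its geometric criterion).

A first-class synthetic-ensemble module (rigid body, iid jitter,
Gaussian network model, two-domain hinge) generates ensembles with
closed-form ground truth, so every stage of the chain is testable
without trajectories.

## Worked example

Two states that differ only in the stiffness of a hinge between two
compact helical domains (Gaussian hinge angle σ = 2° vs 15°, residual
jitter 0.5 Å, 60 residues, split at 30):

```python
import allocomm as ac

ref = ac.make_helix_coordinates(60)
stiff  = ac.sample_hinge(ref, 30, angle_sigma=2.0,  jitter_sigma=0.5, n_frames=5000, seed=1)
floppy = ac.sample_hinge(ref, 30, angle_sigma=15.0, jitter_sigma=0.5, n_frames=5000, seed=2)

profiles = {}
for label, ens in (("stiff", stiff), ("floppy", floppy)):
    cp  = ac.communication_propensity(ens)
    thr = ac.communication_threshold(cp)                  # neighbour-window mean CP
    eff = ac.efficient_pairs(cp, thr)
    profiles[label] = ac.lrcc_profile(eff, ac.mean_distance_matrix(ens),
                                      delta=50.0, state_label=label)
    print(label, "threshold %.3f A^2  mean LRCC(50 A) %.3f"
          % (thr.value, profiles[label].densities.mean()))

rel = ac.relative_lrcc(profiles["stiff"], profiles["floppy"])
print("mean stiff-minus-floppy delta-LRCC: %.3f" % rel.deltas.mean())
```

prints:

```
stiff threshold 0.489 A^2  mean LRCC(50 A) 0.030
floppy threshold 0.494 A^2  mean LRCC(50 A) 0.000
mean stiff-minus-floppy delta-LRCC: 0.030
```

With δ = 50 Å spanning the two domains (each domain extends only
~44 Å), LRCC counts only cross-domain partners: the stiff hinge keeps
its inter-domain distances inside the efficiency threshold (mean LRCC
0.030), the floppy hinge loses them entirely (0.000), and ΔLRCC is
nonnegative everywhere — the designed effect, recovered with its sign.

The same comparison runs end-to-end from a YAML config
(`allocomm run --config run.yaml`), writing CP matrices, threshold
reports, LRCC/ΔLRCC tables, PCA results, flexibility profiles,
occupancy tables, B-factor-annotated PDBs and a checksummed manifest.
The numbered scripts under `analysis/` walk through the same story
stage by stage and write their tables under `results/`.

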