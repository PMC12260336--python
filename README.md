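# dimer-msm

Markov state model (MSM) analysis of reversible protein–protein
dimerization kinetics, built for the kind of question raised by eye-lens
crystallins: two two-domain monomers (e.g. human βB2-crystallin, whose
aggregation underlies cataract) associate and dissociate over microseconds
of coarse-grained simulation, and one wants the metastable binding poses,
their stationary free energies, and the association/dissociation rates —
for instance, how a post-translational modification such as deamidation
shifts the monomer–dimer equilibrium.

The package is aimed at computational biophysicists who have (or want to
emulate) multi-replica coordinate trajectories of a two-chain system and
need the full kinetic-analysis chain as tested, reusable components rather
than a notebook:

1. **Featurization** — the four inter-monomer domain centre-of-mass
   distances (A.Ntd–B.Ntd, A.Ntd–B.Ctd, A.Ctd–B.Ntd, A.Ctd–B.Ctd) plus the
   whole-monomer COM distance, in nm.
2. **TICA** — symmetrized time-lagged independent component analysis
   solving C_τ v = λ C₀ v, keeping components up to a cumulative kinetic
   variance (λ²-weighted) cutoff, default 95% at a 5 ns lag.
3. **Microstates & MSM** — k-means discretization (default 250 states),
   sliding-window counts on the largest connected set, and the reversible
   maximum-likelihood transition matrix T with stationary distribution π
   satisfying detailed balance π_i T_ij = π_j T_ji.
4. **Validation** — implied timescales t_i = −τ/ln λ_i and the
   Chapman–Kolmogorov test comparing T(τ)^k against models re-estimated at
   lag kτ.
5. **Macrostates & kinetics** — PCCA++ metastable coarse-graining (default
   6 states), free energies ΔG(S) = −k_B T ln Σ_{j∈S} π_j, transition path
   theory committors and reactive fluxes, and mean first passage times from
   the absorbing linear system (I − T_rest) m = τ·1.
6. **Structural observables** — binding/unbinding event detection with
   6/7 nm hysteresis thresholds, distance population fractions, inter-chain
   residue contact maps (0.45 nm cutoff, 0.75 fraction filter), and Kabsch
   RMSD.

Because production trajectories of this scale are rarely redistributable,
the package includes first-class synthetic generators — exact Markov-jump
chains with distance emissions and a toy Langevin dimerization of two rigid
two-domain bodies — whose kinetics are known exactly, so every estimator is
validated against ground truth. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Recover a planted fast-association / slow-dissociation equilibrium from one
million frames of synthetic data:

```python
import numpy as np
import dimer_msm as dm

chain = dm.association_chain()              # 6-state ground truth, ~24-fold asymmetry
labels = dm.simulate_markov_chain(chain, 100_000, 10, seed=1234)
feats = dm.emit_distance_trajectories(labels, chain, seed=1235)

tica_model = dm.fit_tica(feats, lag=1.0, variance_cutoff=0.95)
proj = dm.project(tica_model, feats)
disc = dm.cluster_microstates(proj, k=100, seed=0)
model = dm.estimate_msm(disc.labels, lag=1.0, frame_interval=1.0)
macro = dm.pcca_plus(model, 2)

bound, unbound = 0, 1                       # macrostates ordered by stationary weight
print("stationary weights:", np.round(macro.stationary_weights, 3))
print("free energies (kJ/mol):", np.round(macro.relative_free_energies(), 2))
print(f"association MFPT:  {dm.mfpt(model, macro, unbound, bound):8.1f} ns")
print(f"dissociation MFPT: {dm.mfpt(model, macro, bound, unbound):8.1f} ns")
```

Output:

```
stationary weights: [0.961 0.039]
free energies (kJ/mol): [0.   8.28]
association MFPT:      40.3 ns
dissociation MFPT:    989.8 ns
```

The bound super-basin holds 96% of the stationary probability and sits
8.3 kJ/mol (at 310 K) below the unbound state. The recovered MFPTs match
the exact values computed from the planted transition matrix
(`dm.markov_mfpt` gives 42.0 ns and 1016.9 ns) within a few percent, and
their ratio reproduces the planted ~24-fold asymmetry — binding is fast,
unbinding ~24× slower, the signature of a dimer-favoring equilibrium.

The same analysis runs config-driven from the shell, with report tables
(free energies, MFPT matrix, coarse network, CK test), figures, and a
manifest recording every seed:

```bash
dimer-msm fit --out report/ --n-microstates 250 --msm-lag-ns 5.0
dimer-msm report --report-dir report/
```

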