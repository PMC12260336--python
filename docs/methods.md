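# Methods

## Scope and model

`dimer_msm` implements the kinetic-analysis chain used to characterize
reversible protein–protein dimerization in long coarse-grained simulations
of two-domain proteins such as human βB2-crystallin: distance featurization
→ TICA → k-means microstates → reversible Markov state model (MSM) →
PCCA++ metastable macrostates → Chapman–Kolmogorov (CK) validation →
stationary free energies, transition-path-theory (TPT) committors/fluxes and
mean first passage times (MFPTs). Because production trajectories of that
kind are rarely redistributable, the package ships synthetic generators with
exactly known kinetics, so every estimator can be validated against ground
truth rather than against another implementation.

Units are fixed package-wide: nm for distances, ns for times, K for
temperature, kJ/mol for free energies. PDB files (Å) are converted to nm on
load.

## Featurization

The kinetic feature set is the four inter-monomer domain centre-of-mass
(COM) distances in the fixed order (A.Ntd–B.Ntd, A.Ntd–B.Ctd, A.Ctd–B.Ntd,
A.Ctd–B.Ctd), plus the whole-monomer COM distance for event detection and
population histograms. COMs are mass-weighted by default (`mass_weighted=False`
switches to geometric); terminal-arm beads (`domain == "arm"`) are excluded
from domain COMs — the feature is the distance between the globular N- and
C-terminal domains — but do contribute to whole-chain COMs. Intra-monomer
domain distances are not computed by default; the feature describes the
inter-monomer geometry that distinguishes binding poses. All features are
invariant under global rotation/translation of a frame and transform under a
chain A↔B relabeling by the documented column permutation (0,2,1,3).

## TICA

The estimator is the symmetrized (reversible) one: means and instantaneous
covariance C0 are accumulated over *both* ends of every lagged frame pair,
and the time-lagged covariance is averaged with its transpose. This
guarantees a real spectrum and makes the fit exactly invariant under time
reversal of the data; it assumes the underlying dynamics are reversible,
which holds for equilibrium simulations and for every generator in this
package. C0 is regularized by discarding directions whose C0 eigenvalue
falls below 1e-10 of the largest (degenerate features must not break the
whitened solve). Kinetic variance of component *i* is defined spectrally as
λᵢ²/Σλⱼ²; components are kept until the cumulative kinetic variance reaches
the configured cutoff (default 0.95). The standard lag is 5.0 ns; lags are
converted to frames by nearest-frame rounding with a logged warning when
inexact.

## Microstates and the reversible MSM

Discretization uses k-means (k-means++ initialization, Lloyd iterations,
seeded; scikit-learn backend). The standard configuration is 250
microstates; planted-chain validation uses 50–100, which is dense relative
to those chains' 6 hidden states.

Transition counting is sliding-window at lag τ, pooled over replicas and
never across replica boundaries — sliding-window uses all the data at the
cost of correlated counts, which only affects error bars, not the estimate.
Estimation is restricted to the largest strongly connected component of the
count graph (ties broken by total counts); the fraction of counted
transitions covered is reported.

The reversible maximum-likelihood transition matrix is obtained by the
standard self-consistent iteration on the symmetric flow x_ij = x_ji,

    x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j),

iterated until the maximum relative change drops below 1e-10 (hard cap 1e6
sweeps, error on non-convergence). At the fixed point T_ij = x_ij/x_i
satisfies detailed balance exactly and π_i ∝ x_i; π is additionally verified
to be the leading left eigenvector to 1e-8. Spectral quantities use the
√π-similarity transform, which makes the problem symmetric and the spectrum
exactly real.

Implied timescales are t_i = −τ/ln λ_i (NaN and a log message for
non-positive eigenvalues). The CK test compares, for each macrostate set I,
the model prediction Σ_{i∈I} π_i [T(τ)^k 1_I]_i / π(I) against the same
quantity from a model re-estimated at lag kτ; uncertainty bands use the
binomial normal approximation √(p(1−p)/N_I) with N_I the transition pairs
leaving I at lag kτ. Factors whose lag exceeds the replica length are
dropped with a warning.

Stationary free energies of a state group S are ΔG(S) = −RT ln Σ_{j∈S} π_j
with R·T in kJ/mol (T defaults to 310 K); only differences are physical, and
the report also lists values relative to the most stable macrostate. Empty
groups get +∞ and a warning.

## PCCA++ and kinetics

PCCA++ uses the n dominant right eigenvectors (first column fixed to the
exact constant), an inner-simplex vertex search (farthest-point
orthogonalization), and the linear transform onto barycentric coordinates,
clipped at zero and row-renormalized. The crisp partition is the row argmax.
Macrostates are renumbered by descending stationary weight, since any
figure-specific numbering is arbitrary. The method is deterministic given
the model; a warning is emitted when the requested number of macrostates
exceeds the positive part of the spectrum.

Macro-level MFPT is defined as the stationary-weighted average of microstate
first-passage times over the source's crisp set, with the target's crisp set
absorbing: (I − T_rest) m = τ·1, then Σ_{i∈src} π_i m_i / Σ_{i∈src} π_i.
Crisp sets are used for all MFPT/flux computations; fuzzy memberships are
retained for reporting. The same aggregation applied directly to a planted
transition matrix (`markov_mfpt`) supplies ground-truth values, so recovered
and true MFPTs are always compared like for like.

Committors solve the standard harmonic system (q⁺ = 0 on A, 1 on B); the
backward committor uses the reversible identity q⁻ = 1 − q⁺. Gross flux is
f_ij = π_i q⁻_i T_ij q⁺_j, net flux its positive antisymmetric part, and the
A→B rate the net reactive flux out of A divided by τ·Σ_i π_i q⁻_i. The
coarse network reports P_IJ = Σ_{i∈I,j∈J} π_i T_ij / π(I) over crisp sets.

## Event detection, populations, contacts, RMSD

Binding/unbinding events on the monomer COM distance use dual hysteresis
thresholds, enter-bound < 6 nm and enter-unbound > 7 nm: frames inside the
band keep the previous state, so events strictly alternate and threshold
chatter is impossible. Initial in-band frames are labelled "intermediate"
until the first crossing. Population fractions are P(d < 6), P(d > 7) and
the in-band remainder, which sum to one exactly.

When the config-driven pipeline runs from emitted distance features rather
than coordinates (the Markov generator produces domain distances only), the
event/population stage uses the mean of the four inter-domain distances as
its monomer-distance proxy; with coordinate ensembles the true
mass-weighted monomer COM distance is used instead.

Residue–residue contacts between chains use the minimum inter-bead distance
per residue pair with a 0.45 nm cutoff; the contact fraction is the fraction
of frames in contact, and pairs are reported above a 0.75 fraction
threshold. RMSD uses Kabsch superposition (SVD with the determinant
correction enforcing a proper rotation) over an optional chain/domain
selection.

## Synthetic generators

**Markov-jump chains with distance emissions.** A `GroundTruthChain` holds a
row-stochastic matrix, a lag step (ns), per-state mean 4-vectors of
inter-domain distances, and a shared Gaussian emission width truncated at
zero. Gaussian emissions with shared σ are the simplest model under which a
fine discretization can recover the hidden states. Initial states are drawn
from the stationary distribution so empirical occupancies are stationary
from frame one; `start_unbound=True` instead starts every replica in an
unbound state, mimicking a dissociated initial condition (whether real
replicas share identical starting coordinates is protocol-dependent, so both
options are exposed).

The default `association_chain()` is the package's planted study system: six
states — two unbound (emissions above 7 nm; state 1 is the encounter
gateway) and a four-state bound basin (emissions below 6 nm, pairwise mean
separation ≥ 2.3 nm against σ = 0.35 nm, so state overlap is negligible) —
built from a symmetric weight matrix, hence reversible by construction. Its
basin depths plant a fast-association / slow-dissociation asymmetry:
association MFPT 42.0 steps, dissociation 1016.9 steps, ratio ≈ 24 — the
same direction and magnitude of asymmetry reported for deamidated
βB2-crystallin dimerization. The weights were designed once from the exact
MFPT solve; the package never hard-codes the resulting MFPTs, always
recomputing them from the matrix.

**Toy Langevin dimerization.** Two rigid bodies (each two bead-cluster
domains; internal flexibility is not the object of study) undergo overdamped
translational Euler–Maruyama dynamics in a reflecting cube. The pair
potential is a flat-bottom well of depth `well_depth` (kT) inside
`contact_radius`, returning to zero over a linear ramp of width
`ramp_width` (default 0.5 nm) — the ramp exists because a discontinuous
well exerts no force under Euler–Maruyama; all analytic checks integrate the
actual ramped potential. Rotational diffusion is omitted: with a radially
symmetric pair potential it would not change the COM-separation kinetics.
Replicas start at 8.0 nm COM separation (clipped into the box). A step
displacement exceeding the box size raises a stability error. Defaults
(D = 0.5 nm²/ns, dt = 0.02 ns, contact radius 1.5 nm, box half-width 5 nm)
give a few binding/unbinding events per 10⁴ steps at moderate well depths.

## What the generators do and do not emulate

They reproduce the statistical structure the estimators rely on: two
well-separated timescales, reversible dynamics, multi-replica bookkeeping
(15 × 5 μs = 75 μs in the standard configuration), distance observables
with bound (< 6 nm) and unbound (> 7 nm) populations. They do not emulate
force-field energetics, internal protein flexibility, solvent, or
electrostatics, and emission noise is i.i.d. given the state, whereas real
trajectory features decorrelate smoothly. Passing tests therefore
demonstrate correctness of the estimators and pipeline plumbing — not that
any particular biological system satisfies MSM assumptions.

## Problem sizes and numerical choices

Validation workloads were sized so the statistical claims are sharp at
moderate cost: 10⁶ steps for estimator recovery (entrywise error ≲ 1e-3
against a planted 3-state matrix), 10⁶ frames (10 replicas × 10⁵) for
full-pipeline MFPT recovery (observed errors ≲ 5%, asserted at 20%), 10⁵
Monte Carlo paths for the MFPT oracle (3-SE agreement), 2×10⁵ frames for the
AR(1) TICA test (|r| > 0.99 with analytic eigenvalues φ^lag). Stochastic
tests fix seeds; tolerances are derived from binomial/CLT standard errors
where a rate is estimated, and set to 1e-8..1e-12 where an identity is
exact.

Known limitations: no Bayesian/posterior uncertainty on T or MFPTs, no
hidden-Markov or Koopman variants, no pathway decomposition of reactive
flux, and the PCCA++ variant is the deterministic linear-transform one
(no simplex-volume optimization refinement).
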