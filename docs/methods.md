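# Methods

`coevocv` implements a pipeline for discovering collective variables (CVs)
from sequence coevolution and analysing the enhanced-sampling simulations
run along them. The molecular-dynamics engine itself is out of scope: the
toolkit emits the engine's configuration (pull and adaptive-bias
parameter fragments) and consumes its outputs (distance time series and
per-walker histograms).

## Coevolution model

Aligned sequences are modelled by a Potts Markov random field over the 20
amino acids plus an explicit gap state (q = 21),

    P(s) ∝ exp( Σ_i v[i, s_i] + Σ_{i<j} w[i, j, s_i, s_j] ),

with fields `v` and couplings `w` symmetric under the simultaneous swap
of positions and states. Because the partition function is intractable,
the fit maximises the *pseudo*-likelihood: the product over positions of
the conditional probability of each state given the rest of its
sequence, normalised per position. Preprocessing follows standard DCA
practice: columns with more than 20% gaps are removed (a `column_map`
preserves original numbering) and each sequence is down-weighted by
1/N, where N counts its neighbours above 90% identity (self included,
strictly greater than). The weighted negative log pseudo-likelihood is
minimised by full-batch Adam with an analytic gradient (verified against
central finite differences to ~1e-9 relative error). An L2 penalty is
applied to both blocks; the pair-block strength defaults to
`0.01·(L−1)·q` relative to the field penalty, the usual
pseudo-likelihood-DCA scaling.

**Initialisation.** The defaults (`iterations=300`, `learning_rate=1e-4`,
standard-normal initialisation) are deliberately conservative, but note
that Adam's step size bounds total parameter motion by roughly
`lr · iterations ≈ 0.03`, far below the O(1) noise a standard-normal
start puts into the ~L²q² coupling entries. For coupling *recovery* the
package therefore recommends — and its own pipeline and verification
scripts use — `init="zeros"` (the independent-columns model) with
`learning_rate=0.05`. On Gibbs-sampled alignments with planted
couplings (L=20, 10 disjoint pairs, 2 000 sequences) this recovers all
ten pairs in the top-10 scores.

**Scores.** Couplings reduce to one scalar per pair over the 20×20
amino-acid block only (the gap state is modelled but never scored). The
default reduction is the Frobenius norm — a signed sum can cancel;
`abs_sum` is available. The average product correction subtracts
`mean_i · mean_j / mean` from each entry, with means taken over the full
matrix: this annihilates any rank-1 background exactly and makes the
correction idempotent (a corrected matrix has zero row means and passes
through unchanged, guarded by a zero-mean early return). The score map
zeroes its diagonal afterwards; self-pairs are undefined.

## Structure overlay and pull coordinates

Contacts are defined on minimum inter-residue heavy-atom distances; the
default cutoff (5.5 Å) and minimum sequence separation (5) are common
contact-prediction-benchmark conventions and deliberately exposed as
mandatory parameters — the choice materially affects which pairs count
as "false positives" and should be user-explorable. MSA columns map to
structure residues through a global pairwise alignment (BLOSUM62) of the
ungapped query against the structure sequence, rejected below 90%
identity over the aligned span.

Among the top-2L APC scores, pairs not in structural contact are the
false positives: candidate contacts of an alternative conformational
state. They are clustered on their 1-D score distribution — cluster
count by mean shift, assignment by seeded K-means, clusters relabelled
by descending mean score. Each cluster becomes one pull coordinate: a
weighted mean of its pair distances with weights proportional to APC
scores (a uniform-weight mode gives the plain mean; both are exposed
because either weighting is defensible), per-contact force constant
200 kJ mol⁻¹ nm⁻², target 0.2 nm. Duplicate listings of a pair merge
before renormalisation, so coordinates are invariant to duplication.

Exported configuration uses the GROMACS `.mdp` key=value dialect and
round-trips byte-identically through the bundled parser. Adaptive-bias
defaults: 4 walkers sharing one bias, cover diameter 0.4 nm, energy
cutoff 120 kJ/mol, 10 steps per sample and 10 samples per update, growth
factor 2.0 (prolonging the initial stage before the Wang–Landau
refinement), CV windows 0.4–1.3 nm and 0.3–1.0 nm, and per-condition
force/diffusion constants from a packaged table (10 000 kJ mol⁻¹ nm⁻²
throughout; diffusion 0.0005–0.005 nm² ps⁻¹ by ligand).

## CV refinement

Given two ensembles (reference vs explored) described by the same pair
distances, a linear-kernel SVM (C = 1.0, inverse-frequency class
weights) separates them after per-feature z-scoring; standardisation is
needed because raw distances differ in scale, and it makes the top-k
ranking invariant to rescaling any feature. Coefficients are reported
in standardised space with the scaler stored. The top 20 pairs by
|coefficient| (ties broken by pair identity for reproducibility) split
by sign into two CVs; weights are |coefficient| renormalised to sum to
one per CV, so each CV responds monotonically to increasing distances.
The solver tolerance is tightened to 1e-7 so that swapping the ensemble
labels negates the separator to ~1e-6 — the max-margin problem is
exactly antisymmetric, an iterative solver only approximately so.

## Free-energy analysis

With a converged (nearly static) bias, frames are binned along the CV
and each bin's free energy is `U = −RT ln(count/total)`, anchored so the
lowest visited bin is zero. RT defaults to 2.4790 kJ/mol (298.15 K) and
is configurable. Never-visited bins are masked, never zero-energy, and
the surface records a *detection-limit* energy (`energy_cap`,
−RT ln of the smallest observable mass): an unvisited bin is known to
lie at or above it.

Projection onto a new observable Y: every frame carries its share of its
source bin's Boltzmann mass, `w_t = exp(−U_bin/RT)/n_bin`; the masses
accumulate into Y-bins and convert back to energies `−RT ln(mass)`,
re-anchored. This conserves total Boltzmann weight exactly and makes
projection onto the original CV with the original binning the identity.
The alternative per-bin aggregation (plain `exp(−U_t/RT)` sums without
the bin-count share) is available by omitting the counts; it is
appropriate when the frame energies come from an external estimator
rather than from the binned histogram itself.

**Basins.** Visited bins descend to their lowest neighbour (4-connected
in 2-D, ties towards the smaller flat index) until a fixpoint; bins
sharing a fixpoint form a watershed basin. Border bins whose discrete
second difference is negative along every defined axis — concave
shoulders and barrier tops — are released, approximating an
inflection-point border on the grid; the trim is restricted to
watershed borders because on sampled surfaces count noise makes
interior curvature signs meaningless. Basins under 3 bins are discarded
and their bins left unassigned. A surface with no strict minimum is one
basin. Populations are Boltzmann weights of basin bins, normalised over
assigned bins only. On 2-D surfaces, basins can additionally be tagged
by CV-space quadrant (R upper-right, A1 lower-left, A2 lower-right, I
upper-left), mirroring the convention that the contacted (low-CV)
corner is the activated one.

**Functional labels.** A basin's frames are superposed onto an active
reference (Kabsch, via `scipy`'s `Rotation.align_vectors`) on an
alignment selection (default: all shared atoms, typically Cα), then the
RMSD over a separate selection — for a GPCR, the TM6 helix, residues
269–298 by default (a 266–298 variant appears in the literature; the
range is configurable and logged) — is averaged over frames. Strictly
below 3.0 Å means active; exactly at the cutoff is resting.

**Energetic coupling.** For a 1-D profile with at least two strict local
minima, the coupling is the highest barrier separating any two minima
minus the global minimum; unsampled bins between minima count as the
detection-limit energy (an unsampled barrier is at least that high).
Profiles with fewer than two minima couple nothing (0 kJ/mol).

## Convergence diagnostics

When an adaptive bias has converged, the effective Hamiltonian is flat,
so the sampled histogram should match the target distribution; the
per-bin deviation is `−RT ln(p̂_i/target_i)`. The 80% equilibration rule
is reported in both defensible readings (every visited bin ≥ 80% of its
share; mean ratio ≥ 80%). Transition counts between frames feed a
neighbour-edge imbalance `|n_ij − n_ji|/(n_ij + n_ji)` (4-connected on
2-D grids; imbalance and flatness deviation are reported separately
rather than combined by an invented conversion). Walker overlap counts,
per bin, the walkers whose own normalised density strictly exceeds 10%
of the across-walker mean density; empty walkers are excluded with a
warning.

## Coupling networks

Every eligible residue pair — by default, minimum distance under 0.6 nm
in at least 5% of frames, since a pair that never approaches contact
cannot report on the conformational change — contributes one projected
1-D profile; its energetic coupling is the edge weight of an undirected
residue graph. Edges at or below RT are dropped: sub-thermal barriers
are not metastability, and bin-count shot noise (~RT/√n per bin) can
fake shallow double wells. Strong coupling should make communication
cheap, so Dijkstra and betweenness centrality run on edge costs
`1/(coupling + 1e-6)` (a `max − coupling` transform is available; both
are recorded in the report). Sources and sinks are runtime parameters.
Condition comparison uses mean-centred PCA on per-residue total
coupling vectors (adjacency row sums) over the union of residues,
missing entries zero.

## Synthetic ground truth

The generator module produces every input the analysis consumes, with
known truth, as pure functions of seed and spec:

- **MSAs**: one independent Gibbs chain per sequence, uniform random
  start, 100 full sweeps of burn-in by default. Planted couplings favour
  identical amino acids at a pair (`w[i,j,a,a] = strength`, gap state
  uncoupled), strength 1.0 by default — strong enough to dominate
  finite-sample noise at 2 000 sequences yet far from deterministic.
- **Toy structures**: CA-only point residues (no chain connectivity)
  embedded by seeded penalty minimisation so requested contacts sit at
  4 Å and all other pairs beyond 12 Å; infeasible patterns (a contact
  chain bounding a non-contact pair below the floor) are rejected by a
  shortest-path check before optimisation.
- **Two-state trajectories**: Metropolis sampling of a double well
  `U(x) = h(x²−1)² + Δ·[x>0]` (default h = 10 kJ/mol ≈ 4 RT, a
  realistic conformational barrier). The step offset makes the
  ground-truth well odds exactly `exp(Δ/RT)` (quadrature over each
  half-line confirms it). Proposals mix local Gaussian steps
  (σ = 0.35) with 20% reflection moves (x → −x + noise) — a symmetric
  mixture, so detailed balance holds — chosen so the occupancy
  estimator at 10⁵ frames has a standard error of about 0.004.
  Informative pair distances follow the latent coordinate affinely
  (0.85 + 0.25·x nm plus bounded uniform noise, clipped at zero); noise
  pairs fluctuate independently. The linear latent-to-distance map
  keeps the planted CV exactly linear, so max-margin recovery is exact
  in expectation.
- **Walker histograms**: deterministic counts with controllable
  defects. A planted half-density bin redistributes its deficit over
  the other bins, so its sampled-to-target ratio is exactly ½ and the
  flatness deviation there is exactly RT ln 2.

What the generators do *not* emulate: force-field physics, correlated
multi-pair kinetics, membrane/ligand chemistry, alignment phylogeny
(sequences are exchangeable draws from the Potts model). Passing tests
therefore certify the inference and analysis machinery — estimator
correctness, ranking behaviour, closed-form limits — not performance on
real evolutionary or simulation data.

## Problem sizes and numerical choices

The bundled verification (test suite and `scripts/acceptance.py`) runs
the Potts recovery at L = 20, q = 21, 2 000 sequences and 300 Adam
iterations; the population recovery at 10⁵ Metropolis frames and 50
bins; the classifier recovery at 52 pairs with ~4 000 frames per
ensemble; and the graph oracles on 100 random graphs of ≤ 8 nodes,
sizes at which the independent oracles (finite differences, quadrature,
exhaustive path enumeration) are exact and fast. Degenerate inputs have
defined behaviour throughout: all-gap alignments and empty pair lists
raise; an all-zero score matrix passes APC unchanged; flat surfaces
yield one basin and zero coupling; unreachable sinks are reported, not
raised. All stochastic entry points take explicit seeds and are
deterministic given them.

## Known limitations

- The inflection-border rule is a grid heuristic; a Gaussian-mixture
  density model (as in mixture-based basin detection) would be the
  natural extension for smooth, low-noise surfaces.
- Pseudo-likelihood DCA only; no mean-field or Boltzmann-machine
  alternatives, and no MSA construction.
- `project_fes` assumes the converged-bias regime in which the binned
  histogram is a faithful free-energy estimate; it is not a multi-
  ensemble reweighting estimator (no WHAM/MBAR).
- The exploration loop (steer → classify → re-bias) is supported one
  round at a time; automated iteration is left to the user.
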