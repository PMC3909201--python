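# Methods

## The model

`gofrust` implements a coarse-grained, structure-based (Gō-like) model of
protein folding with optional energetic frustration.  The chain is reduced
to its Cα trace; the native structure supplies every equilibrium quantity.
The potential, in reduced units (energy ε = 1, k_B = 1, bead mass m = 1,
lengths in Å), is

    E = Σ K_b (r − r0)²                              bonds
      + Σ K_a (θ − θ0)²                              angles
      + Σ [K1 (1 − cos(φ − φ0)) + K3 (1 − cos 3(φ − φ0))]   dihedrals
      + Σ_(i,j)∈NC  e_ij ε [5 (r0ij/r)¹² − 6 (r0ij/r)¹⁰]    native contacts
      + Σ_(i,j)∈NNC ε (σ/r)¹²                        excluded volume
      + Σ_(i,j)∈F   ε_f [(C_f/r)¹² − 2 (C_f/r)⁶]     frustration (optional)

* **Native contacts (NC)** — residue pairs, separated by at least 4
  positions in sequence, whose minimum heavy-atom distance in the native
  structure is below 5.5 Å.  The 12–10 well acts on the Cα–Cα separation
  with its minimum at the *native Cα–Cα distance* r0ij; detection and
  interaction operate on deliberately different length scales, since the
  bead model has no side chains to act on.  Well depths carry
  Miyazawa–Jernigan (MJ 1996, Table 5) flavoring: e_ij ∝ |MJ(a_i, a_j)|,
  rescaled so the mean over the contact list is exactly 1.  A 12–6 contact
  form is available (`contact_form="12-6"`).
* **Excluded volume (NNC)** — all non-native pairs at or beyond the same
  sequence separation.  The power law is truncated and energy- and
  force-shifted to zero at the contact cutoff (5.5 Å).  Because every
  non-native pair is at least 5.5 Å apart in the native state (its minimum
  heavy-atom distance — which bounds the Cα–Cα distance from below —
  exceeds the cutoff by definition), the native configuration is an exact
  stationary point of the frustration-free potential.  Setting
  `repulsion_cutoff=None` restores the untruncated (σ/r)¹² law.
* **Frustration (F)** — non-native pairs whose residues are both
  hydrophobic (default set: Ala, Val, Leu, Ile, Met, Phe, Trp, Cys) attract
  through a 12–6 well of depth ε_f with its minimum at C_f = 5.5 Å, the
  same length that defines a native contact.  A frustration pair is
  governed by this term *instead of* the plain repulsion (the 12–6 form
  carries its own core); with frustration disabled or ε_f = 0 the pair
  reverts to plain repulsion, recovering the conventional Gō model exactly.

Default constants: K_b = 100 ε/Å², K_a = 20 ε/rad², K1 = 1 ε, K3 = 0.5 ε,
σ = 4 Å, ε_f = 0.2 ε.  These are the standard Cα Gō-model values of the
Clementi–Onuchic lineage; ε_f is deliberately weak relative to the unit
native-contact depth, consistent with a minimally frustrated landscape, and
is the natural sweep parameter.  All are exposed in `ModelParameters` and
logged with each run.

Forces are exact analytic gradients (verified against central finite
differences at 1e-5 relative tolerance on random configurations); the
angle gradient guards collinear geometries (sin θ floored at 1e-8) and the
dihedral gradient guards degenerate normals.

## Dynamics

Underdamped Langevin dynamics with the BAOAB splitting, dt = 0.005 τ and
γ = 1/τ by default (high-friction but inertial; an instability guard aborts
when any coordinate moves more than 1 Å in one step).  The integrator
satisfies equipartition and the Boltzmann distribution on analytic test
systems (free particle, harmonic well) to statistical accuracy.  All
randomness flows from a single integer seed: per-window generator seeds are
derived with `numpy.random.SeedSequence`, making every snapshot stream
bit-reproducible.

## The adaptive-temperature protocol

Locating the collapse temperature T_θ normally requires scanning many long
constant-temperature runs.  The adaptive protocol instead adjusts the
temperature on the fly: after every window of N_T steps, the histogram of
the native-contact count Q (bin width 1) is inspected; if the non-native
side outweighs the native side the temperature drops by ΔT, in the opposite
case it rises by ΔT, and exact ties are broken randomly.  T_θ is then
estimated as the mean window temperature after discarding the first 30% of
windows (burn-in), with a standard error over windows.

Design choices made where the procedure is genuinely open:

* **Which histogram drives the decision.**  The default is the cumulative
  (up-to-now) histogram; a per-window variant (`cumulative=False`) exists
  for sensitivity analysis.  The cumulative controller is an integral
  controller: it converges in the sense that the *accumulated* occupancies
  of the two basins equalize, while the instantaneous temperature executes
  slow bounded oscillations around the coexistence point.  T_θ estimates
  therefore carry a seed-to-seed spread set by how many oscillation periods
  the post-burn-in average covers (about 10% at the run lengths used here).
* **How the two sides are weighed.**  The protocol's goal is an equal
  opportunity to stay in either state, so the default compares the total
  occupancy (mass) of the two basins on either side of the valley
  (`compare="mass"`); comparing raw peak heights (`compare="peak"`) is
  available but biased toward whichever basin is narrower.
* **Peak and valley location.**  The histogram is smoothed with a 3-bin
  moving average; the second mode is the bin of maximal prominence
  (min(two peak heights) − deepest intervening bin), and the valley is the
  deepest bin strictly between the modes.
* **Unimodal windows.**  When no two-mode structure exists yet, the lone
  mode is classified against a native anchor at 0.75·NC: a mode below it is
  a (partially) unfolded population → cool; above it → heat.  The naive
  midpoint NC/2 misclassifies systems whose unfolded state retains local
  structure (e.g. undocked-but-helical states at ~0.6·NC).
* **Floor.**  The temperature never drops below ΔT.
* **Two T_θ estimators.**  `estimate_T_theta` averages the post-burn-in
  window temperatures (the direct protocol definition); its seed-to-seed
  spread is limited by how many controller oscillation periods the average
  covers (~10% at the bundled run lengths).  `transition_temperature`
  instead averages the instantaneous temperature over the transition-state
  snapshots — the temperatures at which barrier crossings are actually
  visited — which is insensitive to the oscillation phase and reproducible
  to ~4% at the same run lengths.  The latter is used wherever a single
  coexistence temperature must be handed to a follow-up simulation.

Defaults: ΔT = 0.005, N_T = 50 000 steps, T_init = 0.5 for the bundled toy
system.  At publication scale the protocol uses windows long enough to
equilibrate within each window; the desk-scale defaults here are the result
of a stability study across window sizes and ΔT values.

## Transition-state-ensemble analytics

* **Kept contacts.**  A native contact is kept in a snapshot when the
  Cα separation satisfies r ≤ 1.2·r0 (λ configurable; boundary inclusive).
* **Free-energy profiles.**  F(Q) = −k_B·T_avg · ln P(Q) on populated bins
  of width 1, offset to zero at the minimum; T_avg is the estimated T_θ.
* **TSE selection.**  The TSE comprises snapshots whose Q falls strictly
  between the two P(Q) peaks, restricted to populated bins within
  δ = 0.5·k_B·T_avg of the barrier top (the highest populated free-energy
  point between the peaks).  Unimodal traces raise a selection error rather
  than returning an arbitrary window.
* **φ-values.**  φ_i = ⟨N_i⟩_TSE / N_i^native with N_i the number of kept
  contacts incident on residue i.  Residues without native contacts are
  reported as undefined (NaN) and excluded pairwise from correlations and
  increment statistics, never imputed as zero.
* **h_p tables.**  For two TSEs (conventional vs frustrated), Δprob_ij is
  the change in each contact's probability of being kept.  h_p counts the
  contacts with Δprob ≥ p, resolved by unordered secondary-structure
  element pair (user-declared residue ranges; intra-element contacts count
  once on the diagonal).  h_p is non-increasing in p by construction.  A
  signed variant (count of Δprob ≥ p minus count of Δprob ≤ −p) is also
  reported, since decreased-probability contacts are informative and a
  signed reading of tabulated values is otherwise irrecoverable.
* **Rounding in reports.**  φ statistics to 2 decimals, h_p as integers.

## Synthetic test systems

**Tip-docking helical hairpin.**  The bundled fixture is a 27-residue
two-helix protein built from ideal geometry (Cα helix: rise 1.5 Å/residue,
radius 2.3 Å, 100°/residue; full backbone + Cβ placed from local frames
with standard bond lengths).  Its architecture is designed for genuine
two-state thermodynamics under the default model:

* the helix bodies are Leu/Lys-rich, giving strong intra-helix (i, i+4)
  contacts that keep the helices folded through the docking transition;
* the two chain termini carry Ser/Lys "docking tips" whose mutual contacts
  are MJ-weak (weights ≈ 0.3–0.8), so helix docking equilibrates at a
  temperature where the helices themselves are stable;
* the hinge is splayed by 30°, so the helices touch only at the tips —
  this removes the progressive zipping pathway from the loop outward that
  otherwise makes small hairpins fold downhill with no free-energy barrier.

The result is a bimodal P(Q) near T ≈ 0.45 (undocked basin at Q ≈ 16/27
with intact helices, docked basin at Q ≈ 24–27), a genuine barrier, and
frequent round trips — the minimal system on which TSE selection,
φ-analysis and the adaptive-temperature protocol are all exercisable in
seconds.  What it does *not* emulate: side-chain packing, a hydrophobic
core with dozens of long-range contacts, rugged unfolded-state structure,
or the contact density (NC ≈ 2–3 per residue) of real proteins — so
passing tests demonstrate the correctness of the machinery, not
quantitative transferability to crystal-structure inputs.

**Asymmetric double well.**  A 1-D Langevin particle in a piecewise
quartic potential, C¹ at the barrier top: the right ("native") well is
deeper but narrower, so a finite temperature exists at which both wells are
equally populated.  The equilibrium occupancies have a quadrature closed
form, giving an independent oracle for the adaptive-temperature controller.
Snapshots map onto a two-level Q histogram (0 or 10), exercising the same
histogram/update interface as the folding simulator.

## Numerical choices and degenerate inputs

* Histogram bin width is fixed at 1 contact; profiles are only defined on
  populated bins.
* Ties in peak finding resolve to the lowest-index bin; the random
  tie-break in the temperature update draws from the run's seeded
  generator stream.
* Structures with alternate locations resolve to the highest-occupancy
  conformer; insertion codes are flattened to sequential 1-based indices.
* Native Cα–Cα bond lengths outside 2.5–4.5 Å (chain breaks) are rejected
  at topology construction.
* Mutation to alanine requires a Cβ atom; glycine targets are an explicit
  error rather than a silent no-op.
* Unknown residue types take raw MJ magnitude 1 before normalization, with
  a logged warning.

## Problem sizes used in the bundled analyses

The packaged studies run the 27-residue toy system with 5×10⁴-step
adjustment windows, 6×10⁶ steps per adaptive trajectory and five random
seeds per protocol arm; these sizes give stable TSEs of 10³–10⁴ snapshots
and φ-profile correlations that are converged to the second decimal.
Constant-temperature cross-checks near coexistence use two-sided sampling
— one leg started from the native state and one from an unfolded snapshot
of the adaptive run, pooled — since a single 3×10⁶-step trajectory visits
both basins only stochastically (the toy's folding round-trip time is of
order 10⁶ steps).

## Known limitations

* The cumulative-histogram controller's temperature trace oscillates
  (integral control); T_θ estimates are reproducible to ~10% at the bundled
  run lengths, tightening with run length.
* The MJ weighting uses absolute contact energies as magnitudes; residue
  pairs with near-zero MJ energy (e.g. Lys–Lys) receive near-zero native
  well depths, which is a modelling choice inherited from the weighting
  scheme, not a statement about real energetics.
* Reduced units throughout; the mapping τ ≈ 1.47 ps (average residue mass
  119 amu, 3.8 Å Cα spacing, folding temperature calibration) is reported
  as metadata only and never used in computation.
* No solvent, no electrostatics, no side-chain degrees of freedom; no
  automatic secondary-structure assignment (segments are user-declared).
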