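# gofrust

Coarse-grained Gō-model protein folding with energetic frustration:
structure preparation, adaptive-temperature Langevin sampling, and
transition-state-ensemble (TSE) analytics at residue resolution.

`gofrust` is for people who study how a protein's native-contact network
shapes its folding — the audience that runs structure-based (Gō-like)
folding simulations and reads the results through φ-values and free-energy
profiles along the folding coordinate Q.

## What it computes

The chain is reduced to its Cα trace; the native structure defines the
model.  The potential combines harmonic bonds/angles, a two-term dihedral,
a 12–10 Lennard-Jones well of depth e_ij·ε for every native contact
(residue pairs with minimum heavy-atom distance < 5.5 Å, weights e_ij from
Miyazawa–Jernigan contact energies normalized to ⟨e_ij⟩ = 1), excluded-
volume repulsion elsewhere, and — optionally — *energetic frustration*:
non-native hydrophobic residue pairs attract through a 12–6 well of depth
ε_f centred at C_f = 5.5 Å.

On top of the model:

* **Adaptive-temperature sampling.**  Instead of hunting the collapse
  temperature T_θ with temperature scans, the simulation adjusts T by ±ΔT
  every N_T steps so that folded and unfolded states are visited with equal
  opportunity; T_θ falls out as the post-burn-in average.
* **TSE analytics.**  Q histograms; apparent free energy
  F(Q) = −k_B·T_θ·ln P(Q); TSE = snapshots in the valley between the two
  P(Q) peaks; per-residue φ-values φ_i = ⟨N_i⟩_TSE / N_i^native; per-contact
  probability changes between two models; representative native-contact
  numbers h_p resolved by secondary-structure element pair.
* **Structure utilities.**  PDB parsing, in-silico side-chain truncation
  (X→Ala), Kabsch RMSD matrices.

See `docs/methods.md` for the full model description, parameter defaults
and design decisions.

## Worked example

```python
import numpy as np
from gofrust import (
    ToyProteinSpec, make_toy_hairpin, build_topology, build_frustration_set,
    ModelParameters, LangevinConfig, VariTempConfig,
    run_variable_temperature, estimate_T_theta, select_tse, phi_values,
)

s = make_toy_hairpin(ToyProteinSpec())      # bundled 27-residue two-state toy
topo = build_topology(s)
print(topo.n_residues, topo.n_contacts)     # 27 27

cfg = LangevinConfig(n_steps=6_000_000, stride=200, seed=1)
vt = VariTempConfig(t_init=0.5, delta_t=0.005, n_t=50_000)
traj, trace = run_variable_temperature(topo, None, ModelParameters(), cfg, vt)
t_theta, se = estimate_T_theta(trace)
print(round(t_theta, 3))                    # 0.434  (collapse temperature)

tse = select_tse(traj.qtrace(), t_avg=t_theta)
phi = phi_values(traj.kept[tse.indices], topo)
print(len(tse))                             # 3321   (TSE snapshots)
print(np.round(phi.phi[:5], 2))             # [0.37 0.46 0.92 0.66 0.61]
print(np.round(phi.phi[6:12], 2))           # [0.93 0.96 0.93 0.99 0.94 1.]
```

The toy system docks two helices through terminal contact patches: at the
barrier the helix bodies are fully formed (φ ≈ 0.93–1.0 mid-helix) while
the docking tips are only partially structured (φ ≈ 0.37–0.66) — the
per-residue picture of a two-state docking transition.

The same pipeline runs from the shell:

```bash
gofrust prepare  --config run.yaml --out run/
gofrust simulate --mode vari --config run.yaml --seed 1 --out run/
gofrust analyze  --run run/
gofrust compare  --run-a conventional/ --run-b frustrated/ --out cmp/ \
                 --thresholds 0.05,0.10 --ss-config ss.yaml
gofrust rmsd     a.pdb b.pdb c.pdb          # mutual Cα RMSD matrix
```

where `run.yaml` names a PDB file (or the bundled toy), the model
parameters, and the integrator/protocol settings; `compare` writes the
φ-increment table, the per-contact probability changes, and h_p matrices.

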