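"""The frustrated Gō-like potential and its analytic forces.

The potential acts on the Cα bead chain and has six terms:

* harmonic bonds            K_bond (r − r0)²
* harmonic angles           K_angle (θ − θ0)²
* dihedrals                 K1 [1 − cos(φ − φ0)] + K3 [1 − cos 3(φ − φ0)]
* native contacts           e_ij ε [5 (r0/r)¹² − 6 (r0/r)¹⁰]   (12–10 well,
                            depth e_ij ε at r = r0; 12–6 form optional)
* excluded volume           ε (σ/r)¹² over non-native, non-frustration pairs,
                            truncated and force-shifted at the contact cutoff
                            by default so the native state is an exact
                            stationary point of the frustration-free model
* frustration (optional)    ε_f [(C_f/r)¹² − 2 (C_f/r)⁶] over non-native
                            hydrophobic pairs, minimum −ε_f at C_f = 5.5 Å

Reduced units throughout: ε = 1 energy unit, k_B = 1, bead mass = 1,
lengths in Å.  Hydrophobic non-native pairs are governed by the frustration
well *instead of* the plain repulsion (the 12–6 form carries its own core);
with frustration disabled (or ε_f = 0) they revert to plain repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .structures import (
    CONTACT_CUTOFF,
    FrustrationSet,
    InputError,
    NativeTopology,
)


class NumericError(ArithmeticError):
    """Non-finite coordinates or a degenerate geometry (r = 0)."""


@dataclass
class ModelParameters:
    """Tunable constants of the frustrated Gō-like model (reduced units)."""

    epsilon: float = 1.0              # energy unit; native well depth scale
    k_bond: float = 100.0             # ε/Å²
    k_angle: float = 20.0             # ε/rad²
    k_dihedral_1: float = 1.0         # ε
    k_dihedral_3: float = 0.5         # ε
    sigma_rep: float = 4.0            # Å, excluded-volume diameter
    repulsion_cutoff: float | None = CONTACT_CUTOFF   # Å; None → untruncated
    eps_frustration: float = 0.2      # ε, depth of non-native hydrophobic well
    c_frustration: float = CONTACT_CUTOFF   # Å, frustration well minimum
    frustration_enabled: bool = False
    contact_form: str = "12-10"       # or "12-6"

    def __post_init__(self) -> None:
        for name in ("epsilon", "k_bond", "k_angle", "k_dihedral_1",
                     "k_dihedral_3", "sigma_rep", "c_frustration"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.eps_frustration < 0:
            raise InputError("eps_frustration must be non-negative")
        if self.contact_form not in ("12-10", "12-6"):
            raise InputError("contact_form must be '12-10' or '12-6'")

    @property
    def frustration_active(self) -> bool:
        """Frustration pairs leave the repulsion list only when the well has
        nonzero depth; at ε_f = 0 the model is exactly the conventional one."""
        return self.frustration_enabled and self.eps_frustration > 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass
class EnergyBreakdown:
    """Per-term energies (ε); ``total`` is their sum."""

    bond: float
    angle: float
    dihedral: float
    native_contact: float
    repulsion: float
    frustration: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.bond + self.angle + self.dihedral
                      + self.native_contact + self.repulsion + self.frustration)


@dataclass
class ModelArrays:
    """Flat-array view of (topology, frustration set, parameters) consumed by
    the compiled kernels."""

    bond_r0: np.ndarray
    theta0: np.ndarray
    phi0: np.ndarray
    ci: np.ndarray
    cj: np.ndarray
    cr0: np.ndarray
    cw: np.ndarray
    ri: np.ndarray
    rj: np.ndarray
    fi: np.ndarray
    fj: np.ndarray
    kb: float
    ka: float
    k1: float
    k3: float
    eps: float
    sig: float
    rcut: float
    epsf: float
    cf: float
    form: int

    def kernel_args(self) -> tuple:
        return (self.bond_r0, self.theta0, self.phi0, self.ci, self.cj,
                self.cr0, self.cw, self.ri, self.rj, self.fi, self.fj,
                self.kb, self.ka, self.k1, self.k3, self.eps, self.sig,
                self.rcut, self.epsf, self.cf, self.form)


def nonbonded_pairs(
    topo: NativeTopology,
    fset: FrustrationSet | None,
    p: ModelParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """0-based (i, j) arrays of repulsion pairs: all pairs at or beyond the
    minimum sequence separation that are neither native contacts nor (when
    frustration is active) frustration pairs."""
    n = topo.n_residues
    excluded = {(c.i - 1, c.j - 1) for c in topo.contacts}
    if fset is not None and p.frustration_active:
        excluded |= {(i - 1, j - 1) for i, j in fset.pairs}
    ri, rj = [], []
    for i in range(n):
        for j in range(i + topo.min_separation, n):
            if (i, j) not in excluded:
                ri.append(i)
                rj.append(j)
    return (np.asarray(ri, dtype=np.int64), np.asarray(rj, dtype=np.int64))


def pack_model(
    topo: NativeTopology,
    fset: FrustrationSet | None,
    p: ModelParameters,
) -> ModelArrays:
    ci, cj, cr0, cw = topo.contact_index_arrays()
    if np.any(np.isnan(cw)):
        raise InputError("contact weights unset; run assign_mj_weights first")
    ri, rj = nonbonded_pairs(topo, fset, p)
    if fset is not None and p.frustration_active:
        fi, fj = fset.pair_index_arrays()
    else:
        fi = np.zeros(0, dtype=np.int64)
        fj = np.zeros(0, dtype=np.int64)
    rcut = -1.0 if p.repulsion_cutoff is None else float(p.repulsion_cutoff)
    return ModelArrays(
        bond_r0=topo.bond_r0.astype(float), theta0=topo.angle_theta0.astype(float),
        phi0=topo.dihedral_phi0.astype(float), ci=ci, cj=cj, cr0=cr0, cw=cw,
        ri=ri, rj=rj, fi=fi, fj=fj,
        kb=p.k_bond, ka=p.k_angle, k1=p.k_dihedral_1, k3=p.k_dihedral_3,
        eps=p.epsilon, sig=p.sigma_rep, rcut=rcut,
        epsf=p.eps_frustration if p.frustration_active else 0.0,
        cf=p.c_frustration,
        form=0 if p.contact_form == "12-10" else 1,
    )


def _check_coords(x: np.ndarray, n: int) -> np.ndarray:
    x = np.ascontiguousarray(x, dtype=float)
    if x.shape != (n, 3):
        raise InputError(f"coordinates must have shape ({n}, 3), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise NumericError("non-finite coordinates")
    return x


def _check_energy(e: float) -> float:
    if not np.isfinite(e):
        raise NumericError("non-finite energy (overlapping beads?)")
    return float(e)


def bonded_energy_forces(
    x: np.ndarray, topo: NativeTopology, p: ModelParameters
) -> tuple[float, np.ndarray]:
    """Bond + angle + dihedral energy and forces."""
    x = _check_coords(x, topo.n_residues)
    f = np.zeros_like(x)
    e = _kernels.bond_term(x, f, topo.bond_r0.astype(float), p.k_bond)
    e += _kernels.angle_term(x, f, topo.angle_theta0.astype(float), p.k_angle)
    e += _kernels.dihedral_term(
        x, f, topo.dihedral_phi0.astype(float), p.k_dihedral_1, p.k_dihedral_3
    )
    return _check_energy(e), f


def native_contact_energy_forces(
    x: np.ndarray, topo: NativeTopology, p: ModelParameters
) -> tuple[float, np.ndarray]:
    if not topo.contacts:
        raise InputError("topology has no native contacts")
    x = _check_coords(x, topo.n_residues)
    ci, cj, cr0, cw = topo.contact_index_arrays()
    f = np.zeros_like(x)
    form = 0 if p.contact_form == "12-10" else 1
    e = _kernels.contact_term(x, f, ci, cj, cr0, cw, p.epsilon, form)
    return _check_energy(e), f


def repulsion_energy_forces(
    x: np.ndarray,
    topo: NativeTopology,
    p: ModelParameters,
    fset: FrustrationSet | None = None,
) -> tuple[float, np.ndarray]:
    x = _check_coords(x, topo.n_residues)
    ri, rj = nonbonded_pairs(topo, fset, p)
    f = np.zeros_like(x)
    rcut = -1.0 if p.repulsion_cutoff is None else float(p.repulsion_cutoff)
    e = _kernels.repulsion_term(x, f, ri, rj, p.epsilon, p.sigma_rep, rcut)
    return _check_energy(e), f


def frustration_energy_forces(
    x: np.ndarray, fset: FrustrationSet, p: ModelParameters
) -> tuple[float, np.ndarray]:
    if not p.frustration_enabled:
        raise InputError("frustration term requested but frustration_enabled is False")
    x = np.ascontiguousarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NumericError("non-finite coordinates")
    fi, fj = fset.pair_index_arrays()
    f = np.zeros_like(x)
    e = _kernels.frustration_term(x, f, fi, fj, p.eps_frustration, p.c_frustration)
    return _check_energy(e), f


def total_energy_forces(
    x: np.ndarray,
    topo: NativeTopology,
    fset: FrustrationSet | None,
    p: ModelParameters,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Full potential: breakdown by term and the exact negative gradient."""
    x = _check_coords(x, topo.n_residues)
    arrays = pack_model(topo, fset, p)
    f = np.zeros_like(x)
    eb, ea, ed, en, er, ef = _kernels.total_force(x, f, *arrays.kernel_args())
    breakdown = EnergyBreakdown(
        bond=_check_energy(eb), angle=_check_energy(ea),
        dihedral=_check_energy(ed), native_contact=_check_energy(en),
        repulsion=_check_energy(er), frustration=_check_energy(ef),
    )
    if not np.all(np.isfinite(f)):
        raise NumericError("non-finite forces")
    return breakdown, f
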