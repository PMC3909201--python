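"""Deterministic synthetic test systems.

Two fixtures make the whole pipeline runnable without any structure
downloads:

* a toy helical hairpin — two ideal α-helices (parametric helix: rise
  1.5 Å, radius 2.3 Å, 100°/residue) joined by an arc loop, with full
  backbone + Cβ atoms placed from idealized local frames.  It is a pure
  function of its spec, forms a nontrivial native-contact network, and
  folds two-state under the default model;
* a 1-D Langevin particle in an asymmetric piecewise-quartic double well
  whose equilibrium occupancies have a quadrature closed form — the
  testbed for the adaptive-temperature controller.

``brute_force_contacts`` re-implements the native-contact rule as a naive
O(atoms²) double loop and exists purely as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from . import _kernels
from .structures import (
    CONTACT_CUTOFF,
    MIN_SEPARATION,
    ContactPair,
    InputError,
    Residue,
    Structure,
)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class ToyProteinSpec:
    """Helical-hairpin construction parameters (all geometric, no noise)."""

    helix_len: int = 12           # residues per helix
    loop_len: int = 3             # residues bridging the two helices
    rise: float = 1.5             # Å per residue along the helix axis
    radius: float = 2.3           # Å, Cα helix radius
    twist_deg: float = 100.0      # degrees per residue
    axis_separation: float = 7.6  # Å between the helix axes at the termini
    splay_deg: float = 30.0       # tilt of helix B away from A toward the
                                  # loop end; splaying the hinge suppresses
                                  # progressive zipping from the loop and
                                  # makes docking cooperative (two-state)
    helix_pattern: str = "LK"     # cycled codes for the helix body
    tip_pattern: str = "SK"       # cycled codes for the docking tips
    tip_len: int = 5              # residues of each terminal docking patch
    loop_pattern: str = "GSG"     # cycled 1-letter codes for loop residues
    seed: int = 0                 # reserved; construction is deterministic

    def __post_init__(self) -> None:
        if self.helix_len < 4:
            raise InputError("helix_len must be at least 4")
        if self.loop_len < 1:
            raise InputError("loop_len must be at least 1")

    @property
    def n_residues(self) -> int:
        return 2 * self.helix_len + self.loop_len


def _helix_ca(spec: ToyProteinSpec, s: float, phase: float) -> np.ndarray:
    alpha = math.radians(spec.twist_deg)
    return np.array([
        spec.radius * math.cos(alpha * s + phase),
        spec.radius * math.sin(alpha * s + phase),
        spec.rise * s,
    ])


def _helix_frame(spec: ToyProteinSpec, s: float,
                 phase: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local orthonormal frame at helix parameter s: (tangent, outward, binormal)."""
    alpha = math.radians(spec.twist_deg)
    ang = alpha * s + phase
    t = np.array([
        -spec.radius * alpha * math.sin(ang),
        spec.radius * alpha * math.cos(ang),
        spec.rise,
    ])
    t /= np.linalg.norm(t)
    u = np.array([math.cos(ang), math.sin(ang), 0.0])
    u = u - (u @ t) * t
    u /= np.linalg.norm(u)
    w = np.cross(t, u)
    return t, u, w


def _backbone_atoms(ca: np.ndarray, t: np.ndarray, u: np.ndarray,
                    w: np.ndarray, with_cb: bool) -> list[tuple[str, np.ndarray]]:
    """Idealized backbone + Cβ in a local frame (bond lengths standard;
    orientations approximate — sufficient for 5.5 Å-scale contact realism)."""

    def off(dt: float, du: float, dw: float, length: float) -> np.ndarray:
        d = dt * t + du * u + dw * w
        return ca + d / np.linalg.norm(d) * length

    atoms = [
        ("N", off(-1.25, -0.75, 0.0, 1.458)),
        ("CA", ca.copy()),
        ("C", off(1.30, -0.70, 0.25, 1.525)),
    ]
    c_pos = atoms[2][1]
    o_dir = 0.85 * t + 0.40 * w - 0.2 * u
    atoms.append(("O", c_pos + o_dir / np.linalg.norm(o_dir) * 1.231))
    if with_cb:
        atoms.append(("CB", off(-0.25, 1.00, 0.35, 1.530)))
    return atoms


def _arc_points(a: np.ndarray, b: np.ndarray, n_interior: int,
                target_bond: float = 3.8) -> list[np.ndarray]:
    """Interior points of a circular arc from a to b bulging along +z, with
    the bulge height solved so adjacent chords ≈ target_bond."""
    chord_vec = b - a
    dist = float(np.linalg.norm(chord_vec))
    e1 = chord_vec / dist
    up = np.array([0.0, 0.0, 1.0])
    e2 = up - (up @ e1) * e1
    if np.linalg.norm(e2) < 1e-8:
        e2 = np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ e1) * e1
    e2 /= np.linalg.norm(e2)
    mid = 0.5 * (a + b)
    hs = 0.5 * dist
    n_pts = n_interior + 2

    def chord_len(bulge: float) -> float:
        r = (hs * hs + bulge * bulge) / (2.0 * bulge)
        beta = math.asin(min(1.0, hs / r)) if bulge <= hs else math.pi - math.asin(hs / r)
        delta = 2.0 * beta / (n_pts - 1)
        return 2.0 * r * math.sin(0.5 * delta)

    if chord_len(1e-6) > target_bond:
        raise InputError(
            "loop endpoints too far apart for the requested loop length"
        )
    bulge = brentq(lambda h: chord_len(h) - target_bond, 1e-6, 4.0 * dist)
    r = (hs * hs + bulge * bulge) / (2.0 * bulge)
    beta = math.asin(min(1.0, hs / r)) if bulge <= hs else math.pi - math.asin(hs / r)
    center = mid + (bulge - r) * e2
    pts = []
    for k in range(1, n_pts - 1):
        theta = -beta + 2.0 * beta * k / (n_pts - 1)
        pts.append(center + r * (math.sin(theta) * e1 + math.cos(theta) * e2))
    return pts


def make_toy_hairpin(spec: ToyProteinSpec | None = None) -> Structure:
    """Build the deterministic helical-hairpin structure."""
    spec = spec or ToyProteinSpec()
    L, k = spec.helix_len, spec.loop_len

    # Cα trace: helix A up, arc loop, helix B down.  Helix phases are chosen
    # so the chain ends near the loop face each other regardless of helix
    # length; helix B is the 180°-about-x image of an ideal helix, offset in
    # +x and optionally tilted away from A at the loop end (splay).
    d = spec.axis_separation
    z0 = spec.rise * (L - 1)
    alpha = math.radians(spec.twist_deg)
    phase_a = -alpha * (L - 1) - math.radians(20.0)
    phase_b = math.radians(180.0)
    psi = math.radians(spec.splay_deg)
    flip = np.diag([1.0, -1.0, -1.0])                 # 180° about x
    tilt = np.array([                                  # about +y: +z leans to +x
        [math.cos(psi), 0.0, math.sin(psi)],
        [0.0, 1.0, 0.0],
        [-math.sin(psi), 0.0, math.cos(psi)],
    ])
    rot = tilt @ flip
    # pivot: helix B's far (bottom) end stays at separation d from A's axis
    pivot_local = flip @ _helix_ca(spec, L - 1, phase_b)
    shift = np.array([d, 0.0, z0]) + pivot_local - rot @ _helix_ca(spec, L - 1, phase_b)

    def helix_b(pos: np.ndarray) -> np.ndarray:
        return rot @ pos + shift

    ca_a = [_helix_ca(spec, s, phase_a) for s in range(L)]
    ca_b = [helix_b(_helix_ca(spec, s, phase_b)) for s in range(L)]
    ca_loop = _arc_points(ca_a[-1], ca_b[0], k)

    frames: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for s in range(L):
        frames.append(_helix_frame(spec, s, phase_a))
    cas = ca_a + ca_loop + ca_b
    for idx in range(L, L + k):
        t = cas[idx + 1] - cas[idx - 1]
        t = t / np.linalg.norm(t)
        up = np.array([0.0, 0.0, 1.0])
        u = up - (up @ t) * t
        if np.linalg.norm(u) < 1e-8:
            u = np.array([1.0, 0.0, 0.0]) - (np.array([1.0, 0.0, 0.0]) @ t) * t
        u /= np.linalg.norm(u)
        frames.append((t, u, np.cross(t, u)))
    for s in range(L):
        t, u, w = _helix_frame(spec, s, phase_b)
        frames.append((rot @ t, rot @ u, rot @ w))

    # sequence: docking tips at the chain termini (helix A head, helix B
    # tail), helix-body pattern elsewhere
    tl = min(spec.tip_len, L)

    def _cyc(pat: str, n: int) -> list[str]:
        return [pat[i % len(pat)] for i in range(n)]

    helix_a_seq = _cyc(spec.tip_pattern, tl) + _cyc(spec.helix_pattern, L - tl)
    helix_b_seq = _cyc(spec.helix_pattern, L - tl) + _cyc(spec.tip_pattern, tl)
    seq1 = helix_a_seq + _cyc(spec.loop_pattern, k) + helix_b_seq
    residues = []
    for idx, (ca, (t, u, w), code) in enumerate(zip(cas, frames, seq1), start=1):
        name = _ONE_TO_THREE[code]
        atoms = _backbone_atoms(ca, t, u, w, with_cb=(name != "GLY"))
        residues.append(Residue(idx, name, atoms))
    s = Structure(residues, chain_id="A", source_id="toy_hairpin")

    # a hairpin must actually pack: require inter-helix contacts
    inter = [
        c for c in brute_force_contacts(s, CONTACT_CUTOFF)
        if c.i <= L and c.j > L + k
    ]
    if not inter:
        raise InputError(
            "toy hairpin forms no inter-helix contacts; helices too short "
            "or axis separation too large"
        )
    return s


def structure_to_pdb_text(s: Structure) -> str:
    """Serialize a Structure as minimal PDB ATOM records (single chain)."""
    lines = []
    serial = 1
    for r in s.residues:
        for name, xyz in r.atoms:
            pad = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad}{'':1s}{r.name:>3s} {s.chain_id}"
                f"{r.index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def brute_force_contacts(
    s: Structure,
    cutoff: float,
    min_separation: int = MIN_SEPARATION,
) -> list[ContactPair]:
    """Naive all-atom double loop implementing the native-contact rule;
    test oracle for ``compute_native_contacts``."""
    out: list[ContactPair] = []
    n = s.n_residues
    for a in range(n):
        ra = s.residues[a]
        for b in range(a + min_separation, n):
            rb = s.residues[b]
            found = False
            for _, xa in ra.atoms:
                for _, xb in rb.atoms:
                    dd = 0.0
                    for c in range(3):
                        dd += (xa[c] - xb[c]) ** 2
                    if dd < cutoff * cutoff:
                        found = True
                        break
                if found:
                    break
            if found:
                r0 = float(np.linalg.norm(ra.ca - rb.ca))
                out.append(ContactPair(ra.index, rb.index, r0))
    return out


# ---------------------------------------------------------------------------
# Double-well controller testbed


@dataclass
class DoubleWellSpec:
    """Asymmetric piecewise-quartic double well (C¹ at x = 0).

    Left branch (x<0):  (barrier+depth_left)·((x/a_left)²−1)² − depth_left
    Right branch (x≥0): (barrier+depth_right)·((x/a_right)²−1)² − depth_right

    With depths 0 and a_left = a_right the potential is symmetric.  The
    default tilt makes the right ("native") well deeper but narrower, so a
    finite temperature exists at which the two wells are equally populated —
    the closed-form target for the adaptive-temperature controller.
    """

    barrier: float = 1.2          # reduced energy at x = 0
    depth_left: float = 0.0
    depth_right: float = 0.4
    a_left: float = 1.5
    a_right: float = 0.6
    gamma: float = 1.0
    dt: float = 0.01
    nq: float = 10                # "native-contact count" assigned to x ≥ 0
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.barrier <= 0 or self.a_left <= 0 or self.a_right <= 0:
            raise InputError("barrier and well positions must be positive")
        if self.mass != 1.0:
            raise InputError("double-well sampler supports unit mass only")


class DoubleWellSampler:
    """1-D Langevin particle with the folding simulator's histogram/update
    interface: snapshots map to a two-level Q histogram (0 = left well /
    non-native, nq = right well / native)."""

    def __init__(self, spec: DoubleWellSpec):
        self.spec = spec
        self.x = spec.a_right       # start "native"
        self.v = 0.0
        self.nq = int(spec.nq)

    # -- dynamics -----------------------------------------------------------

    def run_window(self, n_steps: int, temperature: float, seed: int,
                   stride: int = 10) -> np.ndarray:
        """Advance the particle and return per-snapshot Q counts."""
        sp = self.spec
        state = np.array([self.x, self.v])
        snaps = np.empty(n_steps // stride)
        nsnap = _kernels.run_dw_segment(
            state, sp.barrier, sp.depth_left, sp.depth_right, sp.a_left,
            sp.a_right, sp.dt, sp.gamma, temperature, n_steps, stride,
            np.uint32(seed), snaps,
        )
        self.x, self.v = float(state[0]), float(state[1])
        return np.where(snaps[:nsnap] >= 0.0, self.nq, 0).astype(np.int64)

    # -- closed-form equilibrium -------------------------------------------

    def potential(self, x: float) -> float:
        sp = self.spec
        if x < 0:
            u = x / sp.a_left
            return (sp.barrier + sp.depth_left) * (u * u - 1) ** 2 - sp.depth_left
        u = x / sp.a_right
        return (sp.barrier + sp.depth_right) * (u * u - 1) ** 2 - sp.depth_right

    def boltzmann_p_right(self, temperature: float) -> float:
        """Exact equilibrium probability of the native (x ≥ 0) state."""
        lo = -6.0 * self.spec.a_left
        hi = 6.0 * self.spec.a_right
        zl, _ = quad(lambda x: math.exp(-self.potential(x) / temperature), lo, 0.0,
                     limit=200)
        zr, _ = quad(lambda x: math.exp(-self.potential(x) / temperature), 0.0, hi,
                     limit=200)
        return zr / (zl + zr)

    def equalization_temperature(self, t_lo: float = 0.02,
                                 t_hi: float = 5.0) -> float:
        """Temperature at which both wells are equally populated (brentq on
        the quadrature occupancy); raises if no crossing in the bracket."""
        return float(brentq(
            lambda t: self.boltzmann_p_right(t) - 0.5, t_lo, t_hi, xtol=1e-6,
        ))


def make_double_well_sampler(spec: DoubleWellSpec | None = None) -> DoubleWellSampler:
    return DoubleWellSampler(spec or DoubleWellSpec())
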