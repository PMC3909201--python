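"""Native-topology construction for coarse-grained Gō-model folding.

This module turns an all-atom protein structure (PDB) into the geometric
ground truth of a Cα bead model: the native bond lengths, bond angles and
dihedrals of the Cα trace, the native-contact network with
Miyazawa–Jernigan-flavored per-contact weights, and the set of non-native
hydrophobic pairs that act as energetic frustrations.  It also provides
in-silico side-chain truncation (X→Ala) and Kabsch RMSD for structural
comparisons.

Conventions: coordinates in Å, residue indices 1-based, angles in radians,
dihedrals in (−π, π].
"""

from __future__ import annotations

import copy
import io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Default minimum sequence separation |j - i| for native contacts,
#: non-native repulsion and frustration pairs.  Pairs closer in sequence are
#: governed by the bonded (bond/angle/dihedral) terms.
MIN_SEPARATION = 4

#: Default all-heavy-atom distance cutoff (Å) defining a native contact.
CONTACT_CUTOFF = 5.5

#: Default hydrophobic residue classification (Kyte–Doolittle-positive core).
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS"}
)


class StructureError(ValueError):
    """A structure violates a model precondition (e.g. missing CA atom)."""


class InputError(ValueError):
    """Malformed or empty input."""


@dataclass
class Residue:
    """One residue: 1-based sequence position, 3-letter name, heavy atoms."""

    index: int
    name: str
    atoms: list[tuple[str, np.ndarray]]

    def atom(self, name: str) -> np.ndarray:
        for a, xyz in self.atoms:
            if a == name:
                return xyz
        raise KeyError(f"residue {self.index} ({self.name}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a == name for a, _ in self.atoms)

    @property
    def ca(self) -> np.ndarray:
        return self.atom("CA")

    def coords(self) -> np.ndarray:
        return np.asarray([xyz for _, xyz in self.atoms], dtype=float)


@dataclass
class Structure:
    """An ordered single-chain protein structure (heavy atoms only)."""

    residues: list[Residue]
    chain_id: str = "A"
    source_id: str = ""

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("residue indices must be strictly increasing")
        for r in self.residues:
            if not r.has_atom("CA"):
                raise StructureError(f"residue {r.index} ({r.name}) has no CA atom")
            if not np.all(np.isfinite(r.coords())):
                raise StructureError(f"residue {r.index} has non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.asarray([r.ca for r in self.residues], dtype=float)

    def sequence3(self) -> list[str]:
        return [r.name for r in self.residues]

    def sequence(self) -> str:
        """1-letter sequence; unknown residue types map to 'X'."""
        return "".join(seq1(n, undef_code="X") for n in self.sequence3())


@dataclass
class ContactPair:
    """Native contact between residues i < j (1-based).

    ``r0`` is the native Cα–Cα distance (Å) — the contact is *detected* with
    the all-heavy-atom minimum distance but the bead model *acts* on Cα–Cα
    separations.  ``weight`` is the MJ-flavored dimensionless depth
    coefficient, normalized to unit mean over a contact list.
    """

    i: int
    j: int
    r0: float
    weight: float = float("nan")


@dataclass
class NativeTopology:
    """Geometric ground truth of the Cα Gō model measured in the native state."""

    n_residues: int
    ca0: np.ndarray                  # (n, 3) native Cα coordinates, Å
    bond_r0: np.ndarray              # (n-1,) native bond lengths, Å
    angle_theta0: np.ndarray         # (n-2,) native bond angles, rad
    dihedral_phi0: np.ndarray        # (n-3,) native dihedrals, rad in (−π, π]
    contacts: list[ContactPair]
    sequence: str = ""
    min_separation: int = MIN_SEPARATION

    def __post_init__(self) -> None:
        if np.any(self.bond_r0 <= 0):
            raise StructureError("non-positive native bond length")
        if np.any((self.bond_r0 < 2.5) | (self.bond_r0 > 4.5)):
            raise StructureError(
                "native Cα–Cα bond length outside 2.5–4.5 Å: not a trans "
                "peptide chain (chain breaks?)"
            )
        for c in self.contacts:
            if not (1 <= c.i < c.j <= self.n_residues):
                raise StructureError(f"contact ({c.i},{c.j}) out of range")
            if c.r0 <= 0:
                raise StructureError(f"contact ({c.i},{c.j}) has r0 <= 0")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def contact_index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """0-based (i, j) index arrays plus r0 and weight arrays."""
        if not self.contacts:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z, z
        ii = np.asarray([c.i - 1 for c in self.contacts], dtype=np.int64)
        jj = np.asarray([c.j - 1 for c in self.contacts], dtype=np.int64)
        r0 = np.asarray([c.r0 for c in self.contacts], dtype=float)
        w = np.asarray([c.weight for c in self.contacts], dtype=float)
        return ii, jj, r0, w

    def native_contact_counts(self) -> np.ndarray:
        """Per-residue number of native contacts (denominator of φ)."""
        counts = np.zeros(self.n_residues, dtype=np.int64)
        for c in self.contacts:
            counts[c.i - 1] += 1
            counts[c.j - 1] += 1
        return counts


@dataclass
class FrustrationSet:
    """Non-native hydrophobic pairs eligible for the frustration attraction."""

    pairs: list[tuple[int, int]]     # 1-based, i < j
    hydrophobic_indices: frozenset[int] = frozenset()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            z = np.zeros(0, dtype=np.int64)
            return z, z
        ii = np.asarray([p[0] - 1 for p in self.pairs], dtype=np.int64)
        jj = np.asarray([p[1] - 1 for p in self.pairs], dtype=np.int64)
        return ii, jj


@dataclass
class SecondaryStructureMap:
    """User-declared secondary-structure segments covering 1..n_residues."""

    elements: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        prev_end = 0
        for label, first, last in self.elements:
            if first != prev_end + 1:
                raise InputError(
                    f"segment {label!r} starts at {first}, expected {prev_end + 1}: "
                    "segments must be contiguous, ordered and non-overlapping"
                )
            if last < first:
                raise InputError(f"segment {label!r} has last < first")
            prev_end = last

    @property
    def n_residues(self) -> int:
        return self.elements[-1][2]

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.elements]

    def element_of(self, residue_index: int) -> str:
        for label, first, last in self.elements:
            if first <= residue_index <= last:
                return label
        raise InputError(f"residue {residue_index} outside the secondary-structure map")


# ---------------------------------------------------------------------------
# PDB parsing


def parse_structure(pdb_text: str, chain: str = "A", source_id: str = "") -> Structure:
    """Parse ATOM records of one chain (first model) into a :class:`Structure`.

    HETATM records and waters are skipped; alternate locations resolve to the
    highest-occupancy conformer; insertion codes are flattened into the
    sequential 1-based numbering the bead model uses.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_struct = parser.get_structure("s", io.StringIO(pdb_text))
    try:
        model = next(iter(bio_struct))
    except StopIteration:
        raise InputError("no models in PDB text") from None
    if chain not in [c.id for c in model]:
        raise InputError(f"chain {chain!r} not present in PDB text")

    residues: list[Residue] = []
    seq_index = 0
    for bio_res in model[chain]:
        hetflag = bio_res.id[0]
        if hetflag != " ":          # skip HETATM, waters
            continue
        atoms: list[tuple[str, np.ndarray]] = []
        for bio_atom in bio_res:
            if bio_atom.element == "H":
                continue
            # DisorderedAtom yields its highest-occupancy child by default
            atoms.append((bio_atom.get_name(), np.array(bio_atom.get_coord(), dtype=float)))
        if not atoms:
            continue
        seq_index += 1
        if not any(a == "CA" for a, _ in atoms):
            raise StructureError(
                f"residue {bio_res.get_resname()} {bio_res.id[1]} in chain "
                f"{chain} has no CA atom"
            )
        residues.append(Residue(seq_index, bio_res.get_resname(), atoms))
    if not residues:
        raise InputError(f"chain {chain!r} contains no ATOM records")
    return Structure(residues, chain_id=chain, source_id=source_id)


# ---------------------------------------------------------------------------
# Native contacts and MJ weights


def compute_native_contacts(
    s: Structure,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
) -> list[ContactPair]:
    """Detect native contacts: residue pairs with |j−i| ≥ ``min_separation``
    whose minimum heavy-atom distance is below ``cutoff`` Å.

    ``r0`` of each returned pair is the native Cα–Cα distance, the length
    scale the 12–10 contact potential acts on.  Weights are left unset.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    if s.n_residues < 2:
        raise InputError("need at least 2 residues to form contacts")

    all_coords = np.concatenate([r.coords() for r in s.residues], axis=0)
    counts = [len(r.atoms) for r in s.residues]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    dmat = cdist(all_coords, all_coords)
    ca = s.ca_coords()

    contacts: list[ContactPair] = []
    n = s.n_residues
    for a in range(n):
        for b in range(a + min_separation, n):
            block = dmat[offsets[a]:offsets[a + 1], offsets[b]:offsets[b + 1]]
            if block.min() < cutoff:
                r0 = float(np.linalg.norm(ca[a] - ca[b]))
                contacts.append(ContactPair(a + 1, b + 1, r0))
    return contacts


def _load_mj_table() -> dict[tuple[str, str], float]:
    text = resources.files("gofrust.data").joinpath("mj1996.txt").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    order = lines[0].split()
    table: dict[tuple[str, str], float] = {}
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        res_i = parts[0]
        assert res_i == order[i]
        for k, val in enumerate(parts[1:]):
            res_j = order[i + k]
            e = float(val)
            table[(res_i, res_j)] = e
            table[(res_j, res_i)] = e
    return table


_MJ_TABLE: dict[tuple[str, str], float] | None = None


def mj_energy(res_a: str, res_b: str) -> float:
    """MJ contact energy e(a,b) in RT units; KeyError for unknown types."""
    global _MJ_TABLE
    if _MJ_TABLE is None:
        _MJ_TABLE = _load_mj_table()
    return _MJ_TABLE[(res_a, res_b)]


def assign_mj_weights(contacts: list[ContactPair], sequence3: list[str]) -> list[ContactPair]:
    """Set per-contact weights ∝ |MJ(a_i, a_j)|, rescaled to unit mean.

    Unknown residue types fall back to a raw magnitude of 1 (logged).  The
    returned list is new; inputs are not modified.
    """
    if not contacts:
        return []
    raw = np.empty(len(contacts))
    for k, c in enumerate(contacts):
        try:
            raw[k] = abs(mj_energy(sequence3[c.i - 1], sequence3[c.j - 1]))
        except KeyError:
            logger.warning(
                "unknown residue type in contact (%d,%d): %s-%s; weight falls back to 1",
                c.i, c.j, sequence3[c.i - 1], sequence3[c.j - 1],
            )
            raw[k] = 1.0
    weights = raw / raw.mean()
    return [ContactPair(c.i, c.j, c.r0, float(w)) for c, w in zip(contacts, weights)]


# ---------------------------------------------------------------------------
# Topology


def _bond_angles(x: np.ndarray) -> np.ndarray:
    u = x[:-2] - x[1:-1]
    w = x[2:] - x[1:-1]
    cosang = np.einsum("ij,ij->i", u, w) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(x: np.ndarray) -> np.ndarray:
    b1 = x[1:-2] - x[:-3]
    b2 = x[2:-1] - x[1:-2]
    b3 = x[3:] - x[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    xcomp = np.einsum("ij,ij->i", n1, n2)
    ycomp = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(ycomp, xcomp)


def build_topology(
    s: Structure,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
) -> NativeTopology:
    """Measure bonds/angles/dihedrals on the native Cα trace and attach the
    weighted native-contact list."""
    ca = s.ca_coords()
    if len(ca) < 2:
        raise InputError("need at least 2 residues")
    bond_r0 = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    theta0 = _bond_angles(ca) if len(ca) >= 3 else np.zeros(0)
    phi0 = _dihedrals(ca) if len(ca) >= 4 else np.zeros(0)
    contacts = assign_mj_weights(
        compute_native_contacts(s, cutoff=cutoff, min_separation=min_separation),
        s.sequence3(),
    )
    return NativeTopology(
        n_residues=s.n_residues,
        ca0=ca,
        bond_r0=bond_r0,
        angle_theta0=theta0,
        dihedral_phi0=phi0,
        contacts=contacts,
        sequence=s.sequence(),
        min_separation=min_separation,
    )


def build_frustration_set(
    s: Structure,
    topo: NativeTopology,
    hydrophobic: frozenset[str] | set[str] = HYDROPHOBIC_RESIDUES,
    min_separation: int = MIN_SEPARATION,
) -> FrustrationSet:
    """All non-native hydrophobic pairs: both residues hydrophobic,
    |j−i| ≥ ``min_separation``, and not a native contact."""
    hydro_idx = frozenset(
        r.index for r in s.residues if r.name in hydrophobic
    )
    native = {(c.i, c.j) for c in topo.contacts}
    pairs = [
        (i, j)
        for i in sorted(hydro_idx)
        for j in sorted(hydro_idx)
        if j - i >= min_separation and (i, j) not in native
    ]
    logger.info(
        "frustration set: %d hydrophobic residues (%s), %d non-native pairs",
        len(hydro_idx), ",".join(sorted(hydrophobic)), len(pairs),
    )
    return FrustrationSet(pairs=pairs, hydrophobic_indices=hydro_idx)


# ---------------------------------------------------------------------------
# Mutation and RMSD

_ALA_ATOMS = {"N", "CA", "C", "O", "CB"}


def mutate_side_chain_to_ala(s: Structure, residue_index: int) -> Structure:
    """Truncate one residue's side chain to Cβ (X→Ala), leaving ``s`` intact.

    This is the in-silico construction used for hydrophilic-to-hydrophobic
    point mutants: no atoms are rebuilt, side-chain atoms beyond Cβ are
    simply removed and the residue renamed ALA.
    """
    target = next((r for r in s.residues if r.index == residue_index), None)
    if target is None:
        raise InputError(f"no residue with index {residue_index}")
    if not target.has_atom("CB"):
        raise InputError(
            f"residue {residue_index} ({target.name}) has no CB atom "
            "(glycine cannot be truncated to alanine)"
        )
    new_residues = []
    for r in s.residues:
        if r.index == residue_index:
            atoms = [(a, xyz.copy()) for a, xyz in r.atoms if a in _ALA_ATOMS]
            new_residues.append(Residue(r.index, "ALA", atoms))
        else:
            new_residues.append(copy.deepcopy(r))
    return Structure(new_residues, chain_id=s.chain_id, source_id=s.source_id + "x")


def _selected_coords(s: Structure, atom_selection: str) -> np.ndarray:
    if atom_selection == "CA":
        names = ("CA",)
    elif atom_selection == "backbone":
        names = ("N", "CA", "C", "O")
    else:
        raise InputError(f"unknown atom selection {atom_selection!r}")
    coords = []
    for r in s.residues:
        for name in names:
            coords.append(r.atom(name))
    return np.asarray(coords, dtype=float)


def kabsch_rmsd(a: Structure, b: Structure, atom_selection: str = "CA") -> float:
    """RMSD (Å) after optimal rigid superposition (rotation + translation,
    proper rotations only)."""
    if a.n_residues != b.n_residues:
        raise InputError(
            f"residue count mismatch: {a.n_residues} vs {b.n_residues}"
        )
    p = _selected_coords(a, atom_selection)
    q = _selected_coords(b, atom_selection)
    return kabsch_rmsd_points(p, q)


def kabsch_rmsd_points(p: np.ndarray, q: np.ndarray) -> float:
    """Kabsch RMSD between two equally-sized point sets (SVD algorithm)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputError(f"point set shape mismatch: {p.shape} vs {q.shape}")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (rot @ pc.T).T - qc
    return float(np.sqrt((diff ** 2).sum() / len(p)))
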