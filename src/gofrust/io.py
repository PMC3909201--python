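"""Plain-text persistence: topology files, secondary-structure maps, reports.

The topology file is a JSON document listing everything a simulation needs
(bonds, angles, dihedrals, weighted contacts, frustration pairs, native Cα
coordinates), so runs are reproducible without re-parsing the source PDB.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .structures import (
    ContactPair,
    FrustrationSet,
    InputError,
    NativeTopology,
    SecondaryStructureMap,
)

_FORMAT = "gofrust-topology-1"


def topology_to_dict(topo: NativeTopology,
                     fset: FrustrationSet | None = None) -> dict:
    d = {
        "format": _FORMAT,
        "n_residues": topo.n_residues,
        "sequence": topo.sequence,
        "min_separation": topo.min_separation,
        "ca0": topo.ca0.tolist(),
        "bond_r0": topo.bond_r0.tolist(),
        "angle_theta0": topo.angle_theta0.tolist(),
        "dihedral_phi0": topo.dihedral_phi0.tolist(),
        "contacts": [
            {"i": c.i, "j": c.j, "r0": c.r0, "weight": c.weight}
            for c in topo.contacts
        ],
    }
    if fset is not None:
        d["frustration_pairs"] = [list(p) for p in fset.pairs]
        d["hydrophobic_indices"] = sorted(fset.hydrophobic_indices)
    return d


def dict_to_topology(d: dict) -> tuple[NativeTopology, FrustrationSet | None]:
    if d.get("format") != _FORMAT:
        raise InputError(f"not a {_FORMAT} document")
    topo = NativeTopology(
        n_residues=int(d["n_residues"]),
        ca0=np.asarray(d["ca0"], dtype=float),
        bond_r0=np.asarray(d["bond_r0"], dtype=float),
        angle_theta0=np.asarray(d["angle_theta0"], dtype=float),
        dihedral_phi0=np.asarray(d["dihedral_phi0"], dtype=float),
        contacts=[
            ContactPair(int(c["i"]), int(c["j"]), float(c["r0"]),
                        float(c["weight"]))
            for c in d["contacts"]
        ],
        sequence=d.get("sequence", ""),
        min_separation=int(d.get("min_separation", 4)),
    )
    fset = None
    if "frustration_pairs" in d:
        fset = FrustrationSet(
            pairs=[tuple(p) for p in d["frustration_pairs"]],
            hydrophobic_indices=frozenset(d.get("hydrophobic_indices", [])),
        )
    return topo, fset


def save_topology(path: str | Path, topo: NativeTopology,
                  fset: FrustrationSet | None = None) -> None:
    Path(path).write_text(json.dumps(topology_to_dict(topo, fset), indent=1))


def load_topology(path: str | Path) -> tuple[NativeTopology, FrustrationSet | None]:
    return dict_to_topology(json.loads(Path(path).read_text()))


def trajectory_to_pdb(traj, sequence: str = "", max_models: int = 100) -> str:
    """Multi-model PDB text of the Cα trace for external viewers.

    Snapshots are subsampled evenly down to ``max_models`` models.
    """
    m = len(traj.steps)
    pick = np.linspace(0, m - 1, min(m, max_models)).astype(int)
    lines = []
    for model_no, k in enumerate(np.unique(pick), start=1):
        lines.append(f"MODEL     {model_no:4d}")
        for i, xyz in enumerate(traj.coords[k], start=1):
            res = "ALA"
            if sequence and i <= len(sequence):
                res = _THREE.get(sequence[i - 1], "UNK")
            lines.append(
                f"ATOM  {i:5d}  CA  {res:>3s} A{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def ss_map_from_config(elements: list) -> SecondaryStructureMap:
    """Build a secondary-structure map from config entries
    [[label, first, last], ...]."""
    return SecondaryStructureMap(
        elements=[(str(e[0]), int(e[1]), int(e[2])) for e in elements]
    )
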