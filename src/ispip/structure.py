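"""Structure parsing, interface annotation and surface-residue counting.

Ground truth for interface prediction comes from complex structures: a
residue of the query chain is *interfacial* when at least one of its heavy
atoms lies within a distance cutoff (4.0 Å by convention) of any heavy atom
of a partner chain.  The same module counts surface-exposed residues — the
``R`` that drives the dynamic top-N classification cutoff — from relative
solvent accessibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "ResidueKey",
    "StructureModel",
    "InterfaceAnnotation",
    "SurfaceCount",
    "StructureParseError",
    "parse_structure",
    "annotate_interface",
    "surface_residues",
    "MAX_ASA",
]


class StructureParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class ResidueKey(NamedTuple):
    """Identity of a residue: chain id, author residue number, insertion code."""

    chain: str
    resnum: int
    icode: str


class Atom(NamedTuple):
    chain: str
    resnum: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class StructureModel:
    """A set of atoms with chain/residue identity; residue order per chain is
    the order of first appearance in the coordinate file (no renumbering)."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureParseError("structure contains no atoms")
        coords = self.coords()
        if not np.all(np.isfinite(coords)):
            raise StructureParseError("non-finite coordinates in structure")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residue_keys(self, chain: str | None = None) -> list[ResidueKey]:
        """Residue keys in file order, optionally restricted to one chain."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            if chain is None or a.chain == chain:
                seen.setdefault(ResidueKey(a.chain, a.resnum, a.icode), None)
        return list(seen)

    def coords(self, chain: str | None = None) -> np.ndarray:
        return np.array(
            [(a.x, a.y, a.z) for a in self.atoms if chain is None or a.chain == chain],
            dtype=float,
        ).reshape(-1, 3)

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain]

    def transformed(self, rotation: np.ndarray | None = None, translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "StructureModel":
        """Return a rigidly transformed copy (rotation then translation)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        xyz = self.coords() @ R.T + t
        atoms = [a._replace(x=p[0], y=p[1], z=p[2]) for a, p in zip(self.atoms, xyz)]
        return StructureModel(atoms)


@dataclass
class InterfaceAnnotation:
    """Binary interface labels for every residue of one query chain."""

    protein_id: str
    chain: str
    labels: dict[ResidueKey, int]
    cutoff: float

    def positives(self) -> list[ResidueKey]:
        return [k for k, v in self.labels.items() if v == 1]


@dataclass
class SurfaceCount:
    """Surface-exposed residue count R and the underlying relative accessibilities."""

    R: int
    relative_accessibility: dict[ResidueKey, float] = field(default_factory=dict)
    threshold: float = 0.05


# Theoretical maximum accessible surface areas (Å²) per residue type,
# Tien et al. 2013 "Maximum allowed solvent accessibilites of residues in
# proteins" — the standard normalisation for relative exposure.
MAX_ASA: Mapping[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
# Non-standard residues fall back to the glycine maximum.
_FALLBACK_MAX_ASA = MAX_ASA["GLY"]

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def parse_structure(
    pdb_text: str,
    *,
    include_hetatm: bool = False,
    keep_hydrogens: bool = False,
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Waters are always dropped; HETATM records are dropped unless
    ``include_hetatm``.  Alternate locations are resolved per atom name to the
    conformer with the highest occupancy (first wins on ties).  Hydrogens are
    excluded by default since contact detection is a heavy-atom convention.
    """
    import gemmi

    # gemmi forgives malformed coordinate fields; reject them explicitly
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise StructureParseError(
                    f"line {lineno}: truncated coordinate record"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureParseError(
                        f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                    ) from None

    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureParseError(f"malformed PDB text: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError("no model in PDB text")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water() or res.name in _WATER_NAMES:
                continue
            if res.het_flag == "H" and not include_hetatm:
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if not keep_hydrogens and atom.element.name in ("H", "D"):
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        res_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise StructureParseError("no ATOM records found")
    return StructureModel(atoms)


def annotate_interface(
    structure: StructureModel,
    query_chain: str,
    partner_chains: Iterable[str],
    cutoff: float = 4.0,
    *,
    protein_id: str = "",
    contact_filter=None,
) -> InterfaceAnnotation:
    """Label each residue of ``query_chain``: 1 iff any heavy atom is within
    ``cutoff`` Å of any heavy atom of any partner chain.

    ``contact_filter`` is an optional hook ``(query_atom, partner_atom,
    distance) -> bool`` applied on top of the distance criterion, for callers
    that want a stricter contact definition.
    """
    partner_chains = set(partner_chains)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chains = set(structure.chains())
    if query_chain not in chains:
        raise ValueError(f"query chain {query_chain!r} not in structure")
    missing = partner_chains - chains
    if missing:
        raise ValueError(f"partner chain(s) {sorted(missing)} not in structure")
    if query_chain in partner_chains:
        raise ValueError("query chain cannot be its own partner")

    query_atoms = structure.chain_atoms(query_chain)
    partner_atoms = [a for a in structure.atoms if a.chain in partner_chains]
    q_xyz = np.array([(a.x, a.y, a.z) for a in query_atoms])
    p_xyz = np.array([(a.x, a.y, a.z) for a in partner_atoms])

    labels: dict[ResidueKey, int] = {k: 0 for k in structure.residue_keys(query_chain)}
    if len(partner_atoms) > 0:
        tree = cKDTree(p_xyz)
        if contact_filter is None:
            dist, _ = tree.query(q_xyz, k=1)
            for atom, d in zip(query_atoms, dist):
                if d <= cutoff:
                    labels[ResidueKey(atom.chain, atom.resnum, atom.icode)] = 1
        else:
            neighbours = tree.query_ball_point(q_xyz, r=cutoff)
            for atom, q, idxs in zip(query_atoms, q_xyz, neighbours):
                for j in idxs:
                    d = float(np.linalg.norm(q - p_xyz[j]))
                    if contact_filter(atom, partner_atoms[j], d):
                        labels[ResidueKey(atom.chain, atom.resnum, atom.icode)] = 1
                        break
    return InterfaceAnnotation(
        protein_id=protein_id, chain=query_chain, labels=labels, cutoff=cutoff
    )


def surface_residues(
    structure: StructureModel,
    chain: str,
    threshold: float = 0.05,
    *,
    probe_radius: float = 1.4,
    point_number: int = 500,
) -> SurfaceCount:
    """Count surface-exposed residues of one chain.

    Per-residue solvent-accessible surface area is computed with the rolling
    probe (Shrake–Rupley) method on the whole structure, then divided by the
    residue type's theoretical maximum to a relative accessibility clipped to
    [0, 1]; residues at or above ``threshold`` count toward ``R``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    chain_atoms = structure.chain_atoms(chain)
    if not chain_atoms:
        raise ValueError(f"chain {chain!r} has no atoms")

    import biotite.structure as bs

    atoms = structure.atoms
    n = len(atoms)
    arr = bs.AtomArray(n)
    arr.coord = structure.coords().astype(np.float32)
    arr.chain_id = np.array([a.chain for a in atoms])
    arr.res_id = np.array([a.resnum for a in atoms])
    arr.ins_code = np.array([a.icode for a in atoms])
    arr.res_name = np.array([a.res_name for a in atoms])
    arr.atom_name = np.array([a.atom_name for a in atoms])
    arr.element = np.array([a.element.upper() for a in atoms])
    arr.hetero = np.zeros(n, dtype=bool)

    atom_sasa = bs.sasa(
        arr, probe_radius=probe_radius, vdw_radii="Single", point_number=point_number
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)

    per_res: dict[ResidueKey, float] = {}
    res_names: dict[ResidueKey, str] = {}
    for atom, s in zip(atoms, atom_sasa):
        if atom.chain != chain:
            continue
        key = ResidueKey(atom.chain, atom.resnum, atom.icode)
        per_res[key] = per_res.get(key, 0.0) + float(s)
        res_names[key] = atom.res_name

    rel = {
        key: min(1.0, sasa / MAX_ASA.get(res_names[key], _FALLBACK_MAX_ASA))
        for key, sasa in per_res.items()
    }
    R = sum(1 for v in rel.values() if v >= threshold)
    return SurfaceCount(R=R, relative_accessibility=rel, threshold=threshold)


def annotation_to_frame(annotation: InterfaceAnnotation):
    """Annotation as a tidy table (protein_id, chain, resnum, icode, label)."""
    import pandas as pd

    rows = [
        (annotation.protein_id, k.chain, k.resnum, k.icode, v)
        for k, v in annotation.labels.items()
    ]
    return pd.DataFrame(rows, columns=["protein_id", "chain", "resnum", "icode", "label"])
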