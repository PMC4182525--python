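"""Atomic data model for binary protein-RNA complexes and PDB I/O.

A :class:`Complex` holds exactly two partners: one protein molecule and
one RNA molecule, each a list of :class:`ResidueUnit`.  Heavy atoms of
every unit are partitioned into a backbone set and a side-chain set (the
base, for nucleotides).  The RNA backbone includes the phosphate group
and the sugar ring; everything else in a nucleotide is base.

PDB parsing and record formatting go through :mod:`gemmi`; this module
only decides which residues belong to which partner and how alternate
locations are resolved (highest occupancy wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .pose import Pose

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
RNA_RESIDUES = {"A", "C", "G", "U"}
# DNA is out of scope; reject rather than silently treating it as RNA.
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "T"}

PROTEIN_BACKBONE = {"N", "CA", "C", "O"}
# Phosphate group plus the full sugar ring; every other nucleotide heavy
# atom belongs to the base.
RNA_BACKBONE = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}

KIND_PROTEIN = "protein-residue"
KIND_RNA = "rna-nucleotide"


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False
    serial: int = 0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class ResidueUnit:
    """One amino-acid residue or one ribonucleotide."""

    kind: str
    code: str
    seq_id: int
    chain_id: str
    atoms: list[Atom]
    icode: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (KIND_PROTEIN, KIND_RNA):
            raise ValueError(f"unknown unit kind {self.kind!r}")

    @property
    def key(self) -> str:
        """Sequence key: residue number with any insertion code appended."""
        return f"{self.seq_id}{self.icode}"

    @property
    def backbone_names(self) -> frozenset[str]:
        return frozenset(
            PROTEIN_BACKBONE if self.kind == KIND_PROTEIN else RNA_BACKBONE
        )

    @property
    def backbone_atoms(self) -> list[Atom]:
        names = self.backbone_names
        return [a for a in self.atoms if not a.is_hydrogen and a.name in names]

    @property
    def sidechain_atoms(self) -> list[Atom]:
        """Side-chain heavy atoms (the base, for a nucleotide)."""
        names = self.backbone_names
        return [a for a in self.atoms if not a.is_hydrogen and a.name not in names]

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms])


@dataclass
class Complex:
    """A binary complex: one protein partner and one RNA partner."""

    protein: list[ResidueUnit]
    rna: list[ResidueUnit]
    id: str = ""

    def validate(self) -> None:
        if not self.protein or not self.rna:
            raise ValueError("not a binary protein-RNA complex")
        serials = [a.serial for u in self.all_units for a in u.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serial numbers")
        for u in self.protein:
            if u.kind != KIND_PROTEIN:
                raise ValueError(f"non-protein unit {u.code} in protein partner")
        for u in self.rna:
            if u.kind != KIND_RNA:
                raise ValueError(f"non-RNA unit {u.code} in RNA partner")

    @property
    def all_units(self) -> list[ResidueUnit]:
        return list(self.protein) + list(self.rna)

    def partner_heavy_coords(self, partner: str) -> np.ndarray:
        units = self.protein if partner == "protein" else self.rna
        blocks = [u.heavy_coords() for u in units]
        blocks = [b for b in blocks if len(b)]
        if not blocks:
            return np.empty((0, 3))
        return np.vstack(blocks)

    def rna_pivot(self) -> np.ndarray:
        """Geometric centre of the RNA heavy atoms (rotation pivot)."""
        return self.partner_heavy_coords("rna").mean(axis=0)

    def with_pose(self, pose: Pose) -> "Complex":
        """Copy of the complex with ``pose`` applied to the RNA partner."""
        if pose.is_identity:
            return self
        pivot = self.rna_pivot()
        new_rna = []
        for u in self.rna:
            coords = np.array([a.coords for a in u.atoms])
            moved = pose.apply(coords, pivot)
            atoms = [
                Atom(a.name, a.element, c, a.is_hydrogen, a.serial, a.occupancy)
                for a, c in zip(u.atoms, moved)
            ]
            new_rna.append(
                ResidueUnit(u.kind, u.code, u.seq_id, u.chain_id, atoms, u.icode)
            )
        return Complex(protein=self.protein, rna=new_rna, id=self.id)


def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name
    if name and name != "X":
        return name
    # fall back on the first alphabetic character of the atom name
    for ch in atom.name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: the highest-occupancy one."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def read_pdb(path: str | Path) -> Complex:
    """Read a PDB file into a binary protein-RNA :class:`Complex`.

    Residues are assigned to partners by residue name; HETATM records,
    waters and ions are ignored.  Unknown residue names are skipped with
    a warning; if more than half of the residues are skipped the file is
    rejected.  Only the first model of multi-model files is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    protein: list[ResidueUnit] = []
    rna: list[ResidueUnit] = []
    n_skipped = 0
    n_seen = 0
    serial = 0
    for chain in model:
        for res in chain:
            if res.het_flag == "H" or res.is_water():
                continue
            name = res.name.strip()
            n_seen += 1
            if name in PROTEIN_RESIDUES:
                kind = KIND_PROTEIN
            elif name in RNA_RESIDUES:
                kind = KIND_RNA
            else:
                n_skipped += 1
                warnings.warn(
                    f"{path.name}: skipping unrecognized residue "
                    f"{res.name!r} {chain.name}{res.seqid.num}",
                    stacklevel=2,
                )
                continue
            atoms = []
            for ga in _resolve_altlocs(res):
                serial += 1
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=_element_of(ga),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        is_hydrogen=ga.element.is_hydrogen,
                        serial=serial,
                        occupancy=ga.occ,
                    )
                )
            if not atoms:
                continue
            unit = ResidueUnit(
                kind=kind,
                code=name,
                seq_id=res.seqid.num,
                chain_id=chain.name,
                atoms=atoms,
                icode=res.seqid.icode.strip(),
            )
            (protein if kind == KIND_PROTEIN else rna).append(unit)

    if n_seen and n_skipped / n_seen > 0.5:
        raise ValueError(
            f"{path}: {n_skipped}/{n_seen} residues unrecognized"
        )
    cx = Complex(protein=protein, rna=rna, id=path.stem)
    if not cx.protein or not cx.rna:
        raise ValueError(f"{path}: not a binary protein-RNA complex")
    cx.validate()
    return cx


def _to_gemmi(cx: Complex, pose: Pose) -> gemmi.Structure:
    moved = cx.with_pose(pose)
    st = gemmi.Structure()
    st.name = cx.id or "complex"
    model = gemmi.Model("1")
    serial = 0
    for units in (moved.protein, moved.rna):
        by_chain: dict[str, list[ResidueUnit]] = {}
        for u in units:
            by_chain.setdefault(u.chain_id, []).append(u)
        for chain_id, chain_units in by_chain.items():
            chain = gemmi.Chain(chain_id)
            for u in chain_units:
                res = gemmi.Residue()
                res.name = u.code
                res.seqid = gemmi.SeqId(u.seq_id, u.icode or " ")
                res.het_flag = "A"
                for a in u.atoms:
                    serial += 1
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.serial = serial
                    res.add_atom(ga)
                chain.add_residue(res)
            model.add_chain(chain)
    st.add_model(model)
    return st


def write_pdb(cx: Complex, pose: Pose, path: str | Path) -> None:
    """Write the complex as a PDB file, applying ``pose`` to the RNA."""
    cx.validate()
    st = _to_gemmi(cx, pose)
    Path(path).write_text(st.make_pdb_string())
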