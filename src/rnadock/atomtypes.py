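"""Simplified atom typing for the all-atom scoring terms.

Every heavy atom of a standard residue or nucleotide is mapped to one of
~16 element-and-context types carrying Lennard-Jones radius/well depth,
Lazaridis-Karplus solvation parameters, a partial charge and H-bond
donor/acceptor capability.  RNA atoms are mapped onto the same
protein-derived types by element and polarity: anionic phosphate oxygens
share the carboxylate-oxygen type, sugar ester/ring oxygens an ester
type, base ring atoms the aromatic types.  The parameter values are a
compact molecular-mechanics-style set bundled with the package; the
scoring functional forms, not a specific upstream parameterization, are
the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .structure import KIND_PROTEIN, KIND_RNA


@dataclass(frozen=True)
class AtomType:
    name: str
    lj_radius: float
    lj_welldepth: float
    lk_dgfree: float
    lk_lambda: float
    lk_volume: float
    charge: float
    donor: bool
    acceptor: bool


def load_atom_types() -> dict[str, AtomType]:
    with resources.files("rnadock.data").joinpath("atom_types.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[row.type] = AtomType(
            name=row.type,
            lj_radius=float(row.lj_radius),
            lj_welldepth=float(row.lj_welldepth),
            lk_dgfree=float(row.lk_dgfree),
            lk_lambda=float(row.lk_lambda),
            lk_volume=float(row.lk_volume),
            charge=float(row.charge),
            donor=bool(row.donor),
            acceptor=bool(row.acceptor),
        )
    return out


# explicit (residue, atom) -> type overrides; everything else falls back
# to element defaults
_PROTEIN_OVERRIDES: dict[tuple[str, str], str] = {}

# backbone
for _res in (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
):
    _PROTEIN_OVERRIDES[(_res, "N")] = "Nbb"
    _PROTEIN_OVERRIDES[(_res, "CA")] = "CAbb"
    _PROTEIN_OVERRIDES[(_res, "C")] = "CObb"
    _PROTEIN_OVERRIDES[(_res, "O")] = "OCbb"
    _PROTEIN_OVERRIDES[(_res, "OXT")] = "OOC"

_PROTEIN_OVERRIDES.update(
    {
        # charged / polar nitrogens
        ("ARG", "NE"): "Ncat", ("ARG", "NH1"): "Ncat", ("ARG", "NH2"): "Ncat",
        ("ARG", "CZ"): "CObb",
        ("LYS", "NZ"): "Ncat",
        ("HIS", "ND1"): "Naro", ("HIS", "NE2"): "Naro",
        ("ASN", "ND2"): "Npol", ("GLN", "NE2"): "Npol",
        ("TRP", "NE1"): "Npol",
        # carbonyl / carboxylate groups
        ("ASN", "CG"): "CObb", ("ASN", "OD1"): "OCbb",
        ("GLN", "CD"): "CObb", ("GLN", "OE1"): "OCbb",
        ("ASP", "CG"): "CObb", ("ASP", "OD1"): "OOC", ("ASP", "OD2"): "OOC",
        ("GLU", "CD"): "CObb", ("GLU", "OE1"): "OOC", ("GLU", "OE2"): "OOC",
        # hydroxyls
        ("SER", "OG"): "OH", ("THR", "OG1"): "OH", ("TYR", "OH"): "OH",
        # sulfur
        ("CYS", "SG"): "S", ("MET", "SD"): "S",
    }
)

# aromatic ring carbons
for _res, _names in {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "CD2", "CE1"),
}.items():
    for _n in _names:
        _PROTEIN_OVERRIDES.setdefault((_res, _n), "CAro")

_RNA_BASE_OVERRIDES: dict[tuple[str, str], str] = {
    # adenine
    ("A", "N1"): "Naro", ("A", "N3"): "Naro", ("A", "N7"): "Naro",
    ("A", "N9"): "Naro", ("A", "N6"): "Npol",
    # guanine
    ("G", "N1"): "Npol", ("G", "N2"): "Npol", ("G", "N3"): "Naro",
    ("G", "N7"): "Naro", ("G", "N9"): "Naro", ("G", "O6"): "OCbb",
    # cytosine
    ("C", "N1"): "Naro", ("C", "N3"): "Naro", ("C", "N4"): "Npol",
    ("C", "O2"): "OCbb",
    # uracil
    ("U", "N1"): "Naro", ("U", "N3"): "Npol",
    ("U", "O2"): "OCbb", ("U", "O4"): "OCbb",
}

_ELEMENT_DEFAULTS = {"C": "CAli", "N": "Npol", "O": "OH", "S": "S", "P": "P"}

_SUGAR_OXYGEN = {"O5'": "Oest", "O3'": "Oest", "O4'": "Oest", "O2'": "OH"}
_PHOSPHATE_OXYGEN = {"OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}


def assign_type(kind: str, code: str, atom_name: str, element: str) -> str:
    """Atom-type key for a heavy atom (or Hpol/Hapol for hydrogens)."""
    if element == "H" or element == "D":
        return "Hpol"
    if kind == KIND_PROTEIN:
        t = _PROTEIN_OVERRIDES.get((code, atom_name))
        if t:
            return t
    elif kind == KIND_RNA:
        if atom_name == "P":
            return "P"
        if atom_name in _PHOSPHATE_OXYGEN:
            return "OOC"
        if atom_name in _SUGAR_OXYGEN:
            return _SUGAR_OXYGEN[atom_name]
        t = _RNA_BASE_OVERRIDES.get((code, atom_name))
        if t:
            return t
        if element == "C" and not atom_name.endswith("'"):
            return "CAro"  # base carbon
    return _ELEMENT_DEFAULTS.get(element, "CAli")
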