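import numpy as np
import pytest

from rnadock.structure import (
    Atom,
    Complex,
    KIND_PROTEIN,
    KIND_RNA,
    ResidueUnit,
)
from rnadock.synth import FixtureSpec, make_complex


def build_unit(kind, code, seq_id, chain_id, named_coords, start_serial=1):
    """Construct a ResidueUnit from (atom-name, xyz) pairs."""
    atoms = []
    for i, (name, xyz) in enumerate(named_coords):
        elem = "H" if name.startswith("H") else next(c for c in name if c.isalpha())
        atoms.append(
            Atom(
                name=name,
                element=elem,
                coords=np.asarray(xyz, dtype=float),
                is_hydrogen=name.startswith("H"),
                serial=start_serial + i,
            )
        )
    return ResidueUnit(kind=kind, code=code, seq_id=seq_id, chain_id=chain_id, atoms=atoms)


def make_pair_complex(prot_atoms, rna_atoms, prot_code="ALA", rna_code="U"):
    """Minimal one-residue / one-nucleotide complex with given atoms."""
    pu = build_unit(KIND_PROTEIN, prot_code, 1, "A", prot_atoms, start_serial=1)
    ru = build_unit(KIND_RNA, rna_code, 1, "B", rna_atoms, start_serial=100)
    return Complex(protein=[pu], rna=[ru], id="pair")


def rigid_transform_complex(cx, R, t):
    """Apply one global rigid motion to every atom of both partners."""

    def move(units):
        out = []
        for u in units:
            atoms = [
                Atom(a.name, a.element, R @ a.coords + t, a.is_hydrogen, a.serial)
                for a in u.atoms
            ]
            out.append(ResidueUnit(u.kind, u.code, u.seq_id, u.chain_id, atoms, u.icode))
        return out

    return Complex(protein=move(cx.protein), rna=move(cx.rna), id=cx.id)


@pytest.fixture(scope="session")
def small_complex():
    """6-residue / 4-nucleotide fixture with contacts in LJ range."""
    return make_complex(FixtureSpec(6, 4, interface_gap=3.0, seed=11))


@pytest.fixture(scope="session")
def lever_complex():
    """Small protein, long RNA: large perturbations reach the decoy band."""
    return make_complex(FixtureSpec(4, 20, interface_gap=4.0, seed=5))


@pytest.fixture()
def random_rotation():
    rng = np.random.default_rng(17)
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(17)).as_matrix(), rng.normal(
        size=3
    ) * 5.0
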