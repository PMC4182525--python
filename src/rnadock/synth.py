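"""Synthetic protein-RNA fixtures.

Everything the test and smoke pipelines consume is generated here, from
a seed, at run time: idealized binary complexes written as standard PDB,
decoy ensembles with a controlled near-native fraction, and feature
matrices with known ground-truth weights for optimizer-recovery checks.

The complexes use an idealized helical protein backbone with short
schematic side chains and a single-strand RNA with a full
phosphate/sugar/base atom inventory in standard nomenclature, the bases
pointing at the protein so that contacts fall in hydrogen-bond range.
The geometry is parametric, not a real A-form/alpha-helix model: the
fixtures guarantee realistic atom densities and interface distances,
not real structural statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .highres import TERM_KEYS, WeightVector
from .metrics import IrmsdCalculator
from .perturb import (
    Decoy,
    LabelledDecoySet,
    PerturbationSetting,
    label_for,
    sample_pose,
)
from .roger import FeatureMatrix
from .structure import Atom, Complex, KIND_PROTEIN, KIND_RNA, ResidueUnit

# residues cycled through the synthetic protein; includes glycine (no
# side chain), charged, polar, aromatic and aliphatic types
_PROTEIN_CYCLE = ("ALA", "ARG", "SER", "LEU", "GLU", "LYS", "PHE", "ASN", "GLY", "THR")
_RNA_CYCLE = ("A", "C", "G", "U")

_SIDECHAINS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "SER": ("CB", "OG"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLY": (),
    "THR": ("CB", "OG1", "CG2"),
}

_PURINE_BASE = {
    "A": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"),
    "G": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "O6", "N2"),
}
_PYRIMIDINE_BASE = {
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

_SUGAR = ("C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'", "O5'")
_PHOSPHATE = ("P", "OP1", "OP2")


@dataclass(frozen=True)
class FixtureSpec:
    n_protein_residues: int
    n_nucleotides: int
    interface_gap: float = 4.0  # A, min inter-partner heavy-atom distance
    seed: int = 0
    with_hydrogens: bool = True

    def __post_init__(self) -> None:
        if self.n_protein_residues < 1 or self.n_nucleotides < 1:
            raise ValueError("both partners need at least one unit")
        if self.interface_gap <= 0:
            raise ValueError("interface_gap must be positive")


@dataclass(frozen=True)
class SyntheticMatrixSpec:
    n_groups: int
    rows_per_class: int
    true_weights: WeightVector
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _element_of_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _protein_units(spec: FixtureSpec, rng: np.random.Generator) -> list[ResidueUnit]:
    units = []
    serial = 0
    for i in range(spec.n_protein_residues):
        code = _PROTEIN_CYCLE[i % len(_PROTEIN_CYCLE)]
        theta = np.deg2rad(100.0 * i)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])  # radial
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])  # tangential
        z = np.array([0.0, 0.0, 1.0])
        ca = 2.3 * u + np.array([0.0, 0.0, 1.5 * i])
        jitter = lambda: rng.normal(0.0, 0.03, size=3)
        atoms: list[tuple[str, np.ndarray]] = [
            ("N", ca - 1.2 * t + 0.6 * z + jitter()),
            ("CA", ca + jitter()),
            ("C", ca + 1.2 * t + 0.5 * z + jitter()),
            ("O", ca + 1.4 * t + 1.6 * z + jitter()),
        ]
        side = _SIDECHAINS[code]
        if code == "PHE":
            # aromatic ring in the radial/axial plane
            center = ca + 3.0 * u
            atoms.append(("CB", ca + 1.5 * u + jitter()))
            for k, name in enumerate(side[1:]):
                phi = 2 * np.pi * k / 6
                atoms.append(
                    (name, center + 1.35 * (np.cos(phi) * u + np.sin(phi) * z) + jitter())
                )
        else:
            for k, name in enumerate(side):
                branch = 0.7 * ((-1) ** k) * t if name[-1] in "12" else 0.0
                atoms.append((name, ca + (1.5 + 1.25 * k) * u + branch + jitter()))
        if spec.with_hydrogens:
            atoms.append(("H", atoms[0][1] + np.array([0.0, 0.0, -0.98])))
        alist = []
        for name, pos in atoms:
            serial += 1
            alist.append(
                Atom(
                    name=name,
                    element="H" if name == "H" else _element_of_name(name),
                    coords=pos,
                    is_hydrogen=name.startswith("H"),
                    serial=serial,
                )
            )
        units.append(
            ResidueUnit(
                kind=KIND_PROTEIN,
                code=code,
                seq_id=i + 1,
                chain_id="A",
                atoms=alist,
            )
        )
    return units


def _rna_units(
    spec: FixtureSpec, rng: np.random.Generator, x_offset: float
) -> list[ResidueUnit]:
    units = []
    serial = 100_000
    for j in range(spec.n_nucleotides):
        code = _RNA_CYCLE[j % len(_RNA_CYCLE)]
        zc = 2.0 + 4.0 * j
        s_center = np.array([x_offset, 0.8 * ((-1) ** j), zc])
        u = np.array([-1.0, 0.0, 0.0])  # toward the protein
        t = np.array([0.0, 1.0, 0.0])
        z = np.array([0.0, 0.0, 1.0])
        jitter = lambda: rng.normal(0.0, 0.03, size=3)
        atoms: list[tuple[str, np.ndarray]] = []
        # sugar ring: pentagon-ish arrangement around the sugar centre
        for k, name in enumerate(_SUGAR):
            phi = 2 * np.pi * k / len(_SUGAR)
            atoms.append(
                (name, s_center + 1.25 * (np.cos(phi) * t + np.sin(phi) * z) + jitter())
            )
        # phosphate group sits above the sugar along the strand axis
        p_pos = s_center + np.array([0.6, 0.0, 2.1])
        atoms.append(("P", p_pos + jitter()))
        atoms.append(("OP1", p_pos + 1.45 * t + jitter()))
        atoms.append(("OP2", p_pos - 1.45 * t + jitter()))
        # base: ring extending toward the protein partner
        base_names = _PURINE_BASE.get(code) or _PYRIMIDINE_BASE[code]
        b_center = s_center + 3.1 * u
        nb = len(base_names)
        for k, name in enumerate(base_names):
            phi = 2 * np.pi * k / nb
            radius = 1.55 if nb > 8 else 1.35
            atoms.append(
                (name, b_center + radius * (np.cos(phi) * u + np.sin(phi) * z) + jitter())
            )
        if spec.with_hydrogens:
            # one polar hydrogen on the 2'-hydroxyl
            o2 = dict(atoms)["O2'"]
            atoms.append(("HO2'", o2 + np.array([0.6, 0.6, 0.4])))
        alist = []
        for name, pos in atoms:
            serial += 1
            alist.append(
                Atom(
                    name=name,
                    element="H" if name.startswith("H") else _element_of_name(name),
                    coords=pos,
                    is_hydrogen=name.startswith("H"),
                    serial=serial,
                )
            )
        units.append(
            ResidueUnit(
                kind=KIND_RNA,
                code=code,
                seq_id=j + 1,
                chain_id="B",
                atoms=alist,
            )
        )
    return units


def _min_inter_distance(cx: Complex) -> float:
    P = cx.partner_heavy_coords("protein")
    R = cx.partner_heavy_coords("rna")
    return float(cdist(P, R).min())


def make_complex(spec: FixtureSpec, path: str | Path | None = None) -> Complex:
    """Deterministic idealized complex; optionally written as a PDB file.

    The RNA strand is placed so that the minimum inter-partner
    heavy-atom distance equals ``spec.interface_gap`` (to ~0.01 A).
    """
    rng = np.random.default_rng(spec.seed)
    protein = _protein_units(spec, rng)
    rna_rng_state = rng.bit_generator.state  # reuse identical jitter per offset

    def build(offset: float) -> Complex:
        r = np.random.default_rng()
        r.bit_generator.state = rna_rng_state
        return Complex(
            protein=protein,
            rna=_rna_units(spec, r, offset),
            id=f"synth{spec.seed}",
        )

    def gap_error(offset: float) -> float:
        return _min_inter_distance(build(offset)) - spec.interface_gap

    offset = brentq(gap_error, 3.0, 80.0, xtol=1e-3)
    cx = build(float(offset))
    cx.validate()
    if path is not None:
        from .pose import Pose
        from .structure import write_pdb

        write_pdb(cx, Pose.identity(), path)
    return cx


# amplitude regimes used to steer the ensemble's class balance: the
# near-native channel stays well below the 5 A label boundary, the decoy
# channel well above 8 A.  The far channel relies on a large translation
# with only modest rotation: very large rotations can, rarely, map the
# nearly-colinear interface phosphate line back onto itself and produce
# an accidental small-Irmsd pose.
_TIGHT = PerturbationSetting("tight", 0.6, 2.0)
_FAR = PerturbationSetting("far", 60.0, 10.0)


def make_decoy_ensemble(
    cx: Complex, n: int, target_nn_fraction: float, seed: int = 0
) -> LabelledDecoySet:
    """Decoy ensemble with a controlled near-native fraction.

    Mixes low- and high-amplitude perturbations so that the realized
    near-native fraction matches the target to binomial accuracy.
    """
    if not (0.0 <= target_nn_fraction <= 1.0):
        raise ValueError("target_nn_fraction must be within [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    calc = IrmsdCalculator(cx)
    decoys = []
    for _ in range(n):
        setting = _TIGHT if rng.random() < target_nn_fraction else _FAR
        pose = sample_pose(setting, rng)
        r = calc.of_pose(pose)
        decoys.append(Decoy(pose=pose, irmsd=r, label=label_for(r)))
    return LabelledDecoySet(complex_id=cx.id, decoys=decoys, setting_used=_TIGHT)


def make_feature_matrix(spec: SyntheticMatrixSpec) -> FeatureMatrix:
    """Feature matrix whose Bayes-optimal linear score is ``true_weights``.

    Class-conditional Gaussians with isotropic noise, the near-native
    class shifted by one unit along the true weight direction (so the
    optimal linear discriminant direction is exactly the true weight
    vector); ``noise_sd = 0`` gives perfect separation.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.true_weights.as_array()
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("true_weights must be non-zero")
    direction = w / norm
    k = len(w)
    X, y, groups = [], [], []
    for g in range(spec.n_groups):
        for label in (1, 0):
            base = spec.noise_sd * rng.normal(size=(spec.rows_per_class, k))
            shift = -label * direction  # lower energy terms for near-natives
            X.append(base + shift)
            y.extend([label] * spec.rows_per_class)
            groups.extend([f"g{g:03d}"] * spec.rows_per_class)
    return FeatureMatrix(
        X=np.vstack(X), y=np.array(y), groups=np.array(groups), terms=TERM_KEYS
    )
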