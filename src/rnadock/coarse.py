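"""Coarse-grained (low-resolution) representation.

Each residue or nucleotide is reduced to its backbone heavy atoms plus a
single centroid pseudo-atom standing in for the side chain (protein) or
the base (RNA).  The centroid is the unweighted geometric centre of the
side-chain/base heavy atoms; a mass-weighted variant is available as an
option but differs negligibly for C/N/O-dominated groups.  Glycine has
no side-chain heavy atom, so its centroid falls back to the CA position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Complex, ResidueUnit

# monoisotopic-ish masses for the optional mass-weighted centroid
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


@dataclass
class CentroidUnit:
    source: ResidueUnit
    centroid: np.ndarray
    backbone: np.ndarray  # (n, 3) backbone heavy-atom coordinates

    @property
    def code(self) -> str:
        return self.source.code

    @property
    def kind(self) -> str:
        return self.source.kind

    def coarse_coords(self) -> np.ndarray:
        """Backbone atoms plus the centroid, stacked."""
        return np.vstack([self.backbone, self.centroid[None, :]])


@dataclass
class CentroidModel:
    protein_units: list[CentroidUnit]
    rna_units: list[CentroidUnit]

    def centroids(self, partner: str) -> np.ndarray:
        units = self.protein_units if partner == "protein" else self.rna_units
        return np.array([u.centroid for u in units])

    def coarse_coords(self, partner: str) -> np.ndarray:
        units = self.protein_units if partner == "protein" else self.rna_units
        return np.vstack([u.coarse_coords() for u in units])


def _centroid_of(unit: ResidueUnit, mass_weighted: bool) -> np.ndarray:
    side = unit.sidechain_atoms
    if not side:
        # glycine (or stripped side chain): use CA as the centroid
        ca = unit.atom("CA")
        if ca is not None:
            return ca.coords.copy()
        raise ValueError(
            f"unit {unit.code} {unit.chain_id}{unit.key}: no side-chain "
            "heavy atoms and no CA fallback"
        )
    coords = np.array([a.coords for a in side])
    if mass_weighted:
        w = np.array([_MASSES.get(a.element, 12.0) for a in side])
        return (coords * w[:, None]).sum(axis=0) / w.sum()
    return coords.mean(axis=0)


def reduce(cx: Complex, mass_weighted: bool = False) -> CentroidModel:
    """Build the backbone + one-centroid-per-unit model of a complex.

    Raises ``ValueError`` for a unit with no heavy atoms at all.
    """
    cx.validate()

    def _reduce_units(units: list[ResidueUnit]) -> list[CentroidUnit]:
        out = []
        for u in units:
            if not u.heavy_atoms:
                raise ValueError(
                    f"unit {u.code} {u.chain_id}{u.key}: no heavy atoms"
                )
            centroid = _centroid_of(u, mass_weighted)
            bb = u.backbone_atoms
            backbone = (
                np.array([a.coords for a in bb]) if bb else centroid[None, :].copy()
            )
            out.append(CentroidUnit(source=u, centroid=centroid, backbone=backbone))
        return out

    return CentroidModel(
        protein_units=_reduce_units(cx.protein),
        rna_units=_reduce_units(cx.rna),
    )
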