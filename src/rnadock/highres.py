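"""All-atom (high-resolution) scoring function.

Ten term slots combined by a box-constrained weight vector:

* ``fa_atr`` / ``fa_rep`` -- attractive and repulsive halves of a 12-6
  Lennard-Jones potential, split at zero energy, with the repulsive
  branch linearized at very short range;
* ``fa_sol`` -- Lazaridis-Karplus Gaussian-exclusion implicit solvation;
* ``fa_pair`` -- the statistical residue-nucleotide contact potential
  (reuses the table estimated at the centroid level);
* ``fa_dun`` -- rotamer internal energy; rotamer machinery is switched
  off for RNA docking so this term is identically zero, but the slot is
  kept so weight vectors retain the standard ten components;
* ``hack_elec`` -- Coulomb electrostatics with a distance-dependent
  dielectric;
* ``hbond_{lr,sr}_{bb,sc}`` -- a 10-12 hydrogen-bond potential binned
  by backbone/side-chain and sequence range.  Only inter-partner
  interactions are scored (the rigid partners' internal energy is
  pose-invariant and cancels in ranking), so all hydrogen bonds are
  long-range and the short-range slots stay zero.

Lower total = better.  Every term is exactly linear in its weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .atomtypes import AtomType, assign_type, load_atom_types
from .pose import Pose
from .structure import Complex

TERM_KEYS = (
    "fa_atr",
    "fa_rep",
    "fa_sol",
    "fa_pair",
    "fa_dun",
    "hack_elec",
    "hbond_lr_bb",
    "hbond_sr_bb",
    "hbond_lr_sc",
    "hbond_sr_sc",
)

COULOMB_K = 332.0637  # kcal mol^-1 A e^-2


@dataclass(frozen=True)
class WeightVector:
    """Box-constrained weights, one per term key, each in [0, 1]."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(TERM_KEYS):
            raise ValueError(f"expected {len(TERM_KEYS)} weights")
        for k, v in zip(TERM_KEYS, self.values):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"weight {k}={v} outside [0, 1]")

    @staticmethod
    def ones() -> "WeightVector":
        return WeightVector(tuple(1.0 for _ in TERM_KEYS))

    @staticmethod
    def zeros() -> "WeightVector":
        return WeightVector(tuple(0.0 for _ in TERM_KEYS))

    @staticmethod
    def from_dict(d: dict[str, float]) -> "WeightVector":
        return WeightVector(tuple(float(d.get(k, 0.0)) for k in TERM_KEYS))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(TERM_KEYS, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, key: str) -> float:
        return self.values[TERM_KEYS.index(key)]


@dataclass
class ScoreBreakdown:
    terms: dict[str, float]
    total: float

    def __getitem__(self, key: str) -> float:
        return self.terms[key]


@dataclass
class HighResConfig:
    """Cutoffs and constants for the all-atom terms (config-exposed)."""

    lj_cutoff: float = 6.0
    rep_linearize_frac: float = 0.6  # linearize repulsion below this * r_min
    elec_cutoff: float = 5.5
    elec_min_dist: float = 1.45
    solv_cutoff: float = 6.0
    hbond_min: float = 2.2
    hbond_max: float = 3.6
    hbond_r0: float = 2.9
    hbond_eps: float = 2.0
    pair_cutoff: float = 5.0
    hydrogen_bond_search: float = 1.3  # covalent D-H search radius


class _PartnerArrays:
    """Typed numpy views of one partner's atoms."""

    def __init__(self, units, types: dict[str, AtomType]):
        coords, radius, depth, dg, lam, vol, charge = [], [], [], [], [], [], []
        donor, acceptor, backbone, unit_idx, codes = [], [], [], [], []
        h_coords, h_unit = [], []
        for ui, u in enumerate(units):
            codes.append(u.code)
            bb_names = u.backbone_names
            for a in u.atoms:
                if a.is_hydrogen:
                    h_coords.append(a.coords)
                    h_unit.append(ui)
                    continue
                t = types.get(assign_type(u.kind, u.code, a.name, a.element))
                if t is None:
                    raise KeyError(
                        f"no atom type for {u.code}.{a.name} ({a.element})"
                    )
                coords.append(a.coords)
                radius.append(t.lj_radius)
                depth.append(t.lj_welldepth)
                dg.append(t.lk_dgfree)
                lam.append(t.lk_lambda)
                vol.append(t.lk_volume)
                charge.append(t.charge)
                donor.append(t.donor)
                acceptor.append(t.acceptor)
                backbone.append(a.name in bb_names)
                unit_idx.append(ui)
        self.coords = np.array(coords)
        self.radius = np.array(radius)
        self.depth = np.array(depth)
        self.dg = np.array(dg)
        self.lam = np.array(lam)
        self.vol = np.array(vol)
        self.charge = np.array(charge)
        self.donor = np.array(donor, dtype=bool)
        self.acceptor = np.array(acceptor, dtype=bool)
        self.backbone = np.array(backbone, dtype=bool)
        self.unit_idx = np.array(unit_idx, dtype=int)
        self.codes = codes
        self.n_units = len(units)
        self.h_coords = np.array(h_coords) if h_coords else np.empty((0, 3))
        self.h_unit = np.array(h_unit, dtype=int)


class HighResScorer:
    """Precomputes atom arrays for a complex and scores poses.

    The protein partner is fixed; a :class:`Pose` moves the RNA.
    """

    def __init__(
        self,
        cx: Complex,
        pair_table: dict[tuple[str, str], float] | None = None,
        config: HighResConfig | None = None,
        atom_types: dict[str, AtomType] | None = None,
    ):
        cx.validate()
        self.cx = cx
        self.config = config or HighResConfig()
        types = atom_types or load_atom_types()
        self.prot = _PartnerArrays(cx.protein, types)
        self.rna = _PartnerArrays(cx.rna, types)
        self.pair_table = pair_table
        self.pivot = cx.rna_pivot()

    def _rna_coords(self, pose: Pose | None) -> tuple[np.ndarray, np.ndarray]:
        if pose is None or pose.is_identity:
            return self.rna.coords, self.rna.h_coords
        heavy = pose.apply(self.rna.coords, self.pivot)
        hyd = (
            pose.apply(self.rna.h_coords, self.pivot)
            if len(self.rna.h_coords)
            else self.rna.h_coords
        )
        return heavy, hyd

    # --- individual terms -------------------------------------------------

    def lj(self, pose: Pose | None = None) -> tuple[float, float]:
        cfg = self.config
        R, _ = self._rna_coords(pose)
        d = cdist(self.prot.coords, R)
        mask = d < cfg.lj_cutoff
        if not mask.any():
            return 0.0, 0.0
        ii, jj = np.nonzero(mask)
        dij = d[ii, jj]
        rmin = self.prot.radius[ii] + self.rna.radius[jj]
        eps = np.sqrt(self.prot.depth[ii] * self.rna.depth[jj])
        d0 = cfg.rep_linearize_frac * rmin
        dd = np.maximum(dij, d0)
        x6 = (rmin / dd) ** 6
        e = eps * (x6 * x6 - 2.0 * x6)
        # linear continuation of the repulsive wall below d0
        slope = eps * 12.0 * (-(rmin**12) / d0**13 + rmin**6 / d0**7)
        lin = dij < d0
        e = np.where(lin, e + (-slope) * (d0 - dij), e)
        atr = float(e[e <= 0].sum())
        rep = float(e[e > 0].sum())
        return atr, rep

    def elec(self, pose: Pose | None = None) -> float:
        cfg = self.config
        R, _ = self._rna_coords(pose)
        d = cdist(self.prot.coords, R)
        mask = d < cfg.elec_cutoff
        if not mask.any():
            return 0.0
        ii, jj = np.nonzero(mask)
        deff = np.maximum(d[ii, jj], cfg.elec_min_dist)
        q = self.prot.charge[ii] * self.rna.charge[jj]
        # distance-dependent dielectric eps(d) = d -> 1/d^2 falloff
        return float((COULOMB_K * q / (deff * deff)).sum())

    def solv(self, pose: Pose | None = None) -> float:
        cfg = self.config
        R, _ = self._rna_coords(pose)
        d = cdist(self.prot.coords, R)
        mask = d < cfg.solv_cutoff
        if not mask.any():
            return 0.0
        ii, jj = np.nonzero(mask)
        dij = d[ii, jj]
        pref = 2.0 * np.pi**1.5
        xi = (dij - self.prot.radius[ii]) / self.prot.lam[ii]
        xj = (dij - self.rna.radius[jj]) / self.rna.lam[jj]
        term_i = (
            -self.prot.dg[ii]
            / (pref * self.prot.lam[ii] * dij**2)
            * np.exp(-(xi**2))
            * self.rna.vol[jj]
        )
        term_j = (
            -self.rna.dg[jj]
            / (pref * self.rna.lam[jj] * dij**2)
            * np.exp(-(xj**2))
            * self.prot.vol[ii]
        )
        return float((term_i + term_j).sum())

    def _hbond_factor(
        self,
        donors: _PartnerArrays,
        d_coords: np.ndarray,
        h_coords: np.ndarray,
        di: int,
        acc_pos: np.ndarray,
    ) -> float:
        """cos^2 of the D-H...A angle, best over hydrogens bound to donor di.

        Falls back to 1.0 when the donor carries no resolved hydrogen.
        """
        if len(h_coords) == 0:
            return 1.0
        same_unit = donors.h_unit == donors.unit_idx[di]
        if not same_unit.any():
            return 1.0
        hs = h_coords[same_unit]
        dist = np.linalg.norm(hs - d_coords[di], axis=1)
        attached = hs[dist < self.config.hydrogen_bond_search]
        if len(attached) == 0:
            return 1.0
        best = 0.0
        for h in attached:
            v1 = d_coords[di] - h
            v2 = acc_pos - h
            nn = np.linalg.norm(v1) * np.linalg.norm(v2)
            if nn == 0:
                continue
            c = float(np.dot(v1, v2) / nn)
            if c < 0.0:  # angle beyond 90 deg, i.e. roughly linear D-H...A
                best = max(best, c * c)
        return best

    def hbond(self, pose: Pose | None = None) -> tuple[float, float, float, float]:
        """(lr_bb, sr_bb, lr_sc, sr_sc) hydrogen-bond energies."""
        cfg = self.config
        Rh, Rhyd = self._rna_coords(pose)
        lr_bb = 0.0
        lr_sc = 0.0
        for donors, d_coords, d_hyd, accept, a_coords in (
            (self.prot, self.prot.coords, self.prot.h_coords, self.rna, Rh),
            (self.rna, Rh, Rhyd, self.prot, self.prot.coords),
        ):
            d_idx = np.nonzero(donors.donor)[0]
            a_idx = np.nonzero(accept.acceptor)[0]
            if len(d_idx) == 0 or len(a_idx) == 0:
                continue
            d = cdist(d_coords[d_idx], a_coords[a_idx])
            win = (d >= cfg.hbond_min) & (d <= cfg.hbond_max)
            for pi, pj in zip(*np.nonzero(win)):
                di, aj = d_idx[pi], a_idx[pj]
                r = d[pi, pj]
                x10 = (cfg.hbond_r0 / r) ** 10
                radial = cfg.hbond_eps * (5.0 * x10 * (cfg.hbond_r0 / r) ** 2 - 6.0 * x10)
                fac = self._hbond_factor(donors, d_coords, d_hyd, di, a_coords[aj])
                e = radial * fac
                if donors.backbone[di] and accept.backbone[aj]:
                    lr_bb += e
                else:
                    lr_sc += e
        # inter-partner bonds are all long-range by definition
        return lr_bb, 0.0, lr_sc, 0.0

    def pair(self, pose: Pose | None = None) -> float:
        if self.pair_table is None:
            return 0.0
        cfg = self.config
        R, _ = self._rna_coords(pose)
        d = cdist(self.prot.coords, R)
        mins = np.full((self.prot.n_units, self.rna.n_units), np.inf)
        np.minimum.at(
            mins,
            (
                self.prot.unit_idx[:, None].repeat(len(R), axis=1),
                self.rna.unit_idx[None, :].repeat(len(self.prot.coords), axis=0),
            ),
            d,
        )
        total = 0.0
        for i, j in zip(*np.nonzero(mins < cfg.pair_cutoff)):
            key = (self.prot.codes[i], self.rna.codes[j])
            if key not in self.pair_table:
                raise KeyError(f"pair {key} missing from pair table")
            total += self.pair_table[key]
        return total

    # --- combined ---------------------------------------------------------

    def terms(self, pose: Pose | None = None) -> dict[str, float]:
        atr, rep = self.lj(pose)
        lr_bb, sr_bb, lr_sc, sr_sc = self.hbond(pose)
        return {
            "fa_atr": atr,
            "fa_rep": rep,
            "fa_sol": self.solv(pose),
            "fa_pair": self.pair(pose),
            "fa_dun": 0.0,  # rotamer machinery off for rigid RNA docking
            "hack_elec": self.elec(pose),
            "hbond_lr_bb": lr_bb,
            "hbond_sr_bb": sr_bb,
            "hbond_lr_sc": lr_sc,
            "hbond_sr_sc": sr_sc,
        }

    def score(self, pose: Pose | None, weights: WeightVector) -> ScoreBreakdown:
        terms = self.terms(pose)
        total = sum(weights[k] * v for k, v in terms.items())
        return ScoreBreakdown(terms=terms, total=total)


# --- functional wrappers (one-shot convenience API) -----------------------

def score_lj(cx: Complex, pose: Pose | None = None, config: HighResConfig | None = None):
    return HighResScorer(cx, config=config).lj(pose)


def score_elec(cx: Complex, pose: Pose | None = None, config: HighResConfig | None = None):
    return HighResScorer(cx, config=config).elec(pose)


def score_solv(cx: Complex, pose: Pose | None = None, config: HighResConfig | None = None):
    return HighResScorer(cx, config=config).solv(pose)


def score_hbond(cx: Complex, pose: Pose | None = None, config: HighResConfig | None = None):
    return HighResScorer(cx, config=config).hbond(pose)


def score_pair_atomic(
    cx: Complex,
    pose: Pose | None,
    pair_table: dict[tuple[str, str], float],
    config: HighResConfig | None = None,
):
    return HighResScorer(cx, pair_table=pair_table, config=config).pair(pose)


def score_highres(
    cx: Complex,
    pose: Pose | None,
    weights: WeightVector,
    pair_table: dict[tuple[str, str], float] | None = None,
    config: HighResConfig | None = None,
) -> ScoreBreakdown:
    return HighResScorer(cx, pair_table=pair_table, config=config).score(pose, weights)


def save_weights(weights: WeightVector, path, intercept: float | None = None) -> None:
    lines = [f"{k}\t{v!r}" for k, v in weights.as_dict().items()]
    if intercept is not None:
        lines.append(f"intercept\t{intercept!r}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def load_weights(path) -> tuple[WeightVector, float]:
    from pathlib import Path

    d: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        k, v = line.split("\t")
        d[k] = float(v)
    intercept = d.pop("intercept", 0.0)
    return WeightVector.from_dict(d), intercept
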