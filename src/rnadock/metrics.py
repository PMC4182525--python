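"""Assessment metrics for docking decoys.

* Interface RMSD (Irmsd): RMSD over the native-interface backbone atoms
  -- protein N, CA, C, O and RNA phosphorus atoms -- after a
  least-squares rigid superposition of the decoy interface onto the
  native one.  The interface is defined once, on the native complex, as
  every residue/nucleotide with a heavy atom within 10 A of the other
  partner.
* ROC curve and its area (AUC), tie-aware: the probability that a
  random near-native decoy is scored better (lower energy) than a
  random non-native one, ties counted one half.
* Enrichment Score (ES): overlap between the best 10% of decoys by
  energy and the best 10% by Irmsd, normalized so that random scoring
  gives 1 in expectation and perfect agreement gives 10.
* Top-k precision: near-natives among the k best-energy decoys, with
  the chance expectation k * n_near_native / N for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from sklearn.metrics import roc_curve

from .pose import Pose
from .structure import Complex, KIND_PROTEIN

NEAR_NATIVE_IRMSD = 5.0  # assessment threshold: near-native vs non-native

_PROTEIN_FIT_ATOMS = ("N", "CA", "C", "O")
_RNA_FIT_ATOMS = ("P",)


@dataclass
class InterfaceDefinition:
    """Native-interface unit indices per partner."""

    protein_idx: list[int]
    rna_idx: list[int]
    cutoff: float = 10.0

    @staticmethod
    def from_complex(native: Complex, cutoff: float = 10.0) -> "InterfaceDefinition":
        P = native.partner_heavy_coords("protein")
        R = native.partner_heavy_coords("rna")
        d = cdist(P, R)
        # map flat heavy-atom rows back to unit indices
        p_units = np.concatenate(
            [np.full(len(u.heavy_atoms), i) for i, u in enumerate(native.protein)]
        )
        r_units = np.concatenate(
            [np.full(len(u.heavy_atoms), i) for i, u in enumerate(native.rna)]
        )
        close = d < cutoff
        prot = sorted(set(p_units[close.any(axis=1)].tolist()))
        rna = sorted(set(r_units[close.any(axis=0)].tolist()))
        if not prot or not rna:
            raise ValueError("empty native interface")
        return InterfaceDefinition(protein_idx=prot, rna_idx=rna, cutoff=cutoff)


def _fit_atoms(cx: Complex, interface: InterfaceDefinition) -> list[tuple[str, int, str]]:
    """(partner, unit index, atom name) of the superposition atom set."""
    out = []
    for i in interface.protein_idx:
        u = cx.protein[i]
        for name in _PROTEIN_FIT_ATOMS:
            if u.atom(name) is not None:
                out.append(("protein", i, name))
    for j in interface.rna_idx:
        u = cx.rna[j]
        for name in _RNA_FIT_ATOMS:
            if u.atom(name) is not None:
                out.append(("rna", j, name))
    return out


def _gather(cx: Complex, keys: list[tuple[str, int, str]]) -> np.ndarray:
    coords = []
    for partner, i, name in keys:
        u = (cx.protein if partner == "protein" else cx.rna)[i]
        a = u.atom(name)
        if a is None:
            raise ValueError(f"decoy missing atom {name} in {partner} unit {i}")
        coords.append(a.coords)
    return np.array(coords)


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares RMSD of ``b`` onto ``a`` after optimal rotation+translation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def irmsd(
    native: Complex,
    decoy: Complex | Pose,
    interface: InterfaceDefinition | None = None,
) -> float:
    """Interface RMSD of a decoy (a full complex or a rigid pose) vs native."""
    if interface is None:
        interface = InterfaceDefinition.from_complex(native)
    keys = _fit_atoms(native, interface)
    if len(keys) < 3:
        raise ValueError("interface fit set too small")
    ref = _gather(native, keys)
    if isinstance(decoy, Pose):
        mov = _gather(native.with_pose(decoy), keys)
    else:
        mov = _gather(decoy, keys)
    return superposed_rmsd(ref, mov)


class IrmsdCalculator:
    """Precomputed native interface for scoring many poses quickly."""

    def __init__(self, native: Complex, cutoff: float = 10.0):
        self.native = native
        self.interface = InterfaceDefinition.from_complex(native, cutoff)
        keys = _fit_atoms(native, self.interface)
        if len(keys) < 3:
            raise ValueError("interface fit set too small")
        self.ref = _gather(native, keys)
        self._prot_ref = np.array(
            [c for k, c in zip(keys, self.ref) if k[0] == "protein"]
        )
        rna_keys = [k for k in keys if k[0] == "rna"]
        self._rna_ref = np.array([_gather(native, [k])[0] for k in rna_keys])
        self.pivot = native.rna_pivot()

    def of_pose(self, pose: Pose) -> float:
        moved = pose.apply(self._rna_ref, self.pivot) if len(self._rna_ref) else self._rna_ref
        mov = np.vstack([self._prot_ref, moved])
        ref = np.vstack([self._prot_ref, self._rna_ref])
        return superposed_rmsd(ref, mov)


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Tie-aware ROC-AUC for lower-is-better scores.

    Returns ``(auc, points)`` where ``points`` is an (m, 2) array of
    (FPR, TPR) pairs.  The AUC is the Mann-Whitney rank statistic with
    ties counted 1/2, identical to the trapezoidal area under the
    tie-aware ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined: only one class present")
    from scipy.stats import rankdata

    # lower score = better = more near-native-like: rank ascending on -score
    ranks = rankdata(-scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, -scores)
    return float(auc), np.column_stack([fpr, tpr])


def enrichment_score(scores, irmsds, fraction: float = 0.10) -> float:
    """Overlap of the top-``fraction`` sets by energy and by Irmsd.

    ``ES = |E_top & R_top| / (fraction^2 * N)``: 0 for disjoint sets,
    1 in expectation for random scoring, ``1/fraction`` for perfect
    agreement of the two orderings.
    """
    scores = np.asarray(scores, dtype=float)
    irmsds = np.asarray(irmsds, dtype=float)
    n = len(scores)
    if n != len(irmsds):
        raise ValueError("scores and irmsds must have equal length")
    if n < 1.0 / fraction:
        raise ValueError(f"need at least {int(np.ceil(1 / fraction))} decoys")
    k = int(np.floor(fraction * n))
    e_top = set(np.argsort(scores, kind="stable")[:k].tolist())
    r_top = set(np.argsort(irmsds, kind="stable")[:k].tolist())
    return len(e_top & r_top) / (fraction * fraction * n)


def topk_stats(scores, labels, ks=(10, 100)) -> dict[str, float]:
    """Near-natives among the k best-energy decoys, plus chance expectation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    if n < max(ks):
        raise ValueError("fewer decoys than the largest k")
    order = np.argsort(scores, kind="stable")
    n_nn = int(labels.sum())
    out: dict[str, float] = {"n_near_native": n_nn}
    for k in ks:
        out[f"top{k}"] = int(labels[order[:k]].sum())
        out[f"expected_top{k}"] = k * n_nn / n
    return out


@dataclass
class EvaluationReport:
    auc: float
    roc_points: np.ndarray
    es: float
    top10_nn: int
    top100_nn: int
    expected_top10: float
    n_near_native: int


def evaluate_ranked(
    scores,
    irmsds,
    nn_threshold: float = NEAR_NATIVE_IRMSD,
    fraction: float = 0.10,
) -> EvaluationReport:
    """Full assessment of one decoy set: AUC, ES, and top-k precision."""
    scores = np.asarray(scores, dtype=float)
    irmsds = np.asarray(irmsds, dtype=float)
    labels = (irmsds < nn_threshold).astype(int)
    auc, points = roc_auc(scores, labels)
    es = enrichment_score(scores, irmsds, fraction)
    tk = topk_stats(scores, labels)
    return EvaluationReport(
        auc=auc,
        roc_points=points,
        es=es,
        top10_nn=int(tk["top10"]),
        top100_nn=int(tk["top100"]),
        expected_top10=float(tk["expected_top10"]),
        n_near_native=int(tk["n_near_native"]),
    )
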