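"""Low-resolution (centroid-level) scoring function and its parameters.

The score combines four weighted terms computed on the coarse-grained
model:

* ``contact`` -- the number of interface units, an interface residue or
  nucleotide having its centroid less than ``contact_cutoff`` (6 A by
  default) from a centroid of the other partner; more contacts are
  rewarded, so the term enters the total with a negative sign;
* ``bump`` -- a quadratic steric-clash penalty summed over coarse-atom
  pairs closer than ``clash_distance``;
* ``env`` -- a one-body environment potential, the negative log
  probability of finding each residue/nucleotide type in its
  environment class (interface/non-interface x buried/exposed);
* ``pair`` -- a two-body contact potential, the negative log odds of a
  protein type and a nucleotide type being found in centroid contact.

The ``env`` and ``pair`` tables are counting statistics estimated from
a reference set of complexes with additive pseudocounts; they are not
optimized further.  An alignment-pattern term used for antibody docking
has no protein-RNA counterpart and is not included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .coarse import CentroidModel, reduce
from .structure import Complex, PROTEIN_RESIDUES, RNA_RESIDUES

PROTEIN_TYPES = tuple(sorted(PROTEIN_RESIDUES))
RNA_TYPES = tuple(sorted(RNA_RESIDUES))
ALL_TYPES = PROTEIN_TYPES + RNA_TYPES

ENV_CLASSES = (
    "interface|buried",
    "interface|exposed",
    "non_interface|buried",
    "non_interface|exposed",
)

_EPS = 1e-6  # pseudo-probability floor for the pair log-odds


@dataclass
class LowResParams:
    env_logprob: dict[str, dict[str, float]] = field(default_factory=dict)
    pair_logodds: dict[tuple[str, str], float] = field(default_factory=dict)
    contact_cutoff: float = 6.0
    clash_distance: float = 3.0
    burial_radius: float = 10.0
    burial_threshold: int = 8
    # term weights: (contact, bump, env, pair); counting statistics are
    # not optimized, so the weights default to unity
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def validate_tables(self) -> None:
        for t in ALL_TYPES:
            if t not in self.env_logprob:
                raise KeyError(f"env table missing type {t}")
            for e in ENV_CLASSES:
                if e not in self.env_logprob[t]:
                    raise KeyError(f"env table missing class {e} for {t}")
        for p in PROTEIN_TYPES:
            for n in RNA_TYPES:
                if (p, n) not in self.pair_logodds:
                    raise KeyError(f"pair table missing ({p}, {n})")


@dataclass
class LowResScore:
    contact: int
    bump: float
    env: float
    pair: float
    total: float


def score_contact(model: CentroidModel, cutoff: float = 6.0) -> int:
    """Number of units whose centroid is within ``cutoff`` of the other partner."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    P = model.centroids("protein")
    R = model.centroids("rna")
    if len(P) == 0 or len(R) == 0:
        raise ValueError("both partners must be non-empty")
    d = cdist(P, R)
    return int((d.min(axis=1) < cutoff).sum() + (d.min(axis=0) < cutoff).sum())


def score_bump(model: CentroidModel, clash_distance: float = 3.0) -> float:
    """Quadratic clash penalty over inter-partner coarse-atom pairs."""
    if clash_distance <= 0:
        raise ValueError("clash_distance must be positive")
    P = model.coarse_coords("protein")
    R = model.coarse_coords("rna")
    d = cdist(P, R)
    close = d < clash_distance
    return float(np.square(clash_distance - d[close]).sum())


def _unit_environments(model: CentroidModel, params: LowResParams) -> list[tuple[str, str]]:
    """(type, environment-class) for every unit of both partners."""
    P = model.centroids("protein")
    R = model.centroids("rna")
    d = cdist(P, R)
    out: list[tuple[str, str]] = []
    for units, own, iface_dist in (
        (model.protein_units, P, d.min(axis=1)),
        (model.rna_units, R, d.min(axis=0)),
    ):
        dd = cdist(own, own)
        # neighbours within the burial radius, excluding the unit itself
        n_neigh = (dd < params.burial_radius).sum(axis=1) - 1
        for i, u in enumerate(units):
            iface = "interface" if iface_dist[i] < params.contact_cutoff else "non_interface"
            burial = "buried" if n_neigh[i] >= params.burial_threshold else "exposed"
            out.append((u.code, f"{iface}|{burial}"))
    return out


def estimate_env_params(
    reference: list[Complex], params: LowResParams | None = None
) -> dict[str, dict[str, float]]:
    """Environment table from counting statistics with add-one pseudocounts.

    ``env_logprob[t][e] = -log[(count(t, e) + 1) / (count(e) + T)]`` over
    the T = 24 residue/nucleotide types.
    """
    if not reference:
        raise ValueError("empty reference set")
    params = params or LowResParams()
    counts = {t: {e: 0 for e in ENV_CLASSES} for t in ALL_TYPES}
    class_totals = {e: 0 for e in ENV_CLASSES}
    for cx in reference:
        model = reduce(cx)
        for code, env in _unit_environments(model, params):
            if code in counts:
                counts[code][env] += 1
                class_totals[env] += 1
    T = len(ALL_TYPES)
    return {
        t: {
            e: -math.log((counts[t][e] + 1) / (class_totals[e] + T))
            for e in ENV_CLASSES
        }
        for t in ALL_TYPES
    }


def score_env(model: CentroidModel, params: LowResParams) -> float:
    """Sum of environment log-probabilities over all units."""
    total = 0.0
    for code, env in _unit_environments(model, params):
        try:
            total += params.env_logprob[code][env]
        except KeyError:
            raise KeyError(f"type {code!r} / class {env!r} missing from env table")
    return total


def _contact_pairs(model: CentroidModel, cutoff: float) -> list[tuple[str, str]]:
    P = model.centroids("protein")
    R = model.centroids("rna")
    d = cdist(P, R)
    ii, jj = np.nonzero(d < cutoff)
    return [
        (model.protein_units[i].code, model.rna_units[j].code)
        for i, j in zip(ii, jj)
    ]


def estimate_pair_params(
    reference: list[Complex], params: LowResParams | None = None
) -> dict[tuple[str, str], float]:
    """Contact log-odds table.

    ``pair_logodds[a][b] = -log[(P(a,b | contact) + eps) / (P(a) P(b) + eps)]``
    where a contact is an inter-partner centroid pair closer than the
    contact cutoff and P(a), P(b) are the marginal type frequencies of
    each partner over the reference set.
    """
    if not reference:
        raise ValueError("empty reference set")
    params = params or LowResParams()
    pair_counts = {(p, n): 0 for p in PROTEIN_TYPES for n in RNA_TYPES}
    prot_counts = {p: 0 for p in PROTEIN_TYPES}
    rna_counts = {n: 0 for n in RNA_TYPES}
    n_contacts = 0
    for cx in reference:
        model = reduce(cx)
        for u in model.protein_units:
            if u.code in prot_counts:
                prot_counts[u.code] += 1
        for u in model.rna_units:
            if u.code in rna_counts:
                rna_counts[u.code] += 1
        for p, n in _contact_pairs(model, params.contact_cutoff):
            if (p, n) in pair_counts:
                pair_counts[(p, n)] += 1
                n_contacts += 1
    n_prot = sum(prot_counts.values()) or 1
    n_rna = sum(rna_counts.values()) or 1
    table = {}
    for p in PROTEIN_TYPES:
        for n in RNA_TYPES:
            p_ab = pair_counts[(p, n)] / n_contacts if n_contacts else 0.0
            p_a = prot_counts[p] / n_prot
            p_b = rna_counts[n] / n_rna
            table[(p, n)] = -math.log((p_ab + _EPS) / (p_a * p_b + _EPS))
    return table


def score_pair(model: CentroidModel, params: LowResParams) -> float:
    """Sum of pair log-odds over inter-partner centroid contacts."""
    total = 0.0
    for key in _contact_pairs(model, params.contact_cutoff):
        try:
            total += params.pair_logodds[key]
        except KeyError:
            raise KeyError(f"pair {key} missing from pair table")
    return total


def score_lowres(model: CentroidModel, params: LowResParams) -> LowResScore:
    """Weighted low-resolution total; lower is better.

    The contact count is negated so that forming more interface contacts
    lowers the score, while clashes and unfavourable statistics raise it.
    """
    contact = score_contact(model, params.contact_cutoff)
    bump = score_bump(model, params.clash_distance)
    env = score_env(model, params)
    pair = score_pair(model, params)
    w_c, w_b, w_e, w_p = params.weights
    total = w_c * (-contact) + w_b * bump + w_e * env + w_p * pair
    return LowResScore(contact=contact, bump=bump, env=env, pair=pair, total=total)


# --- parameter-table serialization (tab-delimited text) ---

def save_params(params: LowResParams, path: str | Path) -> None:
    lines = ["table\tkey1\tkey2\tvalue"]
    for name in ("contact_cutoff", "clash_distance", "burial_radius", "burial_threshold"):
        lines.append(f"meta\t{name}\t\t{getattr(params, name)}")
    for i, w in enumerate(params.weights):
        lines.append(f"meta\tweight_{i}\t\t{w}")
    for t, row in params.env_logprob.items():
        for e, v in row.items():
            lines.append(f"env\t{t}\t{e}\t{v!r}")
    for (p, n), v in params.pair_logodds.items():
        lines.append(f"pair\t{p}\t{n}\t{v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_params(path: str | Path) -> LowResParams:
    params = LowResParams()
    weights = list(params.weights)
    env: dict[str, dict[str, float]] = {}
    pair: dict[tuple[str, str], float] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        table, k1, k2, v = line.split("\t")
        if table == "meta":
            if k1 == "burial_threshold":
                params.burial_threshold = int(float(v))
            elif k1.startswith("weight_"):
                weights[int(k1.split("_")[1])] = float(v)
            else:
                setattr(params, k1, float(v))
        elif table == "env":
            env.setdefault(k1, {})[k2] = float(v)
        elif table == "pair":
            pair[(k1, k2)] = float(v)
    params.weights = tuple(weights)
    params.env_logprob = env
    params.pair_logodds = pair
    return params
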