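"""Rigid-body perturbation decoys around the native pose.

Decoys are generated by perturbing the RNA partner (the protein stays
fixed) with a random rigid motion.  The translation magnitude and each
of the three Euler-angle magnitudes follow a normal law of variance 1
around a setting-dependent mean, clamped at zero; the translation
direction is uniform on the sphere and each rotation sign is random.
Three amplitude regimes are defined:

====================  ===============  ============
setting               translation (A)  rotation (deg)
====================  ===============  ============
small                 1                4
regular               3                8
large                 9                27
====================  ===============  ============

Each decoy is labelled from its interface RMSD against the native:
near-native below 5 A, decoy above 8 A, and ``test`` in between (the
ambiguous band is excluded from learning).  For a given complex the
chosen regime is the smallest one that yields enough (30 by default)
near-natives *and* decoys out of the requested ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .highres import ScoreBreakdown
from .metrics import IrmsdCalculator
from .pose import Pose
from .structure import Complex

LEARN_NEAR_NATIVE_IRMSD = 5.0  # A, label boundary for near-natives
LEARN_DECOY_IRMSD = 8.0  # A, label boundary for decoys

LABEL_NEAR_NATIVE = "near_native"
LABEL_DECOY = "decoy"
LABEL_TEST = "test"


@dataclass(frozen=True)
class PerturbationSetting:
    name: str
    translation_mean: float  # A
    rotation_mean: float  # degrees
    variance: float = 1.0  # fixed by the protocol

    def __post_init__(self) -> None:
        if self.translation_mean < 0 or self.rotation_mean < 0:
            raise ValueError("perturbation means must be non-negative")


SMALL = PerturbationSetting("small", 1.0, 4.0)
REGULAR = PerturbationSetting("regular", 3.0, 8.0)
LARGE = PerturbationSetting("large", 9.0, 27.0)
SETTINGS = (SMALL, REGULAR, LARGE)


@dataclass
class Decoy:
    pose: Pose
    irmsd: float
    label: str
    scores: ScoreBreakdown | None = None


@dataclass
class LabelledDecoySet:
    complex_id: str
    decoys: list[Decoy]
    setting_used: PerturbationSetting

    def count(self, label: str) -> int:
        return sum(1 for d in self.decoys if d.label == label)

    def of_label(self, label: str) -> list[Decoy]:
        return [d for d in self.decoys if d.label == label]

    def irmsds(self) -> np.ndarray:
        return np.array([d.irmsd for d in self.decoys])


def label_for(irmsd_value: float) -> str:
    if irmsd_value < LEARN_NEAR_NATIVE_IRMSD:
        return LABEL_NEAR_NATIVE
    if irmsd_value > LEARN_DECOY_IRMSD:
        return LABEL_DECOY
    return LABEL_TEST


def sample_pose(setting: PerturbationSetting, rng: np.random.Generator) -> Pose:
    """One random rigid perturbation under the given amplitude regime.

    The translation magnitude is ``max(N(mean, 1), 0)`` along a uniform
    random direction; each Euler-angle magnitude is ``max(N(mean, 1), 0)``
    with a random sign.
    """
    sd = np.sqrt(setting.variance)
    t_mag = max(rng.normal(setting.translation_mean, sd), 0.0)
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    translation = t_mag * direction
    angles = []
    for _ in range(3):
        mag = max(rng.normal(setting.rotation_mean, sd), 0.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        angles.append(sign * mag)
    return Pose(rotation=tuple(angles), translation=tuple(translation))


def generate_decoys(
    cx: Complex,
    n: int,
    setting: PerturbationSetting,
    seed: int | np.random.Generator,
) -> LabelledDecoySet:
    """``n`` labelled perturbation decoys of a native complex."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calc = IrmsdCalculator(cx)
    decoys = []
    for _ in range(n):
        pose = sample_pose(setting, rng)
        r = calc.of_pose(pose)
        decoys.append(Decoy(pose=pose, irmsd=r, label=label_for(r)))
    return LabelledDecoySet(complex_id=cx.id, decoys=decoys, setting_used=setting)


def select_setting(
    cx: Complex,
    n: int,
    required: int = 30,
    seed: int = 0,
) -> PerturbationSetting:
    """Smallest amplitude regime yielding >= ``required`` of both classes.

    Tries small, then regular, then large, regenerating the ensemble at
    each regime; raises with the per-regime class counts if none works.
    """
    counts = {}
    for k, setting in enumerate(SETTINGS):
        ds = generate_decoys(cx, n, setting, np.random.default_rng([seed, k]))
        nn, dec = ds.count(LABEL_NEAR_NATIVE), ds.count(LABEL_DECOY)
        counts[setting.name] = (nn, dec)
        if nn >= required and dec >= required:
            return setting
    raise RuntimeError(
        f"{cx.id}: no perturbation setting yields {required} near-natives "
        f"and {required} decoys out of {n}; counts per setting: {counts}"
    )


def assemble_learning_set(
    sets: list[LabelledDecoySet],
    per_class: int = 30,
    seed: int = 0,
) -> list[tuple[str, Decoy]]:
    """Balanced learning sample: ``per_class`` near-natives + decoys per complex.

    Sampling is uniform without replacement; the ambiguous ``test`` band
    never enters the learning set.  Returns (complex id, decoy) rows,
    ``2 * per_class * len(sets)`` in total.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, Decoy]] = []
    for ds in sets:
        for label in (LABEL_NEAR_NATIVE, LABEL_DECOY):
            pool = ds.of_label(label)
            if len(pool) < per_class:
                raise ValueError(
                    f"{ds.complex_id}: only {len(pool)} {label} decoys, "
                    f"need {per_class}"
                )
            picked = rng.choice(len(pool), size=per_class, replace=False)
            rows.extend((ds.complex_id, pool[i]) for i in picked)
    return rows
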