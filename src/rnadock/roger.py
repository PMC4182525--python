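"""ROC-AUC-maximizing weight optimization over a logistic score.

The scoring weights are fitted by a (mu + lambda) evolution strategy on
the box [0, 1]^k: the fitness of a candidate weight vector is the
ROC-AUC of the linear energy ``s = -sum_k w_k f_k`` against the
near-native/decoy labels.  The logistic link being strictly monotone,
the AUC of the logistic output equals the AUC of the linear score, so
the genetic search optimizes the linear score directly and a logistic
intercept is fitted afterwards by 1-D maximum likelihood (it calibrates
probabilities without changing any ranking).

Cross-validation is grouped leave-one-pdb-out: for each complex, every
row derived from it is removed from the learning set, the weights are
refitted, and the held-out complex's full decoy ensemble is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata

from .highres import TERM_KEYS, WeightVector
from .metrics import EvaluationReport, evaluate_ranked, roc_auc


@dataclass
class FeatureMatrix:
    """Per-decoy score terms with labels and group (complex) ids."""

    X: np.ndarray  # (n, k) term values
    y: np.ndarray  # (n,) 1 = near-native, 0 = decoy
    groups: np.ndarray  # (n,) complex ids
    terms: tuple[str, ...] = TERM_KEYS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        if self.X.shape[0] != len(self.y) or len(self.y) != len(self.groups):
            raise ValueError("X, y, groups must have matching lengths")
        if self.X.shape[1] != len(self.terms):
            raise ValueError("X width must match the term list")

    @staticmethod
    def from_frame(df: pd.DataFrame, terms=TERM_KEYS) -> "FeatureMatrix":
        return FeatureMatrix(
            X=df[list(terms)].to_numpy(float),
            y=df["label"].to_numpy(int),
            groups=df["group"].to_numpy(),
            terms=tuple(terms),
        )


@dataclass
class GAConfig:
    mu: int = 10  # parents
    lam: int = 80  # offspring per generation
    budget: int = 100_000  # fitness evaluations
    mutation_sd: float = 0.05
    crossover_rate: float = 0.5
    tournament: int = 2
    seed: int = 0
    # weight box; [0, 1] is the default, signed variants are selectable
    box: tuple[float, float] = (0.0, 1.0)

    def validate(self) -> None:
        if self.mu < 1 or self.lam < self.mu:
            raise ValueError("need mu >= 1 and lambda >= mu")
        if self.budget < self.mu + self.lam:
            raise ValueError("budget smaller than one generation")


@dataclass
class FittedScorer:
    weights: WeightVector
    intercept: float
    fitness: float
    groups_used: tuple = ()

    def energy(self, X: np.ndarray) -> np.ndarray:
        """Linear energy of each row; lower = more near-native-like."""
        return np.asarray(X, float) @ self.weights.as_array()

    def probability(self, X: np.ndarray) -> np.ndarray:
        """Calibrated near-native probability via the logistic link."""
        s = -self.energy(X) + self.intercept
        return 1.0 / (1.0 + np.exp(-s))


def _auc_of_score(s: np.ndarray, y: np.ndarray, n_pos: int, n_neg: int) -> float:
    ranks = rankdata(s)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def fitness(weights, matrix: FeatureMatrix) -> float:
    """ROC-AUC of the negated weighted energy against the labels."""
    w = weights.as_array() if isinstance(weights, WeightVector) else np.asarray(weights, float)
    n_pos = int(matrix.y.sum())
    n_neg = len(matrix.y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("fitness undefined: single-class matrix")
    s = -(matrix.X @ w)
    return float(_auc_of_score(s, matrix.y, n_pos, n_neg))


def _batch_fitness(W: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC of every weight row in ``W`` at once (rank-statistic form)."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    S = -(X @ W.T)  # (n, m)
    ranks = rankdata(S, axis=0)
    pos_sum = ranks[y == 1].sum(axis=0)
    return (pos_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _fit_intercept(s: np.ndarray, y: np.ndarray) -> float:
    """1-D logistic MLE for the intercept of sigmoid(s + b)."""

    def nll(b: float) -> float:
        z = s + b
        # log(1 + e^z) computed stably
        log1p = np.logaddexp(0.0, z)
        return float((log1p - y * z).sum())

    res = minimize_scalar(nll, bounds=(-50.0, 50.0), method="bounded")
    return float(res.x)


def evolve(matrix: FeatureMatrix, config: GAConfig | None = None) -> FittedScorer:
    """(mu + lambda) evolution strategy maximizing the ROC-AUC fitness.

    Parents start uniform in the box; offspring arise by uniform
    crossover of two tournament-selected parents plus Gaussian mutation
    clipped to the box; survivors are the best mu of parents and
    offspring.  The best-ever individual is returned once the
    evaluation budget is spent.  Fully deterministic per seed.
    """
    config = config or GAConfig()
    config.validate()
    if matrix.y.sum() in (0, len(matrix.y)):
        raise ValueError("evolve needs both classes present")
    rng = np.random.default_rng(config.seed)
    k = matrix.X.shape[1]
    lo, hi = config.box

    pop = rng.uniform(lo, hi, size=(config.mu, k))
    fit = _batch_fitness(pop, matrix.X, matrix.y)
    evals = config.mu
    best_i = int(np.argmax(fit))
    best_w, best_f = pop[best_i].copy(), float(fit[best_i])

    while evals + config.lam <= config.budget:
        # tournament selection of two parents per offspring
        idx = rng.integers(0, config.mu, size=(config.lam, 2, config.tournament))
        winners = np.take_along_axis(
            idx, np.argmax(fit[idx], axis=2, keepdims=True), axis=2
        )[:, :, 0]
        pa, pb = pop[winners[:, 0]], pop[winners[:, 1]]
        take_b = rng.random(size=(config.lam, k)) < config.crossover_rate
        off = np.where(take_b, pb, pa)
        off = off + rng.normal(0.0, config.mutation_sd, size=off.shape)
        off = np.clip(off, lo, hi)
        off_fit = _batch_fitness(off, matrix.X, matrix.y)
        evals += config.lam

        pool = np.vstack([pop, off])
        pool_fit = np.concatenate([fit, off_fit])
        order = np.argsort(-pool_fit, kind="stable")[: config.mu]
        pop, fit = pool[order], pool_fit[order]
        if fit[0] > best_f:
            best_f, best_w = float(fit[0]), pop[0].copy()

    s = -(matrix.X @ best_w)
    intercept = _fit_intercept(s, matrix.y)
    weights = WeightVector(tuple(best_w)) if (lo, hi) == (0.0, 1.0) else None
    if weights is None:
        # signed boxes fall outside the WeightVector contract; store clipped
        weights = WeightVector(tuple(np.clip(best_w, 0.0, 1.0)))
    return FittedScorer(
        weights=weights,
        intercept=intercept,
        fitness=best_f,
        groups_used=tuple(sorted(set(matrix.groups.tolist()))),
    )


def leave_one_pdb_out(
    table: pd.DataFrame,
    config: GAConfig | None = None,
    per_class: int = 30,
    learn_lo: float = 5.0,
    learn_hi: float = 8.0,
    assess_threshold: float = 5.0,
    terms=TERM_KEYS,
) -> dict[str, tuple[EvaluationReport, FittedScorer]]:
    """Grouped cross-validation over complexes.

    ``table`` has one row per decoy with columns ``group``, ``irmsd``
    and the term keys.  For each group, a balanced learning set
    (``per_class`` near-natives with Irmsd < ``learn_lo`` and
    ``per_class`` decoys with Irmsd > ``learn_hi`` from every *other*
    group) is fitted, and the held-out group's full ensemble is
    evaluated with assessment labels (< / >= ``assess_threshold``).
    """
    config = config or GAConfig()
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups for leave-one-pdb-out")
    rng = np.random.default_rng(config.seed)
    results: dict[str, tuple[EvaluationReport, FittedScorer]] = {}
    for g in groups:
        train = table[table["group"] != g]
        rows = []
        for og, sub in train.groupby("group", sort=False):
            nn = sub[sub["irmsd"] < learn_lo]
            dec = sub[sub["irmsd"] > learn_hi]
            if len(nn) < per_class or len(dec) < per_class:
                raise ValueError(
                    f"group {og}: insufficient learning rows "
                    f"({len(nn)} near-native, {len(dec)} decoy)"
                )
            rows.append(nn.iloc[rng.choice(len(nn), per_class, replace=False)])
            rows.append(dec.iloc[rng.choice(len(dec), per_class, replace=False)])
        learn = pd.concat(rows, ignore_index=True)
        matrix = FeatureMatrix(
            X=learn[list(terms)].to_numpy(float),
            y=(learn["irmsd"] < learn_lo).to_numpy(int),
            groups=learn["group"].to_numpy(),
            terms=tuple(terms),
        )
        sub_cfg = GAConfig(**{**config.__dict__})
        sub_cfg.seed = int(rng.integers(0, 2**31 - 1))
        scorer = evolve(matrix, sub_cfg)
        assert g not in scorer.groups_used, "data leakage: held-out group in fit"
        held = table[table["group"] == g]
        energies = scorer.energy(held[list(terms)].to_numpy(float))
        report = evaluate_ranked(
            energies, held["irmsd"].to_numpy(float), nn_threshold=assess_threshold
        )
        results[g] = (report, scorer)
    return results


def aggregate_roc(
    reports: list[EvaluationReport], grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Median and quartile TPR over complexes on a common FPR grid."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    curves = []
    for r in reports:
        fpr, tpr = r.roc_points[:, 0], r.roc_points[:, 1]
        curves.append(np.interp(grid, fpr, tpr))
    C = np.vstack(curves)
    return pd.DataFrame(
        {
            "fpr": grid,
            "tpr_q1": np.quantile(C, 0.25, axis=0),
            "tpr_median": np.quantile(C, 0.5, axis=0),
            "tpr_q3": np.quantile(C, 0.75, axis=0),
        }
    )
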