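"""Random-forest ensemble training with negative resampling.

Because no database of true negative kinase-substrate pairs exists and
biological networks are sparse, negatives are drawn uniformly at random from
the specificity-respecting pair space minus the positives. Feature selection
runs recursive feature elimination with cross-validation on 100 resampled
training sets (negatives 10x the positives) and keeps features appearing in
strictly more than half of the selected subsets. The final model is an
ensemble of grid-searched random forests, each trained on the positives plus
a fresh 50x negative sample; edge probabilities are the arithmetic mean of
member outputs.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline

from .feature_engine import FeatureTable
from .types import KSPair, Label, ProbabilisticNetwork

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [10, 20, 50, 70, 80, 100],
    "min_samples_split": [8, 10, 12],
    "n_estimators": [150, 500, 1000, 1500],
}


@dataclass
class TrainingConfig:
    """Knobs of the ensemble training procedure.

    Defaults reproduce the published protocol: 10x negatives for feature
    selection, 50x for final training, 100 ensemble runs, stratified 10-fold
    CV, a 72-point random-forest grid, and a strict >50% feature vote.
    """

    neg_ratio_feature_selection: int = 10
    neg_ratio_final: int = 50
    n_runs: int = 100
    k_folds: int = 10
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    vote_threshold: float = 0.5
    seed: int = 0
    # CV folds used inside RFE and grid search; defaults to k_folds.
    inner_cv: int | None = None

    def __post_init__(self) -> None:
        if self.neg_ratio_feature_selection < 1 or self.neg_ratio_final < 1:
            raise ValueError("negative ratios must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid lists must be non-empty")

    @property
    def grid_points(self) -> list[dict]:
        keys = sorted(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]

    def _inner_cv(self) -> int:
        return self.inner_cv if self.inner_cv is not None else self.k_folds


@dataclass
class EnsembleMember:
    pipeline: Pipeline
    params: dict
    cv_auc: float
    seed: int


@dataclass
class EnsembleModel:
    members: list[EnsembleMember]
    selected_features: list[str]
    config: TrainingConfig

    @property
    def cv_metrics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": range(len(self.members)),
                "cv_auc": [m.cv_auc for m in self.members],
                "params": [repr(m.params) for m in self.members],
            }
        )


def _derive_seeds(seed: int, n: int, label: str) -> list[int]:
    # Stable label hash (Python's str hash is salted per process).
    tag = zlib.crc32(label.encode()) % 2**31
    ss = np.random.SeedSequence([seed, tag])
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def sample_negatives(
    positives: set[tuple[str, str]] | list,
    universe: list[tuple[str, str]],
    ratio: int,
    seed: int,
) -> list[KSPair]:
    """Uniform sample of ``ratio * |positives|`` pairs from universe minus positives."""
    pos_keys = {p.key if isinstance(p, KSPair) else tuple(p) for p in positives}
    pool = [pair for pair in universe if tuple(pair) not in pos_keys]
    n_needed = ratio * len(pos_keys)
    if len(pool) < n_needed:
        raise ValueError(
            f"cannot sample {n_needed} negatives: only {len(pool)} "
            f"non-positive pairs available in the universe"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_needed, replace=False)
    return [KSPair(pool[int(i)][0], pool[int(i)][1], Label.NEGATIVE) for i in idx]


def stratified_folds(labels: np.ndarray | list[int], k: int, seed: int) -> np.ndarray:
    """Stratified k-fold assignment (0..k-1) preserving the class ratio."""
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError(
            f"every class needs >= k={k} members, got counts {counts.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def _training_frame(
    table: FeatureTable,
    positives: list[KSPair],
    negatives: list[KSPair],
) -> tuple[np.ndarray, np.ndarray]:
    keys = [p.key for p in positives] + [n.key for n in negatives]
    sub = table.data.loc[keys]
    y = np.array([1] * len(positives) + [0] * len(negatives))
    return sub.to_numpy(dtype=float), y


def _rf(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        bootstrap=True, random_state=seed, n_jobs=1, **params
    )


def _pipeline(params: dict, seed: int) -> Pipeline:
    # Median imputation is fit on the training portion only (inside CV, per
    # fold), never on the assembled table.
    return Pipeline(
        [("impute", SimpleImputer(strategy="median")), ("rf", _rf(params, seed))]
    )


def majority_vote(subsets: list[list[str]], vote_threshold: float = 0.5) -> list[str]:
    """Features present in strictly more than ``vote_threshold`` of the subsets."""
    if not subsets:
        raise ValueError("no feature subsets to vote over")
    counts: dict[str, int] = {}
    for sub in subsets:
        for f in sub:
            counts[f] = counts.get(f, 0) + 1
    n = len(subsets)
    kept = [f for f, c in counts.items() if c / n > vote_threshold]
    if not kept:
        raise ValueError("majority vote retained no feature (degenerate signal)")
    order = {f: i for i, f in enumerate(dict.fromkeys(f for s in subsets for f in s))}
    return sorted(kept, key=lambda f: order[f])


def rfe_majority_vote(
    table: FeatureTable,
    positives: list[KSPair],
    universe: list[tuple[str, str]],
    config: TrainingConfig,
    rfe_params: dict | None = None,
) -> tuple[list[str], list[list[str]]]:
    """RFE-CV on resampled training sets; majority vote over selected subsets.

    For each of ``config.n_runs`` training sets (positives + fresh negatives
    at ``neg_ratio_feature_selection``) RFE with cross-validation picks the
    AUC-ROC-optimal feature subset; the final list keeps features appearing
    in strictly more than ``vote_threshold`` of the subsets.
    """
    names = table.feature_names
    if len(names) < 2:
        raise ValueError("feature selection needs >= 2 features")
    rfe_params = dict(rfe_params or {})
    est_params = rfe_params.pop("estimator_params", {"n_estimators": 50})
    seeds = _derive_seeds(config.seed, config.n_runs, "rfe")
    subsets: list[list[str]] = []
    for run, run_seed in enumerate(seeds):
        negatives = sample_negatives(
            positives, universe, config.neg_ratio_feature_selection, run_seed
        )
        X, y = _training_frame(table, positives, negatives)
        X = SimpleImputer(strategy="median").fit_transform(X)
        subsets.append(_rfe_cv_once(X, y, names, est_params, config, run_seed))
    return majority_vote(subsets, config.vote_threshold), subsets


def _rfe_cv_once(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    est_params: dict,
    config: TrainingConfig,
    seed: int,
) -> list[str]:
    """One recursive-feature-elimination pass with CV scoring.

    Eliminates the least important feature (forest impurity importance) one
    at a time, scoring every subset along the path by stratified CV AUC-ROC.
    The returned subset is the smallest whose mean AUC lies within one
    standard error of the best path point: near-saturated AUCs make the raw
    argmax a coin flip among subsets that include uninformative columns, and
    the parsimony rule resolves that deterministically.
    """
    k = config._inner_cv()
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    remaining = list(range(len(names)))
    path: list[tuple[list[int], float, float]] = []
    while remaining:
        scores = cross_val_score(
            _rf(est_params, seed), X[:, remaining], y, cv=cv,
            scoring="roc_auc", n_jobs=1,
        )
        path.append((list(remaining), float(np.mean(scores)),
                     float(np.std(scores))))
        if len(remaining) == 1:
            break
        model = _rf(est_params, seed).fit(X[:, remaining], y)
        drop = int(np.argmin(model.feature_importances_))
        remaining.pop(drop)
    best_mean, best_std = max((m, s) for _, m, s in path)
    threshold = best_mean - best_std / np.sqrt(k)
    chosen = min(
        (subset for subset, m, _ in path if m >= threshold), key=len
    )
    return [names[i] for i in sorted(chosen)]


def grid_search_auc(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    seed: int,
) -> tuple[dict, float]:
    """Mean-CV-AUC grid search with deterministic tie-breaking.

    Ties are broken towards smaller ``n_estimators``, then smaller
    ``max_depth``.
    """
    cv = StratifiedKFold(n_splits=config._inner_cv(), shuffle=True, random_state=seed)
    best: tuple[float, int, int] | None = None
    best_params: dict | None = None
    for params in config.grid_points:
        pipe = _pipeline(params, seed)
        scores = cross_val_score(pipe, X, y, cv=cv, scoring="roc_auc", n_jobs=1)
        mean_auc = float(np.mean(scores))
        key = (
            -mean_auc,
            params.get("n_estimators", 0),
            params.get("max_depth", 0),
        )
        if best is None or key < best:
            best = key
            best_params = params
    assert best_params is not None
    return best_params, -best[0]


def train_ensemble(
    table: FeatureTable,
    positives: list[KSPair],
    universe: list[tuple[str, str]],
    config: TrainingConfig,
    selected_features: list[str] | None = None,
) -> EnsembleModel:
    """Train the n_runs-member ensemble on fresh negative resamples.

    Each member draws negatives at ``neg_ratio_final``, grid-searches the
    forest hyper-parameters by stratified CV AUC-ROC, and is refit on its
    full training set. ``selected_features`` (from :func:`rfe_majority_vote`)
    restricts the columns; by default all registry features are used.
    """
    features = selected_features or table.feature_names
    missing = [f for f in features if f not in table.feature_names]
    if missing:
        raise ValueError(f"selected features absent from table: {missing}")
    data = table.data[features]

    seeds = _derive_seeds(config.seed, config.n_runs, "train")
    members: list[EnsembleMember] = []
    for run, run_seed in enumerate(seeds):
        negatives = sample_negatives(
            positives, universe, config.neg_ratio_final, run_seed
        )
        keys = [p.key for p in positives] + [n.key for n in negatives]
        X = data.loc[keys].to_numpy(dtype=float)
        y = np.array([1] * len(positives) + [0] * len(negatives))
        params, cv_auc = grid_search_auc(X, y, config, run_seed)
        pipe = _pipeline(params, run_seed)
        pipe.fit(X, y)
        members.append(EnsembleMember(pipe, params, cv_auc, run_seed))
    return EnsembleModel(members, list(features), config)


def predict_network(
    model: EnsembleModel,
    table: FeatureTable,
    universe: list[tuple[str, str]],
    provenance: dict | None = None,
) -> tuple[ProbabilisticNetwork, pd.DataFrame]:
    """Score every universe pair; probability = mean over ensemble members.

    Pairs without a feature row are excluded and reported (second return
    value). The per-edge standard deviation across members is carried in the
    ``prob_std`` column.
    """
    keys = [tuple(p) for p in universe]
    have = set(map(tuple, table.data.index))
    usable = [k for k in keys if k in have]
    skipped = pd.DataFrame(
        [k for k in keys if k not in have], columns=["kinase_id", "site_id"]
    )
    if not usable:
        raise ValueError("no universe pair has a feature row")
    X = table.data.loc[usable, model.selected_features].to_numpy(dtype=float)
    probs = np.column_stack(
        [m.pipeline.predict_proba(X)[:, 1] for m in model.members]
    )
    mean = probs.mean(axis=1)
    std = probs.std(axis=1)
    edges = pd.DataFrame(
        {
            "kinase_id": [k for k, _ in usable],
            "site_id": [s for _, s in usable],
            "probability": mean,
            "prob_std": std,
        }
    )
    prov = {
        "n_runs": len(model.members),
        "seed": model.config.seed,
        "features": list(model.selected_features),
    }
    prov.update(provenance or {})
    return ProbabilisticNetwork(edges, prov), skipped


def holdout_benchmark(
    world,
    config: TrainingConfig,
    test_frac: float = 0.3,
    neg_ratio_test: int = 10,
    seed: int = 0,
    table: FeatureTable | None = None,
) -> dict:
    """Held-out evaluation of the ensemble on a synthetic world.

    Splits the planted truth into train/test, trains the ensemble on the
    training positives (test positives are removed from the negative-sampling
    universe), and scores the held-out positives against a fresh
    ``neg_ratio_test``x negative sample. Also reports the AUC of the
    per-kinase PSSM percentile feature alone on the same test pairs.
    """
    from .evaluation import auc_roc
    from .feature_engine import DEFAULT_REGISTRY, assemble_features

    if table is None:
        pairs = [KSPair(k, s) for k, s in world.universe()]
        table, _ = assemble_features(
            pairs,
            world.kinase_map(),
            world.site_map(),
            world.pssms,
            {"expression": world.expression, "proteomics": world.proteomics},
            DEFAULT_REGISTRY,
        )
    universe = world.universe()
    truth = sorted(world.truth_keys)
    rng = np.random.default_rng(seed)
    rng.shuffle(truth)
    n_test = max(1, int(round(test_frac * len(truth))))
    test_pos, train_pos = truth[:n_test], truth[n_test:]
    train_universe = [p for p in universe if p not in set(test_pos)]
    positives = [KSPair(k, s, Label.POSITIVE) for k, s in train_pos]
    model = train_ensemble(table, positives, train_universe, config)
    test_neg = [
        n.key
        for n in sample_negatives(
            set(truth), universe, neg_ratio_test, seed=seed + 1
        )[: neg_ratio_test * n_test]
    ]
    test_pairs = list(test_pos) + list(test_neg)
    net, _ = predict_network(model, table, test_pairs)
    labels = np.array([1] * len(test_pos) + [0] * len(test_neg))
    auc = auc_roc(net.edges["probability"].to_numpy(), labels)
    baseline = table.data.loc[test_pairs, "pssm_percentile"].to_numpy(dtype=float)
    baseline = np.nan_to_num(baseline, nan=0.5)
    auc_pssm = auc_roc(baseline, labels)
    return {
        "auc_ensemble": float(auc),
        "auc_pssm_only": float(auc_pssm),
        "n_test_pos": len(test_pos),
        "n_test_neg": len(test_neg),
        "mean_cv_auc": float(model.cv_metrics["cv_auc"].mean()),
        "model": model,
        "table": table,
    }
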