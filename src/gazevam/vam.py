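"""Visual attention models: pixel-level training, feature selection, saliency.

One VAM is trained per diagnostic group (TD, ASD). Its training set is
assembled at the pixel level: for each frame group, pixels in the top
quantile of the cohort fixation map are labeled *fixed* and pixels in the
bottom quantile *not fixed*, balanced per frame group. Three classifier
families are supported:

  nn  - multilayer perceptron, one hidden layer of 10 sigmoid units and a
        linear output, L2 weight decay standing in for Bayesian
        regularization, learning rate 0.01, at most 1000 epochs or
        training error < 1e-7
  svm - linear support-vector classifier (liblinear, default regularization);
        continuous scores from a logistic squash of the margin
  rf  - bagged decision-tree ensemble; trees in {25, 50, 100, 200} and mtry
        in 3..9 chosen by out-of-bag score when not pinned

Feature selection modes: all 28 channels, a fixed config-supplied list,
ReliefF (k=60 nearest neighbors, keep weights above the mean), or a
genetic-algorithm wrapper selecting a fixed-size subset (default 15).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPRegressor
from sklearn.svm import LinearSVC

from .features import FEATURE_NAMES, N_FEATURES, FeatureStack
from .preprocess import FixationMap

__all__ = [
    "PixelTable",
    "VAModel",
    "SaliencyMap",
    "GAConfig",
    "assemble_training_set",
    "relief_weights",
    "relief_select",
    "ga_select",
    "train_vam",
    "predict_saliency",
    "cross_validate",
    "make_folds",
]

RF_TREE_GRID = (25, 50, 100, 200)
RF_MTRY_GRID = tuple(range(3, 10))


@dataclass
class PixelTable:
    """Balanced fixed / not-fixed pixel samples with their feature vectors."""

    X: np.ndarray  # (n, 28)
    y: np.ndarray  # (n,) 1 = fixed, 0 = not fixed
    frame_group_ids: np.ndarray  # (n,)
    group: str  # TD | ASD
    skipped_groups: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class SaliencyMap:
    group_index: int
    group: str
    values: np.ndarray  # (H, W) in [0, 1]


@dataclass
class VAModel:
    """A trained per-pixel fixed/not-fixed classifier for one group."""

    group: str
    algorithm: str  # nn | svm | rf
    selected_features: tuple[int, ...]  # 0-based channel indices
    hyperparams: dict
    fitted_state: object
    training_folds: tuple[int, ...] = ()

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous fixed-probability scores in [0, 1]."""
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} channels, got {X.shape[1]}")
        Xs = X[:, list(self.selected_features)]
        est = self.fitted_state
        if self.algorithm == "rf":
            return est.predict_proba(Xs)[:, 1]
        if self.algorithm == "svm":
            return expit(est.decision_function(Xs))
        return np.clip(est.predict(Xs), 0.0, 1.0)  # nn: linear output

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) > 0.5).astype(int)

    def save(self, path: str | Path) -> Path:
        """Versioned archive: JSON manifest alongside the pickled estimator."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "group": self.group,
            "algorithm": self.algorithm,
            "selected_features": list(self.selected_features),
            "selected_feature_names": [FEATURE_NAMES[i] for i in self.selected_features],
            "hyperparams": self.hyperparams,
            "training_folds": list(self.training_folds),
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        joblib.dump(self.fitted_state, path / "weights.joblib")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VAModel":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        return cls(
            group=manifest["group"],
            algorithm=manifest["algorithm"],
            selected_features=tuple(manifest["selected_features"]),
            hyperparams=manifest["hyperparams"],
            fitted_state=joblib.load(path / "weights.joblib"),
            training_folds=tuple(manifest["training_folds"]),
        )


# ---------------------------------------------------------------------------
# training-set assembly


def assemble_training_set(
    feature_stacks: dict[int, FeatureStack],
    cohort_fixation_maps: dict[int, FixationMap],
    group: str,
    q_pos: float = 0.80,
    q_neg: float = 0.70,
    n_per_class: int = 50,
    seed: int = 0,
) -> PixelTable:
    """Sample balanced fixed / not-fixed pixels per frame group.

    Positives come from pixels at or above the ``q_pos`` quantile of the
    cohort fixation map (default: top 20%), negatives from pixels at or
    below the ``q_neg`` quantile (default: bottom 70%). Frame groups whose
    cohort map has no fixations are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    xs, ys, gids = [], [], []
    skipped = []
    for gid in sorted(feature_stacks):
        fmap = cohort_fixation_maps[gid]
        if fmap.n_fixations == 0:
            skipped.append(gid)
            continue
        density = fmap.density.ravel()
        feats = feature_stacks[gid].stack.reshape(-1, N_FEATURES)
        # positives additionally require nonzero density: on sparse maps the
        # upper quantile can be 0, which would admit unfixated pixels
        pos_pool = np.flatnonzero((density >= np.quantile(density, q_pos)) & (density > 0))
        neg_pool = np.flatnonzero(density <= np.quantile(density, q_neg))
        n = min(n_per_class, len(pos_pool), len(neg_pool))
        if n == 0:
            skipped.append(gid)
            continue
        pos = rng.choice(pos_pool, size=n, replace=False)
        neg = rng.choice(neg_pool, size=n, replace=False)
        xs.append(feats[pos])
        ys.append(np.ones(n, dtype=int))
        gids.append(np.full(n, gid))
        xs.append(feats[neg])
        ys.append(np.zeros(n, dtype=int))
        gids.append(np.full(n, gid))
    if skipped:
        warnings.warn(f"skipped frame groups with no usable fixations: {skipped}")
    if not xs:
        return PixelTable(
            X=np.empty((0, N_FEATURES)),
            y=np.empty(0, dtype=int),
            frame_group_ids=np.empty(0, dtype=int),
            group=group,
            skipped_groups=skipped,
        )
    return PixelTable(
        X=np.concatenate(xs).astype(np.float64),
        y=np.concatenate(ys),
        frame_group_ids=np.concatenate(gids),
        group=group,
        skipped_groups=skipped,
    )


# ---------------------------------------------------------------------------
# ReliefF feature selection


def relief_weights(X: np.ndarray, y: np.ndarray, k: int = 60) -> np.ndarray:
    """ReliefF feature weights with k nearest hits and misses per instance.

    Features are min-max scaled; distances are Euclidean; every instance is
    used. For each instance the weight of a feature decreases by its mean
    absolute difference to the k nearest same-class neighbors (hits) and
    increases by the prior-weighted mean difference to the k nearest
    neighbors of each other class (misses).
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least two classes")
    if k >= counts.min():
        raise ValueError(f"k={k} must be smaller than the smallest class count {counts.min()}")
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / span
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    by_class = {c: np.flatnonzero(y == c) for c in classes}

    weights = np.zeros(p)
    chunk = 256
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        diffs = np.abs(Xs[idx, None, :] - Xs[None, :, :])  # (m, n, p)
        dists = np.sqrt((diffs**2).sum(axis=2))
        for row, i in enumerate(idx):
            ci = y[i]
            for c in classes:
                members = by_class[c]
                if c == ci:
                    members = members[members != i]
                order = members[np.argsort(dists[row, members], kind="stable")[:k]]
                contrib = diffs[row, order, :].mean(axis=0)
                if c == ci:
                    weights -= contrib / n
                else:
                    weights += (priors[c] / (1.0 - priors[ci])) * contrib / n
    return weights


def relief_select(table: PixelTable, k: int = 60) -> tuple[np.ndarray, tuple[int, ...]]:
    """Select features whose ReliefF weight is strictly above the mean weight."""
    w = relief_weights(table.X, table.y, k=k)
    selected = tuple(int(i) for i in np.flatnonzero(w > w.mean()))
    return w, selected


# ---------------------------------------------------------------------------
# genetic-algorithm wrapper selection


@dataclass(frozen=True)
class GAConfig:
    population: int = 30
    generations: int = 20
    tournament: int = 3
    mutation_rate: float = 0.05
    probe_folds: int = 3


def _probe_fitness(
    X: np.ndarray, y: np.ndarray, subset: tuple[int, ...], n_folds: int, seed: int
) -> float:
    """Internal-CV AUC of a fast logistic-regression probe on a feature subset."""
    from .diagnose import rank_auc

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, n_folds)
    aucs = []
    cols = list(subset)
    for f in range(n_folds):
        test = folds[f]
        train = np.concatenate([folds[j] for j in range(n_folds) if j != f])
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            continue
        clf = LogisticRegression(max_iter=200)
        clf.fit(X[train][:, cols], y[train])
        scores = clf.decision_function(X[test][:, cols])
        aucs.append(rank_auc(scores, y[test]))
    return float(np.mean(aucs)) if aucs else 0.5


def ga_select(
    table: PixelTable,
    n_features: int = 15,
    ga_cfg: GAConfig = GAConfig(),
    seed: int = 0,
) -> tuple[int, ...]:
    """Genetic search over fixed-size feature subsets.

    Fitness is the internal cross-validated AUC of a fast linear probe on
    the pixel table. Tournament selection, single-point crossover with
    repair to the fixed subset size, and per-gene swap mutation; fully
    deterministic under ``seed``.
    """
    p = table.X.shape[1]
    if n_features > p:
        raise ValueError(f"n_features={n_features} exceeds available features {p}")
    rng = np.random.default_rng(seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = _probe_fitness(
                table.X, table.y, subset, ga_cfg.probe_folds, seed
            )
        return cache[subset]

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(p, size=n_features, replace=False).tolist()))

    population = [random_subset() for _ in range(ga_cfg.population)]
    for _ in range(ga_cfg.generations):
        scored = [(fitness(s), s) for s in population]
        scored.sort(key=lambda t: (-t[0], t[1]))
        elite = scored[0][1]
        new_pop = [elite]
        while len(new_pop) < ga_cfg.population:
            parents = []
            for _ in range(2):
                contenders = [population[i] for i in rng.integers(0, len(population), ga_cfg.tournament)]
                parents.append(max(contenders, key=fitness))
            pool = sorted(set(parents[0]) | set(parents[1]))
            child = set(rng.choice(pool, size=min(n_features, len(pool)), replace=False).tolist())
            while len(child) < n_features:  # repair
                child.add(int(rng.integers(0, p)))
            child = list(child)
            for gi in range(len(child)):  # swap mutation
                if rng.random() < ga_cfg.mutation_rate:
                    candidates = np.setdiff1d(np.arange(p), child)
                    child[gi] = int(rng.choice(candidates))
            new_pop.append(tuple(sorted(child)))
        population = new_pop
    best = max(population, key=lambda s: (fitness(s), tuple(-i for i in s)))
    return best


# ---------------------------------------------------------------------------
# model training


GRID_SUBSAMPLE = 3000


def _fit_rf(X: np.ndarray, y: np.ndarray, hyperparams: dict, seed: int):
    """Random forest with trees/mtry chosen by out-of-bag score when not pinned.

    The grid is scored on a seeded subsample of at most ``GRID_SUBSAMPLE``
    rows (OOB estimates stabilize well below that); the winning
    configuration is refit on the full table.
    """
    p = X.shape[1]
    trees = hyperparams.get("n_trees")
    mtry = hyperparams.get("mtry")
    tree_grid = [trees] if trees else list(RF_TREE_GRID)
    mtry_grid = [mtry] if mtry else [m for m in RF_MTRY_GRID if m <= p]
    if not mtry_grid:
        mtry_grid = [max(1, int(np.sqrt(p)))]

    def make(nt: int, m: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=nt,
            max_features=m,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )

    n_eval = len(tree_grid) * len(mtry_grid)
    if n_eval == 1:
        nt, m = tree_grid[0], mtry_grid[0]
    else:
        if len(X) > GRID_SUBSAMPLE:
            idx = np.random.default_rng(seed).choice(len(X), GRID_SUBSAMPLE, replace=False)
            Xg, yg = X[idx], y[idx]
        else:
            Xg, yg = X, y
        best = None
        for nt_c in tree_grid:
            for m_c in mtry_grid:
                rf = make(nt_c, m_c)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # tiny tables: some OOB rows unseen
                    rf.fit(Xg, yg)
                if best is None or rf.oob_score_ > best[0]:
                    best = (rf.oob_score_, nt_c, m_c)
        _, nt, m = best
    rf = make(nt, m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, y)
    return rf, {"n_trees": nt, "mtry": m, "n_grid_evaluated": n_eval}


def train_vam(
    table: PixelTable,
    algorithm: str,
    hyperparams: dict | None = None,
    seed: int = 0,
    selected_features: tuple[int, ...] | None = None,
    group: str | None = None,
) -> VAModel:
    """Fit one group's attention model on a pixel table.

    ``selected_features`` restricts the model to a channel subset (0-based);
    the fitted model never reads unselected channels.
    """
    if len(table) == 0:
        raise ValueError("empty pixel table")
    hyperparams = dict(hyperparams or {})
    if selected_features is None:
        selected_features = tuple(range(table.X.shape[1]))
    selected_features = tuple(int(i) for i in selected_features)
    Xs = table.X[:, list(selected_features)]
    y = table.y

    if algorithm == "nn":
        est = MLPRegressor(
            hidden_layer_sizes=(10,),
            activation="logistic",
            solver="adam",
            alpha=hyperparams.get("l2_decay", 1e-3),
            learning_rate_init=hyperparams.get("learning_rate", 0.01),
            max_iter=hyperparams.get("max_epochs", 1000),
            tol=hyperparams.get("error_goal", 1e-7),
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xs, y.astype(float))
        fitted = est
    elif algorithm == "svm":
        fitted = LinearSVC(random_state=seed, dual="auto")
        fitted.fit(Xs, y)
    elif algorithm == "rf":
        fitted, chosen = _fit_rf(Xs, y, hyperparams, seed)
        hyperparams.update(chosen)
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return VAModel(
        group=group or table.group,
        algorithm=algorithm,
        selected_features=selected_features,
        hyperparams=hyperparams,
        fitted_state=fitted,
    )


def predict_saliency(
    model: VAModel, feature_stack: FeatureStack, stride: int = 1
) -> SaliencyMap:
    """Per-pixel fixed-probability map over the full frame, in [0, 1].

    ``stride`` > 1 scores every stride-th pixel and bilinearly upsamples
    the result; saliency maps are spatially smooth, so this is a cheap,
    close approximation used by the cross-validation driver.
    """
    h, w, c = feature_stack.stack.shape
    if c != N_FEATURES:
        raise ValueError(f"feature stack has {c} channels, expected {N_FEATURES}")
    if stride <= 1:
        scores = model.scores(feature_stack.stack.reshape(-1, c).astype(np.float64))
        values = scores.reshape(h, w)
    else:
        sub = feature_stack.stack[::stride, ::stride, :]
        scores = model.scores(sub.reshape(-1, c).astype(np.float64))
        from skimage.transform import resize

        values = resize(
            scores.reshape(sub.shape[:2]), (h, w), order=1, mode="edge",
            anti_aliasing=False,
        )
        values = np.clip(values, 0.0, 1.0)
    return SaliencyMap(
        group_index=feature_stack.group_index,
        group=model.group,
        values=values,
    )


# ---------------------------------------------------------------------------
# cross-validation over frame groups


def make_folds(group_ids: list[int], n_folds: int) -> list[list[int]]:
    """Contiguous chronological blocks of frame groups, sizes differing by <= 1."""
    if len(group_ids) < n_folds:
        raise ValueError(
            f"{len(group_ids)} frame groups is fewer than {n_folds} folds"
        )
    return [list(a) for a in np.array_split(sorted(group_ids), n_folds)]


@dataclass
class FoldResult:
    fold_id: int
    test_group_ids: list[int]
    models: dict[str, VAModel]  # cohort -> model
    saliency: dict[str, dict[int, SaliencyMap]]  # cohort -> gid -> held-out map
    selected_features: dict[str, tuple[int, ...]]


def _select_features(
    table: PixelTable,
    feature_mode: str,
    fixed_list: tuple[int, ...] | None,
    relief_k: int,
    ga_cfg: GAConfig,
    ga_n_features: int,
    seed: int,
) -> tuple[int, ...]:
    if feature_mode == "all":
        return tuple(range(N_FEATURES))
    if feature_mode == "fixed":
        if not fixed_list:
            raise ValueError("feature_mode='fixed' requires a config-supplied channel list")
        return tuple(int(i) for i in fixed_list)
    if feature_mode == "relief":
        _, selected = relief_select(table, k=relief_k)
        return selected or tuple(range(N_FEATURES))
    if feature_mode == "ga":
        return ga_select(table, n_features=ga_n_features, ga_cfg=ga_cfg, seed=seed)
    raise ValueError(f"unknown feature_mode: {feature_mode!r}")


def cross_validate(
    feature_stacks: dict[int, FeatureStack],
    cohort_maps: dict[str, dict[int, FixationMap]],
    algorithm: str = "rf",
    feature_mode: str = "all",
    n_folds: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
    fixed_features: tuple[int, ...] | None = None,
    relief_k: int = 60,
    ga_cfg: GAConfig = GAConfig(),
    ga_n_features: int = 15,
    sampling: dict | None = None,
    predict_stride: int = 2,
) -> list[FoldResult]:
    """Train both cohorts' VAMs per fold and predict held-out saliency maps.

    Frame groups are partitioned into ``n_folds`` contiguous chronological
    blocks; per fold each cohort's model is trained on the training blocks
    only (feature selection included), and saliency maps are emitted only
    for the held-out frame groups.
    """
    gids = sorted(feature_stacks)
    folds = make_folds(gids, n_folds)
    sampling = sampling or {}
    results = []
    for fold_id, test_ids in enumerate(folds):
        train_ids = [g for g in gids if g not in set(test_ids)]
        models, sal, sel = {}, {}, {}
        for cohort in sorted(cohort_maps):
            table = assemble_training_set(
                {g: feature_stacks[g] for g in train_ids},
                {g: cohort_maps[cohort][g] for g in train_ids},
                group=cohort,
                seed=seed + fold_id,
                **sampling,
            )
            if len(table) == 0:
                raise ValueError(
                    f"fold {fold_id}: no usable training pixels for cohort {cohort}"
                )
            selected = _select_features(
                table, feature_mode, fixed_features, relief_k, ga_cfg, ga_n_features,
                seed + fold_id,
            )
            model = train_vam(
                table, algorithm, hyperparams, seed=seed + fold_id,
                selected_features=selected,
            )
            model.training_folds = tuple(
                f for f in range(n_folds) if f != fold_id
            )
            models[cohort] = model
            sel[cohort] = selected
            sal[cohort] = {
                g: predict_saliency(model, feature_stacks[g], stride=predict_stride)
                for g in test_ids
            }
        results.append(
            FoldResult(
                fold_id=fold_id,
                test_group_ids=list(test_ids),
                models=models,
                saliency=sal,
                selected_features=sel,
            )
        )
    return results
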