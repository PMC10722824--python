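"""Individual diagnosis by per-frame similarity voting, and its evaluation.

For every held-out frame group the subject's fixation map is compared with
the TD and the ASD saliency maps; the more similar map wins one vote
(Pearson correlation by default). The subject is classified by majority
vote; the fraction of ASD votes is a continuous score, from which ROC/AUC
is computed with the rank (Mann-Whitney) formulation. AUC sets from
different configurations are compared with exact Wilcoxon signed-rank
(paired) or Mann-Whitney (unpaired) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .preprocess import FixationMap
from .vam import VAModel, SaliencyMap, FoldResult

__all__ = [
    "DiagnosisResult",
    "EvalReport",
    "similarity",
    "frame_vote",
    "classify_subject",
    "diagnose_cohort",
    "rank_auc",
    "evaluate",
    "compare_auc_sets",
    "threshold_sweep",
    "rf_feature_importance",
]

POSITIVE_CLASS = "ASD"


@dataclass
class DiagnosisResult:
    subject_id: str
    votes: list[str]  # per-frame-group "TD" | "ASD" | "abstain"
    score: float  # fraction of non-abstain votes cast for ASD
    predicted: str
    fold_id: int
    flagged: bool = False  # tie or all-abstain fallback


@dataclass
class EvalReport:
    """Fold-wise and averaged diagnostic metrics; positive class is ASD."""

    per_fold: pd.DataFrame  # columns: fold, auc, f1, accuracy, sensitivity, precision, specificity
    mean: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            cols = ["auc", "f1", "accuracy", "sensitivity", "precision", "specificity"]
            self.mean = {c: float(self.per_fold[c].mean()) for c in cols}


# ---------------------------------------------------------------------------
# voting


def similarity(a: np.ndarray, b: np.ndarray, metric: str = "pearson") -> float:
    """Similarity between two maps; higher means more alike.

    Pearson correlation is the default; cosine and histogram intersection
    are available for sensitivity analysis. A constant map has zero Pearson
    similarity to anything (no covariation to measure).
    """
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    x = a.ravel().astype(np.float64)
    y = b.ravel().astype(np.float64)
    if metric == "pearson":
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        return float((xc * yc).sum() / denom) if denom > 0 else 0.0
    if metric == "cosine":
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        return float(x @ y / denom) if denom > 0 else 0.0
    if metric == "intersection":
        sx, sy = x.sum(), y.sum()
        if sx <= 0 or sy <= 0:
            return 0.0
        return float(np.minimum(x / sx, y / sy).sum())
    raise ValueError(f"unknown similarity metric: {metric!r}")


def frame_vote(
    subject_map: FixationMap,
    sal_td: SaliencyMap,
    sal_asd: SaliencyMap,
    metric: str = "pearson",
) -> str:
    """One frame group's vote: TD, ASD, or abstain.

    Abstains when the subject has no fixations on the group or when the two
    similarities tie exactly (including identical saliency maps).
    """
    if sal_td.values.shape != sal_asd.values.shape:
        raise ValueError("saliency map shapes differ")
    if subject_map.n_fixations == 0:
        return "abstain"
    s_td = similarity(subject_map.density, sal_td.values, metric)
    s_asd = similarity(subject_map.density, sal_asd.values, metric)
    if s_td == s_asd:
        return "abstain"
    return "TD" if s_td > s_asd else "ASD"


def classify_subject(
    subject_id: str, votes: list[str], fold_id: int = -1
) -> DiagnosisResult:
    """Majority vote over non-abstaining frame groups.

    score = ASD-vote fraction among non-abstain votes; predicted ASD iff
    score > 0.5. Ties and all-abstain cases fall back to TD (conservative
    toward no diagnosis) and are flagged.
    """
    if not votes:
        raise ValueError("empty vote list")
    n_asd = votes.count("ASD")
    n_td = votes.count("TD")
    n_cast = n_asd + n_td
    if n_cast == 0:
        return DiagnosisResult(subject_id, votes, 0.5, "TD", fold_id, flagged=True)
    score = n_asd / n_cast
    if score > 0.5:
        return DiagnosisResult(subject_id, votes, score, "ASD", fold_id)
    return DiagnosisResult(
        subject_id, votes, score, "TD", fold_id, flagged=(score == 0.5)
    )


def diagnose_cohort(
    fold_results: list[FoldResult],
    subject_maps: dict[str, dict[int, FixationMap]],
    metric: str = "pearson",
) -> list[DiagnosisResult]:
    """Diagnose every subject within each fold's held-out frame groups."""
    results = []
    for fr in fold_results:
        for sid in sorted(subject_maps):
            votes = [
                frame_vote(
                    subject_maps[sid][gid],
                    fr.saliency["TD"][gid],
                    fr.saliency["ASD"][gid],
                    metric,
                )
                for gid in fr.test_group_ids
            ]
            results.append(classify_subject(sid, votes, fr.fold_id))
    return results


# ---------------------------------------------------------------------------
# evaluation


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation with midrank ties.

    ``labels`` are 1 for the positive class. Returns NaN when only one
    class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # midranks on ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _threshold_metrics(predicted: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    tp = int(((predicted == 1) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / len(truth)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "f1": f1,
        "accuracy": acc,
        "sensitivity": sens,
        "precision": prec,
        "specificity": spec,
    }


def evaluate(
    results: list[DiagnosisResult], true_labels: dict[str, str]
) -> EvalReport:
    """Per-fold and averaged AUC / F1 / accuracy / sensitivity / precision / specificity.

    AUC uses the continuous vote-fraction scores; threshold metrics use the
    predicted labels. A fold with one-class truth reports AUC as missing.
    """
    missing = {r.subject_id for r in results} - set(true_labels)
    if missing:
        raise ValueError(f"subjects without truth labels: {sorted(missing)}")
    rows = []
    for fold_id in sorted({r.fold_id for r in results}):
        fold = [r for r in results if r.fold_id == fold_id]
        truth = np.array(
            [1 if true_labels[r.subject_id] == POSITIVE_CLASS else 0 for r in fold]
        )
        scores = np.array([r.score for r in fold])
        predicted = np.array([1 if r.predicted == POSITIVE_CLASS else 0 for r in fold])
        row = {"fold": fold_id, "auc": rank_auc(scores, truth)}
        row.update(_threshold_metrics(predicted, truth))
        rows.append(row)
    return EvalReport(per_fold=pd.DataFrame(rows))


def compare_auc_sets(
    aucs_a: np.ndarray, aucs_b: np.ndarray, paired: bool
) -> tuple[float, float]:
    """Compare two AUC sets: Wilcoxon signed-rank (paired) or Mann-Whitney.

    Exact two-sided null distributions for small samples (n <= 25, no ties
    or zero differences); otherwise the standard approximation.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 observations per set")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        method = "exact" if len(d) <= 25 and np.all(d != 0) else "auto"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    else:
        pooled = np.concatenate([a, b])
        exact_ok = len(pooled) <= 50 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact_ok else "auto"
        )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# end-to-end sweep and importance


DEFAULT_SWEEP_THRESHOLDS = (0.05, 0.08, 0.10, 0.15, 0.20, 0.25, 0.30, 0.33, 0.35)


def threshold_sweep(
    stimulus,
    recordings,
    thresholds=DEFAULT_SWEEP_THRESHOLDS,
    algorithm: str = "rf",
    seed: int = 0,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Re-run the full pipeline per aggregation threshold.

    Returns a table of threshold, frame-group count, mean cross-validated
    AUC and feasibility; a threshold that yields fewer frame groups than
    cross-validation folds is marked infeasible (AUC missing).
    """
    from .interface import run_analysis

    rows = []
    for thr in thresholds:
        try:
            report, extras = run_analysis(
                stimulus,
                recordings,
                aggregation_threshold=thr,
                algorithm=algorithm,
                seed=seed,
                **pipeline_kwargs,
            )
            rows.append(
                {
                    "threshold": thr,
                    "n_groups": extras["n_groups"],
                    "mean_auc": report.mean["auc"],
                    "feasible": True,
                }
            )
        except ValueError:
            from .preprocess import aggregate_frames

            n_groups = len(aggregate_frames(stimulus, threshold=thr))
            rows.append(
                {
                    "threshold": thr,
                    "n_groups": n_groups,
                    "mean_auc": float("nan"),
                    "feasible": False,
                }
            )
    return pd.DataFrame(rows)


def rf_feature_importance(
    model: VAModel,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of the selected channels, normalized to sum 1.

    Each selected channel is permuted in the evaluation set and the drop in
    accuracy recorded; negative drops are clipped at zero before
    normalization. Requires a random-forest model.
    """
    from .features import FEATURE_NAMES

    if model.algorithm != "rf":
        raise ValueError("feature importance is defined for rf models only")
    rng = np.random.default_rng(seed)
    base = (model.predict(X) == y).mean()
    drops = []
    for ch in model.selected_features:
        drop = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, ch] = Xp[rng.permutation(len(Xp)), ch]
            drop += base - (model.predict(Xp) == y).mean()
        drops.append(max(drop / n_repeats, 0.0))
    drops = np.asarray(drops)
    total = drops.sum()
    norm = drops / total if total > 0 else np.full(len(drops), 1.0 / len(drops))
    df = pd.DataFrame(
        {
            "channel": list(model.selected_features),
            "name": [FEATURE_NAMES[i] for i in model.selected_features],
            "importance": norm,
        }
    )
    return df.sort_values("importance", ascending=False, kind="stable").reset_index(
        drop=True
    )
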