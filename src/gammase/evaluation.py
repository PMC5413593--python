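"""k-NN classification, holdout validation, ROC metrics and the
ranked-vs-non-ranked experiment grid.

The evaluation asks one question: do the top-ranked channels carry more
discriminative information than the same number of channels taken in
native dataset order? For each configuration (number of channels N,
ranked or not, number of principal components d) the feature matrix is
split 50/50 (stratified, seeded), the channel subset is selected, PCA is
fitted on the training half, both halves are projected to d components,
and a k-NN classifier votes among the k nearest training epochs.
"alcoholic" is the positive class for sensitivity/specificity, and
"efficiency" is the conventional term for accuracy in this literature.

A single holdout split is not a testable contract, so every entry point
takes an explicit seed and the grid runner replicates over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .epochs import POSITIVE_LABEL, FeatureMatrix
from .errors import DegenerateSamplesError, ParameterError, SizeError
from .ranking import RankResult, rank_channels
from .reduction import fit_pca, pca_transform


# ---------------------------------------------------------------------------
# k-NN
# ---------------------------------------------------------------------------

def knn_classify(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    k: int = 3,
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote among the k nearest training epochs.

    Returns ``(predicted labels, positive-class scores)`` where the score
    of a test point is the fraction of its k neighbors labeled positive.
    Distance ties break toward the lower training-point index; vote ties
    (possible for even k) break toward the class of the single nearest
    neighbor.
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    train_y = np.asarray(train_y, dtype=object)
    if metric != "euclidean":
        raise ParameterError(f"unsupported metric {metric!r}")
    if train_x.shape[0] == 0:
        raise SizeError("empty training set")
    if not 1 <= k <= train_x.shape[0]:
        raise ParameterError(f"k={k} outside 1..{train_x.shape[0]} training points")
    dists = cdist(test_x, train_x, metric="euclidean")
    # stable argsort: equal distances keep ascending training-index order
    nearest = np.argsort(dists, axis=1, kind="stable")[:, :k]
    pos = np.asarray([lab == POSITIVE_LABEL for lab in train_y], dtype=float)
    votes = pos[nearest]
    scores = votes.mean(axis=1)
    pred = np.where(scores > 0.5, POSITIVE_LABEL, "control").astype(object)
    tie = scores == 0.5
    if np.any(tie):
        nearest_lab = train_y[nearest[tie, 0]]
        pred[tie] = nearest_lab
    return pred, scores


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, truth) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from positive-class scores.

    Thresholds sweep the distinct score values (predict positive when
    score >= threshold); the curve is anchored at (0,0) and (1,1). With
    trapezoidal integration the area equals the Mann–Whitney concordance
    probability, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=object)
    is_pos = np.asarray([lab == POSITIVE_LABEL for lab in truth], dtype=bool)
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateSamplesError("ROC undefined with a single-class truth")
    points = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        called = scores >= thr
        tpr = float((called & is_pos).sum()) / n_pos
        fpr = float((called & ~is_pos).sum()) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    roc = np.asarray(points)
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc


@dataclass
class ClassificationReport:
    """Confusion counts and derived metrics; alcoholic is positive."""

    tp: int
    fp: int
    tn: int
    fn: int
    efficiency: float
    sensitivity: float
    specificity: float
    roc: np.ndarray
    auc: float

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classification_report(truth, pred, scores) -> ClassificationReport:
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    t_pos = np.asarray([lab == POSITIVE_LABEL for lab in truth], dtype=bool)
    p_pos = np.asarray([lab == POSITIVE_LABEL for lab in pred], dtype=bool)
    tp = int((t_pos & p_pos).sum())
    fp = int((~t_pos & p_pos).sum())
    tn = int((~t_pos & ~p_pos).sum())
    fn = int((t_pos & ~p_pos).sum())
    roc, auc = roc_auc(scores, truth)
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        efficiency=(tp + tn) / truth.size,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        roc=roc, auc=auc,
    )


# ---------------------------------------------------------------------------
# Holdout evaluation
# ---------------------------------------------------------------------------

def stratified_split(
    labels, split: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified partition; ``split`` is the training fraction."""
    if not 0 < split < 1:
        raise ParameterError(f"split fraction must be in (0, 1), got {split}")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for lab in sorted({str(v) for v in labels}):
        idx = np.flatnonzero(np.asarray([v == lab for v in labels]))
        idx = rng.permutation(idx)
        n_train = int(round(split * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def holdout_evaluate(
    fm: FeatureMatrix,
    n_channels: int,
    n_pcs: int,
    *,
    ranked: bool = False,
    rank: RankResult | None = None,
    k: int = 3,
    split: float = 0.5,
    seed: int = 0,
    rank_scope: str = "train",
    pca_scope: str = "train",
    alpha: float = 0.05,
) -> ClassificationReport:
    """One stratified holdout run of the channel-selection pipeline.

    ``ranked=True`` selects the first ``n_channels`` of the t-test channel
    ordering — computed on the training partition (``rank_scope="train"``,
    the leakage-safe default) or on the whole matrix
    (``rank_scope="pooled"``, mirroring a whole-dataset ranking). A
    precomputed ``rank`` overrides both and implies ranked mode.
    ``ranked=False`` takes the first ``n_channels`` in native dataset
    order. PCA is fitted on the training rows of the selected channels
    (or on all rows with ``pca_scope="pooled"``), both partitions are
    projected to ``n_pcs`` components, and k-NN is evaluated on the
    held-out half.
    """
    if not 1 <= n_channels <= fm.n_channels:
        raise ParameterError(
            f"N={n_channels} outside 1..{fm.n_channels} available channels"
        )
    if not 1 <= n_pcs <= n_channels:
        raise ParameterError(f"d={n_pcs} outside 1..{n_channels} (d must be <= N)")
    if rank_scope not in ("train", "pooled") or pca_scope not in ("train", "pooled"):
        raise ParameterError("rank_scope and pca_scope must be 'train' or 'pooled'")

    train_idx, test_idx = stratified_split(fm.labels, split, seed)

    if rank is not None:
        ranked = True
    if ranked:
        if rank is None:
            scope_rows = train_idx if rank_scope == "train" else np.arange(fm.n_epochs)
            rank = rank_channels(
                FeatureMatrix(
                    values=fm.values[scope_rows],
                    labels=fm.labels[scope_rows],
                    channel_names=fm.channel_names,
                    band=fm.band,
                ),
                alpha=alpha,
            )
        subset = np.asarray(rank.order[:n_channels], dtype=int)
    else:
        subset = np.arange(n_channels)

    X = fm.values[:, subset]
    fit_rows = train_idx if pca_scope == "train" else np.arange(fm.n_epochs)
    model = fit_pca(X[fit_rows])
    train_z = pca_transform(model, X[train_idx], n_pcs)
    test_z = pca_transform(model, X[test_idx], n_pcs)
    pred, scores = knn_classify(train_z, fm.labels[train_idx], test_z, k=k)
    return classification_report(fm.labels[test_idx], pred, scores)


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

@dataclass
class GridRow:
    """One grid cell: a holdout report at (N, ranked?, d, seed)."""

    n_channels: int
    ranked: bool
    n_pcs: int
    seed: int
    report: ClassificationReport = field(repr=False)


def run_grid(
    fm: FeatureMatrix,
    pcs_per_n: dict[int, list[int]],
    ranked_modes: tuple[bool, ...] = (True, False),
    k: int = 3,
    seeds: tuple[int, ...] = (0,),
    **holdout_kwargs,
) -> list[GridRow]:
    """Full factorial over (N, ranked, d, seed) holdout evaluations.

    ``pcs_per_n`` maps each channel-subset size N to its list of
    principal-component counts d (each d <= N).
    """
    for n, ds in pcs_per_n.items():
        for d in ds:
            if d > n:
                raise ParameterError(f"grid cell N={n}, d={d}: d must be <= N")
    rows = []
    for n, ds in pcs_per_n.items():
        for mode in ranked_modes:
            for d in ds:
                for seed in seeds:
                    try:
                        report = holdout_evaluate(
                            fm, n, d, ranked=mode, k=k, seed=seed, **holdout_kwargs
                        )
                    except Exception as exc:
                        raise type(exc)(
                            f"grid cell N={n} ranked={mode} d={d} seed={seed}: {exc}"
                        ) from exc
                    rows.append(GridRow(n, mode, d, seed, report))
    return rows


def grid_to_frame(rows: list[GridRow]) -> pd.DataFrame:
    """Long-format results table, one holdout run per line."""
    return pd.DataFrame(
        {
            "n_channels": r.n_channels,
            "ranked": r.ranked,
            "n_pcs": r.n_pcs,
            "seed": r.seed,
            "efficiency_pct": 100.0 * r.report.efficiency,
            "sensitivity": r.report.sensitivity,
            "specificity": r.report.specificity,
            "auc": r.report.auc,
        }
        for r in rows
    )


def grid_pivot(rows: list[GridRow]) -> pd.DataFrame:
    """Mean-over-seeds pivot shaped like the classifier-performance table:
    one row per (N, d), ranked and non-ranked metric columns side by side."""
    df = grid_to_frame(rows)
    pivot = df.pivot_table(
        index=["n_channels", "n_pcs"],
        columns="ranked",
        values=["efficiency_pct", "sensitivity", "specificity"],
        aggfunc="mean",
    )
    pivot.columns = [
        f"{metric}_{'ranked' if mode else 'nonranked'}" for metric, mode in pivot.columns
    ]
    return pivot.sort_index(ascending=[False, True]).reset_index()
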