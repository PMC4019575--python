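"""Random-forest training, importance ranking, incremental feature selection
and full-map prediction.

The forest itself is scikit-learn's RandomForestClassifier (ntree trees, m
randomly chosen candidate variables per split); everything around it — the
scaled importance ranking, the two-rule subset construction and the map
prediction contract — is implemented here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core_io import FeatureStack, GroundTruthPoint, RasterGrid, sample_stack
from .evaluate import ErrorMatrix, EvaluationResult, accuracy_stats, error_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    ntree: int = 200
    m: int | None = None  # None -> floor(sqrt(p)) at fit time
    seed: int = 0
    importance: str = "impurity"  # or "permutation"

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")

    def resolve_m(self, p: int) -> int:
        m = self.m if self.m is not None else int(math.floor(math.sqrt(p)))
        if not 1 <= m <= p:
            raise ValueError(f"m must be in 1..{p}, got {m}")
        return m


@dataclass
class ImportanceRanking:
    """Variables ranked by importance, scaled so the maximum is 1."""

    names: list[str]
    raw: np.ndarray
    scaled: np.ndarray

    @classmethod
    def from_raw(cls, names: list[str], raw: np.ndarray) -> "ImportanceRanking":
        raw = np.asarray(raw, dtype=float)
        order = np.argsort(-raw, kind="stable")
        names = [names[i] for i in order]
        raw = raw[order]
        top = raw.max()
        scaled = raw / top if top > 0 else np.zeros_like(raw)
        return cls(names=names, raw=raw, scaled=scaled)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.scaled.tolist()))


@dataclass
class ModelRun:
    subset: list[str]
    forest: RandomForestClassifier
    ranking: ImportanceRanking
    test_predictions: list[str]
    test_reference: list[str]
    matrix: ErrorMatrix
    result: EvaluationResult

    @property
    def overall_accuracy(self) -> float:
        return self.result.overall_accuracy

    @property
    def kappa(self) -> float:
        return self.result.kappa


def train_rf(
    table: np.ndarray,
    labels: list[str],
    cfg: RFConfig = RFConfig(),
    names: list[str] | None = None,
) -> tuple[RandomForestClassifier, ImportanceRanking]:
    """Fit a random forest and return it with its scaled importance ranking."""
    table = np.asarray(table, dtype=float)
    if np.isnan(table).any():
        raise ValueError("feature table contains nodata rows; drop them before training")
    classes = set(labels)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    p = table.shape[1]
    if names is None:
        names = [f"v{i}" for i in range(p)]
    forest = RandomForestClassifier(
        n_estimators=cfg.ntree,
        max_features=cfg.resolve_m(p),
        random_state=cfg.seed,
    )
    forest.fit(table, labels)
    if cfg.importance == "impurity":
        raw = forest.feature_importances_
    else:
        from sklearn.inspection import permutation_importance

        raw = permutation_importance(
            forest, table, labels, n_repeats=5, random_state=cfg.seed
        ).importances_mean
        raw = np.clip(raw, 0, None)
    return forest, ImportanceRanking.from_raw(list(names), raw)


def select_features(
    ranking: ImportanceRanking,
    max_group: int = 3,
    max_gap: float = 0.2,
    floor: float = 0.05,
    top_tol: float = 1e-9,
) -> list[list[str]]:
    """Build the nested sequence of variable subsets from an importance ranking.

    The first subset holds every variable whose scaled importance equals 1
    (within ``top_tol``). Walking down the ranking, later subsets append
    groups of at most ``max_group`` variables whose importance scores differ
    by less than ``max_gap`` within the group. Variables at or below ``floor``
    are never added. Each subset is a strict superset of the previous one.
    """
    names = ranking.names
    imp = ranking.scaled
    subsets: list[list[str]] = []
    top = [n for n, v in zip(names, imp) if v >= 1.0 - top_tol]
    rest = [(n, v) for n, v in zip(names, imp) if v < 1.0 - top_tol and v > floor]
    if not top:
        # degenerate ranking (all-zero importances): start from the first variable
        top = names[:1]
        rest = [(n, v) for n, v in zip(names[1:], imp[1:]) if v > floor]
    current = list(top)
    subsets.append(list(current))
    i = 0
    while i < len(rest):
        group = [rest[i]]
        j = i + 1
        while (
            j < len(rest)
            and len(group) < max_group
            and group[0][1] - rest[j][1] < max_gap
        ):
            group.append(rest[j])
            j += 1
        current = current + [n for n, _ in group]
        subsets.append(list(current))
        i = j
    return subsets


def split_points(points: list[GroundTruthPoint]) -> tuple[list[GroundTruthPoint], list[GroundTruthPoint]]:
    train = [p for p in points if p.split == "train"]
    test = [p for p in points if p.split == "test"]
    return train, test


def build_table(
    stack: FeatureStack, points: list[GroundTruthPoint], subset: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Feature rows (subset columns) and labels for ground-truth points.

    Rows with nodata in any subset layer are dropped.
    """
    subset = list(stack.names) if subset is None else subset
    sub_stack = FeatureStack(names=subset, layers=[stack[n] for n in subset])
    table, valid = sample_stack(sub_stack, [(p.x, p.y) for p in points])
    labels = [p.label for p in points]
    if not valid.all():
        log.warning("dropping %d ground-truth rows with nodata features", int((~valid).sum()))
    table = table[valid]
    labels = [l for l, v in zip(labels, valid) if v]
    return table, labels


def run_model(
    stack: FeatureStack,
    points: list[GroundTruthPoint],
    subset: list[str],
    cfg: RFConfig = RFConfig(),
) -> ModelRun:
    """Train on the train split restricted to ``subset``, evaluate on the test split."""
    if not subset:
        raise ValueError("variable subset must not be empty")
    deduped = list(dict.fromkeys(subset))
    if len(deduped) != len(subset):
        log.warning("duplicate variables in subset deduplicated: %s", subset)
    subset = deduped
    missing = [n for n in subset if n not in stack]
    if missing:
        raise ValueError(f"subset variables not in stack: {missing}")

    train_pts, test_pts = split_points(points)
    X_train, y_train = build_table(stack, train_pts, subset)
    X_test, y_test = build_table(stack, test_pts, subset)
    forest, ranking = train_rf(X_train, y_train, cfg, names=subset)
    y_pred = list(forest.predict(X_test))
    matrix = error_matrix(y_pred, y_test)
    return ModelRun(
        subset=subset,
        forest=forest,
        ranking=ranking,
        test_predictions=y_pred,
        test_reference=list(y_test),
        matrix=matrix,
        result=accuracy_stats(matrix),
    )


def predict_map(
    forest: RandomForestClassifier, stack: FeatureStack, subset: list[str]
) -> RasterGrid:
    """Predict a class-id map over the whole stack extent by per-pixel voting.

    Pixels with nodata in any subset layer are nodata (-1). Class ids are the
    indices into ``forest.classes_``; scikit-learn resolves vote ties toward
    the lowest class id.
    """
    layers = [stack[n] for n in subset]
    ref = layers[0]
    valid = np.ones(ref.shape, dtype=bool)
    for g in layers:
        valid &= g.mask()
    X = np.column_stack([g.values[valid] for g in layers])
    out = np.full(ref.shape, -1.0)
    if X.size:
        pred = forest.predict(X)
        class_index = {c: i for i, c in enumerate(forest.classes_)}
        out[valid] = np.array([class_index[c] for c in pred], dtype=float)
    grid = ref.copy_with(out)
    grid.nodata = -1.0
    return grid
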