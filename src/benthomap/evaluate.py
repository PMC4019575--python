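"""Thematic-map accuracy assessment and layer diagnostics.

Error matrices are oriented predicted-rows x reference-columns. Kappa and its
large-sample (delta-method) variance follow the standard four-term estimator
from the accuracy-assessment literature; pairwise model comparison uses
Z = |k_a - k_b| / sqrt(var_a + var_b) against the 1.96 critical value.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import FeatureStack

Z_CRITICAL_95 = 1.96


@dataclass
class ErrorMatrix:
    classes: list[str]
    counts: np.ndarray  # (k, k) ints, rows = predicted, cols = reference

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("error matrix must contain at least one observation")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["predicted\\reference"] + self.classes)
            for cls, row in zip(self.classes, self.counts):
                writer.writerow([cls] + row.tolist())


@dataclass
class EvaluationResult:
    overall_accuracy: float  # percent
    kappa: float
    kappa_variance: float
    per_class: dict[str, dict[str, float | None]] = field(default_factory=dict)


def error_matrix(predicted: list[str], reference: list[str], classes: list[str] | None = None) -> ErrorMatrix:
    """Cross-tabulate predicted against reference labels."""
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference label vectors must have equal length")
    if classes is None:
        classes = sorted(set(predicted) | set(reference))
    index = {c: i for i, c in enumerate(classes)}
    bad = [l for l in list(predicted) + list(reference) if l not in index]
    if bad:
        raise ValueError(f"label(s) outside the class vocabulary: {sorted(set(bad))}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, r in zip(predicted, reference):
        counts[index[p], index[r]] += 1
    return ErrorMatrix(classes=list(classes), counts=counts)


def kappa_and_variance(matrix: ErrorMatrix) -> tuple[float, float]:
    """Kappa coefficient and its delta-method large-sample variance.

    With theta1 = observed agreement, theta2 = chance agreement,
    theta3 = sum_i x_ii (x_i+ + x_+i) / N^2 and
    theta4 = sum_ij x_ij (x_j+ + x_+i)^2 / N^3:

        var(k) = [ t1(1-t1)/(1-t2)^2
                   + 2(1-t1)(2 t1 t2 - t3)/(1-t2)^3
                   + (1-t1)^2 (t4 - 4 t2^2)/(1-t2)^4 ] / N
    """
    x = matrix.counts.astype(float)
    N = float(matrix.N)
    rows = x.sum(axis=1)
    cols = x.sum(axis=0)
    diag = np.diag(x)
    t1 = diag.sum() / N
    t2 = float(rows @ cols) / N**2
    if t2 == 1.0:
        return (1.0 if t1 == 1.0 else 0.0), 0.0
    kappa = (t1 - t2) / (1 - t2)
    t3 = float(diag @ (rows + cols)) / N**2
    # weight for cell (i, j) is (x_j+ + x_+i): row sum of j plus column sum of i
    t4 = float((x * np.add.outer(cols, rows) ** 2).sum()) / N**3
    var = (
        t1 * (1 - t1) / (1 - t2) ** 2
        + 2 * (1 - t1) * (2 * t1 * t2 - t3) / (1 - t2) ** 3
        + (1 - t1) ** 2 * (t4 - 4 * t2**2) / (1 - t2) ** 4
    ) / N
    return float(kappa), float(max(var, 0.0))


def accuracy_stats(matrix: ErrorMatrix) -> EvaluationResult:
    """Overall accuracy (%), kappa with variance, and per-class accuracies.

    Per class: user's accuracy = diagonal / row sum (commission view),
    producer's = diagonal / column sum (omission view), and their mean.
    Empty rows or columns leave the corresponding accuracy as None.
    """
    x = matrix.counts
    N = matrix.N
    oa = 100.0 * float(np.trace(x)) / N
    kappa, var = kappa_and_variance(matrix)
    per_class: dict[str, dict[str, float | None]] = {}
    rows = matrix.row_sums()
    cols = matrix.col_sums()
    for i, cls in enumerate(matrix.classes):
        users = 100.0 * x[i, i] / rows[i] if rows[i] > 0 else None
        producers = 100.0 * x[i, i] / cols[i] if cols[i] > 0 else None
        mean = (users + producers) / 2.0 if users is not None and producers is not None else None
        per_class[cls] = {"users": users, "producers": producers, "mean": mean}
    return EvaluationResult(
        overall_accuracy=oa, kappa=kappa, kappa_variance=var, per_class=per_class
    )


def z_test(matrix_a: ErrorMatrix, matrix_b: ErrorMatrix) -> tuple[float, bool]:
    """Pairwise kappa Z statistic and its significance at the 95% level.

    Returns (Z, significant). Z is NaN (and not significant) when both
    variances are zero, which only happens for degenerate matrices.
    """
    ka, va = kappa_and_variance(matrix_a)
    kb, vb = kappa_and_variance(matrix_b)
    denom = va + vb
    if denom == 0.0:
        if ka == kb:
            return 0.0, False
        return float("nan"), False
    z = abs(ka - kb) / math.sqrt(denom)
    return float(z), z > Z_CRITICAL_95


def layer_correlation(stack: FeatureStack, stride: int = 1) -> tuple[np.ndarray, list[str]]:
    """Symmetric table of squared Pearson correlations between all layer pairs.

    Pixels with nodata in either member of a pair are excluded pairwise.
    Entries involving a constant layer are NaN. ``stride`` subsamples pixels
    for very large grids.
    """
    names = list(stack.names)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 layers to correlate")
    data = [g.masked()[::stride, ::stride].ravel() for g in stack.layers]
    table = np.full((k, k), np.nan)
    for i in range(k):
        table[i, i] = 1.0
        for j in range(i + 1, k):
            a, b = data[i], data[j]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2:
                continue
            av, bv = a[ok], b[ok]
            sa, sb = av.std(), bv.std()
            if sa == 0 or sb == 0:
                continue  # constant layer: undefined, left NaN
            r = float(np.corrcoef(av, bv)[0, 1])
            table[i, j] = table[j, i] = r * r
    return table, names


def correlation_to_csv(table: np.ndarray, names: list[str], path: str, flag_above: float = 0.5) -> None:
    """Lower-triangle R^2 report; values above the flag threshold get a '*'."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + names)
        for i, name in enumerate(names):
            row: list[str] = [name]
            for j in range(len(names)):
                if j > i:
                    row.append("-")
                else:
                    v = table[i, j]
                    if np.isnan(v):
                        row.append("NA")
                    else:
                        row.append(f"{v:.2f}*" if v > flag_above and i != j else f"{v:.2f}")
            writer.writerow(row)
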