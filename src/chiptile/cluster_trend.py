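"""SOM clustering of gene occupancy features and correlation/trend analyses.

Genes are described by per-experiment promoter and/or ORF median Z-scores
and clustered with a classic one-dimensional Kohonen self-organizing map:
``k`` prototype vectors on a line, competitive training with a Gaussian
neighborhood whose radius and learning rate decay linearly over the
epochs.  Only genes with no missing value enter the clustering
(complete-case rule), and cluster labels are arbitrary — partitions should
be compared with a chance-corrected agreement index, never by label.

The trend tools quantify how one occupancy feature varies with another:
a plain Pearson coefficient over complete cases, and a sliding-median
curve (window of 300 genes ranked by the x feature, step 1) that exposes
non-linear trends the single coefficient hides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summarize import GeneSummaryTable
from .tracks_io import ValidationError

__all__ = [
    "FeatureMatrix",
    "SomModel",
    "feature_matrix",
    "som_fit",
    "pearson",
    "TrendCurve",
    "sliding_median_trend",
    "derived_feature",
    "select_transcribed",
]


@dataclass
class FeatureMatrix:
    """Complete-case genes x features matrix for clustering."""

    gene_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.gene_ids), len(self.feature_names)):
            raise ValidationError("feature matrix shape mismatch")
        if np.isnan(self.X).any():
            raise ValidationError(
                "clustering input must be complete-case (no missing values)"
            )


def feature_matrix(
    summary: GeneSummaryTable,
    experiments: Sequence[str],
    regions: Sequence[str] = ("promoter", "orf"),
) -> FeatureMatrix:
    """Assemble (experiment, region) median-Z columns, complete cases only.

    Genes with any missing value across the selected columns are dropped,
    mirroring the complete-case rule for clustering input.
    """
    cols = [f"{exp}_{region}" for exp in experiments for region in regions]
    missing_cols = [c for c in cols if c not in summary.df.columns]
    if missing_cols:
        raise ValidationError(f"summary lacks columns {missing_cols}")
    sub = summary.df[cols].dropna()
    return FeatureMatrix(
        tuple(sub.index), tuple(cols), sub.to_numpy(dtype=np.float64)
    )


@dataclass
class SomModel:
    """A trained 1 x k self-organizing map."""

    k: int
    codebook: np.ndarray  # k x d
    epochs: int
    alpha: tuple[float, float]
    radius: tuple[float, float]
    seed: int

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Best-matching node (Euclidean) for each row of X."""
        d2 = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def som_fit(
    X: np.ndarray | FeatureMatrix,
    k: int,
    epochs: int = 100,
    seed: int = 0,
    alpha: tuple[float, float] = (0.05, 0.005),
    radius: tuple[float, float] | None = None,
) -> tuple[SomModel, np.ndarray]:
    """Train a 1 x k Kohonen map and assign every gene to its best node.

    Codebook vectors are initialized from distinct data rows (seeded).
    Each epoch presents the rows in a fresh shuffled order; the winning
    node and its neighbors (Gaussian kernel over grid distance) move
    toward the sample by a learning rate that decays linearly from
    ``alpha[0]`` to ``alpha[1]`` while the neighborhood radius decays from
    ``k/2`` to 0.5.  Deterministic given the seed.

    Returns the trained model and the final per-row node assignment.
    Missing values and ``k > n_rows`` are errors.
    """
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("X must be 2-dimensional (genes x features)")
    n, d = X.shape
    if np.isnan(X).any():
        raise ValidationError("only genes with no missing value can be clustered")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of genes ({n})")
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")
    if radius is None:
        radius = (max(k / 2.0, 0.5), 0.5)

    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(n, size=k, replace=False)].astype(np.float64).copy()
    positions = np.arange(k, dtype=np.float64)
    total = epochs * n
    t = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = t / max(total - 1, 1)
            a = alpha[0] + (alpha[1] - alpha[0]) * frac
            r = radius[0] + (radius[1] - radius[0]) * frac
            x = X[i]
            bmu = int(((x - codebook) ** 2).sum(axis=1).argmin())
            h = np.exp(-((positions - bmu) ** 2) / (2.0 * r * r))
            codebook += a * h[:, None] * (x - codebook)
            t += 1
    model = SomModel(k, codebook, epochs, alpha, radius, seed)
    return model, model.assign(X)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation over complete cases (>=3 required)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValidationError("need at least 3 complete pairs")
    return float(stats.pearsonr(x[ok], y[ok]).statistic)


@dataclass
class TrendCurve:
    """A sliding-median trend: one (median x, median y) point per window."""

    x: np.ndarray
    y: np.ndarray
    window: int

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValidationError("trend arrays must have equal length")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window": np.arange(self.x.size), "x_median": self.x,
             "y_median": self.y}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sliding_median_trend(
    x: Sequence[float],
    y: Sequence[float],
    window: int = 300,
    ids: Sequence[str] | None = None,
) -> TrendCurve:
    """Median-vs-median trend over genes ranked by x.

    Complete cases are sorted by x (ties broken by gene id when given, by
    input position otherwise, for determinism); every run of ``window``
    consecutive genes yields one (median x, median y) point, step 1, so a
    curve of ``n - window + 1`` points.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    if window < 1:
        raise ValidationError("window must be >= 1")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ids is not None:
        tie = np.asarray(ids, dtype=object)[ok]
    else:
        tie = np.arange(x.size)[ok]
    xs, ys = x[ok], y[ok]
    n = xs.size
    if n < window:
        raise ValidationError(
            f"{n} complete cases < window of {window}; use a smaller window"
        )
    order = np.lexsort((tie, xs))
    xs, ys = xs[order], ys[order]
    mx = pd.Series(xs).rolling(window).median().to_numpy()[window - 1:]
    my = pd.Series(ys).rolling(window).median().to_numpy()[window - 1:]
    return TrendCurve(mx, my, window)


def derived_feature(
    summary: GeneSummaryTable,
    exp_a: str,
    exp_b: str,
    region: str = "orf",
) -> pd.Series:
    """Per-gene difference of two experiments' median Z (A - B).

    On the standardized scale a difference of summaries stands in for an
    occupancy ratio (mutant minus wild type, or factor minus polymerase);
    missing values propagate.
    """
    return summary.column(exp_a, region) - summary.column(exp_b, region)


def select_transcribed(
    summary: GeneSummaryTable,
    experiment: str,
    threshold: float = 0.0,
    region: str = "orf",
) -> tuple[str, ...]:
    """Genes whose polymerase-occupancy median Z is strictly above threshold.

    On the Z scale, threshold 0 selects genes with above-average
    polymerase occupancy — the operational 'transcribed' set.
    """
    col = summary.column(experiment, region)
    return tuple(col.index[col > threshold])
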