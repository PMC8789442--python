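"""Seven-dimensional feature vector and random-forest evaluation.

Per time-aligned epoch pair (channels FZCZ and CZPZ by default) the
detector uses:

* two adjusted sample entropies — one per channel, computed on the
  amplitude-transformed signal;
* five phase-synchronization indexes — one per rank-matched VMD mode pair
  IMF1..IMF5 (the highest-frequency mode is excluded), computed on the
  outlier-cleaned but *untransformed* signal, since logarithmic amplitude
  compression would distort the modes' center frequencies.

Classification is a random forest (default 900 trees, 5 candidate
variables per split — values found by grid search in the source study)
evaluated by seeded stratified 10-fold cross-validation; reported metrics
treat the epileptic class as positive:

    accuracy    = (TP + TN) / N
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .entropy import SampEnParams, improved_sample_entropy
from .phase_sync import imf_pair_psi
from .preprocess import Epoch, nonuniform_transform
from .vmd import VMDConfig, vmd_decompose

__all__ = [
    "FeatureVector",
    "RFConfig",
    "FoldCounts",
    "DetectionReport",
    "FEATURE_COLUMNS",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "build_feature_vector",
    "anova_screen",
    "cross_validate",
    "features_to_frame",
    "frame_to_features",
    "save_features",
    "load_features",
    "balanced_subsample",
]

POSITIVE_LABEL = "epileptic"
NEGATIVE_LABEL = "nonepileptic"
FEATURE_COLUMNS = (
    "sampen_imp_FZCZ",
    "sampen_imp_CZPZ",
    "psi_1",
    "psi_2",
    "psi_3",
    "psi_4",
    "psi_5",
)


@dataclass(frozen=True)
class FeatureVector:
    """The 7 features of one epoch pair, with an optional training label."""

    sampen_imp_a: float
    sampen_imp_b: float
    psi: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        object.__setattr__(self, "psi", psi)
        if psi.shape != (5,):
            raise ValueError("psi must hold exactly 5 values")
        if np.any((psi < 0) | (psi > 1)):
            raise ValueError("psi values must lie in [0, 1]")
        if self.label is not None and self.label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def values(self) -> np.ndarray:
        return np.concatenate(([self.sampen_imp_a, self.sampen_imp_b], self.psi))


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings; ``grid`` (trees x variables-per-split)
    enables an inner grid search on the training folds only."""

    n_trees: int = 900
    n_vars_per_split: int = 5
    seed: int = 0
    grid: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_vars_per_split <= len(FEATURE_COLUMNS):
            raise ValueError("n_vars_per_split must be between 1 and 7")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def default_grid() -> dict[str, list[int]]:
    return {"n_trees": [300, 600, 900, 1200], "n_vars_per_split": [2, 3, 5, 7]}


@dataclass(frozen=True)
class FoldCounts:
    """Confusion counts of one CV fold (epileptic = positive)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DetectionReport:
    """Pooled cross-validation outcome with per-fold confusion counts."""

    folds: tuple[FoldCounts, ...]
    fold_assignments: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    config: dict

    @property
    def pooled(self) -> FoldCounts:
        return FoldCounts(
            tp=sum(f.tp for f in self.folds),
            fp=sum(f.fp for f in self.folds),
            tn=sum(f.tn for f in self.folds),
            fn=sum(f.fn for f in self.folds),
        )

    def to_dict(self) -> dict:
        p = self.pooled
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "pooled_counts": {"tp": p.tp, "fp": p.fp, "tn": p.tn, "fn": p.fn},
            "folds": [
                {"tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn} for f in self.folds
            ],
            "fold_assignments": self.fold_assignments.tolist(),
            "config": self.config,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def build_feature_vector(
    epoch_a: Epoch,
    epoch_b: Epoch,
    mu_a: float,
    mu_b: float,
    vmd_config: VMDConfig = VMDConfig(),
    sampen_params: SampEnParams = SampEnParams(),
    n_segments: int = 8,
    trim_frac: float = 0.05,
    label: str | None = None,
) -> FeatureVector:
    """Extract the 7 features from one outlier-cleaned epoch pair.

    The entropy branch applies the nonuniform amplitude transform before
    the adjusted sample entropy; the phase branch decomposes the untouched
    (cleaned) signals and computes PSI for mode pairs 1..5.
    """
    if epoch_a.fs != epoch_b.fs:
        raise ValueError("epochs must share a sampling rate")
    if epoch_a.n_samples != epoch_b.n_samples:
        raise ValueError("epochs must be time-aligned (equal length)")

    ent_a = improved_sample_entropy(
        epoch_a.copy_with(nonuniform_transform(epoch_a.samples)),
        mu=mu_a, params=sampen_params, n_segments=n_segments,
    )
    ent_b = improved_sample_entropy(
        epoch_b.copy_with(nonuniform_transform(epoch_b.samples)),
        mu=mu_b, params=sampen_params, n_segments=n_segments,
    )
    imfs_a = vmd_decompose(epoch_a, vmd_config)
    imfs_b = vmd_decompose(epoch_b, vmd_config)
    psi = imf_pair_psi(imfs_a, imfs_b, n_pairs=5, trim_frac=trim_frac)
    return FeatureVector(
        sampen_imp_a=ent_a.adjusted,
        sampen_imp_b=ent_b.adjusted,
        psi=psi,
        label=label,
    )


def anova_screen(group0: Sequence[float], group1: Sequence[float]) -> float:
    """One-way fixed-effects ANOVA P-value for two groups (equivalent to
    the squared two-sample t test)."""
    g0 = np.asarray(group0, dtype=float)
    g1 = np.asarray(group1, dtype=float)
    if g0.size < 2 or g1.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(g0) == 0 and np.ptp(g1) == 0:
        # no within-group variance: P = 1 when the means agree, else 0
        return 1.0 if g0.mean() == g1.mean() else 0.0
    return float(sstats.f_oneway(g0, g1).pvalue)


def _make_classifier(config: RFConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.n_vars_per_split,
        random_state=config.seed,
        n_jobs=1,
    )


def cross_validate(
    features: Sequence[FeatureVector],
    config: RFConfig = RFConfig(),
    n_folds: int = 10,
) -> DetectionReport:
    """Seeded stratified k-fold evaluation of the random forest.

    When ``config.grid`` is set, hyperparameters are re-selected inside
    each training fold by 3-fold grid search on accuracy; test folds never
    influence the choice.  Metrics are computed from the pooled confusion
    counts.
    """
    feats = list(features)
    if any(f.label is None for f in feats):
        raise ValueError("all feature vectors must be labeled")
    X = np.vstack([f.values for f in feats])
    y = np.array([f.label for f in feats])
    for cls in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if np.sum(y == cls) < n_folds:
            raise ValueError(
                f"need at least {n_folds} samples of class {cls!r} for "
                f"{n_folds}-fold stratified CV"
            )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    assignments = np.empty(len(feats), dtype=int)
    folds: list[FoldCounts] = []
    for fold_id, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        assignments[test_idx] = fold_id
        if set(y[train_idx]) != {POSITIVE_LABEL, NEGATIVE_LABEL}:
            raise ValueError("a class is absent from a training fold")
        if config.grid is not None:
            search = GridSearchCV(
                _make_classifier(config),
                param_grid={
                    "n_estimators": config.grid.get("n_trees", [config.n_trees]),
                    "max_features": config.grid.get(
                        "n_vars_per_split", [config.n_vars_per_split]
                    ),
                },
                scoring="accuracy",
                cv=StratifiedKFold(3, shuffle=True, random_state=config.seed),
                n_jobs=1,
            )
            search.fit(X[train_idx], y[train_idx])
            clf = search.best_estimator_
        else:
            clf = _make_classifier(config)
            clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        folds.append(
            FoldCounts(
                tp=int(np.sum((pred == POSITIVE_LABEL) & (truth == POSITIVE_LABEL))),
                fp=int(np.sum((pred == POSITIVE_LABEL) & (truth == NEGATIVE_LABEL))),
                tn=int(np.sum((pred == NEGATIVE_LABEL) & (truth == NEGATIVE_LABEL))),
                fn=int(np.sum((pred == NEGATIVE_LABEL) & (truth == POSITIVE_LABEL))),
            )
        )

    tp = sum(f.tp for f in folds)
    fp = sum(f.fp for f in folds)
    tn = sum(f.tn for f in folds)
    fn = sum(f.fn for f in folds)
    return DetectionReport(
        folds=tuple(folds),
        fold_assignments=assignments,
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        config={
            "n_trees": config.n_trees,
            "n_vars_per_split": config.n_vars_per_split,
            "seed": config.seed,
            "grid": config.grid,
            "n_folds": n_folds,
            "n_per_class": {
                POSITIVE_LABEL: int(np.sum(y == POSITIVE_LABEL)),
                NEGATIVE_LABEL: int(np.sum(y == NEGATIVE_LABEL)),
            },
        },
    )


# ---------------------------------------------------------------------------
# Feature-table IO and balance helper

def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    rows = []
    for f in features:
        row = dict(zip(FEATURE_COLUMNS, f.values))
        row["label"] = f.label
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["label"])


def frame_to_features(df: pd.DataFrame) -> list[FeatureVector]:
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        label = getattr(row, "label", None)
        if isinstance(label, float) and np.isnan(label):
            label = None
        out.append(
            FeatureVector(
                sampen_imp_a=float(getattr(row, FEATURE_COLUMNS[0])),
                sampen_imp_b=float(getattr(row, FEATURE_COLUMNS[1])),
                psi=np.array([getattr(row, c) for c in FEATURE_COLUMNS[2:]], dtype=float),
                label=label,
            )
        )
    return out


def save_features(features: Sequence[FeatureVector], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, index=False)


def load_features(path: str | Path) -> list[FeatureVector]:
    return frame_to_features(pd.read_csv(path))


def balanced_subsample(
    features: Sequence[FeatureVector], rng: np.random.Generator | None = None
) -> list[FeatureVector]:
    """Random subsample with equal class counts (no hidden rebalancing is
    ever applied by the trainer; call this explicitly if desired)."""
    if rng is None:
        rng = np.random.default_rng()
    by_class: dict[str, list[FeatureVector]] = {}
    for f in features:
        if f.label is None:
            raise ValueError("cannot balance unlabeled features")
        by_class.setdefault(f.label, []).append(f)
    n_min = min(len(v) for v in by_class.values())
    out: list[FeatureVector] = []
    for group in by_class.values():
        idx = rng.choice(len(group), size=n_min, replace=False)
        out.extend(group[i] for i in sorted(idx))
    return out
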