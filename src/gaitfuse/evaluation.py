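"""End-to-end recognition pipeline and evaluation harness.

``GaitClassifier`` chains the four stages — feature extraction, KDE-based
calibration, z-score normalization, KELM scoring — with all statistics
fitted on the training split only.  Per-recording identification converts
the per-frame KELM outputs to fuzzy memberships and fuses them with a
chosen rule.  ``fusion_accuracy_curve`` reproduces the standard evaluation
design: subject-level accuracy as the fraction of fused test frames grows
from 0.1 to 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as _cal
from . import features as _feat
from . import fusion as _fus
from . import kelm as _kelm
from .trajectory import GaitDataset, GaitTrajectory


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full recognition pipeline."""

    h: float = _kelm.DEFAULT_H
    lam: float = _kelm.DEFAULT_LAMBDA
    p_th: float = _cal.DEFAULT_P_TH
    calibration_strategy: str = "clamp"  # clamp | mean | off
    gamma: float = _fus.DEFAULT_GAMMA
    rel_lower: float = _fus.DEFAULT_REL_LOWER
    rel_span: float = _fus.DEFAULT_REL_SPAN
    delta: float = _fus.DEFAULT_DELTA


def frame_accuracy(predictions, truth) -> float:
    """Fraction of exact label matches."""
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    if not predictions:
        raise ValueError("need at least one prediction")
    return sum(p == t for p, t in zip(predictions, truth)) / len(predictions)


def tracker_subset(dataset: GaitDataset, subset) -> GaitDataset:
    """Restrict every trajectory to the given marker indices.

    Downstream feature dimension becomes ``|S|(|S|-1)/2 + |S|`` (21 for the
    common 6-marker configuration of thigh, knee-front and ankle per side).
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("need at least 2 markers for pairwise distances")
    n = dataset.trajectories[0].n_markers
    if any(not 0 <= i < n for i in subset):
        raise ValueError(f"marker index out of range 0..{n - 1}")
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate marker index")
    new = [
        GaitTrajectory.from_array(
            t.positions[:, subset, :], subject_label=t.subject_label, tau=t.tau,
            frame_indices=np.array([f.frame_index for f in t.frames]),
        )
        for t in dataset.trajectories
    ]
    return GaitDataset(trajectories=new, class_list=list(dataset.class_list))


@dataclass
class GaitClassifier:
    """Fitted pipeline: calibration bounds, normalizer and KELM model."""

    config: PipelineConfig
    bounds: _cal.FeatureBounds | None
    normalizer: _feat.NormalizerStats
    model: _kelm.KELMModel

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    def transform(self, raw_features: np.ndarray) -> np.ndarray:
        """Calibrate (training-fitted bounds) then z-score a feature matrix."""
        X = np.asarray(raw_features, dtype=float)
        if self.bounds is not None:
            X = _cal.calibrate_features(X, self.bounds, self.config.calibration_strategy)
        return _feat.apply_normalizer(self.normalizer, X)

    def frame_outputs(self, traj: GaitTrajectory) -> np.ndarray:
        """Per-frame KELM score vectors for one recording."""
        X = self.transform(_feat.extract_feature_sequence(traj))
        return _kelm.predict_outputs(self.model, X)

    def frame_labels(self, traj: GaitTrajectory) -> list[str]:
        O = self.frame_outputs(traj)
        return [self.classes[k] for k in np.argmax(O, axis=1)]

    def classify(
        self, traj: GaitTrajectory, rule: str = "rws", n_frames: int | None = None
    ) -> _fus.GlobalDecision:
        """Fuse the (leading ``n_frames``) per-frame decisions of a recording."""
        O = self.frame_outputs(traj)
        if n_frames is not None:
            O = O[:n_frames]
        M = _fus.membership_matrix(O, gamma=self.config.gamma)
        if rule == "rws":
            return _fus.rws_fuse(M, a=self.config.rel_lower, b=self.config.rel_span)
        return _fus.baseline_fuse(
            M, rule, delta=self.config.delta,
            a=self.config.rel_lower, b=self.config.rel_span,
            hard_indices=np.argmax(O, axis=1),
        )


def _stack_features(dataset: GaitDataset) -> tuple[np.ndarray, list[str]]:
    mats, labels = [], []
    for traj in dataset.trajectories:
        X = _feat.extract_feature_sequence(traj)
        mats.append(X)
        labels.extend([traj.subject_label] * X.shape[0])
    return np.vstack(mats), labels


def fit_pipeline(train: GaitDataset, config: PipelineConfig = PipelineConfig()) -> GaitClassifier:
    """Fit calibration bounds, normalizer and KELM on a training dataset."""
    if len(train.class_list) < 2:
        raise ValueError("training needs at least 2 subjects")
    X, labels = _stack_features(train)
    n_markers = train.trajectories[0].n_markers
    names = _feat.feature_names(n_markers)
    bounds = None
    if config.calibration_strategy != "off":
        bounds = _cal.fit_feature_bounds(X, p_th=config.p_th, feature_names=names)
        X = _cal.calibrate_features(X, bounds, config.calibration_strategy)
    normalizer = _feat.fit_normalizer(X)
    Xn = _feat.apply_normalizer(normalizer, X)
    model = _kelm.train_kelm(
        Xn, labels, h=config.h, lam=config.lam, classes=train.class_list
    )
    return GaitClassifier(config=config, bounds=bounds, normalizer=normalizer, model=model)


@dataclass
class EvalResult:
    """Accuracy-vs-ratio curves plus single-frame summary statistics."""

    ratios: np.ndarray
    rule_accuracy: dict[str, np.ndarray]
    single_frame_accuracy: float
    confusion: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rule_accuracy, index=np.round(self.ratios, 3))
        df.index.name = "ratio"
        return df


def single_frame_accuracy(clf: GaitClassifier, test: GaitDataset) -> float:
    """Frame-level accuracy of the raw KELM hard decisions on a test set."""
    preds, truth = [], []
    for traj in test.trajectories:
        labs = clf.frame_labels(traj)
        preds.extend(labs)
        truth.extend([traj.subject_label] * len(labs))
    return frame_accuracy(preds, truth)


def fusion_accuracy_curve(
    clf: GaitClassifier,
    test: GaitDataset,
    rules=("rws", "sum", "product", "majority", "belief", "weighted_belief"),
    ratios=None,
    subset_mode: str = "leading",
    seed: int = 0,
) -> EvalResult:
    """Subject-level accuracy of each fusion rule vs. fused-frame ratio.

    For ratio r each recording contributes its leading ``ceil(r * T)``
    frame decisions (or a seeded random subset with
    ``subset_mode='random'``).
    """
    if ratios is None:
        ratios = np.arange(1, 11) / 10.0
    ratios = np.asarray(ratios, dtype=float)
    if np.any((ratios <= 0) | (ratios > 1)):
        raise ValueError("ratios must lie in (0, 1]")
    if np.any(np.diff(ratios) <= 0):
        raise ValueError("ratio grid must be strictly increasing")
    if subset_mode not in ("leading", "random"):
        raise ValueError("subset_mode must be 'leading' or 'random'")
    rng = np.random.default_rng(seed)

    # cache per-recording memberships once
    cached = []
    frame_preds, frame_truth = [], []
    for traj in test.trajectories:
        O = clf.frame_outputs(traj)
        M = _fus.membership_matrix(O, gamma=clf.config.gamma)
        hard = np.argmax(O, axis=1)
        cached.append((M, hard, traj.subject_label))
        frame_preds.extend(clf.classes[k] for k in hard)
        frame_truth.extend([traj.subject_label] * O.shape[0])

    classes = clf.classes
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for p, t in zip(frame_preds, frame_truth):
        conf.loc[t, p] += 1

    rule_acc = {rule: np.empty(ratios.size) for rule in rules}
    for k, r in enumerate(ratios):
        per_rule_hits = {rule: 0 for rule in rules}
        for M, hard, truth in cached:
            T = M.shape[0]
            n = max(1, math.ceil(r * T))
            if subset_mode == "leading":
                idx = np.arange(n)
            else:
                idx = np.sort(rng.choice(T, size=n, replace=False))
            sub, sub_hard = M[idx], hard[idx]
            for rule in rules:
                if rule == "rws":
                    dec = _fus.rws_fuse(sub, a=clf.config.rel_lower, b=clf.config.rel_span)
                else:
                    dec = _fus.baseline_fuse(
                        sub, rule, delta=clf.config.delta,
                        a=clf.config.rel_lower, b=clf.config.rel_span,
                        hard_indices=sub_hard,
                    )
                per_rule_hits[rule] += dec.label(classes) == truth
        for rule in rules:
            rule_acc[rule][k] = per_rule_hits[rule] / len(cached)

    return EvalResult(
        ratios=ratios,
        rule_accuracy=rule_acc,
        single_frame_accuracy=frame_accuracy(frame_preds, frame_truth),
        confusion=conf,
    )
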