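"""Cross-validation protocols and classifier performance metrics.

Twofold: one stratified random half split (9 ACL-D + 14 ACL-I training
subjects for the study-sized 18/28 cohort; odd group sizes put the extra
subject in training).  Leave-one-subject-out (LOSO): each subject classified
by a bank trained on the remaining n-1.  The feature normalizer and every
estimator are refit per fold from training data only.

Metrics use ACL-D as the positive class (sensitivity = injured-knee detection
rate) and exact rational arithmetic before display rounding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from gaitdyn.classify import ClassificationResult, EstimatorBank, classify_pattern
from gaitdyn.config import PipelineConfig
from gaitdyn.detlearn import LearnedPattern, build_lattice, train_pattern
from gaitdyn.errors import ConfigError, GaitDataError
from gaitdyn.gait_io import Cohort, GaitTrial, Group
from gaitdyn.psr import FeatureTrajectory, build_features, fit_normalizer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with ACL-D as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise GaitDataError("confusion counts must be non-negative")
        if self.total < 1:
            raise GaitDataError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def metrics(cm: ConfusionMatrix) -> Dict[str, Optional[float]]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total.

    Computed in exact rational arithmetic, returned as floats; a metric whose
    denominator is zero is returned as None (undefined), never NaN.
    """
    out: Dict[str, Optional[float]] = {}
    out["sensitivity"] = (
        float(Fraction(cm.tp, cm.tp + cm.fn)) if cm.tp + cm.fn > 0 else None
    )
    out["specificity"] = (
        float(Fraction(cm.tn, cm.tn + cm.fp)) if cm.tn + cm.fp > 0 else None
    )
    out["accuracy"] = float(Fraction(cm.tp + cm.tn, cm.total))
    return out


def twofold_split(cohort: Cohort, seed: int) -> Tuple[List[GaitTrial], List[GaitTrial]]:
    """Stratified random half split; extra subject of an odd group trains."""
    rng = np.random.default_rng(seed)
    train: List[GaitTrial] = []
    test: List[GaitTrial] = []
    for group in Group:
        members = cohort.by_group(group)
        if len(members) < 2:
            raise GaitDataError(
                f"group {group.value} has {len(members)} subject(s); "
                "need >= 2 for a twofold split"
            )
        order = rng.permutation(len(members))
        n_train = (len(members) + 1) // 2
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test


@dataclass
class FoldPrediction:
    subject_id: str
    true_group: Group
    predicted_group: Optional[Group]
    matched_pattern: str
    margin: float


@dataclass
class CVReport:
    protocol: str
    seed: int
    predictions: List[FoldPrediction]
    confusion: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "seed": self.seed,
            "confusion": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "positive_class": Group.ACL_D.value,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "predictions": [
                {
                    "subject_id": p.subject_id,
                    "true_group": p.true_group.value,
                    "predicted_group": (
                        p.predicted_group.value if p.predicted_group else None
                    ),
                    "matched_pattern": p.matched_pattern,
                    "margin": p.margin,
                }
                for p in self.predictions
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _confusion_from_predictions(preds: List[FoldPrediction]) -> ConfusionMatrix:
    tp = sum(
        1 for p in preds
        if p.true_group == Group.ACL_D and p.predicted_group == Group.ACL_D
    )
    fn = sum(
        1 for p in preds
        if p.true_group == Group.ACL_D and p.predicted_group != Group.ACL_D
    )
    tn = sum(
        1 for p in preds
        if p.true_group == Group.ACL_I and p.predicted_group == Group.ACL_I
    )
    fp = sum(
        1 for p in preds
        if p.true_group == Group.ACL_I and p.predicted_group != Group.ACL_I
    )
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


class _PatternCache:
    """Memoizes trained patterns by (subject, normalizer parameters).

    Within a cross-validation run the lattice and training config are fixed,
    so a subject retrained under a bit-identical train-only normalizer yields
    bit-identical weights; caching is pure memoization and does not leak test
    data into a fold.
    """

    def __init__(self) -> None:
        self._store: Dict[Tuple[str, bytes], LearnedPattern] = {}
        self.hits = 0
        self.misses = 0

    def get(self, subject_id: str, norm_key: bytes) -> Optional[LearnedPattern]:
        pat = self._store.get((subject_id, norm_key))
        if pat is not None:
            self.hits += 1
        return pat

    def put(self, subject_id: str, norm_key: bytes, pattern: LearnedPattern) -> None:
        self.misses += 1
        self._store[(subject_id, norm_key)] = pattern


def _train_bank(
    train_feats: List[FeatureTrajectory],
    config: PipelineConfig,
    lattice,
    cache: Optional[_PatternCache],
) -> Tuple[EstimatorBank, "object"]:
    normalizer = fit_normalizer(train_feats)
    patterns = []
    for feat in train_feats:
        cached = cache.get(feat.subject_id, normalizer.key()) if cache else None
        if cached is None:
            normalized = normalizer.apply(feat)
            cached = train_pattern(normalized, lattice, config.training)
            if cache is not None:
                cache.put(feat.subject_id, normalizer.key(), cached)
        patterns.append(cached)
    bank = EstimatorBank(
        patterns=patterns, b=config.classifier.b, tc_s=config.classifier.tc_s
    )
    return bank, normalizer


def _classify_subjects(
    bank: EstimatorBank,
    normalizer,
    test_feats: List[FeatureTrajectory],
    config: PipelineConfig,
) -> List[FoldPrediction]:
    preds = []
    for feat in test_feats:
        result = classify_pattern(
            bank, normalizer.apply(feat), aggregate=config.classifier.aggregate
        )
        preds.append(
            FoldPrediction(
                subject_id=feat.subject_id,
                true_group=feat.group,
                predicted_group=result.predicted_group,
                matched_pattern=result.pattern_ids[result.matched_pattern],
                margin=result.margin,
            )
        )
    return preds


def run_cv(
    cohort: Cohort,
    protocol: str,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> CVReport:
    """Run a full cross-validated pipeline on a cohort.

    Features are extracted per trial (a per-subject operation); the
    normalizer and all estimators are refit within each fold from training
    subjects only.
    """
    config = config or PipelineConfig()
    if protocol not in ("twofold", "loso"):
        raise ConfigError("protocol must be 'twofold' or 'loso'")
    seed = config.evaluation.seed if seed is None else seed
    feats = {
        t.subject_id: build_features(t, config.embedding) for t in cohort
    }
    lattice = build_lattice(
        nodes_per_dim=config.lattice.nodes_per_dim,
        span=config.lattice.span,
        width=config.lattice.width,
        state_dim=len(next(iter(feats.values())).states[0]),
    )
    cache = _PatternCache()
    predictions: List[FoldPrediction] = []
    if protocol == "twofold":
        train, test = twofold_split(cohort, seed)
        bank, normalizer = _train_bank(
            [feats[t.subject_id] for t in train], config, lattice, cache
        )
        predictions = _classify_subjects(
            bank, normalizer, [feats[t.subject_id] for t in test], config
        )
    else:
        for held_out in cohort:
            train_feats = [
                feats[t.subject_id]
                for t in cohort
                if t.subject_id != held_out.subject_id
            ]
            bank, normalizer = _train_bank(train_feats, config, lattice, cache)
            predictions.extend(
                _classify_subjects(
                    bank, normalizer, [feats[held_out.subject_id]], config
                )
            )
        logger.info(
            "LOSO pattern cache: %d trainings, %d reused",
            cache.misses,
            cache.hits,
        )
    cm = _confusion_from_predictions(predictions)
    m = metrics(cm)
    return CVReport(
        protocol=protocol,
        seed=seed,
        predictions=predictions,
        confusion=cm,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
    )
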