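"""Bayesian-model-averaging ensemble over the gated model pool.

Each surviving model M_i contributes its prediction p(T | X, M_i) with weight

    w_i = (AUC_ROC_i - 0.7) / sum_j (AUC_ROC_j - 0.7)

where AUC_ROC_i is the model's training cross-validation score. Because the
gate threshold (0.80) exceeds the 0.7 offset, every weight is positive and
the weights sum to one. Member outputs are heterogeneous (probabilities,
margins, raw regression predictions), so each member's score is first mapped
to [0, 1] by min-max over its *own training-set* scores before weighting;
the weighted sum is then itself min-max rescaled to [0, 1] using bounds fixed
on the training cohort, and held-out samples falling outside those bounds
clamp. Higher ensemble scores mean more case-like.

A squared-weight variant ((AUC - 0.7)^2, normalized) is exposed for
sensitivity analysis.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harness import FittedModel

logger = logging.getLogger(__name__)

WEIGHT_OFFSET = 0.7
BUNDLE_VERSION = 1


def compute_bma_weights(auc_values, offset: float = WEIGHT_OFFSET,
                        squared: bool = False) -> np.ndarray:
    """Normalized (AUC - offset) weights; every AUC must exceed the offset."""
    auc = np.asarray(auc_values, dtype=float)
    if auc.size == 0:
        raise ValueError("no AUC values")
    excess = auc - offset
    if (excess <= 0).any():
        bad = auc[excess <= 0][0]
        raise ValueError(f"AUC value {bad} does not exceed the weight offset {offset}")
    if squared:
        excess = excess**2
    return excess / excess.sum()


def rescale_scores(raw_scores, bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Affine map to [0, 1]; with external bounds, out-of-range values clamp."""
    raw = np.asarray(raw_scores, dtype=float)
    if bounds is None:
        lo, hi = float(raw.min()), float(raw.max())
        if hi <= lo:
            raise ValueError("constant scores: rescaling bounds are degenerate")
        return (raw - lo) / (hi - lo)
    lo, hi = bounds
    if hi <= lo:
        raise ValueError("invalid rescaling bounds")
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class EnsembleModel:
    members: list[FittedModel]
    weights: np.ndarray
    weight_offset: float = WEIGHT_OFFSET
    rescale_min: float | None = None
    rescale_max: float | None = None
    # per-member training-score bounds for commensuration
    member_bounds: list[tuple[float, float]] = field(default_factory=list)

    def raw_predict(self, matrix: np.ndarray) -> np.ndarray:
        """Weighted sum of member scores, each min-max mapped by its own
        training bounds. Members that fail to score are dropped with
        renormalized weights (logged)."""
        contributions, kept_weights = [], []
        for member, w, (lo, hi) in zip(self.members, self.weights, self.member_bounds):
            try:
                s = member.predict(matrix)
            except Exception as exc:  # member scoring failure: drop + renormalize
                logger.warning("dropping ensemble member %s: %s", member.spec, exc)
                continue
            contributions.append(np.clip((s - lo) / (hi - lo), 0.0, 1.0) if hi > lo
                                 else np.full(len(s), 0.5))
            kept_weights.append(w)
        if not contributions:
            raise RuntimeError("no ensemble member could score the samples")
        w = np.asarray(kept_weights)
        w = w / w.sum()
        return np.einsum("i,ij->j", w, np.vstack(contributions))

    def save(self, path) -> None:
        """Serialize the fitted ensemble (members, weights, bounds) to a
        versioned bundle."""
        with open(path, "wb") as fh:
            pickle.dump({"version": BUNDLE_VERSION, "model": self}, fh)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if bundle.get("version") != BUNDLE_VERSION:
            raise ValueError(f"unsupported ensemble bundle version: "
                             f"{bundle.get('version')!r}")
        return bundle["model"]

    def predict(self, matrix: np.ndarray, use_training_bounds: bool = True) -> np.ndarray:
        """Rescaled [0, 1] ensemble scores.

        ``use_training_bounds=False`` rescales by the scored batch's own
        min/max instead of the stored training bounds.
        """
        raw = self.raw_predict(matrix)
        if use_training_bounds:
            return rescale_scores(raw, (self.rescale_min, self.rescale_max))
        return rescale_scores(raw)


def build_ensemble(members: list[FittedModel], train_matrix,
                   weight_offset: float = WEIGHT_OFFSET,
                   squared_weights: bool = False) -> EnsembleModel:
    """Assemble the BMA model from gated members and fix the rescaling bounds
    on the training cohort."""
    if not members:
        raise ValueError("ensemble needs at least one gated member")
    weights = compute_bma_weights([m.train_cv_auc_roc for m in members],
                                  offset=weight_offset, squared=squared_weights)
    bounds = [(float(m.train_scores.min()), float(m.train_scores.max()))
              for m in members]
    model = EnsembleModel(members=members, weights=weights,
                          weight_offset=weight_offset, member_bounds=bounds)
    raw_train = model.raw_predict(np.asarray(train_matrix, dtype=float))
    model.rescale_min = float(raw_train.min())
    model.rescale_max = float(raw_train.max())
    if model.rescale_max <= model.rescale_min:
        raise ValueError("training ensemble scores are constant; cannot rescale")
    return model


def score_table(sample_ids, diagnoses, raw, rescaled, strata=None) -> pd.DataFrame:
    frame = pd.DataFrame({
        "sample_id": sample_ids, "diagnosis": diagnoses,
        "raw_score": raw, "rescaled_score": rescaled})
    if strata is not None:
        frame["stratum"] = strata
    return frame


def stratify_by_group_mean(scores, diagnoses) -> tuple[np.ndarray, float]:
    """Label each case subject above/below the case-group mean score.

    Returns (labels, case_mean). Cases scoring at or above the mean are
    "above", strictly below are "below"; controls are labeled "TD".
    """
    scores = np.asarray(scores, dtype=float)
    dx = np.asarray(diagnoses)
    asd = dx == "ASD"
    if not asd.any():
        raise ValueError("no ASD subjects to stratify")
    mean = float(scores[asd].mean())
    labels = np.where(asd, np.where(scores >= mean, "above", "below"), "TD")
    return labels, mean
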