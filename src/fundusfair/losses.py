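"""Composite training objective for the two-branch classifier.

    L_total = l1*L_patho + l2*L_disea + l3*L_joint + l4*L_consis

* ``L_patho`` / ``L_disea`` -- asymmetric loss (ASL) on the pathology and
  disease heads. ASL decouples the focusing of positives and negatives
  (exponents gamma+ / gamma-) and shifts negative probabilities down by a
  margin ``clip`` so easy negatives stop contributing -- the standard
  remedy for the extreme positive/negative imbalance of multi-label
  screening.
* ``L_joint`` -- prediction-consistency penalty tying the disease
  probabilities to the score implied by the predicted fundus features
  through a feature-disease relation matrix.
* ``L_consis`` -- mean squared difference between the two encoders'
  feature volumes.

Each loss ships its analytic gradient; gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "asl",
    "asl_grad",
    "bce",
    "consis_loss",
    "consis_grad",
    "joint_loss",
    "joint_grad",
    "total_loss",
]

EPS = 1e-8  # probability clamp before logs

_warned_skipped: set[tuple] = set()


@dataclass
class LossWeights:
    """Loss-term weights and ASL hyperparameters."""

    lambda1: float = 0.01  # pathology classification
    lambda2: float = 1.0  # disease classification
    lambda3: float = 0.01  # prediction consistency
    lambda4: float = 1e-5  # feature-map consistency
    asl_gamma_pos: float = 0.0
    asl_gamma_neg: float = 4.0
    asl_clip: float = 0.05

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "asl_gamma_pos", "asl_gamma_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.asl_clip < 1:
            raise ValueError("asl_clip must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "lambda1", "lambda2", "lambda3", "lambda4",
            "asl_gamma_pos", "asl_gamma_neg", "asl_clip",
        )}

    @classmethod
    def from_dict(cls, d: dict) -> "LossWeights":
        return cls(**d)


@dataclass
class LossBreakdown:
    """Per-term values of one batch's objective."""

    patho: float
    disea: float
    joint: float
    consis: float
    total: float

    def to_dict(self) -> dict:
        return {
            "patho": self.patho,
            "disea": self.disea,
            "joint": self.joint,
            "consis": self.consis,
            "total": self.total,
        }


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)


def asl(probs: np.ndarray, labels: np.ndarray, weights: LossWeights) -> float:
    """Asymmetric loss, mean over samples and classes.

    Positives: -(1-p)^{g+} log p.  Negatives: -(p_m)^{g-} log(1-p_m)
    with the shifted probability p_m = max(p - clip, 0).
    """
    p = _clamp(probs)
    y = np.asarray(labels).astype(bool)
    if p.shape != y.shape:
        raise ValueError(f"probs shape {p.shape} != labels shape {y.shape}")
    if np.isnan(probs).any():
        raise ValueError("NaN in probabilities")
    gp, gn, c = weights.asl_gamma_pos, weights.asl_gamma_neg, weights.asl_clip
    pm = np.clip(p - c, 0.0, 1.0 - EPS)
    loss_pos = -((1.0 - p) ** gp) * np.log(p)
    loss_neg = -(pm**gn) * np.log1p(-pm)
    return float(np.where(y, loss_pos, loss_neg).mean())


def asl_grad(probs: np.ndarray, labels: np.ndarray, weights: LossWeights) -> np.ndarray:
    """dASL/dp, same shape as ``probs`` (mean-reduced loss)."""
    p = _clamp(probs)
    y = np.asarray(labels).astype(bool)
    gp, gn, c = weights.asl_gamma_pos, weights.asl_gamma_neg, weights.asl_clip
    # positive: d/dp[-(1-p)^gp log p] = gp (1-p)^(gp-1) log p - (1-p)^gp / p
    gpos = -((1.0 - p) ** gp) / p
    if gp > 0:
        gpos = gpos + gp * (1.0 - p) ** (gp - 1.0) * np.log(p)
    pm = np.clip(p - c, 0.0, 1.0 - EPS)
    active = p > c  # beyond the clip the negative term is flat
    # negative (p > c): d/dp[-pm^gn log(1-pm)] = -gn pm^(gn-1) log(1-pm) + pm^gn/(1-pm)
    safe_pm = np.where(active, pm, 0.5)  # dummy value off-support, masked below
    gneg_core = safe_pm**gn / (1.0 - safe_pm)
    if gn > 0:
        gneg_core = gneg_core - gn * safe_pm ** (gn - 1.0) * np.log1p(-safe_pm)
    gneg = np.where(active, gneg_core, 0.0)
    grad = np.where(y, gpos, gneg)
    return grad / p.size


def bce(probs: np.ndarray, labels: np.ndarray) -> float:
    """Binary cross-entropy, mean-reduced (the ASL gamma=0, clip=0 limit)."""
    p = _clamp(probs)
    y = np.asarray(labels).astype(float)
    return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())


def consis_loss(f_p: np.ndarray, f_d: np.ndarray) -> float:
    """Feature-map consistency: mean squared difference over all entries."""
    f_p = np.asarray(f_p, dtype=float)
    f_d = np.asarray(f_d, dtype=float)
    if f_p.shape != f_d.shape:
        raise ValueError(f"feature shapes differ: {f_p.shape} vs {f_d.shape}")
    return float(((f_p - f_d) ** 2).mean())


def consis_grad(f_p: np.ndarray, f_d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(dL/dF_p, dL/dF_d) of the mean squared difference."""
    diff = 2.0 * (np.asarray(f_p, float) - np.asarray(f_d, float)) / f_p.size
    return diff, -diff


def _implied_scores(patho_probs: np.ndarray, relation: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pathology-implied disease scores and the kept-disease mask.

    ``relation`` is a binary (n_features, n_diseases) matrix; each kept
    disease's implied score is the mean of its related feature
    probabilities (the relation column normalised to sum 1). Diseases
    related to no feature are skipped with a warning.
    """
    rel = np.asarray(relation, dtype=float)
    col_sums = rel.sum(axis=0)
    kept = col_sums > 0
    if not kept.all():
        skipped = tuple(np.flatnonzero(~kept).tolist())
        if skipped not in _warned_skipped:  # warn once per relation pattern
            _warned_skipped.add(skipped)
            logger.warning("joint loss: diseases %s have no related features; skipped", list(skipped))
    norm = np.where(kept, col_sums, 1.0)
    implied = patho_probs @ (rel / norm)
    return implied, kept


def joint_loss(patho_probs: np.ndarray, disease_probs: np.ndarray, relation: np.ndarray) -> float:
    """Prediction-consistency penalty between the two heads.

    Mean squared difference between the disease probabilities and the
    pathology-implied disease scores, over samples and kept diseases.
    """
    patho_probs = np.asarray(patho_probs, dtype=float)
    disease_probs = np.asarray(disease_probs, dtype=float)
    rel = np.asarray(relation)
    if rel.shape != (patho_probs.shape[1], disease_probs.shape[1]):
        raise ValueError(
            f"relation shape {rel.shape} != (n_features={patho_probs.shape[1]}, "
            f"n_diseases={disease_probs.shape[1]})"
        )
    implied, kept = _implied_scores(patho_probs, rel)
    if not kept.any():
        return 0.0
    diff = (disease_probs - implied)[:, kept]
    return float((diff**2).mean())


def joint_grad(
    patho_probs: np.ndarray, disease_probs: np.ndarray, relation: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(dL/dpatho_probs, dL/ddisease_probs) of :func:`joint_loss`."""
    patho_probs = np.asarray(patho_probs, dtype=float)
    disease_probs = np.asarray(disease_probs, dtype=float)
    rel = np.asarray(relation, dtype=float)
    implied, kept = _implied_scores(patho_probs, rel)
    if not kept.any():
        return np.zeros_like(patho_probs), np.zeros_like(disease_probs)
    n = disease_probs.shape[0] * int(kept.sum())
    diff = np.where(kept[None, :], disease_probs - implied, 0.0)
    d_disease = 2.0 * diff / n
    norm = np.where(rel.sum(axis=0) > 0, rel.sum(axis=0), 1.0)
    d_patho = -(2.0 * diff / n) @ (rel / norm).T
    return d_patho, d_disease


def total_loss(
    patho: float, disea: float, joint: float, consis: float, weights: LossWeights
) -> LossBreakdown:
    """Weighted sum of the four terms."""
    total = (
        weights.lambda1 * patho
        + weights.lambda2 * disea
        + weights.lambda3 * joint
        + weights.lambda4 * consis
    )
    return LossBreakdown(
        patho=float(patho), disea=float(disea), joint=float(joint),
        consis=float(consis), total=float(total),
    )
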