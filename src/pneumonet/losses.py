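"""Binary classification losses: cross-entropy, focal loss, and the
class-count-normalized ("modified") focal loss.

All losses consume a :class:`PredictionBatch` of predicted class-1
(pneumonia) probabilities ``y_prime`` and binary labels ``y``. The focal
loss down-weights easy samples through the modulating factor
``(1 - p_t)**gamma`` where ``p_t`` is the probability assigned to the true
class. The modified variant additionally rescales each label branch by the
inverse square root of a class sample count:

    y = 1:  -(1/sqrt(n_a)) * alpha     * (1 - y')**gamma * log(y')
    y = 0:  -(1/sqrt(n_b)) * (1-alpha) * (y')**gamma     * log(1 - y')

With ``count_mapping="as_printed"`` the y=1 branch uses the *normal* count
and the y=0 branch the *pneumonia* count, reproducing the source formula
verbatim. Under this package's label convention (1 = pneumonia) that pairing
is inverted relative to the stated intent of up-weighting the minority
class, so ``count_mapping="per_class"`` (the training default) scales each
branch by its own class count instead. Both are exposed because the source
is internally ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPSILON",
    "LossConfig",
    "PredictionBatch",
    "class_weight",
    "cross_entropy",
    "focal_loss",
    "modified_focal_loss",
    "cross_entropy_grad",
    "focal_loss_grad",
    "modified_focal_loss_grad",
]

#: probability clamp applied before any logarithm
EPSILON = 1e-7

_REDUCTIONS = ("mean", "sum", "none")


class LossConfigError(ValueError):
    pass


@dataclass
class LossConfig:
    """Parameters of the modified focal loss.

    alpha weights the y=1 branch (1-alpha the y=0 branch); gamma is the
    focusing exponent; n_normal / n_pneumonia are the per-class sample counts
    feeding the 1/sqrt(n) factors.
    """

    alpha: float = 0.25
    gamma: float = 2.0
    n_normal: int = 1583
    n_pneumonia: int = 4273
    count_mapping: str = "per_class"
    reduction: str = "mean"
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise LossConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.gamma < 0:
            raise LossConfigError(f"gamma must be >= 0, got {self.gamma}")
        if self.n_normal < 1 or self.n_pneumonia < 1:
            raise LossConfigError(
                f"class counts must be >= 1, got normal={self.n_normal}, "
                f"pneumonia={self.n_pneumonia}")
        if self.count_mapping not in ("as_printed", "per_class"):
            raise LossConfigError(f"unknown count_mapping {self.count_mapping!r}")
        if self.reduction not in _REDUCTIONS:
            raise LossConfigError(f"unknown reduction {self.reduction!r}")

    def branch_weights(self) -> tuple[float, float]:
        """(w1, w0): the per-branch scale factors for y=1 and y=0."""
        if self.count_mapping == "as_printed":
            return (class_weight(self.n_normal) * self.alpha,
                    class_weight(self.n_pneumonia) * (1.0 - self.alpha))
        return (class_weight(self.n_pneumonia) * self.alpha,
                class_weight(self.n_normal) * (1.0 - self.alpha))


@dataclass
class PredictionBatch:
    """Predicted class-1 probabilities and binary ground-truth labels.

    Probabilities are clamped into [epsilon, 1-epsilon] on construction so
    downstream logarithms are always finite.
    """

    y_prime: np.ndarray
    y: np.ndarray
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        yp = np.atleast_1d(np.asarray(self.y_prime, dtype=float))
        y = np.atleast_1d(np.asarray(self.y))
        if yp.shape != y.shape:
            raise LossConfigError(
                f"y_prime and y have different shapes: {yp.shape} vs {y.shape}")
        if not np.isin(y, (0, 1)).all():
            raise LossConfigError("labels must be binary (0/1)")
        self.y_prime = np.clip(yp, self.epsilon, 1.0 - self.epsilon)
        self.y = y.astype(int)

    @property
    def p_t(self) -> np.ndarray:
        """Probability assigned to the true class."""
        return np.where(self.y == 1, self.y_prime, 1.0 - self.y_prime)


def _reduce(values: np.ndarray, reduction: str):
    if reduction == "mean":
        return float(values.mean())
    if reduction == "sum":
        return float(values.sum())
    if reduction == "none":
        return values
    raise LossConfigError(f"unknown reduction {reduction!r}")


def class_weight(n: int) -> float:
    """Inverse-square-root class weight 1/sqrt(n)."""
    if n < 1:
        raise LossConfigError(f"sample count must be >= 1, got {n}")
    return 1.0 / np.sqrt(n)


def cross_entropy(batch: PredictionBatch, reduction: str = "mean"):
    """Binary cross-entropy -[y ln y' + (1-y) ln(1-y')]."""
    per_sample = -np.log(batch.p_t)
    return _reduce(per_sample, reduction)


def focal_loss(batch: PredictionBatch, alpha_t: float = 0.25,
               gamma: float = 2.0, reduction: str = "mean"):
    """Focal loss -alpha_t (1-p_t)**gamma ln(p_t) per sample."""
    if gamma < 0:
        raise LossConfigError(f"gamma must be >= 0, got {gamma}")
    p = batch.p_t
    per_sample = -alpha_t * (1.0 - p) ** gamma * np.log(p)
    return _reduce(per_sample, reduction)


def modified_focal_loss(batch: PredictionBatch, config: LossConfig):
    """Class-count-normalized focal loss (see module docstring)."""
    w1, w0 = config.branch_weights()
    yp = batch.y_prime
    loss1 = -w1 * (1.0 - yp) ** config.gamma * np.log(yp)
    loss0 = -w0 * yp ** config.gamma * np.log(1.0 - yp)
    per_sample = np.where(batch.y == 1, loss1, loss0)
    return _reduce(per_sample, config.reduction)


# ---------------------------------------------------------------------------
# analytic gradients w.r.t. y_prime (per sample, no reduction)
# ---------------------------------------------------------------------------

def _focal_dp(p: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    """d/dp of -alpha (1-p)**gamma ln p."""
    if gamma == 0:
        return -alpha / p
    mod = (1.0 - p) ** gamma
    dmod = gamma * (1.0 - p) ** (gamma - 1.0)
    return alpha * (dmod * np.log(p) - mod / p)


def cross_entropy_grad(batch: PredictionBatch) -> np.ndarray:
    """d(per-sample BCE)/d y_prime."""
    yp = batch.y_prime
    return np.where(batch.y == 1, -1.0 / yp, 1.0 / (1.0 - yp))


def focal_loss_grad(batch: PredictionBatch, alpha_t: float = 0.25,
                    gamma: float = 2.0) -> np.ndarray:
    """d(per-sample focal loss)/d y_prime; chain rule through p_t = y' or 1-y'."""
    p = batch.p_t
    dp = _focal_dp(p, alpha_t, gamma)
    return np.where(batch.y == 1, dp, -dp)


def modified_focal_loss_grad(batch: PredictionBatch,
                             config: LossConfig) -> np.ndarray:
    """d(per-sample modified focal loss)/d y_prime."""
    w1, w0 = config.branch_weights()
    yp = batch.y_prime
    d1 = _focal_dp(yp, w1, config.gamma)
    d0 = -_focal_dp(1.0 - yp, w0, config.gamma)
    return np.where(batch.y == 1, d1, d0)
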