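"""Maximum-margin RBF-kernel classification under leave-one-participant-out CV.

The classifier is the standard soft-margin support vector machine with the
Gaussian kernel ``k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))``: the dual
coefficients ``a_i`` maximise ``sum_i a_i - 1/2 sum_ij y_i y_j a_i a_j
k(x_i, x_j)`` subject to ``0 <= a_i <= C`` and ``sum_i a_i y_i = 0``, and the
decision function is ``f(x) = sum_i a_i y_i k(x_i, x) - b``.  The quadratic
programme is solved by scikit-learn's SMO implementation; this module owns
the protocol around it — per-fold standardisation, the median-heuristic
kernel width, and the leave-one-participant-out fold construction in which
every window of one subject forms the test set, so no within-subject
correlation links training and test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .exceptions import ValidationError
from .features import FeatureMatrix

__all__ = [
    "KernelParams",
    "TrainedKernelClassifier",
    "FoldResult",
    "train",
    "predict",
    "lopo_cv",
]


@dataclass(frozen=True)
class KernelParams:
    """RBF width and box constraint.

    With ``sigma_policy="median_heuristic"`` the width is set to the median
    pairwise Euclidean distance between standardised training points — a
    deterministic, scale-free default; ``"fixed"`` uses ``sigma`` as given.
    """

    sigma: float | None = None
    soft_margin_C: float = 1.0
    sigma_policy: str = "median_heuristic"

    def __post_init__(self):
        if self.sigma_policy not in ("fixed", "median_heuristic"):
            raise ValidationError(
                f"sigma_policy must be 'fixed' or 'median_heuristic', "
                f"got {self.sigma_policy!r}"
            )
        if self.sigma_policy == "fixed":
            if self.sigma is None or not self.sigma > 0:
                raise ValidationError("fixed sigma_policy needs sigma > 0")
        if not self.soft_margin_C > 0:
            raise ValidationError(f"soft_margin_C must be > 0, got {self.soft_margin_C}")


@dataclass
class TrainedKernelClassifier:
    """Fitted classifier: support expansion plus training standardisation.

    ``dual_signed[i] = a_i * y_i`` for support vector i; the decision value
    is ``f(x) = sum_i dual_signed[i] k(sv_i, x) - b`` on standardised x.
    """

    support_vectors: np.ndarray = field(repr=False)
    dual_signed: np.ndarray = field(repr=False)
    bias: float = 0.0
    sigma: float = 1.0
    soft_margin_C: float = 1.0
    feature_mean: np.ndarray = field(default=None, repr=False)
    feature_sd: np.ndarray = field(default=None, repr=False)
    _svc: SVC = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def standardise(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_sd


def median_heuristic_sigma(Z: np.ndarray) -> float:
    """Median pairwise Euclidean distance; falls back to 1.0 if degenerate."""
    d = pdist(Z)
    med = float(np.median(d)) if d.size else 0.0
    return med if med > 0 else 1.0


def train(
    X: np.ndarray,
    y: np.ndarray,
    params: KernelParams = KernelParams(),
) -> TrainedKernelClassifier:
    """Fit the soft-margin RBF classifier on standardised features.

    Features are standardised with the training mean and SD (constant
    features get SD 1 so they standardise to zero and drop out of the
    kernel).  Raises on non-finite features or a single-class label vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValidationError("X must be 2-D with one label per row")
    if X.shape[0] < 2:
        raise ValidationError("need at least two training samples")
    if not np.all(np.isfinite(X)):
        raise ValidationError("training features must be finite")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValidationError("training set must contain both classes")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd

    if params.sigma_policy == "median_heuristic":
        sigma = median_heuristic_sigma(Z)
    else:
        sigma = float(params.sigma)

    gamma = 1.0 / (2.0 * sigma**2)
    svc = SVC(
        C=params.soft_margin_C,
        kernel="rbf",
        gamma=gamma,
        tol=1e-3,
        shrinking=True,
        random_state=0,
    )
    svc.fit(Z, np.where(y > 0, 1, -1))
    return TrainedKernelClassifier(
        support_vectors=svc.support_vectors_,
        dual_signed=svc.dual_coef_[0],
        bias=-float(svc.intercept_[0]),
        sigma=sigma,
        soft_margin_C=params.soft_margin_C,
        feature_mean=mean,
        feature_sd=sd,
        _svc=svc,
    )


def decision_values(model: TrainedKernelClassifier, X: np.ndarray) -> np.ndarray:
    """Decision value f(x) for each row of X (raw, unstandardised features)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    return model._svc.decision_function(model.standardise(X))


def predict(model: TrainedKernelClassifier, X: np.ndarray):
    """Predicted labels (+1 patient, -1 control) and decision values.

    A decision value of exactly zero predicts control: on the boundary the
    classifier withholds the positive (patient) call.
    """
    f = decision_values(model, X)
    labels = np.where(f > 0, 1, -1)
    return labels, f


@dataclass
class FoldResult:
    """One leave-one-participant-out fold."""

    held_out_subject: str
    true_label: int
    predicted: np.ndarray = field(repr=False)
    decision: np.ndarray = field(repr=False)
    fold_accuracy: float = 0.0

    @property
    def majority_label(self) -> int:
        """Subject-level call by majority vote over the subject's windows."""
        return 1 if (self.predicted > 0).sum() * 2 > len(self.predicted) else -1


def lopo_cv(
    features: FeatureMatrix,
    params: KernelParams = KernelParams(),
) -> list:
    """Leave-one-participant-out cross-validation.

    One fold per subject: all of that subject's windows are held out while
    the classifier is trained — including standardisation and the
    median-heuristic width — on the remaining subjects only.  Fold order
    follows sorted subject ids so results do not depend on row order.
    """
    subjects = np.asarray(features.subjects)
    unique = sorted(set(subjects.tolist()))
    label_of = {}
    for s in unique:
        mask = subjects == s
        if not mask.any():
            raise ValidationError(f"subject {s} has no windows")
        labs = set(features.y[mask].tolist())
        if len(labs) != 1:
            raise ValidationError(f"subject {s} has inconsistent group labels")
        label_of[s] = labs.pop()
    per_class = {+1: 0, -1: 0}
    for lab in label_of.values():
        per_class[lab] += 1
    if min(per_class.values()) < 2:
        raise ValidationError(
            "leave-one-participant-out needs >= 2 subjects per class "
            f"(got {per_class})"
        )

    results = []
    for s in unique:
        test = subjects == s
        model = train(features.X[~test], features.y[~test], params)
        pred, f = predict(model, features.X[test])
        truth = features.y[test]
        results.append(
            FoldResult(
                held_out_subject=s,
                true_label=label_of[s],
                predicted=pred,
                decision=f,
                fold_accuracy=float(np.mean(pred == truth)),
            )
        )
    return results
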