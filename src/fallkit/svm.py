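"""Maximum-margin detectors over the record kernel, and the uniform
anomaly-score contract shared by all four detector families.

The quadratic programs are delegated to libsvm (through scikit-learn) with
``kernel="precomputed"``: every kernel value entering the solver is
produced by this package's own record distance and RBF kernel, never by a
library's feature-space kernel.  Scores are oriented so that larger always
means more fall-like:

* NN: distance to the nearest ADL exemplar;
* LOF: the local outlier factor itself;
* one-class SVM: minus the signed decision value (inliers are positive);
* two-class SVM: the signed decision value on the FALL side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC, OneClassSVM

from .records import ADL, FALL, Record
from .novelty import (
    ExemplarSet,
    LOFConfig,
    kernel_matrix,
    lof_score,
    nn_score,
)


@dataclass
class NNModel:
    """Nearest-neighbor novelty detector; parameter-free."""

    exemplars: ExemplarSet

    def score(self, record: Record) -> float:
        return nn_score(record, self.exemplars)

    def score_many(self, records: Sequence[Record]) -> np.ndarray:
        return np.array([self.score(r) for r in records])


@dataclass
class LOFModel:
    """Local-outlier-factor novelty detector with neighbor count k."""

    exemplars: ExemplarSet
    config: LOFConfig

    def score(self, record: Record) -> float:
        return lof_score(record, self.exemplars, self.config)

    def score_many(self, records: Sequence[Record]) -> np.ndarray:
        return np.array([self.score(r) for r in records])


class SolverError(RuntimeError):
    """Raised when the underlying QP solver fails to produce a model."""


@dataclass
class OneClassSVMModel:
    """nu-one-class SVM trained on ADL only.

    nu upper-bounds the fraction of training records on the outlier side
    of the hyperplane (up to 1/N slack).
    """

    support_records: list[Record]
    dual_coef: np.ndarray  # non-negative, scaled to sum to 1
    offset: float
    gamma: float
    nu: float
    kernel_form: str

    def decision_value(self, record: Record) -> float:
        """Signed distance to the hyperplane; > 0 on the inlier side."""
        k = kernel_matrix([record], self.support_records, self.gamma,
                          self.kernel_form)[0]
        return float(k @ self.dual_coef - self.offset)

    def score(self, record: Record) -> float:
        return -self.decision_value(record)

    def score_many(self, records: Sequence[Record]) -> np.ndarray:
        k = kernel_matrix(records, self.support_records, self.gamma,
                          self.kernel_form)
        return -(k @ self.dual_coef - self.offset)


@dataclass
class SVMModel:
    """Soft-margin two-class SVM (ADL vs FALL) over the record kernel."""

    support_records: list[Record]
    dual_coef: np.ndarray  # signed alpha_i * y_i, |.| <= C
    bias: float
    gamma: float
    c_penalty: float
    kernel_form: str

    def decision_value(self, record: Record) -> float:
        """Signed decision value; > 0 on the FALL side."""
        k = kernel_matrix([record], self.support_records, self.gamma,
                          self.kernel_form)[0]
        return float(k @ self.dual_coef + self.bias)

    def score(self, record: Record) -> float:
        return self.decision_value(record)

    def score_many(self, records: Sequence[Record]) -> np.ndarray:
        k = kernel_matrix(records, self.support_records, self.gamma,
                          self.kernel_form)
        return k @ self.dual_coef + self.bias


TrainedModel = NNModel | LOFModel | OneClassSVMModel | SVMModel


def train_nn(exemplars: ExemplarSet | Sequence[Record]) -> NNModel:
    if not isinstance(exemplars, ExemplarSet):
        exemplars = ExemplarSet(list(exemplars))
    if len(exemplars) == 0:
        raise ValueError("NN needs at least one exemplar")
    return NNModel(exemplars)


def train_lof(exemplars: ExemplarSet | Sequence[Record], k: int,
              variant: str = "breunig") -> LOFModel:
    if not isinstance(exemplars, ExemplarSet):
        exemplars = ExemplarSet(list(exemplars))
    cfg = LOFConfig(k=k, variant=variant)
    if not 1 <= cfg.k < len(exemplars):
        raise ValueError(
            f"k={k} invalid for {len(exemplars)} exemplars"
        )
    return LOFModel(exemplars, cfg)


def train_oneclass(
    exemplars: ExemplarSet | Sequence[Record],
    nu: float,
    gamma: float,
    kernel_form: str = "distance",
) -> OneClassSVMModel:
    """Solve the standard nu-one-class dual over the record kernel."""
    if not isinstance(exemplars, ExemplarSet):
        exemplars = ExemplarSet(list(exemplars))
    n = len(exemplars)
    if n < 2:
        raise ValueError("one-class SVM needs at least 2 exemplars")
    if not 0.0 < nu < 1.0:
        raise ValueError("nu must be in (0, 1)")
    recs = exemplars.exemplars
    gram = kernel_matrix(recs, recs, gamma, kernel_form)
    est = OneClassSVM(kernel="precomputed", nu=nu, tol=1e-6)
    try:
        est.fit(gram)
    except Exception as exc:  # pragma: no cover - solver diagnostics
        raise SolverError(f"one-class QP failed: {exc}") from exc
    support = [recs[i] for i in est.support_]
    # libsvm alphas sum to nu*N with each <= 1; rescale to the standard
    # nu-formulation (sum 1, each <= 1/(nu*N)); the sign of the decision
    # value is unchanged
    coef = est.dual_coef_[0] / (nu * n)
    return OneClassSVMModel(
        support_records=support,
        dual_coef=coef,
        offset=float(est.offset_[0]) / (nu * n),
        gamma=gamma,
        nu=nu,
        kernel_form=kernel_form,
    )


def train_svm(
    records: Sequence[Record],
    labels: Sequence[str] | None = None,
    c_penalty: float = 1.0,
    gamma: float = 1.0,
    kernel_form: str = "distance",
) -> SVMModel:
    """Soft-margin SVM on an ADL+FALL training set over the record kernel."""
    recs = list(records)
    y_labels = [r.label for r in recs] if labels is None else list(labels)
    if set(y_labels) != {ADL, FALL}:
        raise ValueError(
            f"SVM training needs both labels {ADL} and {FALL}; "
            f"got {sorted(set(y_labels))}"
        )
    y = np.array([1 if lab == FALL else -1 for lab in y_labels])
    gram = kernel_matrix(recs, recs, gamma, kernel_form)
    est = SVC(kernel="precomputed", C=c_penalty, tol=1e-6)
    try:
        est.fit(gram, y)
    except Exception as exc:  # pragma: no cover - solver diagnostics
        raise SolverError(f"SVM QP failed: {exc}") from exc
    support = [recs[i] for i in est.support_]
    return SVMModel(
        support_records=support,
        dual_coef=est.dual_coef_[0].copy(),
        bias=float(est.intercept_[0]),
        gamma=gamma,
        c_penalty=c_penalty,
        kernel_form=kernel_form,
    )


def training_outlier_fraction(
    model: OneClassSVMModel, records: Sequence[Record], tol: float = 1e-6
) -> float:
    """Fraction of records strictly on the outlier side of the hyperplane.

    Margin support vectors sit at decision value 0 up to the solver
    tolerance; only decisions below -tol count as outliers, matching the
    nu-property bound (fraction <= nu + 1/N).
    """
    dec = -model.score_many(records)
    return float((dec < -tol).mean())


def anomaly_score(model: TrainedModel, record: Record) -> float:
    """Uniform anomaly score: larger = more fall-like, for any detector."""
    return model.score(record)


def anomaly_scores(model: TrainedModel, records: Sequence[Record]) -> np.ndarray:
    return model.score_many(records)
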