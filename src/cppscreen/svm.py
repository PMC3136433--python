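"""PUK-kernel support vector classifier (Model / Results pair).

The classifier is a soft-margin binary SVM whose kernel is the Pearson VII
universal function (PUK)

    K(x, y) = 1 / [1 + (2 * ||x - y|| * sqrt(2**(1/omega) - 1) / sigma)**2]**omega

with ``omega`` controlling the tail shape (Lorentzian at omega=1, Gaussian
as omega grows) and ``sigma`` the half-width. The dual quadratic program is
solved by sequential minimal optimization (delegated to libsvm via
scikit-learn over a precomputed PUK Gram matrix); the fitted solution —
support rows, dual coefficients, bias — is carried by
:class:`PukSvmResults`, which predicts, serializes and summarizes without
any further dependence on the solver.

Usage follows the model/results convention::

    model = PukSvm(X, y, feature_names=names)
    res = model.fit()
    labels, scores = res.predict(X_new)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .descriptors import (FEATURE_NAMES, NormalizationParams, apply_normalizer,
                          compute_feature_vector, fit_normalizer)
from .errors import DegenerateLabels, DimensionError, EmptySubset
from .peptides import Label, Peptide

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class KernelParams:
    """Pearson VII kernel shape: tailing exponent omega, half-width sigma."""

    omega: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.omega > 0 and np.isfinite(self.omega)):
            raise ValueError("omega must be positive and finite")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError("sigma must be positive and finite")


@dataclass(frozen=True)
class SVMConfig:
    """Soft-margin penalty and solver tolerances."""

    C: float = 1.0
    kkt_tolerance: float = 1e-3
    epsilon: float = 1e-12
    max_iter: int = 1_000_000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kkt_tolerance <= 0:
            raise ValueError("tolerance must be positive")


def puk_kernel(x: np.ndarray, y: np.ndarray, params: KernelParams) -> float:
    """PUK similarity of two vectors; 1 at zero distance, symmetric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError(f"shape mismatch {x.shape} vs {y.shape}")
    d = np.linalg.norm(x - y)
    root = np.sqrt(2.0 ** (1.0 / params.omega) - 1.0)
    return float(1.0 / (1.0 + (2.0 * d * root / params.sigma) ** 2) ** params.omega)


def puk_gram(X: np.ndarray, Y: np.ndarray, params: KernelParams) -> np.ndarray:
    """PUK Gram matrix between the rows of X and the rows of Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise DimensionError(f"column mismatch {X.shape[1]} vs {Y.shape[1]}")
    # squared distances via the expansion ||x-y||^2 = x.x + y.y - 2 x.y
    sq = (np.sum(X * X, axis=1)[:, None] + np.sum(Y * Y, axis=1)[None, :]
          - 2.0 * X @ Y.T)
    np.maximum(sq, 0.0, out=sq)
    root2 = 2.0 ** (1.0 / params.omega) - 1.0
    return 1.0 / (1.0 + 4.0 * sq * root2 / params.sigma ** 2) ** params.omega


class PukSvm:
    """PUK-kernel SVM model specification bound to training data.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
        Raw (unnormalized) feature rows. Min-max normalization to [0, 1]
        is fit on these rows during :meth:`fit` and stored with the
        results.
    y : array-like of {+1, -1}
        +1 marks the cell-penetrating class.
    feature_names : sequence of str, optional
        Names for the columns; inferred from a DataFrame.
    kernel, config
        :class:`KernelParams` and :class:`SVMConfig`; defaults omega=1,
        sigma=1, C=1.
    """

    def __init__(self, X, y, feature_names: Sequence[str] | None = None,
                 kernel: KernelParams = KernelParams(),
                 config: SVMConfig = SVMConfig(),
                 normalize: bool = True):
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = list(X.columns)
            X = X.to_numpy()
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise DimensionError("X must be 2-D with one row per label")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be coded +1/-1")
        if len(set(self.y)) < 2:
            raise DegenerateLabels("training data contains a single class")
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        if len(feature_names) != self.X.shape[1]:
            raise DimensionError("feature_names length != number of columns")
        self.feature_names = list(feature_names)
        self.kernel = kernel
        self.config = config
        self.normalize = normalize

    @classmethod
    def from_dataset(cls, dataset, subset: Sequence[str] | None = None,
                     kernel: KernelParams = KernelParams(),
                     config: SVMConfig = SVMConfig()) -> "PukSvm":
        """Build from a :class:`~cppscreen.datasets.LabeledDataset`,
        optionally restricted to a named feature subset."""
        X = dataset.X
        if subset is not None:
            subset = list(subset)
            if not subset:
                raise EmptySubset("feature subset is empty")
            unknown = [s for s in subset if s not in X.columns]
            if unknown:
                raise EmptySubset(f"unknown feature names {unknown}")
            X = X[subset]
        return cls(X, dataset.y, kernel=kernel, config=config)

    def fit(self) -> "PukSvmResults":
        """Solve the dual QP by SMO and return the fitted results."""
        if self.normalize:
            norm = fit_normalizer(self.X)
            Z = apply_normalizer(norm, self.X)
        else:
            p = self.X.shape[1]
            norm = NormalizationParams(np.zeros(p), np.ones(p))
            Z = self.X
        gram = puk_gram(Z, Z, self.kernel)
        solver = SVC(C=self.config.C, kernel="precomputed",
                     tol=self.config.kkt_tolerance * 1e-2,
                     max_iter=self.config.max_iter, shrinking=True)
        solver.fit(gram, self.y)
        support = solver.support_
        return PukSvmResults(
            model=self,
            support_vectors=Z[support].copy(),
            support_labels=self.y[support].copy(),
            dual_coef=solver.dual_coef_.ravel().copy(),
            intercept=float(solver.intercept_[0]),
            kernel=self.kernel,
            config=self.config,
            normalization=norm,
            feature_names=list(self.feature_names),
            nobs=len(self.y),
        )


@dataclass
class PukSvmResults:
    """Fitted PUK-SVM: everything needed to predict and audit the solution.

    ``dual_coef`` holds alpha_i * y_i for the support rows; the decision
    function is ``f(x) = sum_i dual_coef_i K(x, s_i) + intercept`` on
    normalized inputs, and a row is classified CPP iff ``f(x) > 0``.
    """

    support_vectors: np.ndarray
    support_labels: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    kernel: KernelParams
    config: SVMConfig
    normalization: NormalizationParams
    feature_names: list[str]
    nobs: int
    model: "PukSvm | None" = field(default=None, repr=False)

    # -- prediction --------------------------------------------------------

    def _normalize(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise DimensionError(f"missing features {missing}")
            X = X[self.feature_names].to_numpy()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise DimensionError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        return apply_normalizer(self.normalization, X)

    def decision_function(self, X) -> np.ndarray:
        """Signed distance-like score; positive means CPP."""
        Z = self._normalize(X)
        K = puk_gram(Z, self.support_vectors, self.kernel)
        return K @ self.dual_coef + self.intercept

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(labels in {+1, -1}, decision values); ties score as -1."""
        f = self.decision_function(X)
        return np.where(f > 0, 1, -1), f

    def predict_peptides(self, peptides: Sequence[Peptide]
                         ) -> tuple[list[Label], np.ndarray]:
        """Featurize, normalize, restrict and classify peptides."""
        full = pd.DataFrame(
            np.vstack([compute_feature_vector(p) for p in peptides]),
            columns=list(FEATURE_NAMES))
        labels, f = self.predict(full)
        return [Label.CPP if l == 1 else Label.NON_CPP for l in labels], f

    # -- diagnostics -------------------------------------------------------

    @property
    def alphas(self) -> np.ndarray:
        """Dual variables alpha_i (non-negative) of the support rows."""
        return np.abs(self.dual_coef)

    def dual_objective(self) -> float:
        """Value of the dual objective sum(a) - 0.5 aᵀ diag(y) K diag(y) a."""
        K = puk_gram(self.support_vectors, self.support_vectors, self.kernel)
        return float(self.alphas.sum()
                     - 0.5 * self.dual_coef @ K @ self.dual_coef)

    def kkt_violation(self) -> float:
        """Largest violation of the KKT conditions on the training rows.

        Requires the originating model (not available after deserialization).
        """
        if self.model is None:
            raise ValueError("training data unavailable on a loaded model")
        _, f = self.predict(self.model.X)
        yf = self.model.y * f
        alpha = np.zeros(len(self.model.y))
        # map support rows back to training indices by matching scores
        Z = self._normalize(self.model.X)
        sup_idx = []
        used = set()
        for s in self.support_vectors:
            d = np.linalg.norm(Z - s, axis=1)
            for j in np.argsort(d):
                if j not in used:
                    used.add(int(j))
                    sup_idx.append(int(j))
                    break
        alpha[sup_idx] = self.alphas
        C = self.config.C
        viol = np.zeros_like(yf)
        free = (alpha > 1e-8) & (alpha < C - 1e-8)
        viol[alpha <= 1e-8] = np.maximum(0.0, 1.0 - yf[alpha <= 1e-8])
        viol[free] = np.abs(yf[free] - 1.0)
        viol[alpha >= C - 1e-8] = np.maximum(0.0, yf[alpha >= C - 1e-8] - 1.0)
        return float(viol.max())

    def summary(self) -> str:
        """Plain-text summary table in the model/results style."""
        lines = [
            "PUK-SVM classification results",
            "=" * 46,
            f"{'No. observations:':<28}{self.nobs}",
            f"{'No. features:':<28}{len(self.feature_names)}",
            f"{'No. support vectors:':<28}{len(self.dual_coef)}",
            f"{'Kernel omega:':<28}{self.kernel.omega:g}",
            f"{'Kernel sigma:':<28}{self.kernel.sigma:g}",
            f"{'Soft-margin C:':<28}{self.config.C:g}",
            f"{'Bias (intercept):':<28}{self.intercept: .6f}",
            f"{'Dual objective:':<28}{self.dual_objective(): .6f}",
            f"{'sum(alpha_i y_i):':<28}{self.dual_coef.sum(): .2e}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "version": SERIALIZATION_VERSION,
            "feature_names": self.feature_names,
            "kernel": {"omega": self.kernel.omega, "sigma": self.kernel.sigma},
            "config": {"C": self.config.C,
                       "kkt_tolerance": self.config.kkt_tolerance},
            "normalization": {"min": self.normalization.minimum.tolist(),
                              "max": self.normalization.maximum.tolist()},
            "support_vectors": self.support_vectors.tolist(),
            "support_labels": self.support_labels.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "nobs": self.nobs,
        }
        return json.dumps(payload, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "PukSvmResults":
        d = json.loads(text)
        if d.get("version") != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported model version {d.get('version')}")
        return cls(
            support_vectors=np.array(d["support_vectors"], dtype=float),
            support_labels=np.array(d["support_labels"], dtype=int),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            kernel=KernelParams(**d["kernel"]),
            config=SVMConfig(**d["config"]),
            normalization=NormalizationParams(
                np.array(d["normalization"]["min"], dtype=float),
                np.array(d["normalization"]["max"], dtype=float)),
            feature_names=list(d["feature_names"]),
            nobs=int(d["nobs"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PukSvmResults":
        return cls.from_json(Path(path).read_text())


def train_svm(dataset, subset: Sequence[str] | None = None,
              config: SVMConfig = SVMConfig(),
              kernel: KernelParams = KernelParams()) -> PukSvmResults:
    """Convenience wrapper: fit a PUK-SVM on a labeled dataset."""
    return PukSvm.from_dataset(dataset, subset=subset, kernel=kernel,
                               config=config).fit()
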