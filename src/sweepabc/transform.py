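"""Linearization and compression of the summary statistics.

Raw statistics are imputed (NaN -> per-statistic reference minimum minus one
reference SD), shifted to positivity and Box-Cox transformed (lambda by
profile-likelihood grid search), standardized, and compressed to five PLS-DA
components — the directions maximizing covariance between the statistics and
the model labels.  The whole pipeline is fit once on the pooled reference
tables of all candidate models, then frozen and applied identically to
simulated and observed data; it serializes to a JSON sidecar so a reference
table can be reused bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import boxcox_llf
from sklearn.cross_decomposition import PLSRegression

__all__ = ["BoxCoxParams", "PLSDAModel", "TransformPipeline",
           "boxcox_fit", "boxcox_apply", "plsda_fit", "plsda_project"]

_LAMBDA_GRID = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.01), 10)


@dataclass
class BoxCoxParams:
    """Per-statistic positivity shift and Box-Cox exponent."""

    shifts: np.ndarray
    lambdas: np.ndarray
    identity: np.ndarray  # constant columns pass through untouched

    def to_dict(self) -> dict:
        return {
            "shifts": self.shifts.tolist(),
            "lambdas": self.lambdas.tolist(),
            "identity": self.identity.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoxCoxParams":
        return cls(
            shifts=np.asarray(d["shifts"], dtype=float),
            lambdas=np.asarray(d["lambdas"], dtype=float),
            identity=np.asarray(d["identity"], dtype=bool),
        )


def boxcox_fit(table: np.ndarray) -> BoxCoxParams:
    """Fit shift and lambda per column by profile-likelihood grid search
    (lambda in [-5, 5], step 0.01)."""
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D table")
    if np.isnan(X).any():
        raise ValueError("impute NaNs before Box-Cox fitting")
    if X.shape[0] < 100:
        raise ValueError("need >= 100 rows to fit the transform")
    ncol = X.shape[1]
    shifts = np.zeros(ncol)
    lambdas = np.ones(ncol)
    identity = np.zeros(ncol, dtype=bool)
    for j in range(ncol):
        col = X[:, j]
        if np.ptp(col) == 0:
            identity[j] = True
            warnings.warn(f"column {j} is constant; using identity transform")
            continue
        mn = col.min()
        shift = 1.0 - mn if mn <= 0 else 0.0
        shifted = col + shift
        lls = np.array([boxcox_llf(lam, shifted) for lam in _LAMBDA_GRID])
        lambdas[j] = float(_LAMBDA_GRID[int(np.argmax(lls))])
        shifts[j] = shift
    return BoxCoxParams(shifts=shifts, lambdas=lambdas, identity=identity)


def boxcox_apply(params: BoxCoxParams, X: np.ndarray) -> np.ndarray:
    """Apply a fitted Box-Cox transform to rows (1-D or 2-D)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        if params.identity[j]:
            out[:, j] = X[:, j]
            continue
        shifted = X[:, j] + params.shifts[j]
        # observed data may fall below the fitted support; clamp to a tiny
        # positive value so the transform stays defined
        shifted = np.maximum(shifted, 1e-12)
        lam = params.lambdas[j]
        if abs(lam) < 1e-12:
            out[:, j] = np.log(shifted)
        else:
            out[:, j] = (shifted**lam - 1.0) / lam
    return out


@dataclass
class PLSDAModel:
    """Frozen PLS-DA projection: centering/scaling of the (transformed)
    statistics, X-weights (rotations) for k components, and the per-component
    standardization used to make Euclidean distances scale-free."""

    x_mean: np.ndarray
    x_std: np.ndarray
    rotations: np.ndarray        # (n_stats x k)
    weights: np.ndarray          # unit-norm X weights (n_stats x k)
    comp_scale: np.ndarray       # pooled training SD of each score
    classes: tuple[str, ...]
    class_coding: np.ndarray     # dummy-coded class matrix used in fitting

    @property
    def k(self) -> int:
        return self.rotations.shape[1]

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "rotations": self.rotations.tolist(),
            "weights": self.weights.tolist(),
            "comp_scale": self.comp_scale.tolist(),
            "classes": list(self.classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDAModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], float),
            x_std=np.asarray(d["x_std"], float),
            rotations=np.asarray(d["rotations"], float),
            weights=np.asarray(d["weights"], float),
            comp_scale=np.asarray(d["comp_scale"], float),
            classes=tuple(d["classes"]),
            class_coding=np.empty((0, 0)),
        )


def plsda_fit(X: np.ndarray, labels: Sequence[str], k: int = 5) -> PLSDAModel:
    """Fit a k-component PLS-DA (PLS2 on a dummy-coded class matrix)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least two distinct labels")
    Y = np.zeros((len(labels), len(classes)))
    for ci, c in enumerate(classes):
        Y[labels == c, ci] = 1.0
    rank = min(X.shape[1], np.linalg.matrix_rank(X - X.mean(0)))
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; reducing")
        k = rank
    pls = PLSRegression(n_components=k, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, Y)
    scores = pls.x_scores_
    comp_scale = scores.std(axis=0, ddof=1)
    comp_scale[comp_scale == 0] = 1.0
    return PLSDAModel(
        x_mean=pls._x_mean,
        x_std=pls._x_std,
        rotations=pls.x_rotations_,
        weights=pls.x_weights_,
        comp_scale=comp_scale,
        classes=classes,
        class_coding=Y,
    )


def plsda_project(model: PLSDAModel, X: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Project rows onto the PLS-DA components (optionally standardized by the
    pooled training SD of each score)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = (X - model.x_mean) / model.x_std
    scores = Z @ model.rotations
    if standardize:
        scores = scores / model.comp_scale
    return scores


@dataclass
class TransformPipeline:
    """Impute -> Box-Cox -> PLS-DA -> per-component standardization."""

    fill_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    boxcox: BoxCoxParams = None  # type: ignore[assignment]
    plsda: PLSDAModel = None  # type: ignore[assignment]
    n_imputed: int = 0

    def fit(self, table: np.ndarray, labels: Sequence[str], k: int = 5) -> "TransformPipeline":
        X = np.asarray(table, dtype=float).copy()
        # undefined statistics: region-specific finite minimum minus one SD
        fills = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            col = X[:, j]
            finite = col[np.isfinite(col)]
            if len(finite) == 0:
                fills[j] = 0.0
            elif np.ptp(finite) == 0:
                fills[j] = finite[0]
            else:
                fills[j] = finite.min() - finite.std(ddof=1)
        self.fill_values = fills
        X, n_imp = self._impute(X)
        self.n_imputed = n_imp
        self.boxcox = boxcox_fit(X)
        B = boxcox_apply(self.boxcox, X)
        self.plsda = plsda_fit(B, labels, k=k)
        return self

    def _impute(self, X: np.ndarray) -> tuple[np.ndarray, int]:
        X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
        bad = ~np.isfinite(X)
        n = int(bad.sum())
        if n:
            X[bad] = np.broadcast_to(self.fill_values, X.shape)[bad]
        return X, n

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Rows of raw statistics -> standardized PLS-DA components."""
        if self.plsda is None:
            raise RuntimeError("pipeline not fitted")
        X, _ = self._impute(X)
        B = boxcox_apply(self.boxcox, X)
        return plsda_project(self.plsda, B)

    # -- JSON sidecar ------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        d = {
            "format_version": self.FORMAT_VERSION,
            "fill_values": self.fill_values.tolist(),
            "boxcox": self.boxcox.to_dict(),
            "plsda": self.plsda.to_dict(),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TransformPipeline":
        d = json.loads(Path(path).read_text())
        if d.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError("unsupported transform sidecar version")
        obj = cls()
        obj.fill_values = np.asarray(d["fill_values"], float)
        obj.boxcox = BoxCoxParams.from_dict(d["boxcox"])
        obj.plsda = PLSDAModel.from_dict(d["plsda"])
        return obj
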