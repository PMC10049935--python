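"""Affine calibration-transfer models between two biometers' power vectors.

A conversion maps a 3-component power vector measured on one device to
the expected vector on the other:  y = b + A.x  with intercept b (dpt)
and a 3x3 matrix A.  The full model is fitted by ordinary least squares
per target component (identical point estimates to multivariate
Gaussian maximum likelihood with unrestricted residual covariance); the
simplified "diagonal" variant suppresses cross-talk between components
by fitting three independent simple regressions.

``PUBLISHED_MODELS`` ships the six fitted conversions reported for the
IOLMaster700 (Z) / Anterion (H) pair — front surface, back surface and
Gullstrand total power, in both directions — and
``PUBLISHED_DIAGONAL_MODELS`` the simplified Z->H variants, usable
without any patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .optics import PowerVector
from .stats import DescriptiveSummary, descriptive_summary

__all__ = [
    "ConversionModel",
    "CrossValReport",
    "PUBLISHED_MODELS",
    "PUBLISHED_DIAGONAL_MODELS",
    "fit_affine_conversion",
    "fit_diagonal_conversion",
    "apply_conversion",
    "invert_conversion",
    "cross_validate",
    "model_loglikelihood",
]

_COMPONENTS = ("veq", "v0", "v45")


def _as_matrix(pvs) -> np.ndarray:
    """Coerce a PowerVector-of-arrays, list of PowerVectors or (n,3)
    array to an (n, 3) float array."""
    if isinstance(pvs, PowerVector):
        return np.atleast_2d(pvs.as_array().astype(float))
    if isinstance(pvs, (list, tuple)) and pvs and isinstance(pvs[0], PowerVector):
        return np.array([[p.veq, p.v0, p.v45] for p in pvs], dtype=float)
    arr = np.asarray(pvs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of power-vector components")
    return arr


@dataclass(frozen=True)
class ConversionModel:
    """Affine power-vector conversion y = intercept + matrix @ x."""

    intercept: np.ndarray  # (3,) dpt
    matrix: np.ndarray  # (3, 3)
    surface: str = ""  # "front" | "back" | "total" | ""
    direction: str = ""  # "z_to_h" | "h_to_z" | ""
    residual_sd: np.ndarray | None = None  # (3,) dpt
    loglik: float | None = None
    n_fit: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intercept", np.asarray(self.intercept, dtype=float).reshape(3))
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float).reshape(3, 3))
        if not np.isfinite(np.linalg.cond(self.matrix)):
            raise ValueError("conversion matrix must be invertible")

    @classmethod
    def identity(cls) -> "ConversionModel":
        return cls(intercept=np.zeros(3), matrix=np.eye(3))

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialise intercept, matrix and metadata to a JSON document."""
        doc = {
            "intercept": self.intercept.tolist(),
            "matrix": self.matrix.tolist(),
            "surface": self.surface,
            "direction": self.direction,
            "residual_sd": None if self.residual_sd is None else list(map(float, self.residual_sd)),
            "loglik": self.loglik,
            "n_fit": self.n_fit,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ConversionModel":
        p = Path(source)
        doc = json.loads(p.read_text() if p.is_file() else str(source))
        return cls(
            intercept=np.array(doc["intercept"]),
            matrix=np.array(doc["matrix"]),
            surface=doc.get("surface", ""),
            direction=doc.get("direction", ""),
            residual_sd=None if doc.get("residual_sd") is None else np.array(doc["residual_sd"]),
            loglik=doc.get("loglik"),
            n_fit=doc.get("n_fit"),
        )


@dataclass(frozen=True)
class CrossValReport:
    """Hold-out performance of an affine conversion.

    Euclidean-norm prediction errors (dpt) summarised separately on the
    training and test split, plus per-component RMS errors on the test
    split."""

    train_fraction: float
    seed: int
    n_train: int
    n_test: int
    train_norm: DescriptiveSummary
    test_norm: DescriptiveSummary
    test_rmse_by_component: dict[str, float]
    model: ConversionModel


def fit_affine_conversion(x, y, surface: str = "", direction: str = "") -> ConversionModel:
    """Least-squares fit of the full affine conversion y = b + A.x.

    Each target component is regressed on all three source components
    (plus intercept) by OLS; requires n >= 4 and a full-rank design.
    """
    X = _as_matrix(x)
    Y = _as_matrix(y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("x and y must hold the same number of vectors")
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 paired vectors to fit an affine conversion")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("rank-deficient design; source vectors are degenerate")
    intercept = np.empty(3)
    matrix = np.empty((3, 3))
    resid = np.empty_like(Y)
    for j in range(3):
        res = sm.OLS(Y[:, j], design).fit()
        intercept[j] = res.params[0]
        matrix[j] = res.params[1:]
        resid[:, j] = res.resid
    ddof = min(4, n - 1)
    residual_sd = resid.std(axis=0, ddof=ddof) if n > ddof else np.full(3, np.nan)
    model = ConversionModel(
        intercept=intercept,
        matrix=matrix,
        surface=surface,
        direction=direction,
        residual_sd=residual_sd,
        n_fit=n,
    )
    ll = _gaussian_loglik(resid)
    return replace(model, loglik=ll)


def fit_diagonal_conversion(x, y, surface: str = "", direction: str = "") -> ConversionModel:
    """Simplified conversion without cross-talk: three independent
    simple regressions, one per component; off-diagonal entries are 0."""
    X = _as_matrix(x)
    Y = _as_matrix(y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("x and y must hold the same number of vectors")
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 paired vectors")
    intercept = np.empty(3)
    matrix = np.zeros((3, 3))
    resid = np.empty_like(Y)
    for j in range(3):
        design = sm.add_constant(X[:, j], has_constant="add")
        if np.linalg.matrix_rank(design) < 2:
            raise ValueError(f"component {_COMPONENTS[j]} has zero variance")
        res = sm.OLS(Y[:, j], design).fit()
        intercept[j] = res.params[0]
        matrix[j, j] = res.params[1]
        resid[:, j] = res.resid
    residual_sd = resid.std(axis=0, ddof=min(2, n - 1))
    return ConversionModel(
        intercept=intercept,
        matrix=matrix,
        surface=surface,
        direction=direction,
        residual_sd=residual_sd,
        loglik=_gaussian_loglik(resid),
        n_fit=n,
    )


def apply_conversion(m: ConversionModel, pv) -> PowerVector:
    """Map power vectors through the conversion (broadcasts over rows)."""
    if isinstance(pv, PowerVector):
        arr = pv.as_array().astype(float)
        scalar = arr.ndim == 1
        out = m.intercept + np.atleast_2d(arr) @ m.matrix.T
        if scalar:
            out = out[0]
        return PowerVector(veq=out[..., 0], v0=out[..., 1], v45=out[..., 2])
    arr = _as_matrix(pv)
    out = m.intercept + arr @ m.matrix.T
    return PowerVector(veq=out[:, 0], v0=out[:, 1], v45=out[:, 2])


def invert_conversion(m: ConversionModel) -> ConversionModel:
    """Exact algebraic inverse: x = A^-1.(y - b)."""
    try:
        inv = np.linalg.inv(m.matrix)
    except np.linalg.LinAlgError as exc:
        raise ValueError("conversion matrix is singular") from exc
    direction = {"z_to_h": "h_to_z", "h_to_z": "z_to_h"}.get(m.direction, "")
    return ConversionModel(
        intercept=-inv @ m.intercept,
        matrix=inv,
        surface=m.surface,
        direction=direction,
    )


def _gaussian_loglik(resid: np.ndarray, cov: np.ndarray | None = None) -> float:
    """Multivariate Gaussian log-likelihood of residual rows.

    With ``cov`` omitted the maximum-likelihood residual covariance
    (denominator n) is used, in which case the quadratic form collapses
    to n*k/2.  All constants (2*pi terms) are included.
    """
    n, k = resid.shape
    if cov is None:
        cov = resid.T @ resid / n
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("residual covariance is singular; supply a covariance floor")
    quad = 0.5 * float(np.einsum("ij,jk,ik->", resid, np.linalg.inv(cov), resid))
    return float(-0.5 * n * (k * np.log(2.0 * np.pi) + logdet) - quad)


def model_loglikelihood(m: ConversionModel, x, y, residual_cov: np.ndarray | None = None) -> float:
    """Gaussian log-likelihood of ``y`` given ``x`` under the model.

    By default the residual covariance is the full 3x3 ML estimate from
    the residuals themselves; pass ``residual_cov`` to evaluate under a
    fixed covariance (e.g. the identity)."""
    X = _as_matrix(x)
    Y = _as_matrix(y)
    resid = Y - (m.intercept + X @ m.matrix.T)
    return _gaussian_loglik(resid, residual_cov)


def cross_validate(
    x, y, train_fraction: float = 0.7, seed: int = 0, surface: str = "", direction: str = ""
) -> CrossValReport:
    """Seeded random train/test split, full-model fit on the training
    part, Euclidean-norm prediction errors on both parts."""
    X = _as_matrix(x)
    Y = _as_matrix(y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("x and y must hold the same number of vectors")
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 pairs for cross-validation")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train < 4 or n - n_train < 2:
        raise ValueError("degenerate split sizes for this n and train_fraction")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    model = fit_affine_conversion(X[tr], Y[tr], surface=surface, direction=direction)
    pred = model.intercept + X @ model.matrix.T
    err = Y - pred
    norms = np.linalg.norm(err, axis=1)
    rmse = {
        _COMPONENTS[j]: float(np.sqrt(np.mean(err[te, j] ** 2))) for j in range(3)
    }
    return CrossValReport(
        train_fraction=train_fraction,
        seed=seed,
        n_train=int(n_train),
        n_test=int(n - n_train),
        train_norm=descriptive_summary(norms[tr]),
        test_norm=descriptive_summary(norms[te]),
        test_rmse_by_component=rmse,
        model=model,
    )


def _model(surface, direction, intercept, matrix) -> ConversionModel:
    return ConversionModel(
        intercept=np.array(intercept),
        matrix=np.array(matrix),
        surface=surface,
        direction=direction,
        n_fit=854,
    )


#: Published full affine conversions between the IOLMaster700 (Z) and the
#: Anterion (H) for the corneal front surface, back surface and the
#: Gullstrand total power, fitted on 854 eyes.  Note: the published
#: reverse ("h_to_z") intercepts are the negated forward intercepts, so a
#: published forward/reverse pair composes to the identity only to within
#: the accuracy of that approximation (a few hundredths of a dioptre over
#: the physiologic range); use :func:`invert_conversion` for an exact
#: algebraic inverse.
PUBLISHED_MODELS: dict[tuple[str, str], ConversionModel] = {
    ("front", "z_to_h"): _model(
        "front",
        "z_to_h",
        [1.2298, 0.6591, 0.3079],
        [[0.9748, -0.0060, 0.0075], [-0.0111, 0.9107, 0.0075], [-0.0054, 0.0053, 0.8745]],
    ),
    ("front", "h_to_z"): _model(
        "front",
        "h_to_z",
        [-1.2298, -0.6591, -0.3079],
        [[1.0259, 0.0068, -0.0089], [0.0125, 1.0982, -0.0095], [0.0063, -0.0066, 1.1435]],
    ),
    ("back", "z_to_h"): _model(
        "back",
        "z_to_h",
        [-0.3482, -0.0496, 0.1572],
        [[1.0000, 0.0078, 0.0562], [-0.0010, 0.8805, 0.0573], [0.0223, 0.0038, 0.6958]],
    ),
    ("back", "h_to_z"): _model(
        "back",
        "h_to_z",
        [0.3482, 0.0496, -0.1572],
        [[1.0018, -0.0086, -0.0802], [0.0032, 1.1362, -0.0938], [-0.0321, -0.0059, 1.4403]],
    ),
    ("total", "z_to_h"): _model(
        "total",
        "z_to_h",
        [0.8804, 0.5128, 0.4241],
        [[0.9715, -0.0032, 0.0058], [-0.0100, 0.9114, 0.0154], [-0.0080, 0.0051, 0.8570]],
    ),
    ("total", "h_to_z"): _model(
        "total",
        "h_to_z",
        [-0.8804, -0.5128, -0.4241],
        [[1.0293, 0.0037, -0.0070], [0.0112, 1.0974, -0.0198], [0.0096, -0.0064, 1.1669]],
    ),
}

#: Published simplified (no cross-talk) Z->H conversions.
PUBLISHED_DIAGONAL_MODELS: dict[str, ConversionModel] = {
    "front": _model(
        "front", "z_to_h", [1.2398, 0.1176, 0.0459], np.diag([0.9745, 0.9096, 0.8744])
    ),
    "back": _model(
        "back", "z_to_h", [-0.3484, -0.0459, 0.0271], np.diag([1.0007, 0.8920, 0.6957])
    ),
    "total": _model(
        "total", "z_to_h", [0.8844, 0.0797, 0.0790], np.diag([0.9714, 0.9106, 0.8565])
    ),
}
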