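"""Calibration curves linking Multiplex indices to wet chemistry.

Three model families cover the published index↔chemistry relationships:

* **linear** — ``y = m·x + q`` (e.g. SFR_R vs TSS above the 10 °Brix
  threshold; ANTH_RG vs anthocyanins in low-pigment cultivars; the
  cluster-side concordance regressions),
* **polynomial** — least-squares polynomial of caller-chosen degree
  (quadratic for FLAV_UV vs flavonols, quartic for the bi-phasic ANTH_RG vs
  anthocyanin curves of strong color accumulators),
* **sigmoid** — ``y = a / (1 + exp(b − c·x))``, the saturating FERARI vs
  anthocyanin curve whose upper asymptote ``a`` is the pigment plateau.

Each family is exposed as a scikit-learn style estimator
(:class:`LinearCalibration`, :class:`PolynomialCalibration`,
:class:`SigmoidCalibration`) whose fitted state is summarized in a
:class:`CalibrationModel` record; module-level ``fit_*`` functions are thin
wrappers over the estimators. Linear and sigmoid models are monotone and
support exact inversion (index → chemistry or back), which the synthetic
generator relies on.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateFitError,
    FitFailureError,
    InvalidRatioError,
    OutOfRangeError,
    PairingError,
    SelectionFailureError,
    UnsupportedFamilyError,
)
from .records import RipeningSample

FAMILIES = ("linear", "polynomial", "sigmoid")

#: Default lower TSS bound (°Brix) below which SFR_R is not a sugar proxy.
TSS_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# fitted-model record


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted (or published) index↔chemistry relationship.

    ``coefficients`` are ordered: ``(slope, intercept)`` for linear,
    descending powers for polynomial, ``(a, b, c)`` for the sigmoid
    ``a / (1 + exp(b - c·x))``. ``domain`` optionally records inclusive
    bounds on the predictor (or an auxiliary variable such as TSS) within
    which the model is meant to apply.
    """

    family: str
    coefficients: tuple[float, ...]
    x_name: str = "x"
    y_name: str = "y"
    degree: int | None = None
    domain: tuple[float | None, float | None] | None = None
    r2: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise UnsupportedFamilyError(f"unknown family {self.family!r}")
        if self.family == "sigmoid":
            a = self.coefficients[0]
            if not a > 0:
                raise ValueError(f"sigmoid asymptote must be positive, got {a!r}")

    # -- evaluation ---------------------------------------------------------

    def predict(self, x):
        """Evaluate the model at ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        if self.family == "linear":
            m, q = self.coefficients
            out = m * x + q
        elif self.family == "polynomial":
            out = np.polyval(self.coefficients, x)
        else:
            a, b, c = self.coefficients
            out = a / (1.0 + np.exp(b - c * x))
        return out.item() if out.ndim == 0 else out

    def invert(self, y):
        """Unique ``x`` with ``predict(x) == y``; monotone families only."""
        if self.family == "polynomial":
            raise UnsupportedFamilyError("polynomial models are not invertible")
        y = np.asarray(y, dtype=float)
        if self.family == "linear":
            m, q = self.coefficients
            if m == 0:
                raise DegenerateFitError("cannot invert a zero-slope linear model")
            out = (y - q) / m
        else:
            a, b, c = self.coefficients
            if np.any(y <= 0) or np.any(y >= a):
                raise OutOfRangeError(
                    f"sigmoid inverse requires 0 < y < a={a}, got {y!r}"
                )
            if c == 0:
                raise DegenerateFitError("cannot invert a flat sigmoid (c = 0)")
            out = (b - np.log(a / y - 1.0)) / c
        return out.item() if out.ndim == 0 else out

    def in_domain(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ok = np.ones_like(x, dtype=bool)
        if self.domain is not None:
            lo, hi = self.domain
            if lo is not None:
                ok &= x >= lo
            if hi is not None:
                ok &= x <= hi
        return ok

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        d["domain"] = list(self.domain) if self.domain is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        d["coefficients"] = tuple(d["coefficients"])
        if d.get("domain") is not None:
            d["domain"] = tuple(d["domain"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Conventional coefficient of determination, 1 - SSE/SST about the mean."""
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else 0.0
    return 1.0 - sse / sst


def _as_1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise DegenerateFitError(f"expected a 1-D predictor, got shape {x.shape}")
    return x


# ---------------------------------------------------------------------------
# estimators


class _CalibrationEstimator(RegressorMixin, BaseEstimator):
    """Shared scikit-learn plumbing for the three calibration families."""

    def __init__(self, x_name="x", y_name="y", domain=None):
        self.x_name = x_name
        self.y_name = y_name
        self.domain = domain

    def predict(self, X):
        self._check_fitted()
        return self.model_.predict(_as_1d(X))

    def invert(self, y):
        self._check_fitted()
        return self.model_.invert(y)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise DegenerateFitError(
                f"{type(self).__name__} is not fitted; call fit(X, y) first"
            )

    def _finalize(self, family, coefficients, x, y, degree=None):
        model = CalibrationModel(
            family=family,
            coefficients=tuple(float(c) for c in coefficients),
            x_name=self.x_name,
            y_name=self.y_name,
            degree=degree,
            domain=tuple(self.domain) if self.domain is not None else None,
            r2=_r_squared(y, np.asarray(CalibrationModel(
                family, tuple(float(c) for c in coefficients)).predict(x))),
            n=int(len(x)),
        )
        self.model_ = model
        self.coef_ = np.asarray(model.coefficients)
        self.r2_ = model.r2
        self.n_ = model.n
        return self


class LinearCalibration(_CalibrationEstimator):
    """Ordinary least-squares line ``y = m·x + q``."""

    def fit(self, X, y):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(x) < 3:
            raise DegenerateFitError(f"need at least 3 points, got {len(x)}")
        if len(x) != len(y):
            raise PairingError(f"x and y lengths differ: {len(x)} vs {len(y)}")
        if np.ptp(x) == 0:
            raise DegenerateFitError("predictor has zero variance")
        m, q = np.polyfit(x, y, 1)
        return self._finalize("linear", (m, q), x, y)

    @property
    def slope_(self):
        return self.coef_[0]

    @property
    def intercept_(self):
        return self.coef_[1]


class PolynomialCalibration(_CalibrationEstimator):
    """Least-squares polynomial of fixed degree (coefficients in descending powers)."""

    def __init__(self, degree=2, x_name="x", y_name="y", domain=None):
        super().__init__(x_name=x_name, y_name=y_name, domain=domain)
        self.degree = degree

    def fit(self, X, y):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise PairingError(f"x and y lengths differ: {len(x)} vs {len(y)}")
        if len(x) < self.degree + 2:
            raise DegenerateFitError(
                f"degree {self.degree} needs at least {self.degree + 2} points, "
                f"got {len(x)}"
            )
        if len(np.unique(x)) < self.degree + 1:
            raise DegenerateFitError(
                f"degree {self.degree} needs at least {self.degree + 1} distinct "
                f"x values"
            )
        coeffs = np.polyfit(x, y, self.degree)
        return self._finalize("polynomial", coeffs, x, y, degree=self.degree)


def _sigmoid(x, a, b, c):
    return a / (1.0 + np.exp(b - c * x))


class SigmoidCalibration(_CalibrationEstimator):
    """Nonlinear least squares for the saturating curve ``a / (1 + exp(b - c·x))``.

    Starting values follow the logit trick: ``a0`` slightly above max(y), then
    ``log(y/(a0-y))`` is linear in x with slope ``c`` and intercept ``-b``.
    Up to ``max_restarts`` jittered restarts are attempted before declaring
    failure (the last residual norm travels on the exception).
    """

    def __init__(self, x_name="x", y_name="y", domain=None, init=None,
                 max_restarts=10, max_iter=500, tol=1e-10):
        super().__init__(x_name=x_name, y_name=y_name, domain=domain)
        self.init = init
        self.max_restarts = max_restarts
        self.max_iter = max_iter
        self.tol = tol

    def _initial_guess(self, x, y):
        if self.init is not None:
            return tuple(float(v) for v in self.init)
        a0 = 1.05 * float(np.max(y))
        interior = (y > 0) & (y < a0)
        if interior.sum() >= 2 and np.ptp(x[interior]) > 0:
            z = np.log(y[interior] / (a0 - y[interior]))
            c0, negb0 = np.polyfit(x[interior], z, 1)
            b0 = -negb0
            if not np.isfinite(c0) or c0 == 0:
                c0 = 1.0
        else:
            c0 = 1.0
            b0 = c0 * float(np.median(x))
        return a0, float(b0), float(c0)

    def fit(self, X, y):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise PairingError(f"x and y lengths differ: {len(x)} vs {len(y)}")
        if len(x) < 5:
            raise DegenerateFitError(f"need at least 5 points, got {len(x)}")
        if np.any(y < 0):
            raise DegenerateFitError("sigmoid fitting requires non-negative y")
        if np.ptp(y) == 0:
            raise DegenerateFitError("y has no spread; sigmoid fit is degenerate")

        p0 = np.asarray(self._initial_guess(x, y), dtype=float)
        rng = np.random.default_rng(0)  # jitter only; fit itself is deterministic
        last_resid = math.inf
        for attempt in range(self.max_restarts + 1):
            start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, size=3)
            if start[0] <= 0:
                start[0] = abs(start[0]) or 1.0
            try:
                popt, _ = curve_fit(
                    _sigmoid, x, y, p0=start, maxfev=self.max_iter * 10,
                    ftol=self.tol, xtol=self.tol,
                    bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                )
            except (RuntimeError, ValueError):
                continue
            resid = float(np.linalg.norm(y - _sigmoid(x, *popt)))
            last_resid = min(last_resid, resid)
            if np.all(np.isfinite(popt)):
                return self._finalize("sigmoid", popt, x, y)
        raise FitFailureError(
            f"sigmoid fit failed after {self.max_restarts} restarts",
            residual_norm=None if math.isinf(last_resid) else last_resid,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_linear(x, y, x_name="x", y_name="y", domain=None) -> CalibrationModel:
    return LinearCalibration(x_name=x_name, y_name=y_name, domain=domain).fit(x, y).model_


def fit_polynomial(x, y, degree, x_name="x", y_name="y", domain=None) -> CalibrationModel:
    est = PolynomialCalibration(degree=degree, x_name=x_name, y_name=y_name, domain=domain)
    return est.fit(x, y).model_


def fit_sigmoid(x, y, init=None, x_name="x", y_name="y", domain=None) -> CalibrationModel:
    est = SigmoidCalibration(x_name=x_name, y_name=y_name, domain=domain, init=init)
    return est.fit(x, y).model_


def predict(model: CalibrationModel, x):
    return model.predict(x)


def invert(model: CalibrationModel, y):
    return model.invert(y)


def filter_tss_domain(samples: Sequence[RipeningSample],
                      threshold: float = TSS_THRESHOLD) -> list[RipeningSample]:
    """Keep only samples at or above the TSS threshold (order preserved).

    Below roughly 10 °Brix the berry is still chlorophyll-green and SFR_R is
    dominated by tissue-scattering changes rather than chlorophyll loss, so
    the sugar calibration only applies above the threshold.
    """
    if threshold < 0:
        raise InvalidRatioError("TSS threshold must be non-negative")
    return [s for s in samples if s.tss >= threshold]


def convert_anth_basis(anth_berry: float, skin_to_berry_pct: float) -> float:
    """mg anthocyanin per g fresh berry → mg per g fresh skin.

    Pigment resides almost entirely in the skin, so dividing by the
    skin-to-berry fresh-mass fraction re-expresses the same pigment pool on
    the tissue that actually holds it.
    """
    if not 0 < skin_to_berry_pct <= 100:
        raise InvalidRatioError(
            f"skin_to_berry_pct must be in (0, 100], got {skin_to_berry_pct!r}"
        )
    return anth_berry / (skin_to_berry_pct / 100.0)


def side_concordance(sw, ne) -> tuple[CalibrationModel, float]:
    """Regress the south-west reading on the north-east reading of the same cluster.

    Returns the OLS line (slope/intercept/r²) plus the mean absolute deviation
    from the 1:1 line, the natural summary of within-cluster uniformity.
    """
    sw = np.asarray(sw, dtype=float)
    ne = np.asarray(ne, dtype=float)
    if sw.shape != ne.shape:
        raise PairingError(f"paired vectors differ in length: {sw.shape} vs {ne.shape}")
    if len(sw) < 3:
        raise DegenerateFitError(f"need at least 3 pairs, got {len(sw)}")
    model = fit_linear(ne, sw, x_name="NE", y_name="SW")
    mad = float(np.mean(np.abs(sw - ne)))
    return model, mad


def select_model(x, y, candidates) -> CalibrationModel:
    """Fit every candidate family and keep the best by r² (ties → fewest coefficients).

    Candidates are family names (``"linear"``, ``"sigmoid"``) or
    ``("polynomial", degree)`` pairs; candidates whose preconditions fail are
    skipped.
    """
    if not candidates:
        raise SelectionFailureError("empty candidate list")
    fitted: list[CalibrationModel] = []
    for cand in candidates:
        try:
            if cand == "linear":
                fitted.append(fit_linear(x, y))
            elif cand == "sigmoid":
                fitted.append(fit_sigmoid(x, y))
            elif isinstance(cand, (tuple, list)) and cand[0] == "polynomial":
                fitted.append(fit_polynomial(x, y, degree=int(cand[1])))
            else:
                raise SelectionFailureError(f"unknown candidate {cand!r}")
        except (DegenerateFitError, FitFailureError):
            continue
    if not fitted:
        raise SelectionFailureError("no candidate family could be fitted")
    # highest r2 wins; near-ties resolved by parsimony
    best = max(fitted, key=lambda m: (round(m.r2, 9), -len(m.coefficients)))
    return best
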