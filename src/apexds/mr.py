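"""Double-observer mark-recapture detection models.

Each detected group carries a capture history (det1, det2) over the two
observers (pilot, back-seat).  Conditional on detection by at least one
observer, the history probabilities are

    P(11) = p1 p2,  P(10) = p1 (1 - p2),  P(01) = (1 - p1) p2,

normalized by 1 - (1 - p1)(1 - p2), with each observer's detection modeled
on the logit scale as a linear function of perpendicular distance, covariates
and an optional observer-role effect.  Maximizing this conditional likelihood
gives absolute detection probabilities, which is what conventional distance
sampling cannot provide.

Two ways of using the fitted model correspond to the two independence
assumptions of mark-recapture distance sampling:

* ``full`` independence trusts p1(x, z), p2(x, z) at every distance;
* ``point`` independence evaluates the model only at the apex of the
  detection function, where detections are most plausibly independent, and
  lets the distance model supply the shape elsewhere.

Distance is internally expressed per 100 m so that the optimizer sees
comparably scaled columns; reported coefficients keep that unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools import numdiff

from .errors import InsufficientDataError, ValidationError
from .tables import build_design_matrix

__all__ = [
    "MRModelSpec",
    "MRFit",
    "fit_mr_conditional",
    "apex_probability",
    "mean_apex_probability",
]

DISTANCE_SCALE_M = 100.0  # distance column is x / 100 m


@dataclass(frozen=True)
class MRModelSpec:
    """Fitted double-observer logistic detection model.

    ``coefficients`` are ordered as (intercept, distance feature column(s),
    covariates..., observer-2 role effect if present); ``column_names``
    records the order.

    ``distance_feature`` controls how perpendicular distance enters the
    linear predictor:

    * ``"linear"`` - x / 100 m;
    * ``"quadratic"`` - x / 100 m and its square;
    * ``"shape"`` - log g_hat(x) and its square, where g_hat is a fitted
      detection-function shape (``ds_spec``).  Used inside the MRDS
      two-stage fit: at the apex both features vanish, so the apex
      probability depends on the intercept(s) alone, and away from the
      apex the mark-recapture curve inherits the distance model's shape
      rather than forcing a monotone logit in raw distance.
    """

    coefficients: tuple[float, ...]
    column_names: tuple[str, ...]
    independence_mode: str = "point"
    apex: float | None = None
    covariate_names: tuple[str, ...] = ()
    distance_feature: str = "linear"
    ds_spec: object | None = None
    role: str = "intercept"

    def __post_init__(self) -> None:
        if self.role not in ("none", "intercept", "full"):
            raise ValidationError(f"unknown role treatment {self.role!r}")
        if self.independence_mode not in ("full", "point"):
            raise ValidationError(
                f"independence_mode must be 'full' or 'point', got "
                f"{self.independence_mode!r}"
            )
        if self.distance_feature not in ("linear", "quadratic", "shape"):
            raise ValidationError(
                f"unknown distance_feature {self.distance_feature!r}"
            )
        if self.distance_feature == "shape" and self.ds_spec is None:
            raise ValidationError("shape distance feature needs ds_spec")
        if self.independence_mode == "point" and self.apex is not None:
            if not np.isfinite(self.apex) or self.apex < 0:
                raise ValidationError(f"invalid apex {self.apex}")

    def _distance_columns(self, x: np.ndarray) -> list[np.ndarray]:
        if self.distance_feature == "shape":
            from .detection import eval_detection

            g = np.atleast_1d(eval_detection(self.ds_spec, x))
            lg = np.log(np.clip(g, 1e-300, None))
            return [lg, lg**2]
        xs = x / DISTANCE_SCALE_M
        return [xs, xs**2] if self.distance_feature == "quadratic" else [xs]

    def _design(self, x: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        cols = [np.ones_like(x), *self._distance_columns(x)]
        if self.covariate_names:
            if Z is None:
                raise ValidationError("covariate values required")
            Z = np.atleast_2d(np.asarray(Z, dtype=float))
            if Z.shape[0] == 1 and x.shape[0] > 1:
                Z = np.repeat(Z, x.shape[0], axis=0)
            cols.extend(Z[:, j] for j in range(Z.shape[1]))
        return np.column_stack(cols)

    def predict_p(self, x, z=None, observer: int = 1) -> np.ndarray:
        """Detection probability of one observer at distance(s) x."""
        X = self._design(x, z)
        a = np.asarray(self.coefficients)
        k = X.shape[1]
        if self.role == "full":
            eta = X @ (a[:k] if observer == 1 else a[k:])
        elif self.role == "intercept":
            eta = X @ a[:-1] + (a[-1] if observer == 2 else 0.0)
        else:
            eta = X @ a
        return special.expit(eta)

    def pooled_p(self, x, z=None) -> np.ndarray:
        """Probability at least one observer detects: p1 + p2 - p1 p2."""
        p1 = self.predict_p(x, z, observer=1)
        p2 = self.predict_p(x, z, observer=2)
        return p1 + p2 - p1 * p2


@dataclass
class MRFit:
    """Conditional-likelihood fit of an :class:`MRModelSpec`."""

    spec: MRModelSpec
    loglik: float
    n_params: int
    n_obs: int
    vcov: np.ndarray | None = None
    converged: bool = True
    boundary: bool = False
    separation: bool = False
    message: str = ""
    likelihood_type: str = "mark_recapture"

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _history_negloglik(alpha, X, y1, y2, role, penalty=0.0):
    k = X.shape[1]
    if role == "full":
        eta1, eta2 = X @ alpha[:k], X @ alpha[k:]
    elif role == "intercept":
        eta1 = X @ alpha[:-1]
        eta2 = eta1 + alpha[-1]
    else:
        eta1 = eta2 = X @ alpha
    # log p, log(1-p) via logaddexp for numerical stability
    lp1, lq1 = -np.logaddexp(0, -eta1), -np.logaddexp(0, eta1)
    lp2, lq2 = -np.logaddexp(0, -eta2), -np.logaddexp(0, eta2)
    ll = y1 * lp1 + (1 - y1) * lq1 + y2 * lp2 + (1 - y2) * lq2
    log_p_any = np.log1p(-np.exp(np.minimum(lq1 + lq2, -1e-12)))
    val = -(np.sum(ll - log_p_any)) + penalty * np.sum(alpha**2)
    return val if np.isfinite(val) else 1e10


def fit_mr_conditional(
    obs: pd.DataFrame,
    covariates: Sequence[str] = (),
    mode: str = "point",
    apex: float | None = None,
    distance_feature: str = "linear",
    ds_spec=None,
    role: str = "intercept",
    include_distance: bool = True,
) -> MRFit:
    """Fit the double-observer conditional likelihood over detected groups.

    Requires at least one duplicate (1,1) history - without recaptures the
    absolute scale is inestimable - and flags (rather than silently
    reporting) boundary fits when discordant histories are absent and
    complete separation, the latter refit with a mild ridge penalty.
    """
    y1 = obs["det1"].to_numpy(dtype=float)
    y2 = obs["det2"].to_numpy(dtype=float)
    n11 = int(np.sum((y1 == 1) & (y2 == 1)))
    n_disc = int(np.sum(y1 != y2))
    if n11 == 0:
        raise InsufficientDataError(
            "no duplicate (1,1) capture histories: the mark-recapture scale "
            "is inestimable"
        )
    x = obs["distance"].to_numpy(dtype=float) if include_distance else np.zeros(len(obs))
    Z, znames = build_design_matrix(obs, covariates)

    spec0 = MRModelSpec(
        coefficients=(),
        column_names=(),
        independence_mode=mode,
        apex=apex,
        covariate_names=tuple(znames),
        distance_feature=distance_feature,
        ds_spec=ds_spec,
        role=role,
    )
    X = spec0._design(x, Z if znames else None)
    if not include_distance:
        X[:, 1:1 + len(spec0._distance_columns(np.zeros(1)))] = 0.0
    k = X.shape[1]
    p = {"none": k, "intercept": k + 1, "full": 2 * k}[role]

    def _fit(penalty):
        res = optimize.minimize(
            _history_negloglik, np.zeros(p), args=(X, y1, y2, role, penalty),
            method="BFGS", options={"maxiter": 500},
        )
        return res

    res = _fit(0.0)
    boundary = n_disc == 0
    separation = bool(np.max(np.abs(res.x)) > 15.0)
    if separation and not boundary:
        res = _fit(0.01)
        separation = True
    alpha = res.x

    if distance_feature == "shape":
        names = ["intercept", "log_g", "log_g_sq"]
    elif distance_feature == "quadratic":
        names = ["intercept", "distance_per_100m", "distance_per_100m_sq"]
    else:
        names = ["intercept", "distance_per_100m"]
    names.extend(znames)
    if role == "full":
        names = [f"{nm}:obs1" for nm in names] + [f"{nm}:obs2" for nm in names]
    elif role == "intercept":
        names.append("observer2")

    vcov = None
    if not (boundary or separation):
        try:
            H = numdiff.approx_hess1(alpha, _history_negloglik,
                                     args=(X, y1, y2, role, 0.0))
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = None

    spec = MRModelSpec(
        coefficients=tuple(alpha),
        column_names=tuple(names),
        independence_mode=mode,
        apex=apex,
        covariate_names=tuple(znames),
        distance_feature=distance_feature,
        ds_spec=ds_spec,
        role=role,
    )
    return MRFit(
        spec=spec,
        loglik=-res.fun,
        n_params=p,
        n_obs=len(obs),
        vcov=vcov,
        converged=bool(res.success) or boundary or separation,
        boundary=boundary,
        separation=separation,
        message=str(res.message),
    )


def apex_probability(mr: MRModelSpec, theta: float, z=None) -> float | np.ndarray:
    """Pooled detection probability p_dot = p1 + p2 - p1 p2 at the apex.

    Under point independence this is the absolute scaling applied to the
    distance model; under full independence the same pooled formula may be
    evaluated at any distance.
    """
    out = mr.pooled_p(theta, z)
    return float(out[0]) if np.ndim(out) and out.shape[0] == 1 else out


def mean_apex_probability(
    mr: MRFit | MRModelSpec,
    obs: pd.DataFrame,
    theta: float,
    weights: str = "ht",
    pa: np.ndarray | None = None,
    Z: np.ndarray | None = None,
) -> dict:
    """Weighted mean (with SE and range) of per-detection apex probabilities.

    ``weights="ht"`` weighs each detection by its Horvitz-Thompson weight
    1 / P_a(z_i) (pass the per-detection inclusion probabilities as ``pa``);
    ``weights="equal"`` averages plainly.  The SE propagates coefficient
    uncertainty through the delta method when a covariance is available.
    """
    fit = mr if isinstance(mr, MRFit) else None
    spec = mr.spec if isinstance(mr, MRFit) else mr
    if weights == "ht":
        if pa is None:
            raise ValidationError(
                "HT weighting needs per-detection inclusion probabilities (pa)"
            )
        wgt = 1.0 / np.asarray(pa, dtype=float)
    elif weights == "equal":
        wgt = np.ones(len(obs))
    else:
        raise ValidationError(f"unknown weights {weights!r}")
    if Z is None and spec.covariate_names:
        # covariate_names are already-expanded numeric columns; pass Z
        # explicitly when the model used categorical covariates
        Z, _ = build_design_matrix(obs, spec.covariate_names)
    x_apex = np.full(len(obs), float(theta))
    p_i = spec.pooled_p(x_apex, Z)
    mean = float(np.sum(wgt * p_i) / np.sum(wgt))

    se = None
    if fit is not None and fit.vcov is not None:
        a0 = np.asarray(spec.coefficients)

        def _mean(alpha):
            s = MRModelSpec(tuple(alpha), spec.column_names, spec.independence_mode,
                            spec.apex, spec.covariate_names, spec.distance_feature,
                            spec.ds_spec, spec.role)
            pi = s.pooled_p(x_apex, Z)
            return np.sum(wgt * pi) / np.sum(wgt)

        grad = np.ravel(numdiff.approx_fprime(a0, _mean, centered=True))
        v = float(grad @ fit.vcov @ grad)
        se = float(np.sqrt(v)) if v >= 0 else None
    return {
        "mean": mean,
        "se": se,
        "min": float(np.min(p_i)),
        "max": float(np.max(p_i)),
        "weights": weights,
    }
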