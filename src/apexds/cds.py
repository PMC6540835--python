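"""Conventional and multiple-covariate distance sampling (CDS / MCDS).

The detection model is fit by maximizing the likelihood of the observed
perpendicular distances conditional on detection,

    l(psi) = sum_i log[ g(x_i; z_i, psi) / mu(z_i, psi) ],

which assumes certain detection at the curve's apex.  Abundance follows by
Horvitz-Thompson weighting of group sizes with the within-strip inclusion
probability P_a(z) = mu(z) / w.  Group size enters only through the HT sum
unless it is listed as a covariate of the scale model.

Left truncation (needed to fit a monotone half-normal to aerial data whose
detection peaks off the line) shifts distances to x - t and integrates the
detection function over [0, w - t]; by default the truncation point for a
half-normal fit is the apex of a two-piece normal fit to the same data.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .detection import DetectionFunctionSpec, _partial_integral_closed, detection_cdf
from .errors import FitError, InsufficientDataError, ValidationError
from .tables import FitResult, M_PER_KM, SurveyDesign, build_design_matrix

__all__ = [
    "fit_cds",
    "estimate_abundance_cds",
    "encounter_rate_variance",
    "gof_ks",
    "aic_select",
    "horvitz_thompson",
]

MIN_RECOMMENDED_DETECTIONS = 60


def horvitz_thompson(sizes, pa, area_ratio: float = 1.0) -> tuple[float, float]:
    """Horvitz-Thompson abundance of (individuals, groups).

    Sums group sizes (and ones) weighted by the inverse per-detection
    inclusion probability, scaled by the study-to-covered-area ratio A/a.
    """
    sizes = np.asarray(sizes, dtype=float)
    pa = np.asarray(pa, dtype=float)
    if np.any(pa <= 0) or np.any(pa > 1):
        raise ValidationError("inclusion probabilities must lie in (0, 1]")
    return (float(area_ratio * np.sum(sizes / pa)),
            float(area_ratio * np.sum(1.0 / pa)))


def _unpack(params: np.ndarray, form: str, W: float):
    """Map the unconstrained optimizer vector to (sigma1, sigma2, theta, beta)."""
    if form == "half_normal":
        s1 = np.exp(params[0])
        return s1, s1, 0.0, params[1:]
    s1, s2 = np.exp(params[0]), np.exp(params[1])
    theta = W * special.expit(params[2])
    return s1, s2, theta, params[3:]


def _negloglik(params, form, x, Z, W):
    s1, s2, theta, beta = _unpack(params, form, W)
    mult = np.exp(Z @ beta) if Z.shape[1] else 1.0
    s1v, s2v = s1 * mult, s2 * mult
    d = x - theta
    sig = np.where(d <= 0, s1v, s2v)
    log_g = -0.5 * (d / sig) ** 2

    class _Tmp:
        apex = theta

    mu = _partial_integral_closed(_Tmp, W, np.atleast_1d(s1v), np.atleast_1d(s2v))
    if np.any(mu <= 0) or np.any(~np.isfinite(mu)):
        return 1e10
    log_mu_sum = len(x) * np.log(mu[0]) if mu.shape[0] == 1 else np.sum(np.log(mu))
    val = -(np.sum(log_g) - log_mu_sum)
    return val if np.isfinite(val) else 1e10


def _starts(form, x, W, p):
    """Starting points for the optimizer; several apex starts for the 2PN."""
    s_hn = np.sqrt(np.mean(x**2)) if np.mean(x**2) > 0 else W / 4
    s_hn = float(np.clip(s_hn, 1e-3, 10 * W))
    if form == "half_normal":
        yield np.r_[np.log(s_hn), np.zeros(p)]
        yield np.r_[np.log(W / 2.0), np.zeros(p)]
        return
    spread = float(np.std(x)) or W / 6
    for q in (0.15, 0.35, 0.55):
        th = float(np.quantile(x, q))
        th = np.clip(th, 0.02 * W, 0.9 * W)
        u = special.logit(th / W)
        yield np.r_[np.log(0.7 * spread), np.log(spread), u, np.zeros(p)]


def fit_cds(
    obs: pd.DataFrame,
    design: SurveyDesign,
    form: str = "half_normal",
    covariates: Sequence[str] = (),
    left_truncation: float | str = "auto",
    compute_abundance: bool = True,
    compute_vcov: bool = True,
) -> FitResult:
    """Fit a CDS (no covariates) or MCDS detection model and estimate abundance.

    Parameters
    ----------
    obs, design
        Observation table and survey design (see :mod:`apexds.tables`).
    form
        ``"half_normal"`` or ``"two_piece_normal"``.
    covariates
        Column names entering the scale model sigma_k(z) = sigma_k exp(beta'z).
    left_truncation
        Distance t below which detections are discarded; distances are
        shifted to x - t and the detection function integrated over
        [0, w - t].  ``"auto"`` truncates a half-normal fit at the apex of a
        two-piece normal fit to the same data (and is 0 for the two-piece
        normal itself, which needs no truncation).
    """
    w = design.w
    if left_truncation == "auto":
        if form == "half_normal" and len(obs) >= 2:
            pre = fit_cds(obs, design, form="two_piece_normal", covariates=(),
                          left_truncation=0.0, compute_abundance=False,
                          compute_vcov=False)
            left_truncation = float(pre.theta)
        else:
            left_truncation = 0.0
    t = float(left_truncation)
    if not 0 <= t < w:
        raise ValidationError(f"left truncation {t} outside [0, w)")

    kept = obs[obs["distance"] >= t].reset_index(drop=True)
    n = len(kept)
    if n < 2 or kept["distance"].nunique() < 2:
        raise InsufficientDataError(
            f"{n} detection(s) after truncation at {t} m; need >= 2 distinct distances"
        )
    if n < MIN_RECOMMENDED_DETECTIONS:
        warnings.warn(
            f"only {n} detections; 60-80 are generally needed to fit a CDS "
            "detection model reliably",
            stacklevel=2,
        )
    W = w - t
    x = kept["distance"].to_numpy(dtype=float) - t
    Z, znames = build_design_matrix(kept, covariates)

    best = None
    for x0 in _starts(form, x, W, Z.shape[1]):
        res = optimize.minimize(
            _negloglik, x0, args=(form, x, Z, W), method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is not None and not best.success:
        res = optimize.minimize(  # derivative-free fallback
            _negloglik, best.x, args=(form, x, Z, W), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res.fun <= best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or not np.all(np.isfinite(best.x)):
        raise FitError(f"distance-likelihood optimization failed: {best}")

    s1, s2, theta, beta = _unpack(best.x, form, W)
    if form == "half_normal":
        spec = DetectionFunctionSpec("half_normal", s1, beta=tuple(beta),
                                     covariate_names=tuple(znames))
        k = 1 + len(beta)
    else:
        spec = DetectionFunctionSpec("two_piece_normal", s1, s2, apex=theta,
                                     beta=tuple(beta), covariate_names=tuple(znames))
        k = 3 + len(beta)

    vcov = None
    if compute_vcov:
        try:
            H = numdiff.approx_hess1(best.x, _negloglik, args=(form, x, Z, W))
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = None

    fit = FitResult(
        spec=spec,
        loglik=-best.fun,
        n_params=k,
        theta=theta + t if form == "two_piece_normal" else t,
        n_obs=n,
        left_truncation=t,
        w=w,
        likelihood_type="distance",
        vcov=vcov,
        converged=bool(best.success),
        message=str(best.message),
        extras={"opt_x": best.x, "form": form, "covariates": tuple(covariates)},
    )
    if compute_abundance:
        estimate_abundance_cds(fit, obs, design)
    return fit


def _pa_cds(fit: FitResult, kept: pd.DataFrame) -> np.ndarray:
    """Within-strip inclusion probability mu(z)/W for each kept detection."""
    W = fit.w - fit.left_truncation
    Z, _ = build_design_matrix(kept, fit.extras.get("covariates", ()))
    if fit.spec.beta:
        mu = np.atleast_1d(
            _partial_integral_closed(fit.spec, W, *map(np.atleast_1d, fit.spec.scales(Z)))
        )
    else:
        s1, s2 = fit.spec.scales(None)
        mu = np.full(len(kept), float(
            _partial_integral_closed(fit.spec, W, np.atleast_1d(s1), np.atleast_1d(s2))[0]
        ))
    return mu / W


def estimate_abundance_cds(fit: FitResult, obs: pd.DataFrame,
                           design: SurveyDesign) -> FitResult:
    """Horvitz-Thompson abundance under the certain-apex-detection assumption.

    N_hat = (A / a) * sum_i s_i / P_a(z_i) with P_a(z) = mu(z) / W over the
    (possibly left-truncated) strip.  The variance combines the delta-method
    detection-parameter component with the between-transect encounter-rate
    component.
    """
    t = fit.left_truncation
    kept = obs[obs["distance"] >= t].reset_index(drop=True)
    W = fit.w - t
    a = design.sides * (W / M_PER_KM) * design.total_length_km
    A = design.area_km2
    pa = _pa_cds(fit, kept)
    if np.any(pa < 0.01):
        warnings.warn("inclusion probability below 0.01: extreme extrapolation",
                      stacklevel=2)
    s = kept["size"].to_numpy(dtype=float)
    ratio = A / a
    fit.abundance, fit.abundance_groups = horvitz_thompson(s, pa, ratio)
    fit.pa = pa

    var_det = 0.0
    if fit.vcov is not None:
        form = fit.extras["form"]
        Z, _ = build_design_matrix(kept, fit.extras.get("covariates", ()))

        def _nhat(params):
            s1, s2, theta, beta = _unpack(params, form, W)
            mult = np.exp(Z @ beta) if Z.shape[1] else np.ones(len(kept))

            class _Tmp:
                apex = theta

            mu = _partial_integral_closed(_Tmp, W, s1 * mult, s2 * mult)
            return ratio * np.sum(s * W / mu)

        grad = np.ravel(numdiff.approx_fprime(fit.extras["opt_x"], _nhat, centered=True))
        var_det = float(grad @ fit.vcov @ grad)
        var_det = max(var_det, 0.0)
    try:
        er = encounter_rate_variance(kept, design)
        cv_n2 = er["var_n"] / len(kept) ** 2 if len(kept) else 0.0
    except InsufficientDataError:
        cv_n2 = np.nan
    var_er = fit.abundance**2 * cv_n2
    fit.var_components = {"detection": var_det, "encounter_rate": var_er}
    total = var_det + var_er
    fit.se = float(np.sqrt(total)) if np.isfinite(total) else None
    return fit


def encounter_rate_variance(obs: pd.DataFrame, design: SurveyDesign) -> dict:
    """Between-transect (empirical) variance of the encounter rate n/L.

    Uses the standard replicate-line estimator with transect lengths as
    weights:

        var(n/L) = [K / (L^2 (K-1))] * sum_k l_k^2 (n_k/l_k - n/L)^2

    and var(n) = L^2 var(n/L).  Transects with no detections count as zeros,
    so the design's full transect list is required.
    """
    t = design.transects
    K = len(t)
    if K < 2:
        raise InsufficientDataError(
            "encounter-rate variance needs >= 2 transects; with a single "
            "transect use the transect bootstrap instead"
        )
    counts = obs.groupby("transect").size()
    n_k = t["transect"].map(counts).fillna(0).to_numpy(dtype=float)
    l_k = t["length_km"].to_numpy(dtype=float)
    L = l_k.sum()
    n = n_k.sum()
    rate = n / L
    var_rate = (K / (L**2 * (K - 1))) * np.sum(l_k**2 * (n_k / l_k - rate) ** 2)
    return {"var_rate": float(var_rate), "var_n": float(L**2 * var_rate),
            "n": float(n), "L": float(L), "K": K}


def gof_ks(fit: FitResult, obs: pd.DataFrame) -> tuple[float, float]:
    """Kolmogorov-Smirnov goodness of fit of the fitted distance model.

    Each observed distance is probability-integral transformed through its
    own conditional CDF F(x | z_i) (so covariate models are handled per
    observation) and the transformed sample is tested against Uniform(0, 1).
    Returns (D, p) with the asymptotic KS p-value.
    """
    t = fit.left_truncation
    kept = obs[obs["distance"] >= t].reset_index(drop=True)
    W = fit.w - t
    x = kept["distance"].to_numpy(dtype=float) - t
    Z, _ = build_design_matrix(kept, fit.extras.get("covariates", ()))
    u = detection_cdf(fit.spec, x, W, Z if fit.spec.beta else None)
    res = stats.kstest(np.atleast_1d(u), "uniform")
    return float(res.statistic), float(res.pvalue)


def aic_select(candidates: Sequence[FitResult]) -> list[FitResult]:
    """Rank fitted models by AIC (ascending); ties go to the smaller model.

    All candidates must have been fit to the same detections, truncation and
    likelihood type - AICs of different likelihoods (e.g. distance-only vs
    distance + mark-recapture) are not comparable.
    """
    if not candidates:
        raise ValidationError("no candidate fits supplied")
    ref = candidates[0]
    for c in candidates[1:]:
        if c.likelihood_type != ref.likelihood_type:
            raise ValidationError(
                f"AICs not comparable: likelihood {c.likelihood_type!r} vs "
                f"{ref.likelihood_type!r}"
            )
        if c.n_obs != ref.n_obs or c.left_truncation != ref.left_truncation:
            raise ValidationError(
                "AICs not comparable: candidates differ in detections or truncation"
            )
    ranked = sorted(candidates, key=lambda f: f.aic)
    changed = True
    while changed:  # bubble near-ties (|dAIC| < 1e-6) toward fewer parameters
        changed = False
        for i in range(len(ranked) - 1):
            a, b = ranked[i], ranked[i + 1]
            if abs(a.aic - b.aic) < 1e-6 and a.n_params > b.n_params:
                ranked[i], ranked[i + 1] = b, a
                changed = True
    return ranked
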