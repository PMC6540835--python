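"""Mark-recapture distance sampling (MRDS) abundance estimation.

The estimator is two-stage:

1. an MCDS conditional distance likelihood fit to the pooled detections
   (detected by at least one observer) supplies the detection-function
   *shape* - for aerial surveys a two-piece normal with an estimated apex;
2. a double-observer logistic model fit to the capture histories supplies
   the absolute *scale*.

Under point independence the per-detection inclusion probability is

    P_a(z) = p_dot(theta_hat, z) * mu(z) / w,

the mark-recapture model entering only at the apex, where detections are
most plausibly independent.  Under full independence the mark-recapture
model is trusted at every distance and

    P_a(z) = (1/w) * int_0^w [1 - (1 - p1(x, z))(1 - p2(x, z))] dx.

Abundance is the Horvitz-Thompson sum of group sizes over P_a, scaled by the
study-to-covered-area ratio.  The transect bootstrap is the reference
variance method; it captures encounter-rate variance by construction and is
the only route by which apex uncertainty propagates (the delta method treats
the fitted apex as fixed).
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.tools import numdiff

from .cds import encounter_rate_variance, fit_cds, gof_ks, horvitz_thompson, _pa_cds
from .detection import _partial_integral_closed
from .errors import FitError, InsufficientDataError, ValidationError
from .mr import MRModelSpec, fit_mr_conditional, mean_apex_probability
from .tables import FitResult, SurveyDesign, build_design_matrix

__all__ = ["fit_mrds", "bootstrap_variance", "truncation_fraction"]

_GL_NODES = 64


def _full_independence_pa(spec: MRModelSpec, Z, w: float, n: int) -> np.ndarray:
    """(1/w) int_0^w pooled MR detection dx by Gauss-Legendre quadrature."""
    nodes, wts = np.polynomial.legendre.leggauss(_GL_NODES)
    xs = 0.5 * w * (nodes + 1.0)
    acc = np.zeros(n)
    for xk, wk in zip(xs, wts):
        acc += wk * spec.pooled_p(np.full(n, xk), Z)
    return 0.5 * acc  # (w/2) * sum / w


def fit_mrds(
    obs: pd.DataFrame,
    design: SurveyDesign,
    form: str = "two_piece_normal",
    ds_covariates: Sequence[str] = (),
    mr_covariates: Sequence[str] = (),
    independence: str = "point",
    mr_distance_feature: str | None = None,
    mr_role: str = "full",
    compute_vcov: bool = True,
) -> FitResult:
    """Fit the two-stage MRDS estimator and return abundance with variance.

    ``independence`` selects point (default) or full independence.  The
    distance stage is fit without left truncation - the two-piece normal
    models both sides of the apex, which is the point of using it.  If the
    mark-recapture stage fails, the distance-stage result is returned with
    ``status="partial"`` and no abundance rather than raising.
    """
    if mr_distance_feature is None:
        # point independence borrows the fitted shape (only the apex value
        # matters, and the shape feature is exact there); full independence
        # keeps the classic logistic-in-distance mark-recapture curve.
        mr_distance_feature = "shape" if independence == "point" else "linear"
    ds = fit_cds(obs, design, form=form, covariates=ds_covariates,
                 left_truncation=0.0, compute_abundance=False,
                 compute_vcov=compute_vcov)
    theta = float(ds.theta)
    w = design.w
    status = "ok"
    if form == "two_piece_normal" and not (0.005 * w < theta < 0.95 * w):
        status = "apex_at_boundary"

    bare_spec = ds.spec
    if bare_spec.beta:  # shape feature is a pure distance transform
        from .detection import DetectionFunctionSpec

        bare_spec = DetectionFunctionSpec(
            bare_spec.form, bare_spec.sigma1, bare_spec.sigma2,
            apex=bare_spec.apex)
    try:
        mr = fit_mr_conditional(
            obs, covariates=mr_covariates, mode=independence, apex=theta,
            distance_feature=mr_distance_feature,
            ds_spec=bare_spec if mr_distance_feature == "shape" else None,
            role=mr_role,
        )
    except (InsufficientDataError, FitError) as exc:
        ds.status = "partial"
        ds.message = f"mark-recapture stage failed: {exc}"
        return ds

    kept = obs.reset_index(drop=True)
    n = len(kept)
    mu_over_w = _pa_cds(ds, kept)  # mu(z)/w from the distance stage
    Zmr, _ = build_design_matrix(kept, mr_covariates)
    Zmr = Zmr if mr.spec.covariate_names else None
    if independence == "point":
        p_apex = np.atleast_1d(mr.spec.pooled_p(np.full(n, theta), Zmr))
        pa = p_apex * mu_over_w
    else:
        pa = _full_independence_pa(mr.spec, Zmr, w, n)
        p_apex = np.atleast_1d(mr.spec.pooled_p(np.full(n, theta), Zmr))
    pa = np.clip(pa, 1e-10, 1.0)
    if np.any(pa < 0.01):
        warnings.warn("inclusion probability below 0.01: extreme extrapolation",
                      stacklevel=2)

    a = design.covered_area_km2
    A = design.area_km2
    ratio = A / a
    s = kept["size"].to_numpy(dtype=float)
    nhat, nhat_groups = horvitz_thompson(s, pa, ratio)

    apex_stats = mean_apex_probability(mr, kept, theta, weights="ht", pa=pa, Z=Zmr)

    # delta-method variance: DS-parameter and MR-parameter components treated
    # as independent (two-stage), apex held fixed, plus encounter rate.
    var_det = var_mr = 0.0
    if compute_vcov and ds.vcov is not None:
        from .cds import _unpack

        Zds, _ = build_design_matrix(kept, ds_covariates)

        def _nhat_ds(params):
            s1, s2, th, beta = _unpack(params, form, w)
            mult = np.exp(Zds @ beta) if Zds.shape[1] else np.ones(n)

            class _Tmp:
                apex = th

            mu = _partial_integral_closed(_Tmp, w, s1 * mult, s2 * mult)
            if independence == "point":
                return ratio * np.sum(s * w / (mu * p_apex))
            return nhat  # full mode: DS shape does not enter P_a

        grad = np.ravel(numdiff.approx_fprime(ds.extras["opt_x"], _nhat_ds, centered=True))
        var_det = max(float(grad @ ds.vcov @ grad), 0.0)
    if compute_vcov and mr.vcov is not None:
        a0 = np.asarray(mr.spec.coefficients)

        def _nhat_mr(alpha):
            spec = MRModelSpec(tuple(alpha), mr.spec.column_names,
                               mr.spec.independence_mode, mr.spec.apex,
                               mr.spec.covariate_names, mr.spec.distance_feature,
                               mr.spec.ds_spec, mr.spec.role)
            if independence == "point":
                p = np.atleast_1d(spec.pooled_p(np.full(n, theta), Zmr))
                return ratio * np.sum(s / (p * mu_over_w))
            return ratio * np.sum(s / _full_independence_pa(spec, Zmr, w, n))

        grad = np.ravel(numdiff.approx_fprime(a0, _nhat_mr, centered=True))
        var_mr = max(float(grad @ mr.vcov @ grad), 0.0)
    try:
        er = encounter_rate_variance(kept, design)
        cv_n2 = er["var_n"] / n**2
    except InsufficientDataError:
        cv_n2 = np.nan
    var_er = nhat**2 * cv_n2
    total = var_det + var_mr + var_er

    trunc_n, trunc_pct = truncation_fraction(kept, theta)
    result = FitResult(
        spec=ds.spec,
        loglik=ds.loglik + mr.loglik,
        n_params=ds.n_params + mr.n_params,
        abundance=nhat,
        abundance_groups=nhat_groups,
        se=float(np.sqrt(total)) if np.isfinite(total) else None,
        var_components={"detection": var_det, "mark_recapture": var_mr,
                        "encounter_rate": var_er},
        theta=theta,
        mr=mr,
        mean_apex_p=apex_stats["mean"],
        min_apex_p=apex_stats["min"],
        max_apex_p=apex_stats["max"],
        apex_p_se=apex_stats["se"],
        n_obs=n,
        left_truncation=0.0,
        w=w,
        likelihood_type="distance+mr",
        vcov=ds.vcov,
        converged=ds.converged and mr.converged,
        status=status,
        pa=pa,
        extras={
            "independence": independence,
            "ds_loglik": ds.loglik,
            "ds_n_params": ds.n_params,
            "ds_aic": ds.aic,
            "mr_aic": mr.aic,
            "opt_x": ds.extras["opt_x"],
            "form": form,
            "covariates": tuple(ds_covariates),
            "hn_truncation_n": trunc_n,
            "hn_truncation_pct": trunc_pct,
        },
    )
    try:
        d_stat, p_val = gof_ks(result, kept)
        result.extras["gof_ks_D"], result.extras["gof_ks_p"] = d_stat, p_val
    except Exception:  # GOF is reporting, never fatal
        pass
    return result


def truncation_fraction(obs: pd.DataFrame, theta: float) -> tuple[int, float]:
    """Count and percentage of detections nearer than the apex.

    This is the share of data a left-truncated half-normal analysis would
    discard if it truncated at the apex distance.
    """
    if theta < 0:
        raise ValidationError(f"apex must be non-negative, got {theta}")
    x = obs["distance"].to_numpy(dtype=float)
    count = int(np.sum(x < theta))
    pct = 100.0 * count / len(x) if len(x) else 0.0
    return count, pct


def bootstrap_variance(
    fitter: Callable[[pd.DataFrame, SurveyDesign], FitResult | float],
    obs: pd.DataFrame,
    design: SurveyDesign,
    B: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Transect bootstrap SE and percentile CI for any abundance fitter.

    Transects are resampled with replacement within strata (keeping each
    stratum's transect count); a resampled transect brings its detections
    with it under a fresh id.  Replicates whose fit fails are dropped; more
    than 20% failures aborts.  Encounter-rate variance is captured by
    construction.
    """
    t = design.transects
    if len(t) < 2:
        raise InsufficientDataError(
            "transect bootstrap needs >= 2 transects"
        )
    if B < 100:
        raise ValidationError(f"B={B} too small; use >= 100 replicates")
    rng = np.random.default_rng(seed)
    by_transect = {tid: g for tid, g in obs.groupby("transect")}
    estimates = []
    n_failed = 0
    for _ in range(B):
        rows, obs_parts = [], []
        for stratum, grp in t.groupby("stratum", sort=False):
            idx = rng.integers(0, len(grp), size=len(grp))
            for j, i in enumerate(idx):
                row = grp.iloc[i]
                new_id = f"{row['transect']}#b{len(rows)}"
                rows.append({"transect": new_id, "length_km": row["length_km"],
                             "stratum": stratum})
                part = by_transect.get(row["transect"])
                if part is not None and len(part):
                    part = part.copy()
                    part["transect"] = new_id
                    obs_parts.append(part)
        bdesign = SurveyDesign(pd.DataFrame(rows), design.w, design.area_km2,
                               design.sides)
        bobs = (pd.concat(obs_parts, ignore_index=True) if obs_parts
                else obs.iloc[0:0].copy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fitter(bobs, bdesign)
            nhat = fit if isinstance(fit, (int, float)) else fit.abundance
            if nhat is None or not np.isfinite(nhat):
                raise FitError("no abundance")
            estimates.append(float(nhat))
        except Exception:
            n_failed += 1
    if n_failed > 0.2 * B:
        raise FitError(
            f"{n_failed}/{B} bootstrap replicates failed to fit"
        )
    est = np.asarray(estimates)
    lo, hi = np.percentile(est, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return {
        "se": float(np.std(est, ddof=1)),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "estimates": est,
        "n_failed": n_failed,
        "B": B,
    }
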