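"""Survey data containers, validation and delimited-text I/O.

Observations live in a plain :class:`pandas.DataFrame` with one row per
detected group and columns

``transect, distance, size, det1, det2, <covariates...>``

where ``distance`` is the perpendicular distance from the line in metres
(0-based), ``size`` the group size, and ``det1``/``det2`` the binary
detection indicators for the two observers (pilot and back-seat observer);
only groups detected by at least one observer appear.  Transect geometry and
the sampling frame live in :class:`SurveyDesign`.

Units are fixed package-wide: distances and strip half-widths in metres,
transect lengths in kilometres, areas in square kilometres.  All conversions
happen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SurveyDesign",
    "FitResult",
    "validate_observations",
    "read_observations",
    "write_observations",
    "read_transects",
    "write_transects",
    "build_design_matrix",
    "M_PER_KM",
]

M_PER_KM = 1000.0

REQUIRED_OBS_COLUMNS = ("transect", "distance", "size", "det1", "det2")


@dataclass(frozen=True)
class SurveyDesign:
    """Transect layout and sampling frame of a line-transect survey.

    Parameters
    ----------
    transects
        DataFrame with columns ``transect`` (id), ``length_km`` and
        ``stratum`` (optional; a single stratum ``"all"`` is assumed).
    w
        Strip half-width, m: detections farther than ``w`` are off-strip.
    area_km2
        Size of the study area, km^2.
    sides
        Number of sides of the line searched (1 for surveys where pilot and
        observer search the same side of the aircraft, the default; 2 for
        ground surveys walked with both sides visible).
    """

    transects: pd.DataFrame
    w: float
    area_km2: float
    sides: int = 1
    stratum_areas: dict | None = None

    def __post_init__(self) -> None:
        t = self.transects
        if not {"transect", "length_km"}.issubset(t.columns):
            raise ValidationError("transects need columns transect, length_km")
        if "stratum" not in t.columns:
            t = t.assign(stratum="all")
        t = t.reset_index(drop=True)
        object.__setattr__(self, "transects", t)
        if len(t) == 0:
            raise ValidationError("design has no transects")
        if t["transect"].duplicated().any():
            dup = t.loc[t["transect"].duplicated(), "transect"].iloc[0]
            raise ValidationError(f"duplicate transect id {dup!r}")
        if (t["length_km"] <= 0).any():
            bad = t.index[t["length_km"] <= 0][0]
            raise ValidationError(f"non-positive transect length in row {bad}")
        if self.w <= 0:
            raise ValidationError(f"strip half-width must be positive, got {self.w}")
        if self.sides not in (1, 2):
            raise ValidationError(f"sides must be 1 or 2, got {self.sides}")
        if not (0 < self.covered_area_km2 <= self.area_km2):
            raise ValidationError(
                f"covered area {self.covered_area_km2:.3f} km^2 must lie in "
                f"(0, study area {self.area_km2} km^2]"
            )
        if self.stratum_areas is not None:
            missing = set(t["stratum"]) - set(self.stratum_areas)
            if missing:
                raise ValidationError(
                    f"stratum_areas missing stratum(s): {sorted(missing)}"
                )
            total = sum(self.stratum_areas.values())
            if abs(total - self.area_km2) > 1e-6 * max(self.area_km2, 1.0):
                raise ValidationError(
                    f"stratum areas sum to {total}, study area is {self.area_km2}"
                )

    @property
    def total_length_km(self) -> float:
        """Total line length L (km)."""
        return float(self.transects["length_km"].sum())

    @property
    def covered_area_km2(self) -> float:
        """Covered area a = sides * w * L (km^2)."""
        return self.sides * (self.w / M_PER_KM) * self.total_length_km

    def strata(self) -> list[Any]:
        return list(self.transects["stratum"].unique())

    def subset(self, stratum) -> "SurveyDesign":
        """Design restricted to one stratum.

        Uses the stratum's true area when ``stratum_areas`` is set; without
        it the study area is apportioned by effort share, which is only
        appropriate for equal-intensity designs.
        """
        sub = self.transects[self.transects["stratum"] == stratum]
        if len(sub) == 0:
            raise ValidationError(f"no transects in stratum {stratum!r}")
        if self.stratum_areas is not None:
            area = self.stratum_areas[stratum]
        else:
            area = self.area_km2 * sub["length_km"].sum() / self.total_length_km
        return SurveyDesign(sub.copy(), self.w, area, self.sides)


@dataclass
class FitResult:
    """Outcome of a CDS/MCDS/MRDS fit.

    Attributes follow the reporting columns of aerial bear-survey analyses:
    the fitted detection curve and its apex, the log likelihood and AIC of
    the distance component, the Horvitz-Thompson abundance of individuals
    (and of groups), its variance split into detection and encounter-rate
    components, and - for MRDS fits - the mark-recapture model with the
    mean/min/max apex detection probabilities.
    """

    spec: Any
    loglik: float
    n_params: int
    abundance: float | None = None
    abundance_groups: float | None = None
    se: float | None = None
    var_components: dict[str, float] = field(default_factory=dict)
    theta: float | None = None
    mr: Any = None
    mean_apex_p: float | None = None
    min_apex_p: float | None = None
    max_apex_p: float | None = None
    apex_p_se: float | None = None
    n_obs: int = 0
    left_truncation: float = 0.0
    w: float | None = None
    likelihood_type: str = "distance"
    vcov: np.ndarray | None = None
    converged: bool = True
    message: str = ""
    status: str = "ok"
    pa: np.ndarray | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def cv(self) -> float | None:
        if self.se is None or not self.abundance:
            return None
        return self.se / self.abundance

    def report(self) -> dict[str, Any]:
        """Machine-readable key-value summary (the survey-table column set)."""
        out = {
            "N_hat": self.abundance,
            "N_hat_groups": self.abundance_groups,
            "SE": self.se,
            "CV": self.cv,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "AIC": self.aic,
            "apex_m": self.theta,
            "mean_apex_p": self.mean_apex_p,
            "min_apex_p": self.min_apex_p,
            "max_apex_p": self.max_apex_p,
            "n_detections": self.n_obs,
            "left_truncation_m": self.left_truncation,
            "converged": self.converged,
            "status": self.status,
        }
        out.update({f"var_{k}": v for k, v in self.var_components.items()})
        out.update(self.extras)
        return out


def validate_observations(obs: pd.DataFrame, design: SurveyDesign | None = None,
                          w: float | None = None) -> pd.DataFrame:
    """Validate an observation table, returning it with canonical dtypes.

    Raises :class:`ValidationError` naming the offending column or row.
    Rows with ``det1 = det2 = 0`` are rejected: undetected groups cannot
    appear in a detection-conditioned table.
    """
    missing = [c for c in REQUIRED_OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValidationError(f"observations missing column(s): {', '.join(missing)}")
    obs = obs.reset_index(drop=True).copy()
    for col in ("distance", "size", "det1", "det2"):
        try:
            obs[col] = pd.to_numeric(obs[col])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"column {col!r} is not numeric: {exc}") from exc
    if w is None and design is not None:
        w = design.w

    def _bad(mask, msg):
        if mask.any():
            rows = [int(r) for r in np.flatnonzero(mask.to_numpy())[:5]]
            raise ValidationError(f"{msg} in row(s) {rows}")

    _bad(obs["distance"] < 0, "negative distance")
    if w is not None:
        _bad(obs["distance"] > w, f"distance beyond strip half-width w={w}")
    _bad(obs["size"] < 1, "group size below 1")
    _bad(~obs["det1"].isin((0, 1)) | ~obs["det2"].isin((0, 1)),
         "det1/det2 must be 0 or 1")
    _bad((obs["det1"] == 0) & (obs["det2"] == 0), "det1=det2=0 (undetected group)")
    if design is not None:
        known = set(design.transects["transect"])
        _bad(~obs["transect"].isin(known), "unknown transect id")
    return obs


def build_design_matrix(
    obs: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Expand covariate columns into a numeric design matrix.

    Numeric columns pass through; categorical/object columns are dummy-coded
    against the first level in sorted order (treatment coding).  Returns the
    (n, p) matrix and the expanded column names.
    """
    if not covariates:
        return np.empty((len(obs), 0)), []
    missing = [c for c in covariates if c not in obs.columns]
    if missing:
        raise ValidationError(f"covariate column(s) not found: {', '.join(missing)}")
    sub = obs[list(covariates)]
    expanded = pd.get_dummies(sub, drop_first=True, dtype=float)
    # get_dummies leaves numeric columns untouched and in place
    return expanded.to_numpy(dtype=float), list(expanded.columns)


# ---------------------------------------------------------------------------
# delimited-text I/O (CSV, UTF-8, "." decimal)

def read_observations(path: str | Path, design: SurveyDesign | None = None,
                      w: float | None = None) -> pd.DataFrame:
    return validate_observations(pd.read_csv(path), design=design, w=w)


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    obs.to_csv(path, index=False)


def read_transects(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path)
    missing = [c for c in ("transect", "length_km") if c not in t.columns]
    if missing:
        raise ValidationError(f"transects missing column(s): {', '.join(missing)}")
    return t


def write_transects(transects: pd.DataFrame, path: str | Path) -> None:
    transects.to_csv(path, index=False)
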