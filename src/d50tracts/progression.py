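"""Sigmoidal (D50) disease-progression model for ALS functional decline.

The model describes a patient's ALSFRS-R trajectory as a logistic state
transition from full health (48 points) to complete functional loss::

    cFS(t) = 48 / (1 + exp((t - D50) / dx))

where ``D50`` is the time in months from symptom onset at which half of the
functionality is lost (cFS = 24) and ``dx`` is the time constant of the
decline.  The closed form is the unique symmetric logistic satisfying the
model's stated anchors (full-health upper asymptote of 48 points, half
functionality at ``t = D50``, ``dx`` acting as the slope time constant); it is
a reconstruction, since only the anchors are published.

Derived descriptors:

* ``cFL(t) = -d cFS/dt`` — calculated functional loss, reported as a positive
  rate in points lost per month (peaks at ``48 / (4 dx)`` at ``t = D50``);
* ``rD50(t) = t / (2 D50)`` — an open-ended linear reference scale with 0 at
  symptom onset and 0.5 at the half-functionality time point (also a
  reconstruction from those two anchors);
* disease phases from rD50: semistable Phase I (rD50 < 0.25), early
  progressive Phase II (0.25 <= rD50 < 0.5), merged late Phases III/IV
  (rD50 >= 0.5);
* disease aggressiveness: high iff D50 < 30 months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FULL_HEALTH_SCORE",
    "DAYS_PER_MONTH",
    "AGGRESSIVENESS_CUTOFF_MONTHS",
    "D50_RELIABILITY_MAX_MONTHS",
    "MRI_PAIRING_WINDOW_DAYS",
    "PHASE_I",
    "PHASE_II",
    "PHASE_III_IV",
    "InvalidParameterError",
    "InsufficientDataError",
    "AlsfrsObservation",
    "PatientRecord",
    "D50Fit",
    "DiseaseState",
    "FilterReport",
    "D50CurveModel",
    "cfs_curve",
    "cfl_curve",
    "rd50_at",
    "assign_phase",
    "classify_aggressiveness",
    "progression_rate",
    "fit_d50",
    "state_at",
    "apply_inclusion_filters",
    "pair_alsfrs_to_mri",
    "cfs_residual_summary",
    "summarize_cohort",
    "load_cohort",
    "fit_cohort",
    "fits_table",
]

#: ALSFRS-R total score of a fully healthy individual.
FULL_HEALTH_SCORE = 48

#: Mean Gregorian month length used to convert day intervals to months.
DAYS_PER_MONTH = 30.4375

#: D50 below this many months classifies the disease course as aggressive.
AGGRESSIVENESS_CUTOFF_MONTHS = 30.0

#: Fits with D50 above this are considered unreliable and excluded.
D50_RELIABILITY_MAX_MONTHS = 100.0

#: An ALSFRS-R assessment within this many days of the MRI counts as paired.
MRI_PAIRING_WINDOW_DAYS = 10.0

PHASE_I = "I"
PHASE_II = "II"
PHASE_III_IV = "III_IV"

# fitting box constraints and derived-ratio initialisation constant
_D50_BOUNDS = (0.5, 200.0)
_DX_BOUNDS = (0.25, 100.0)
_DX_INIT_RATIO = 2.5


class InvalidParameterError(ValueError):
    """Model parameter outside its admissible domain."""


class InsufficientDataError(ValueError):
    """Too few observations to attempt a fit or summary."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlsfrsObservation:
    """One ALSFRS-R assessment: months since symptom onset and total score."""

    t_months: float
    score: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_months) or self.t_months < 0:
            raise InvalidParameterError(
                f"t_months must be finite and >= 0, got {self.t_months}"
            )
        if not 0 <= self.score <= FULL_HEALTH_SCORE:
            raise InvalidParameterError(
                f"score must be within [0, {FULL_HEALTH_SCORE}], got {self.score}"
            )


@dataclass
class PatientRecord:
    """Demographics plus the longitudinal ALSFRS-R record of one patient."""

    id: str
    age_at_mri: float
    sex: str
    onset_type: str
    mri_t_months: float
    observations: list[AlsfrsObservation] = field(default_factory=list)
    handedness: str = "unknown"
    group: str = "patient"

    def __post_init__(self) -> None:
        if self.mri_t_months < 0:
            raise InvalidParameterError("mri_t_months must be >= 0")
        self.observations = sorted(self.observations, key=lambda o: o.t_months)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.t_months for o in self.observations], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array([o.score for o in self.observations], dtype=float)


@dataclass(frozen=True)
class D50Fit:
    """Fitted sigmoid parameters with fit diagnostics."""

    d50: float
    dx: float
    n_obs: int
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.d50 <= 0 or self.dx <= 0:
            raise InvalidParameterError("d50 and dx must be positive")
        if self.rss < 0:
            raise InvalidParameterError("rss must be >= 0")


@dataclass(frozen=True)
class DiseaseState:
    """rD50 / cFS / cFL / phase evaluated at a single time point."""

    t_months: float
    rd50: float
    cfs: float
    cfl: float
    phase: str


@dataclass
class FilterReport:
    """Outcome of the cohort reliability filter: who is in and why not."""

    included: list[str]
    excluded: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# model curves and derived parameters
# ---------------------------------------------------------------------------


def _check_params(d50: float, dx: float) -> None:
    if not (d50 > 0):
        raise InvalidParameterError(f"d50 must be > 0, got {d50}")
    if not (dx > 0):
        raise InvalidParameterError(f"dx must be > 0, got {dx}")


def cfs_curve(t, d50: float, dx: float):
    """Calculated functional state (points) at time ``t`` months from onset.

    Strictly decreasing in ``t``; maps the real line onto (0, 48) and equals
    24 exactly at ``t = d50``.
    """
    _check_params(d50, dx)
    t = np.asarray(t, dtype=float)
    out = FULL_HEALTH_SCORE * expit(-(t - d50) / dx)
    return out if out.ndim else float(out)


def cfl_curve(t, d50: float, dx: float):
    """Calculated functional loss (points lost per month) at time ``t``.

    The negative analytic derivative of :func:`cfs_curve`, reported as a
    positive rate; symmetric about and maximal (``48 / (4 dx)``) at
    ``t = d50``.
    """
    _check_params(d50, dx)
    t = np.asarray(t, dtype=float)
    s = expit(-(t - d50) / dx)
    out = FULL_HEALTH_SCORE / dx * s * (1.0 - s)
    return out if out.ndim else float(out)


def rd50_at(t, d50: float):
    """Relative D50: elapsed time normalised so 0 is onset and 0.5 is D50."""
    _check_params(d50, 1.0)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0 for rd50")
    out = t / (2.0 * d50)
    return out if out.ndim else float(out)


def assign_phase(rd50: float) -> str:
    """Disease phase from rD50 (half-open intervals, boundaries go up)."""
    if rd50 < 0:
        raise InvalidParameterError(f"rd50 must be >= 0, got {rd50}")
    if rd50 < 0.25:
        return PHASE_I
    if rd50 < 0.5:
        return PHASE_II
    return PHASE_III_IV


def classify_aggressiveness(
    d50: float, cutoff: float = AGGRESSIVENESS_CUTOFF_MONTHS
) -> str:
    """``"high"`` iff D50 < cutoff (strict), else ``"low"``."""
    _check_params(d50, 1.0)
    return "high" if d50 < cutoff else "low"


def progression_rate(score: float, duration_months: float) -> float:
    """Linear progression rate (48 - ALSFRS-R) / symptom duration."""
    if not 0 <= score <= FULL_HEALTH_SCORE:
        raise InvalidParameterError(f"score outside [0, 48]: {score}")
    if duration_months <= 0:
        raise InvalidParameterError("duration must be > 0 months")
    return (FULL_HEALTH_SCORE - score) / duration_months


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class D50CurveModel(RegressorMixin, BaseEstimator):
    """Least-squares estimator of the sigmoidal decline curve of one patient.

    Parameters
    ----------
    d50_bounds, dx_bounds : tuple of float
        Box constraints (months) for the optimiser.
    n_starts : int
        Number of multi-start initialisations (deterministically jittered
        around the heuristic start) to reduce local-minimum risk.
    xtol : float
        Parameter convergence tolerance passed to the optimiser.

    Attributes
    ----------
    d50_ : float
        Months from symptom onset to half functionality (cFS = 24).
    dx_ : float
        Time constant of the decline (months).
    rss_ : float
        Residual sum of squares (points^2) at the optimum.
    n_obs_ : int
        Number of observations used.
    converged_ : bool
        False when the optimiser failed or the data carry no decline signal
        (all scores at full health).
    """

    def __init__(
        self,
        d50_bounds: tuple[float, float] = _D50_BOUNDS,
        dx_bounds: tuple[float, float] = _DX_BOUNDS,
        n_starts: int = 3,
        xtol: float = 1e-10,
    ) -> None:
        self.d50_bounds = d50_bounds
        self.dx_bounds = dx_bounds
        self.n_starts = n_starts
        self.xtol = xtol

    # -- initialisation heuristics ---------------------------------------

    def _initial_d50(self, t: np.ndarray, y: np.ndarray) -> float:
        """Linear interpolation of the score-24 crossing; fallback 1.5x last t."""
        half = FULL_HEALTH_SCORE / 2.0
        below = np.nonzero(y <= half)[0]
        if below.size and below[0] > 0:
            j = below[0]
            t0, t1 = t[j - 1], t[j]
            y0, y1 = y[j - 1], y[j]
            if y0 != y1:
                return float(t0 + (y0 - half) * (t1 - t0) / (y0 - y1))
            return float(0.5 * (t0 + t1))
        if below.size:  # already past half functionality at first visit
            return float(max(t[0], 1.0) * 0.5) or 1.0
        return float(t[-1] * 1.5) if t[-1] > 0 else 1.0

    def fit(self, X, y) -> "D50CurveModel":
        """Fit (d50, dx) to assessment times ``X`` (months) and scores ``y``."""
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("times and scores must have equal length")
        if t.size < 2 or np.unique(t).size < 2:
            raise InsufficientDataError(
                "at least two assessments at distinct times are required"
            )
        if np.any(y < 0) or np.any(y > FULL_HEALTH_SCORE):
            raise InvalidParameterError("scores must lie within [0, 48]")

        no_signal = bool(np.all(y == FULL_HEALTH_SCORE))

        lo = np.array([self.d50_bounds[0], self.dx_bounds[0]])
        hi = np.array([self.d50_bounds[1], self.dx_bounds[1]])
        d50_0 = float(np.clip(self._initial_d50(t, y), lo[0], hi[0]))
        dx_0 = float(np.clip(d50_0 / _DX_INIT_RATIO, lo[1], hi[1]))

        if no_signal:
            # a flat full-health record carries no decline information: the
            # optimum runs away along the d50 axis, so return the heuristic
            # start flagged as non-converged instead of optimising
            self.d50_, self.dx_ = d50_0, dx_0
            self.rss_ = float(np.sum((cfs_curve(t, d50_0, dx_0) - y) ** 2))
            self.n_obs_ = int(t.size)
            self.converged_ = False
            return self

        def residuals(p: np.ndarray) -> np.ndarray:
            return cfs_curve(t, p[0], p[1]) - y

        # deterministic multiplicative jitter keeps refits reproducible
        jitters = [1.0, 0.5, 1.8][: max(1, self.n_starts)]
        best = None
        best_cost = np.inf
        any_success = False
        for jit in jitters:
            x0 = np.clip([d50_0 * jit, dx_0 * jit], lo, hi)
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                xtol=self.xtol,
                ftol=self.xtol,
                gtol=None,
                method="trf",
            )
            if not np.all(np.isfinite(res.x)):
                continue
            any_success = any_success or res.success
            if best is None or res.cost < best_cost:
                best, best_cost = res, res.cost

        if best is None:
            self.d50_, self.dx_ = d50_0, dx_0
            self.rss_ = float(np.sum((cfs_curve(t, d50_0, dx_0) - y) ** 2))
            self.n_obs_ = int(t.size)
            self.converged_ = False
            return self

        self.d50_ = float(best.x[0])
        self.dx_ = float(best.x[1])
        self.rss_ = float(2.0 * best.cost)
        self.n_obs_ = int(t.size)
        self.converged_ = bool(any_success)
        return self

    def predict(self, X):
        """Calculated functional state at times ``X`` (months)."""
        return cfs_curve(np.asarray(X, dtype=float).ravel(), self.d50_, self.dx_)

    def to_fit(self) -> D50Fit:
        return D50Fit(
            d50=self.d50_,
            dx=self.dx_,
            n_obs=self.n_obs_,
            rss=self.rss_,
            converged=self.converged_,
        )


def fit_d50(
    observations: Sequence[AlsfrsObservation] | Iterable[tuple[float, float]],
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    init: tuple[float, float] | None = None,
) -> D50Fit:
    """Fit the decline curve to a patient's observations.

    ``bounds`` is ((d50_lo, d50_hi), (dx_lo, dx_hi)); ``init`` overrides the
    heuristic start.  Raises :class:`InsufficientDataError` for fewer than two
    distinct assessment times.
    """
    obs = list(observations)
    if obs and isinstance(obs[0], AlsfrsObservation):
        t = np.array([o.t_months for o in obs], dtype=float)
        y = np.array([o.score for o in obs], dtype=float)
    else:
        arr = np.asarray(obs, dtype=float).reshape(-1, 2)
        t, y = arr[:, 0], arr[:, 1]
    model = D50CurveModel()
    if bounds is not None:
        model.set_params(d50_bounds=tuple(bounds[0]), dx_bounds=tuple(bounds[1]))
    if init is not None:
        model._initial_d50 = lambda *_: float(init[0])  # noqa: SLF001
    model.fit(t, y)
    return model.to_fit()


def state_at(fit: D50Fit, t: float) -> DiseaseState:
    """Bundle rD50, cFS, cFL and phase at one time point of a fitted course."""
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    r = rd50_at(t, fit.d50)
    return DiseaseState(
        t_months=float(t),
        rd50=r,
        cfs=cfs_curve(t, fit.d50, fit.dx),
        cfl=cfl_curve(t, fit.d50, fit.dx),
        phase=assign_phase(r),
    )


# ---------------------------------------------------------------------------
# cohort-level utilities
# ---------------------------------------------------------------------------


def apply_inclusion_filters(
    cohort: Sequence[PatientRecord],
    fits: dict[str, D50Fit | None],
    d50_max: float = D50_RELIABILITY_MAX_MONTHS,
    min_obs: int = 2,
) -> FilterReport:
    """Reliability filter: drop failed fits, sparse records and slow fits.

    Exclusion reasons are ``too_few_scores`` (fewer than ``min_obs``
    assessments), ``fit_failed`` (no fit or non-converged) and
    ``d50_above_max`` (fitted D50 exceeding ``d50_max`` months).  The included
    and excluded id sets always partition the input cohort.
    """
    included: list[str] = []
    excluded: list[tuple[str, str]] = []
    for rec in cohort:
        if len(rec.observations) < min_obs:
            excluded.append((rec.id, "too_few_scores"))
            continue
        fit = fits.get(rec.id)
        if fit is None or not fit.converged:
            excluded.append((rec.id, "fit_failed"))
            continue
        if fit.d50 > d50_max:
            excluded.append((rec.id, "d50_above_max"))
            continue
        included.append(rec.id)
    return FilterReport(included=included, excluded=excluded)


def pair_alsfrs_to_mri(
    patient: PatientRecord, window_days: float = MRI_PAIRING_WINDOW_DAYS
) -> AlsfrsObservation | None:
    """The assessment closest to the MRI date, if within the pairing window.

    Ties between an equidistant earlier and later assessment go to the
    earlier one (the pre-MRI state is causally prior).  Returns ``None``
    when no assessment falls within ``window_days`` of the MRI.
    """
    if not patient.observations:
        return None
    window_months = window_days / DAYS_PER_MONTH
    best: AlsfrsObservation | None = None
    best_delta = np.inf
    for obs in patient.observations:  # sorted: earlier obs wins ties via <
        delta = abs(obs.t_months - patient.mri_t_months)
        if delta < best_delta - 1e-12:
            best, best_delta = obs, delta
    if best is not None and best_delta <= window_months + 1e-12:
        return best
    return None


def cfs_residual_summary(patient: PatientRecord, fit: D50Fit) -> float:
    """Mean difference between the fitted curve and the observed scores.

    Positive values mean the curve runs above the patient's actual scores.
    """
    if not patient.observations:
        raise InsufficientDataError("patient has no observations")
    pred = cfs_curve(patient.times, fit.d50, fit.dx)
    return float(np.mean(pred - patient.scores))


def _lilliefors_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Normality screen used to pick mean/SD vs median/IQR summaries."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.std(x) == 0:
        return True
    _, p = lilliefors(x, dist="norm")
    return bool(p > alpha)


def summarize_cohort(
    table: pd.DataFrame,
    categorical: Sequence[str] = ("sex", "onset_type", "handedness", "phase", "aggressiveness", "group"),
) -> pd.DataFrame:
    """Cohort summary table in the style of a clinical demographics table.

    Continuous variables are summarised as mean +/- SD when a Lilliefors test
    does not reject normality, otherwise as median +/- IQR; the observed range
    is always attached.  Categorical variables are reported as counts and
    percentages per level.
    """
    if table.empty:
        raise InsufficientDataError("empty cohort")
    rows: list[dict] = []
    n = len(table)
    for col in table.columns:
        vals = table[col].dropna()
        if col in categorical or vals.dtype == object or vals.dtype == bool:
            counts = vals.value_counts()
            for level, cnt in counts.items():
                rows.append(
                    {
                        "variable": col,
                        "level": str(level),
                        "summary": "count_pct",
                        "center": float(cnt),
                        "spread": 100.0 * cnt / n,
                        "min": np.nan,
                        "max": np.nan,
                    }
                )
            continue
        x = vals.to_numpy(dtype=float)
        if x.size == 0:
            continue
        if _lilliefors_normal(x):
            center, spread, kind = float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0, "mean_sd"
        else:
            q1, q3 = np.percentile(x, [25, 75])
            center, spread, kind = float(np.median(x)), float(q3 - q1), "median_iqr"
        rows.append(
            {
                "variable": col,
                "level": "",
                "summary": kind,
                "center": center,
                "spread": spread,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------


def load_cohort(clinical: pd.DataFrame, demographics: pd.DataFrame) -> list[PatientRecord]:
    """Assemble patient records from long-format clinical + demographic tables.

    ``clinical`` columns: patient_id, t_months, alsfrs_r.
    ``demographics`` columns: patient_id, age_at_mri, sex, onset_type,
    mri_t_months and optionally handedness, group.
    """
    records: list[PatientRecord] = []
    obs_by_id: dict[str, list[AlsfrsObservation]] = {}
    for row in clinical.itertuples(index=False):
        obs_by_id.setdefault(str(row.patient_id), []).append(
            AlsfrsObservation(t_months=float(row.t_months), score=int(row.alsfrs_r))
        )
    for row in demographics.itertuples(index=False):
        pid = str(row.patient_id)
        records.append(
            PatientRecord(
                id=pid,
                age_at_mri=float(row.age_at_mri),
                sex=str(row.sex),
                onset_type=str(row.onset_type),
                mri_t_months=float(row.mri_t_months),
                observations=obs_by_id.get(pid, []),
                handedness=str(getattr(row, "handedness", "unknown")),
                group=str(getattr(row, "group", "patient")),
            )
        )
    return records


def fit_cohort(records: Sequence[PatientRecord]) -> dict[str, D50Fit | None]:
    """Fit every patient with enough data; map id -> fit (None if unfittable)."""
    fits: dict[str, D50Fit | None] = {}
    for rec in records:
        try:
            fits[rec.id] = fit_d50(rec.observations)
        except (InsufficientDataError, InvalidParameterError):
            fits[rec.id] = None
    return fits


def fits_table(
    records: Sequence[PatientRecord], fits: dict[str, D50Fit | None]
) -> pd.DataFrame:
    """Per-patient fit results evaluated at the MRI time point."""
    rows = []
    for rec in records:
        fit = fits.get(rec.id)
        row: dict = {"patient_id": rec.id}
        if fit is None:
            row.update(
                d50=np.nan, dx=np.nan, n_obs=len(rec.observations), rss=np.nan,
                converged=False, rd50_at_mri=np.nan, cfs_at_mri=np.nan,
                cfl_at_mri=np.nan, phase="", aggressiveness="",
            )
        else:
            st = state_at(fit, rec.mri_t_months)
            row.update(
                d50=fit.d50, dx=fit.dx, n_obs=fit.n_obs, rss=fit.rss,
                converged=fit.converged, rd50_at_mri=st.rd50, cfs_at_mri=st.cfs,
                cfl_at_mri=st.cfl, phase=st.phase,
                aggressiveness=classify_aggressiveness(fit.d50),
            )
        rows.append(row)
    return pd.DataFrame(rows)
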