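"""Log2-linear growth modelling and lesion-fate classification.

A lesion's volume trajectory V(t) (um^3, biweekly sessions) is log2 transformed
and fit by ordinary least squares, log2 V = a + b * t with t in weeks. The fate
rule then reads, in order:

1. regressing  — endpoint volume <= 25% of the peak volume
   (complete if the endpoint is below the detection floor, else partial);
2. progressing — r^2 > 0.5 and b > 0.1;
3. stable      — everything else.

Regression is tested before progression: a lesion that grew and then collapsed
meets the explicit endpoint/peak criterion regardless of fit quality. Weekly
percent growth is the back-transformed slope, (2^b - 1) * 100.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .types import FateLabel, FitResult, InsufficientDataError

__all__ = [
    "fit_log2_linear",
    "classify_fate",
    "weekly_growth_percent",
    "cohort_fate_summary",
    "LesionFateClassifier",
]


def fit_log2_linear(weeks, volumes, censored=None) -> FitResult:
    """OLS fit of log2(volume) on week over uncensored points.

    Parameters
    ----------
    weeks : array-like
        Strictly increasing session times in weeks.
    volumes : array-like
        Volumes in um^3, strictly positive where uncensored.
    censored : array-like of bool, optional
        Points below the detection floor; excluded from the fit.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 uncensored points remain.
    """
    weeks = np.asarray(weeks, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if weeks.shape != volumes.shape or weeks.ndim != 1:
        raise ValueError("weeks and volumes must be 1D arrays of equal length")
    if np.any(np.diff(weeks) <= 0):
        raise ValueError("weeks must be strictly increasing")
    keep = np.ones(weeks.size, dtype=bool)
    if censored is not None:
        keep = ~np.asarray(censored, dtype=bool)
    w, v = weeks[keep], volumes[keep]
    if w.size < 3:
        raise InsufficientDataError(f"need >= 3 uncensored points to fit, got {w.size}")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("uncensored volumes must be positive and finite")
    y = np.log2(v)
    X = np.column_stack([np.ones_like(w), w])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 0.0  # zero-variance response convention
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
    return FitResult(a=a, b=b, r2=r2, n_points=int(w.size))


def classify_fate(
    weeks,
    volumes,
    censored=None,
    fit: FitResult | None = None,
    r2_min: float = 0.5,
    b_min: float = 0.1,
    endpoint_frac: float = 0.25,
    detection_floor: float = 0.0,
) -> FateLabel:
    """Assign exactly one fate label to a trajectory.

    ``peak`` is the maximum observed volume, ``endpoint`` the last session;
    a censored endpoint counts as below the detection floor.
    """
    weeks = np.asarray(weeks, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    cens = (
        np.zeros(weeks.size, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    obs = volumes[~cens]
    if obs.size == 0:
        raise InsufficientDataError("trajectory has no uncensored observations")
    peak = float(obs.max())
    endpoint = 0.0 if cens[-1] else float(volumes[-1])
    ratio = min(endpoint / peak, 1.0) if peak > 0 else 0.0
    if ratio <= endpoint_frac:
        label = "regressing_complete" if endpoint < detection_floor else "regressing_partial"
        return FateLabel(label=label, peak_volume=peak, endpoint_ratio=ratio)
    if fit is None:
        fit = fit_log2_linear(weeks, volumes, cens)
    if fit.r2 > r2_min and fit.b > b_min:
        return FateLabel(label="progressing", peak_volume=peak, endpoint_ratio=ratio)
    return FateLabel(label="stable", peak_volume=peak, endpoint_ratio=ratio)


def weekly_growth_percent(b) -> float:
    """Back-transform a log2 slope per week into percent volume growth per week."""
    return (np.power(2.0, b) - 1.0) * 100.0


def cohort_fate_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of per-mouse fate proportions.

    ``labels`` needs columns ``mouse_id`` and ``label``. Partial and complete
    regression are pooled into ``regressing``. Fractions are computed per mouse
    first, then averaged without weighting across mice (SD uses ddof=1; a
    single mouse reports SD 0). Mice with zero lesions are excluded with a
    warning when present as categories.

    Returns
    -------
    DataFrame indexed by fate with columns ``mean_pct`` and ``sd_pct``.
    """
    if labels.empty:
        raise ValueError("need at least one labelled lesion")
    df = labels.copy()
    df["fate"] = df["label"].str.replace(r"regressing_(partial|complete)", "regressing", regex=True)
    counts = df.groupby("mouse_id")["fate"].value_counts().unstack(fill_value=0)
    for fate in ("progressing", "regressing", "stable"):
        if fate not in counts:
            counts[fate] = 0
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} mice with zero lesions", stacklevel=2)
        counts = counts[~empty]
        totals = totals[~empty]
    frac = counts[["progressing", "regressing", "stable"]].div(totals, axis=0) * 100.0
    sd = frac.std(ddof=1).fillna(0.0) if len(frac) > 1 else frac.iloc[0] * 0.0
    return pd.DataFrame({"mean_pct": frac.mean(), "sd_pct": sd})


class LesionFateClassifier(BaseEstimator):
    """Fit log2-linear growth models per lesion and classify fate.

    A rule-based classifier over lesion volume trajectories. ``fit`` consumes a
    long-format trajectory table (columns ``mouse_id``, ``lesion_id``, ``week``,
    ``volume_um3`` and optional ``censored``) and exposes ``results_`` with one
    row per lesion: fitted intercept/slope/r^2, peak volume, endpoint ratio,
    weekly percent growth and the fate label.

    Parameters mirror the published decision rule: ``r2_min`` 0.5, ``b_min``
    0.1 (log2 per week), ``endpoint_frac`` 0.25, plus the detection floor that
    separates complete from partial regression and the minimum number of
    uncensored sessions required to fit.
    """

    def __init__(
        self,
        r2_min: float = 0.5,
        b_min: float = 0.1,
        endpoint_frac: float = 0.25,
        detection_floor: float = 0.0,
        min_points: int = 3,
    ):
        self.r2_min = r2_min
        self.b_min = b_min
        self.endpoint_frac = endpoint_frac
        self.detection_floor = detection_floor
        self.min_points = min_points

    def _classify_one(self, group: pd.DataFrame) -> dict:
        group = group.sort_values("week")
        weeks = group["week"].to_numpy(dtype=float)
        vols = group["volume_um3"].to_numpy(dtype=float)
        cens = (
            group["censored"].to_numpy(dtype=bool)
            if "censored" in group
            else np.zeros(len(group), dtype=bool)
        )
        fit = fit_log2_linear(weeks, vols, cens)
        lab = classify_fate(
            weeks,
            vols,
            cens,
            fit=fit,
            r2_min=self.r2_min,
            b_min=self.b_min,
            endpoint_frac=self.endpoint_frac,
            detection_floor=self.detection_floor,
        )
        return {
            "a": fit.a,
            "b": fit.b,
            "r2": fit.r2,
            "n_points": fit.n_points,
            "peak_um3": lab.peak_volume,
            "endpoint_ratio": lab.endpoint_ratio,
            "weekly_growth_pct": weekly_growth_percent(fit.b),
            "label": lab.label,
        }

    def fit(self, X: pd.DataFrame, y=None):  # noqa: ARG002
        """Fit growth models and assign labels for every lesion in ``X``."""
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        rows = []
        for (mouse, lesion), group in X.groupby(["mouse_id", "lesion_id"], sort=True):
            rows.append({"mouse_id": mouse, "lesion_id": lesion, **self._classify_one(group)})
        self.results_ = pd.DataFrame(rows)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fate label per lesion of ``X`` (same grouping as ``fit``)."""
        labels = [
            self._classify_one(group)["label"]
            for _, group in X.groupby(["mouse_id", "lesion_id"], sort=True)
        ]
        return np.asarray(labels, dtype=object)

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X, y).results_["label"].to_numpy(dtype=object)

    def summary(self) -> pd.DataFrame:
        """Cohort fate mix (mean +/- SD of per-mouse proportions)."""
        return cohort_fate_summary(self.results_)
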