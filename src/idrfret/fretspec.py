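"""Plate-reader and spectral FRET analysis.

Covers the population-level readouts of a ratiometric biosensor:
per-well DxAm/DxDm ratios normalized to the untreated control mean,
emission-spectrum normalization at an anchor wavelength, in vitro
acceptor/donor band ratios, single-coefficient donor-bleedthrough
correction, a dose-response sensitivity score, and loess-style
time-course smoothing with a confidence band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    DivisionError,
    InsufficientDataError,
    InvalidParameterError,
    MissingControlError,
    NormalizationError,
    SpanError,
)

__all__ = [
    "EmissionSpectrum",
    "SensitivityScore",
    "fret_ratio_normalize",
    "normalize_spectrum",
    "band_ratio",
    "bleedthrough_correct",
    "dose_response_sensitivity",
    "smooth_timecourse",
]


@dataclass
class EmissionSpectrum:
    """Sampled fluorescence emission spectrum (wavelengths strictly increasing)."""

    wavelengths: np.ndarray  # nm
    intensities: np.ndarray  # au

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise InvalidParameterError("wavelengths and intensities must match")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise InvalidParameterError("intensities must be non-negative")


@dataclass
class SensitivityScore:
    """Slope of normalized FRET ratio vs concentration with a sign call.

    ``direction`` is "compaction" for slopes above the dead-band
    threshold (ratio rises as the chain compacts), "expansion" below the
    negative threshold, "none" inside the band.
    """

    slope: float
    direction: str
    r_squared: float
    stderr: float = float("nan")
    threshold: float = 0.01


def fret_ratio_normalize(
    wells: pd.DataFrame,
    control_label: str = "control",
    group_by: Optional[str] = None,
) -> pd.DataFrame:
    """Per-well DxAm/DxDm ratios normalized to the control-group mean.

    ``group_by`` optionally names a column (e.g. a plate identifier)
    within which the control reference mean is computed; by default one
    reference is used for the whole table.  The mean normalized ratio of
    the control group is exactly 1 by construction.
    """
    required = {"DxDm", "DxAm", "treatment"}
    missing = required - set(wells.columns)
    if missing:
        raise InvalidParameterError(f"missing columns: {sorted(missing)}")
    zero = wells["DxDm"] <= 0
    if zero.any():
        ids = wells.loc[zero, "well_id"].tolist() if "well_id" in wells else list(
            wells.index[zero]
        )
        raise DivisionError(f"DxDm is zero for wells {ids}")
    out = wells.copy()
    out["raw_ratio"] = out["DxAm"] / out["DxDm"]

    def _reference(df: pd.DataFrame) -> float:
        ctrl = df[df["treatment"] == control_label]
        if ctrl.empty:
            raise MissingControlError(
                f"no wells labelled {control_label!r} in group"
            )
        return float(ctrl["raw_ratio"].mean())

    if group_by is None:
        ref = _reference(out)
        out["reference_mean"] = ref
    else:
        refs = {k: _reference(g) for k, g in out.groupby(group_by)}
        out["reference_mean"] = out[group_by].map(refs)
    out["normalized_ratio"] = out["raw_ratio"] / out["reference_mean"]
    return out


def normalize_spectrum(spec: EmissionSpectrum, anchor: float = 515.0) -> EmissionSpectrum:
    """Divide a spectrum by its intensity at the anchor wavelength.

    The anchor is read at the nearest sampled wavelength (ties resolve
    to the lower wavelength), so e.g. anchor 514.6 on a 5 nm grid snaps
    to 515.
    """
    w = spec.wavelengths
    if anchor < w[0] or anchor > w[-1]:
        raise InvalidParameterError(
            f"anchor {anchor} nm outside sampled range [{w[0]}, {w[-1]}]"
        )
    idx = int(np.argmin(np.abs(w - anchor)))  # first minimum = lower wavelength
    ref = spec.intensities[idx]
    if ref == 0:
        raise NormalizationError(f"zero intensity at anchor sample {w[idx]} nm")
    return EmissionSpectrum(wavelengths=w.copy(), intensities=spec.intensities / ref)


def band_ratio(
    spec: EmissionSpectrum,
    acceptor_band: Tuple[float, float] = (500.0, 600.0),
    donor_band: Tuple[float, float] = (460.0, 499.0),
) -> float:
    """Acceptor/donor band ratio: sum of sampled intensities inside the
    inclusive acceptor band divided by the sum inside the inclusive
    donor band."""
    w, inten = spec.wavelengths, spec.intensities
    acc = (w >= acceptor_band[0]) & (w <= acceptor_band[1])
    don = (w >= donor_band[0]) & (w <= donor_band[1])
    if not acc.any() or not don.any():
        raise InvalidParameterError("spectrum does not cover both bands")
    denom = inten[don].sum()
    if denom == 0:
        raise DivisionError("donor band sum is zero")
    return float(inten[acc].sum() / denom)


def bleedthrough_correct(
    table: pd.DataFrame,
    beta="estimate",
    photobleached_set: Optional[pd.DataFrame] = None,
):
    """Subtract donor bleedthrough from the DxAm channel.

    ``beta`` is the fraction of DxDm signal leaking into DxAm.  With
    ``beta="estimate"`` it is the least-squares slope of DxAm against
    DxDm on an acceptor-photobleached dataset, where all DxAm signal is
    bleedthrough; the fitted intercept (background) is reported but only
    the slope is applied.  Returns ``(corrected table, beta, intercept)``.
    """
    intercept = 0.0
    if beta == "estimate":
        if photobleached_set is None or len(photobleached_set) < 3:
            raise InsufficientDataError(
                "need >= 3 photobleached points to estimate bleedthrough"
            )
        x = photobleached_set["DxDm"].to_numpy(float)
        y = photobleached_set["DxAm"].to_numpy(float)
        if np.ptp(x) == 0:
            raise DegenerateDesignError("photobleached DxDm values are constant")
        beta, intercept = np.polyfit(x, y, 1)
    beta = float(beta)
    out = table.copy()
    out["DxAm"] = np.clip(out["DxAm"] - beta * out["DxDm"], 0.0, None)
    return out, beta, float(intercept)


def dose_response_sensitivity(
    results: pd.DataFrame,
    ratio_column: str = "normalized_ratio",
    concentration_column: str = "concentration_M",
    threshold: float = 0.01,
) -> SensitivityScore:
    """OLS slope of normalized ratio vs concentration with a sign dead-band.

    Positive slopes beyond the threshold are called "compaction" (the
    sensor ratio rises as the chain compacts under osmotic challenge),
    negative ones "expansion", and |slope| < threshold "none".
    """
    x = results[concentration_column].to_numpy(float)
    y = results[ratio_column].to_numpy(float)
    if len(np.unique(x)) < 3:
        if len(np.unique(x)) == 1:
            raise DegenerateDesignError("all concentrations identical")
        raise InvalidParameterError("need >= 3 distinct concentrations")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope > threshold:
        direction = "compaction"
    elif slope < -threshold:
        direction = "expansion"
    else:
        direction = "none"
    return SensitivityScore(
        slope=slope,
        direction=direction,
        r_squared=float(fit.rvalue**2),
        stderr=float(fit.stderr),
        threshold=threshold,
    )


def smooth_timecourse(
    times,
    values,
    span: float = 0.3,
    conf_level: float = 0.95,
):
    """Loess-style smoothing: tricube-weighted local linear regression.

    At each input time the ``ceil(span * n)`` nearest points are fitted
    by weighted least squares with tricube weights; the returned band is
    the pointwise ``conf_level`` interval from the local weighted
    residual variance and the equivalent-kernel norm.  Constant and
    exactly linear series are reproduced to machine precision (local
    linear fits are exact on degree <= 1 data).

    Returns ``(smoothed, lower, upper)`` arrays aligned with ``times``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidParameterError("times and values must be equal-length 1-D")
    n = t.size
    if n < 5:
        raise InsufficientDataError("need at least 5 points to smooth")
    if not 0 < span <= 1:
        raise InvalidParameterError("span must be in (0, 1]")
    k = int(np.ceil(span * n))
    if k < 3:
        raise SpanError(f"span {span} covers only {k} points; need >= 3")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    smoothed = np.empty(n)
    half = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = (1.0 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
            w[w <= 0] = 1e-12
        x = t[idx] - t[i]
        X = np.column_stack([np.ones(k), x])
        W = w
        XtW = X.T * W
        A = XtW @ X
        try:
            coef = np.linalg.solve(A, XtW @ y[idx])
            l_vec = np.linalg.solve(A, XtW)[0]  # equivalent kernel at x = 0
        except np.linalg.LinAlgError:
            coef = np.array([np.average(y[idx], weights=W), 0.0])
            l_vec = W / W.sum()
        smoothed[i] = coef[0]
        resid = y[idx] - X @ coef
        # local residual variance; k/(k-2) corrects for the 2 fitted parameters
        sigma2 = float(np.sum(W * resid**2) / np.sum(W)) * k / max(k - 2, 1)
        half[i] = z * np.sqrt(max(sigma2, 0.0) * np.sum(l_vec**2))
    return smoothed, smoothed - half, smoothed + half
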