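"""Performance and uncertainty statistics for volume prediction.

Definitions (obs = observed, pred = predicted, both in mm³):

* R      — Pearson correlation between obs and pred;
* SI     — scatter index, RMSE / mean(obs);
* MAPE   — 100 · mean(|obs − pred| / obs), percent;
* RMSRE  — sqrt(mean(((obs − pred) / obs)²));
* frac_re_lt — fraction of samples with relative error below a threshold
  (10% and 15% by default);
* SDFE   — standard deviation of the forecasting error pred − obs, mm³;
* WUB    — 95% uncertainty band of halfwidth 1.96·SDFE around the
  bias-corrected prediction; reported as halfwidth and total width;
* Taylor coordinates — (σ_pred/σ_obs, R, centered RMS difference), which
  satisfy cRMS² = σ_o² + σ_p² − 2σ_oσ_p·R.

All functions are pure; relative errors use observed values as denominator
and a zero observation is a hard error, never a silent skip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def _check_pair(observed, predicted, min_n: int = 2):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if len(obs) < min_n:
        raise ValueError(f"need at least {min_n} samples")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values")
    return obs, pred


@dataclass
class MetricSet:
    R: float
    SI: float
    MAPE: float  # percent
    RMSRE: float
    n: int
    frac_re_lt: dict[float, float] = field(default_factory=dict)
    r_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "R": self.R,
            "SI": self.SI,
            "MAPE": self.MAPE,
            "RMSRE": self.RMSRE,
            "n": self.n,
            "frac_re_lt": {f"{k:g}": v for k, v in self.frac_re_lt.items()},
            "r_defined": self.r_defined,
        }


def compute_metrics(
    observed, predicted, thresholds: tuple[float, ...] = (0.10, 0.15)
) -> MetricSet:
    obs, pred = _check_pair(observed, predicted)
    if np.any(obs == 0):
        raise ValueError("observed values must be non-zero for relative errors")
    err = obs - pred
    rel = np.abs(err) / np.abs(obs)
    rmse = math.sqrt(float(np.mean(err**2)))
    r_defined = bool(obs.std(ddof=0) > 0 and pred.std(ddof=0) > 0)
    r = float(np.corrcoef(obs, pred)[0, 1]) if r_defined else math.nan
    return MetricSet(
        R=r,
        SI=rmse / float(np.mean(obs)),
        MAPE=100.0 * float(np.mean(rel)),
        RMSRE=math.sqrt(float(np.mean(rel**2))),
        n=len(obs),
        frac_re_lt={t: float(np.mean(rel < t)) for t in thresholds},
        r_defined=r_defined,
    )


@dataclass
class UncertaintyReport:
    mean_error: float  # mm³, mean of pred − obs
    SDFE: float  # mm³
    wub_halfwidth: float  # mm³, 1.96 · SDFE
    wub_width: float  # mm³, 2 × halfwidth
    band_coverage: float  # fraction of observations inside the band
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_error": self.mean_error,
            "SDFE": self.SDFE,
            "wub_halfwidth": self.wub_halfwidth,
            "wub_width": self.wub_width,
            "band_coverage": self.band_coverage,
            "n": self.n,
        }


def uncertainty_band(observed, predicted) -> UncertaintyReport:
    """SDFE and the 95% width of uncertainty band (WUB).

    The band is centered at the bias-corrected prediction
    (pred − mean_error) with halfwidth 1.96·SDFE; coverage is the observed
    fraction of samples whose true value falls inside.
    """
    obs, pred = _check_pair(observed, predicted, min_n=3)
    e = pred - obs
    mean_error = float(np.mean(e))
    sdfe = float(np.std(e, ddof=1))
    half = 1.96 * sdfe
    inside = np.abs(obs - (pred - mean_error)) <= half
    return UncertaintyReport(
        mean_error=mean_error,
        SDFE=sdfe,
        wub_halfwidth=half,
        wub_width=2.0 * half,
        band_coverage=float(np.mean(inside)),
        n=len(obs),
    )


@dataclass
class TaylorStats:
    std_obs: float
    std_pred: float
    std_ratio: float  # σ_pred / σ_obs
    correlation: float
    crms: float  # centered RMS difference
    r_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "std_obs": self.std_obs,
            "std_pred": self.std_pred,
            "std_ratio": self.std_ratio,
            "correlation": self.correlation,
            "crms": self.crms,
            "r_defined": self.r_defined,
        }


def taylor_stats(observed, predicted) -> TaylorStats:
    """Taylor-diagram coordinates (population standard deviations).

    The law-of-cosines identity cRMS² = σ_o² + σ_p² − 2σ_oσ_p·R holds
    exactly with this ddof=0 convention.
    """
    obs, pred = _check_pair(observed, predicted)
    so = float(np.std(obs, ddof=0))
    sp = float(np.std(pred, ddof=0))
    if so == 0:
        raise ValueError("observed series has zero variance")
    r_defined = bool(sp > 0)
    r = float(np.corrcoef(obs, pred)[0, 1]) if r_defined else math.nan
    crms = float(
        np.sqrt(np.mean(((pred - pred.mean()) - (obs - obs.mean())) ** 2))
    )
    return TaylorStats(
        std_obs=so,
        std_pred=sp,
        std_ratio=sp / so,
        correlation=r,
        crms=crms,
        r_defined=r_defined,
    )
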