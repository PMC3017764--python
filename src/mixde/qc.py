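"""Spot-level quality filters, background correction and log2 transform.

Two data-acquisition criteria are applied to every spot channel reading:

* signal-to-noise ``s = (fg_mean - bg_mean) / bg_sd`` must exceed 1, and
* mean/median agreement ``r = min(fg_mean, fg_median) / max(fg_mean, fg_median)``
  must reach 0.85 (``>=`` by default; a strict ``>`` is available).

Passing spots get ``log2(fg_mean - bg_mean)``; failing spots are treated as
missing for modelling (the written tables print 0 for them).  A zero
background SD or a non-positive background-corrected intensity also fails the
spot.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


class DegenerateBackgroundError(ValueError):
    """Raised when a spot's background pixel SD is zero (s undefined)."""


def signal_to_noise(fg_mean: float, bg_mean: float, bg_sd: float) -> float:
    """Background-corrected intensity divided by the background pixel SD."""
    if bg_sd == 0:
        raise DegenerateBackgroundError("background SD is zero; s undefined")
    return (fg_mean - bg_mean) / bg_sd


def mean_median_agreement(fg_mean: float, fg_median: float) -> float:
    """Smaller of foreground mean/median divided by the larger, in (0, 1]."""
    if fg_mean <= 0 or fg_median <= 0:
        raise ValueError("foreground statistics must be positive")
    lo, hi = sorted((fg_mean, fg_median))
    return lo / hi


class SpotFilter(BaseEstimator, TransformerMixin):
    """Vectorised QC transformer over a spot table.

    Parameters
    ----------
    snr_threshold : float
        Spots must have ``s`` strictly greater than this (default 1).
    r_threshold : float
        Mean/median agreement threshold (default 0.85).
    r_strict : bool
        If True require ``r > r_threshold``; default is ``r >= r_threshold``,
        which retains boundary spots.
    """

    def __init__(self, snr_threshold: float = 1.0, r_threshold: float = 0.85,
                 r_strict: bool = False):
        self.snr_threshold = snr_threshold
        self.r_threshold = r_threshold
        self.r_strict = r_strict

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the QC table: per spot s, r, pass flag and log2 intensity."""
        if len(X) == 0:
            warnings.warn("empty spot table", stacklevel=2)
            out = X.copy()
            for col in ("s", "r", "passed", "log2_intensity"):
                out[col] = pd.Series(dtype=float)
            return out
        fg = X["fg_mean"].to_numpy(float)
        med = X["fg_median"].to_numpy(float)
        bg = X["bg_mean"].to_numpy(float)
        bg_sd = X["bg_sd"].to_numpy(float)

        corrected = fg - bg
        sd_ok = bg_sd > 0
        n_degenerate = int((~sd_ok).sum())
        if n_degenerate:
            logger.warning("%d spots with zero background SD failed QC",
                           n_degenerate)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(sd_ok, corrected / np.where(sd_ok, bg_sd, 1.0), np.nan)
            fg_ok = (fg > 0) & (med > 0)
            r = np.where(fg_ok,
                         np.minimum(fg, med) / np.maximum(fg, med), np.nan)

        s_pass = sd_ok & (s > self.snr_threshold)
        if self.r_strict:
            r_pass = fg_ok & (r > self.r_threshold)
        else:
            r_pass = fg_ok & (r >= self.r_threshold)
        passed = s_pass & r_pass & (corrected > 0)

        out = X.copy()
        out["s"] = s
        out["r"] = r
        out["passed"] = passed
        out["log2_intensity"] = np.where(passed, np.log2(
            np.where(passed, corrected, 1.0)), np.nan)
        logger.info("QC: %d/%d spots passed (%.1f%%)", int(passed.sum()),
                    len(out), 100.0 * passed.mean())
        return out


def apply_qc(spots: pd.DataFrame, snr_threshold: float = 1.0,
             r_threshold: float = 0.85, r_strict: bool = False) -> pd.DataFrame:
    """Functional wrapper around :class:`SpotFilter`."""
    return SpotFilter(snr_threshold=snr_threshold, r_threshold=r_threshold,
                      r_strict=r_strict).fit_transform(spots)


def channel_summary(qc: pd.DataFrame) -> pd.DataFrame:
    """Per-dye mean and SD of the background-corrected log2 intensities.

    Channels with fewer than two passing spots get NaN SD (mean too when
    empty); mirrors the study's reporting of channel-wise arithmetic mean
    and SD.
    """
    rows = []
    for dye in ("red", "green"):
        vals = qc.loc[(qc["dye"] == dye) & qc["passed"], "log2_intensity"]
        n = len(vals)
        rows.append({"dye": dye, "n": n,
                     "mean": vals.mean() if n else np.nan,
                     "sd": vals.std(ddof=1) if n >= 2 else np.nan})
    return pd.DataFrame(rows)
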