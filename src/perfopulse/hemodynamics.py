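"""Scan-level hemodynamic outcomes: V_mean and the velocity pulsatility index.

For every detected perforator the velocity waveform is read out at its
representative voxel over the cardiac cycle.  Two scan-level outcomes are
derived:

* ``V_mean`` -- the temporal mean of the average waveform over all vessels;
* ``vPI``   -- the velocity pulsatility index
  ``(V_max - V_min) / V_mean`` of the *mean normalized* curve, where each
  vessel's curve is first divided by its own temporal mean (so the mean of
  the averaged normalized curve is 1 by construction) and ``V_max``/``V_min``
  are the extrema of that averaged curve on the cardiac-phase grid.

Velocity magnitudes are used throughout: detection ranks by |velocity| and
flow direction carries no information for these outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pc_io import CinePCSeries
from .vessel_detection import VesselSet

log = logging.getLogger(__name__)

__all__ = [
    "WaveformStats",
    "extract_waveforms",
    "compute_v_mean",
    "compute_vpi",
    "normalized_mean_curve",
    "analyze_scan",
]


@dataclass
class WaveformStats:
    """Per-scan velocity-waveform summary."""

    curves: np.ndarray  # (n_vessels, n_phases), |velocity| in cm/s
    mean_curve: np.ndarray
    normalized_mean_curve: np.ndarray
    v_mean: float
    v_max: float  # max of the normalized mean curve (dimensionless)
    v_min: float
    vpi: float
    n_detected: int
    n_excluded: int = 0  # curves with nonpositive temporal mean, left out of vPI


def extract_waveforms(series: CinePCSeries, vessels: VesselSet) -> np.ndarray:
    """|velocity| over the cardiac cycle at each vessel's representative voxel.

    Returns an ``(n_vessels, n_phases)`` array in VesselSet order; an empty
    vessel set yields a ``(0, n_phases)`` array (logged).
    """
    v = np.abs(series.velocity())
    if vessels.n_detected == 0:
        log.warning("no vessels detected; returning empty waveform array")
        return np.empty((0, series.n_cardiac_phases))
    rows = vessels.table["row"].to_numpy()
    cols = vessels.table["col"].to_numpy()
    return v[:, rows, cols].T.copy()


def _validate_curves(curves: np.ndarray) -> np.ndarray:
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if curves.shape[0] < 1:
        raise ValueError("need at least one velocity curve")
    if curves.shape[1] < 2:
        raise ValueError("curves must span at least two cardiac phases")
    return curves


def compute_v_mean(curves: np.ndarray) -> float:
    """Temporal mean of the elementwise average of all vessel curves (cm/s)."""
    curves = _validate_curves(curves)
    return float(curves.mean(axis=0).mean())


def normalized_mean_curve(curves: np.ndarray) -> np.ndarray:
    """Average of the per-vessel curves each divided by its own temporal mean.

    Its temporal mean is 1 by construction, which is what makes the
    pulsatility index a pure shape measure.
    """
    curves = _validate_curves(curves)
    return _normalized_mean_curve(curves)[0]


def _normalized_mean_curve(curves: np.ndarray) -> tuple[np.ndarray, int]:
    means = curves.mean(axis=1)
    ok = means > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("excluding %d curve(s) with nonpositive temporal mean from vPI", n_excluded)
    if not ok.any():
        raise ValueError("no curve with positive temporal mean; vPI undefined")
    normalized = curves[ok] / means[ok, None]
    return normalized.mean(axis=0), n_excluded


def compute_vpi(curves: np.ndarray) -> float:
    """Velocity pulsatility index of the mean normalized curve.

    Each curve is divided by its own temporal mean, the normalized curves
    are averaged elementwise, and ``vPI = (max - min) / mean`` of that
    average; the mean equals 1 by the normalization, making vPI invariant
    to per-vessel velocity scale and to vessel duplication.
    """
    curves = _validate_curves(curves)
    mean_norm, _ = _normalized_mean_curve(curves)
    return float((mean_norm.max() - mean_norm.min()) / mean_norm.mean())


def analyze_scan(series: CinePCSeries, vessels: VesselSet) -> WaveformStats:
    """Extract waveforms and compute N_detected, V_mean and vPI for one scan."""
    curves = extract_waveforms(series, vessels)
    if curves.shape[0] == 0:
        nan_curve = np.full(series.n_cardiac_phases, np.nan)
        return WaveformStats(
            curves=curves,
            mean_curve=nan_curve,
            normalized_mean_curve=nan_curve,
            v_mean=float("nan"),
            v_max=float("nan"),
            v_min=float("nan"),
            vpi=float("nan"),
            n_detected=0,
        )
    mean_curve = curves.mean(axis=0)
    mean_norm, n_excluded = _normalized_mean_curve(curves)
    return WaveformStats(
        curves=curves,
        mean_curve=mean_curve,
        normalized_mean_curve=mean_norm,
        v_mean=float(mean_curve.mean()),
        v_max=float(mean_norm.max()),
        v_min=float(mean_norm.min()),
        vpi=float((mean_norm.max() - mean_norm.min()) / mean_norm.mean()),
        n_detected=int(curves.shape[0]),
        n_excluded=n_excluded,
    )
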