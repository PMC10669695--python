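"""Lesion-level measurement and inter-observer agreement.

A lesion VOI drawn on one parametric map is propagated (identity copy with a
grid/affine check) onto the co-registered maps, summarised by a whole-lesion
mean over valid voxels, and the three observers' measurements are averaged.
Inter-observer agreement is quantified with the two-way random-effects,
absolute-agreement, single-rater intraclass correlation coefficient
(McGraw & Wong ICC(A,1)) with its F-based 95% confidence interval, and
labelled with the conventional interpretation bands (poor < 0.2 ≤ fair
< 0.4 ≤ moderate < 0.6 ≤ substantial < 0.8 ≤ excellent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlignmentError",
    "MeasurementError",
    "IccResult",
    "propagate_voi",
    "whole_lesion_mean",
    "average_observers",
    "icc_two_way",
    "icc_band",
    "observer_measurements",
]


class AlignmentError(ValueError):
    """Source and target maps do not share a voxel grid."""


class MeasurementError(ValueError):
    """A lesion measurement could not be made."""


def propagate_voi(voi: np.ndarray, source_affine: np.ndarray,
                  target_shape: tuple[int, ...],
                  target_affine: np.ndarray) -> np.ndarray:
    """Replicate a VOI onto a co-registered map (identity copy after checks)."""
    if tuple(voi.shape) != tuple(target_shape):
        raise AlignmentError(
            f"grid mismatch: VOI {voi.shape} vs target {tuple(target_shape)}")
    if not np.allclose(source_affine, target_affine):
        raise AlignmentError("affine mismatch between source and target maps")
    return voi.copy()


def whole_lesion_mean(param_map: np.ndarray, voi: np.ndarray) -> float:
    """Arithmetic mean of a parametric map over the valid voxels of a VOI.

    Invalid (NaN) voxels are excluded; an empty or all-invalid VOI raises
    :class:`MeasurementError`.
    """
    if voi.shape != param_map.shape:
        raise AlignmentError("VOI and map shapes differ")
    values = param_map[voi.astype(bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise MeasurementError("VOI contains no valid voxels")
    return float(values.mean())


def average_observers(values: Sequence[float]) -> float:
    """Average exactly three finite observer measurements."""
    v = np.asarray(values, dtype=float)
    if v.shape != (3,):
        raise MeasurementError("exactly three observer measurements required")
    if not np.all(np.isfinite(v)):
        raise MeasurementError("observer measurement missing or non-finite")
    return float(v.mean())


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    model: str  # "absolute" or "consistency"


def icc_band(icc: float) -> str:
    """Interpretation band; boundary values go to the higher band."""
    if np.isnan(icc):
        return "undefined"
    if not -1.0 <= icc <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    if icc >= 0.8:
        return "excellent"
    if icc >= 0.6:
        return "substantial"
    if icc >= 0.4:
        return "moderate"
    if icc >= 0.2:
        return "fair"
    return "poor"


def icc_two_way(ratings: np.ndarray, model: str = "absolute",
                alpha: float = 0.05) -> IccResult:
    """Two-way random-effects single-rater ICC from the ANOVA mean squares.

    ``ratings`` is subjects × raters with no missing cells.  ``model`` is
    "absolute" (agreement, the default — radiologists are interchangeable)
    or "consistency".  Zero between-subject variance makes the coefficient
    undefined; it is reported as NaN.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must not contain missing cells")
    n, k = x.shape

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msb = ss_rows / (n - 1)          # between subjects
    msj = ss_cols / (k - 1)          # between raters
    mse = ss_err / ((n - 1) * (k - 1))

    if msb <= 0 or np.isclose(ss_rows, 0.0):
        return IccResult(float("nan"), float("nan"), float("nan"),
                         "undefined", model)

    if model == "consistency":
        icc = (msb - mse) / (msb + (k - 1) * mse)
        if mse == 0:
            return IccResult(float(icc), float(icc), float(icc),
                             icc_band(icc), model)
        f_obs = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif model == "absolute":
        icc = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
        if mse == 0 and msj == 0:
            return IccResult(float(icc), float(icc), float(icc),
                             icc_band(icc), model)
        # Satterthwaite df for the F-based interval
        fj = msj / mse if mse > 0 else np.inf
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b) and mse > 0:
            v = ((a * msj + b * mse) ** 2
                 / ((a * msj) ** 2 / (k - 1)
                    + (b * mse) ** 2 / ((n - 1) * (k - 1))))
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msb - f1 * mse)
                  / (f1 * (k * msj + (k * n - k - n) * mse) + n * msb))
            hi = (n * (f2 * msb - mse)
                  / (k * msj + (k * n - k - n) * mse + n * f2 * msb))
        else:
            lo = hi = icc
    else:
        raise ValueError("model must be 'absolute' or 'consistency'")

    icc = float(np.clip(icc, -1.0, 1.0))
    lo = float(np.clip(min(lo, icc), -1.0, 1.0))
    hi = float(np.clip(max(hi, icc), -1.0, 1.0))
    return IccResult(icc, lo, hi, icc_band(icc), model)


def observer_measurements(cohort, param_maps_by_patient: dict,
                          parameters: Sequence[str]) -> pd.DataFrame:
    """Tidy per-observer lesion means for a fitted synthetic cohort.

    Returns rows of (patient_id, grade, parameter, observer, value); the
    per-patient aggregate is obtained downstream via
    :func:`average_observers`.
    """
    rows = []
    for patient in cohort.patients:
        pm = param_maps_by_patient[patient.patient_id]
        for param in parameters:
            arr = pm.maps[param].copy()
            arr[~pm.valid] = np.nan
            for obs_idx, voi in enumerate(patient.observer_vois, 1):
                voi = propagate_voi(voi, patient.volume.affine,
                                    arr.shape, pm.affine)
                rows.append({
                    "patient_id": patient.patient_id,
                    "grade": patient.grade,
                    "parameter": param,
                    "observer": obs_idx,
                    "value": whole_lesion_mean(arr, voi),
                })
    return pd.DataFrame(rows)
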