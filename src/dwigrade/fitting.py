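"""Voxel-wise DWI parameter estimation.

Produces the six parametric maps (ADC, D, D_p, f, D_app, K_app) plus S0 from
a 4D DWI volume:

* ADC by the two-point closed form over b = 0 and 800 s/mm² implied by the
  mono-exponential model;
* (f, D, D_p) by bounded nonlinear least squares on the IVIM bi-exponential
  over the twelve b-values up to 800 s/mm², started from a segmented
  log-linear initialisation (high-b tail → D and f, fixed D_p start);
* (D_app, K_app) by bounded least squares on the DKI model in log-signal
  space over b = 0, 800, 1500, 2000 s/mm².

S0 is fixed to the measured b = 0 signal in both nonlinear fits (the models
are normalised ratios).  Estimates are constrained to the standard bounds;
an estimate that ends on a bound is snapped exactly onto it and flagged.
All fits are deterministic: identical inputs and config give identical
output bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .signal_models import (
    ADC_BOUNDS,
    D_BOUNDS,
    DAPP_BOUNDS,
    DP_BOUNDS,
    F_BOUNDS,
    KAPP_BOUNDS,
    BScheme,
    DkiParams,
    IvimParams,
)
from .volume import DwiVolume

__all__ = [
    "FitConfig",
    "VoxelFitResult",
    "ParamMaps",
    "fit_adc",
    "fit_ivim",
    "fit_dki",
    "fit_parameter_maps",
    "save_param_maps",
]

PARAM_NAMES = ("s0", "adc", "d", "dp", "f", "dapp", "kapp")


@dataclass(frozen=True)
class FitConfig:
    """Bounds, tolerances and initialisation settings for the voxel fits."""

    adc_bounds: tuple[float, float] = ADC_BOUNDS
    d_bounds: tuple[float, float] = D_BOUNDS
    dp_bounds: tuple[float, float] = DP_BOUNDS
    f_bounds: tuple[float, float] = F_BOUNDS
    dapp_bounds: tuple[float, float] = DAPP_BOUNDS
    kapp_bounds: tuple[float, float] = KAPP_BOUNDS
    #: segmented IVIM initialisation: log-linear fit over b >= this (s/mm²)
    segment_bmin: float = 200.0
    #: starting value for the pseudo-diffusion coefficient (mm²/s)
    dp_init: float = 10.0e-3
    max_iter: int = 400
    tol: float = 1e-15
    #: voxels with S0 at or below this are not fitted
    s0_threshold: float = 0.0
    # a coordinate ending within this fraction of its range from a bound is
    # a snap candidate (accepted only if the snapped point fits no worse)
    snap_frac: float = 1e-3

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class VoxelFitResult:
    """One voxel's estimate with convergence bookkeeping."""

    params: IvimParams | DkiParams
    converged: bool
    n_iterations: int
    residual_norm: float
    at_bound: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


def fit_adc(signal_at_b0: float, signal_at_b800: float, *,
            b: float = 800.0,
            bounds: tuple[float, float] = ADC_BOUNDS) -> float:
    """Two-point ADC (mm²/s): ln(S0/Sb)/b, clipped to the fitting bounds.

    Returns NaN for non-positive signals (the log is undefined).
    """
    if signal_at_b0 <= 0 or signal_at_b800 <= 0:
        return float("nan")
    adc = np.log(signal_at_b0 / signal_at_b800) / b
    return float(np.clip(adc, *bounds))


def _strict_interior(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    eps = 1e-9 * (hi - lo)
    return np.clip(x, lo + eps, hi - eps)


def _snap_to_bounds(
    x: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    ssr_of: Callable[[np.ndarray], float],
    snap_frac: float,
) -> tuple[np.ndarray, float, list[int]]:
    """Snap near-bound coordinates exactly onto the bound when not worse.

    Bounded trust-region solvers keep iterates strictly feasible, so a
    boundary optimum is returned a hair inside the box; this restores the
    exact clipped estimate the constraint implies.
    """
    x = np.clip(x, lo, hi)
    ssr = ssr_of(x)
    active: list[int] = []
    for i in range(x.size):
        rng = hi[i] - lo[i]
        for bound in (lo[i], hi[i]):
            if x[i] != bound and abs(x[i] - bound) <= snap_frac * rng:
                cand = x.copy()
                cand[i] = bound
                ssr_c = ssr_of(cand)
                if ssr_c <= ssr + 1e-12 * (1.0 + ssr):
                    x, ssr = cand, ssr_c
        if x[i] == lo[i] or x[i] == hi[i]:
            active.append(i)
    return x, ssr, active


def fit_ivim(signals: Sequence[float], scheme: BScheme,
             cfg: FitConfig | None = None) -> VoxelFitResult:
    """Fit (f, D, D_p) to the twelve-point IVIM signal decay of one voxel.

    ``signals`` must match ``scheme.ivim_subset`` in order; the first entry
    is the b = 0 signal, to which S0 is fixed.
    """
    cfg = cfg or FitConfig()
    b = scheme.b(scheme.ivim_subset)
    s = np.asarray(signals, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"expected {b.size} IVIM signals, got {s.size}")
    if np.any(s <= 0):
        raise ValueError("IVIM fitting requires strictly positive signals")
    s0 = s[0]
    if s0 <= cfg.s0_threshold:
        raise ValueError("b=0 signal at or below the fitting threshold")
    y = s / s0

    names = ("f", "d", "dp")
    lo = np.array([cfg.f_bounds[0], cfg.d_bounds[0], cfg.dp_bounds[0]])
    hi = np.array([cfg.f_bounds[1], cfg.d_bounds[1], cfg.dp_bounds[1]])

    if np.ptp(y) == 0.0:  # flat decay: no information on any rate
        params = IvimParams(s0=s0, f=0.0, d=0.0, dp=0.0)
        ssr = float(np.sum((1.0 - y) ** 2))
        return VoxelFitResult(params, converged=False, n_iterations=0,
                              residual_norm=ssr, at_bound=("f", "d", "dp"),
                              flags=("degenerate", "dp_unidentifiable"))

    # segmented start: at b >= ~200 the perfusion compartment has decayed, so
    # ln y is ~linear with slope -D and intercept ln(1 - f)
    tail = b >= cfg.segment_bmin
    slope, intercept = np.polyfit(b[tail], np.log(y[tail]), 1)
    d0 = -slope
    f0 = 1.0 - np.exp(intercept)
    x0 = _strict_interior(np.array([f0, d0, cfg.dp_init]), lo, hi)

    def resid(x: np.ndarray) -> np.ndarray:
        f, d, dp = x
        return (1.0 - f) * np.exp(-b * d) + f * np.exp(-b * dp) - y

    def ssr_of(x: np.ndarray) -> float:
        return float(np.sum(resid(x) ** 2))

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol,
                        max_nfev=cfg.max_iter)
    x, ssr, active = _snap_to_bounds(sol.x, lo, hi, ssr_of, cfg.snap_frac)
    flags = tuple()
    if x[0] == 0.0:  # no perfusion compartment: dp drops out of the model
        flags = ("dp_unidentifiable",)
    params = IvimParams(s0=s0, f=float(x[0]), d=float(x[1]), dp=float(x[2]))
    return VoxelFitResult(
        params,
        converged=bool(sol.status > 0) and not active,
        n_iterations=int(sol.nfev),
        residual_norm=ssr,
        at_bound=tuple(names[i] for i in active),
        flags=flags,
    )


def fit_dki(signals: Sequence[float], scheme: BScheme,
            cfg: FitConfig | None = None) -> VoxelFitResult:
    """Fit (D_app, K_app) in log-signal space over b = 0, 800, 1500, 2000."""
    cfg = cfg or FitConfig()
    b = scheme.b(scheme.dki_subset)
    s = np.asarray(signals, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"expected {b.size} DKI signals, got {s.size}")
    if np.any(s <= 0):
        raise ValueError("DKI fitting requires strictly positive signals")
    s0 = s[0]
    if s0 <= cfg.s0_threshold:
        raise ValueError("b=0 signal at or below the fitting threshold")
    ln_s0 = np.log(s0)
    y = np.log(s)

    names = ("dapp", "kapp")
    lo = np.array([cfg.dapp_bounds[0], cfg.kapp_bounds[0]])
    hi = np.array([cfg.dapp_bounds[1], cfg.kapp_bounds[1]])

    # quadratic start: ln S ≈ ln S0 − A·b + B·b² gives A → D_app, 6B/A² → K_app
    design = np.column_stack([-b[1:], b[1:] ** 2])
    coef, *_ = np.linalg.lstsq(design, y[1:] - ln_s0, rcond=None)
    a, bq = coef
    k0 = 6.0 * bq / (a * a) if abs(a) > 1e-12 else 0.5
    x0 = _strict_interior(np.array([a, k0]), lo, hi)

    def resid(x: np.ndarray) -> np.ndarray:
        dapp, kapp = x
        return ln_s0 - b * dapp + (b * dapp) ** 2 * kapp / 6.0 - y

    def ssr_of(x: np.ndarray) -> float:
        return float(np.sum(resid(x) ** 2))

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol,
                        max_nfev=cfg.max_iter)
    x, ssr, active = _snap_to_bounds(sol.x, lo, hi, ssr_of, cfg.snap_frac)
    params = DkiParams(s0=s0, dapp=float(x[0]), kapp=float(x[1]))
    return VoxelFitResult(
        params,
        converged=bool(sol.status > 0) and not active,
        n_iterations=int(sol.nfev),
        residual_norm=ssr,
        at_bound=tuple(names[i] for i in active),
    )


@dataclass
class ParamMaps:
    """Co-registered voxel maps of all fitted parameters.

    ``maps[name]`` is a 3D float array (NaN where invalid) for each of
    S0, ADC, D, D_p, f, D_app, K_app; ``valid`` marks fitted voxels and
    ``converged`` those whose nonlinear fits finished off all bounds.
    """

    maps: dict[str, np.ndarray]
    valid: np.ndarray
    converged: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        shapes |= {self.valid.shape, self.converged.shape}
        if len(shapes) != 1:
            raise ValueError("all parameter maps must share one grid shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.valid.shape

    def report(self) -> dict:
        return {
            "n_voxels": int(self.valid.size),
            "n_fitted": int(self.valid.sum()),
            "n_converged": int(self.converged.sum()),
        }


def fit_parameter_maps(volume: DwiVolume, mask: np.ndarray | None = None,
                       cfg: FitConfig | None = None) -> ParamMaps:
    """Apply all three voxel fits across a volume (optionally inside a mask).

    Voxels outside the mask, with S0 at or below the threshold, or with any
    non-positive signal in a fitted subset are marked invalid (NaN maps)
    rather than raising.
    """
    cfg = cfg or FitConfig()
    scheme = volume.scheme
    try:
        adc_idx = list(scheme.adc_subset)
        ivim_idx = list(scheme.ivim_subset)
        dki_idx = list(scheme.dki_subset)
    except ValueError as exc:
        raise ValueError(f"scheme lacks a required fitting subset: {exc}") from exc

    shape = volume.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match the volume grid")

    maps = {name: np.full(shape, np.nan) for name in PARAM_NAMES}
    valid = np.zeros(shape, dtype=bool)
    converged = np.zeros(shape, dtype=bool)

    needed = sorted(set(adc_idx) | set(ivim_idx) | set(dki_idx))
    for i, j, k in zip(*np.nonzero(mask)):
        sig = volume.data[i, j, k, :]
        if sig[0] <= cfg.s0_threshold or np.any(sig[needed] <= 0):
            continue
        ivim = fit_ivim(sig[ivim_idx], scheme, cfg)
        dki = fit_dki(sig[dki_idx], scheme, cfg)
        maps["s0"][i, j, k] = sig[0]
        maps["adc"][i, j, k] = fit_adc(sig[adc_idx[0]], sig[adc_idx[1]],
                                       bounds=cfg.adc_bounds)
        maps["f"][i, j, k] = ivim.params.f
        maps["d"][i, j, k] = ivim.params.d
        maps["dp"][i, j, k] = ivim.params.dp
        maps["dapp"][i, j, k] = dki.params.dapp
        maps["kapp"][i, j, k] = dki.params.kapp
        valid[i, j, k] = True
        converged[i, j, k] = ivim.converged and dki.converged

    return ParamMaps(maps=maps, valid=valid, converged=converged,
                     affine=volume.affine)


def save_param_maps(pm: ParamMaps, outdir: str | Path,
                    cfg: FitConfig | None = None) -> None:
    """Write one NIfTI per parametric map plus a JSON fit report."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in pm.maps.items():
        nib.save(nib.Nifti1Image(arr, pm.affine), str(outdir / f"{name}.nii.gz"))
    nib.save(nib.Nifti1Image(pm.valid.astype(np.uint8), pm.affine),
             str(outdir / "valid.nii.gz"))
    report = pm.report()
    if cfg is not None:
        report["config"] = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
    (outdir / "fit_report.json").write_text(json.dumps(report, indent=2))
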