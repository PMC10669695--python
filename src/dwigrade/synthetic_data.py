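"""Synthetic DWI phantom cohorts.

The patient DICOM data behind this kind of study cannot be shared, so the
pipeline is exercised on phantoms engineered to carry the same statistical
structure the analysis assumes:

* two WHO-grade classes (low = G1/G2, high = G3) whose lesion-wise
  parameters follow published group means ± SDs for ADC, D, D_p, f, D_app
  and K_app on the conventional ×10⁻³ mm²/s reporting scale;
* the published inter-parameter correlation structure, imposed through a
  Gaussian copula (multivariate normal with nearest-PSD-repaired
  correlation, rejection-truncated at the fitting bounds);
* rendering of each lesion to a 4D volume over the 14-point acquisition
  b-scheme — IVIM forward model up to b = 800 s/mm², DKI model at
  b = 1500 and 2000 s/mm² — with Rician magnitude noise;
* three simulated radiologists delineating the lesion, emulated by smooth
  random perturbations of the true boundary.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .signal_models import BScheme, DkiParams, IvimParams, dki_signal, ivim_signal
from .volume import DwiVolume

__all__ = [
    "PARAM_ORDER",
    "PRINTED_SCALE",
    "PRINTED_BOUNDS",
    "GRADE_COMPOSITION",
    "GroupDistributionSpec",
    "PhantomSpec",
    "SyntheticPatient",
    "SyntheticCohort",
    "nearest_psd",
    "sample_cohort_parameters",
    "render_phantom",
    "add_rician_noise",
    "simulate_observer_vois",
    "simulate_cohort",
]

#: canonical parameter order used everywhere downstream
PARAM_ORDER = ("adc", "d", "dp", "f", "dapp", "kapp")

#: factor converting the printed reporting scale to SI (mm²/s) units
PRINTED_SCALE = {"adc": 1e-3, "d": 1e-3, "dp": 1e-3, "f": 1.0,
                 "dapp": 1e-3, "kapp": 1.0}

#: fitting bounds expressed on the printed scale
PRINTED_BOUNDS = {"adc": (0.0, 5.0), "d": (0.0, 5.0), "dp": (0.0, 80.0),
                  "f": (0.0, 0.8), "dapp": (0.0, 5.0), "kapp": (0.0, 2.5)}

#: WHO-grade composition of the emulated cohort (G1, G2 → low; G3 → high)
GRADE_COMPOSITION = {"G1": 17, "G2": 36, "G3": 32}

# group mean ± SD per class, printed scale (×10⁻³ mm²/s for diffusivities)
_CLASS_STATS = {
    "low": {"adc": (1.471, 0.202), "d": (1.339, 0.201), "dp": (45.952, 12.376),
            "f": (0.239, 0.068), "dapp": (1.499, 0.231), "kapp": (0.678, 0.133)},
    "high": {"adc": (1.321, 0.143), "d": (1.129, 0.146), "dp": (48.165, 12.368),
             "f": (0.197, 0.055), "dapp": (1.297, 0.224), "kapp": (0.819, 0.130)},
}

# published pairwise correlations; pairs not listed default to 0
_CORRELATIONS = {
    ("adc", "d"): 0.877, ("adc", "dapp"): 0.779, ("d", "dapp"): 0.840,
    ("adc", "f"): 0.408, ("d", "f"): 0.484, ("dapp", "f"): 0.466,
    ("adc", "kapp"): -0.578, ("d", "kapp"): -0.648, ("dapp", "kapp"): -0.514,
    ("f", "dp"): -0.544, ("f", "kapp"): -0.609, ("dp", "kapp"): 0.297,
}


def nearest_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Nearest positive semi-definite correlation matrix (eigenvalue clip)."""
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= eps:
        return sym
    w = np.clip(w, eps, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def default_correlation_matrix() -> np.ndarray:
    corr = np.eye(len(PARAM_ORDER))
    idx = {p: i for i, p in enumerate(PARAM_ORDER)}
    for (a, b), r in _CORRELATIONS.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return nearest_psd(corr)


@dataclass
class GroupDistributionSpec:
    """Per-class truncated-Gaussian lesion parameter distributions.

    ``class_stats[cls][param] = (mean, sd)`` on the printed scale;
    ``correlation`` is the 6×6 copula correlation over ``PARAM_ORDER``
    (``None`` for independent sampling).  Sampling is rejection-truncated
    at the fitting bounds so generated and fitted supports coincide.
    """

    class_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _CLASS_STATS.items()})
    correlation: np.ndarray | None = field(
        default_factory=default_correlation_matrix)
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PRINTED_BOUNDS))

    def __post_init__(self) -> None:
        for cls, stats in self.class_stats.items():
            for p, (_, sd) in stats.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {cls}/{p}")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (len(PARAM_ORDER),) * 2:
                raise ValueError("correlation matrix must be 6x6")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            c = nearest_psd(c)
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError("correlation not PSD even after repair")
            self.correlation = c


def sample_cohort_parameters(spec: GroupDistributionSpec, n_low: int,
                             n_high: int, seed: int) -> pd.DataFrame:
    """Draw lesion-wise parameter tuples for a two-class cohort.

    Returns a DataFrame with ``patient_id``, ``grade`` ('low'/'high') and one
    column per parameter on the printed scale, reproducible per seed.
    """
    if n_low <= 0 or n_high <= 0:
        raise ValueError("class counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n in (("low", n_low), ("high", n_high)):
        stats = spec.class_stats[cls]
        mean = np.array([stats[p][0] for p in PARAM_ORDER])
        sd = np.array([stats[p][1] for p in PARAM_ORDER])
        lo = np.array([spec.bounds[p][0] for p in PARAM_ORDER])
        hi = np.array([spec.bounds[p][1] for p in PARAM_ORDER])
        if spec.correlation is None:
            cov = np.diag(sd ** 2)
        else:
            cov = spec.correlation * np.outer(sd, sd)
        jitter = 1e-12 * float(np.mean(np.diag(cov)))
        chol = np.linalg.cholesky(cov + jitter * np.eye(len(PARAM_ORDER)))
        got = 0
        while got < n:
            z = rng.standard_normal((max(4 * (n - got), 16), len(PARAM_ORDER)))
            x = mean + z @ chol.T
            ok = np.all((x >= lo) & (x <= hi), axis=1)
            for tup in x[ok]:
                if got >= n:
                    break
                rows.append((cls, *tup))
                got += 1
    df = pd.DataFrame(rows, columns=["grade", *PARAM_ORDER])
    df.insert(0, "patient_id", [f"P{i:03d}" for i in range(len(df))])
    return df


@dataclass
class PhantomSpec:
    """Geometry and noise settings of one rendered phantom volume."""

    shape: tuple[int, int, int] = (16, 16, 8)
    lesion_center: tuple[float, float, float] | None = None
    lesion_radius: float = 3.0
    #: background tissue parameters on the printed scale
    background: dict[str, float] = field(default_factory=lambda: {
        "adc": 1.9, "d": 1.8, "dp": 20.0, "f": 0.12, "dapp": 1.9, "kapp": 0.4})
    s0: float = 1000.0
    snr: float = 50.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        c = self.lesion_center or tuple((s - 1) / 2.0 for s in self.shape)
        self.lesion_center = tuple(float(x) for x in c)
        for x, s in zip(self.lesion_center, self.shape):
            if x - self.lesion_radius < 0 or x + self.lesion_radius > s - 1:
                raise ValueError("lesion must lie strictly inside the grid")

    @property
    def noise_sigma(self) -> float:
        """Noise SD in signal units, derived from the b=0 lesion SNR."""
        return self.s0 / self.snr


def _to_si(params: Mapping[str, float]) -> dict[str, float]:
    return {p: params[p] * PRINTED_SCALE[p] for p in params}


def _render_series(params: Mapping[str, float], s0: float,
                   scheme: BScheme) -> np.ndarray:
    """One voxel's 14-point signal series from printed-scale parameters.

    Signals at b ≤ 800 come from the IVIM model, the high-b points
    (1500, 2000) from the DKI model — one stitched series, as a real
    acquisition would measure.
    """
    si = _to_si(params)
    ivim = IvimParams(s0=s0, f=si["f"], d=si["d"], dp=si["dp"])
    dki = DkiParams(s0=s0, dapp=si["dapp"], kapp=si["kapp"])
    b = scheme.b()
    out = np.empty_like(b)
    low = b <= 800.0
    out[low] = ivim_signal(ivim, b[low])
    out[~low] = dki_signal(dki, b[~low])
    return out


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in spec.shape],
                        indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, spec.lesion_center))
    return r2 <= spec.lesion_radius ** 2


def render_phantom(params: Mapping[str, float], spec: PhantomSpec,
                   scheme: BScheme | None = None
                   ) -> tuple[DwiVolume, np.ndarray]:
    """Render a noise-free phantom: spherical lesion in homogeneous background.

    ``params`` are the lesion's printed-scale parameters.  Returns the 4D
    volume and the true lesion VOI mask.
    """
    scheme = scheme or BScheme()
    voi = lesion_mask(spec)
    lesion_series = _render_series(params, spec.s0, scheme)
    bg_series = _render_series(spec.background, spec.s0, scheme)
    data = np.empty(spec.shape + (len(scheme.values),))
    data[...] = bg_series
    data[voi] = lesion_series
    return DwiVolume(data=data, scheme=scheme), voi


def add_rician_noise(volume: DwiVolume, sigma: float,
                     seed: int | np.random.Generator) -> DwiVolume:
    """Corrupt magnitude signal with Rician noise of Gaussian SD ``sigma``.

    Each sample s becomes sqrt((s + g1)² + g2²) with independent zero-mean
    Gaussians g1, g2 of SD sigma; sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DwiVolume(data=volume.data.copy(), scheme=volume.scheme,
                         affine=volume.affine.copy())
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    g1 = rng.normal(0.0, sigma, size=volume.data.shape)
    g2 = rng.normal(0.0, sigma, size=volume.data.shape)
    noisy = np.sqrt((volume.data + g1) ** 2 + g2 ** 2)
    return DwiVolume(data=noisy, scheme=volume.scheme, affine=volume.affine.copy())


def simulate_observer_vois(true_voi: np.ndarray, perturbation: float,
                           seed: int | np.random.SeedSequence,
                           n_observers: int = 3,
                           smoothness: float = 2.0) -> list[np.ndarray]:
    """Emulate freehand lesion delineation by several observers.

    Each observer's mask is the zero superlevel set of the true VOI's signed
    Euclidean distance plus a smooth unit-variance Gaussian random field
    scaled by ``perturbation`` (in voxels); perturbation = 0 reproduces the
    truth exactly.  Distinct sub-seeds give distinct masks.
    """
    if perturbation < 0:
        raise ValueError("perturbation must be non-negative")
    if perturbation == 0:
        return [true_voi.copy() for _ in range(n_observers)]
    signed = (ndimage.distance_transform_edt(true_voi)
              - ndimage.distance_transform_edt(~true_voi))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    masks = []
    for sub in ss.spawn(n_observers):
        rng = np.random.default_rng(sub)
        fld = ndimage.gaussian_filter(rng.standard_normal(true_voi.shape),
                                      smoothness)
        sd = fld.std()
        if sd > 0:
            fld = fld / sd
        masks.append((signed + perturbation * fld) > 0)
    return masks


@dataclass
class SyntheticPatient:
    patient_id: str
    grade: str
    true_params: dict[str, float]  # printed scale
    volume: DwiVolume
    true_voi: np.ndarray
    observer_vois: list[np.ndarray]


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    scheme: BScheme
    manifest: dict

    def parameter_table(self) -> pd.DataFrame:
        rows = [{"patient_id": p.patient_id, "grade": p.grade, **p.true_params}
                for p in self.patients]
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path, write_volumes: bool = True) -> None:
        import json

        from .volume import save_mask

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.parameter_table().to_csv(outdir / "cohort.csv", index=False)
        self.scheme.to_csv(outdir / "btable.csv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        if write_volumes:
            for p in self.patients:
                pdir = outdir / p.patient_id
                pdir.mkdir(exist_ok=True)
                p.volume.save(pdir / "dwi.nii.gz")
                save_mask(p.true_voi, p.volume.affine, pdir / "voi_true.nii.gz")
                for i, m in enumerate(p.observer_vois, 1):
                    save_mask(m, p.volume.affine, pdir / f"voi_obs{i}.nii.gz")


def simulate_cohort(n_low: int, n_high: int, seed: int,
                    dist_spec: GroupDistributionSpec | None = None,
                    phantom_spec: PhantomSpec | None = None,
                    scheme: BScheme | None = None,
                    observer_perturbation: float = 1.0) -> SyntheticCohort:
    """Full cohort simulation: sample, render, add noise, delineate.

    All randomness derives from ``seed`` (parameter draws, per-patient noise
    and per-observer boundary jitter use deterministic sub-seeds).
    """
    dist_spec = dist_spec or GroupDistributionSpec()
    phantom_spec = phantom_spec or PhantomSpec()
    scheme = scheme or BScheme()
    table = sample_cohort_parameters(dist_spec, n_low, n_high, seed)
    root = np.random.SeedSequence(seed)
    patients = []
    for (_, row), sub in zip(table.iterrows(), root.spawn(len(table))):
        params = {p: float(row[p]) for p in PARAM_ORDER}
        clean, voi = render_phantom(params, phantom_spec, scheme)
        noise_seed, obs_seed = sub.spawn(2)
        noisy = add_rician_noise(clean, phantom_spec.noise_sigma,
                                 np.random.default_rng(noise_seed))
        obs = simulate_observer_vois(voi, observer_perturbation, seed=obs_seed)
        patients.append(SyntheticPatient(
            patient_id=str(row["patient_id"]), grade=str(row["grade"]),
            true_params=params, volume=noisy, true_voi=voi,
            observer_vois=obs))
    manifest = {
        "seed": int(seed), "n_low": int(n_low), "n_high": int(n_high),
        "snr": phantom_spec.snr, "shape": list(phantom_spec.shape),
        "lesion_radius": phantom_spec.lesion_radius,
        "observer_perturbation": observer_perturbation,
        "b_values": list(scheme.values),
    }
    return SyntheticCohort(patients=patients, scheme=scheme, manifest=manifest)
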