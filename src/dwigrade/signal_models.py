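"""Forward signal models for diffusion-weighted MRI.

Three scalar (orientation-averaged) models are supported:

* mono-exponential decay, parameterised by the apparent diffusion
  coefficient (ADC) — a proxy for cellular density;
* the intravoxel incoherent motion (IVIM) bi-exponential, which separates
  true tissue diffusion ``D`` from perfusion-driven pseudo-diffusion ``D_p``
  with perfusion fraction ``f``;
* diffusion kurtosis imaging (DKI), which quantifies non-Gaussian water
  displacement through the apparent diffusivity ``D_app`` and the apparent
  kurtosis ``K_app``.

These functions are the single source of truth for both the fitting engine
(residual evaluation) and the phantom generator (signal rendering).  b-values
are carried in s/mm² and diffusivities in mm²/s throughout; the conventional
``×10⁻³ mm²/s`` display scale is applied only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ADC_BOUNDS",
    "D_BOUNDS",
    "DP_BOUNDS",
    "F_BOUNDS",
    "DAPP_BOUNDS",
    "KAPP_BOUNDS",
    "DEFAULT_BVALUES",
    "BScheme",
    "MonoParams",
    "IvimParams",
    "DkiParams",
    "mono_signal",
    "ivim_signal",
    "dki_signal",
    "dki_log_signal",
]

# Fitting/validity bounds (SI units: mm²/s for diffusivities).
ADC_BOUNDS = (0.0, 5.0e-3)
D_BOUNDS = (0.0, 5.0e-3)
DP_BOUNDS = (0.0, 80.0e-3)
F_BOUNDS = (0.0, 0.8)
DAPP_BOUNDS = (0.0, 5.0e-3)
KAPP_BOUNDS = (0.0, 2.5)

#: Acquisition b-values (s/mm²) of the single-shot EPI protocol emulated here.
DEFAULT_BVALUES: tuple[float, ...] = (
    0, 10, 20, 30, 50, 80, 100, 150, 200, 400, 600, 800, 1500, 2000,
)

_ADC_BVALUES = (0.0, 800.0)
_IVIM_MAX_B = 800.0
_DKI_BVALUES = (0.0, 800.0, 1500.0, 2000.0)


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


@dataclass(frozen=True)
class BScheme:
    """Ordered diffusion-weighting scheme with named fitting subsets.

    ``values`` must be strictly increasing, non-negative and start at b = 0.
    The three index subsets select the b-values each model is fitted on:
    ADC uses {0, 800}, IVIM everything up to 800, DKI {0, 800, 1500, 2000}
    (all in s/mm²).
    """

    values: tuple[float, ...] = DEFAULT_BVALUES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise ValueError("a b-scheme needs at least two b-values")
        if v[0] != 0:
            raise ValueError("the first b-value must be 0")
        if np.any(v < 0) or np.any(np.diff(v) <= 0):
            raise ValueError("b-values must be non-negative and strictly increasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    # -- subsets ----------------------------------------------------------
    def _indices_of(self, targets: Iterable[float]) -> tuple[int, ...]:
        idx = []
        for t in targets:
            matches = [i for i, b in enumerate(self.values) if b == t]
            if not matches:
                raise ValueError(f"b = {t} s/mm² not present in scheme")
            idx.append(matches[0])
        return tuple(idx)

    @property
    def adc_subset(self) -> tuple[int, ...]:
        return self._indices_of(_ADC_BVALUES)

    @property
    def ivim_subset(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.values) if b <= _IVIM_MAX_B)

    @property
    def dki_subset(self) -> tuple[int, ...]:
        return self._indices_of(_DKI_BVALUES)

    def b(self, subset: Sequence[int] | None = None) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        return v if subset is None else v[list(subset)]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        lines = ["index,b_value_s_per_mm2"]
        lines += [f"{i},{b:g}" for i, b in enumerate(self.values)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "BScheme":
        """Read a b-table: two-column CSV or whitespace-separated values."""
        text = Path(path).read_text().strip()
        rows: list[list[float]] = []
        for line in text.splitlines():
            line = line.strip().replace(",", " ")
            if not line:
                continue
            try:
                rows.append([float(x) for x in line.split()])
            except ValueError:
                continue  # header line
        if len(rows) > 1 and all(len(r) == 2 for r in rows):
            values = [r[1] for r in rows]  # (index, b) CSV layout
        else:
            values = [x for r in rows for x in r]
        return cls(values=tuple(values))


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential model parameters: S0 > 0 and ADC ∈ [0, 5e-3] mm²/s."""

    s0: float
    adc: float

    def __post_init__(self) -> None:
        _require(self.s0 > 0, "s0 must be positive")
        _require(ADC_BOUNDS[0] <= self.adc <= ADC_BOUNDS[1],
                 f"adc outside bounds {ADC_BOUNDS}")


@dataclass(frozen=True)
class IvimParams:
    """IVIM bi-exponential parameters.

    ``f`` ∈ [0, 0.8] is the perfusion fraction, ``d`` ∈ [0, 5e-3] mm²/s the
    true diffusion coefficient and ``dp`` ∈ [0, 80e-3] mm²/s the
    pseudo-diffusion coefficient of the microcirculation compartment.
    """

    s0: float
    f: float
    d: float
    dp: float

    def __post_init__(self) -> None:
        _require(self.s0 > 0, "s0 must be positive")
        _require(F_BOUNDS[0] <= self.f <= F_BOUNDS[1], f"f outside bounds {F_BOUNDS}")
        _require(D_BOUNDS[0] <= self.d <= D_BOUNDS[1], f"d outside bounds {D_BOUNDS}")
        _require(DP_BOUNDS[0] <= self.dp <= DP_BOUNDS[1],
                 f"dp outside bounds {DP_BOUNDS}")


@dataclass(frozen=True)
class DkiParams:
    """DKI parameters: apparent diffusivity ``dapp`` and kurtosis ``kapp``."""

    s0: float
    dapp: float
    kapp: float

    def __post_init__(self) -> None:
        _require(self.s0 > 0, "s0 must be positive")
        _require(DAPP_BOUNDS[0] <= self.dapp <= DAPP_BOUNDS[1],
                 f"dapp outside bounds {DAPP_BOUNDS}")
        _require(KAPP_BOUNDS[0] <= self.kapp <= KAPP_BOUNDS[1],
                 f"kapp outside bounds {KAPP_BOUNDS}")


def mono_signal(p: MonoParams, b) -> np.ndarray | float:
    """S(b) = S0 · exp(−b·ADC)."""
    b = _check_b(b)
    return p.s0 * np.exp(-b * p.adc)


def ivim_signal(p: IvimParams, b) -> np.ndarray | float:
    """S(b) = S0 · [(1−f)·exp(−b·D) + f·exp(−b·D_p)].

    Collapses to :func:`mono_signal` when ``f = 0``.
    """
    b = _check_b(b)
    return p.s0 * ((1.0 - p.f) * np.exp(-b * p.d) + p.f * np.exp(-b * p.dp))


def dki_log_signal(p: DkiParams, b) -> np.ndarray | float:
    """ln S(b) = ln S0 − b·D_app + (1/6)·b²·D_app²·K_app.

    The log form is the residual basis for DKI fitting.
    """
    b = _check_b(b)
    return np.log(p.s0) - b * p.dapp + (b * p.dapp) ** 2 * p.kapp / 6.0


def dki_signal(p: DkiParams, b) -> np.ndarray | float:
    """Signal-space DKI model; reduces to :func:`mono_signal` when K_app = 0."""
    return np.exp(dki_log_signal(p, b))
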