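"""4D diffusion-weighted volumes and their NIfTI / b-table I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .signal_models import BScheme

__all__ = ["DwiVolume", "load_dwi", "save_mask", "load_mask"]


@dataclass
class DwiVolume:
    """Magnitude DWI signal on an (x, y, z, b) grid with its b-scheme."""

    data: np.ndarray
    scheme: BScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-dimensional (x, y, z, b)")
        if self.data.shape[3] != len(self.scheme.values):
            raise ValueError(
                f"last axis ({self.data.shape[3]}) does not match the "
                f"b-scheme length ({len(self.scheme.values)})"
            )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def save(self, path: str | Path, btable_path: str | Path | None = None) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))
        if btable_path is not None:
            self.scheme.to_csv(btable_path)


def load_dwi(path: str | Path, btable_path: str | Path) -> DwiVolume:
    img = nib.load(str(path))
    scheme = BScheme.from_table(btable_path)
    return DwiVolume(data=np.asarray(img.dataobj, dtype=float),
                     scheme=scheme, affine=img.affine)


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, img.affine
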