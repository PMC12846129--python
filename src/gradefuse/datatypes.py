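"""Core in-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel spacing (mm), modality tag and
    acquisition timestamp (days relative to imaging baseline)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "CT"
    timestamp: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage expects a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(data=data, spacing=self.spacing,
                           modality=self.modality, timestamp=self.timestamp)

    # NIfTI round trip: RAS orientation, spacing carried on the affine diagonal
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str = "CT",
                   timestamp: float = 0.0) -> "VolumeImage":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=np.asarray(img.get_fdata(), dtype=np.float64),
                   spacing=spacing, modality=modality, timestamp=timestamp)


@dataclass
class ClinicalRecord:
    """Per-patient structured features plus labels and survival outcome."""

    patient_id: str
    features: dict = field(default_factory=dict)
    grade: int | None = None          # 0 = GI-II, 1 = GIII
    response: int | None = None       # 1 = responder (CR/PR)
    pfs_time: float | None = None     # months
    pfs_event: int | None = None      # 1 = progression observed
    timestamp: float = 0.0            # record time, days
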