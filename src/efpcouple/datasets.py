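"""In-memory containers for BOLD data with voxel geometry and masks.

BOLD data are carried as a flat ``voxels x volumes`` matrix together
with integer lattice coordinates, an isotropic-by-default mm spacing and
an mm origin, so that mm-radius seed spheres are well defined, plus a
dictionary of named voxel masks (index arrays into the voxel axis).
NIfTI serialization (dense 4-D grid + JSON sidecar with TR, masks and
geometry) lives in :mod:`efpcouple.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BOLDDataset"]


@dataclass
class BOLDDataset:
    """Voxels-by-volumes BOLD matrix with geometry and named masks.

    Parameters
    ----------
    data : (V, T) array
        One row per voxel, one column per volume, arbitrary units.
    tr : float
        Volume repetition time in seconds.
    voxel_coords : (V, 3) int array
        Lattice indices of each voxel.
    spacing : (3,) array
        mm per lattice step along each axis (default 2.2 mm isotropic,
        matching the acquisition voxel size).
    origin : (3,) array
        mm coordinate of lattice index (0, 0, 0).
    masks : dict
        label -> sorted int array of voxel indices.
    """

    data: np.ndarray
    tr: float
    voxel_coords: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 2.2))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    masks: dict = field(default_factory=dict)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be (voxels, volumes) with >= 2 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.voxel_coords.shape != (self.data.shape[0], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.masks = {k: np.asarray(v, dtype=int) for k, v in self.masks.items()}

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def coords_mm(self) -> np.ndarray:
        """(V, 3) mm coordinates of voxel centers."""
        return self.origin[None, :] + self.voxel_coords * self.spacing[None, :]

    @property
    def volume_times(self) -> np.ndarray:
        """Acquisition onset time of each volume (0, TR, 2·TR, ...)."""
        return np.arange(self.n_volumes) * self.tr

    def mask_indices(self, label: str) -> np.ndarray:
        if label not in self.masks:
            raise KeyError(f"no mask named {label!r}; have {sorted(self.masks)}")
        return self.masks[label]

    def mask_data(self, label: str) -> np.ndarray:
        """(n_masked, T) view of the data restricted to one mask."""
        return self.data[self.mask_indices(label)]

    def with_data(self, data: np.ndarray) -> "BOLDDataset":
        """Copy of this dataset with the data matrix replaced."""
        return BOLDDataset(
            data=np.asarray(data, dtype=float),
            tr=self.tr,
            voxel_coords=self.voxel_coords,
            spacing=self.spacing,
            origin=self.origin,
            masks=dict(self.masks),
            subject_id=self.subject_id,
        )
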