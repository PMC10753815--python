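"""Phantom brain geometry and a coarse bilateral territory atlas.

The phantom head is an ellipsoid on a regular voxel grid, mirror-symmetric
about the mid-sagittal (x) plane. A deep ellipsoidal core models the
perforator-supplied territory; the shell between core and surface models
the cortical-branch territory. Each depth class is split into left/right
hemispheres and anterior/middle/posterior thirds, giving 12 labeled
regions: 6 cortical (ACA/MCA/PCA-like per side) and 6 perforating zones.

An additional boolean channel marks artifact-prone zones — the inferior
cortical rim, where susceptibility artifacts typically produce symmetric
high DWI signal near the skull base.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

#: Fractional semi-axes of the brain ellipsoid (x: left-right,
#: y: anterior-posterior, z: inferior-superior) relative to grid extent.
BRAIN_SEMI_AXES = (0.40, 0.46, 0.42)

#: Deep (perforating) core as a fraction of the brain semi-axes.
DEEP_SCALE = 0.55

#: Fraction of the slice range (from the bottom) whose cortical rim is
#: marked artifact-prone.
ARTIFACT_Z_FRACTION = 0.25

_CORTICAL_NAMES = ("ACA", "MCA", "PCA")
_PERFORATING_NAMES = ("ant_perf", "lenticulostriate", "thalamoperf")


@dataclass(frozen=True)
class Atlas:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray  # bool
    labels: np.ndarray  # int, 0 = background, 1..12 = regions
    names: tuple[str, ...]  # names[label - 1]
    is_cortical: tuple[bool, ...]  # per label
    artifact_zone: np.ndarray  # bool
    brain_edt_mm: np.ndarray  # distance to brain boundary, mm

    @property
    def cortical_mask(self) -> np.ndarray:
        lut = np.array([False] + list(self.is_cortical))
        return lut[self.labels]

    @property
    def perforating_mask(self) -> np.ndarray:
        return self.brain_mask & ~self.cortical_mask

    def territory_name(self, label: int) -> str:
        return self.names[label - 1]


def _ellipsoid(shape, spacing, semi_axes_mm) -> np.ndarray:
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes_mm))
    return q <= 1.0


@lru_cache(maxsize=8)
def build_atlas(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Atlas:
    """Construct the phantom atlas for a grid. Cached: geometry is pure."""
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    extent = [n * s for n, s in zip(shape, spacing)]
    semi = [f * e for f, e in zip(BRAIN_SEMI_AXES, extent)]
    brain = _ellipsoid(shape, spacing, semi)
    deep = _ellipsoid(shape, spacing, [DEEP_SCALE * a for a in semi])

    nx, ny, _ = shape
    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    left = xi < (nx - 1) / 2.0  # ties (odd grid midline) go right
    third = np.minimum((yi * 3) // ny, 2)  # 0 anterior, 1 middle, 2 posterior

    labels = np.zeros(shape, dtype=np.int16)
    names: list[str] = []
    is_cortical: list[bool] = []
    label = 0
    for depth_mask, depth_names, cortical in (
        (brain & ~deep, _CORTICAL_NAMES, True),
        (deep, _PERFORATING_NAMES, False),
    ):
        for side, side_mask in (("L", left), ("R", ~left)):
            for t, tname in enumerate(depth_names):
                label += 1
                region = depth_mask & (side_mask & (third == t))[:, :, None]
                labels[region] = label
                names.append(f"{side}_{tname}")
                is_cortical.append(cortical)

    nz = shape[2]
    z_low = np.arange(nz) < ARTIFACT_Z_FRACTION * nz
    artifact_zone = (brain & ~deep) & z_low[None, None, :]

    edt = ndimage.distance_transform_edt(brain, sampling=spacing)
    return Atlas(
        shape=shape,
        spacing=spacing,
        brain_mask=brain,
        labels=labels,
        names=tuple(names),
        is_cortical=tuple(is_cortical),
        artifact_zone=artifact_zone,
        brain_edt_mm=edt,
    )
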