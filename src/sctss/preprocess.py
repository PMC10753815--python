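"""Intensity and geometry standardization for DWI/ADC volume pairs.

Three corrections are applied, mirroring the variability seen across
scanners and acquisitions: (1) multiplicative intensity rescaling that maps
the in-brain histogram peak (mode) of each modality to a reference value;
(2) in-plane head-rotation correction from the second moments of the brain
mask on the central axial slices; (3) slice-axis (z) alignment of the
per-slice brain-area profile to a reference volume by dynamic time warping,
followed by resampling along the warping path.

All geometric steps apply the identical transform to DWI, ADC, brain mask
and (when present) the ground-truth lesion mask: linear interpolation for
intensities, nearest-neighbor for masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from sctss.types import VolumePair

#: Histogram bins used for peak (mode) finding.
PEAK_BINS = 256

#: Default reference peaks the standardized volumes are mapped to.
REFERENCE_PEAK_DWI = 100.0
REFERENCE_PEAK_ADC = 800.0


# --------------------------------------------------------------------------
# Peak-based intensity normalization
# --------------------------------------------------------------------------


def histogram_mode(values: np.ndarray, bins: int = PEAK_BINS) -> float:
    """Mode of a sample as the center of the fullest histogram bin.

    Ties break toward the lower bin. A constant sample returns that value.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot take the mode of an empty sample")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def normalize_intensity_by_peak(
    vol: VolumePair,
    reference_peak_dwi: float = REFERENCE_PEAK_DWI,
    reference_peak_adc: float = REFERENCE_PEAK_ADC,
    bins: int = PEAK_BINS,
) -> VolumePair:
    """Rescale DWI and ADC so their in-mask histogram peaks hit the references."""
    if reference_peak_dwi <= 0 or reference_peak_adc <= 0:
        raise ValueError("reference peaks must be positive")
    if not vol.brain_mask.any():
        raise ValueError("brain mask is empty; cannot locate an intensity peak")
    out = vol.copy()
    scales = {}
    for name, arr, ref in (
        ("dwi", out.dwi, reference_peak_dwi),
        ("adc", out.adc, reference_peak_adc),
    ):
        peak = histogram_mode(arr[vol.brain_mask], bins=bins)
        if peak == 0:
            raise ValueError(f"{name} in-mask peak is zero; cannot rescale")
        arr *= ref / peak
        scales[name] = {"peak": peak, "scale": ref / peak}
    return out.with_meta(peak_normalization={"bins": bins, **scales})


# --------------------------------------------------------------------------
# Rotation correction
# --------------------------------------------------------------------------


def _principal_axis_tilt(mask2d: np.ndarray) -> tuple[float, float]:
    """In-plane tilt (deg) of the major principal axis from the y axis,
    and the axis-length eccentricity used to flag degeneracy."""
    idx = np.argwhere(mask2d)
    centered = idx - idx.mean(axis=0)
    cov = centered.T @ centered / len(idx)
    # orientation of the major axis measured from the x (first) axis
    theta = 0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])
    evals = np.linalg.eigvalsh(cov)
    ecc = float(evals[1] / max(evals[0], 1e-12))
    # the phantom's major axis is anterior-posterior (y); tilt is the
    # deviation of that axis from y, wrapped to (-45, 45]
    tilt = np.degrees(theta) - 90.0
    while tilt <= -45.0:
        tilt += 90.0
    while tilt > 45.0:
        tilt -= 90.0
    return float(tilt), ecc


def rotate_inplane(arr: np.ndarray, deg: float, order: int) -> np.ndarray:
    """Rotate about the grid center in the axial (x, y) plane."""
    if deg == 0.0:
        return arr.copy()
    return ndimage.rotate(
        arr.astype(float), deg, axes=(0, 1), reshape=False, order=order, mode="constant"
    )


def correct_rotation(
    vol: VolumePair, degeneracy_tol: float = 1.02
) -> tuple[VolumePair, float]:
    """Estimate and undo in-plane head tilt.

    The tilt is the angle between the brain mask's major principal axis
    (second moments pooled over the central third of axial slices) and the
    anterior-posterior axis. A mask whose principal axes are too close to
    rotational symmetry (eccentricity below ``degeneracy_tol``) yields
    estimate 0 and a warning flag in ``meta``.
    """
    nz = vol.brain_mask.shape[2]
    central = vol.brain_mask[:, :, nz // 3 : max(nz // 3 + 1, 2 * nz // 3)]
    pooled = central.any(axis=2)
    if not pooled.any():
        raise ValueError("brain mask empty on the central slices")
    tilt, ecc = _principal_axis_tilt(pooled)
    degenerate = ecc < degeneracy_tol
    if degenerate:
        tilt = 0.0
    out = vol.copy()
    if tilt != 0.0:
        out.dwi = rotate_inplane(out.dwi, -tilt, order=1)
        out.adc = rotate_inplane(out.adc, -tilt, order=1)
        out.brain_mask = rotate_inplane(out.brain_mask.astype(float), -tilt, order=0) >= 0.5
        if out.lesion_mask is not None:
            out.lesion_mask = (
                rotate_inplane(out.lesion_mask.astype(float), -tilt, order=0) >= 0.5
            )
    out = out.with_meta(
        rotation_correction={"estimate_deg": tilt, "degenerate": bool(degenerate)}
    )
    return out, tilt


# --------------------------------------------------------------------------
# Dynamic time warping along the slice axis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentResult:
    """A monotone DTW path between two per-slice descriptor sequences."""

    warping_path: tuple[tuple[int, int], ...]  # (query_slice, reference_slice)
    total_cost: float
    z_offset_estimate: int

    def __post_init__(self) -> None:
        qs, rs = zip(*self.warping_path)
        if any(np.diff(qs) < 0) or any(np.diff(rs) < 0):
            raise ValueError("warping path must be monotone non-decreasing")
        if self.total_cost < 0:
            raise ValueError("total_cost must be nonnegative")


def dtw_align(
    query_profile: Sequence[float],
    reference_profile: Sequence[float],
    local_cost: Optional[Callable[[float, float], float]] = None,
) -> AlignmentResult:
    """Minimum-cost monotone alignment under the classic DTW recurrence.

    Symmetric step pattern (match / insert / delete), absolute-difference
    local cost by default, no window constraint. The signed z offset is the
    median of ``reference_slice - query_slice`` along the path.
    """
    q = np.asarray(query_profile, dtype=float)
    r = np.asarray(reference_profile, dtype=float)
    if q.size == 0 or r.size == 0:
        raise ValueError("DTW requires non-empty profiles")
    if np.isnan(q).any() or np.isnan(r).any():
        raise ValueError("DTW profiles must not contain NaN")
    if local_cost is None:
        cost = np.abs(q[:, None] - r[None, :])
    else:
        cost = np.array([[local_cost(a, b) for b in r] for a in q], dtype=float)
    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(
                acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            )
    # backtrack; prefer the diagonal on ties for the shortest path
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        moves = []
        if i > 1 and j > 1:
            moves.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 1:
            moves.append((acc[i - 1, j], (i - 1, j)))
        if j > 1:
            moves.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(moves, key=lambda t: t[0])
        path.append((i - 1, j - 1))
    path.reverse()
    offsets = [rj - qi for qi, rj in path]
    return AlignmentResult(
        warping_path=tuple(path),
        total_cost=float(acc[n, m]),
        z_offset_estimate=int(np.median(offsets)),
    )


def slice_area_profile(vol: VolumePair) -> np.ndarray:
    """Brain-mask area (mm^2) per axial slice — the DTW descriptor."""
    sx, sy, _ = vol.spacing
    return vol.brain_mask.sum(axis=(0, 1)).astype(float) * sx * sy


def resample_along_path(
    arr: np.ndarray, path: Sequence[tuple[int, int]], n_ref: int, is_mask: bool
) -> np.ndarray:
    """Resample the z axis so slice j of the output matches reference slice j.

    Each reference slice takes the mean of the query slices its path pairs
    point to (majority for masks); unmatched reference slices cannot occur
    because the path covers both sequences end to end.
    """
    groups: list[list[int]] = [[] for _ in range(n_ref)]
    for qi, rj in path:
        groups[rj].append(qi)
    out = np.zeros(arr.shape[:2] + (n_ref,), dtype=float)
    for j, g in enumerate(groups):
        out[:, :, j] = arr[:, :, g].mean(axis=2)
    if is_mask:
        return out >= 0.5
    return out


def standardize(
    vol: VolumePair,
    reference: VolumePair,
    bins: int = PEAK_BINS,
    reference_peak_dwi: float = REFERENCE_PEAK_DWI,
    reference_peak_adc: float = REFERENCE_PEAK_ADC,
) -> VolumePair:
    """Full standardization: peak normalization, rotation correction, then
    z alignment to the reference via DTW on slice-area profiles."""
    out = normalize_intensity_by_peak(
        vol, reference_peak_dwi=reference_peak_dwi,
        reference_peak_adc=reference_peak_adc, bins=bins,
    )
    out, _tilt = correct_rotation(out)
    align = dtw_align(slice_area_profile(out), slice_area_profile(reference))
    n_ref = reference.brain_mask.shape[2]
    dwi = resample_along_path(out.dwi, align.warping_path, n_ref, is_mask=False)
    adc = resample_along_path(out.adc, align.warping_path, n_ref, is_mask=False)
    brain = resample_along_path(out.brain_mask, align.warping_path, n_ref, is_mask=True)
    lesion = (
        None
        if out.lesion_mask is None
        else resample_along_path(out.lesion_mask, align.warping_path, n_ref, is_mask=True)
    )
    result = VolumePair(
        dwi=dwi, adc=adc, spacing=out.spacing, brain_mask=brain,
        lesion_mask=lesion, meta=dict(out.meta),
    )
    return result.with_meta(
        standardized=True,
        z_alignment={
            "z_offset_estimate": align.z_offset_estimate,
            "total_cost": align.total_cost,
        },
    )
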