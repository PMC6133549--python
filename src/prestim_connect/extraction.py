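"""ROI time-series extraction from 4D images with voxel-exclusion rules.

Masks arrive registered to functional space (binary or weighted — small
brainstem nuclei such as the RVM use weighted masks). Before extraction,
voxels sitting in signal-dropout zones (mean intensity more than 10% below a
robust maximum-signal reference) and voxels segmented as CSF are removed.
The per-volume weighted mean over the surviving voxels is the ROI series;
preprocessing applies optional grand-mean scaling, high-pass temporal
filtering (Gaussian-weighted running-line detrending, the FSL convention)
and demeaning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "ROIMask",
    "ROITimeSeriesSet",
    "EmptyMaskError",
    "dropout_reference",
    "exclude_dropout_voxels",
    "exclude_csf_voxels",
    "extract_series",
    "preprocess_series",
    "highpass_matrix",
]


class EmptyMaskError(ValueError):
    """Every voxel of an ROI was excluded."""


def _as_data(image) -> np.ndarray:
    """Accept a plain ndarray or any nibabel spatial image."""
    if hasattr(image, "get_fdata"):
        return np.asarray(image.get_fdata())
    return np.asarray(image, dtype=float)


@dataclass(frozen=True)
class ROIMask:
    label: str
    indices: np.ndarray  # (n_voxels, 3) integer voxel coordinates
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    space: str = "functional"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("indices must be (n_voxels, 3)")
        if idx.shape[0] == 0:
            raise EmptyMaskError(f"ROI {self.label!r} has no voxels")
        w = (
            np.ones(idx.shape[0])
            if self.weights is None
            else np.asarray(self.weights, dtype=float)
        )
        if w.shape != (idx.shape[0],) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per voxel")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.indices.shape[0]

    @classmethod
    def from_image(cls, label: str, mask_image, space: str = "functional") -> "ROIMask":
        data = _as_data(mask_image)
        idx = np.argwhere(data > 0)
        return cls(label=label, indices=idx, weights=data[data > 0], space=space)


def dropout_reference(image, masks=None, percentile: float = 98.0) -> float:
    """Robust maximum-signal reference of the temporal-mean image.

    The literal voxelwise maximum is a single noisy voxel, so the reference
    is a high percentile of the mean image, taken over the union of the
    supplied masks (or all positive voxels when none are given).
    """
    mean_img = _as_data(image).mean(axis=-1)
    if masks:
        idx = np.vstack([m.indices for m in masks])
        vals = mean_img[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        vals = mean_img[mean_img > 0]
    return float(np.percentile(vals, percentile))


def exclude_dropout_voxels(
    mask: ROIMask,
    image,
    threshold: float = 0.10,
    reference: float | None = None,
    percentile: float = 98.0,
) -> tuple[ROIMask, int]:
    """Drop voxels with > ``threshold`` signal loss from the reference.

    Returns the pruned mask and the number of voxels removed. An ROI losing
    every voxel raises :class:`EmptyMaskError` naming the region — the
    situation that forced exclusion of infants whose RVM fell outside the
    usable field of view.
    """
    data = _as_data(image)
    if reference is None:
        reference = dropout_reference(data, percentile=percentile)
    mean_img = data.mean(axis=-1)
    vals = mean_img[mask.indices[:, 0], mask.indices[:, 1], mask.indices[:, 2]]
    keep = vals >= (1.0 - threshold) * reference
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise EmptyMaskError(
            f"ROI {mask.label!r}: all {len(mask)} voxels fall in signal dropout"
        )
    pruned = replace(mask, indices=mask.indices[keep], weights=mask.weights[keep])
    return pruned, n_excluded


def exclude_csf_voxels(
    mask: ROIMask, segmentation, csf_value: int = 1
) -> tuple[ROIMask, int]:
    """Drop mask voxels labelled CSF in a segmentation label image."""
    seg = _as_data(segmentation)
    if not np.any(seg == csf_value):
        warnings.warn(
            f"segmentation contains no voxel labelled {csf_value} (CSF); "
            f"mask {mask.label!r} left unchanged",
            stacklevel=2,
        )
        return mask, 0
    labels = seg[mask.indices[:, 0], mask.indices[:, 1], mask.indices[:, 2]]
    keep = labels != csf_value
    if not keep.any():
        raise EmptyMaskError(f"ROI {mask.label!r}: every voxel is CSF")
    pruned = replace(mask, indices=mask.indices[keep], weights=mask.weights[keep])
    return pruned, int((~keep).sum())


def extract_series(image, mask: ROIMask) -> np.ndarray:
    """Per-volume weighted mean of voxel intensities (weights sum to 1)."""
    data = _as_data(image)
    voxels = data[mask.indices[:, 0], mask.indices[:, 1], mask.indices[:, 2], :]
    w = mask.weights / mask.weights.sum()
    return w @ voxels


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Per-ROI signal vectors with preprocessing provenance."""

    tr: float
    series: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) > 1:
            raise ValueError("all ROI series must share one length")

    @property
    def n_volumes(self) -> int:
        return len(next(iter(self.series.values())))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.series)

    def to_matrix(self) -> np.ndarray:
        """(n_volumes, n_rois) array in label order."""
        return np.column_stack([self.series[k] for k in self.series])

    def to_csv(self, path, provenance_path=None) -> None:
        pd.DataFrame(self.series).to_csv(path, index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump({"tr": self.tr, **self.provenance}, fh, indent=2)

    @classmethod
    def from_csv(cls, path, tr: float) -> "ROITimeSeriesSet":
        table = pd.read_csv(path)
        return cls(tr=tr, series={c: table[c].to_numpy(float) for c in table})


@lru_cache(maxsize=8)
def highpass_matrix(n_volumes: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Linear operator for Gaussian-weighted running-line high-pass filtering.

    At each timepoint a straight line is fitted to the series under Gaussian
    weights of width sigma = period/2 (in seconds) and subtracted; slow
    trends up to the cutoff period are removed while faster fluctuations
    pass nearly unattenuated. Returned as an (n, n) matrix so repeated
    filtering at a fixed length is a single matmul.
    """
    sigma_vol = (1.0 / cutoff_hz) / 2.0 / tr
    t = np.arange(n_volumes, dtype=float)
    smoother = np.empty((n_volumes, n_volumes))
    for i in range(n_volumes):
        x = t - t[i]
        w = np.exp(-0.5 * (x / sigma_vol) ** 2)
        s0, s1, s2 = w.sum(), (w * x).sum(), (w * x * x).sum()
        smoother[i] = w * (s2 - x * s1) / (s0 * s2 - s1 * s1)
    return np.eye(n_volumes) - smoother


def preprocess_series(
    tset: ROITimeSeriesSet,
    highpass_hz: float | None = 0.01,
    grand_mean_target: float | None = None,
    demean: bool = True,
) -> ROITimeSeriesSet:
    """Grand-mean scale, high-pass filter and demean every ROI series."""
    series = {k: np.asarray(v, dtype=float) for k, v in tset.series.items()}
    provenance = dict(tset.provenance)

    if grand_mean_target is not None:
        grand = float(np.mean([v.mean() for v in series.values()]))
        if grand <= 0:
            raise ValueError("grand mean must be positive to rescale")
        factor = grand_mean_target / grand
        series = {k: v * factor for k, v in series.items()}
        provenance["grand_mean_target"] = grand_mean_target

    if highpass_hz is not None:
        nyquist = 0.5 / tset.tr
        if highpass_hz >= nyquist:
            raise ValueError(
                f"high-pass cutoff {highpass_hz} Hz at or above Nyquist {nyquist} Hz"
            )
        H = highpass_matrix(tset.n_volumes, tset.tr, highpass_hz)
        series = {k: H @ v for k, v in series.items()}
        provenance["highpass_hz"] = highpass_hz

    if demean:
        series = {k: v - v.mean() for k, v in series.items()}
        provenance["demeaned"] = True

    return ROITimeSeriesSet(tr=tset.tr, series=series, provenance=provenance)
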