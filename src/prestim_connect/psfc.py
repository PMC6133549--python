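"""Pre-stimulus functional connectivity (psFC).

For each noxious stimulus, the three volumes acquired immediately before the
stimulus volume form a pre-stimulus window (7.5 s of data at TR 2.5 s; since
a stimulus can land anywhere within its volume, the window opens 7.5–10 s
before the stimulus itself). For every ROI pair, the Pearson correlation of
the two 3-sample segments is computed per stimulus and averaged across
stimuli, yielding a per-infant connectivity matrix; network connectivity is
the mean of its below-diagonal entries restricted to the network's ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import StimulusProtocol
from .extraction import ROITimeSeriesSet

__all__ = [
    "PreStimWindowSet",
    "ConnectivityMatrix",
    "extract_prestim_windows",
    "pairwise_prestim_correlation",
    "build_connectivity_matrix",
    "network_mean_psfc",
    "psfc_by_stimulus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreStimWindowSet:
    """Per-stimulus pre-stimulus windows for every ROI.

    ``segments`` maps each ROI label to an (n_stimuli, n_prestim) array;
    ``lags`` gives, per stimulus, onset minus the window's start time.
    """

    tr: float
    window_indices: np.ndarray  # (n_stimuli, n_prestim)
    segments: dict[str, np.ndarray]
    lags: np.ndarray

    @property
    def n_stimuli(self) -> int:
        return self.window_indices.shape[0]

    @property
    def n_prestim(self) -> int:
        return self.window_indices.shape[1]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.segments)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """ROI x ROI mean pre-stimulus correlation for one infant."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    per_stimulus: np.ndarray  # (n_stimuli, n_rois, n_rois), NaN where undefined
    n_stimuli: int
    networks: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def edge_series(self) -> pd.Series:
        """Below-diagonal entries keyed 'A-B' in label order."""
        out = {}
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                out[f"{a}-{self.labels[j]}"] = self.matrix[j, i]
        return pd.Series(out)


def extract_prestim_windows(
    tset: ROITimeSeriesSet,
    protocol: StimulusProtocol,
    n_prestim: int = 3,
) -> PreStimWindowSet:
    """Select the ``n_prestim`` volumes immediately before each stimulus.

    A stimulus at time t occupies volume floor(t/TR); its window is the
    ``n_prestim`` volumes preceding that one. Raises if any stimulus falls
    too early in the scan for a complete window.
    """
    tr = tset.tr
    n_vol = tset.n_volumes
    windows, lags = [], []
    for s, onset in enumerate(protocol.onsets):
        k = int(np.floor(onset / tr))
        if k >= n_vol:
            raise ValueError(f"stimulus {s} at {onset:.2f} s beyond scan end")
        if k < n_prestim:
            raise ValueError(
                f"stimulus {s} at {onset:.2f} s has fewer than "
                f"{n_prestim} preceding volumes"
            )
        idx = np.arange(k - n_prestim, k)
        windows.append(idx)
        lags.append(onset - idx[0] * tr)
    window_indices = (
        np.array(windows, dtype=int)
        if windows
        else np.empty((0, n_prestim), dtype=int)
    )
    segments = {
        lab: np.array([v[idx] for idx in windows]).reshape(-1, n_prestim)
        for lab, v in tset.series.items()
    }
    return PreStimWindowSet(
        tr=tr,
        window_indices=window_indices,
        segments=segments,
        lags=np.asarray(lags, dtype=float),
    )


def _per_stimulus_corr(seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """Pearson r per stimulus row; NaN where a segment has zero variance."""
    a = seg_a - seg_a.mean(axis=1, keepdims=True)
    b = seg_b - seg_b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)
    return r


def pairwise_prestim_correlation(
    windows: PreStimWindowSet, roi_a: str, roi_b: str
) -> tuple[float, np.ndarray]:
    """Mean of the per-stimulus window correlations for one ROI pair.

    Stimuli whose segment has zero variance (undefined r) are dropped from
    the average rather than set to 0; the drop count is logged.
    """
    if windows.n_stimuli == 0:
        raise ValueError("no stimuli: cannot compute a pre-stimulus correlation")
    r = _per_stimulus_corr(windows.segments[roi_a], windows.segments[roi_b])
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        logger.info(
            "pair %s-%s: %d of %d stimulus windows had zero variance; excluded",
            roi_a, roi_b, n_bad, windows.n_stimuli,
        )
    if n_bad == windows.n_stimuli:
        return float("nan"), r
    return float(np.nanmean(r)), r


def build_connectivity_matrix(
    windows: PreStimWindowSet,
    rois: tuple[str, ...] | None = None,
    networks: dict[str, tuple[str, ...]] | None = None,
    average: str = "mean",
) -> ConnectivityMatrix:
    """Fill the symmetric matrix of mean pre-stimulus correlations.

    ``average='fisher'`` averages on the Fisher-z scale before transforming
    back; the default is the plain arithmetic mean of per-stimulus r values.
    """
    labels = tuple(rois) if rois is not None else windows.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 ROIs for a connectivity matrix")
    n_stim, n_roi = windows.n_stimuli, len(labels)
    data = np.stack([windows.segments[lab] for lab in labels])  # (R, S, 3)
    centred = data - data.mean(axis=2, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=2))  # (R, S)
    per_stim = np.full((n_stim, n_roi, n_roi), np.nan)
    for s in range(n_stim):
        x = centred[:, s, :]
        denom = np.outer(norms[:, s], norms[:, s])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (x @ x.T) / denom, np.nan)
        per_stim[s] = r
    with np.errstate(invalid="ignore"):
        if average == "fisher":
            z = np.arctanh(np.clip(per_stim, -1 + 1e-12, 1 - 1e-12))
            matrix = np.tanh(np.nanmean(z, axis=0))
        elif average == "mean":
            matrix = np.nanmean(per_stim, axis=0)
        else:
            raise ValueError(f"unknown averaging mode {average!r}")
    np.fill_diagonal(matrix, 1.0)
    matrix = np.clip(matrix, -1.0, 1.0)
    matrix = 0.5 * (matrix + matrix.T)  # symmetrise away float round-off
    return ConnectivityMatrix(
        labels=labels,
        matrix=matrix,
        per_stimulus=per_stim,
        n_stimuli=n_stim,
        networks=dict(networks or {}),
    )


def _lower_triangle_mean(matrix: np.ndarray, idx: np.ndarray) -> float:
    sub = matrix[np.ix_(idx, idx)]
    tri = sub[np.tril_indices(len(idx), k=-1)]
    return float(np.nanmean(tri))


def network_mean_psfc(cm: ConnectivityMatrix, network) -> float:
    """Mean of the below-diagonal entries restricted to a ROI subset.

    ``network`` is a network name registered on the matrix or an explicit
    sequence of ROI labels — e.g. the DPMS minus its brainstem nodes
    (PAG, RVM) for the sensitivity analysis.
    """
    if isinstance(network, str):
        members = cm.networks[network]
    else:
        members = tuple(network)
    if len(members) < 2:
        raise ValueError("network must contain at least 2 ROIs")
    idx = np.array([cm.labels.index(m) for m in members])
    return _lower_triangle_mean(cm.matrix, idx)


def psfc_by_stimulus(cm: ConnectivityMatrix, network) -> np.ndarray:
    """Per-stimulus network mean, from each stimulus's single-window matrix."""
    members = cm.networks[network] if isinstance(network, str) else tuple(network)
    if len(members) < 2:
        raise ValueError("network must contain at least 2 ROIs")
    idx = np.array([cm.labels.index(m) for m in members])
    return np.array(
        [_lower_triangle_mean(cm.per_stimulus[s], idx) for s in range(cm.n_stimuli)]
    )
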