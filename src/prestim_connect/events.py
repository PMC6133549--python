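"""Stimulus event timing on the acquisition clock.

Noxious stimuli are brief (~1 s) events delivered during a continuous EPI
acquisition. Onsets are seconds from the start of the scan; the protocol
enforces a minimum inter-stimulus interval so that each evoked haemodynamic
response has largely resolved before the next pre-stimulus window opens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StimulusProtocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Onsets and durations of noxious events, seconds from scan start."""

    onsets: np.ndarray
    durations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        if self.durations is None:
            durations = np.ones_like(onsets)
        else:
            durations = np.asarray(self.durations, dtype=float)
        if onsets.ndim != 1 or durations.shape != onsets.shape:
            raise ValueError("onsets and durations must be 1-D and equal length")
        if onsets.size and np.any(onsets < 0):
            raise ValueError("onsets must be non-negative")
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)

    @property
    def n_stimuli(self) -> int:
        return int(self.onsets.size)

    def validate(self, scan_duration: float | None = None,
                 min_isi: float | None = None) -> None:
        """Raise if the protocol violates the acquisition span or ISI floor."""
        if scan_duration is not None and self.onsets.size:
            if self.onsets[-1] >= scan_duration:
                raise ValueError(
                    f"onset {self.onsets[-1]:.2f} s lies beyond the "
                    f"{scan_duration:.2f} s acquisition span"
                )
        if min_isi is not None and self.onsets.size > 1:
            gaps = np.diff(self.onsets)
            if np.any(gaps < min_isi):
                bad = float(gaps.min())
                raise ValueError(
                    f"inter-stimulus interval {bad:.2f} s below the "
                    f"{min_isi:.2f} s minimum"
                )

    @classmethod
    def from_tsv(cls, path) -> "StimulusProtocol":
        """Read a tab-separated events table with columns onset, duration.

        Rows are sorted by onset, so the file's row order is immaterial.
        """
        table = pd.read_csv(path, sep="\t")
        missing = {"onset", "duration"} - set(table.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        table = table.sort_values("onset")
        return cls(table["onset"].to_numpy(float), table["duration"].to_numpy(float))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"onset": self.onsets, "duration": self.durations}).to_csv(
            path, sep="\t", index=False
        )
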