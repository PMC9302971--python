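"""FRAP trace processing: background subtraction and first-frame normalization.

A photobleaching experiment records intensity in three regions per frame —
the bleached ROI, an unbleached ROI on the opposite side of the structure,
and a cell-free background ROI.  The processing is deliberately minimal and
mirrors standard practice: subtract the background from the bleached signal,
then divide by the background-subtracted intensity of the first frame
imaged, so the normalized trace starts at exactly 1 and post-bleach values
are fractions of the pre-bleach level.  Summary statistics are the
immediately-post-bleach fraction (how much signal the bleach removed) and
the recovery percentage at a chosen time such as 220 s (how much exchanged
back in).  No diffusion model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "normalize_trace",
    "recovery_at",
    "postbleach_fraction",
]


@dataclass
class FrapTrace:
    """Raw per-frame ROI intensities; the bleach happens between samples
    ``bleach_index - 1`` and ``bleach_index``."""

    times: np.ndarray
    bleached: np.ndarray
    unbleached: np.ndarray
    background: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.unbleached = np.asarray(self.unbleached, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.times.size
        for arr, name in [
            (self.bleached, "bleached"),
            (self.unbleached, "unbleached"),
            (self.background, "background"),
        ]:
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != times length {n}")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not 1 <= self.bleach_index <= n - 1:
            raise ValueError("need at least one pre-bleach and one post-bleach sample")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FrapTrace":
        """Build from a tidy table with columns time_s, bleached, unbleached,
        background, phase (pre|post)."""
        df = df.sort_values("time_s")
        phase = df["phase"].to_numpy()
        post = np.flatnonzero(phase == "post")
        if post.size == 0 or post[0] == 0:
            raise ValueError("trace must contain pre-bleach then post-bleach samples")
        return cls(
            times=df["time_s"].to_numpy(),
            bleached=df["bleached"].to_numpy(),
            unbleached=df["unbleached"].to_numpy(),
            background=df["background"].to_numpy(),
            bleach_index=int(post[0]),
        )


@dataclass
class NormalizedTrace:
    """Background-subtracted trace as fractions of the first frame imaged."""

    times: np.ndarray
    normalized: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if self.normalized[0] != 1.0:
            raise ValueError("first normalized sample must be exactly 1")


def normalize_trace(trace: FrapTrace, reference: str = "first") -> NormalizedTrace:
    """Background-subtract and normalize a FRAP trace.

    normalized_i = (bleached_i − background_i) / (bleached_0 − background_0).

    ``reference="first"`` divides by the first frame imaged;
    ``reference="prebleach_mean"`` divides by the mean of all pre-bleach
    frames instead (robustness option, off by default).  With the first-frame
    reference the first sample is exactly 1 by construction; with the mean
    reference the trace is rescaled so the first sample is still exactly 1.
    """
    signal = trace.bleached - trace.background
    if reference == "first":
        denom = signal[0]
    elif reference == "prebleach_mean":
        denom = signal[: trace.bleach_index].mean()
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if not denom > 0:
        raise ValueError("non-positive first-frame background-subtracted intensity")
    normalized = signal / denom
    normalized = normalized / normalized[0]  # exact 1 at the first sample
    return NormalizedTrace(trace.times, normalized, trace.bleach_index)


def recovery_at(trace: NormalizedTrace, t_s: float) -> float:
    """Recovery percentage at the post-bleach sample nearest ``t_s`` seconds.

    No interpolation: reported values correspond to acquired timepoints.
    ``t_s`` must be at or after the first post-bleach sample.
    """
    post_times = trace.times[trace.bleach_index :]
    if t_s < post_times[0]:
        raise ValueError(f"t={t_s}s is before the first post-bleach sample ({post_times[0]}s)")
    idx = int(np.argmin(np.abs(post_times - t_s)))
    return float(trace.normalized[trace.bleach_index + idx] * 100.0)


def postbleach_fraction(trace: NormalizedTrace) -> float:
    """Percentage of initial intensity immediately after the bleach."""
    return float(trace.normalized[trace.bleach_index] * 100.0)
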