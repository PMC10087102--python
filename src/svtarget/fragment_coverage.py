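"""Per-base coverage, read-length distributions, and Dicer-dependent
fragment calling over a small reference (e.g. a vault gene).

Coordinates are 0-based half-open throughout; depth mirrors a per-position
genome-coverage dump, optionally RPM-scaled (1e6 / total mapped reads).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, CoordinateError


@dataclass(frozen=True)
class CoverageProfile:
    reference_id: str
    values: np.ndarray
    scale: float | None = None

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FragmentCall:
    start: int
    end: int
    mean_wt: float
    mean_kd: float
    depletion_ratio: float
    dicer_dependent: bool

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _read_interval(read) -> tuple[int, int]:
    if isinstance(read, tuple):
        return read[0], read[1]
    return read.start, read.end


def per_base_coverage(reads, reference_length: int, reference_id: str = "",
                      rpm_total: int | None = None) -> CoverageProfile:
    """Depth at position p = number of reads covering p.

    If ``rpm_total`` is given, depths are multiplied by 1e6 / rpm_total and
    the factor is recorded on the profile.
    """
    delta = np.zeros(reference_length + 1)
    for read in reads:
        start, end = _read_interval(read)
        if not (0 <= start < end <= reference_length):
            raise CoordinateError(
                f"read [{start}, {end}) outside reference of length "
                f"{reference_length}")
        delta[start] += 1
        delta[end] -= 1
    depth = np.cumsum(delta[:-1])
    scale = None
    if rpm_total is not None:
        if rpm_total <= 0:
            raise ConfigurationError("rpm_total: must be > 0")
        scale = 1e6 / rpm_total
        depth = depth * scale
    return CoverageProfile(reference_id=reference_id, values=depth, scale=scale)


def size_distribution(reads, min_len: int = 15, max_len: int = 30
                      ) -> dict[int, int]:
    """Histogram of read lengths inside the [min_len, max_len] filter window."""
    if min_len > max_len:
        raise ConfigurationError("min_len: must be <= max_len")
    hist: dict[int, int] = {}
    for read in reads:
        start, end = _read_interval(read)
        length = end - start
        if min_len <= length <= max_len:
            hist[length] = hist.get(length, 0) + 1
    return dict(sorted(hist.items()))


def call_fragment(profile_wt: CoverageProfile, profile_kd: CoverageProfile,
                  rel_threshold: float = 0.5, ratio_threshold: float = 2.0
                  ) -> list[FragmentCall]:
    """Maximal runs of positions with WT depth >= rel_threshold * max depth.

    Each run is annotated with its WT/KD mean-depth ratio (the KD mean is
    floored at one raw read-equivalent to avoid division by zero) and a
    dicer_dependent flag (ratio >= ratio_threshold). Calls are disjoint and
    sorted. An all-zero WT profile yields an empty list.
    """
    if profile_wt.length != profile_kd.length:
        raise CoordinateError("profiles must cover the same reference length")
    wt = profile_wt.values
    kd = profile_kd.values
    peak = wt.max() if wt.size else 0.0
    if peak <= 0:
        return []
    mask = wt >= rel_threshold * peak
    # one raw read of depth in the KD profile's units
    kd_floor = profile_kd.scale if profile_kd.scale is not None else 1.0

    calls: list[FragmentCall] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        mean_wt = float(wt[start:end].mean())
        mean_kd = float(kd[start:end].mean())
        ratio = mean_wt / max(mean_kd, kd_floor)
        calls.append(FragmentCall(
            start=int(start), end=int(end), mean_wt=mean_wt, mean_kd=mean_kd,
            depletion_ratio=ratio,
            dicer_dependent=ratio >= ratio_threshold))
    return calls
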