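"""Segment chromosomes into two arms and one pericentromeric region.

Pericentromeres in grass genomes are recombination-suppressed, gene-poor and
repeat-rich.  This module computes windowed gene density, repeat length and
recombination rate (1 Mb windows advancing by 500 kb), then grows the
pericentromeric interval outwards from the centromere through every window
whose smoothed recombination rate stays below ``r_max`` and whose repeat
fraction stays above ``t_min``.  Explicit boundaries can be supplied instead,
so manually curated partitions are reproducible exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW = 1_000_000
STEP = 500_000


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class GenomePartition:
    """Arm/peri intervals (bp, half-open) tiling one chromosome."""

    chrom: str
    length: int
    arm1: tuple[int, int]
    peri: tuple[int, int]
    arm2: tuple[int, int]
    centromere: tuple[int, int]

    def __post_init__(self):
        a1, p, a2 = self.arm1, self.peri, self.arm2
        if not (a1[0] == 0 and a1[1] == p[0] and p[1] == a2[0] and a2[1] == self.length):
            raise PartitionError(f"{self.chrom}: arm1/peri/arm2 do not tile [0,{self.length})")
        c = self.centromere
        if not (p[0] <= c[0] and c[1] <= p[1]):
            raise PartitionError(f"{self.chrom}: centromere {c} not inside peri {p}")

    def classify(self, start: int, end: int) -> str:
        """'arm' or 'peri' for an interval, by midpoint."""
        mid = (start + end) / 2.0
        return "peri" if self.peri[0] <= mid < self.peri[1] else "arm"


class RecombinationMap:
    """Piecewise-linear genetic map from (bp, cM) markers on one chromosome.

    The local rate between consecutive markers is dcM/dMb; queries outside the
    marker span get the nearest interval's rate of 0 beyond the map ends
    clamped to the terminal intervals.
    """

    def __init__(self, bp: np.ndarray, cm: np.ndarray):
        bp = np.asarray(bp, dtype=float)
        cm = np.asarray(cm, dtype=float)
        if len(bp) < 2:
            raise ValueError("need at least two markers")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("marker bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("genetic map inconsistency: cM must be non-decreasing")
        self.bp = bp
        self.cm = cm

    def cm_at(self, pos) -> np.ndarray:
        """Interpolated genetic position (cM), clamped at the map ends."""
        return np.interp(np.asarray(pos, dtype=float), self.bp, self.cm)

    def rate_at(self, pos) -> np.ndarray:
        """cM/Mb of the marker interval enclosing each query position."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        idx = np.clip(np.searchsorted(self.bp, pos, side="right") - 1, 0, len(self.bp) - 2)
        dcm = self.cm[idx + 1] - self.cm[idx]
        dmb = (self.bp[idx + 1] - self.bp[idx]) / 1e6
        return dcm / dmb

    def interval_rate(self, start: float, end: float) -> float:
        """Mean rate over [start, end): interpolated dcM over dMb."""
        if end <= start:
            raise ValueError("empty interval")
        return float((self.cm_at(end) - self.cm_at(start)) / ((end - start) / 1e6))

    def interval_rates(self) -> pd.DataFrame:
        """Per-marker-interval rates (start, end, rate)."""
        return pd.DataFrame(
            {
                "start": self.bp[:-1].astype(int),
                "end": self.bp[1:].astype(int),
                "rate": np.diff(self.cm) / (np.diff(self.bp) / 1e6),
            }
        )


def n_windows(chrom_length: int) -> int:
    if chrom_length < WINDOW:
        return 1
    return (chrom_length - WINDOW) // STEP + 1


def window_stats(
    gene_starts: np.ndarray,
    repeat_intervals: np.ndarray,
    chrom_length: int,
    recomb_map: RecombinationMap | None = None,
    chrom: str = "chr",
) -> pd.DataFrame:
    """Windowed gene density, repeat length and recombination rate.

    Genes are counted in a window if their start lies in it (each gene counted
    once per window pass); repeat length is overlapping repeat bp per window
    bp.  Windows are 1 Mb advancing by 500 kb; a short chromosome gets one
    window truncated at its end.
    """
    gene_starts = np.asarray(gene_starts, dtype=float)
    if gene_starts.size and (gene_starts.min() < 0 or gene_starts.max() >= chrom_length):
        raise ValueError("gene start outside [0, chrom_length)")
    rep = np.asarray(repeat_intervals, dtype=float).reshape(-1, 2)
    if rep.size and rep.min() < 0:
        raise ValueError("negative repeat coordinate")

    starts = np.arange(n_windows(chrom_length)) * STEP
    ends = np.minimum(starts + WINDOW, chrom_length)
    gene_sorted = np.sort(gene_starts)
    counts = np.searchsorted(gene_sorted, ends) - np.searchsorted(gene_sorted, starts)

    repeat_bp = np.zeros(len(starts))
    if rep.size:
        for ws_i, (ws, we) in enumerate(zip(starts, ends)):
            ov = np.minimum(rep[:, 1], we) - np.maximum(rep[:, 0], ws)
            repeat_bp[ws_i] = ov[ov > 0].sum()

    widths_mb = (ends - starts) / 1e6
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "window_start": starts.astype(int),
            "window_end": ends.astype(int),
            "gene_density": counts / widths_mb,
            "repeat_length": repeat_bp / (ends - starts),
        }
    )
    if recomb_map is not None:
        out["recombination"] = [
            recomb_map.interval_rate(s, e) for s, e in zip(starts, ends)
        ]
    else:
        out["recombination"] = np.nan
    return out


def segment(
    track: pd.DataFrame,
    centromere: tuple[int, int],
    chrom_length: int | None = None,
    r_max: float = 1.0,
    t_min: float | None = None,
    smooth_windows: int = 5,
) -> GenomePartition:
    """Grow the pericentromere from the centromere through qualifying windows.

    A window qualifies when its ``smooth_windows``-point running-mean
    recombination rate is below ``r_max`` and its repeat fraction exceeds
    ``t_min`` (default: the chromosome's median repeat fraction).  The
    pericentromere is the maximal contiguous qualifying run containing the
    centromere, expanded if needed so the centromere is fully inside it.
    """
    chrom = str(track["chrom"].iloc[0])
    if chrom_length is None:
        chrom_length = int(track["window_end"].max())
    c0, c1 = int(centromere[0]), int(centromere[1])
    if not (0 <= c0 < c1 <= chrom_length):
        raise PartitionError(f"{chrom}: centromere {centromere} outside [0,{chrom_length})")

    if t_min is None:
        t_min = float(track["repeat_length"].median())
    smoothed = (
        track["recombination"].rolling(smooth_windows, center=True, min_periods=1).mean()
    )
    ok = ((smoothed < r_max) & (track["repeat_length"] > t_min)).to_numpy()

    starts = track["window_start"].to_numpy()
    ends = track["window_end"].to_numpy()
    cen_mid = (c0 + c1) / 2.0
    covering = np.where((starts <= cen_mid) & (cen_mid < ends))[0]
    if covering.size == 0:
        covering = np.array([np.argmin(np.abs((starts + ends) / 2.0 - cen_mid))])
    seed = int(covering[0])

    if ok.all():
        warnings.warn(
            f"{chrom}: thresholds admit every window; pericentromere spans the "
            "whole chromosome and the arms are empty",
            stacklevel=2,
        )
        lo, hi = 0, len(ok) - 1
    elif not ok[seed]:
        warnings.warn(
            f"{chrom}: centromere window fails the pericentromere criteria; "
            "pericentromere restricted to the centromere span",
            stacklevel=2,
        )
        lo = hi = seed
    else:
        lo = hi = seed
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        while hi < len(ok) - 1 and ok[hi + 1]:
            hi += 1

    peri_start = int(min(starts[lo], c0))
    peri_end = int(max(ends[hi], c1))
    peri_start = max(peri_start, 0)
    peri_end = min(peri_end, chrom_length)
    return GenomePartition(
        chrom=chrom,
        length=int(chrom_length),
        arm1=(0, peri_start),
        peri=(peri_start, peri_end),
        arm2=(peri_end, int(chrom_length)),
        centromere=(c0, c1),
    )


def partition_from_boundaries(
    chrom: str,
    chrom_length: int,
    peri: tuple[int, int],
    centromere: tuple[int, int] | None = None,
) -> GenomePartition:
    """Build a partition from explicit (e.g. manually curated) boundaries."""
    if centromere is None:
        centromere = peri
    return GenomePartition(
        chrom=chrom,
        length=int(chrom_length),
        arm1=(0, int(peri[0])),
        peri=(int(peri[0]), int(peri[1])),
        arm2=(int(peri[1]), int(chrom_length)),
        centromere=(int(centromere[0]), int(centromere[1])),
    )


def classify_region(
    start: int, end: int, chrom: str, partitions: dict[str, GenomePartition]
) -> str:
    """'arm' or 'peri' for a feature, by its midpoint."""
    if chrom not in partitions:
        raise PartitionError(f"chromosome {chrom!r} absent from partition")
    return partitions[chrom].classify(start, end)


def classify_frame(
    features: pd.DataFrame, partitions: dict[str, GenomePartition]
) -> pd.Series:
    """Vectorised :func:`classify_region` over a chrom/start/end frame."""
    return pd.Series(
        [
            classify_region(s, e, c, partitions)
            for c, s, e in zip(features["chrom"], features["start"], features["end"])
        ],
        index=features.index,
        name="region",
    )


def partitions_to_bed(partitions: dict[str, GenomePartition]) -> pd.DataFrame:
    """Flatten partitions into a BED-like frame (name = arm1/peri/arm2)."""
    rows = []
    for p in partitions.values():
        for name, (s, e) in (("arm1", p.arm1), ("peri", p.peri), ("arm2", p.arm2)):
            if e > s:
                rows.append({"chrom": p.chrom, "start": s, "end": e, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
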