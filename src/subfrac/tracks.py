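"""Per-position signal containers with fast windowed range sums.

A :class:`SignalTrack` wraps a bedGraph-like table (chrom, pos, value
columns).  Positions are the starts of fine-grained bins (or single bases);
a value is attributed to a query window when its position falls inside it.
Range sums are O(log n) via per-chromosome cumulative sums.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KIND_COLUMNS = {
    "sirna": ("count",),
    "methylation": ("meth", "total"),
    "histone": ("treat", "input"),
    "generic": ("value",),
}


class SignalTrack:
    """Sorted, indexed per-position signal for one data kind.

    Parameters
    ----------
    df : frame with columns chrom, pos and the kind's value columns
         (methylation additionally has a ``context`` column).
    kind : one of sirna / methylation / histone / generic.
    library_total : total mapped library size (required for TP10M scaling
         of small-RNA tracks).
    """

    def __init__(self, df: pd.DataFrame, kind: str, library_total: float | None = None):
        if kind not in KIND_COLUMNS:
            raise ValueError(f"unknown track kind {kind!r}")
        needed = ("chrom", "pos") + KIND_COLUMNS[kind]
        for col in needed:
            if col not in df.columns:
                raise ValueError(f"{kind} track missing column {col!r}")
        if kind == "methylation" and "context" not in df.columns:
            raise ValueError("methylation track missing 'context' column")
        for col in KIND_COLUMNS[kind]:
            if (df[col].to_numpy() < 0).any():
                raise ValueError(f"negative values in column {col!r}")
        if kind == "methylation" and (df["meth"] > df["total"]).any():
            raise ValueError("methylated_reads exceed total_reads")
        self.kind = kind
        self.library_total = library_total
        self.df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self._index: dict = {}

    def _chrom_index(self, chrom: str, context: str | None = None):
        key = (chrom, context)
        if key not in self._index:
            sub = self.df[self.df["chrom"] == chrom]
            if context is not None:
                sub = sub[sub["context"] == context]
            pos = sub["pos"].to_numpy(dtype=float)
            cums = {
                col: np.concatenate([[0.0], np.cumsum(sub[col].to_numpy(dtype=float))])
                for col in KIND_COLUMNS[self.kind]
            }
            self._index[key] = (pos, cums)
        return self._index[key]

    def window_sums(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        field: str,
        context: str | None = None,
    ) -> np.ndarray:
        """Sum of ``field`` over positions in each half-open [start, end)."""
        pos, cums = self._chrom_index(chrom, context)
        cum = cums[field]
        lo = np.searchsorted(pos, np.asarray(starts, dtype=float), side="left")
        hi = np.searchsorted(pos, np.asarray(ends, dtype=float), side="left")
        return cum[hi] - cum[lo]


class CoverageIndex:
    """bp-coverage queries against a set of (possibly overlapping) intervals."""

    def __init__(self, intervals_by_chrom: dict[str, np.ndarray]):
        self._cov = {}
        for chrom, iv in intervals_by_chrom.items():
            iv = np.asarray(iv, dtype=float).reshape(-1, 2)
            iv = iv[np.argsort(iv[:, 0])]
            merged = []
            for s, e in iv:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            merged = np.asarray(merged) if merged else np.empty((0, 2))
            # breakpoints and cumulative covered bp up to each breakpoint
            bounds = merged.ravel()
            cum = np.zeros(len(bounds) + 1)
            covered = 0.0
            for i, (s, e) in enumerate(merged):
                cum[2 * i + 1] = covered  # at start of interval
                covered += e - s
                cum[2 * i + 2] = covered  # at end of interval
            self._cov[chrom] = (merged, bounds, cum)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoverageIndex":
        return cls(
            {
                str(c): g[["start", "end"]].to_numpy()
                for c, g in df.groupby("chrom")
            }
        )

    def _cum_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        merged, bounds, cum = self._cov[chrom]
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(bounds, x, side="right")
        base = cum[idx]
        inside = (idx % 2) == 1  # within an interval: add partial coverage
        if inside.any():
            starts = merged[(idx[inside] - 1) // 2, 0]
            base = base.copy()
            base[inside] += x[inside] - starts
        return base

    def coverage(self, chrom: str, starts, ends) -> np.ndarray:
        """Covered bp of each half-open [start, end)."""
        if chrom not in self._cov:
            return np.zeros(np.asarray(starts).shape)
        return self._cum_at(chrom, ends) - self._cum_at(chrom, starts)

    def chroms(self):
        return self._cov.keys()
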