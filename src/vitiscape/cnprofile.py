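"""Fixed-unmasked-size windows, per-window depth and absolute copy number.

Windows contain a fixed number of unmasked bases (1000 by default — the
"KbUS" unit of WSSD-style analyses): masked bases inside a window extend its
genomic span but not its unmasked count, so every window carries the same
amount of alignable sequence.  Per-window depth is calibrated to absolute
copy number by locating the diploid (copy-2) background with iterative
3-sigma trimming, the control-region logic of window-based CN estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import ReferenceGenome


@dataclass
class WindowSet:
    """Ordered genomic windows, each with exactly ``size`` unmasked bases.

    ``df`` columns: chrom, start, end (0-based half-open genomic), unmasked,
    gc (fraction over unmasked bases).  ``unmasked_positions`` maps each
    chromosome to the boolean per-base "is unmasked" array used to build the
    windows; depth computation needs it to honour the rule that a read only
    counts for a window when it overlaps unmasked sequence.
    """

    df: pd.DataFrame
    size: int
    unmasked_positions: dict[str, np.ndarray]

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class CopyNumberProfile:
    """Per-window depth and calibrated absolute copy number for one sample."""

    sample_id: str
    windows: WindowSet
    raw_depth: np.ndarray
    corrected_depth: np.ndarray
    cn: np.ndarray
    control_mean: float
    control_sd: float

    def to_tsv(self, path: str | Path) -> None:
        out = self.windows.df.copy()
        out["raw_depth"] = self.raw_depth
        out["corrected_depth"] = self.corrected_depth
        out["cn"] = self.cn
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_depths(
        cls, sample_id: str, windows: WindowSet, depths: np.ndarray, **kw
    ) -> "CopyNumberProfile":
        """Calibrate raw depths straight into a profile (no GC correction)."""
        return calibrate_cn(depths, windows, sample_id=sample_id, **kw)


def define_windows(reference: ReferenceGenome, size: int = 1000) -> WindowSet:
    """Tile each chromosome into windows of exactly ``size`` unmasked bases.

    Scanning left to right, a window closes when ``size`` unmasked bases have
    accumulated; the next window starts at the following base, so windows are
    contiguous and masked bases belong to the window whose span they fall in.
    A terminal window with fewer than ``size`` unmasked bases is dropped.  A
    fully masked chromosome simply contributes no windows.
    """
    if size < 100:
        raise ValueError("window size must be >= 100 unmasked bases")
    rows = []
    unmasked_positions: dict[str, np.ndarray] = {}
    for chrom, seq in reference.chromosomes:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        masked = reference.mask_array(chrom)
        unmasked = ~masked & (arr != ord("N"))
        unmasked_positions[chrom] = unmasked
        idx = np.flatnonzero(unmasked)
        n_windows = len(idx) // size
        if n_windows == 0:
            continue
        # window k covers [prev_end, position of its size-th unmasked base + 1)
        ends = idx[size - 1 :: size][:n_windows] + 1
        starts = np.concatenate(([0], ends[:-1]))
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        gc_cum = np.concatenate(([0], np.cumsum(is_gc & unmasked)))
        gc = (gc_cum[ends] - gc_cum[starts]) / size
        for s, e, g in zip(starts, ends, gc):
            rows.append((chrom, int(s), int(e), size, float(g)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "unmasked", "gc"])
    return WindowSet(df=df, size=size, unmasked_positions=unmasked_positions)


def window_depth(
    read_starts: dict[str, np.ndarray],
    windows: WindowSet,
    read_length: int,
) -> np.ndarray:
    """Raw per-window depth (mean coverage per unmasked base).

    A read is assigned to the window owning the left-most unmasked base its
    alignment span overlaps, so each read counts exactly once.  Depth of a
    window is ``assigned_reads * read_length / size``.
    """
    depths = np.zeros(len(windows.df), dtype=float)
    df = windows.df
    for chrom, counts in read_starts.items():
        if chrom not in windows.unmasked_positions:
            continue
        unmasked = windows.unmasked_positions[chrom]
        L = len(unmasked)
        counts = np.asarray(counts)
        if len(counts) != L:
            raise ValueError(
                f"read starts for {chrom} have length {len(counts)}, "
                f"chromosome has {L} bases"
            )
        sub = df[df.chrom == chrom]
        if sub.empty:
            continue
        # map every unmasked position to its window's row index (or -1)
        win_of = np.full(L, -1, dtype=np.int64)
        for row, (s, e) in zip(sub.index, zip(sub.start, sub.end)):
            win_of[s:e] = row
        win_of[~unmasked] = -1
        # next unmasked position at or after p (L if none)
        nxt = np.full(L + 1, L, dtype=np.int64)
        idx = np.flatnonzero(unmasked)
        if len(idx):
            nxt[: idx[-1] + 1] = idx[np.searchsorted(idx, np.arange(idx[-1] + 1))]
        starts = np.repeat(np.arange(L), counts)
        first = nxt[starts]
        ok = first < np.minimum(starts + read_length, L)
        w = win_of[first[ok]]
        w = w[w >= 0]
        np.add.at(depths, w, 1)
    return depths * read_length / windows.size


def gc_correct(
    raw_depth: np.ndarray,
    gc: np.ndarray,
    n_bins: int = 20,
    min_bin_windows: int = 10,
    enabled: bool = True,
) -> np.ndarray:
    """Median-ratio GC correction over equal-width GC bins.

    Each depth is scaled by (global median / median of its GC bin); bins with
    fewer than ``min_bin_windows`` windows inherit the nearest populated
    bin's factor.  With ``enabled=False`` the input is returned unchanged.
    """
    raw_depth = np.asarray(raw_depth, dtype=float)
    if not enabled:
        return raw_depth.copy()
    if len(raw_depth) < 200:
        raise ValueError("need >= 200 windows for stable GC bins")
    if not np.any(raw_depth > 0):
        raise ValueError("all-zero depths")
    gc = np.asarray(gc, dtype=float)
    edges = np.linspace(gc.min(), gc.max() + 1e-9, n_bins + 1)
    bin_of = np.clip(np.digitize(gc, edges) - 1, 0, n_bins - 1)
    global_median = np.median(raw_depth)
    factors = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bin_of == b
        if sel.sum() >= min_bin_windows:
            m = np.median(raw_depth[sel])
            if m > 0:
                factors[b] = global_median / m
    populated = np.flatnonzero(~np.isnan(factors))
    if len(populated) == 0:
        raise ValueError("no populated GC bins")
    for b in range(n_bins):
        if np.isnan(factors[b]):
            factors[b] = factors[populated[np.argmin(np.abs(populated - b))]]
    return raw_depth * factors[bin_of]


def calibrate_cn(
    corrected_depth: np.ndarray,
    windows: WindowSet,
    sample_id: str = "sample",
    raw_depth: np.ndarray | None = None,
    max_iter: int | None = None,
) -> CopyNumberProfile:
    """Calibrate depths to absolute copy number via 3-sigma iterative trimming.

    The copy-2 control set starts as all windows; windows outside mean ± 3 sd
    are dropped and the statistics recomputed until the set is stable.  The
    final mean is the diploid depth, and ``cn_i = 2 * depth_i / control_mean``.
    Profiles where trimming discards more than 90% of windows are rejected as
    pathological.
    """
    d = np.asarray(corrected_depth, dtype=float)
    if len(d) < 50:
        raise ValueError("need >= 50 windows to calibrate")
    keep = np.ones(len(d), dtype=bool)
    # trimming is monotone, so it converges within len(d) iterations
    for _ in range(max_iter if max_iter is not None else len(d) + 1):
        mu = d[keep].mean()
        sd = d[keep].std()
        new = keep & (np.abs(d - mu) <= 3 * sd)  # dropped windows stay dropped
        if new.sum() < 0.1 * len(d):
            raise ValueError("control trimming removed >90% of windows")
        if np.array_equal(new, keep):
            break
        keep = new
    mu = float(d[keep].mean())
    sd = float(d[keep].std())
    if mu <= 0:
        raise ValueError("non-positive control mean")
    return CopyNumberProfile(
        sample_id=sample_id,
        windows=windows,
        raw_depth=np.asarray(raw_depth if raw_depth is not None else d, dtype=float),
        corrected_depth=d,
        cn=2.0 * d / mu,
        control_mean=mu,
        control_sd=sd,
    )


def profile_sample(
    reference: ReferenceGenome,
    read_starts: dict[str, np.ndarray],
    read_length: int,
    sample_id: str = "sample",
    window_size: int = 1000,
    windows: WindowSet | None = None,
    gc_correction: bool = False,
) -> CopyNumberProfile:
    """Convenience path: windows -> depth -> (GC) -> absolute CN."""
    if windows is None:
        windows = define_windows(reference, window_size)
    raw = window_depth(read_starts, windows, read_length)
    corrected = gc_correct(raw, windows.df.gc.to_numpy(), enabled=gc_correction)
    return calibrate_cn(corrected, windows, sample_id=sample_id, raw_depth=raw)
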