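"""Duplication/deletion calling, digital CGH and shared-CNVR intersection.

Segmental duplications and deletions are defined directly on the absolute
copy-number track: maximal runs of at least five consecutive windows with
CN > 2.5 (duplication) or CN < 1.5 (deletion).  Digital CGH compares two
profiles window by window through the log2 ratio of their copy numbers and
keeps runs longer than 10 kbp beyond |L2R| > 0.25.  Regions called in several
varieties are intersected base-wise into shared copy-number-variant regions
(CNVRs); gene content is annotated from a GFF3 file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cnprofile import CopyNumberProfile

REGION_COLUMNS = ["chrom", "start", "end", "kind", "n_windows", "mean_value"]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first, last+1) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _smooth(values: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return values
    kernel = np.ones(k) / k
    pad = k // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(values)]


def call_wssd(
    profile: CopyNumberProfile,
    min_windows: int = 5,
    dup_threshold: float = 2.5,
    del_threshold: float = 1.5,
    smooth: int = 1,
) -> pd.DataFrame:
    """WSSD-style duplication/deletion calls from a copy-number profile.

    A window is in the duplicated state when its CN exceeds ``dup_threshold``
    and in the deleted state when below ``del_threshold``; maximal runs of at
    least ``min_windows`` consecutive same-state windows become regions whose
    bounds are the genomic bounds of the first and last member window.
    ``smooth`` > 1 applies a centered rolling mean of that many windows to the
    CN track before thresholding (off by default).

    Returns a BED-like frame with columns chrom, start, end, kind, n_windows,
    mean_value (mean CN over member windows).
    """
    df = profile.windows.df
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        cn = _smooth(profile.cn[sub.index.to_numpy()], smooth)
        raw_cn = profile.cn[sub.index.to_numpy()]
        for kind, state in (
            ("duplication", cn > dup_threshold),
            ("deletion", cn < del_threshold),
        ):
            for first, last in _runs(state):
                if last - first < min_windows:
                    continue
                rows.append(
                    (
                        chrom,
                        int(sub.start.iloc[first]),
                        int(sub.end.iloc[last - 1]),
                        kind,
                        last - first,
                        float(raw_cn[first:last].mean()),
                    )
                )
    out = pd.DataFrame(rows, columns=REGION_COLUMNS)
    return out.sort_values(["chrom", "start"], ignore_index=True)


def compute_l2r(
    sample: CopyNumberProfile,
    reference: CopyNumberProfile,
    min_cn: float = 0.1,
) -> np.ndarray:
    """Per-window log2 ratio of sample CN over reference CN.

    Windows where either profile has CN below ``min_cn`` are undefined (NaN)
    and excluded from downstream segmentation.  Both profiles must be built
    on the identical window set.
    """
    a, b = sample.windows.df, reference.windows.df
    if len(a) != len(b) or not (
        a[["chrom", "start", "end"]].values == b[["chrom", "start", "end"]].values
    ).all():
        raise ValueError("profiles are built on different window sets")
    with np.errstate(divide="ignore", invalid="ignore"):
        l2r = np.log2(sample.cn / reference.cn)
    l2r[(sample.cn < min_cn) | (reference.cn < min_cn)] = np.nan
    return l2r


def call_cgh(
    l2r: np.ndarray,
    windows,
    threshold: float = 0.25,
    min_length: int = 10_000,
) -> pd.DataFrame:
    """Digital-CGH gain/loss regions from a per-window L2R track.

    Undefined (NaN) windows are removed before segmentation; maximal runs of
    remaining consecutive windows with L2R > threshold (gain) or
    L2R < -threshold (loss) whose genomic span exceeds ``min_length`` are
    reported.  mean_value is the mean L2R over member windows.
    """
    df = windows.df
    l2r = np.asarray(l2r, dtype=float)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        vals = l2r[sub.index.to_numpy()]
        defined = ~np.isnan(vals)
        sub = sub[defined]
        vals = vals[defined]
        if not len(vals):
            continue
        for kind, state in (("gain", vals > threshold), ("loss", vals < -threshold)):
            for first, last in _runs(state):
                start = int(sub.start.iloc[first])
                end = int(sub.end.iloc[last - 1])
                if end - start <= min_length:
                    continue
                rows.append(
                    (chrom, start, end, kind, last - first, float(vals[first:last].mean()))
                )
    out = pd.DataFrame(rows, columns=REGION_COLUMNS)
    return out.sort_values(["chrom", "start"], ignore_index=True)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_cnvrs(
    region_sets: dict[str, pd.DataFrame],
    kind: str,
) -> pd.DataFrame:
    """Shared vs sample-specific CNVRs across two or more samples.

    A shared CNVR is a maximal interval covered by a same-kind region in
    every sample (base-wise intersection, then merged).  Input regions that
    do not touch any shared interval are reported as sample-specific.

    Returns a frame with columns chrom, start, end, kind, status
    ('shared' / 'sample-specific'), samples (comma list; for shared rows all
    samples), mean_values (comma list of each overlapping region's mean, in
    sample order).
    """
    if len(region_sets) < 2:
        raise ValueError("need regions from at least two samples")
    per_sample: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for sample, df in region_sets.items():
        if not df.empty and not (df.kind == kind).all():
            raise ValueError(f"region set for {sample!r} mixes kinds (expected {kind})")
        ivals: dict[str, list[tuple[int, int]]] = {}
        for r in df.itertuples():
            ivals.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
        per_sample[sample] = {c: _merge_intervals(v) for c, v in ivals.items()}

    samples = list(region_sets)
    chroms = sorted({c for m in per_sample.values() for c in m})
    shared: list[tuple[str, int, int]] = []
    for chrom in chroms:
        current = per_sample[samples[0]].get(chrom, [])
        for sample in samples[1:]:
            other = per_sample[sample].get(chrom, [])
            nxt = []
            for s1, e1 in current:
                for s2, e2 in other:
                    s, e = max(s1, s2), min(e1, e2)
                    if s < e:
                        nxt.append((s, e))
            current = _merge_intervals(nxt)
            if not current:
                break
        shared.extend((chrom, s, e) for s, e in current)

    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in shared:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)

    rows = []
    for chrom, s, e in shared:
        means = []
        for sample in samples:
            df = region_sets[sample]
            hit = df[(df.chrom == chrom) & (df.start < e) & (df.end > s)]
            means.append(f"{hit.mean_value.mean():g}" if not hit.empty else "")
        rows.append((chrom, s, e, kind, "shared", ",".join(samples), ",".join(means)))
    for sample in samples:
        for r in region_sets[sample].itertuples():
            tree = trees.get(r.chrom)
            if tree is None or not tree.overlap(r.start, r.end):
                rows.append(
                    (r.chrom, int(r.start), int(r.end), kind, "sample-specific",
                     sample, f"{r.mean_value:g}")
                )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "kind", "status", "samples", "mean_values"],
    )
    return out.sort_values(["chrom", "start", "status"], ignore_index=True)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features (type == 'gene') from a GFF3 file.

    Returns columns chrom, start, end (converted to 0-based half-open),
    gene_id.  Malformed feature lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, _, _, attrs = fields
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 line {lineno}: bad coordinates") from exc
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                raise ValueError(f"malformed GFF3 line {lineno}: gene without ID")
            rows.append((chrom, s - 1, e, gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def annotate_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame | str | Path,
) -> tuple[pd.DataFrame, float]:
    """Attach overlapping gene ids to regions.

    ``genes`` is either a frame from :func:`read_gff3_genes` or a GFF3 path.
    Returns (regions with an added ``genes`` column of comma-joined ids, and
    the fraction of regions containing at least one gene).
    """
    if not isinstance(genes, pd.DataFrame):
        genes = read_gff3_genes(genes)
    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    out = regions.copy()
    hits = []
    for r in regions.itertuples():
        tree = trees.get(r.chrom)
        ids = sorted(iv.data for iv in tree.overlap(r.start, r.end)) if tree else []
        hits.append(",".join(ids))
    out["genes"] = hits
    with_genes = sum(1 for h in hits if h)
    fraction = with_genes / len(regions) if len(regions) else float("nan")
    return out, fraction
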