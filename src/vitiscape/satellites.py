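"""Satellite-DNA characterization and in-silico chromosomal mapping.

A satellite family is summarized by its repeating unit: the monomer length
(the array's fundamental period, estimated by shifted self-identity), a
majority-vote consensus monomer, its A+T content, and any internal
reverse-complement palindrome (a recurrent feature of satellite monomers).
Monomers are then mapped onto assemblies by seeded ungapped alignment; runs
of closely spaced hits become tandem loci, whose per-chromosome counts are
the in-silico analogue of FISH signal counts, and locus sets from two
haplotype assemblies are compared to expose hemizygous arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kmers
from .simdata import ReferenceGenome, reverse_complement

_SENTINEL = np.uint64(1 << 63)


@dataclass
class SatelliteFamily:
    id: str
    consensus: str
    at_fraction: float
    genome_proportion: float | None = None
    palindrome: tuple[int, int, int] | None = None  # (offset, length, mismatches)

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)


HIT_COLUMNS = ["chrom", "start", "end", "strand", "identity"]
LOCUS_COLUMNS = ["chrom", "start", "end", "n_hits", "mean_identity", "fwd_fraction"]


# ---------------------------------------------------------------------------
# monomer characterization
# ---------------------------------------------------------------------------

def estimate_period(
    sequences: str | list[str],
    min_period: int = 10,
    max_period: int = 2000,
    min_score: float = 0.8,
    min_margin: float = 0.05,
) -> int | None:
    """Monomer length of tandem-derived sequences, or None.

    For each candidate period p the score is the fraction of positions i
    with base(i) == base(i+p), averaged over sequences long enough to
    support the shift.  The reported period is the smallest p that is a
    local maximum of the score profile, exceeds ``min_score`` and sits at
    least ``min_margin`` above the median score (the background identity of
    unrelated shifts); picking the smallest qualifying p avoids reporting
    dimer/multimer harmonics.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    if not sequences or sum(len(s) for s in sequences) < 30:
        raise ValueError("need at least 30 nt of sequence")
    arrs = [_kmers.encode(s) for s in sequences]
    longest = max(len(a) for a in arrs)
    hi = min(max_period, longest // 3)
    if hi < min_period:
        return None
    scores = np.full(hi + 1, np.nan)
    for p in range(min_period, hi + 1):
        num = den = 0
        for a in arrs:
            if len(a) < 3 * p:
                continue
            num += int(np.count_nonzero(a[:-p] == a[p:]))
            den += len(a) - p
        if den:
            scores[p] = num / den
    valid = ~np.isnan(scores)
    if not valid.any():
        return None
    background = np.nanmedian(scores)
    for p in range(min_period, hi + 1):
        s = scores[p]
        if np.isnan(s) or s < min_score or s < background + min_margin:
            continue
        left = scores[p - 1] if p - 1 >= min_period else -np.inf
        right = scores[p + 1] if p + 1 <= hi else -np.inf
        if s >= left and s >= right:
            return p
    return None


def build_consensus(sequences: str | list[str], period: int) -> str:
    """Majority-vote consensus monomer from period-phased frames.

    Each sequence is cut into full ``period``-length frames; frames from
    sequences after the first are rotated to the phase that best matches the
    running consensus.  Column ties break lexicographically (A < C < G < T).
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    frames: list[np.ndarray] = []
    for si, seq in enumerate(sequences):
        a = _kmers.encode(seq)
        n_frames = len(a) // period
        if n_frames == 0:
            continue
        fr = a[: n_frames * period].reshape(n_frames, period)
        if frames:
            ref = _column_majority(np.vstack(frames))
            best_rot, best_score = 0, -1
            for rot in range(period):
                score = int(np.count_nonzero(np.roll(fr[0], -rot) == ref))
                if score > best_score:
                    best_rot, best_score = rot, score
            if best_rot:
                shifted = a[best_rot : best_rot + (len(a) - best_rot) // period * period]
                fr = shifted.reshape(-1, period)
        frames.append(fr)
    if sum(len(f) for f in frames) < 3:
        raise ValueError("need at least 3 full monomer frames")
    cons = _column_majority(np.vstack(frames))
    return "".join("ACGT"[c] for c in cons)


def _column_majority(frames: np.ndarray) -> np.ndarray:
    """Per-column majority base code; ties go to the smallest code."""
    out = np.empty(frames.shape[1], dtype=np.uint8)
    for j in range(frames.shape[1]):
        col = frames[:, j]
        counts = np.bincount(col[col < 4], minlength=4)
        out[j] = np.argmax(counts)  # argmax takes the first (lexicographic) max
    return out


def at_content(sequence: str) -> float:
    """(A+T) / (A+C+G+T); N bases are excluded from both sides."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (counts["A"] + counts["T"]) / total


def find_palindrome(
    monomer: str,
    min_length: int = 20,
    max_mismatch: int = 2,
) -> tuple[int, int, int] | None:
    """Longest reverse-complement palindrome within a (circular) monomer.

    Scans the monomer circularly, expanding around every center and allowing
    up to ``max_mismatch`` internal non-complementary pairs; the outermost
    pair of a reported palindrome must be complementary, so mismatched
    flanking sequence is never absorbed.  An odd-length palindrome's middle
    base can never pair with its own complement and always costs one
    mismatch.  Returns (offset, length, mismatches) with offset on the
    linear monomer, or None if nothing reaches ``min_length``; ties prefer
    longer length, then fewer mismatches, then the smaller offset.
    """
    L = len(monomer)
    if L < min_length:
        raise ValueError("monomer shorter than min_length")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    s = monomer.upper()
    doubled = s + s  # circular scan
    best: tuple[int, int, int] | None = None

    def consider(start: int, length: int, mism: int) -> None:
        nonlocal best
        if length < min_length:
            return
        offset = start % L
        if best is None or (length, -mism, -offset) > (best[1], -best[2], -best[0]):
            best = (offset, length, mism)

    for center in range(2 * L - 1):
        for parity in (0, 1):  # even: gap center; odd: base center
            i, j = center, center + 1 + parity
            mism = parity  # odd middle base is always a mismatch
            if mism > max_mismatch:
                continue
            while i >= 0 and j < 2 * L and j - i + 1 <= L:
                if comp.get(doubled[i]) == doubled[j]:
                    consider(i, j - i + 1, mism)
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                i -= 1
                j += 1
    return best


def characterize(
    sequences: str | list[str],
    family_id: str = "sat",
    genome_proportion: float | None = None,
    **period_kw,
) -> SatelliteFamily | None:
    """Full characterization: period -> consensus -> A/T -> palindrome."""
    period = estimate_period(sequences, **period_kw)
    if period is None:
        return None
    consensus = build_consensus(sequences, period)
    pal = None
    if len(consensus) >= 20:
        pal = find_palindrome(consensus)
    return SatelliteFamily(
        id=family_id,
        consensus=consensus,
        at_fraction=at_content(consensus),
        genome_proportion=genome_proportion,
        palindrome=pal,
    )


# ---------------------------------------------------------------------------
# in-silico mapping ("in-silico FISH")
# ---------------------------------------------------------------------------

def _seed_candidates(
    chrom_codes: np.ndarray, monomer_codes: np.ndarray, k: int
) -> np.ndarray:
    """Candidate alignment start positions from exact k-mer seed matches."""
    gen_k = _kmers.kmer_codes_1d(chrom_codes, k)[0]
    mon_k = _kmers.kmer_codes_1d(monomer_codes, k)[0]
    order = np.argsort(mon_k, kind="stable").astype(np.int64)
    sorted_codes = mon_k[order]
    lo = np.searchsorted(sorted_codes, gen_k, side="left")
    hi = np.searchsorted(sorted_codes, gen_k, side="right")
    counts = hi - lo
    gpos = np.flatnonzero(counts)
    if not len(gpos):
        return np.empty(0, dtype=np.int64)
    c = counts[gpos]
    total = int(c.sum())
    g_rep = np.repeat(gpos, c)
    within = np.arange(total) - np.repeat(np.cumsum(c) - c, c)
    t_idx = np.repeat(lo[gpos], c) + within
    return np.unique(g_rep - order[t_idx])


def map_monomer(
    monomer: str,
    assembly: ReferenceGenome,
    min_identity: float = 0.8,
    seed_k: int = 12,
) -> pd.DataFrame:
    """Ungapped local matches of a monomer on both strands of an assembly.

    Exact ``seed_k``-mer matches nominate candidate diagonal placements;
    each candidate full-length ungapped alignment is scored and kept when
    identity >= ``min_identity``; overlapping candidates are resolved
    greedily by identity (then coordinate).  Hits are returned sorted by
    coordinate with columns chrom, start, end, strand, identity.
    Chromosomes shorter than the monomer are skipped.
    """
    m = len(monomer)
    rows = []
    for chrom, seq in assembly.chromosomes:
        if len(seq) < m:
            continue
        chrom_codes = _kmers.encode(seq)
        cand: dict[int, tuple[str, float]] = {}
        for strand, probe in (("+", monomer), ("-", reverse_complement(monomer))):
            probe_codes = _kmers.encode(probe)
            starts = _seed_candidates(chrom_codes, probe_codes, seed_k)
            starts = starts[(starts >= 0) & (starts + m <= len(seq))]
            for s in starts:
                ident = float(
                    np.count_nonzero(chrom_codes[s : s + m] == probe_codes) / m
                )
                if ident >= min_identity:
                    prev = cand.get(int(s))
                    if prev is None or ident > prev[1]:
                        cand[int(s)] = (strand, ident)
        # greedy non-overlapping selection, best identity first
        chosen: list[tuple[int, str, float]] = []
        occupied: list[tuple[int, int]] = []
        for s, (strand, ident) in sorted(
            cand.items(), key=lambda kv: (-kv[1][1], kv[0])
        ):
            if any(s < e and o < s + m for o, e in occupied):
                continue
            occupied.append((s, s + m))
            chosen.append((s, strand, ident))
        for s, strand, ident in sorted(chosen):
            rows.append((chrom, s, s + m, strand, ident))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def call_tandem_loci(
    hits: pd.DataFrame,
    monomer_length: int,
    max_gap: int | None = None,
    min_hits: int = 5,
) -> pd.DataFrame:
    """Chain monomer hits into tandem loci and count sites per chromosome.

    Hits on one chromosome closer than ``max_gap`` (default twice the
    monomer length) are chained; chains with at least ``min_hits`` members
    become loci.  Returns a frame with columns chrom, start, end, n_hits,
    mean_identity, fwd_fraction, sorted by coordinate.
    """
    if max_gap is None:
        max_gap = 2 * monomer_length
    rows = []
    for chrom, sub in hits.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        chain: list = []
        prev_end = None
        for h in sub.itertuples():
            if prev_end is not None and h.start - prev_end > max_gap:
                rows.extend(_close_chain(chain, chrom, min_hits))
                chain = []
            chain.append(h)
            prev_end = h.end
        rows.extend(_close_chain(chain, chrom, min_hits))
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def _close_chain(chain: list, chrom: str, min_hits: int) -> list[tuple]:
    if len(chain) < min_hits:
        return []
    return [
        (
            chrom,
            int(chain[0].start),
            int(chain[-1].end),
            len(chain),
            float(np.mean([h.identity for h in chain])),
            float(np.mean([h.strand == "+" for h in chain])),
        )
    ]


def site_counts(loci: pd.DataFrame) -> pd.Series:
    """Number of tandem loci per chromosome (the in-silico FISH signal count)."""
    if loci.empty:
        return pd.Series(dtype=int)
    return loci.groupby("chrom").size()


def compare_haplotypes(
    loci_h1: pd.DataFrame,
    loci_h2: pd.DataFrame,
    homology: dict[str, str],
    min_reciprocal_overlap: float = 0.1,
) -> pd.DataFrame:
    """Pair tandem loci across two haplotype assemblies; flag hemizygous ones.

    ``homology`` maps haplotype-1 chromosome names to their haplotype-2
    homologs.  Two loci pair when they lie on homologous chromosomes and
    reciprocally overlap by at least ``min_reciprocal_overlap`` of each
    locus.  Loci with no partner are hemizygous.  Returns one row per locus:
    haplotype, chrom, start, end, status ('shared'/'hemizygous'), partner.
    """
    for chrom in loci_h1.chrom.unique():
        if chrom not in homology:
            raise KeyError(f"chromosome {chrom!r} absent from homology table")
    reverse = {v: k for k, v in homology.items()}
    for chrom in loci_h2.chrom.unique():
        if chrom not in reverse:
            raise KeyError(f"chromosome {chrom!r} absent from homology table")

    paired_h2 = set()
    rows = []
    for i, a in enumerate(loci_h1.itertuples()):
        partner = None
        target = homology[a.chrom]
        for j, b in enumerate(loci_h2.itertuples()):
            if b.chrom != target:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov <= 0:
                continue
            if (
                ov / (a.end - a.start) >= min_reciprocal_overlap
                and ov / (b.end - b.start) >= min_reciprocal_overlap
            ):
                partner = j
                paired_h2.add(j)
                break
        rows.append(
            (
                "h1", a.chrom, int(a.start), int(a.end),
                "shared" if partner is not None else "hemizygous",
                f"h2:{loci_h2.chrom.iloc[partner]}:{int(loci_h2.start.iloc[partner])}"
                if partner is not None
                else "",
            )
        )
    for j, b in enumerate(loci_h2.itertuples()):
        status = "shared" if j in paired_h2 else "hemizygous"
        rows.append(("h2", b.chrom, int(b.start), int(b.end), status, ""))
    return pd.DataFrame(
        rows, columns=["haplotype", "chrom", "start", "end", "status", "partner"]
    )
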