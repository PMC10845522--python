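"""Vectorized 2-bit k-mer encoding shared by the repeatome and satellite code.

Sequences are packed into uint8 base codes (A=0, C=1, G=2, T=3; anything
else = 255) and k-mers into uint64 words by a rolling polynomial, so whole
read matrices are encoded with O(k) numpy passes.  Canonical k-mers take the
lexicographic minimum of a k-mer and its reverse complement, making every
comparison strand-agnostic.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
for i, b in enumerate(b"acgt"):
    _LUT[b] = i


def encode(seq: str) -> np.ndarray:
    """Base codes 0-3 (255 for non-ACGT) for one sequence."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """(n_reads, read_length) base-code matrix; all reads must be equal length."""
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all reads must have the same length")
    buf = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _LUT[buf].reshape(len(seqs), L)


def kmer_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement k-mer codes along the last axis.

    ``base_codes`` is (..., L) with values 0-3 (255 allowed; any k-mer that
    touches a 255 gets the sentinel ``2**63`` in both outputs so it can be
    filtered).  Returns two (..., L-k+1) uint64 arrays.
    """
    b = base_codes
    L = b.shape[-1]
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    m = L - k + 1
    valid = b != 255
    bb = np.where(valid, b, 0).astype(np.uint64)
    fwd = np.zeros(b.shape[:-1] + (m,), dtype=np.uint64)
    rev = np.zeros_like(fwd)
    shift = np.uint64(2 * (k - 1))
    # rolling build of the first window then slide
    acc_f = np.zeros(b.shape[:-1], dtype=np.uint64)
    acc_r = np.zeros(b.shape[:-1], dtype=np.uint64)
    for j in range(k):
        acc_f = (acc_f << np.uint64(2)) | bb[..., j]
        acc_r = (acc_r >> np.uint64(2)) | ((np.uint64(3) - bb[..., j]) << shift)
    fwd[..., 0] = acc_f
    rev[..., 0] = acc_r
    mask = np.uint64((1 << (2 * k)) - 1)
    for i in range(1, m):
        acc_f = ((acc_f << np.uint64(2)) & mask) | bb[..., i + k - 1]
        acc_r = (acc_r >> np.uint64(2)) | ((np.uint64(3) - bb[..., i + k - 1]) << shift)
        fwd[..., i] = acc_f
        rev[..., i] = acc_r
    # windows containing any invalid base -> sentinel
    bad = ~valid
    if bad.any():
        win_bad = np.zeros(b.shape[:-1] + (m,), dtype=bool)
        cum = np.cumsum(bad, axis=-1)
        pad = np.zeros(b.shape[:-1] + (1,), dtype=cum.dtype)
        cum = np.concatenate([pad, cum], axis=-1)
        win_bad = (cum[..., k:] - cum[..., :-k]) > 0
        sentinel = np.uint64(1 << 63)
        fwd[win_bad] = sentinel
        rev[win_bad] = sentinel
    return fwd, rev


def canonical_kmers(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-agnostic) k-mer codes along the last axis."""
    fwd, rev = kmer_codes(base_codes, k)
    return np.minimum(fwd, rev)


def kmer_codes_1d(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement k-mer codes of one long sequence.

    Same contract as :func:`kmer_codes` for a 1-D input, but built with k
    shifted-slice passes instead of a rolling scan, which is what you want
    for chromosome-length sequences.
    """
    b = np.asarray(base_codes)
    L = len(b)
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    m = L - k + 1
    valid = b != 255
    bb = np.where(valid, b, 0).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd |= bb[j : m + j] << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - bb[j : m + j]) << np.uint64(2 * j)
    bad = ~valid
    if bad.any():
        cum = np.concatenate(([0], np.cumsum(bad)))
        win_bad = (cum[k:] - cum[:-k]) > 0
        sentinel = np.uint64(1 << 63)
        fwd[win_bad] = sentinel
        rev[win_bad] = sentinel
    return fwd, rev


def unique_canonical(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers of one sequence (sentinels removed)."""
    codes = canonical_kmers(encode(seq)[None, :], k)[0]
    codes = codes[codes != np.uint64(1 << 63)]
    return np.unique(codes)
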