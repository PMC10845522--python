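"""Synthetic genomes, copy-number tracks and reads with recorded ground truth.

Every downstream stage of the pipeline (window-based copy-number profiling,
WSSD and digital-CGH calling, repeatome clustering, satellite mapping) is
exercised against genomes produced here, where the implanted events are known
exactly.  The module emulates the signal structure of a grape resequencing
experiment — a repeat-masked multi-chromosome reference, segmental
duplications and deletions at integer copy number, tandem satellite arrays
with a chosen monomer length / divergence / A+T content, dispersed repeat
families at a chosen genome fraction, and Poisson short-read sampling — while
staying a pure function of (configuration, seed).

Read depth is simulated directly on reference coordinates: the read-start
rate at position p is ``coverage / read_length * CN(p) / 2``.  This skips the
aligner entirely yet reproduces exactly the per-window depth signal that
WSSD-style copy-number estimation exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DUPLICATION = "duplication"
DELETION = "deletion"
SATELLITE = "satellite_array"
DISPERSED = "dispersed_family"

#: sample id used for events that are part of the reference sequence itself
#: (satellite arrays, dispersed repeat copies) rather than of one resequenced
#: individual.
REFERENCE_SAMPLE = "reference"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthEvent:
    """One implanted event, as recorded in the ground truth."""

    sample_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    kind: str
    cn: float = 2.0
    family_id: str | None = None
    monomer_length: int | None = None
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.kind == DUPLICATION and self.cn <= 2:
            raise ValueError("duplication requires cn > 2")
        if self.kind == DELETION and self.cn >= 2:
            raise ValueError("deletion requires cn < 2")
        if self.kind == SATELLITE and (self.monomer_length or 0) < 10:
            raise ValueError("satellite_array requires monomer_length >= 10")


@dataclass
class TruthSet:
    events: list[TruthEvent] = field(default_factory=list)

    def for_sample(self, sample_id: str) -> list[TruthEvent]:
        return [e for e in self.events if e.sample_id == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.sample_id, None)
        return list(seen)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                name = f"{e.sample_id}:{e.kind}" + (
                    f":{e.family_id}" if e.family_id else ""
                )
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t{e.cn:g}\n")


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus a repeat/ambiguity mask (BED-style intervals)."""

    chromosomes: list[tuple[str, str]]
    mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = self.lengths
        for chrom, ivals in self.mask.items():
            if chrom not in lengths:
                raise ValueError(f"mask references unknown chromosome {chrom!r}")
            prev = 0
            for s, e in ivals:
                if s < prev or e <= s or e > lengths[chrom]:
                    raise ValueError(
                        f"mask intervals for {chrom} must be sorted, "
                        f"non-overlapping and within bounds"
                    )
                prev = e

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def mask_array(self, chrom: str) -> np.ndarray:
        """Boolean per-base array, True where masked."""
        arr = np.zeros(len(self.sequence(chrom)), dtype=bool)
        for s, e in self.mask.get(chrom, []):
            arr[s:e] = True
        return arr

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def mask_to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, ivals in self.mask.items():
                for s, e in ivals:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass
class Read:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError("quality string length must equal sequence length")


@dataclass
class ReadSet:
    reads: list[Read]
    #: optional per-read true origin, parallel to ``reads``: (chrom, position)
    provenance: list[tuple[str, int]] | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSpec:
    """A requested event, fully positioned by the caller.

    ``cn`` is the sample's true copy number for duplications/deletions.  For
    ``satellite_array`` events the interval is filled with tandem copies of a
    random monomer of ``monomer_length`` bases (target A+T fraction
    ``at_fraction``), each copy carrying independent substitutions at rate
    ``divergence``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: str
    cn: float = 2.0
    family_id: str | None = None
    monomer_length: int | None = None
    divergence: float = 0.0
    at_fraction: float = 0.5


@dataclass(frozen=True)
class DispersedFamilySpec:
    """A dispersed repeat family placed by the builder.

    ``n_copies`` copies of a random ``element_length``-base element are
    implanted at random non-overlapping positions across the genome, each with
    independent substitutions at rate ``divergence``; together they occupy
    ``n_copies * element_length / genome_length`` of the reference.  Copies
    keep at least ``min_separation`` bases of unique sequence between any two
    implanted elements, modelling isolated insertions: no short read can then
    span two different repeat copies.
    """

    family_id: str
    element_length: int
    n_copies: int
    divergence: float = 0.02
    at_fraction: float = 0.5
    #: gap kept around insertions; 500 bases cannot be bridged by chains of
    #: overlapping 100-nt reads at the low sampled coverages used downstream
    min_separation: int = 500
    #: fix the element sequence (e.g. to share one family across several
    #: simulated genomes); drawn randomly when None
    element_seq: str | None = None

    def __post_init__(self) -> None:
        if self.element_seq is not None and len(self.element_seq) != self.element_length:
            raise ValueError("element_seq length must equal element_length")


@dataclass(frozen=True)
class SimConfig:
    chromosomes: tuple[tuple[str, int], ...]
    masked_fraction: float = 0.0
    events: tuple[EventSpec, ...] = ()
    dispersed_families: tuple[DispersedFamilySpec, ...] = ()
    #: by default the mask is placed independently of implanted events; set
    #: True to also mask satellite arrays, mimicking a repeat-masked reference
    mask_satellites: bool = False

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if not 0 <= self.masked_fraction < 1:
            raise ValueError("masked_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, at_fraction: float = 0.5) -> np.ndarray:
    """Random uint8 base codes (ASCII) with the requested A+T fraction."""
    if at_fraction == 0.5:
        return _BASES[rng.integers(0, 4, size=n)]
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return rng.choice(_BASES[[0, 3, 1, 2]], size=n, p=[p_at, p_at, p_gc, p_gc])


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at the given rate (always to a different base)."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits):
        # shift each hit base by 1..3 within the ACGT alphabet
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + rng.integers(1, 4, size=len(hits))) % 4]
    return out


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def make_tandem_array(
    rng: np.random.Generator,
    monomer_length: int,
    n_copies: int,
    divergence: float = 0.0,
    at_fraction: float = 0.5,
) -> tuple[str, str]:
    """Return (monomer, array) for a tandem satellite array."""
    monomer = _random_bases(rng, monomer_length, at_fraction)
    copies = [_mutate(rng, monomer, divergence) for _ in range(n_copies)]
    array = np.concatenate(copies)
    return monomer.tobytes().decode(), array.tobytes().decode()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_reference(config: SimConfig, seed: int) -> tuple[ReferenceGenome, TruthSet]:
    """Build a reference genome with implanted events and its ground truth.

    Deterministic for a fixed (config, seed).  Sequence-level events
    (satellite arrays, dispersed families) are written into the reference and
    recorded under the sample id ``"reference"``; copy-number events
    (duplications, deletions) only appear in the truth set, to be realised by
    :func:`derive_sample` / :func:`simulate_read_starts`.
    """
    rng = np.random.default_rng(seed)
    lengths = dict(config.chromosomes)

    # validate requested events: bounds + per-sample overlap
    by_key: dict[tuple[str, str], list[EventSpec]] = {}
    for ev in config.events:
        if ev.chrom not in lengths:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if ev.start < 0 or ev.end > lengths[ev.chrom]:
            raise ValueError(
                f"event [{ev.start}, {ev.end}) exceeds chromosome "
                f"{ev.chrom} (length {lengths[ev.chrom]})"
            )
        key = (ev.sample_id if ev.kind in (DUPLICATION, DELETION) else REFERENCE_SAMPLE,
               ev.chrom)
        by_key.setdefault(key, []).append(ev)
    for (sample, chrom), evs in by_key.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping requested events for sample {sample!r} on "
                    f"{chrom}: [{a.start},{a.end}) and [{b.start},{b.end})"
                )

    chrom_arrays = {
        name: _random_bases(rng, length) for name, length in config.chromosomes
    }
    truth = TruthSet()
    satellite_intervals: dict[str, list[tuple[int, int]]] = {}

    for ev in config.events:
        if ev.kind == SATELLITE:
            if ev.monomer_length is None:
                raise ValueError("satellite_array event needs monomer_length")
            span = ev.end - ev.start
            n_copies = span // ev.monomer_length
            if n_copies < 1:
                raise ValueError("satellite interval shorter than one monomer")
            _, array = make_tandem_array(
                rng, ev.monomer_length, n_copies, ev.divergence, ev.at_fraction
            )
            arr = np.frombuffer(array.encode(), dtype=np.uint8)
            chrom_arrays[ev.chrom][ev.start : ev.start + len(arr)] = arr
            satellite_intervals.setdefault(ev.chrom, []).append(
                (ev.start, ev.start + len(arr))
            )
            truth.events.append(
                TruthEvent(
                    REFERENCE_SAMPLE, ev.chrom, ev.start, ev.start + len(arr),
                    SATELLITE, cn=2.0, family_id=ev.family_id,
                    monomer_length=ev.monomer_length, divergence=ev.divergence,
                )
            )
        elif ev.kind in (DUPLICATION, DELETION):
            truth.events.append(
                TruthEvent(
                    ev.sample_id, ev.chrom, ev.start, ev.end, ev.kind, cn=ev.cn,
                    family_id=ev.family_id,
                )
            )
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    # dispersed repeat families: random non-overlapping placements; a sorted
    # per-chromosome interval list keeps the overlap check O(log n)
    import bisect

    occ_starts: dict[str, list[int]] = {}
    occ_ends: dict[str, list[int]] = {}
    for c, iv in satellite_intervals.items():
        for s, e in sorted(iv):
            occ_starts.setdefault(c, []).append(s)
            occ_ends.setdefault(c, []).append(e)
    chrom_names = [name for name, _ in config.chromosomes]
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    for fam in config.dispersed_families:
        element = (
            np.frombuffer(fam.element_seq.encode(), dtype=np.uint8).copy()
            if fam.element_seq is not None
            else _random_bases(rng, fam.element_length, fam.at_fraction)
        )
        placed = 0
        attempts = 0
        while placed < fam.n_copies:
            attempts += 1
            if attempts > 50 * fam.n_copies:
                raise ValueError(
                    f"could not place family {fam.family_id!r}: genome too crowded"
                )
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            hi = lengths[chrom] - fam.element_length
            if hi <= 0:
                continue
            start = int(rng.integers(0, hi))
            end = start + fam.element_length
            ss = occ_starts.setdefault(chrom, [])
            ee = occ_ends.setdefault(chrom, [])
            sep = fam.min_separation
            i = bisect.bisect_right(ss, start)
            if (i > 0 and ee[i - 1] + sep > start) or (
                i < len(ss) and ss[i] < end + sep
            ):
                continue
            ss.insert(i, start)
            ee.insert(i, end)
            copy = _mutate(rng, element, fam.divergence)
            chrom_arrays[chrom][start:end] = copy
            truth.events.append(
                TruthEvent(
                    REFERENCE_SAMPLE, chrom, start, end, DISPERSED,
                    cn=2.0, family_id=fam.family_id, divergence=fam.divergence,
                )
            )
            placed += 1

    # mask: random blocks covering masked_fraction of each chromosome,
    # placed independently of events unless mask_satellites is set
    mask: dict[str, list[tuple[int, int]]] = {}
    if config.masked_fraction > 0:
        block = 500
        for name, length in config.chromosomes:
            target = int(round(config.masked_fraction * length))
            chosen: list[tuple[int, int]] = []
            covered = 0
            guard = 0
            while covered < target and guard < 10000:
                guard += 1
                s = int(rng.integers(0, max(1, length - block)))
                e = min(s + min(block, target - covered), length)
                if any(s < ee and ss < e for ss, ee in chosen):
                    continue
                chosen.append((s, e))
                covered += e - s
            mask[name] = sorted(chosen)
    if config.mask_satellites:
        for chrom, ivals in satellite_intervals.items():
            merged = sorted(mask.get(chrom, []) + ivals)
            # coalesce overlaps introduced by the union
            out: list[tuple[int, int]] = []
            for s, e in merged:
                if out and s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            mask[chrom] = out

    genome = ReferenceGenome(
        chromosomes=[
            (name, chrom_arrays[name].tobytes().decode())
            for name, _ in config.chromosomes
        ],
        mask=mask,
    )
    return genome, truth


def derive_sample(
    reference: ReferenceGenome, truth: TruthSet, sample_id: str
) -> dict[str, np.ndarray]:
    """Per-base true copy-number track for one sample.

    Baseline CN is 2 everywhere; intervals of the sample's duplication and
    deletion events are overridden with their true CN.  Returned as one
    float32 array per chromosome on reference coordinates.
    """
    if sample_id not in truth.sample_ids:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    track = {
        name: np.full(len(seq), 2.0, dtype=np.float32)
        for name, seq in reference.chromosomes
    }
    for ev in truth.for_sample(sample_id):
        if ev.kind in (DUPLICATION, DELETION):
            track[ev.chrom][ev.start : ev.end] = ev.cn
    return track


def simulate_read_starts(
    cn_track: dict[str, np.ndarray],
    coverage: float,
    read_length: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Poisson per-position read-start counts on reference coordinates.

    The start rate at position p is ``coverage / read_length * CN(p) / 2`` so
    that diploid background yields the nominal coverage and a CN=k region
    yields ``k/2`` times the background depth.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, cn in cn_track.items():
        rate = (coverage / read_length) * (np.asarray(cn, dtype=float) / 2.0)
        out[chrom] = rng.poisson(rate).astype(np.int32)
    return out


_DEFAULT_QUALITY = {"base_q": 30, "low_q": 10, "low_tail_fraction": 0.0}


def simulate_reads(
    genome: ReferenceGenome,
    coverage: float,
    read_length: int,
    error_rate: float = 0.0,
    quality: dict | None = None,
    seed: int = 0,
) -> ReadSet:
    """Uniform single-end reads from a genome, with substitution errors.

    Reads are drawn uniformly over genome positions, so satellite and
    dispersed arrays are represented in proportion to their genomic fraction.
    The quality model is flat ``base_q`` with, per read, a 3' tail of
    ``low_q`` bases whose length is Binomial(read_length, low_tail_fraction) —
    enough structure to exercise Q<20 trimming rules.
    """
    if not 0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    if genome.total_length == 0 or not genome.chromosomes:
        raise ValueError("empty genome")
    qm = dict(_DEFAULT_QUALITY, **(quality or {}))
    lengths = genome.lengths
    shortest = min(lengths.values())
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest chromosome ({shortest})"
        )
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * genome.total_length / read_length))

    names = [name for name, _ in genome.chromosomes]
    arrays = {
        name: np.frombuffer(seq.encode(), dtype=np.uint8)
        for name, seq in genome.chromosomes
    }
    n_positions = np.array([lengths[n] - read_length + 1 for n in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_reads, p=n_positions / n_positions.sum())

    base_q = chr(33 + qm["base_q"])
    low_q = chr(33 + qm["low_q"])
    tail_lens = (
        rng.binomial(read_length, qm["low_tail_fraction"], size=n_reads)
        if qm["low_tail_fraction"] > 0
        else np.zeros(n_reads, dtype=int)
    )

    reads: list[Read] = []
    provenance: list[tuple[str, int]] = []
    for i in range(n_reads):
        chrom = names[chrom_idx[i]]
        start = int(rng.integers(0, lengths[chrom] - read_length + 1))
        seq = arrays[chrom][start : start + read_length]
        if error_rate > 0:
            seq = _mutate(rng, seq, error_rate)
        tail = int(tail_lens[i])
        qual = base_q * (read_length - tail) + low_q * tail
        reads.append(Read(f"read_{i}", seq.tobytes().decode(), qual))
        provenance.append((chrom, start))
    return ReadSet(reads, provenance)
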