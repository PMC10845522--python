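#!/usr/bin/env python
"""Simulate the study system: a masked reference, two resequenced varieties
with overlapping and private CNVs, satellite arrays and a dispersed repeat
family, plus a toy gene annotation.

Writes reference.fasta, mask.bed, truth.bed, genes.gff3 and per-variety
read-start tables under results/sim/ for the downstream steps.
"""

from pathlib import Path

import numpy as np

from vitiscape import io, simdata
from vitiscape.simdata import DispersedFamilySpec, EventSpec, SimConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1234

CONFIG = SimConfig(
    chromosomes=(("chr1", 1_200_000), ("chr2", 800_000)),
    masked_fraction=0.05,
    events=(
        # shared duplication (overlapping in both varieties)
        EventSpec("AGL", "chr1", 300_000, 320_000, "duplication", cn=4),
        EventSpec("FAL", "chr1", 305_000, 330_000, "duplication", cn=3),
        # AGL-private deletion
        EventSpec("AGL", "chr1", 600_000, 615_000, "deletion", cn=1),
        # FAL-private duplication on chr2
        EventSpec("FAL", "chr2", 200_000, 215_000, "duplication", cn=5),
        # shared deletion
        EventSpec("AGL", "chr2", 500_000, 512_000, "deletion", cn=0.5),
        EventSpec("FAL", "chr2", 498_000, 510_000, "deletion", cn=1),
        # satellite arrays in the reference itself
        EventSpec("reference", "chr1", 900_000, 910_630, "satellite_array",
                  family_id="sat107", monomer_length=107, divergence=0.02,
                  at_fraction=0.51),
        EventSpec("reference", "chr2", 700_000, 705_610, "satellite_array",
                  family_id="sat187", monomer_length=187, divergence=0.02,
                  at_fraction=0.60),
    ),
    dispersed_families=(DispersedFamilySpec("gypsy_like", 3000, 30, 0.02),),
)

COVERAGE = 30
READ_LENGTH = 100


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, truth = simdata.build_reference(CONFIG, seed=SEED)
    genome.to_fasta(OUT / "reference.fasta")
    genome.mask_to_bed(OUT / "mask.bed")
    truth.to_bed(OUT / "truth.bed")

    # toy gene annotation: one gene every ~20 kb
    rng = np.random.default_rng(SEED + 1)
    with open(OUT / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        gid = 0
        for chrom, length in genome.lengths.items():
            pos = int(rng.integers(2000, 20_000))
            while pos + 3000 < length:
                gid += 1
                fh.write(
                    f"{chrom}\tsim\tgene\t{pos + 1}\t{pos + 3000}\t.\t+\t.\t"
                    f"ID=gene{gid}\n"
                )
                pos += int(rng.integers(12_000, 28_000))
    print(f"reference: {sum(genome.lengths.values()):,} bp over "
          f"{len(genome.lengths)} chromosomes, {gid} toy genes")

    for i, sample in enumerate(("AGL", "FAL")):
        track = simdata.derive_sample(genome, truth, sample)
        starts = simdata.simulate_read_starts(
            track, COVERAGE, READ_LENGTH, seed=SEED + 10 + i
        )
        io.write_read_starts(starts, OUT / f"{sample}.starts.tsv")
        n = sum(int(c.sum()) for c in starts.values())
        print(f"{sample}: {n:,} simulated read starts at {COVERAGE}x")

    # diploid depth for the reference genome itself (digital-CGH baseline)
    diploid = {c: np.full(l, 2.0, np.float32) for c, l in genome.lengths.items()}
    starts = simdata.simulate_read_starts(diploid, COVERAGE, READ_LENGTH, SEED + 20)
    io.write_read_starts(starts, OUT / "reference.starts.tsv")
    print(f"events recorded in truth set: {len(truth.events)}")


if __name__ == "__main__":
    main()
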