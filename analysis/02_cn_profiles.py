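#!/usr/bin/env python
"""Build 1-kb-unmasked windows and calibrate per-window absolute copy number
for each simulated variety and for the reference baseline.

Reads results/sim/, writes <sample>.profile.tsv under results/profiles/.
"""

from pathlib import Path

from vitiscape import cnprofile, io

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"
OUT = BASE / "profiles"
READ_LENGTH = 100


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(SIM / "reference.fasta", SIM / "mask.bed")
    windows = cnprofile.define_windows(genome, 1000)
    print(f"{len(windows)} windows of 1,000 unmasked bases "
          f"(genomic spans {windows.df.end.sub(windows.df.start).min()}-"
          f"{windows.df.end.sub(windows.df.start).max()} bp)")
    for sample in ("AGL", "FAL", "reference"):
        starts = io.read_read_starts(SIM / f"{sample}.starts.tsv", genome.lengths)
        profile = cnprofile.profile_sample(
            genome, starts, READ_LENGTH, sample_id=sample, windows=windows
        )
        profile.to_tsv(OUT / f"{sample}.profile.tsv")
        print(
            f"{sample}: control depth {profile.control_mean:.2f} "
            f"+/- {profile.control_sd:.2f}; "
            f"CN range {profile.cn.min():.2f}-{profile.cn.max():.2f}"
        )


if __name__ == "__main__":
    main()
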