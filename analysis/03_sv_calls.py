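#!/usr/bin/env python
"""Call duplications/deletions (WSSD rule), run digital CGH against the
reference baseline, intersect shared CNVRs between the two varieties,
annotate gene content, and test the per-chromosome variant distribution.

Reads results/profiles/, writes BED/TSV tables under results/svcalls/.
"""

from pathlib import Path

import pandas as pd

from vitiscape import svcalls, varstats
from vitiscape.cnprofile import CopyNumberProfile, WindowSet

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "svcalls"


def load_profile(path: Path) -> CopyNumberProfile:
    df = pd.read_csv(path, sep="\t")
    ws = WindowSet(
        df=df[["chrom", "start", "end", "unmasked", "gc"]].copy(),
        size=int(df.unmasked.iloc[0]), unmasked_positions={},
    )
    return CopyNumberProfile(
        sample_id=path.stem.split(".")[0], windows=ws,
        raw_depth=df.raw_depth.to_numpy(),
        corrected_depth=df.corrected_depth.to_numpy(),
        cn=df.cn.to_numpy(), control_mean=float("nan"), control_sd=float("nan"),
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = {
        s: load_profile(BASE / "profiles" / f"{s}.profile.tsv")
        for s in ("AGL", "FAL", "reference")
    }

    wssd = {}
    for sample in ("AGL", "FAL"):
        regions = svcalls.call_wssd(profiles[sample])
        regions.to_csv(OUT / f"{sample}.wssd.bed", sep="\t", index=False)
        wssd[sample] = regions
        dups = (regions.kind == "duplication").sum()
        print(f"{sample}: {dups} duplications, {len(regions) - dups} deletions (WSSD)")

        l2r = svcalls.compute_l2r(profiles[sample], profiles["reference"])
        cgh = svcalls.call_cgh(l2r, profiles[sample].windows)
        cgh.to_csv(OUT / f"{sample}.dcgh.bed", sep="\t", index=False)
        gains = (cgh.kind == "gain").sum()
        print(f"{sample}: {gains} gains, {len(cgh) - gains} losses (digital CGH)")

    for kind in ("duplication", "deletion"):
        sets = {s: df[df.kind == kind] for s, df in wssd.items()}
        shared = svcalls.intersect_cnvrs(sets, kind)
        shared.to_csv(OUT / f"shared.{kind}.tsv", sep="\t", index=False)
        n_sh = (shared.status == "shared").sum()
        n_sp = (shared.status == "sample-specific").sum()
        print(f"{kind}s: {n_sh} shared CNVRs, {n_sp} variety-specific regions")

    all_regions = pd.concat(wssd.values(), ignore_index=True)
    annotated, fraction = svcalls.annotate_regions(
        all_regions, BASE / "sim" / "genes.gff3"
    )
    annotated.to_csv(OUT / "wssd.annotated.tsv", sep="\t", index=False)
    print(f"{fraction:.0%} of called regions contain at least one gene")

    lengths = (
        profiles["AGL"].windows.df.groupby("chrom").end.max().to_dict()
    )
    counts = all_regions.groupby("chrom").size().reindex(lengths, fill_value=0)
    expected = varstats.expected_counts(lengths, float(counts.sum()))
    result = varstats.chisq_randomness(counts, expected)
    table = result.table.copy()
    table["flag"] = varstats.flag_enriched(result)
    table.to_csv(OUT / "variant_chisq.tsv", sep="\t")
    print(f"variant distribution vs chromosome length: {result}")


if __name__ == "__main__":
    main()
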