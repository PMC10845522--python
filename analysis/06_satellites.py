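#!/usr/bin/env python
"""Characterize the simulated satellite families and map them onto a
synthetic diploid assembly pair (in-silico FISH).

From the step-01 reference: extract each satellite array, estimate its
monomer period, build the consensus, measure A/T content and search for
internal palindromes.  Then build two haplotype assemblies sharing one
array while the second carries an extra (hemizygous) locus, map the
consensus monomers, chain hits into tandem loci and compare haplotypes.

Writes results/satellites/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vitiscape import io, satellites, simdata

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "satellites"
SEED = 777


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(BASE / "sim" / "reference.fasta")
    truth = pd.read_csv(
        BASE / "sim" / "truth.bed", sep="\t",
        names=["chrom", "start", "end", "name", "cn"],
    )
    arrays = truth[truth.name.str.contains("satellite_array")]

    families = {}
    rows = []
    for r in arrays.itertuples():
        fam_id = r.name.split(":")[-1]
        seq = genome.sequence(r.chrom)[r.start : r.end]
        fam = satellites.characterize(seq, family_id=fam_id)
        assert fam is not None
        families[fam_id] = fam
        pal = f"{fam.palindrome[1]} nt" if fam.palindrome else "none"
        rows.append((fam_id, fam.monomer_length, round(100 * fam.at_fraction, 1), pal))
        print(f"{fam_id}: monomer {fam.monomer_length} nt, "
              f"A/T {100 * fam.at_fraction:.1f}%, palindrome {pal}")
    pd.DataFrame(
        rows, columns=["family", "monomer_nt", "at_percent", "palindrome"]
    ).to_csv(OUT / "families.tsv", sep="\t", index=False)

    # synthetic diploid: both haplotypes share the sat107 array on chr10;
    # haplotype 2 carries an extra sat187 array on chr15 (hemizygous)
    rng = np.random.default_rng(SEED)
    m107 = families["sat107"].consensus
    m187 = families["sat187"].consensus

    def array_of(mono, n):
        return "".join(
            simdata._mutate(rng, np.frombuffer(mono.encode(), np.uint8), 0.02)
            .tobytes().decode() for _ in range(n)
        )

    bg = "".join(rng.choice(list("ACGT"), 500_000))
    h1 = simdata.ReferenceGenome(chromosomes=[
        ("h1_chr10", bg[:60_000] + array_of(m107, 30) + bg[60_000:140_000]),
        ("h1_chr15", bg[140_000:240_000]),
    ])
    h2 = simdata.ReferenceGenome(chromosomes=[
        ("h2_chr10", bg[250_000:310_000] + array_of(m107, 28) + bg[310_000:390_000]),
        ("h2_chr15", bg[390_000:440_000] + array_of(m187, 25) + bg[440_000:490_000]),
    ])
    homology = {"h1_chr10": "h2_chr10", "h1_chr15": "h2_chr15"}

    for fam_id, mono in (("sat107", m107), ("sat187", m187)):
        loci = {}
        for hap, asm in (("h1", h1), ("h2", h2)):
            hits = satellites.map_monomer(mono, asm)
            loci[hap] = satellites.call_tandem_loci(hits, len(mono))
            counts = satellites.site_counts(loci[hap]).to_dict()
            print(f"{fam_id} on {hap}: {counts or 'no loci'}")
        res = satellites.compare_haplotypes(loci["h1"], loci["h2"], homology)
        res.to_csv(OUT / f"{fam_id}.haplotype_comparison.tsv", sep="\t", index=False)
        shared = (res.status == "shared").sum() // 2
        hemi = (res.status == "hemizygous").sum()
        print(f"{fam_id}: {shared} shared locus pair(s), {hemi} hemizygous")


if __name__ == "__main__":
    main()
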