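"""WSSD calling, digital CGH, CNVR intersection, gene annotation."""

import numpy as np
import pandas as pd
import pytest

from vitiscape.cnprofile import CopyNumberProfile, WindowSet, define_windows
from vitiscape.simdata import ReferenceGenome
from vitiscape.svcalls import (
    annotate_regions,
    call_cgh,
    call_wssd,
    compute_l2r,
    intersect_cnvrs,
    read_gff3_genes,
)


def _profile(cn, chrom="chr1", span=1000):
    """Profile with one window per CN value, contiguous spans."""
    n = len(cn)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * span,
            "end": (np.arange(n) + 1) * span,
            "unmasked": span,
            "gc": 0.5,
        }
    )
    ws = WindowSet(df=df, size=span, unmasked_positions={})
    cn = np.asarray(cn, dtype=float)
    return CopyNumberProfile(
        sample_id="t", windows=ws, raw_depth=cn * 15, corrected_depth=cn * 15,
        cn=cn, control_mean=30.0, control_sd=1.0,
    )


class TestCallWssd:
    def test_five_consecutive_high_windows_called(self):
        regions = call_wssd(_profile([2, 2, 3, 3, 3, 3, 3, 2]))
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r.kind == "duplication"
        assert (r.start, r.end) == (2000, 7000)
        assert r.n_windows == 5
        assert r.mean_value == pytest.approx(3)

    def test_four_consecutive_not_called(self):
        assert call_wssd(_profile([3, 3, 3, 3, 2, 2, 2, 2])).empty

    def test_constant_diploid_no_calls(self):
        assert call_wssd(_profile([2] * 50)).empty

    def test_deletion_called_below_threshold(self):
        regions = call_wssd(_profile([2, 1, 1, 1, 1, 1, 2, 2]))
        assert list(regions.kind) == ["deletion"]
        assert regions.iloc[0].n_windows == 5

    def test_flank_invariance(self):
        """CN=2 padding never changes the member windows of existing calls."""
        core = [3, 3, 3, 3, 3, 1, 1, 1, 1, 1, 1]
        base = call_wssd(_profile([2] * 2 + core + [2] * 2))
        padded = call_wssd(_profile([2] * 7 + core + [2] * 9))
        assert list(base.n_windows) == list(padded.n_windows)
        assert list(base.kind) == list(padded.kind)
        assert np.allclose(padded.start - base.start, 5000)

    def test_chromosomes_processed_independently(self):
        p1 = _profile([3, 3, 3, 3, 3])
        p2 = _profile([2, 2], chrom="chr2")
        df = pd.concat([p1.windows.df, p2.windows.df], ignore_index=True)
        ws = WindowSet(df=df, size=1000, unmasked_positions={})
        cn = np.concatenate([p1.cn, p2.cn])
        prof = CopyNumberProfile("t", ws, cn, cn, cn, 30.0, 1.0)
        regions = call_wssd(prof)
        assert list(regions.chrom) == ["chr1"]


class TestComputeL2r:
    def test_textbook_ratios(self):
        s = _profile([4, 2, 1])
        r = _profile([2, 2, 2])
        assert np.allclose(compute_l2r(s, r), [1, 0, -1])

    def test_low_cn_windows_undefined(self):
        l2r = compute_l2r(_profile([2, 0.05, 2]), _profile([2, 2, 0.01]))
        assert np.isnan(l2r[1]) and np.isnan(l2r[2])
        assert l2r[0] == 0

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError):
            compute_l2r(_profile([2, 2]), _profile([2, 2, 2]))

    def test_antisymmetry(self, rng):
        cn_a = rng.uniform(0.5, 5, 100)
        cn_b = rng.uniform(0.5, 5, 100)
        ab = compute_l2r(_profile(cn_a), _profile(cn_b))
        ba = compute_l2r(_profile(cn_b), _profile(cn_a))
        assert np.allclose(ab, -ba, equal_nan=True)


class TestCallCgh:
    def test_long_gain_called_with_exact_span(self):
        prof = _profile([2] * 3 + [4] * 12 + [2] * 3)
        l2r = compute_l2r(prof, _profile([2] * 18))
        regions = call_cgh(l2r, prof.windows)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r.kind, r.end - r.start) == ("gain", 12_000)

    def test_short_run_filtered_by_length(self):
        # 9 windows of 1 kb = 9,000 bp <= 10 kb: dropped
        prof = _profile([2] * 3 + [4] * 9 + [2] * 3)
        l2r = compute_l2r(prof, _profile([2] * 15))
        assert call_cgh(l2r, prof.windows).empty

    def test_gain_and_loss_separated_by_neutral_window(self):
        prof = _profile([4] * 12 + [2] + [1] * 12)
        l2r = compute_l2r(prof, _profile([2] * 25))
        regions = call_cgh(l2r, prof.windows)
        assert sorted(regions.kind) == ["gain", "loss"]

    def test_self_comparison_yields_nothing(self, rng):
        prof = _profile(rng.uniform(1, 4, 200))
        l2r = compute_l2r(prof, prof)
        assert call_cgh(l2r, prof.windows).empty

    def test_swap_exchanges_gain_and_loss(self):
        a = _profile([2] * 3 + [4] * 12 + [1] * 12 + [2] * 3)
        b = _profile([2] * 30)
        fwd = call_cgh(compute_l2r(a, b), a.windows)
        rev = call_cgh(compute_l2r(b, a), a.windows)
        swap = {"gain": "loss", "loss": "gain"}
        assert [swap[k] for k in fwd.kind] == list(rev.kind)
        assert list(fwd.start) == list(rev.start)


def _regions(intervals, kind="duplication", chrom="chr1"):
    return pd.DataFrame(
        [(chrom, s, e, kind, (e - s) // 1000, 4.0) for s, e in intervals],
        columns=["chrom", "start", "end", "kind", "n_windows", "mean_value"],
    )


class TestIntersectCnvrs:
    def test_two_sample_overlap(self):
        out = intersect_cnvrs(
            {"A": _regions([(100, 200)]), "B": _regions([(150, 300)])}, "duplication"
        )
        shared = out[out.status == "shared"]
        assert [(r.start, r.end) for r in shared.itertuples()] == [(150, 200)]
        assert (out.status == "sample-specific").sum() == 0

    def test_disjoint_regions_all_specific(self):
        out = intersect_cnvrs(
            {"A": _regions([(0, 100)]), "B": _regions([(500, 600)])}, "duplication"
        )
        assert (out.status == "shared").sum() == 0
        assert (out.status == "sample-specific").sum() == 2

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValueError):
            intersect_cnvrs(
                {"A": _regions([(0, 100)]), "B": _regions([(0, 100)], kind="deletion")},
                "duplication",
            )

    def test_matches_per_base_boolean_oracle(self, rng):
        """Base-wise AND oracle over random region sets on a toy genome."""
        L = 100_000
        for _ in range(25):
            n_samples = int(rng.integers(2, 5))
            sets = {}
            masks = []
            for si in range(n_samples):
                n = int(rng.integers(1, 8))
                ivals = []
                for _ in range(n):
                    s = int(rng.integers(0, L - 5000))
                    e = s + int(rng.integers(1000, 5000))
                    ivals.append((s, e))
                sets[f"s{si}"] = _regions(ivals)
                m = np.zeros(L, dtype=bool)
                for s, e in ivals:
                    m[s:e] = True
                masks.append(m)
            out = intersect_cnvrs(sets, "duplication")
            got = np.zeros(L, dtype=bool)
            for r in out[out.status == "shared"].itertuples():
                got[r.start : r.end] = True
            expected = np.logical_and.reduce(masks)
            assert np.array_equal(got, expected)


class TestAnnotateRegions:
    GFF = """##gff-version 3
chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=gene1;Name=g1
chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=gene1
chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=gene2
chr2\tsrc\tgene\t101\t300\t.\t+\t.\tID=gene3
"""

    def _gff(self, tmp_path, text=None):
        p = tmp_path / "genes.gff3"
        p.write_text(text or self.GFF)
        return p

    def test_region_spanning_two_genes(self, tmp_path):
        regions = _regions([(500, 7000)])
        out, frac = annotate_regions(regions, self._gff(tmp_path))
        assert out.genes.iloc[0] == "gene1,gene2"
        assert frac == 1.0

    def test_gene_desert_region(self, tmp_path):
        out, frac = annotate_regions(_regions([(10_000, 20_000)]), self._gff(tmp_path))
        assert out.genes.iloc[0] == ""
        assert frac == 0.0

    def test_fraction_with_genes(self, tmp_path):
        ivals = [(1000, 2000)] * 7 + [(50_000, 51_000)] * 3
        out, frac = annotate_regions(_regions(ivals), self._gff(tmp_path))
        assert frac == pytest.approx(0.7)

    def test_malformed_line_reports_number(self, tmp_path):
        bad = "chr1\tsrc\tgene\t100\n"
        with pytest.raises(ValueError, match="line 1"):
            read_gff3_genes(self._gff(tmp_path, bad))

    def test_coordinate_convention(self, tmp_path):
        genes = read_gff3_genes(self._gff(tmp_path))
        g1 = genes[genes.gene_id == "gene1"].iloc[0]
        assert (g1.start, g1.end) == (1000, 2000)  # GFF3 1-based -> half-open
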