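"""Read-based repeat landscape profiling and cross-variety comparison.

The workflow mirrors assembly-free repeatome analysis: take a modest random
sample of reads from each genome, standardize them (quality-trim, fix the
length), cluster them by shared-k-mer similarity — at low sampled coverage
only repetitive sequence yields reads similar enough to cluster — classify
the clusters against a labeled repeat reference, and express each family's
abundance as the fraction of sampled reads it absorbs (its genome
proportion).  Landscapes from many samples are then compared with PCA,
K-means grouping and per-family Wilcoxon rank-sum tests.

Clustering builds the read graph through k-mer buckets: every pair of reads
co-occurring in a bucket shares that canonical k-mer, so a pair's bucket
multiplicity equals its exact shared-k-mer count.  Buckets larger than a cap
(deep-repeat k-mers) are unioned wholesale instead of enumerating their
quadratic pair set; see docs/methods.md for why this leaves components
unchanged in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from . import _kmers
from .simdata import Read, ReadSet

UNCLASSIFIED = "unclassified"
_SENTINEL = np.uint64(1 << 63)


@dataclass
class RepeatCluster:
    id: int
    members: np.ndarray  # indices into the clustered read list
    proportion: float  # fraction of sampled reads
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# read standardization
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> ReadSet:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    reads = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            reads.append(Read(title.split()[0], seq, qual))
    return ReadSet(reads)


def prepare_reads(
    reads: ReadSet | str | Path,
    n_sample: int = 1_000_000,
    seed: int = 100,
    min_quality: int = 20,
    target_length: int = 100,
    final_n: int = 250_000,
) -> ReadSet:
    """Subsample and standardize raw reads for repeatome clustering.

    A random sample of ``n_sample`` reads is drawn without replacement (all
    reads if fewer); each read's 3' end is trimmed while the base quality is
    below ``min_quality``; reads shorter than ``target_length`` after
    trimming are dropped and survivors are cut to exactly ``target_length``;
    finally a uniform subsample of ``final_n`` reads is kept.  Fully
    deterministic for a fixed seed.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    if not reads.reads:
        raise ValueError("empty read set")
    rng = np.random.default_rng(seed)
    n = len(reads.reads)
    if n > n_sample:
        idx = np.sort(rng.choice(n, size=n_sample, replace=False))
    else:
        idx = np.arange(n)
    survivors: list[Read] = []
    for i in idx:
        r = reads.reads[i]
        end = len(r.seq)
        while end > 0 and (ord(r.qual[end - 1]) - 33) < min_quality:
            end -= 1
        if end < target_length:
            continue
        survivors.append(Read(r.id, r.seq[:target_length], r.qual[:target_length]))
    if not survivors:
        raise ValueError("no reads survive quality standardization")
    if len(survivors) > final_n:
        keep = np.sort(rng.choice(len(survivors), size=final_n, replace=False))
        survivors = [survivors[i] for i in keep]
    return ReadSet(survivors)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _read_kmer_table(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (code, read_index) pairs, deduplicated within each read."""
    mat = _kmers.encode_matrix(seqs)
    codes = _kmers.canonical_kmers(mat, k)
    n, m = codes.shape
    codes.sort(axis=1)
    first = np.ones_like(codes, dtype=bool)
    first[:, 1:] = codes[:, 1:] != codes[:, :-1]
    first &= codes != _SENTINEL
    read_idx = np.repeat(np.arange(n, dtype=np.int64), first.sum(axis=1))
    return codes[first], read_idx


def cluster_reads(
    reads: ReadSet | list[str],
    k: int = 17,
    min_shared_kmers: int = 10,
    min_cluster_proportion: float = 0.0001,
    max_bucket: int = 50,
) -> list[RepeatCluster]:
    """Shared-k-mer connected-component clusters over equal-length reads.

    Two reads are linked when they share at least ``min_shared_kmers``
    canonical k-mers; clusters are the connected components of that graph.
    Components whose read proportion falls below ``min_cluster_proportion``
    (or that are singletons) are discarded.  Buckets of more than
    ``max_bucket`` reads sharing one k-mer are unioned directly rather than
    pair-counted.
    """
    seqs = [r.seq for r in reads.reads] if isinstance(reads, ReadSet) else list(reads)
    n = len(seqs)
    if n == 0:
        return []
    if k > len(seqs[0]):
        raise ValueError(f"k={k} exceeds read length {len(seqs[0])}")
    codes, read_idx = _read_kmer_table(seqs, k)
    order = np.lexsort((read_idx, codes))
    codes, read_idx = codes[order], read_idx[order]

    boundaries = np.concatenate(
        ([0], np.flatnonzero(codes[1:] != codes[:-1]) + 1, [len(codes)])
    )
    sizes = np.diff(boundaries)
    starts = boundaries[:-1]

    # phase 1 — small buckets: enumerate pairs; a pair's multiplicity across
    # buckets equals its exact number of shared canonical k-mers
    edges_a: list[np.ndarray] = []
    edges_b: list[np.ndarray] = []
    pair_codes: list[np.ndarray] = []
    for s in np.unique(sizes):
        if s < 2 or s > max_bucket:
            continue
        which = np.flatnonzero(sizes == s)
        members = read_idx[starts[which, None] + np.arange(s)]
        iu, ju = np.triu_indices(s, 1)
        a = members[:, iu].ravel().astype(np.uint64)
        b = members[:, ju].ravel().astype(np.uint64)
        pair_codes.append(a * np.uint64(n) + b)
    if pair_codes:
        allp = np.concatenate(pair_codes)
        uniq, counts = np.unique(allp, return_counts=True)
        good = uniq[counts >= min_shared_kmers]
        edges_a.append((good // np.uint64(n)).astype(np.int64))
        edges_b.append((good % np.uint64(n)).astype(np.int64))

    if edges_a and len(edges_a[0]):
        a = np.concatenate(edges_a)
        b = np.concatenate(edges_b)
        graph = sparse.coo_matrix(
            (np.ones(len(a), dtype=np.int8), (a, b)), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)

    # phase 2 — deep buckets (high-copy repeat k-mers): a read is assimilated
    # into the bucket-majority component only when it co-occurs with that
    # component in >= min_shared_kmers deep buckets, i.e. genuinely shares
    # that many k-mers with the cluster; a one-off k-mer coincidence between
    # unrelated sequences therefore never merges clusters.
    big = np.flatnonzero(sizes > max_bucket)
    if len(big):
        big_members = [
            read_idx[starts[bi] : starts[bi] + sizes[bi]] for bi in big
        ]
        labels = labels.copy()
        for _ in range(10):
            read_lab_pairs = []
            for members in big_members:
                labs = labels[members]
                uniq_l, cnt_l = np.unique(labs, return_counts=True)
                maj = uniq_l[np.argmax(cnt_l)]
                others = members[labs != maj]
                if len(others):
                    read_lab_pairs.append(
                        others.astype(np.int64) * np.int64(n) + np.int64(maj)
                    )
            if not read_lab_pairs:
                break
            allp = np.concatenate(read_lab_pairs)
            uniq, counts = np.unique(allp, return_counts=True)
            strong = uniq[counts >= min_shared_kmers]
            if not len(strong):
                break
            merge_read = (strong // n).astype(np.int64)
            merge_lab = (strong % n).astype(np.int64)
            # merge at component level through a relabelling pass
            remap = np.arange(n)
            remap[labels[merge_read]] = remap[merge_lab]
            # resolve chains
            for _ in range(3):
                remap = remap[remap]
            new_labels = remap[labels]
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels

    clusters: list[RepeatCluster] = []
    comp_ids, comp_sizes = np.unique(labels, return_counts=True)
    keep = comp_ids[(comp_sizes >= 2) & (comp_sizes / n >= min_cluster_proportion)]
    order_by_size = keep[np.argsort(-comp_sizes[np.searchsorted(comp_ids, keep)])]
    for cid, comp in enumerate(order_by_size):
        members = np.flatnonzero(labels == comp)
        clusters.append(
            RepeatCluster(id=cid, members=members, proportion=len(members) / n)
        )
    return clusters


# ---------------------------------------------------------------------------
# classification and abundance
# ---------------------------------------------------------------------------

def read_labeled_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(family_label, sequence) pairs from a FASTA whose headers are
    ``>seq_id family_label`` (or ``>family_label`` when no id is given)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.description.split(maxsplit=1)[1] if " " in rec.description else rec.id
        out.append((label.strip(), str(rec.seq).upper()))
    return out


def classify_clusters(
    clusters: list[RepeatCluster],
    reads: ReadSet | list[str],
    reference: list[tuple[str, str]] | str | Path,
    k: int = 17,
    min_identity: float = 0.8,
) -> list[RepeatCluster]:
    """Label clusters against a family-labeled repeat reference.

    Each member read is matched to reference sequences through canonical
    k-mer containment; containment c estimates sequence identity as
    c**(1/k), and a read matches when that estimate reaches
    ``min_identity``.  A cluster takes the family of the majority (> 50%) of
    its matched members, otherwise ``unclassified``.  Returns new cluster
    objects with labels filled in; clusters with no matched member stay
    unclassified.
    """
    seqs = [r.seq for r in reads.reads] if isinstance(reads, ReadSet) else list(reads)
    if isinstance(reference, (str, Path)):
        reference = read_labeled_fasta(reference)
    if not reference:
        raise ValueError("empty repeat reference")
    if not clusters:
        return []
    mat = _kmers.encode_matrix(seqs)
    codes = _kmers.canonical_kmers(mat, k)
    n, m = codes.shape
    min_containment = min_identity ** k
    best_frac = np.zeros(n)
    best_family = np.full(n, "", dtype=object)
    for family, seq in reference:
        ref_set = _kmers.unique_canonical(seq, k)
        if not len(ref_set):
            continue
        hit = np.isin(codes, ref_set).sum(axis=1) / m
        better = hit > best_frac
        best_frac[better] = hit[better]
        best_family[better] = family
    matched = best_frac >= min_containment

    out = []
    for c in clusters:
        mm = c.members[matched[c.members]]
        label = UNCLASSIFIED
        if len(mm):
            fams, counts = np.unique(best_family[mm].astype(str), return_counts=True)
            top = np.argmax(counts)
            if counts[top] / len(mm) > 0.5:
                label = str(fams[top])
        out.append(RepeatCluster(c.id, c.members, c.proportion, label))
    return out


def abundance_table(
    labeled_clusters: dict[str, list[RepeatCluster]],
    totals: dict[str, int],
) -> pd.DataFrame:
    """Per-sample genome-proportion matrix (%): samples x repeat families.

    A cell is the summed read count of the family's clusters divided by the
    sample's total sampled reads, times 100.  Families absent from a sample
    get 0; unclassified clusters are pooled under ``unclassified``.
    """
    if not labeled_clusters:
        raise ValueError("need at least one sample")
    rows = {}
    for sample, clusters in labeled_clusters.items():
        total = totals[sample]
        acc: dict[str, float] = {}
        for c in clusters:
            label = c.label or UNCLASSIFIED
            acc[label] = acc.get(label, 0.0) + 100.0 * c.size / total
        rows[sample] = acc
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out.reindex(list(labeled_clusters)).fillna(0.0)
    return out.sort_index(axis=1)


# ---------------------------------------------------------------------------
# landscape comparison
# ---------------------------------------------------------------------------

@dataclass
class LandscapeComparison:
    pca: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    groups: pd.Series  # sample -> K-means group label
    wilcoxon: pd.DataFrame  # family, p[, q], significant
    significant: list[str] = field(default_factory=list)


def compare_landscapes(
    matrix: pd.DataFrame,
    n_groups: int = 2,
    alpha: float = 0.05,
    n_components: int | None = None,
    bh_correction: bool = False,
    random_state: int = 0,
    groups: np.ndarray | list | None = None,
) -> LandscapeComparison:
    """PCA + K-means grouping + per-family Wilcoxon tests on an abundance matrix.

    Columns are centered and scaled to unit variance before PCA; K-means
    (``n_groups`` clusters) runs on the retained principal components (all,
    by default).  Each family is then compared between the two largest
    groups with a two-sided Wilcoxon rank-sum test (exact for small
    tie-free samples); families with p <= alpha are flagged, without
    multiple-testing correction unless ``bh_correction`` is set.

    ``groups`` overrides the K-means assignment with externally known group
    labels — use this when groups are defined a priori (or when calibrating
    the test under a null), since comparing groups that were themselves
    chosen by clustering the same matrix biases the p-values.
    """
    if len(matrix) < n_groups:
        raise ValueError("fewer samples than groups")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if not np.any(sd > 0):
        raise ValueError("all samples identical: no variance to analyse")
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    max_comp = min(Xs.shape) if len(matrix) > min(Xs.shape) else min(Xs.shape) - 1
    ncomp = min(n_components or max_comp, max_comp)
    pca = PCA(n_components=ncomp, random_state=random_state)
    coords = pca.fit_transform(Xs)
    if groups is not None:
        labels = np.asarray(groups)
        if len(labels) != len(matrix):
            raise ValueError("groups must give one label per sample")
    else:
        km = KMeans(n_clusters=n_groups, n_init=10, random_state=random_state)
        labels = km.fit_predict(coords)

    sizes = pd.Series(labels).value_counts()
    g1, g2 = sizes.index[:2]
    in1, in2 = labels == g1, labels == g2
    rows = []
    for j, family in enumerate(matrix.columns):
        x, y = X[in1, j], X[in2, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append((family, p))
    wdf = pd.DataFrame(rows, columns=["family", "p"])
    if bh_correction:
        wdf["q"] = multipletests(wdf.p, method="fdr_bh")[1]
        wdf["significant"] = wdf.q <= alpha
    else:
        wdf["significant"] = wdf.p <= alpha
    return LandscapeComparison(
        pca=pd.DataFrame(
            coords, index=matrix.index, columns=[f"PC{i+1}" for i in range(ncomp)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        groups=pd.Series(labels, index=matrix.index, name="group"),
        wilcoxon=wdf,
        significant=wdf.loc[wdf.significant, "family"].tolist(),
    )
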