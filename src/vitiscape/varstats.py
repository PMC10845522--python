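"""Chromosome-level variant-distribution tests and term enrichment.

Under the null that variants fall uniformly along the genome, the expected
count for a chromosome is the genome-wide rate (variants per kbp) times the
chromosome length.  A chi-square goodness-of-fit statistic over chromosomes
tests that null; per-chromosome standardized residuals localize the signal
and flag enriched/depleted chromosomes.  A hypergeometric term-enrichment
utility with Benjamini-Hochberg FDR covers GO-style gene-set analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    table: pd.DataFrame  # per chromosome: observed, expected, residual, p_component

    def __str__(self) -> str:
        return (
            f"chi-square = {self.statistic:.3f}, df = {self.df}, "
            f"p = {self.pvalue:.3g}"
        )


def expected_counts(lengths: dict[str, int], total_variants: float) -> pd.Series:
    """Length-proportional expected variant counts per chromosome.

    rate = total / (total length / 1000) variants per kbp; the expectation
    for chromosome c is rate * length_c / 1000, so expectations sum to the
    observed total.
    """
    if total_variants <= 0:
        raise ValueError("total_variants must be > 0")
    lens = pd.Series(lengths, dtype=float)
    if (lens <= 0).any():
        bad = lens[lens <= 0].index.tolist()
        raise ValueError(f"non-positive chromosome length for {bad}")
    rate_per_kbp = total_variants / (lens.sum() / 1000.0)
    return rate_per_kbp * lens / 1000.0


def chisq_randomness(
    observed: dict[str, int] | pd.Series,
    expected: dict[str, float] | pd.Series,
) -> ChiSquareResult:
    """Chi-square test of variant counts against length-proportional expectations.

    statistic = sum((O-E)^2 / E) with df = n_chromosomes - 1 (expectations
    derive from the observed total).  The per-chromosome table carries the
    standardized residual (O-E)/sqrt(E) and a descriptive one-df upper-tail
    p-value for each chromosome's component.
    """
    obs = pd.Series(observed, dtype=float)
    exp = pd.Series(expected, dtype=float).reindex(obs.index)
    if (obs < 0).any():
        raise ValueError("negative observed count")
    if exp.isna().any() or (exp <= 0).any():
        raise ValueError("expected counts must be positive for every chromosome")
    if not np.isclose(obs.sum(), exp.sum(), rtol=1e-6):
        raise ValueError("observed and expected totals differ")
    components = (obs - exp) ** 2 / exp
    statistic = float(components.sum())
    df = len(obs) - 1
    pvalue = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    table = pd.DataFrame(
        {
            "observed": obs,
            "expected": exp,
            "residual": (obs - exp) / np.sqrt(exp),
            "component": components,
            "p_component": stats.chi2.sf(components, 1),
        }
    )
    return ChiSquareResult(statistic=statistic, df=df, pvalue=pvalue, table=table)


def flag_enriched(result: ChiSquareResult, residual_threshold: float = 2.0) -> pd.Series:
    """Classify chromosomes as 'enriched', 'depleted' or 'ns' by residual."""
    res = result.table.residual
    return pd.Series(
        np.where(res > residual_threshold, "enriched",
                 np.where(res < -residual_threshold, "depleted", "ns")),
        index=res.index,
    )


def hypergeom_enrich(
    study: set[str] | list[str],
    population: set[str] | list[str],
    term_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per term, BH-corrected.

    For each term, p is the upper-tail probability of drawing at least the
    observed overlap when sampling ``len(study)`` genes from the population
    without replacement.  Fold enrichment is the observed/expected overlap
    ratio.  Returns a frame sorted by p with columns term, overlap,
    term_size, fold, p, q, significant (q <= alpha).
    """
    study = set(study)
    population = set(population)
    missing = study - population
    if missing:
        raise ValueError(f"study genes absent from population: {sorted(missing)}")
    M, N = len(population), len(study)
    rows = []
    for term, genes in term_map.items():
        genes = set(genes) & population
        n = len(genes)
        if n == 0:
            continue
        k = len(genes & study)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        expected = n * N / M
        rows.append((term, k, n, k / expected if expected > 0 else np.nan, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "fold", "p"])
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = multipletests(out.p, method="fdr_bh")[1]
    out["significant"] = out.q <= alpha
    return out.sort_values("p", ignore_index=True)
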