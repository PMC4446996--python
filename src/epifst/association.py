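"""Correlations with genomic covariates and DE-gene over-representation.

Covers three analyses around the per-peak/per-gene statistics: Spearman
rank correlation between windowed SNP counts and peak counts or mean peak
density; the per-peak correlation between within- and between-species sums
of squares; and the hypergeometric over-representation of differentially
expressed genes among the top-K genes ranked by epi-FST or variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ValidationError

__all__ = [
    "CorrelationReport",
    "EnrichmentResult",
    "spearman",
    "window_covariate_table",
    "ss_correlation",
    "top_k_enrichment",
    "rank_genes",
]


@dataclass(frozen=True)
class CorrelationReport:
    variable_pair: tuple[str, str]
    n: int
    spearman_rho: float  # NaN when a vector is constant
    p_value: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.spearman_rho)


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail over-representation of a gene set among the top-n ranked
    genes: overlap m out of top n, with K set members in a universe of N."""

    universe_size: int
    de_in_universe: int
    top_size: int
    overlap: int
    p_value: float
    method: str = "hypergeometric"


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
) -> CorrelationReport:
    """Spearman rank correlation with average ranks for ties; incomplete
    (NaN) pairs are dropped first. Requires >= 3 complete pairs. A constant
    vector yields an undefined (NaN) rho, flagged via ``defined``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationReport(labels, len(x), float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return CorrelationReport(labels, len(x), float(rho), float(p))


def window_covariate_table(
    windows: pd.DataFrame, snp_track: pd.DataFrame
) -> pd.DataFrame:
    """Join a windowed-divergence table with per-window SNP counts.

    A SNP interval's count is attributed to each window proportionally to
    the overlapped fraction of the interval, so overlapping sliding windows
    never double-count ambiguously and attribution is additive. Adds a
    ``snp_count`` column.
    """
    out = windows.copy()
    counts = np.zeros(len(out))
    track = {c: s.sort_values("start") for c, s in snp_track.groupby("chrom", sort=False)}
    for i, w in enumerate(out.itertuples(index=False)):
        sub = track.get(w.chrom)
        if sub is None:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        ov = np.minimum(e, w.end) - np.maximum(s, w.start)
        sel = ov > 0
        if sel.any():
            frac = ov[sel] / (e[sel] - s[sel])
            counts[i] = float((frac * sub["count"].to_numpy()[sel]).sum())
    out["snp_count"] = counts
    return out


def ss_correlation(aneva_table: pd.DataFrame) -> CorrelationReport:
    """Spearman correlation of per-peak (SS_within, SS_between)."""
    return spearman(
        aneva_table["ss_within"], aneva_table["ss_between"],
        labels=("ss_within", "ss_between"),
    )


def rank_genes(
    gene_scores: pd.DataFrame, score_col: str = "mean_epi_fst"
) -> pd.DataFrame:
    """Genes with a defined score, ranked by score descending; ties broken
    by higher n_peaks, then lexicographic gene_id."""
    df = gene_scores[gene_scores[score_col].notna()].copy()
    n_peaks = df["n_peaks"] if "n_peaks" in df.columns else 0
    df["_neg_np"] = -np.asarray(n_peaks)
    df["_neg_score"] = -df[score_col]
    df = df.sort_values(["_neg_score", "_neg_np", "gene_id"], kind="mergesort")
    return df.drop(columns=["_neg_np", "_neg_score"]).reset_index(drop=True)


def top_k_enrichment(
    gene_scores: pd.DataFrame,
    de_genes: Iterable[str],
    k: int,
    universe: Iterable[str] | None = None,
    score_col: str = "mean_epi_fst",
    method: str = "hypergeometric",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Over-representation of DE genes among the top-``k`` ranked genes.

    The universe is the set of genes with a defined score, intersected with
    ``universe`` when given (e.g. the genes present in the expression
    dataset); the DE set is restricted to that universe. With the default
    method, p = P(X >= m) for X ~ Hypergeom(N, K, n). ``method="permutation"``
    instead reassigns the K DE labels uniformly at random ``n_perm`` times
    and reports the add-one tail estimate — a robustness check on the
    analytic tail.
    """
    ranked = rank_genes(gene_scores, score_col=score_col)
    ids = ranked["gene_id"]
    if universe is not None:
        uni = set(universe)
        ids = ids[ids.isin(uni)]
    ids = ids.reset_index(drop=True)
    N = len(ids)
    if k <= 0:
        raise ValidationError("k must be positive")
    if N == 0:
        raise ValidationError("empty gene universe")
    if k > N:
        raise ValidationError(f"k={k} exceeds universe size {N}")
    de = set(de_genes) & set(ids)
    K = len(de)
    top = set(ids.iloc[:k])
    m = len(top & de)
    if method == "hypergeometric":
        p = float(stats.hypergeom.sf(m - 1, N, K, k)) if K else 1.0
        return EnrichmentResult(N, K, k, m, min(p, 1.0))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        all_ids = np.asarray(ids)
        top_mask = np.isin(all_ids, list(top))
        r = 0
        for _ in range(n_perm):
            lab = rng.choice(N, size=K, replace=False)
            mask = np.zeros(N, dtype=bool)
            mask[lab] = True
            if int((mask & top_mask).sum()) >= m:
                r += 1
        return EnrichmentResult(N, K, k, m, (r + 1) / (n_perm + 1), method="permutation")
    raise ValueError(f"unknown method {method!r}")
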