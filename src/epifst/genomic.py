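"""Gene-level aggregation and TSS-proximity classification.

Per-peak statistics are mapped to genes by interval overlap with the gene
body extended by a symmetric flank (default 50 kb on each side), and the
within-species sum of squares is further decomposed per species:

    SS_within = sum_s SS_within_s,   Var_s = SS_within_s / (n_s - 1).

A peak is "near TSS" when its interval overlaps [tss - w, tss + w) for any
transcription start site in the selected mode (all TSSs, or one unique TSS
per gene chosen as the longest transcript's).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .aneva import _check_design, _decompose_rows, _group_layout
from .data import PeakMatrix, ValidationError

__all__ = [
    "TssProximityReport",
    "within_species_variance",
    "within_species_table",
    "assign_peaks_to_genes",
    "gene_scores",
    "tss_proximity",
    "select_unique_tss",
]


@dataclass(frozen=True)
class TssProximityReport:
    """Fraction of peaks whose interval lies within ``window_bp`` of a TSS."""

    window_bp: int
    n_peaks_total: int
    n_peaks_near_tss: int
    tss_mode: str

    @property
    def fraction_near_tss(self) -> float:
        return self.n_peaks_near_tss / self.n_peaks_total


# ---------------------------------------------------------------------------
# within-species decomposition


def within_species_variance(
    values: Sequence[float], species_labels: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Per-species (SS, variance) for one peak.

    SS_s = sum_j (y_sj - ybar_s)^2 and Var_s = SS_s/(n_s - 1); the SS_s sum
    to the pooled within-species SS of the one-way decomposition.
    """
    y = np.asarray(values, dtype=float)
    species, sizes, order = _group_layout(species_labels)
    _check_design(sizes, species)
    out: dict[str, tuple[float, float]] = {}
    pos = 0
    yb = y[order]
    for s, n in zip(species, sizes):
        block = yb[pos:pos + n]
        ss = float(((block - block.mean()) ** 2).sum())
        out[s] = (ss, ss / (n - 1))
        pos += n
    return out


def within_species_table(pm: PeakMatrix) -> pd.DataFrame:
    """Vectorized per-peak per-species SS/variance for a whole matrix.

    Columns: peak coordinates plus ``ss_<species>`` and ``var_<species>``.
    """
    labels = pm.species_labels()
    species, sizes, order = _group_layout(labels)
    _check_design(sizes, species)
    Y = pm.densities[:, order]
    out = pm.peaks.copy()
    pos = 0
    for s, n in zip(species, sizes):
        block = Y[:, pos:pos + n]
        ss = ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        out[f"ss_{s}"] = ss
        out[f"var_{s}"] = ss / (n - 1)
        pos += n
    return out


# ---------------------------------------------------------------------------
# peak -> gene assignment


def _peak_trees(peaks: pd.DataFrame, mode: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        tree = IntervalTree()
        for r in sub.itertuples(index=False):
            if mode == "midpoint":
                mid = (r.start + r.end) // 2
                tree.addi(mid, mid + 1, r.peak_id)
            else:
                tree.addi(r.start, r.end, r.peak_id)
        trees[chrom] = tree
    return trees


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 50_000,
    mode: str = "overlap",
) -> dict[str, list[str]]:
    """Map each gene to the peaks lying within the gene +/- ``flank_bp``.

    A peak is assigned to gene g iff its interval overlaps
    [g.start - flank, g.end + flank) (clamped at 0) on the same chromosome;
    flanks are symmetric regardless of strand. ``mode="midpoint"`` instead
    requires the peak midpoint to fall inside the extended interval. A peak
    may be assigned to several genes; genes without peaks map to [].
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    trees = _peak_trees(peaks, mode)
    assignment: dict[str, list[str]] = {}
    for g in genes.itertuples(index=False):
        tree = trees.get(g.chrom)
        lo = max(0, g.start - flank_bp)
        hi = g.end + flank_bp
        if tree is None:
            assignment[g.gene_id] = []
        else:
            hits = tree.overlap(lo, hi)
            assignment[g.gene_id] = sorted(iv.data for iv in hits)
    return assignment


def gene_scores(
    peak_table: pd.DataFrame,
    assignment: Mapping[str, list[str]],
    genes: pd.DataFrame | None = None,
    value_cols: Sequence[str] = ("epi_fst",),
) -> pd.DataFrame:
    """Per-gene unweighted means of per-peak statistics.

    Undefined (NaN) per-peak values are dropped from the mean and flagged
    via ``partial_coverage`` rather than treated as 0; a gene whose peaks
    are all undefined (or with no peaks) gets NaN means and n_defined = 0.

    Columns: ``gene_id n_peaks n_defined partial_coverage mean_<col>...``.
    """
    cols = [c for c in value_cols if c in peak_table.columns]
    if not cols:
        raise ValueError(f"none of {list(value_cols)} present in peak table")
    by_peak = peak_table.set_index("peak_id")[cols]
    gene_ids = list(genes["gene_id"]) if genes is not None else list(assignment)
    recs = []
    for gid in gene_ids:
        pids = assignment.get(gid, [])
        vals = by_peak.loc[pids] if pids else by_peak.iloc[0:0]
        n_peaks = len(pids)
        n_defined = int(vals[cols[0]].notna().sum())
        rec = {
            "gene_id": gid,
            "n_peaks": n_peaks,
            "n_defined": n_defined,
            "partial_coverage": 0 < n_defined < n_peaks,
        }
        for c in cols:
            ok = vals[c].dropna()
            rec[f"mean_{c}"] = float(ok.mean()) if len(ok) else np.nan
        recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# TSS proximity


def select_unique_tss(tss: pd.DataFrame) -> pd.DataFrame:
    """One TSS per gene: the longest transcript's, ties to the smallest
    coordinate."""
    df = tss.sort_values(
        ["gene_id", "transcript_length", "position"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return df.drop_duplicates("gene_id", keep="first").reset_index(drop=True)


def tss_proximity(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 2_000,
    tss_mode: str = "unique",
) -> TssProximityReport:
    """Fraction of peaks overlapping [tss - window, tss + window) for any
    TSS; each peak is counted at most once.

    ``tss_mode="unique"`` keeps one TSS per gene (longest transcript);
    ``"all"`` uses every TSS row.
    """
    if len(peaks) == 0:
        raise ValidationError("tss_proximity requires a non-empty peak set")
    if tss_mode == "unique":
        anchors = select_unique_tss(tss)
    elif tss_mode == "all":
        anchors = tss
    else:
        raise ValueError(f"unknown tss_mode {tss_mode!r}")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in anchors.groupby("chrom", sort=False):
        tree = IntervalTree()
        for pos in sub["position"]:
            lo = max(0, int(pos) - window_bp)
            hi = int(pos) + window_bp
            if hi > lo:
                tree.addi(lo, hi)
            else:  # window 0: the TSS base itself
                tree.addi(int(pos), int(pos) + 1)
        trees[chrom] = tree
    near = 0
    for p in peaks.itertuples(index=False):
        tree = trees.get(p.chrom)
        if tree is not None and tree.overlap(p.start, p.end):
            near += 1
    return TssProximityReport(
        window_bp=window_bp,
        n_peaks_total=len(peaks),
        n_peaks_near_tss=near,
        tss_mode=tss_mode,
    )
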