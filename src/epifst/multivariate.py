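"""Centered, unscaled PCA of sample density profiles and sliding-window
between-species divergence.

Observations are samples, variables are peaks. Columns are mean-centered
but not scaled, so the analysis is an eigendecomposition of the sample
covariance matrix and the eigenvalue sum equals the total variance
(inertia) of the centered data. Between-species divergence in a genomic
window is the pairwise Euclidean distance between species centroids (the
centers of each species' dispersion ellipse) in the leading principal axes
of a per-window PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .data import PeakMatrix, SampleMetadata, ValidationError

__all__ = [
    "PcaResult",
    "genome_pca",
    "species_centroids",
    "pairwise_centroid_distances",
    "sliding_windows",
    "windowed_divergence",
]


@dataclass
class PcaResult:
    """Result of a centered, unscaled PCA.

    Attributes
    ----------
    scores : DataFrame (samples x components), columns PC1, PC2, ...
    eigenvalues : per-component variance, non-increasing.
    variance_explained : eigenvalues / total variance (zeros when the data
        are constant).
    total_variance : sum of per-peak variances of the centered data.
    divisor : the covariance divisor used ('n' or 'n-1').
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    total_variance: float
    divisor: str = "n"

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _pca(X: np.ndarray, divisor: str) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    denom = n if divisor == "n" else n - 1
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per axis
    for a in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    scores = U * s
    eig = (s**2) / denom
    total = float((Xc**2).sum() / denom)
    return scores, eig, total


def genome_pca(
    pm: PeakMatrix | None = None,
    *,
    densities: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    divisor: str = "n",
) -> PcaResult:
    """Centered, unscaled PCA of samples over peak-density variables.

    Accepts either a :class:`PeakMatrix` or a raw (peaks x samples) density
    array with sample ids. Requires >= 2 samples and >= 1 peak.
    """
    if divisor not in ("n", "n-1"):
        raise ValueError("divisor must be 'n' or 'n-1'")
    if pm is not None:
        densities, sample_ids = pm.densities, pm.sample_ids
    if densities is None or sample_ids is None:
        raise ValueError("provide a PeakMatrix or densities + sample_ids")
    X = np.asarray(densities, dtype=float).T  # samples x peaks
    if X.shape[0] < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if X.shape[1] < 1:
        raise ValidationError("PCA requires at least 1 peak")
    scores, eig, total = _pca(X, divisor)
    ve = eig / total if total > 0 else np.zeros_like(eig)
    cols = [f"PC{a + 1}" for a in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=list(sample_ids), columns=cols),
        eigenvalues=eig,
        variance_explained=ve,
        total_variance=total,
        divisor=divisor,
    )


def species_centroids(
    pca: PcaResult, metadata: SampleMetadata, n_components: int = 2
) -> dict[str, np.ndarray]:
    """Per-species mean of sample scores in the first ``n_components`` axes
    (the center of each species' ellipse of dispersion)."""
    k = min(n_components, pca.n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    labels = dict(zip(metadata.sample_ids, metadata.species_of()))
    out: dict[str, list[np.ndarray]] = {}
    for sid, row in pca.scores.iterrows():
        sp = labels.get(sid)
        if sp is None:
            raise ValidationError(f"sample {sid!r} absent from metadata")
        out.setdefault(sp, []).append(row.to_numpy()[:k])
    missing = [s for s in metadata.species if s not in out]
    if missing:
        raise ValidationError(f"species with zero samples in scores: {missing}")
    return {s: np.mean(rows, axis=0) for s, rows in out.items()}


def pairwise_centroid_distances(
    centroids: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Euclidean distances between all species-centroid pairs."""
    return {
        (a, b): float(np.linalg.norm(np.asarray(centroids[a]) - np.asarray(centroids[b])))
        for a, b in combinations(centroids, 2)
    }


def sliding_windows(
    chrom_lengths: Mapping[str, int],
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
) -> pd.DataFrame:
    """Sliding genomic windows [s, s + window) for s = 0, step, 2*step, ...

    The last start satisfies start <= length - window; a chromosome shorter
    than one window yields a single truncated window covering it entirely.
    """
    if step_bp < 1 or window_bp < step_bp:
        raise ValueError("require window_bp >= step_bp >= 1")
    recs = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        if length < window_bp:
            recs.append((chrom, 0, int(length)))
            continue
        for s in range(0, length - window_bp + 1, step_bp):
            recs.append((chrom, s, s + window_bp))
    return pd.DataFrame(recs, columns=["chrom", "start", "end"])


def windowed_divergence(
    pm: PeakMatrix,
    windows: pd.DataFrame | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    n_components: int = 2,
    min_peaks: int = 2,
    divisor: str = "n",
) -> pd.DataFrame:
    """Per-window species-centroid distances from window-restricted PCAs.

    Each window's PCA uses the peaks whose intervals overlap it (windows
    overlap, so a boundary peak contributes to several). Windows with fewer
    than ``min_peaks`` peaks are emitted with NaN distances. Output columns:
    ``chrom start end n_peaks mean_density dist_<a>__<b>...``.
    """
    if windows is None:
        if chrom_lengths is None:
            raise ValueError("provide windows or chrom_lengths")
        windows = sliding_windows(chrom_lengths, window_bp, step_bp)
    meta = pm.metadata
    pairs = list(combinations(meta.species, 2))
    starts = pm.peaks["start"].to_numpy()
    ends = pm.peaks["end"].to_numpy()
    chroms = pm.peaks["chrom"].to_numpy()
    recs = []
    for w in windows.itertuples(index=False):
        mask = (chroms == w.chrom) & (starts < w.end) & (ends > w.start)
        n = int(mask.sum())
        rec = {"chrom": w.chrom, "start": w.start, "end": w.end, "n_peaks": n,
               "mean_density": float(pm.densities[mask].mean()) if n else np.nan}
        if n >= min_peaks:
            pca = genome_pca(densities=pm.densities[mask], sample_ids=pm.sample_ids,
                             divisor=divisor)
            cent = species_centroids(pca, meta, n_components=n_components)
            dists = pairwise_centroid_distances(cent)
            for a, b in pairs:
                rec[f"dist_{a}__{b}"] = dists[(a, b)]
        else:
            for a, b in pairs:
                rec[f"dist_{a}__{b}"] = np.nan
        recs.append(rec)
    return pd.DataFrame(recs)
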