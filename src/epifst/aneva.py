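"""Per-peak one-way random-effects variance decomposition and epi-FST.

The model for the normalized peak density of individual *j* in species *i* is

    Y_ij = mu + alpha_i + eps_ij,

with random, additive species effects alpha_i ~ (0, sigma2_alpha) and
individual effects eps_ij ~ (0, sigma2_eps). For each peak the total sum of
squares splits into between- and within-species components,

    SS_total = SS_between + SS_within,
    SS_between = sum_i n_i (ybar_i - ybar)^2,
    SS_within  = sum_i sum_j (y_ij - ybar_i)^2,

and the method-of-moments ("natural") estimators are

    S2       = SS_within / (N - k)                 (estimates sigma2_eps)
    S2_alpha = (MS_between - S2) / n0              (estimates sigma2_alpha)

with MS_between = SS_between/(k-1) and effective sample size
n0 = (N - sum_i n_i^2 / N) / (k - 1) for unbalanced designs. The
differentiation statistic is

    epi-FST = S2_alpha / (S2_alpha + S2),

an FST-like fixation index for epigenetic marks. It can be negative; its
infimum over configurations with positive within-species variation is
-1/(n0 - 1), attained as MS_between -> 0, and tends to 0 as n0 grows.
Significance is assessed by permuting individuals between species.

The module exposes both a low-level functional surface
(:func:`variance_components`, :func:`permutation_test`, :func:`aneva_table`)
and a model/results pair (:class:`ANEVA`, :class:`ANEVAResults`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .data import PeakMatrix, SampleMetadata, ValidationError

__all__ = [
    "VarianceComponents",
    "PermutationResult",
    "variance_components",
    "epi_fst",
    "min_epi_fst",
    "permutation_test",
    "aneva_table",
    "ANEVA",
    "ANEVAResults",
]

_EXHAUSTIVE_MAX_N = 12


@dataclass(frozen=True)
class VarianceComponents:
    """One-way ANOVA decomposition for a single peak."""

    peak_id: str | None
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    s2: float
    n0: float
    s2_alpha: float
    epi_fst: float  # NaN when undefined (S2_alpha + S2 == 0)
    group_means: dict[str, float]
    grand_mean: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.epi_fst)

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


@dataclass(frozen=True)
class PermutationResult:
    """Permutation significance of one peak's epi-FST.

    ``p_value`` uses the add-one estimator (r+1)/(n+1); a permuted statistic
    that is undefined counts as not-as-extreme. When the observed statistic
    itself is undefined, ``observed_defined`` is False and p is 1.
    """

    peak_id: str | None
    observed_epi_fst: float
    n_permutations: int
    n_as_extreme: int
    p_value: float
    observed_defined: bool
    exhaustive: bool = False


# ---------------------------------------------------------------------------
# grouping helpers


def _group_layout(species_labels: Sequence[str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (species order, per-group sizes, sample order grouping samples
    into contiguous blocks, species in first-appearance order)."""
    labels = np.asarray(species_labels)
    species = list(dict.fromkeys(labels.tolist()))
    order = np.concatenate([np.flatnonzero(labels == s) for s in species])
    sizes = np.array([int((labels == s).sum()) for s in species])
    return species, sizes, order


def _check_design(sizes: np.ndarray, species: Sequence[str]) -> None:
    if len(sizes) < 2:
        raise ValidationError("at least 2 species are required")
    small = [s for s, n in zip(species, sizes) if n < 2]
    if small:
        raise ValidationError(
            f"species with fewer than 2 samples: {small}; within-species "
            "degrees of freedom would be silently inflated"
        )


def effective_sample_size(sizes: Sequence[int]) -> float:
    """Unbalanced one-way effective sample size n0 = (N - sum n_i^2/N)/(k-1)."""
    n = np.asarray(sizes, dtype=float)
    N, k = n.sum(), len(n)
    return float((N - (n**2).sum() / N) / (k - 1))


def _decompose_rows(Y: np.ndarray, sizes: np.ndarray):
    """Sum-of-squares decomposition for row-vectors of group-blocked values.

    Y has shape (m, N) with samples ordered so each species occupies a
    contiguous block of ``sizes``. Returns (ss_between, ss_within,
    group_means) with shapes (m,), (m,), (m, k).
    """
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    gsum = np.add.reduceat(Y, starts, axis=1)
    gmean = gsum / sizes
    grand = Y.mean(axis=1)
    ssb = (sizes * (gmean - grand[:, None]) ** 2).sum(axis=1)
    centered = Y - np.repeat(gmean, sizes, axis=1)
    ssw = (centered**2).sum(axis=1)
    return ssb, ssw, gmean


def _fst_rows(ssb, ssw, sizes, n0: float | None = None):
    """Vectorized natural estimates and epi-FST from SS rows."""
    N, k = int(sizes.sum()), len(sizes)
    dfb, dfw = k - 1, N - k
    if n0 is None:
        n0 = effective_sample_size(sizes)
    msb = ssb / dfb
    s2 = ssw / dfw
    s2a = (msb - s2) / n0
    denom = s2a + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, s2a / np.where(denom > 0, denom, 1.0), np.nan)
    return {
        "df_between": dfb, "df_within": dfw, "n0": n0,
        "ms_between": msb, "s2": s2, "s2_alpha": s2a, "epi_fst": fst,
    }


# ---------------------------------------------------------------------------
# per-peak functional surface


def variance_components(
    values: Sequence[float],
    species_labels: Sequence[str],
    n0: float | None = None,
    peak_id: str | None = None,
) -> VarianceComponents:
    """Decompose one peak's densities into between/within-species components.

    Parameters
    ----------
    values : per-sample densities for one peak.
    species_labels : species label per sample, aligned with ``values``.
    n0 : optional override of the effective sample size (default: the
        standard unbalanced formula).

    Requires >= 2 species and >= 2 samples in every species.
    """
    y = np.asarray(values, dtype=float)
    species, sizes, order = _group_layout(species_labels)
    if len(y) != len(np.asarray(species_labels)):
        raise ValidationError("values and species_labels differ in length")
    _check_design(sizes, species)
    ssb, ssw, gmean = _decompose_rows(y[order][None, :], sizes)
    est = _fst_rows(ssb, ssw, sizes, n0=n0)
    return VarianceComponents(
        peak_id=peak_id,
        ss_between=float(ssb[0]),
        ss_within=float(ssw[0]),
        df_between=est["df_between"],
        df_within=est["df_within"],
        ms_between=float(est["ms_between"][0]),
        s2=float(est["s2"][0]),
        n0=float(est["n0"]),
        s2_alpha=float(est["s2_alpha"][0]),
        epi_fst=float(est["epi_fst"][0]),
        group_means={s: float(m) for s, m in zip(species, gmean[0])},
        grand_mean=float(y.mean()),
    )


def epi_fst(vc: VarianceComponents) -> float:
    """epi-FST = S2_alpha / (S2_alpha + S2); NaN when the denominator is 0.

    Negative values are retained, never clamped: they arise when the
    between-species mean square falls below the within-species one.
    """
    return vc.epi_fst


def min_epi_fst(n0: float) -> float:
    """Minimum attainable epi-FST, -1/(n0 - 1).

    This is the infimum of the statistic over configurations with
    MS_between = 0 and positive within-species variation; it increases
    monotonically with n0 and tends to 0 as n0 -> infinity.
    """
    if not n0 > 1:
        raise ValueError(f"n0 must exceed 1, got {n0}")
    return -1.0 / (n0 - 1.0)


def _exhaustive_assignments(N: int, sizes: np.ndarray) -> np.ndarray:
    """All distinct assignments of N samples to labelled groups of the given
    sizes, as an (M, N) array of sample indices in group-block order."""
    def rec(indices: tuple[int, ...], sizes: Sequence[int]):
        if len(sizes) == 1:
            yield indices
            return
        for head in combinations(indices, sizes[0]):
            rest = tuple(i for i in indices if i not in set(head))
            for tail in rec(rest, sizes[1:]):
                yield head + tail

    return np.array(list(rec(tuple(range(N)), list(sizes))), dtype=int)


def permutation_test(
    values: Sequence[float],
    species_labels: Sequence[str],
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    n0: float | None = None,
    exhaustive: bool = False,
    peak_id: str | None = None,
) -> PermutationResult:
    """Assess significance of one peak's epi-FST by permuting individuals
    between species (group sizes preserved).

    ``exhaustive=True`` enumerates every distinct assignment instead of
    sampling (only for small designs); the add-one correction is applied in
    both modes.
    """
    y = np.asarray(values, dtype=float)
    species, sizes, order = _group_layout(species_labels)
    _check_design(sizes, species)
    yb = y[order]  # group-blocked
    obs = float(_fst_rows(*_decompose_rows(yb[None, :], sizes)[:2], sizes, n0=n0)["epi_fst"][0])
    observed_defined = not math.isnan(obs)

    N = len(yb)
    if exhaustive:
        if N > _EXHAUSTIVE_MAX_N:
            raise ValidationError(
                f"exhaustive mode supports at most {_EXHAUSTIVE_MAX_N} samples, got {N}"
            )
        idx = _exhaustive_assignments(N, sizes)
    else:
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        idx = rng.permuted(np.tile(np.arange(N), (n_perm, 1)), axis=1)
    perm_fst = _fst_rows(*_decompose_rows(yb[idx], sizes)[:2], sizes, n0=n0)["epi_fst"]
    if observed_defined:
        r = int(np.nansum(perm_fst >= obs))  # NaN perms are not-as-extreme
        n_eff = len(idx)
        p = (r + 1) / (n_eff + 1)
    else:
        r, n_eff, p = 0, len(idx), 1.0
    return PermutationResult(
        peak_id=peak_id,
        observed_epi_fst=obs,
        n_permutations=n_eff,
        n_as_extreme=r,
        p_value=p,
        observed_defined=observed_defined,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# whole-matrix table


def aneva_table(
    pm: PeakMatrix,
    species: Iterable[str] | None = None,
    n_perm: int = 0,
    seed: int = 0,
    n0: float | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Variance components, epi-FST and (optionally) permutation p-values
    for every peak in a matrix.

    Parameters
    ----------
    species : restrict the analysis to these species' samples (e.g.
        ``["human", "chimp"]`` in a three-species matrix); default all.
    n_perm : number of label permutations per peak; 0 skips the test.
    seed : master seed; each peak gets an independent child stream.
    adjust : add a Benjamini-Hochberg ``p_adjusted`` column when permutation
        p-values are computed.
    """
    if species is not None:
        pm = pm.subset_species(species)
    labels = pm.species_labels()
    sp, sizes, order = _group_layout(labels)
    _check_design(sizes, sp)
    Y = pm.densities[:, order]

    ssb, ssw, gmean = _decompose_rows(Y, sizes)
    est = _fst_rows(ssb, ssw, sizes, n0=n0)
    out = pm.peaks.copy()
    out["ss_between"] = ssb
    out["ss_within"] = ssw
    out["df_between"] = est["df_between"]
    out["df_within"] = est["df_within"]
    out["ms_between"] = est["ms_between"]
    out["s2"] = est["s2"]
    out["n0"] = est["n0"]
    out["s2_alpha"] = est["s2_alpha"]
    out["epi_fst"] = est["epi_fst"]
    out["fst_defined"] = ~np.isnan(est["epi_fst"])
    out["grand_mean"] = Y.mean(axis=1)
    for i, s in enumerate(sp):
        out[f"mean_{s}"] = gmean[:, i]

    if n_perm > 0:
        children = np.random.SeedSequence(seed).spawn(pm.n_peaks)
        n_extreme = np.empty(pm.n_peaks, dtype=int)
        pvals = np.empty(pm.n_peaks)
        base = np.tile(np.arange(Y.shape[1]), (n_perm, 1))
        obs = est["epi_fst"]
        for i in range(pm.n_peaks):
            if math.isnan(obs[i]):
                n_extreme[i], pvals[i] = 0, 1.0
                continue
            rng = np.random.default_rng(children[i])
            idx = rng.permuted(base, axis=1)
            pf = _fst_rows(*_decompose_rows(Y[i][idx], sizes)[:2], sizes, n0=n0)["epi_fst"]
            r = int(np.nansum(pf >= obs[i]))
            n_extreme[i] = r
            pvals[i] = (r + 1) / (n_perm + 1)
        out["n_permutations"] = n_perm
        out["n_as_extreme"] = n_extreme
        out["p_value"] = pvals
        if adjust:
            out["p_adjusted"] = false_discovery_control(pvals, method="bh")
    return out


# ---------------------------------------------------------------------------
# model / results


class ANEVA:
    """Analysis of epigenetic variance: a one-way random-effects model of
    per-peak normalized densities with species as the grouping factor.

    Parameters
    ----------
    pm : PeakMatrix binding peak intervals, densities and sample species.
    species : optional subset of species to compare (others' samples are
        excluded from every computation).
    n0 : optional override of the effective sample size used in S2_alpha
        and hence in epi-FST.

    Examples
    --------
    >>> model = ANEVA.from_peak_matrix(pm, species=["human", "chimp"])
    >>> res = model.fit(n_perm=10_000, seed=42)
    >>> res.table[["peak_id", "epi_fst", "p_value"]].head()
    """

    def __init__(self, pm: PeakMatrix, species: Iterable[str] | None = None,
                 n0: float | None = None):
        if species is not None:
            pm = pm.subset_species(species)
        labels = pm.species_labels()
        sp, sizes, _ = _group_layout(labels)
        _check_design(sizes, sp)
        self.pm = pm
        self.species = sp
        self.species_sizes = dict(zip(sp, (int(n) for n in sizes)))
        self.n0_override = n0
        self.n0 = n0 if n0 is not None else effective_sample_size(sizes)

    @classmethod
    def from_peak_matrix(cls, pm: PeakMatrix, species: Iterable[str] | None = None,
                         n0: float | None = None) -> "ANEVA":
        return cls(pm, species=species, n0=n0)

    @classmethod
    def from_dataframe(cls, matrix: pd.DataFrame, metadata: pd.DataFrame,
                       species: Iterable[str] | None = None,
                       n0: float | None = None) -> "ANEVA":
        """Build from in-memory wide matrix and metadata DataFrames (same
        column contracts as the TSV files)."""
        meta = SampleMetadata(metadata)
        from .data import PEAK_FIXED_COLS
        dens = matrix[meta.sample_ids].to_numpy(dtype=float)
        pm = PeakMatrix(matrix[list(PEAK_FIXED_COLS)].copy(), dens, meta)
        return cls(pm, species=species, n0=n0)

    def fit(self, n_perm: int = 10_000, seed: int = 0, adjust: bool = True) -> "ANEVAResults":
        """Estimate per-peak variance components and epi-FST; with
        ``n_perm > 0`` also run the between-species label permutation test."""
        table = aneva_table(self.pm, n_perm=n_perm, seed=seed,
                            n0=self.n0_override, adjust=adjust)
        return ANEVAResults(self, table, n_perm=n_perm, seed=seed)


class ANEVAResults:
    """Fitted per-peak decomposition; one row per peak in :attr:`table`."""

    def __init__(self, model: ANEVA, table: pd.DataFrame, n_perm: int, seed: int):
        self.model = model
        self.table = table
        self.n_perm = n_perm
        self.seed = seed

    # -- aggregation -------------------------------------------------------

    def gene_scores(self, genes: pd.DataFrame, flank_bp: int = 50_000,
                    mode: str = "overlap") -> pd.DataFrame:
        """Per-gene mean epi-FST over peaks within the gene +/- ``flank_bp``."""
        from .genomic import assign_peaks_to_genes, gene_scores
        assignment = assign_peaks_to_genes(self.table, genes, flank_bp=flank_bp, mode=mode)
        return gene_scores(self.table, assignment, genes=genes)

    def within_species(self) -> pd.DataFrame:
        """Per-peak per-species SS and variance (SS_s / (n_s - 1))."""
        from .genomic import within_species_table
        return within_species_table(self.model.pm)

    def ss_correlation(self):
        """Spearman correlation between per-peak SS_within and SS_between."""
        from .association import ss_correlation
        return ss_correlation(self.table)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        t = self.table
        defined = t[t["fst_defined"]]
        lines = [
            "Analysis of epigenetic variance (one-way random effects)",
            "=" * 58,
            f"peaks: {len(t)}    samples: "
            + ", ".join(f"{s}={n}" for s, n in self.model.species_sizes.items()),
            f"effective sample size n0: {self.model.n0:.4f}"
            + ("  (override)" if self.model.n0_override is not None else ""),
            f"defined epi-FST: {len(defined)} / {len(t)}",
        ]
        if len(defined):
            q = defined["epi_fst"].quantile([0.25, 0.5, 0.75])
            lines += [
                f"epi-FST mean {defined['epi_fst'].mean():.4f}, "
                f"median {q.loc[0.5]:.4f}, IQR [{q.loc[0.25]:.4f}, {q.loc[0.75]:.4f}]",
                f"min attainable epi-FST at this n0: {min_epi_fst(self.model.n0):.4f}",
            ]
        if "p_value" in t.columns:
            lines.append(
                f"permutations/peak: {self.n_perm}; peaks with p < 0.05: "
                f"{int((t['p_value'] < 0.05).sum())}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return f"<ANEVAResults: {len(self.table)} peaks, {len(self.model.species)} species>"

    # -- plotting ----------------------------------------------------------

    def plot_ss(self, ax=None, log: bool = True):
        """Scatter of SS_within vs SS_between, coloured by epi-FST."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        sc = ax.scatter(t["ss_within"], t["ss_between"], c=t["epi_fst"],
                        s=6, cmap="YlOrRd")
        if log:
            ax.set_xscale("log"); ax.set_yscale("log")
        ax.set_xlabel("SS within species"); ax.set_ylabel("SS between species")
        ax.figure.colorbar(sc, ax=ax, label="epi-FST")
        return ax

    def plot_fst_hist(self, ax=None, bins: int = 50):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.table.loc[self.table["fst_defined"], "epi_fst"], bins=bins)
        ax.set_xlabel("epi-FST"); ax.set_ylabel("peaks")
        return ax
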