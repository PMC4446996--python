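"""Typed tables and TSV/BED input/output.

All genomic coordinates in this package are 0-based, half-open (BED
convention). Peak densities are normalized, dimensionless, non-negative
values; how they were normalized upstream is the user's responsibility and
is not recorded here.

File dialects
-------------
Peak matrix : TSV with columns ``peak_id chrom start end <sample1> ...``.
Metadata    : TSV with columns ``sample_id species``.
Genes       : BED3/BED6 (``chrom start end [name score strand]``).
TSS         : BED6 where ``start`` is the TSS coordinate (``end = start+1``),
              ``name`` is the gene id and ``score`` the transcript length
              (used to pick the longest-transcript TSS in "unique" mode).
SNP tracks  : ``chrom start end count`` (BED4 with an integer count).

Lines starting with ``#`` are comments in every dialect and are skipped on
read; the CLI writes parameter provenance into such headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SampleMetadata",
    "PeakMatrix",
    "read_sample_metadata",
    "read_peak_matrix",
    "write_peak_matrix",
    "read_bed",
    "read_genes_bed",
    "read_tss_bed",
    "read_interval_counts",
    "read_chrom_sizes",
    "write_bed",
    "write_results",
    "read_results",
]

PEAK_FIXED_COLS = ("peak_id", "chrom", "start", "end")
_UNKNOWN_STRAND = "."


class ValidationError(ValueError):
    """An input table violates a structural invariant; message names the offender."""


@dataclass(frozen=True)
class SampleMetadata:
    """Sample → species mapping.

    Parameters
    ----------
    table : DataFrame with columns ``sample_id`` and ``species``, one row
        per sample, sample_ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sample_id", "species"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata is missing columns: {sorted(missing)}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id in metadata: {dup.iloc[0]!r}")
        object.__setattr__(self, "table", self.table.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        return list(dict.fromkeys(self.table["species"]))

    def species_sizes(self) -> dict[str, int]:
        return dict(self.table["species"].value_counts(sort=False))

    def species_of(self) -> np.ndarray:
        """Species label per sample, aligned with :attr:`sample_ids`."""
        return self.table["species"].to_numpy()

    def subset(self, species: Iterable[str]) -> "SampleMetadata":
        wanted = list(species)
        known = set(self.table["species"])
        unknown = [s for s in wanted if s not in known]
        if unknown:
            raise ValidationError(f"unknown species label(s): {unknown}")
        return SampleMetadata(self.table[self.table["species"].isin(wanted)])


@dataclass
class PeakMatrix:
    """Peak intervals plus one normalized density value per sample per peak.

    Attributes
    ----------
    peaks : DataFrame with columns ``peak_id chrom start end``, sorted by
        (chrom, start), peak_ids unique, 0 <= start < end.
    densities : float array of shape (n_peaks, n_samples), non-negative, no
        missing values; column order is bound to ``metadata.sample_ids``.
    metadata : SampleMetadata
    """

    peaks: pd.DataFrame
    densities: np.ndarray
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        missing = set(PEAK_FIXED_COLS) - set(self.peaks.columns)
        if missing:
            raise ValidationError(f"peak table is missing columns: {sorted(missing)}")
        if self.densities.ndim != 2 or self.densities.shape[0] != len(self.peaks):
            raise ValidationError(
                f"density matrix shape {self.densities.shape} does not match "
                f"{len(self.peaks)} peaks"
            )
        if self.densities.shape[1] != len(self.metadata.sample_ids):
            raise ValidationError(
                f"density matrix has {self.densities.shape[1]} columns but metadata "
                f"lists {len(self.metadata.sample_ids)} samples"
            )
        dup = self.peaks["peak_id"][self.peaks["peak_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate peak_id: {dup.iloc[0]!r}")
        bad = self.peaks.index[
            (self.peaks["start"] < 0) | (self.peaks["start"] >= self.peaks["end"])
        ]
        if len(bad):
            row = self.peaks.loc[bad[0]]
            raise ValidationError(
                f"peak {row['peak_id']!r}: invalid interval [{row['start']}, {row['end']})"
            )
        if np.isnan(self.densities).any():
            i, j = np.argwhere(np.isnan(self.densities))[0]
            raise ValidationError(
                f"missing density for peak {self.peaks['peak_id'].iloc[i]!r}, "
                f"sample {self.metadata.sample_ids[j]!r}"
            )
        if (self.densities < 0).any():
            i, j = np.argwhere(self.densities < 0)[0]
            raise ValidationError(
                f"negative density for peak {self.peaks['peak_id'].iloc[i]!r}, "
                f"sample {self.metadata.sample_ids[j]!r}"
            )
        order = np.lexsort((self.peaks["start"].to_numpy(), self.peaks["chrom"].to_numpy()))
        self.peaks = self.peaks.iloc[order].reset_index(drop=True)
        self.densities = self.densities[order]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def sample_ids(self) -> list[str]:
        return self.metadata.sample_ids

    @property
    def peak_ids(self) -> pd.Series:
        return self.peaks["peak_id"]

    def species_labels(self) -> np.ndarray:
        return self.metadata.species_of()

    def subset_species(self, species: Iterable[str]) -> "PeakMatrix":
        """Restrict to the samples of the given species (peaks unchanged)."""
        meta = self.metadata.subset(species)
        cols = [self.sample_ids.index(s) for s in meta.sample_ids]
        return PeakMatrix(self.peaks.copy(), self.densities[:, cols], meta)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: fixed columns then one density column per sample."""
        out = self.peaks.copy()
        for j, sid in enumerate(self.sample_ids):
            out[sid] = self.densities[:, j]
        return out


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path, dtype={"sample_id": str, "species": str}))


def read_peak_matrix(matrix_path: str | Path, metadata_path: str | Path) -> PeakMatrix:
    """Read a peak-density matrix TSV together with its sample metadata.

    Raises
    ------
    ValidationError
        If a sample column is missing from either file, a peak_id is
        duplicated, a density is negative/missing, or an interval is empty;
        the message names the offending row or column.
    """
    meta = read_sample_metadata(metadata_path)
    df = _read_tsv(matrix_path, dtype={"peak_id": str, "chrom": str})
    missing = set(PEAK_FIXED_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"peak matrix is missing columns: {sorted(missing)}")
    matrix_samples = [c for c in df.columns if c not in PEAK_FIXED_COLS]
    extra = set(matrix_samples) - set(meta.sample_ids)
    if extra:
        raise ValidationError(
            f"matrix sample column(s) absent from metadata: {sorted(extra)}"
        )
    absent = set(meta.sample_ids) - set(matrix_samples)
    if absent:
        raise ValidationError(f"metadata sample(s) absent from matrix: {sorted(absent)}")
    dens = df[meta.sample_ids].to_numpy(dtype=float)
    return PeakMatrix(df[list(PEAK_FIXED_COLS)].copy(), dens, meta)


def write_peak_matrix(
    pm: PeakMatrix,
    matrix_path: str | Path,
    metadata_path: str | Path | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    write_results(pm.to_frame(), matrix_path, header_comments=header_comments,
                  float_format="%.10g")
    if metadata_path is not None:
        write_results(pm.metadata.table, metadata_path)


def _bed_rows(path: str | Path, min_fields: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ValidationError(
                    f"{path}, line {lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValidationError(
                    f"{path}, line {lineno}: malformed coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from None
            if start < 0 or end < start:
                raise ValidationError(
                    f"{path}, line {lineno}: invalid interval [{start}, {end})"
                )
            yield lineno, fields, start, end


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read gene intervals (BED3/BED6) into a GeneTable DataFrame.

    Columns: ``gene_id chrom start end strand``; strand is ``.`` when the
    BED file has no strand column. Unnamed records get positional ids.
    """
    recs = []
    for lineno, fields, start, end in _bed_rows(path, 3):
        if start >= end:
            raise ValidationError(f"{path}, line {lineno}: empty gene interval")
        gene_id = fields[3] if len(fields) > 3 and fields[3] else f"gene_{lineno}"
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else _UNKNOWN_STRAND
        recs.append((gene_id, fields[0], start, end, strand))
    df = pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "strand"])
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    return df


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read TSS positions (BED; start = TSS coordinate).

    Columns: ``gene_id chrom position transcript_length strand``. The BED
    score column, when numeric, is taken as the transcript length so the
    longest-transcript ("unique") TSS per gene can be selected; otherwise 0.
    A gene may have several TSS rows.
    """
    recs = []
    for lineno, fields, start, _end in _bed_rows(path, 3):
        gene_id = fields[3] if len(fields) > 3 and fields[3] else f"tss_{lineno}"
        try:
            length = float(fields[4]) if len(fields) > 4 else 0.0
        except ValueError:
            length = 0.0
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else _UNKNOWN_STRAND
        recs.append((gene_id, fields[0], start, length, strand))
    return pd.DataFrame(
        recs, columns=["gene_id", "chrom", "position", "transcript_length", "strand"]
    )


def read_interval_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-interval count track (``chrom start end count``).

    Within one track, intervals on a chromosome must not overlap.
    """
    recs = []
    for lineno, fields, start, end in _bed_rows(path, 4):
        try:
            count = int(float(fields[3]))
        except ValueError:
            raise ValidationError(
                f"{path}, line {lineno}: malformed count {fields[3]!r}"
            ) from None
        if count < 0:
            raise ValidationError(f"{path}, line {lineno}: negative count {count}")
        recs.append((fields[0], start, end, count))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "count"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    overlap = same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])
    if overlap.any():
        i = int(np.argmax(overlap)) + 1
        raise ValidationError(
            f"{path}: overlapping intervals on {df['chrom'].iloc[i]} near "
            f"position {df['start'].iloc[i]}"
        )
    return df


_BED_KINDS = {
    "genes": read_genes_bed,
    "tss": read_tss_bed,
    "counts": read_interval_counts,
}


def read_bed(path: str | Path, kind: str = "genes") -> pd.DataFrame:
    """Dispatching BED reader; ``kind`` is one of genes/tss/counts."""
    try:
        return _BED_KINDS[kind](path)
    except KeyError:
        raise ValueError(f"unknown BED kind {kind!r}; expected {sorted(_BED_KINDS)}") from None


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read ``chrom<TAB>length`` into an ordered mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_bed(df: pd.DataFrame, path: str | Path, kind: str = "genes") -> None:
    """Write a GeneTable / TssTable / count track back to BED."""
    with open(path, "w") as fh:
        if kind == "genes":
            for r in df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")
        elif kind == "tss":
            for r in df.itertuples(index=False):
                fh.write(
                    f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.gene_id}\t"
                    f"{r.transcript_length:g}\t{r.strand}\n"
                )
        elif kind == "counts":
            for r in df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.count}\n")
        else:
            raise ValueError(f"unknown BED kind {kind!r}")


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    float_format: str = "%.6g",
    header_comments: Sequence[str] = (),
) -> None:
    """Write a result table as TSV: header row, fixed float precision,
    deterministic row order (rows written as given), optional ``#`` comment
    header lines."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return _read_tsv(path)
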