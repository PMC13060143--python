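"""Shared interval/sequence data model, file I/O and count normalization.

Coordinates are 0-based half-open (BED convention) everywhere. Abutting
half-open intervals overlap by 0 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "FragmentSet",
    "CountMatrix",
    "read_intervals",
    "write_intervals",
    "overlap_width",
    "cpm_normalize",
    "tmm_norm_factors",
    "BedParseError",
]


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end (0-based half-open)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_width(a: GenomicInterval, b: GenomicInterval) -> int:
    """Width in bp of the overlap between two intervals.

    Returns 0 for intervals on different chromosomes and for abutting
    half-open intervals.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read intervals from a BED file (>=3 tab-separated columns).

    Column 6, when present, is interpreted as strand. Lines starting with
    ``#``, ``track`` or ``browser`` are skipped. Order is preserved.
    """
    if format != "bed":
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 6-column BED (name '.', score 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


@dataclass
class FragmentSet:
    """A collection of genomic fragments with sample/replicate labels.

    Backed by a DataFrame with columns ``chrom, start, end, sample,
    replicate``. Library size per sample equals its record count.
    """

    frame: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "sample", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"FragmentSet frame missing columns: {missing}")
        if len(self.frame) and (self.frame["end"] <= self.frame["start"]).any():
            raise ValueError("fragments must have end > start")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[GenomicInterval, str, str]]
    ) -> "FragmentSet":
        rows = [
            (iv.chrom, iv.start, iv.end, sample, rep) for iv, sample, rep in records
        ]
        return cls(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "replicate"])
        )

    @classmethod
    def from_bed(
        cls, path: str | Path, sample: str, replicate: str = "rep1"
    ) -> "FragmentSet":
        """Read one fragment per BED line, all tagged with one sample id."""
        ivs = read_intervals(path)
        return cls.from_records((iv, sample, replicate) for iv in ivs)

    @classmethod
    def concat(cls, parts: Sequence["FragmentSet"]) -> "FragmentSet":
        if not parts:
            return cls(
                pd.DataFrame(columns=["chrom", "start", "end", "sample", "replicate"])
            )
        return cls(pd.concat([p.frame for p in parts], ignore_index=True))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.frame.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")

    @property
    def samples(self) -> list[str]:
        return sorted(self.frame["sample"].unique().tolist())

    @property
    def library_sizes(self) -> pd.Series:
        """Record count per sample."""
        return self.frame.groupby("sample").size()

    @property
    def lengths(self) -> pd.Series:
        return self.frame["end"] - self.frame["start"]

    def subset(self, samples: Iterable[str]) -> "FragmentSet":
        keep = set(samples)
        return FragmentSet(self.frame[self.frame["sample"].isin(keep)].copy())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CountMatrix:
    """Integer counts of fragments in intervals (rows) per sample (columns).

    ``library_sizes`` defaults to column sums when not supplied; supply the
    originating FragmentSet sizes when counts cover only part of the library.
    ``norm_factors`` are multiplicative composition corrections (TMM), all 1
    until computed.
    """

    intervals: list[GenomicInterval]
    values: pd.DataFrame
    library_sizes: pd.Series | None = None
    norm_factors: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.values):
            raise ValueError("row count mismatch between intervals and values")
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.values = self.values.astype(np.int64)
        if self.library_sizes is None:
            self.library_sizes = self.values.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=float).reindex(
                self.values.columns
            )
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes missing for some columns")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.values.columns)
        if (self.norm_factors <= 0).any():
            raise ValueError("norm_factors must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def effective_sizes(self) -> pd.Series:
        """Library sizes scaled by composition norm factors."""
        return self.library_sizes * self.norm_factors

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
            }
        )
        df = pd.concat([df, self.values.reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", index=False)


def cpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Counts-per-million using per-column library sizes.

    value = count * 1e6 / library_size.
    """
    libs = counts.library_sizes
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero or negative library size for columns: {bad}")
    return counts.values / libs * 1e6


def _uq(col: np.ndarray, lib: float) -> float:
    pos = col[col > 0]
    if pos.size == 0:
        return 0.0
    return float(np.quantile(pos, 0.75)) / lib


def tmm_norm_factors(
    bin_counts: CountMatrix,
    reference: str | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values composition scaling factors.

    One factor per column, geometric mean 1. Trims 30% of M-values and 5%
    of A-values on each side; precision-weighted mean of surviving M-values.
    The reference column is the one whose upper-quartile count fraction is
    closest to the mean upper quartile (unless named explicitly).

    Raises on columns with all-zero bins.
    """
    values = bin_counts.values
    if values.shape[1] < 2:
        raise ValueError("TMM requires >=2 columns")
    arr = values.to_numpy(dtype=float)
    libs = arr.sum(axis=0)
    if (libs <= 0).any():
        bad = [c for c, l in zip(values.columns, libs) if l <= 0]
        raise ValueError(f"all-zero columns: {bad}")

    if reference is None:
        uqs = np.array([_uq(arr[:, j], libs[j]) for j in range(arr.shape[1])])
        ref_idx = int(np.argmin(np.abs(uqs - uqs.mean())))
    else:
        ref_idx = list(values.columns).index(reference)

    ref = arr[:, ref_idx]
    nref = libs[ref_idx]
    log_factors = np.zeros(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_idx:
            continue
        obs = arr[:, j]
        nobs = libs[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() == 0:
            continue
        o, r = obs[ok], ref[ok]
        m = np.log2((o / nobs) / (r / nref))
        a = 0.5 * np.log2((o / nobs) * (r / nref))
        # asymptotic delta-method variance of M
        w = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
        if np.max(np.abs(m)) < 1e-10:
            continue
        n = len(m)
        m_lo, m_hi = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
        a_lo, a_hi = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
        m_rank = pd.Series(m).rank().to_numpy()
        a_rank = pd.Series(a).rank().to_numpy()
        keep = (m_rank >= m_lo) & (m_rank <= m_hi) & (a_rank >= a_lo) & (a_rank <= a_hi)
        if keep.sum() == 0:
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors /= math.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns)
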