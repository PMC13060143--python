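"""Contact-matrix operations: ICE balancing, O/E normalization, aggregate
loop quantification (APA), differential maps, and coarsening.

Matrices are dense symmetric count arrays over a captured locus with a bin
resolution and genomic offset; masked bins carry NaN balancing weights.
File format is text COO (bin_i, bin_j, count) with a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "AnchorPair",
    "ice_balance",
    "observed_expected",
    "apa",
    "apa_ratio",
    "differential_map",
    "coarsen",
]


@dataclass(frozen=True)
class AnchorPair:
    """A prespecified loop anchor pixel (bin_i <= bin_j)."""

    bin_i: int
    bin_j: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.bin_i > self.bin_j:
            object.__setattr__(self, "bin_i", self.bin_j)
            object.__setattr__(self, "bin_j", self.bin_i)


@dataclass
class ContactMatrix:
    """Binned symmetric contact counts for one captured locus."""

    counts: np.ndarray
    resolution: int
    chrom: str = "chr1"
    start: int = 0
    weights: np.ndarray | None = None  # NaN = masked bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def balanced(self) -> np.ndarray:
        """w_i * w_j * counts with NaN at masked bins (requires balancing)."""
        if self.weights is None:
            raise ValueError("matrix not balanced; call ice_balance first")
        w = self.weights
        return self.counts * w[:, None] * w[None, :]

    def to_coo_text(self, path: str | Path) -> None:
        path = Path(path)
        i, j = np.nonzero(np.triu(self.counts))
        with open(path, "w") as fh:
            fh.write("bin_i\tbin_j\tcount\n")
            for a, b in zip(i, j):
                fh.write(f"{a}\t{b}\t{self.counts[a, b]:.10g}\n")
        sidecar = {
            "n_bins": self.n_bins,
            "resolution": self.resolution,
            "chrom": self.chrom,
            "start": self.start,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_coo_text(cls, path: str | Path) -> "ContactMatrix":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            meta = json.load(fh)
        df = pd.read_csv(path, sep="\t")
        m = np.zeros((meta["n_bins"], meta["n_bins"]))
        i = df["bin_i"].to_numpy(int)
        j = df["bin_j"].to_numpy(int)
        v = df["count"].to_numpy(float)
        m[i, j] = v
        m[j, i] = v
        return cls(m, meta["resolution"], meta["chrom"], meta["start"])


def ice_balance(
    matrix: ContactMatrix,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_count: int = 1,
) -> np.ndarray:
    """Iterative correction: find weights equalizing non-masked marginals.

    Bins whose raw marginal is below ``min_count`` are masked (NaN weight).
    Iterates w_i <- w_i / normalized_marginal_i until the coefficient of
    variation of non-masked balanced marginals drops below ``tol``.
    Weights are rescaled so the mean non-masked balanced marginal is 1.
    Stores the weights on the matrix and returns them.
    """
    m = matrix.counts
    marg = m.sum(axis=1)
    masked = marg < min_count
    w = np.ones(matrix.n_bins)
    w[masked] = np.nan
    active = ~masked
    if not active.any():
        raise ValueError("all bins masked")
    sub = m[np.ix_(active, active)]
    wa = np.ones(active.sum())
    converged = False
    cv = np.inf
    for _ in range(max_iter):
        b = (sub * wa[None, :]).sum(axis=1) * wa
        mean_b = b.mean()
        if mean_b <= 0:
            raise ValueError("degenerate matrix: zero total in active block")
        cv = b.std() / mean_b
        if cv < tol:
            converged = True
            break
        wa = wa / np.sqrt(np.maximum(b / mean_b, 1e-300))
    if not converged:
        # one final check after the last update
        b = (sub * wa[None, :]).sum(axis=1) * wa
        cv = b.std() / b.mean()
        if cv < tol:
            converged = True
    if not converged:
        warnings.warn(f"ICE did not converge: final marginal CV = {cv:.3g}")
    # rescale: mean non-masked balanced marginal = 1
    b = (sub * wa[None, :]).sum(axis=1) * wa
    wa = wa / np.sqrt(b.mean())
    w[active] = wa
    matrix.weights = w
    return w


def observed_expected(matrix: ContactMatrix) -> np.ndarray:
    """O/E of the balanced matrix: expected at distance d is the mean
    balanced value over non-masked pixels on that diagonal."""
    bal = matrix.balanced()
    n = matrix.n_bins
    oe = np.full_like(bal, np.nan)
    for d in range(n):
        diag = np.diagonal(bal, offset=d)
        ok = ~np.isnan(diag)
        if not ok.any():
            continue
        exp = diag[ok].mean()
        if exp <= 0:
            continue
        vals = diag / exp
        idx = np.arange(n - d)
        oe[idx, idx + d] = vals
        oe[idx + d, idx] = vals
    return oe


def apa(
    oe: np.ndarray,
    anchors: list[AnchorPair],
    flank: int = 2,
    low_confidence_masked_fraction: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean O/E in a (2*flank+1)^2 window centered on each anchor.

    Masked (NaN) pixels are excluded from means; windows with more than
    ``low_confidence_masked_fraction`` masked pixels are flagged. Returns
    (per-anchor table, aggregate stack = element-wise nanmean of windows).
    """
    n = oe.shape[0]
    rows = []
    stacks = []
    for a in anchors:
        if (
            a.bin_i - flank < 0
            or a.bin_j - flank < 0
            or a.bin_i + flank >= n
            or a.bin_j + flank >= n
        ):
            raise ValueError(
                f"APA window out of bounds for anchor ({a.bin_i}, {a.bin_j}) "
                f"with flank {flank} on a {n}-bin matrix"
            )
        win = oe[
            a.bin_i - flank : a.bin_i + flank + 1,
            a.bin_j - flank : a.bin_j + flank + 1,
        ]
        masked_frac = float(np.isnan(win).mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = float(np.nanmean(win))
        rows.append(
            {
                "bin_i": a.bin_i,
                "bin_j": a.bin_j,
                "label": a.label,
                "apa": mean,
                "masked_fraction": masked_frac,
                "low_confidence": masked_frac > low_confidence_masked_fraction,
            }
        )
        stacks.append(win)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aggregate = np.nanmean(np.stack(stacks), axis=0) if stacks else np.zeros((0, 0))
    return pd.DataFrame(rows), aggregate


def apa_ratio(
    control_oe: np.ndarray,
    perturbed_oe: np.ndarray,
    anchors: list[AnchorPair],
    flank: int = 2,
) -> pd.DataFrame:
    """Per-anchor APA(control) / APA(perturbed)."""
    if control_oe.shape != perturbed_oe.shape:
        raise ValueError("matrices must share a bin grid")
    ctl, _ = apa(control_oe, anchors, flank)
    prt, _ = apa(perturbed_oe, anchors, flank)
    out = ctl[["bin_i", "bin_j", "label"]].copy()
    out["apa_control"] = ctl["apa"]
    out["apa_perturbed"] = prt["apa"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ctl["apa"].to_numpy() / prt["apa"].to_numpy()
    zero = prt["apa"].to_numpy() == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} anchors with zero perturbed APA -> masked ratio")
        ratio[zero] = np.nan
    out["ratio"] = ratio
    return out


def differential_map(
    a: ContactMatrix | np.ndarray,
    b: ContactMatrix | np.ndarray,
    pseudocount: float | None = None,
) -> np.ndarray:
    """Pixel-wise log2((A + eps) / (B + eps)) of balanced (or O/E) views.

    Default pseudocount: half the smallest positive value across both
    inputs. NaN where either side is masked.
    """
    av = a.balanced() if isinstance(a, ContactMatrix) else np.asarray(a, dtype=float)
    bv = b.balanced() if isinstance(b, ContactMatrix) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("matrices must share a bin grid")
    if pseudocount is None:
        pool = np.concatenate([av[~np.isnan(av)], bv[~np.isnan(bv)]])
        pos = pool[pool > 0]
        pseudocount = 0.5 * pos.min() if pos.size else 1.0
    return np.log2((av + pseudocount) / (bv + pseudocount))


def coarsen(matrix: ContactMatrix, factor: int, balance: bool = True) -> ContactMatrix:
    """Sum raw counts in factor x factor blocks; re-balance at the new
    resolution. A trailing partial block is kept."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = matrix.n_bins
    edges = np.arange(0, n, factor)
    tmp = np.add.reduceat(matrix.counts, edges, axis=0)
    coarse = np.add.reduceat(tmp, edges, axis=1)
    out = ContactMatrix(
        coarse, matrix.resolution * factor, matrix.chrom, matrix.start
    )
    if balance:
        try:
            ice_balance(out)
        except ValueError:
            logger.warning("coarsen: balancing failed at factor %d", factor)
    return out
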