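"""Sorted-bin CRISPR screen analysis.

Reads from high/low sorted bins are cropped to protospacers, counted
against the guide library, normalized with median-of-ratios size factors,
tested per guide with a negative-binomial model (hi vs lo), and
aggregated to element-level calls.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from regscreen import _nbglm

logger = logging.getLogger(__name__)

__all__ = [
    "read_reads",
    "extract_protospacers",
    "count_guides",
    "size_factors",
    "test_guides",
    "aggregate_elements",
]


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTQ (4-line records) or plain one-per-line text."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].startswith("@") and len(lines) % 4 == 0:
        return lines[1::4]
    return lines


def extract_protospacers(reads: list[str], crop: int = 20) -> list[str]:
    """Crop each read to its first ``crop`` bases; drop shorter reads."""
    out = [r[:crop] for r in reads if len(r) >= crop]
    dropped = len(reads) - len(out)
    if dropped:
        logger.info("extract_protospacers: dropped %d short reads", dropped)
    return out


def count_guides(
    protospacers: list[str],
    library: pd.DataFrame,
    policy: str = "exact",
) -> tuple[pd.Series, dict]:
    """Count protospacer reads per library guide.

    ``exact``: hash lookup. ``one-mismatch``: a read matching exactly one
    library guide at Hamming distance <= 1 counts there; reads matching
    two or more guides are discarded as ambiguous. Returns (counts indexed
    like the library with zero fill, totals dict); matched + ambiguous +
    unmatched always equals the number of reads.
    """
    if policy not in ("exact", "one-mismatch"):
        raise ValueError(f"unknown policy {policy!r}")
    guides = library["protospacer"].tolist()
    if len(set(guides)) != len(guides):
        raise ValueError("library protospacers must be unique")
    exact = {g: i for i, g in enumerate(guides)}
    counts = np.zeros(len(guides), dtype=np.int64)
    matched = ambiguous = unmatched = 0

    variant_map: dict[str, set[int]] | None = None
    if policy == "one-mismatch":
        variant_map = {}
        for i, g in enumerate(guides):
            for pos in range(len(g)):
                key = g[:pos] + "*" + g[pos + 1 :]
                variant_map.setdefault(key, set()).add(i)

    for read in protospacers:
        idx = exact.get(read)
        if idx is not None:
            hits = {idx}
        elif policy == "exact":
            hits = set()
        else:
            hits = set()
            for pos in range(len(read)):
                key = read[:pos] + "*" + read[pos + 1 :]
                hits |= variant_map.get(key, set())  # type: ignore[union-attr]
        if len(hits) == 1:
            counts[hits.pop()] += 1
            matched += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unmatched += 1
    totals = {
        "matched": matched,
        "ambiguous": ambiguous,
        "unmatched": unmatched,
        "total": len(protospacers),
    }
    return pd.Series(counts, index=library.index), totals


def size_factors(counts: pd.DataFrame, fallback_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Computed over guides with all-positive counts; if none exist, either
    raise (default) or fall back to a pseudo-reference using positive
    counts only.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        if not fallback_pseudo_reference:
            raise ValueError(
                "no guide has positive counts in all samples; "
                "set fallback_pseudo_reference=True to use a pseudo-reference"
            )
        with np.errstate(divide="ignore"):
            logs = np.where(arr > 0, np.log(arr), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        use = ~np.isnan(ref) & (ref > 0)
        factors = np.array(
            [
                np.median(arr[use & (arr[:, j] > 0), j] / ref[use & (arr[:, j] > 0)])
                for j in range(arr.shape[1])
            ]
        )
    else:
        sub = arr[allpos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("degenerate size factors")
    return pd.Series(factors, index=counts.columns)


def test_guides(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    library: pd.DataFrame | None = None,
    dispersion_prior_df: float = 20.0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-guide NB test of hi-vs-lo differential abundance.

    ``design`` has one row per counts column with columns ``sample,
    replicate, bin`` (bin in {hi, lo}). The model is a log-linear NB GLM
    with a bin effect plus replicate covariates when >=2 replicate pairs
    exist; dispersion is method-of-moments per guide shrunk toward an
    abundance trend; p-values are Wald on the bin coefficient, BH
    adjusted. Positive log2FC = enriched in the hi bin. All-zero guides
    get NA statistics.
    """
    design = design.set_index("sample").loc[list(counts.columns)].reset_index()
    bins = design["bin"].to_numpy()
    if not set(bins) <= {"hi", "lo"}:
        raise ValueError("bin labels must be 'hi' or 'lo'")
    if "hi" not in bins or "lo" not in bins:
        raise ValueError("need samples in both bins")

    sf = (
        factors.reindex(counts.columns)
        if factors is not None
        else size_factors(counts, fallback_pseudo_reference=True)
    )
    offsets = np.log(sf.to_numpy())

    y = counts.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    yk = y[nonzero]

    reps = design["replicate"].unique()
    x_cols = [np.ones(len(design)), (bins == "hi").astype(float)]
    names = ["intercept", "bin_hi"]
    if len(reps) >= 2:
        for r in reps[1:]:
            x_cols.append((design["replicate"] == r).to_numpy(dtype=float))
            names.append(f"rep_{r}")
    x = np.column_stack(x_cols)

    eff = sf.to_numpy()
    phi = _nbglm.estimate_dispersions(yk, eff, bins, prior_df=dispersion_prior_df)
    beta, cov = _nbglm.nb_glm_irls(yk, x, offsets, phi)
    resid_df = max(len(design) - x.shape[1], 1)
    pvals = _nbglm.wald_pvalues(
        beta, cov, index=1, df=resid_df + dispersion_prior_df
    )
    log2fc = beta[:, 1] / np.log(2.0)

    out = pd.DataFrame(
        {
            "guide": counts.index,
            "log2fc": np.nan,
            "pvalue": np.nan,
            "padj": np.nan,
        }
    ).set_index("guide")
    out.loc[counts.index[nonzero], "log2fc"] = log2fc
    out.loc[counts.index[nonzero], "pvalue"] = pvals
    out.loc[counts.index[nonzero], "padj"] = _nbglm.bh_adjust(pvals)
    if library is not None:
        out["region_id"] = library.set_index(library.index)["region_id"]
    out = out.reset_index()
    return out


def aggregate_elements(
    guide_results: pd.DataFrame,
    library: pd.DataFrame,
    sig_threshold: float = 0.05,
    min_sig_guides: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate guide-level results to element-level calls.

    An element is significant when at least ``min_sig_guides`` of its
    guides reach padj < ``sig_threshold``. NTC guides (region_id == 'NTC'
    or is_ntc) are summarized separately as the empirical null.
    """
    res = guide_results.copy()
    if "region_id" not in res.columns:
        lib = library.reset_index(drop=True)
        res = res.merge(
            lib[["protospacer", "region_id"]],
            left_on="guide",
            right_on="protospacer",
            how="left",
        )
    is_ntc = res["region_id"].astype(str) == "NTC"
    ntc = res[is_ntc]
    tested_ntc = ntc["pvalue"].notna()
    ntc_summary = {
        "n_guides": int(len(ntc)),
        "n_tested": int(tested_ntc.sum()),
        "n_significant": int((ntc["padj"] < sig_threshold).sum()),
        "false_positive_rate": float(
            (ntc["padj"] < sig_threshold).sum() / max(tested_ntc.sum(), 1)
        ),
        "mean_log2fc": float(ntc["log2fc"].mean()) if len(ntc) else float("nan"),
    }
    rows = []
    for rid, sub in res[~is_ntc].groupby("region_id", sort=True):
        tested = sub["pvalue"].notna()
        n_sig = int((sub["padj"] < sig_threshold).sum())
        rows.append(
            {
                "region_id": rid,
                "n_guides": int(tested.sum()),
                "n_significant": n_sig,
                "mean_log2fc": float(sub.loc[tested, "log2fc"].mean()),
                "median_log2fc": float(sub.loc[tested, "log2fc"].median()),
                "significant": n_sig >= min_sig_guides,
            }
        )
    cols = [
        "region_id",
        "n_guides",
        "n_significant",
        "mean_log2fc",
        "median_log2fc",
        "significant",
    ]
    return pd.DataFrame(rows, columns=cols), ntc_summary
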