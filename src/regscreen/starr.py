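"""Sliding-window STARR-seq activity calling.

Fragments are filtered by length, counted into fixed-width sliding windows
restricted to a union peak set, tested per window against input DNA with a
negative-binomial log-linear model, merged into regions, and combined into
region-level calls with a weighted-Holm order statistic and BH FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regscreen import _nbglm
from regscreen.core import CountMatrix, FragmentSet, GenomicInterval

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

__all__ = [
    "filter_fragments",
    "make_windows",
    "count_in_windows",
    "test_windows",
    "merge_windows",
    "combine_region_pvalues",
    "classify_regions",
    "run_starr_pipeline",
    "StarrParams",
]


@dataclass
class StarrParams:
    """Tuning knobs for the window pipeline (defaults follow the assay
    conventions: 150-800 bp fragments, 50/25 bp windows, 0 bp merge
    tolerance, 3,000 bp maximum merged width, >=3 significant windows)."""

    min_len: int = 150
    max_len: int = 800
    window: int = 50
    step: int = 25
    merge_tol: int = 0
    max_width: int = 3000
    min_sig_n: int = 3
    summit_weight: float = 4.0
    fdr: float = 0.05
    tmm_bin: int = 2500
    dispersion_prior_df: float = 20.0


def filter_fragments(
    fragments: FragmentSet, min_len: int = 150, max_len: int = 800
) -> FragmentSet:
    """Keep fragments with min_len <= length <= max_len (inclusive bounds)."""
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    lens = fragments.lengths
    keep = (lens >= min_len) & (lens <= max_len)
    kept = FragmentSet(fragments.frame[keep].copy())
    before = fragments.frame.groupby("sample").size()
    after = kept.frame.groupby("sample").size().reindex(before.index, fill_value=0)
    for s in before.index:
        logger.info("filter_fragments %s: %d/%d retained", s, after[s], before[s])
    return kept


def make_windows(
    peaks: list[GenomicInterval], width: int = 50, step: int = 25
) -> list[GenomicInterval]:
    """Tile fixed-width windows at the given stride, keeping those that
    overlap at least one peak by >=1 bp.

    Windows are anchored at multiples of ``step`` from coordinate 0 of each
    chromosome, so the tiling is independent of the peak set.
    """
    if width < step:
        raise ValueError("width must be >= step")
    starts_by_chrom: dict[str, set[int]] = {}
    for pk in peaks:
        # smallest anchored start with start + width > peak.start
        lo = step * math.ceil((pk.start - width + 1) / step)
        hi = step * math.floor((pk.end - 1) / step)  # largest start < peak.end
        s = starts_by_chrom.setdefault(pk.chrom, set())
        for start in range(max(lo, 0), hi + 1, step):
            s.add(start)
    out: list[GenomicInterval] = []
    for chrom in sorted(starts_by_chrom):
        for start in sorted(starts_by_chrom[chrom]):
            out.append(GenomicInterval(chrom, start, start + width))
    return out


def count_in_windows(
    fragments: FragmentSet, windows: list[GenomicInterval]
) -> CountMatrix:
    """Count fragments overlapping each window by >=1 bp, per sample.

    A fragment spanning several windows contributes to each of them.
    Library sizes are taken from the full fragment set (record counts).
    """
    samples = fragments.samples
    counts = np.zeros((len(windows), len(samples)), dtype=np.int64)
    # group window indices per chromosome; windows share a fixed width
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    widths = {len(w) for w in windows}
    frame = fragments.frame
    for chrom, idxs in by_chrom.items():
        idx_arr = np.array(idxs)
        starts = np.array([windows[i].start for i in idxs])
        order = np.argsort(starts)
        starts = starts[order]
        idx_arr = idx_arr[order]
        width = len(windows[idxs[0]])
        chrom_frags = frame[frame["chrom"] == chrom]
        for j, sample in enumerate(samples):
            sf = chrom_frags[chrom_frags["sample"] == sample]
            if not len(sf):
                continue
            fs = sf["start"].to_numpy()
            fe = sf["end"].to_numpy()
            # window overlaps fragment iff start > frag.start - width and
            # start < frag.end (half-open on both sides)
            lo = np.searchsorted(starts, fs - width, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            diff = np.zeros(len(starts) + 1, dtype=np.int64)
            np.add.at(diff, lo, 1)
            np.add.at(diff, hi, -1)
            counts[idx_arr, j] = np.cumsum(diff[:-1])
    values = pd.DataFrame(counts, columns=samples)
    libs = fragments.library_sizes.reindex(samples).astype(float)
    return CountMatrix(list(windows), values, library_sizes=libs)


def test_windows(
    counts: CountMatrix,
    design: dict[str, str],
    input_label: str = "input",
    norm_factors: pd.Series | None = None,
    dispersion_prior_df: float = 20.0,
) -> dict[str, pd.DataFrame]:
    """Per-window NB test of each subset's RNA against input DNA.

    ``design`` maps sample id -> group label; the group named
    ``input_label`` is the shared reference. Dispersions are estimated
    once across all samples (method of moments, shrunk toward an abundance
    trend) and each contrast is a likelihood-ratio test of a two-group NB
    log-linear model on the input + subset columns.

    Returns one DataFrame per subset with columns ``window_index, chrom,
    start, end, log2fc, pvalue, abundance``. All-zero windows are excluded
    (count logged).
    """
    samples = counts.samples
    missing = [s for s in samples if s not in design]
    if missing:
        raise ValueError(f"design missing samples: {missing}")
    groups = np.array([design[s] for s in samples])
    if input_label not in groups:
        raise ValueError(f"no samples labeled {input_label!r}")
    if (groups == input_label).sum() < 2:
        raise ValueError("need >=2 input replicates")
    if norm_factors is None:
        norm_factors = counts.norm_factors
    eff = (counts.library_sizes * norm_factors.reindex(samples)).to_numpy(dtype=float)

    y_all = counts.values.to_numpy(dtype=float)
    nonzero = y_all.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("test_windows: excluded %d all-zero windows", n_dropped)
    y = y_all[nonzero]
    kept_idx = np.flatnonzero(nonzero)

    phi = _nbglm.estimate_dispersions(y, eff, groups, prior_df=dispersion_prior_df)
    abundance = np.log2(y.sum(axis=1) / eff.sum() * 1e6 + 0.5)

    results: dict[str, pd.DataFrame] = {}
    for subset in sorted(set(groups) - {input_label}):
        cols = (groups == subset) | (groups == input_label)
        log2fc, pval = _nbglm.lrt_contrast(
            y[:, cols], eff[cols], (groups[cols] == subset), phi
        )
        results[subset] = pd.DataFrame(
            {
                "window_index": kept_idx,
                "chrom": [counts.intervals[i].chrom for i in kept_idx],
                "start": [counts.intervals[i].start for i in kept_idx],
                "end": [counts.intervals[i].end for i in kept_idx],
                "log2fc": log2fc,
                "pvalue": np.clip(pval, P_FLOOR, 1.0),
                "abundance": abundance,
            }
        )
    return results


def merge_windows(
    windows: list[GenomicInterval],
    tolerance: int = 0,
    max_width: int = 3000,
) -> list[list[int]]:
    """Chain windows whose gap is <= tolerance into clusters; split chains
    spanning more than ``max_width`` into the fewest sub-clusters of
    near-equal window counts, each spanning <= max_width.

    gap(a, b) = b.start - a.end for sorted windows; abutting windows
    (gap 0) merge at tolerance 0. Returns lists of indices into
    ``windows``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    order = sorted(
        range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start)
    )
    chains: list[list[int]] = []
    cur: list[int] = []
    cur_end = None
    cur_chrom = None
    for i in order:
        w = windows[i]
        if cur and w.chrom == cur_chrom and w.start - cur_end <= tolerance:
            cur.append(i)
            cur_end = max(cur_end, w.end)
        else:
            if cur:
                chains.append(cur)
            cur = [i]
            cur_end = w.end
            cur_chrom = w.chrom
    if cur:
        chains.append(cur)

    out: list[list[int]] = []
    for chain in chains:
        span = windows[chain[-1]].end - windows[chain[0]].start
        if span <= max_width:
            out.append(chain)
            continue
        k = math.ceil(span / max_width)
        while True:
            parts = [list(p) for p in np.array_split(np.array(chain), k)]
            spans = [
                windows[p[-1]].end - windows[p[0]].start for p in parts if len(p)
            ]
            if all(s <= max_width for s in spans) or k >= len(chain):
                break
            k += 1
        out.extend(p for p in parts if len(p))
    return out


def _weighted_holm(pvals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Holm step-down adjusted p-values (weights = alpha shares)."""
    p = np.asarray(pvals, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(p / w, kind="mergesort")
    rem = np.cumsum(w[order][::-1])[::-1]  # remaining weight incl. current
    adj_sorted = np.minimum(np.maximum.accumulate(p[order] * rem / w[order]), 1.0)
    adj = np.empty_like(p)
    adj[order] = adj_sorted
    return adj


def combine_region_pvalues(
    pvals: np.ndarray,
    log2fc: np.ndarray,
    weights: np.ndarray | None = None,
    min_sig_n: int = 3,
) -> tuple[float, float, int]:
    """Combine member-window p-values into one region-level p.

    The combined p is the k-th smallest weighted-Holm-adjusted member
    p-value with ``k = min(n, max(min_sig_n, ceil(0.4 n)))``, so a region
    is only as significant as its k-th best window. The representative
    log2FC comes from the best-test window (smallest adjusted p, ties
    broken toward larger \\|log2fc\\|).

    Returns ``(combined_p, rep_log2fc, rep_member_index)``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty cluster")
    fc = np.asarray(log2fc, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    adj = _weighted_holm(p, w)
    n = p.size
    k = min(n, max(min_sig_n, math.ceil(0.4 * n)))
    combined = float(np.sort(adj)[k - 1])
    best = min(range(n), key=lambda i: (adj[i], -abs(fc[i])))
    return max(combined, P_FLOOR), float(fc[best]), best


def classify_regions(regions: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """BH-adjust combined p-values and assign activity classes.

    active: FDR <= threshold and rep_log2fc > 0; repressive: FDR <=
    threshold and rep_log2fc < 0; otherwise not-significant.
    """
    out = regions.copy()
    out["fdr"] = _nbglm.bh_adjust(out["combined_p"].to_numpy())
    cls = np.where(
        (out["fdr"] <= fdr_threshold) & (out["rep_log2fc"] > 0),
        "active",
        np.where(
            (out["fdr"] <= fdr_threshold) & (out["rep_log2fc"] < 0),
            "repressive",
            "not-significant",
        ),
    )
    out["class"] = cls
    return out


def _summit_weights(abundance: np.ndarray, summit_weight: float) -> np.ndarray:
    w = np.ones(len(abundance))
    if len(abundance):
        w[int(np.argmax(abundance))] = summit_weight
    return w


def regions_from_window_stats(
    window_stats: pd.DataFrame,
    windows: list[GenomicInterval],
    clusters: list[list[int]],
    min_sig_n: int = 3,
    summit_weight: float = 4.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Combine per-window stats over precomputed clusters into region calls."""
    stats_by_window = window_stats.set_index("window_index")
    rows = []
    for cluster in clusters:
        members = [i for i in cluster if i in stats_by_window.index]
        if not members:
            continue
        sub = stats_by_window.loc[members]
        weights = _summit_weights(sub["abundance"].to_numpy(), summit_weight)
        combined, rep_fc, _ = combine_region_pvalues(
            sub["pvalue"].to_numpy(), sub["log2fc"].to_numpy(), weights, min_sig_n
        )
        rows.append(
            {
                "chrom": windows[members[0]].chrom,
                "start": min(windows[i].start for i in members),
                "end": max(windows[i].end for i in members),
                "combined_p": combined,
                "rep_log2fc": rep_fc,
                "n_windows": len(members),
            }
        )
    regions = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "combined_p", "rep_log2fc", "n_windows"],
    )
    return classify_regions(regions, fdr_threshold)


def run_starr_pipeline(
    fragments: FragmentSet,
    peaks: list[GenomicInterval],
    design: dict[str, str],
    input_label: str = "input",
    params: StarrParams | None = None,
    tmm: bool = True,
) -> dict:
    """End-to-end window pipeline: filter, window, count, test, merge,
    combine, classify.

    Returns a dict with ``windows``, ``window_stats`` (per subset),
    ``regions`` (per subset), ``activity`` (one row per region, per-subset
    log2fc/fdr/class columns — the input for the specificity projection)
    and a ``manifest`` of parameters and filter statistics.
    """
    params = params or StarrParams()
    before = fragments.library_sizes.to_dict()
    filtered = filter_fragments(fragments, params.min_len, params.max_len)
    after = filtered.library_sizes.to_dict()

    windows = make_windows(peaks, params.window, params.step)
    counts = count_in_windows(filtered, windows)

    norm_factors = None
    if tmm and len(counts.samples) >= 2:
        from regscreen.core import tmm_norm_factors

        bins = make_windows(peaks, params.tmm_bin, params.tmm_bin)
        bin_counts = count_in_windows(filtered, bins)
        try:
            norm_factors = tmm_norm_factors(bin_counts)
        except ValueError:
            logger.warning("TMM failed (all-zero column); using unit factors")
            norm_factors = None
    if norm_factors is None:
        norm_factors = pd.Series(1.0, index=counts.samples)

    window_stats = test_windows(
        counts,
        design,
        input_label=input_label,
        norm_factors=norm_factors,
        dispersion_prior_df=params.dispersion_prior_df,
    )
    clusters = merge_windows(windows, params.merge_tol, params.max_width)

    regions: dict[str, pd.DataFrame] = {}
    for subset, stats in window_stats.items():
        regions[subset] = regions_from_window_stats(
            stats,
            windows,
            clusters,
            min_sig_n=params.min_sig_n,
            summit_weight=params.summit_weight,
            fdr_threshold=params.fdr,
        )

    activity = None
    for subset, reg in regions.items():
        cols = reg[["chrom", "start", "end"]].copy()
        cols[f"log2fc_{subset}"] = reg["rep_log2fc"]
        cols[f"fdr_{subset}"] = reg["fdr"]
        cols[f"class_{subset}"] = reg["class"]
        activity = cols if activity is None else activity.merge(
            cols, on=["chrom", "start", "end"], how="outer"
        )
    if activity is not None:
        activity = activity.sort_values(["chrom", "start"]).reset_index(drop=True)
        activity.insert(
            0,
            "region_id",
            [f"{r.chrom}:{r.start}-{r.end}" for r in activity.itertuples()],
        )

    manifest = {
        "params": params.__dict__,
        "input_label": input_label,
        "design": design,
        "fragments_before_filter": {k: int(v) for k, v in before.items()},
        "fragments_after_filter": {k: int(v) for k, v in after.items()},
        "n_windows": len(windows),
        "n_regions": len(clusters),
        "norm_factors": {k: float(v) for k, v in norm_factors.items()},
        "upstream_filters": "MAPQ>=20 and PCR-duplicate removal are applied "
        "upstream of the fragment files this pipeline reads",
    }
    return {
        "windows": windows,
        "window_stats": window_stats,
        "regions": regions,
        "activity": activity,
        "manifest": manifest,
    }
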