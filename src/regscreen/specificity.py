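"""Star-coordinate subset-specificity projection and enrichment.

Each region's per-subset activity is converted to a weighted effect score
(|log2FC| x -log10 FDR), normalized to proportional shares, and projected
onto a radial plot where each subset owns an equally spaced spoke. Regions
near a spoke are subset-preferred; regions near the origin are shared.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from regscreen._nbglm import bh_adjust

logger = logging.getLogger(__name__)

FDR_FLOOR = 1e-300

__all__ = [
    "subset_angles",
    "weighted_scores",
    "normalize_shares",
    "star_project",
    "classify_regions",
    "motif_family_enrichment",
    "build_profiles",
]


def subset_angles(n_subsets: int) -> np.ndarray:
    """Equally spaced spoke angles: theta_i = 2*pi*i/n, i = 0..n-1."""
    return 2.0 * np.pi * np.arange(n_subsets) / n_subsets


def weighted_scores(
    activity: pd.DataFrame,
    subsets: list[str] | None = None,
    sig_filter: float = 0.01,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Per-region, per-subset raw weights w_i = |log2FC_i| * (-log10 FDR_i).

    Expects columns ``log2fc_<subset>`` and ``fdr_<subset>``. Regions with
    no subset at FDR < ``sig_filter`` are dropped. FDR values are floored
    at 1e-300 before the log. With ``positive_only`` repressive subsets
    (log2FC < 0) contribute zero weight.
    """
    if subsets is None:
        subsets = sorted(
            c.removeprefix("log2fc_") for c in activity.columns if c.startswith("log2fc_")
        )
    if not subsets:
        raise ValueError("no log2fc_<subset> columns found")
    fc = activity[[f"log2fc_{s}" for s in subsets]].to_numpy(dtype=float)
    fdr = activity[[f"fdr_{s}" for s in subsets]].to_numpy(dtype=float)
    fc = np.nan_to_num(fc, nan=0.0)
    fdr = np.where(np.isnan(fdr), 1.0, fdr)
    fdr = np.clip(fdr, FDR_FLOOR, 1.0)

    keep = (fdr < sig_filter).any(axis=1)
    w = np.abs(fc) * (-np.log10(fdr))
    if positive_only:
        w = np.where(fc > 0, w, 0.0)
    out = pd.DataFrame(w[keep], columns=subsets)
    if "region_id" in activity.columns:
        out.insert(0, "region_id", activity.loc[keep, "region_id"].to_numpy())
    else:
        out.insert(0, "region_id", activity.index[keep].astype(str))
    return out


def normalize_shares(weights: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw weights to shares summing to one per region.

    Regions whose weights are all zero are flagged degenerate and excluded
    (count logged) rather than mapped to the origin.
    """
    subsets = [c for c in weights.columns if c != "region_id"]
    w = weights[subsets].to_numpy(dtype=float)
    tot = w.sum(axis=1)
    keep = tot > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("normalize_shares: excluded %d all-zero-weight regions", n_dropped)
    shares = w[keep] / tot[keep, None]
    out = pd.DataFrame(shares, columns=subsets)
    out.insert(0, "region_id", weights.loc[keep, "region_id"].to_numpy())
    return out


def star_project(shares: np.ndarray, n_subsets: int | None = None) -> tuple:
    """Project share vectors to star coordinates.

    x = sum(s_i cos theta_i), y = sum(s_i sin theta_i), r = sqrt(x^2+y^2).
    Accepts one share vector or a (regions x subsets) matrix. Returns
    ``(x, y, r, angle)`` where angle = atan2(y, x).
    """
    s = np.atleast_2d(np.asarray(shares, dtype=float))
    n = n_subsets or s.shape[1]
    if s.shape[1] != n:
        raise ValueError("share vector length does not match n_subsets")
    theta = subset_angles(n)
    x = s @ np.cos(theta)
    y = s @ np.sin(theta)
    r = np.hypot(x, y)
    ang = np.arctan2(y, x)
    if np.ndim(shares) == 1:
        return float(x[0]), float(y[0]), float(r[0]), float(ang[0])
    return x, y, r, ang


def _circular_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % (2.0 * np.pi)
    return np.minimum(d, 2.0 * np.pi - d)


def classify_regions(
    profiles: pd.DataFrame,
    r_specific: float = 0.85,
    r_shared: float = 0.10,
    cap_specific: int = 2000,
    cap_shared: int = 5000,
) -> pd.DataFrame:
    """Label each profiled region subset-preferred, shared or intermediate.

    subset-preferred: r > r_specific, ranked within each dominant subset by
    angular proximity of (x, y) to that subset's spoke, capped at
    ``cap_specific`` per subset. shared: r < r_shared, closest-to-origin
    first, capped at ``cap_shared``. Everything else is intermediate.
    """
    if not (0 <= r_shared < r_specific <= 1):
        raise ValueError("need 0 <= r_shared < r_specific <= 1")
    subsets = [
        c.removeprefix("w_") for c in profiles.columns if c.startswith("w_")
    ]
    out = profiles.copy()
    theta = subset_angles(len(subsets))
    w = out[[f"w_{s}" for s in subsets]].to_numpy(dtype=float)
    dom_idx = np.argmax(w, axis=1)  # ties -> lowest subset index
    n_ties = int((np.sum(w == w[np.arange(len(w)), dom_idx][:, None], axis=1) > 1).sum())
    if n_ties:
        logger.info("classify_regions: %d dominant-subset ties -> lowest index", n_ties)
    out["dominant"] = [subsets[i] for i in dom_idx]
    ang_dev = _circular_diff(out["angle"].to_numpy(), theta[dom_idx])
    out["angular_deviation"] = ang_dev

    cls = np.full(len(out), "intermediate", dtype=object)
    r = out["r"].to_numpy(dtype=float)

    for si, s in enumerate(subsets):
        cand = np.flatnonzero((r > r_specific) & (dom_idx == si))
        ranked = cand[np.argsort(ang_dev[cand], kind="mergesort")][:cap_specific]
        cls[ranked] = "subset-preferred"

    shared_cand = np.flatnonzero(r < r_shared)
    shared_ranked = shared_cand[np.argsort(r[shared_cand], kind="mergesort")][:cap_shared]
    cls[shared_ranked] = "shared"

    out["class"] = cls
    return out


def motif_family_enrichment(
    selected: set[str] | list[str],
    background: set[str] | list[str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher-exact motif-family enrichment of a selected region set.

    ``annotations`` is a region x family binary table indexed by region id.
    Per family a 2x2 table (selected/background x hit/no-hit) yields a
    two-sided Fisher exact p and an odds ratio; when any cell is zero the
    OR uses the Haldane-Anscombe 0.5 correction. BH adjusts across
    families.
    """
    selected = set(selected)
    background = set(background)
    if not selected:
        raise ValueError("empty selected set")
    if selected & background:
        raise ValueError("selected and background sets must be disjoint")
    missing = (selected | background) - set(annotations.index)
    if missing:
        raise ValueError(f"annotations missing {len(missing)} regions")
    sel = annotations.loc[sorted(selected)]
    bg = annotations.loc[sorted(background)]
    rows = []
    for fam in annotations.columns:
        a = int(sel[fam].sum())
        b = len(sel) - a
        c = int(bg[fam].sum())
        d = len(bg) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(
            {"family": fam, "odds_ratio": orr, "pvalue": p, "a": a, "b": b, "c": c, "d": d}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def build_profiles(
    activity: pd.DataFrame,
    sig_filter: float = 0.01,
    positive_only: bool = False,
    r_specific: float = 0.85,
    r_shared: float = 0.10,
    cap_specific: int = 2000,
    cap_shared: int = 5000,
) -> pd.DataFrame:
    """Full projection: weights -> shares -> star coordinates -> classes.

    Returns one row per retained region with ``w_<subset>``, ``s_<subset>``,
    ``x, y, r, angle, dominant, angular_deviation, class`` columns.
    """
    weights = weighted_scores(activity, sig_filter=sig_filter, positive_only=positive_only)
    shares = normalize_shares(weights)
    subsets = [c for c in shares.columns if c != "region_id"]
    x, y, r, ang = star_project(shares[subsets].to_numpy(), len(subsets))

    prof = pd.DataFrame({"region_id": shares["region_id"]})
    w_aligned = weights.set_index("region_id").loc[shares["region_id"]]
    for s in subsets:
        prof[f"w_{s}"] = w_aligned[s].to_numpy()
    for s in subsets:
        prof[f"s_{s}"] = shares[s].to_numpy()
    prof["x"], prof["y"], prof["r"], prof["angle"] = x, y, r, ang
    return classify_regions(
        prof,
        r_specific=r_specific,
        r_shared=r_shared,
        cap_specific=cap_specific,
        cap_shared=cap_shared,
    )
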