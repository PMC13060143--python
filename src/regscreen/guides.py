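"""CRISPR tiling guide library design.

Enumerate 20-mer protospacers adjacent to NGG PAMs, filter on specificity
score and banned repeat strings, score by chromatin accessibility (CPM of
overlapping ATAC fragments), greedily select non-overlapping guides per
region, and generate GC-matched non-targeting controls (NTCs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from regscreen.core import FragmentSet, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "revcomp",
    "scan_pam_sites",
    "filter_candidates",
    "accessibility_score",
    "select_guides",
    "generate_ntc",
    "assemble_library",
    "design_library",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

PROTOSPACER_LEN = 20
DEFAULT_BANNED = ("GGGGG", "TTTT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def scan_pam_sites(sequence: str, region: GenomicInterval) -> pd.DataFrame:
    """All 20-mers immediately 5' of an NGG PAM, on either strand, whose
    20 bp genomic footprint lies inside ``region``.

    ``sequence`` is the full chromosome sequence; coordinates in the
    output are genomic (0-based half-open). A region with no PAM yields an
    empty frame (not an error).
    """
    seq = sequence.upper()
    rows = []
    # plus strand: protospacer [i, i+20), PAM NGG at [i+20, i+23)
    for i in range(region.start, min(region.end - PROTOSPACER_LEN, len(seq) - 23) + 1):
        if i + PROTOSPACER_LEN > region.end:
            break
        if seq[i + 21 : i + 23] == "GG":
            rows.append(
                (region.chrom, i, i + PROTOSPACER_LEN, "+", seq[i : i + PROTOSPACER_LEN])
            )
    # minus strand: genomic CCN at [j, j+3), protospacer footprint [j+3, j+23)
    for j in range(max(region.start - 3, 0), region.end - PROTOSPACER_LEN - 2):
        if j + 3 < region.start or j + 23 > region.end:
            continue
        if j + 23 > len(seq):
            break
        if seq[j : j + 2] == "CC":
            rows.append(
                (region.chrom, j + 3, j + 23, "-", revcomp(seq[j + 3 : j + 23]))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "protospacer"])


def filter_candidates(
    candidates: pd.DataFrame,
    min_specificity: float = 0.2,
    banned_substrings: tuple[str, ...] = DEFAULT_BANNED,
) -> pd.DataFrame:
    """Drop candidates with specificity < min_specificity (exactly 0.2 is
    kept) or any banned repeat string in the protospacer."""
    keep = candidates["specificity"] >= min_specificity
    for sub in banned_substrings:
        keep &= ~candidates["protospacer"].str.contains(sub, regex=False)
    return candidates[keep].reset_index(drop=True)


def accessibility_score(
    candidates: pd.DataFrame, fragments: FragmentSet
) -> np.ndarray:
    """Accessibility in CPM for each candidate's 20 bp footprint.

    Per subset (the fragment ``sample`` label): the mean over replicates of
    the CPM-sum of fragments overlapping the footprint by >=1 bp, where
    each (sample, replicate) pair is its own library for CPM. The final
    score is the maximum of the per-subset means.
    """
    n = len(candidates)
    if n == 0:
        return np.zeros(0)
    frame = fragments.frame
    per_subset: dict[str, np.ndarray] = {}
    for (sample, rep), sub in frame.groupby(["sample", "replicate"]):
        lib = len(sub)
        weight = 1e6 / lib
        vals = np.zeros(n)
        for chrom, csub in sub.groupby("chrom"):
            mask = (candidates["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            fs = np.sort(csub["start"].to_numpy())
            fe = np.sort(csub["end"].to_numpy())
            gs = candidates.loc[mask, "start"].to_numpy()
            ge = candidates.loc[mask, "end"].to_numpy()
            # fragments with start < guide.end minus fragments with end <= guide.start
            n_before_end = np.searchsorted(fs, ge, side="left")
            n_ended = np.searchsorted(fe, gs, side="right")
            vals[mask] = (n_before_end - n_ended) * weight
        per_subset.setdefault(sample, []).append(vals)  # type: ignore[arg-type]
    if not per_subset:
        return np.zeros(n)
    subset_means = np.stack(
        [np.mean(np.stack(reps), axis=0) for reps in per_subset.values()]
    )
    return subset_means.max(axis=0)


def select_guides(
    candidates: pd.DataFrame, cap: int = 10, max_overlap: int = 10
) -> pd.DataFrame:
    """Greedy non-overlapping selection within one region.

    Candidates are scanned in descending ``accessibility_cpm`` order (ties:
    smaller start, then lexicographic protospacer) and accepted only if
    their 20 bp footprint overlaps every previously accepted guide by at
    most ``max_overlap`` bp. Selection stops at ``cap`` guides;
    ``rank_in_peak`` records acceptance order (1-based).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    ranked = candidates.sort_values(
        ["accessibility_cpm", "start", "protospacer"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    accepted: list[int] = []
    spans: list[tuple[int, int]] = []
    for idx, row in ranked.iterrows():
        ok = all(
            min(row.end, e) - max(row.start, s) <= max_overlap for s, e in spans
        )
        if ok:
            accepted.append(idx)
            spans.append((row.start, row.end))
            if len(accepted) >= cap:
                break
    out = candidates.loc[accepted].reset_index(drop=True)
    out["rank_in_peak"] = np.arange(1, len(out) + 1)
    return out


def _genome_kmer_set(genome: str, k: int = PROTOSPACER_LEN) -> set[str]:
    seq = genome.upper()
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    kmers |= {revcomp(s) for s in kmers}
    return kmers


def _hamming1_hits(seq: str, kmers: set[str]) -> bool:
    if seq in kmers:
        return True
    for i, base in enumerate(seq):
        for alt in "ACGT":
            if alt != base and seq[:i] + alt + seq[i + 1 :] in kmers:
                return True
    return False


def generate_ntc(
    targeting: pd.DataFrame,
    fraction: float,
    genome: str,
    matching_policy: str = "one-mismatch",
    seed: int = 0,
    banned_substrings: tuple[str, ...] = DEFAULT_BANNED,
    max_attempts_per_guide: int = 1000,
) -> pd.DataFrame:
    """Generate GC-matched non-targeting control protospacers.

    The NTC count is ``fraction`` of the final library including NTCs:
    n = round(fraction * n_targeting / (1 - fraction)). GC matching is
    distribution-level: NTC GC counts are allocated proportionally to the
    targeting GC-count histogram (largest remainder). Candidates matching
    the genome under the policy (``exact`` or ``one-mismatch``, both
    strands) or containing banned substrings are rejected and redrawn.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if matching_policy not in ("exact", "one-mismatch"):
        raise ValueError(f"unknown matching policy {matching_policy!r}")
    rng = np.random.default_rng(seed)
    n_targeting = len(targeting)
    n_ntc = round(fraction * n_targeting / (1.0 - fraction))
    if n_ntc == 0:
        return pd.DataFrame(columns=["protospacer"])

    gc_counts = (
        targeting["protospacer"].str.count("G") + targeting["protospacer"].str.count("C")
    ).to_numpy()
    strata, freq = np.unique(gc_counts, return_counts=True)
    quota = _largest_remainder(freq / freq.sum(), n_ntc)

    kmers = _genome_kmer_set(genome)
    check = (
        (lambda s: s in kmers)
        if matching_policy == "exact"
        else (lambda s: _hamming1_hits(s, kmers))
    )

    out: list[str] = []
    seen: set[str] = set(targeting["protospacer"])
    for gc, want in zip(strata, quota):
        made = 0
        attempts = 0
        while made < want:
            attempts += 1
            if attempts > max_attempts_per_guide * max(want, 1):
                raise RuntimeError(
                    "NTC rejection rate too high; relax the matching policy "
                    "or banned-substring list"
                )
            proto = _random_kmer_with_gc(rng, int(gc))
            if proto in seen:
                continue
            if any(b in proto for b in banned_substrings):
                continue
            if check(proto):
                continue
            out.append(proto)
            seen.add(proto)
            made += 1
    df = pd.DataFrame({"protospacer": out})
    df["region_id"] = "NTC"
    df["is_ntc"] = True
    return df


def _largest_remainder(probs: np.ndarray, n: int) -> np.ndarray:
    raw = probs * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _random_kmer_with_gc(rng: np.random.Generator, gc: int) -> str:
    bases = np.empty(PROTOSPACER_LEN, dtype="<U1")
    pos = rng.permutation(PROTOSPACER_LEN)
    bases[pos[:gc]] = rng.choice(list("GC"), size=gc)
    bases[pos[gc:]] = rng.choice(list("AT"), size=PROTOSPACER_LEN - gc)
    return "".join(bases)


def assemble_library(selected: pd.DataFrame, ntc: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Combine per-region selections and NTCs into one library table.

    Duplicate protospacers across regions are deduplicated with a warning
    (the first region keeps the guide). Returns (table, summary).
    """
    if selected.empty or selected["region_id"].nunique() == 0:
        raise ValueError("no target regions with selected guides")
    sel = selected.copy()
    sel["is_ntc"] = False
    dup = sel.duplicated(subset="protospacer", keep="first")
    if dup.any():
        logger.warning("assemble_library: dropped %d duplicate protospacers", dup.sum())
        sel = sel[~dup]
    cols = [
        "region_id",
        "chrom",
        "start",
        "end",
        "strand",
        "protospacer",
        "specificity",
        "accessibility_cpm",
        "rank_in_peak",
        "is_ntc",
    ]
    ntc = ntc.copy()
    if "region_id" not in ntc.columns:
        ntc["region_id"] = "NTC"
    ntc["is_ntc"] = True
    for frame in (sel, ntc):
        for c in cols:
            if c not in frame.columns:
                frame[c] = np.nan
    table = pd.concat([sel[cols], ntc[cols]], ignore_index=True)
    table["is_ntc"] = table["is_ntc"].astype(bool)
    n_t = int((~table["is_ntc"]).sum())
    n_n = int(table["is_ntc"].sum())
    summary = {
        "n_targeting": n_t,
        "n_ntc": n_n,
        "n_total": n_t + n_n,
        "ntc_fraction": n_n / (n_t + n_n) if n_t + n_n else 0.0,
        "n_regions": int(selected["region_id"].nunique()),
    }
    return table, summary


def design_library(
    genome: str,
    regions: list[GenomicInterval],
    candidates: pd.DataFrame,
    fragments: FragmentSet | None = None,
    cap: int = 10,
    max_overlap: int = 10,
    min_specificity: float = 0.2,
    ntc_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Filter, score, select per region, add NTCs, and assemble.

    ``candidates`` must carry region_id, chrom, start, end, strand,
    protospacer and specificity columns; accessibility is computed from
    ``fragments`` when given, else taken from an existing
    ``accessibility_cpm`` column (zeros if absent).
    """
    filt = filter_candidates(candidates, min_specificity)
    if fragments is not None:
        filt = filt.copy()
        filt["accessibility_cpm"] = accessibility_score(filt, fragments)
    elif "accessibility_cpm" not in filt.columns:
        filt = filt.copy()
        filt["accessibility_cpm"] = 0.0
    parts = []
    for rid, sub in filt.groupby("region_id", sort=True):
        parts.append(select_guides(sub.reset_index(drop=True), cap, max_overlap))
    selected = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=list(filt.columns) + ["rank_in_peak"])
    )
    ntc = generate_ntc(selected, ntc_fraction, genome, seed=seed)
    return assemble_library(selected, ntc)
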