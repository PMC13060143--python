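"""Synthetic data generators with planted ground truth.

Every generator is reproducible under a fixed seed and emits its truth in
machine-readable form so downstream recovery tests need no re-derivation.
Noise models: Poisson for fragments and contacts, gamma-Poisson (negative
binomial) for screen counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from regscreen.core import FragmentSet, GenomicInterval
from regscreen.contacts import ContactMatrix
from regscreen.guides import scan_pam_sites

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_peaks",
    "simulate_activity_truth",
    "simulate_starr_experiment",
    "simulate_guide_candidates",
    "simulate_screen_counts",
    "simulate_contact_map",
    "simulate_contact_pair",
]

DEFAULT_SUBSETS = ("Th0", "Th1", "Th2", "Th17", "Treg")


@dataclass
class SimulationConfig:
    """Knobs for the STARR fragment simulator."""

    seed: int = 0
    subsets: tuple[str, ...] = DEFAULT_SUBSETS
    n_input_reps: int = 2
    n_output_reps: int = 2
    depth: int = 1_000_000  # fragments per sample
    contaminant_fraction: float = 0.0  # short (<140 bp) fragments in outputs
    dispersion: float = 0.05  # replicate-level gamma overdispersion
    frag_len_mean: float = 350.0
    frag_len_sd: float = 120.0
    contaminant_len_range: tuple[int, int] = (50, 139)

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random sequence with expected GC fraction ``gc``."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def simulate_peaks(
    genome_length: int,
    n_peaks: int,
    width: int = 500,
    min_gap: int = 500,
    chrom: str = "chr1",
    seed: int = 0,
) -> list[GenomicInterval]:
    """Evenly spaced-ish non-overlapping peaks with jittered positions."""
    rng = np.random.default_rng(seed)
    slot = genome_length // n_peaks
    if slot < width + min_gap:
        raise ValueError("genome too short for requested peaks")
    peaks = []
    for i in range(n_peaks):
        lo = i * slot
        start = int(lo + rng.integers(0, slot - width - min_gap + 1))
        peaks.append(GenomicInterval(chrom, start, start + width))
    return peaks


def simulate_activity_truth(
    peaks: list[GenomicInterval],
    subsets: tuple[str, ...] = DEFAULT_SUBSETS,
    proportions: dict[str, float] | None = None,
    active_multiplier: float = 4.0,
    repressive_multiplier: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each peak a class and per-subset activity multipliers.

    Classes: inactive (multiplier 1 everywhere), shared-active
    (``active_multiplier`` in all subsets), subset-specific (multiplier in
    exactly one subset), repressive (``repressive_multiplier`` in all).
    """
    props = proportions or {
        "inactive": 0.6,
        "shared-active": 0.15,
        "subset-specific": 0.2,
        "repressive": 0.05,
    }
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(list(props), size=len(peaks), p=list(props.values()))
    rows = []
    for i, (pk, cls) in enumerate(zip(peaks, classes)):
        mult = {s: 1.0 for s in subsets}
        specific_subset = ""
        if cls == "shared-active":
            mult = {s: active_multiplier for s in subsets}
        elif cls == "subset-specific":
            specific_subset = str(rng.choice(subsets))
            mult[specific_subset] = active_multiplier
        elif cls == "repressive":
            mult = {s: repressive_multiplier for s in subsets}
        row = {
            "region_id": f"peak{i}",
            "chrom": pk.chrom,
            "start": pk.start,
            "end": pk.end,
            "class": cls,
            "specific_subset": specific_subset,
        }
        row.update({f"mult_{s}": mult[s] for s in subsets})
        rows.append(row)
    return pd.DataFrame(rows)


def _draw_fragments(
    rng: np.random.Generator,
    peaks: list[GenomicInterval],
    per_peak_counts: np.ndarray,
    len_mean: float,
    len_sd: float,
    len_bounds: tuple[int, int],
) -> pd.DataFrame:
    chroms, starts, ends = [], [], []
    for pk, n in zip(peaks, per_peak_counts):
        if n == 0:
            continue
        lengths = rng.normal(len_mean, len_sd, size=n)
        lengths = np.clip(np.round(lengths), len_bounds[0], len_bounds[1]).astype(int)
        mid = rng.integers(pk.start, pk.end, size=n)
        s = np.maximum(mid - lengths // 2, 0)
        e = s + lengths
        chroms.extend([pk.chrom] * n)
        starts.extend(s.tolist())
        ends.extend(e.tolist())
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def simulate_starr_experiment(
    peaks: list[GenomicInterval],
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> FragmentSet:
    """Simulate input DNA and per-subset RNA output fragment libraries.

    Input fragments are uniform over peaks (rate proportional to width)
    with lengths from a 150-800 bp mode; output fragment rates are input
    rate x the planted multiplier, with per-peak counts Poisson at the
    configured depth (optionally gamma-overdispersed per replicate), plus
    a short-fragment (<140 bp) contaminant mode in outputs only.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if len(truth) != len(peaks):
        raise ValueError("truth must cover all peaks")
    widths = np.array([len(p) for p in peaks], dtype=float)
    input_p = widths / widths.sum()

    parts = []
    for rep in range(cfg.n_input_reps):
        counts = rng.poisson(cfg.depth * input_p)
        df = _draw_fragments(
            rng, peaks, counts, cfg.frag_len_mean, cfg.frag_len_sd, (150, 800)
        )
        df["sample"] = "input"
        df["replicate"] = f"rep{rep + 1}"
        parts.append(df)

    for subset in cfg.subsets:
        mult = truth[f"mult_{subset}"].to_numpy(dtype=float)
        rate = input_p * mult
        rate = rate / rate.sum()
        for rep in range(cfg.n_output_reps):
            n_main = int(round(cfg.depth * (1 - cfg.contaminant_fraction)))
            lam = n_main * rate
            if cfg.dispersion > 0:
                lam = lam * rng.gamma(1 / cfg.dispersion, cfg.dispersion, size=len(lam))
            counts = rng.poisson(lam)
            df = _draw_fragments(
                rng, peaks, counts, cfg.frag_len_mean, cfg.frag_len_sd, (150, 800)
            )
            if cfg.contaminant_fraction > 0:
                n_cont = int(round(cfg.depth * cfg.contaminant_fraction))
                cont_counts = rng.poisson(n_cont * rate)
                lo, hi = cfg.contaminant_len_range
                cont = _draw_fragments(
                    rng, peaks, cont_counts, (lo + hi) / 2, (hi - lo) / 4, (lo, hi)
                )
                df = pd.concat([df, cont], ignore_index=True)
            df["sample"] = f"{subset}_rna"
            df["replicate"] = f"rep{rep + 1}"
            parts.append(df)
    frame = pd.concat(parts, ignore_index=True)
    # sample column encodes subset; replicate kept separately
    frame["sample"] = frame["sample"] + "_" + frame["replicate"]
    return FragmentSet(frame)


def simulate_guide_candidates(
    sequence: str,
    regions: list[GenomicInterval],
    seed: int = 0,
    specificity_beta: tuple[float, float] = (5.0, 1.5),
) -> pd.DataFrame:
    """Enumerate PAM-adjacent 20-mers in each region and attach specificity
    scores drawn from a Beta distribution."""
    rng = np.random.default_rng(seed)
    parts = []
    for i, region in enumerate(regions):
        if region.end > len(sequence) or region.start < 0:
            raise ValueError(f"region {i} outside sequence bounds")
        cand = scan_pam_sites(sequence, region)
        cand["region_id"] = f"region{i}"
        parts.append(cand)
    out = pd.concat(parts, ignore_index=True)
    out["specificity"] = rng.beta(*specificity_beta, size=len(out))
    return out


def simulate_screen_counts(
    library: pd.DataFrame,
    planted_effects: pd.Series,
    depth: float = 500.0,
    dispersion: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
    bin_depth_ratio: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial hi/lo screen counts with planted per-guide effects.

    Expected hi/lo ratio per guide = 2**effect x ``bin_depth_ratio``. NTC
    guides must have effect 0. ``depth`` is the mean lo-bin reads per
    guide. Returns (counts guides x samples, design table).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    guides = library["protospacer"].tolist()
    effects = planted_effects.reindex(guides).fillna(0.0).to_numpy(dtype=float)
    # mild baseline abundance variation between guides
    base = rng.gamma(20.0, 1 / 20.0, size=len(guides))

    cols = {}
    design_rows = []
    for rep in range(1, n_replicates + 1):
        for bin_label, scale in (("lo", 1.0), ("hi", bin_depth_ratio)):
            mu = depth * base * scale * (2.0 ** (effects if bin_label == "hi" else 0.0))
            if dispersion > 0:
                lam = mu * rng.gamma(1 / dispersion, dispersion, size=len(mu))
            else:
                lam = mu
            name = f"{bin_label}_rep{rep}"
            cols[name] = rng.poisson(lam)
            design_rows.append({"sample": name, "replicate": f"rep{rep}", "bin": bin_label})
    counts = pd.DataFrame(cols, index=guides)
    return counts, pd.DataFrame(design_rows)


def _expected_contacts(
    nbins: int, decay_exponent: float, loops: list[tuple[int, int, float]]
) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(nbins), np.arange(nbins)))
    expected = (1.0 + d) ** (-decay_exponent)
    for i, j, enr in loops:
        if enr <= 0:
            raise ValueError("loop enrichment must be > 0")
        if not (0 <= i < nbins and 0 <= j < nbins):
            raise ValueError("loop coordinates outside matrix")
        if i > j:
            logger.info("symmetrizing loop spec (%d, %d)", i, j)
            i, j = j, i
        lo_i, hi_i = max(i - 1, 0), min(i + 2, nbins)
        lo_j, hi_j = max(j - 1, 0), min(j + 2, nbins)
        expected[lo_i:hi_i, lo_j:hi_j] *= enr
        expected[lo_j:hi_j, lo_i:hi_i] *= enr
    return expected


def simulate_contact_map(
    nbins: int,
    resolution: int = 500,
    decay_exponent: float = 1.0,
    loops: list[tuple[int, int, float]] | None = None,
    depth: float = 1e6,
    seed: int = 0,
    chrom: str = "chr1",
) -> ContactMatrix:
    """Distance-decay contact map with planted loops, Poisson sampled.

    Expected count at bin distance d is proportional to (1+d)**(-decay);
    loop pixels and their +/-1-bin neighborhood are multiplied by the loop
    enrichment before scaling the total to ``depth`` and Poisson sampling
    (symmetric output).
    """
    expected = _expected_contacts(nbins, decay_exponent, loops or [])
    expected *= depth / np.triu(expected).sum()
    rng = np.random.default_rng(seed)
    upper = rng.poisson(np.triu(expected))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(counts.astype(float), resolution, chrom)


def simulate_contact_pair(
    nbins: int,
    loops: list[tuple[int, int, float]],
    depletion: float,
    resolution: int = 500,
    decay_exponent: float = 1.0,
    depth: float = 1e6,
    seed: int = 0,
    flank: int = 2,
) -> tuple[ContactMatrix, ContactMatrix]:
    """A control map plus a perturbed partner whose loop-anchor windows
    (+/- ``flank`` bins) are scaled down by ``depletion``."""
    if depletion <= 0:
        raise ValueError("depletion must be > 0")
    expected = _expected_contacts(nbins, decay_exponent, loops)
    scale = depth / np.triu(expected).sum()
    expected_ctl = expected * scale
    expected_prt = expected_ctl.copy()
    for i, j, _ in loops:
        i, j = min(i, j), max(i, j)
        expected_prt[i - flank : i + flank + 1, j - flank : j + flank + 1] /= depletion
        expected_prt[j - flank : j + flank + 1, i - flank : i + flank + 1] /= depletion
    rng = np.random.default_rng(seed)
    maps = []
    for exp in (expected_ctl, expected_prt):
        upper = rng.poisson(np.triu(exp))
        counts = upper + np.triu(upper, 1).T
        maps.append(ContactMatrix(counts.astype(float), resolution))
    return maps[0], maps[1]
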