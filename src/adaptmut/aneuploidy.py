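"""Whole-chromosome duplication detection from windowed read coverage.

Random fixed-size windows are summarised per chromosome and each
chromosome's median window depth is compared against the median over all
other chromosomes; on a haploid background a duplication shows up as a
ratio near 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genomes import CoverageTrack

DEFAULT_BAND = (1.75, 2.25)


@dataclass(frozen=True)
class WindowCoverageSummary:
    strain_id: str
    window_means: dict[str, np.ndarray]
    window_size: int
    n_windows: int


@dataclass(frozen=True)
class DuplicationCall:
    strain_id: str
    chrom: str
    ratio: float
    duplicated: bool


def sample_windows(
    track: CoverageTrack,
    window_size: int = 10_000,
    n_windows: int = 500,
    seed: int = 0,
    *,
    min_windows_per_chrom: int = 20,
) -> WindowCoverageSummary:
    """Mean depth in random fixed-size windows.

    Windows are sampled uniformly over valid start positions, allocated to
    chromosomes proportionally to length with a floor of
    ``min_windows_per_chrom`` so short chromosomes stay callable.
    Chromosomes shorter than the window are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    eligible: dict[str, np.ndarray] = {}
    for chrom, depth in track.depth.items():
        depth = np.asarray(depth)
        if depth.size < window_size:
            warnings.warn(
                f"{chrom} shorter than window size {window_size}; excluded",
                stacklevel=2,
            )
            continue
        eligible[chrom] = depth
    if not eligible:
        raise ValueError("no chromosome is at least one window long")
    lengths = {c: d.size for c, d in eligible.items()}
    total_len = sum(lengths.values())
    floor_total = min_windows_per_chrom * len(eligible)
    if n_windows < floor_total:
        raise ValueError(
            f"n_windows={n_windows} cannot give every chromosome "
            f"{min_windows_per_chrom} windows"
        )
    # proportional allocation of the remainder, largest-remainder rounding
    spare = n_windows - floor_total
    shares = {c: spare * lengths[c] / total_len for c in eligible}
    alloc = {c: min_windows_per_chrom + int(shares[c]) for c in eligible}
    leftovers = sorted(
        eligible, key=lambda c: shares[c] - int(shares[c]), reverse=True
    )
    for c in leftovers[: n_windows - sum(alloc.values())]:
        alloc[c] += 1

    window_means: dict[str, np.ndarray] = {}
    for chrom, depth in eligible.items():
        csum = np.concatenate(([0], np.cumsum(depth, dtype=np.float64)))
        starts = rng.integers(0, depth.size - window_size + 1, size=alloc[chrom])
        window_means[chrom] = (
            csum[starts + window_size] - csum[starts]
        ) / window_size
    return WindowCoverageSummary(
        strain_id=track.strain_id,
        window_means=window_means,
        window_size=window_size,
        n_windows=int(sum(alloc.values())),
    )


def call_duplications(
    summary: WindowCoverageSummary,
    band: tuple[float, float] = DEFAULT_BAND,
) -> list[DuplicationCall]:
    """One duplication verdict per chromosome.

    The ratio is the chromosome's median window depth over the median window
    depth of all other chromosomes (medians are robust to focal outliers);
    a chromosome is duplicated when the ratio falls inside ``band``.
    """
    chroms = list(summary.window_means)
    if len(chroms) < 2:
        raise ValueError("duplication calling needs at least 2 chromosomes")
    calls = []
    for chrom in chroms:
        own = float(np.median(summary.window_means[chrom]))
        rest = np.concatenate(
            [summary.window_means[c] for c in chroms if c != chrom]
        )
        denom = float(np.median(rest))
        if denom == 0:
            raise ValueError(f"zero median coverage outside {chrom}")
        ratio = own / denom
        calls.append(
            DuplicationCall(
                strain_id=summary.strain_id,
                chrom=chrom,
                ratio=ratio,
                duplicated=band[0] <= ratio <= band[1],
            )
        )
    return calls
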