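"""Build the per-base accessibility mask from per-sample depth tracks.

A base is *accessible* when its summed mapping depth lies inside a band around
the modal genome-wide depth (peak +/- 50% by default) and at least half of the
samples have mapped reads there.  The accessible-base set is the denominator
for every per-base statistic downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import AccessibilityMask


@dataclass
class DepthProfile:
    """Per-contig summed depth and per-base count of samples with coverage."""

    total: dict[str, np.ndarray]  # summed depth across samples, int
    n_mapped: dict[str, np.ndarray]  # samples with >= 1 read
    n_samples: int

    def __post_init__(self) -> None:
        for ctg in self.total:
            t = np.asarray(self.total[ctg])
            m = np.asarray(self.n_mapped[ctg])
            if (t < 0).any():
                raise ValueError("negative depth")
            if (m > self.n_samples).any():
                raise ValueError("n_mapped exceeds panel size")

    def genome_length(self) -> int:
        return sum(len(v) for v in self.total.values())


@dataclass
class DepthThresholds:
    peak_depth: int
    lower: int
    upper: int
    min_samples: int

    def __post_init__(self) -> None:
        if not self.lower < self.peak_depth < self.upper:
            raise ValueError("thresholds must bracket the peak")


def read_depth_tsv(path, n_samples: int) -> DepthProfile:
    """Read a pre-summed depth track TSV: contig, pos (1-based), total, n_mapped."""
    df = pd.read_csv(
        path, sep="\t", names=["contig", "pos", "total", "n_mapped"], dtype={"contig": str}
    )
    total, n_mapped = {}, {}
    for ctg, sub in df.groupby("contig", sort=False):
        if not (np.diff(sub["pos"].to_numpy()) == 1).all() or sub["pos"].iloc[0] != 1:
            raise ValueError(f"depth track not contiguous from position 1 on {ctg}")
        total[ctg] = sub["total"].to_numpy(np.int64)
        n_mapped[ctg] = sub["n_mapped"].to_numpy(np.int64)
    return DepthProfile(total, n_mapped, n_samples)


def write_depth_tsv(profile: DepthProfile, path) -> None:
    with open(path, "w") as fh:
        for ctg in sorted(profile.total):
            t = profile.total[ctg]
            m = profile.n_mapped[ctg]
            for i in range(len(t)):
                fh.write(f"{ctg}\t{i + 1}\t{t[i]}\t{m[i]}\n")


def depth_histogram(profile: DepthProfile) -> np.ndarray:
    """Counts per integer total depth; sums to the genome length."""
    if profile.genome_length() == 0:
        raise ValueError("empty depth profile")
    top = max(int(v.max(initial=0)) for v in profile.total.values())
    hist = np.zeros(top + 1, dtype=np.int64)
    for v in profile.total.values():
        hist += np.bincount(v, minlength=top + 1)
    return hist


def detect_peak(hist: np.ndarray, smooth_window: int = 5) -> int:
    """Modal depth after moving-average smoothing; ties -> smaller depth."""
    hist = np.asarray(hist, dtype=float)
    if hist.sum() == 0:
        raise ValueError("all-zero depth histogram")
    w = max(1, int(smooth_window))
    kernel = np.ones(w)
    # normalize by the in-range window size so edges are not biased down
    sm = np.convolve(hist, kernel, mode="same") / np.convolve(
        np.ones_like(hist), kernel, mode="same"
    )
    return int(np.argmax(sm))  # argmax returns the first (smallest) on ties


def thresholds_from_peak(
    peak: int,
    frac: float = 0.5,
    n_samples: int | None = None,
    lower: int | None = None,
    upper: int | None = None,
    min_samples: int | None = None,
) -> DepthThresholds:
    """Depth band peak*(1 -/+ frac) (rounded) and the >=50%-of-samples rule.

    Explicit ``lower``/``upper``/``min_samples`` override the derived values,
    so any externally published band is reproducible exactly.
    """
    lo = int(round(peak * (1 - frac))) if lower is None else int(lower)
    hi = int(round(peak * (1 + frac))) if upper is None else int(upper)
    if min_samples is None:
        if n_samples is None:
            raise ValueError("need n_samples or explicit min_samples")
        min_samples = math.ceil(0.5 * n_samples)
    return DepthThresholds(int(peak), lo, hi, int(min_samples))


def build_mask(profile: DepthProfile, thr: DepthThresholds) -> AccessibilityMask:
    """Accessible iff lower <= total depth <= upper AND n_mapped >= min_samples."""
    flags = {}
    for ctg in profile.total:
        t = profile.total[ctg]
        m = profile.n_mapped[ctg]
        flags[ctg] = (t >= thr.lower) & (t <= thr.upper) & (m >= thr.min_samples)
    return AccessibilityMask.from_boolean(flags)
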