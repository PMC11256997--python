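"""Density-gradient fraction analysis for DNA stable-isotope probing.

A CsCl isopycnic gradient is collected as a series of fractions whose buoyant
density (BD) is close to linear in fraction number.  Comparing per-fraction
16S rRNA copy totals between the ¹³C treatment and the ¹²C control locates
the "heavy" window (where labelled DNA accumulates) and the "light" window
(the bulk unlabelled community).  The packaged default windows are
1.7042–1.7089 g/ml (light) and 1.7342–1.7411 g/ml (heavy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Fraction",
    "GradientRun",
    "FractionWindows",
    "WindowParams",
    "BdFit",
    "DEFAULT_WINDOWS",
    "fit_bd_vs_fraction",
    "identify_windows",
    "classify_fraction",
]

TREATMENTS = ("12C", "13C")


@dataclass(frozen=True)
class Fraction:
    """One collected gradient fraction."""

    treatment: str
    fraction_number: int
    buoyant_density: float  # g/ml
    copies_16s: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.fraction_number < 1:
            raise ValueError("fraction_number must be >= 1")
        if not (1.60 < self.buoyant_density < 1.85):
            raise ValueError(
                f"buoyant density {self.buoyant_density} g/ml outside plausible CsCl range"
            )
        if self.copies_16s < 0:
            raise ValueError("copies_16s must be non-negative")


@dataclass
class GradientRun:
    """One treatment's ordered collection of fractions (14 by default)."""

    treatment: str
    fractions: list[Fraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        numbers = [f.fraction_number for f in self.fractions]
        if len(numbers) != len(set(numbers)):
            raise ValueError("fraction numbers must be unique")
        if any(f.treatment != self.treatment for f in self.fractions):
            raise ValueError("fraction treatment labels disagree with run treatment")
        self.fractions = sorted(self.fractions, key=lambda f: f.fraction_number)

    @property
    def fraction_numbers(self) -> np.ndarray:
        return np.array([f.fraction_number for f in self.fractions])

    @property
    def buoyant_densities(self) -> np.ndarray:
        return np.array([f.buoyant_density for f in self.fractions])

    @property
    def copies(self) -> np.ndarray:
        return np.array([f.copies_16s for f in self.fractions])


@dataclass(frozen=True)
class FractionWindows:
    """Closed BD intervals delimiting light and heavy DNA fractions."""

    light_lo: float
    light_hi: float
    heavy_lo: float
    heavy_hi: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if not (self.light_lo < self.light_hi < self.heavy_lo < self.heavy_hi):
            raise ValueError(
                "windows must satisfy light_lo < light_hi < heavy_lo < heavy_hi; got "
                f"({self.light_lo}, {self.light_hi}, {self.heavy_lo}, {self.heavy_hi})"
            )

    def to_dict(self) -> dict:
        return {
            "light": [self.light_lo, self.light_hi],
            "heavy": [self.heavy_lo, self.heavy_hi],
            "fallback": self.fallback,
        }


#: Windows used by the study: light 1.7042–1.7089, heavy 1.7342–1.7411 g/ml.
DEFAULT_WINDOWS = FractionWindows(1.7042, 1.7089, 1.7342, 1.7411)


@dataclass(frozen=True)
class WindowParams:
    """Detection rule parameters for :func:`identify_windows`.

    ``bd_split`` separates the candidate heavy region from the light region;
    a fraction above the split qualifies as heavy when its total-normalised
    ¹³C copies exceed the ¹²C copies by ``ratio_min`` AND carry at least
    ``min_copy_frac`` of the ¹³C run's copies.  The copy floor exists only to
    reject near-zero/near-zero ratios at the very dense tail of the gradient
    where both treatments' copies vanish; it is deliberately small so the
    ratio criterion, not the floor, decides membership elsewhere.  The light
    window is grown around the ¹²C copy peak below the split down to
    ``light_rel_height`` of the peak.
    """

    bd_split: float = 1.72
    ratio_min: float = 1.5
    min_copy_frac: float = 0.001
    light_rel_height: float = 0.5


@dataclass(frozen=True)
class BdFit:
    slope: float
    intercept: float
    r: float
    degenerate: bool = False


def fit_bd_vs_fraction(run: GradientRun) -> BdFit:
    """Ordinary least squares of buoyant density on fraction number.

    Returns slope (g/ml per fraction), intercept, and Pearson r.  A constant-BD
    run has an undefined correlation and is flagged degenerate.
    """
    if len(run.fractions) < 3:
        raise ValueError("need at least 3 fractions to fit BD vs fraction number")
    x = run.fraction_numbers.astype(float)
    y = run.buoyant_densities
    if np.ptp(y) == 0.0:
        return BdFit(slope=0.0, intercept=float(y[0]), r=float("nan"), degenerate=True)
    res = stats.linregress(x, y)
    return BdFit(slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue))


def _contiguous_blocks(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal runs of True."""
    blocks = []
    start = None
    for i, ok in enumerate(mask):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            blocks.append((start, i))
            start = None
    if start is not None:
        blocks.append((start, len(mask)))
    return blocks


def identify_windows(
    run12: GradientRun,
    run13: GradientRun,
    params: WindowParams = WindowParams(),
) -> FractionWindows:
    """Detect light/heavy BD windows from the two treatments' copy profiles.

    Heavy: the BD span of the largest contiguous block of fractions above
    ``bd_split`` where normalised ¹³C copies exceed ¹²C copies per the rule in
    :class:`WindowParams` (largest = most fractions, ties broken by summed ¹³C
    copies).  Light: the BD span of the contiguous block around the ¹²C copy
    peak below the split.  If no qualifying heavy block exists (no labelling
    signal), the packaged reference windows are returned with ``fallback=True``.
    """
    if not run12.fractions or not run13.fractions:
        raise ValueError("both gradient runs must contain fractions")
    n12 = {f.fraction_number: f for f in run12.fractions}
    n13 = {f.fraction_number: f for f in run13.fractions}
    common = sorted(set(n12) & set(n13))
    if not common:
        raise ValueError("runs share no fraction numbers")

    bd = np.array([(n12[k].buoyant_density + n13[k].buoyant_density) / 2 for k in common])
    c12 = np.array([n12[k].copies_16s for k in common])
    c13 = np.array([n13[k].copies_16s for k in common])
    if c12.sum() == 0 or c13.sum() == 0:
        raise ValueError("a run has zero total 16S copies")
    c12 = c12 / c12.sum()  # normalise to each run's total recovery
    c13 = c13 / c13.sum()

    eps = 1e-12
    above = bd > params.bd_split
    qualifies = (
        above
        & ((c13 + eps) / (c12 + eps) >= params.ratio_min)
        & (c13 >= params.min_copy_frac)
    )
    blocks = _contiguous_blocks(qualifies)
    below = bd < params.bd_split
    if not blocks or not np.any(below):
        return FractionWindows(
            DEFAULT_WINDOWS.light_lo,
            DEFAULT_WINDOWS.light_hi,
            DEFAULT_WINDOWS.heavy_lo,
            DEFAULT_WINDOWS.heavy_hi,
            fallback=True,
        )
    # a fraction represents a BD bin, not a point: pad zero-width spans by half
    # the local inter-fraction spacing so single-fraction windows stay valid
    halfstep = float(np.median(np.abs(np.diff(bd))) / 2) if bd.size > 1 else 1e-4

    best = max(blocks, key=lambda b: (b[1] - b[0], c13[b[0] : b[1]].sum()))
    heavy_bd = bd[best[0] : best[1]]
    heavy_lo, heavy_hi = float(heavy_bd.min()), float(heavy_bd.max())
    if heavy_lo == heavy_hi:
        heavy_lo, heavy_hi = heavy_lo - halfstep, heavy_hi + halfstep

    below_idx = np.flatnonzero(below)
    peak = below_idx[int(np.argmax(c12[below_idx]))]
    floor = params.light_rel_height * c12[peak]
    lo = hi = peak
    while lo - 1 in below_idx and c12[lo - 1] >= floor:
        lo -= 1
    while hi + 1 in below_idx and c12[hi + 1] >= floor:
        hi += 1
    light_bd = bd[lo : hi + 1]
    light_lo, light_hi = float(light_bd.min()), float(light_bd.max())
    if light_lo == light_hi:
        light_lo, light_hi = light_lo - halfstep, light_hi + halfstep

    if not (light_lo < light_hi < heavy_lo < heavy_hi):
        # degenerate geometry (e.g. single-fraction windows touching): fall back
        return FractionWindows(
            DEFAULT_WINDOWS.light_lo,
            DEFAULT_WINDOWS.light_hi,
            DEFAULT_WINDOWS.heavy_lo,
            DEFAULT_WINDOWS.heavy_hi,
            fallback=True,
        )
    return FractionWindows(light_lo, light_hi, heavy_lo, heavy_hi)


def classify_fraction(
    bd: float, windows: FractionWindows
) -> Literal["light", "heavy", "neither"]:
    """Classify a buoyant density into light/heavy/neither (closed intervals)."""
    if windows.light_lo <= bd <= windows.light_hi:
        return "light"
    if windows.heavy_lo <= bd <= windows.heavy_hi:
        return "heavy"
    return "neither"
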