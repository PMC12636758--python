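"""Phosphate normalization, diagnostic band ratios, and WHO-group statistics.

Bone Raman analysis normalizes every spectrum to the phosphate nu1 peak
(~960 cm^-1) and tracks five diagnostic ratios — four mineral-to-matrix
ratios (PO4/CO3, PO4/Amide III, PO4/CH2, PO4/Amide I) and the carbonate
substitution contrast CO3/Amide III.  Band quantities default to the
baseline-chord-corrected peak height inside a +-20 cm^-1 window; trapezoidal
band area above the same chord is available.  Group differences use a
two-sided Mann-Whitney U test (Welch's t optional) with Bonferroni
correction across the three pairwise WHO comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import WHOClass

#: (numerator, denominator) pairs of the five diagnostic ratios.
RATIO_DEFS = (
    ("PO4", "CO3"),
    ("PO4", "AmideIII"),
    ("PO4", "CH2"),
    ("PO4", "AmideI"),
    ("CO3", "AmideIII"),
)

#: WHO group pairs in reporting order.
GROUP_PAIRS = (
    ("N-OP", WHOClass.NORMAL, WHOClass.OSTEOPOROSIS),
    ("N-OPE", WHOClass.NORMAL, WHOClass.OSTEOPENIA),
    ("OPE-OP", WHOClass.OSTEOPENIA, WHOClass.OSTEOPOROSIS),
)

#: star-annotation thresholds, inclusive.
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class BandDefinition:
    name: str
    center: float          # cm^-1
    half_window: float = 20.0
    quantifier: str = "height"  # "height" | "area"

    def __post_init__(self) -> None:
        if self.half_window <= 0:
            raise ValueError("half_window must be positive")
        if self.quantifier not in ("height", "area"):
            raise ValueError("quantifier must be 'height' or 'area'")

    @property
    def window(self) -> tuple[float, float]:
        return (self.center - self.half_window, self.center + self.half_window)


def default_bands(quantifier: str = "height") -> list[BandDefinition]:
    from .synthetic import BAND_CENTERS

    return [BandDefinition(n, c, quantifier=quantifier) for n, c in BAND_CENTERS.items()]


@dataclass
class RatioSet:
    """The five diagnostic ratios for one specimen/offset."""

    specimen_id: str
    offset_mm: int
    values: dict            # "PO4/CO3" -> float (NaN if denominator invalid)
    who_class: WHOClass | None = None

    def as_row(self) -> dict:
        row = {"specimen_id": self.specimen_id, "offset_mm": self.offset_mm}
        if self.who_class is not None:
            row["who_class"] = self.who_class.value
        row.update(self.values)
        return row


@dataclass
class GroupComparison:
    ratio: str
    pair: str               # "N-OP" | "N-OPE" | "OPE-OP"
    p_value: float
    stars: str
    n: tuple[int, int] = (0, 0)


def band_intensity(spectrum, band: BandDefinition) -> float:
    """Band quantity above a local linear chord between the window endpoints.

    height: maximum of (intensity - chord) inside the window;
    area:   trapezoidal integral of (intensity - chord) over the window.
    """
    shifts = np.asarray(spectrum.shifts, dtype=float)
    intensity = np.asarray(spectrum.intensity, dtype=float)
    lo, hi = band.window
    if lo < shifts[0] or hi > shifts[-1]:
        raise ValueError(f"band window {band.window} outside axis range")
    sel = (shifts >= lo) & (shifts <= hi)
    if sel.sum() < 3:
        raise ValueError(f"band window {band.window} covers too few pixels")
    x, y = shifts[sel], intensity[sel]
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    excess = y - chord
    if band.quantifier == "height":
        return float(excess.max())
    return float(np.trapezoid(excess, x))


def normalize_to_phosphate(spectrum, bands: list[BandDefinition] | None = None):
    """Rescale so the phosphate band quantity equals 1 (scale-invariant output)."""
    bands = bands or default_bands()
    po4 = next(b for b in bands if b.name == "PO4")
    q = band_intensity(spectrum, po4)
    if q <= 0:
        raise ValueError("non-positive phosphate signal: spectrum unusable")
    return spectrum.scaled(1.0 / q)


def compute_ratio_set(
    spectrum,
    bands: list[BandDefinition] | None = None,
    specimen_id: str = "",
    who_class: WHOClass | None = None,
) -> RatioSet:
    """The five diagnostic ratios; non-positive denominators yield NaN."""
    bands = bands or default_bands()
    by_name = {b.name: b for b in bands}
    quantities = {n: band_intensity(spectrum, b) for n, b in by_name.items()}
    values = {}
    for num, den in RATIO_DEFS:
        q_den = quantities[den]
        if q_den <= 0:
            warnings.warn(f"non-positive {den} band; {num}/{den} flagged missing")
            values[f"{num}/{den}"] = float("nan")
        else:
            values[f"{num}/{den}"] = quantities[num] / q_den
    return RatioSet(
        specimen_id=specimen_id,
        offset_mm=getattr(spectrum, "offset_mm", 0),
        values=values,
        who_class=who_class,
    )


def ratio_table(ratio_sets: list[RatioSet]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in ratio_sets])


def significance_stars(p: float) -> str:
    """Map a p-value to its star annotation (thresholds inclusive)."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def _two_sample_p(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    if method == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    raise ValueError(f"unknown test method {method!r}")


def pairwise_group_tests(
    ratio_sets: list[RatioSet],
    labels=None,
    method: str = "mannwhitney",
    correction: str = "bonferroni",
) -> list[GroupComparison]:
    """Pairwise WHO-group tests for each ratio, with star annotation.

    ``labels`` may override the classes stored on the ratio sets.  With
    ``correction="bonferroni"`` each p-value is multiplied by the number of
    pairwise comparisons per ratio (3) and capped at 1.  Pairs with fewer
    than 2 specimens in either group are skipped with a warning.
    """
    if labels is None:
        labels = [r.who_class for r in ratio_sets]
    labels = [WHOClass(l) for l in labels]
    if len(labels) != len(ratio_sets):
        raise ValueError("labels and ratio sets differ in length")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    ratio_names = list(ratio_sets[0].values)
    out: list[GroupComparison] = []
    for name in ratio_names:
        by_class: dict[WHOClass, list[float]] = {}
        for r, cls in zip(ratio_sets, labels):
            v = r.values[name]
            if np.isfinite(v):
                by_class.setdefault(cls, []).append(v)
        for pair, c1, c2 in GROUP_PAIRS:
            g1, g2 = by_class.get(c1, []), by_class.get(c2, [])
            if len(g1) < 2 or len(g2) < 2:
                warnings.warn(f"{pair} comparison for {name} skipped (group < 2)")
                continue
            p = _two_sample_p(np.asarray(g1), np.asarray(g2), method)
            if correction == "bonferroni":
                p = min(p * len(GROUP_PAIRS), 1.0)
            out.append(GroupComparison(
                ratio=name, pair=pair, p_value=p,
                stars=significance_stars(p), n=(len(g1), len(g2)),
            ))
    return out


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Wide table mirroring the study's pairwise p-value layout."""
    df = pd.DataFrame([{
        "ratio": c.ratio, "pair": c.pair,
        "p_value": c.p_value, "stars": c.stars,
    } for c in comparisons])
    if df.empty:
        return df
    wide = df.pivot(index="ratio", columns="pair", values="p_value")
    order = [p for p, *_ in GROUP_PAIRS if p in wide.columns]
    return wide[order].rename(columns=lambda p: f"p({p})").reset_index()
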