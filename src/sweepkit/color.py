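"""Pericarp-color phenotyping: seed-image RGB averaging and CIE-L*a*b*.

Per genotype, the phenotype is the channel-wise average RGB over images of
five seed surfaces, converted to the device-independent CIE-L*a*b* space
(L lightness 0-100, a green-red, b blue-yellow).  Averaging happens in RGB
space first and the mean is then converted — the order matters because the
transform is nonlinear, and this matches how the trait was scored.

The conversion assumes sRGB primaries with the D65 white point (2 degree
observer): gamma expansion to linear RGB, the linear sRGB->XYZ matrix, then
the CIE piecewise cube-root f(t) with threshold (6/29)^3.  No camera profile
is modelled; absolute L*a*b* values from real images are profile-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class RGBColor:
    """8-bit RGB triple."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for v in (self.r, self.g, self.b):
            if not (0 <= v <= 255):
                raise ValueError(f"RGB channel {v} outside [0, 255]")


@dataclass(frozen=True)
class LabColor:
    """CIE-L*a*b* triple (L in [0, 100]; a, b signed)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.L <= 100 + 1e-9):
            raise ValueError(f"L {self.L} outside [0, 100]")


def average_seed_color(colors: Sequence[RGBColor]) -> RGBColor:
    """Channel-wise mean of seed colors, rounded half-up to integers."""
    if len(colors) == 0:
        raise ValueError("need at least one seed color")
    n = len(colors)

    def mean_round(vals: Iterable[int]) -> int:
        return int(math.floor(sum(vals) / n + 0.5))

    return RGBColor(mean_round(c.r for c in colors),
                    mean_round(c.g for c in colors),
                    mean_round(c.b for c in colors))


# sRGB (D65) -> XYZ linear transform, IEC 61966-2-1
_SRGB_TO_XYZ = (
    (0.4124564, 0.3575761, 0.1804375),
    (0.2126729, 0.7151522, 0.0721750),
    (0.0193339, 0.1191920, 0.9503041),
)
# D65 reference white, 2 degree observer
_WHITE = (0.95047, 1.0, 1.08883)
_DELTA3 = (6.0 / 29.0) ** 3


def _gamma_expand(u: float) -> float:
    return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4


def _f(t: float) -> float:
    if t > _DELTA3:
        return t ** (1.0 / 3.0)
    return t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0


def rgb_to_lab(c: RGBColor) -> LabColor:
    """Convert an 8-bit sRGB color to CIE-L*a*b* (D65, 2 degree observer)."""
    lin = [_gamma_expand(v / 255.0) for v in (c.r, c.g, c.b)]
    xyz = [sum(m * u for m, u in zip(row, lin)) for row in _SRGB_TO_XYZ]
    fx, fy, fz = (_f(v / w) for v, w in zip(xyz, _WHITE))
    L = 116.0 * fy - 16.0
    return LabColor(L=min(max(L, 0.0), 100.0),
                    a=500.0 * (fx - fy),
                    b=200.0 * (fy - fz))


def phenotype_table(seed_colors: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype averaged RGB and L*a*b* from a per-seed color table.

    Input columns: genotype_id, seed_index, R, G, B (one row per seed image).
    Output columns: genotype_id, R, G, B, L, a, b — the GWAS-ready phenotype.
    """
    required = {"genotype_id", "R", "G", "B"}
    if not required.issubset(seed_colors.columns):
        raise ValueError(f"seed color table needs columns {sorted(required)}")
    rows = []
    for gid, grp in seed_colors.groupby("genotype_id", sort=False):
        colors = [RGBColor(int(r), int(g), int(b))
                  for r, g, b in zip(grp["R"], grp["G"], grp["B"])]
        avg = average_seed_color(colors)
        lab = rgb_to_lab(avg)
        rows.append((gid, avg.r, avg.g, avg.b, lab.L, lab.a, lab.b))
    return pd.DataFrame(rows, columns=["genotype_id", "R", "G", "B", "L", "a", "b"])
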