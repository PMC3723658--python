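"""Plumage colour quantification from RGB photographs.

Feather samples are photographed under standardised light and RGB values
read from a fixed number of small sampling squares per individual.  The
squares are averaged and converted to the hexcone colour model: hue
(perceived colour tone, degrees), saturation (intensity of colour,
max-normalised fraction) and brightness (total reflected light, fraction
of full scale).  Measurement repeatability is summarised by the one-way
ANOVA intraclass correlation coefficient with the unequal-group-size
correction ``k0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RGBSample",
    "ColourPhenotype",
    "RepeatabilityResult",
    "average_squares",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "repeatability",
    "phenotypes_from_rgb",
    "read_rgb_table",
    "write_phenotypes",
]


@dataclass(frozen=True)
class RGBSample:
    """One sampling square's RGB reading for one individual.

    Channel values are 8-bit (0–255); ``square_index`` identifies the
    square within the individual and must be unique per individual.
    """

    individual_id: str
    square_index: int
    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"channel {name}={v} outside [0, 255]")


@dataclass(frozen=True)
class ColourPhenotype:
    """Hue/saturation/brightness phenotype of one individual.

    ``hue`` is in degrees [0, 360) and is NaN for achromatic colours
    (saturation 0), where hue is undefined.  ``saturation`` and
    ``brightness`` are fractions in [0, 1].
    """

    hue: float
    saturation: float
    brightness: float

    @property
    def hue_defined(self) -> bool:
        return not math.isnan(self.hue)


@dataclass(frozen=True)
class RepeatabilityResult:
    """One-way ANOVA repeatability (intraclass correlation)."""

    icc: float
    ms_among: float
    ms_within: float
    k0: float
    n_groups: int
    n_total: int


def average_squares(samples: Sequence[RGBSample]) -> np.ndarray:
    """Average the per-square RGB readings of one individual.

    Returns the arithmetic channel means as a length-3 float array
    (r, g, b).  Order of the squares is irrelevant.

    Raises
    ------
    ValueError
        If ``samples`` is empty (missing measurement) or mixes
        individuals, or if square indices repeat within the individual.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no RGB samples provided: missing colour measurement")
    ids = {s.individual_id for s in samples}
    if len(ids) != 1:
        raise ValueError(f"samples mix individuals: {sorted(ids)}")
    idx = [s.square_index for s in samples]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate square_index within individual")
    arr = np.array([[s.r, s.g, s.b] for s in samples], dtype=float)
    return arr.mean(axis=0)


def rgb_to_hsb(rgb: Sequence[float]) -> ColourPhenotype:
    """Convert an (averaged) RGB triple on the 0–255 scale to HSB.

    Standard hexcone model: brightness = max/255, saturation =
    (max − min)/max (0 for black), hue from 60°-sector arithmetic on the
    chroma.  Achromatic inputs (max == min) have undefined hue, returned
    as NaN rather than 0 to avoid spurious hue values.
    """
    r, g, b = (float(v) for v in rgb)
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not (0 <= v <= 255):
            raise ValueError(f"channel {name}={v} outside [0, 255]")
    mx = max(r, g, b)
    mn = min(r, g, b)
    chroma = mx - mn
    brightness = mx / 255.0
    saturation = 0.0 if mx == 0 else chroma / mx
    if chroma == 0:
        return ColourPhenotype(hue=float("nan"), saturation=saturation, brightness=brightness)
    if mx == r:
        hue = 60.0 * (((g - b) / chroma) % 6.0)
    elif mx == g:
        hue = 60.0 * ((b - r) / chroma + 2.0)
    else:
        hue = 60.0 * ((r - g) / chroma + 4.0)
    return ColourPhenotype(hue=hue % 360.0, saturation=saturation, brightness=brightness)


def hsb_to_rgb(hue: float, saturation: float, brightness: float) -> tuple[float, float, float]:
    """Inverse hexcone conversion, back to the 0–255 RGB scale."""
    if not (0 <= saturation <= 1 and 0 <= brightness <= 1):
        raise ValueError("saturation and brightness must lie in [0, 1]")
    v = brightness * 255.0
    c = v * saturation
    hp = (hue % 360.0) / 60.0
    x = c * (1.0 - abs(hp % 2.0 - 1.0))
    sector = int(hp)
    r1, g1, b1 = [
        (c, x, 0.0),
        (x, c, 0.0),
        (0.0, c, x),
        (0.0, x, c),
        (x, 0.0, c),
        (c, 0.0, x),
    ][sector % 6]
    m = v - c
    return (r1 + m, g1 + m, b1 + m)


def repeatability(values: Iterable[float], groups: Iterable) -> RepeatabilityResult:
    """One-way ANOVA intraclass correlation of repeated measurements.

    ``values`` are trait measurements, ``groups`` the individual each
    measurement belongs to.  The among-individual variance component is
    (MS_among − MS_within)/k0 with k0 the standard unequal-group-size
    coefficient; the ICC is that component's share of the total and is
    truncated at 0.
    """
    y = np.asarray(list(values), dtype=float)
    g = pd.Series(list(groups))
    if len(y) != len(g):
        raise ValueError("values and groups have different lengths")
    counts = g.value_counts()
    a = len(counts)
    n_total = len(y)
    if a < 2:
        raise ValueError("repeatability needs at least 2 individuals")
    if n_total - a < 1:
        raise ValueError("repeatability needs repeated measurements (>=2 for some individual)")
    grand = y.mean()
    frame = pd.DataFrame({"y": y, "g": g.values})
    means = frame.groupby("g")["y"].mean()
    n_i = frame.groupby("g")["y"].size()
    ss_among = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((frame["y"] - means.loc[frame["g"]].values) ** 2).sum())
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_total - a)
    k0 = (n_total - float((n_i**2).sum()) / n_total) / (a - 1)
    s2_among = (ms_among - ms_within) / k0
    denom = s2_among + ms_within
    icc = 0.0 if denom <= 0 else max(0.0, s2_among / denom)
    return RepeatabilityResult(
        icc=icc,
        ms_among=ms_among,
        ms_within=ms_within,
        k0=k0,
        n_groups=a,
        n_total=n_total,
    )


def phenotypes_from_rgb(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format RGB table to one phenotype row per individual.

    Expects columns ``individual_id, square_index, r, g, b``; returns
    ``individual_id, hue, saturation, brightness`` with the squares of
    each individual averaged before conversion.
    """
    required = {"individual_id", "square_index", "r", "g", "b"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"RGB table missing columns: {sorted(missing)}")
    rows = []
    for ind, sub in table.groupby("individual_id", sort=True):
        samples = [
            RGBSample(str(ind), int(s.square_index), float(s.r), float(s.g), float(s.b))
            for s in sub.itertuples()
        ]
        phen = rgb_to_hsb(average_squares(samples))
        rows.append(
            {
                "individual_id": ind,
                "hue": phen.hue,
                "saturation": phen.saturation,
                "brightness": phen.brightness,
            }
        )
    return pd.DataFrame(rows)


def read_rgb_table(path) -> pd.DataFrame:
    """Read a long-format RGB CSV (individual_id, square_index, r, g, b)."""
    return pd.read_csv(path)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    """Write a phenotype table (individual_id, hue, saturation, brightness)."""
    table.to_csv(path, index=False)
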