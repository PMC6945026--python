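"""CHEF pulsed-field gel band sizing and conversion to repeat copies.

Contour-clamped homogeneous electric field (CHEF) electrophoresis resolves
megabase DNA. A restriction digest releases the intact repeat array; the
band's migration distance is converted to a physical size against a
chromosomal ladder, and copies follow by subtracting the restriction-site
flank distances and dividing by the repeat-unit length:

    copies = (band_size - flank_left - flank_right) / unit_length

Ladder interpolation is piecewise-linear in (migration, log size): gel
mobility is far closer to log-linear than linear in fragment size, and the
piecewise form is exact at every ladder rung by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .results import CopyNumberEstimate

__all__ = [
    "LadderCalibration",
    "ChefMeasurement",
    "calibrate_size",
    "chef_copy_number",
    "chef_replicates",
    "hansenula_ladder",
]

#: BamHI flank distances around the S. cerevisiae rDNA array on ChrXII (bp):
#: nearest sites sit 8.8 kb centromere-proximal and 30.9 kb telomere-proximal.
CEREVISIAE_BAMHI_FLANKS = (8_800, 30_900)
#: SwaI cuts 3,927 bp upstream of the C. elegans array's proximal edge. The
#: worm workflow divides total band size by the unit length without flank
#: subtraction by default; this constant is available when a user chooses
#: to subtract it.
CELEGANS_SWAI_FLANK = 3_927


@dataclass
class LadderCalibration:
    """Monotone (migration distance, fragment size) pairs from a ladder lane."""

    migration: np.ndarray  # arbitrary units, increasing
    size: np.ndarray  # bases, strictly decreasing with migration

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if len(self.migration) != len(self.size) or len(self.size) < 2:
            raise ValueError("ladder needs >= 2 (migration, size) pairs")
        order = np.argsort(self.migration)
        self.migration = self.migration[order]
        self.size = self.size[order]
        if np.any(np.diff(self.size) >= 0):
            raise ValueError("ladder sizes must strictly decrease with migration")
        if np.any(self.size <= 0):
            raise ValueError("ladder sizes must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LadderCalibration":
        df = pd.read_csv(path)
        return cls(df["distance"].to_numpy(), df["size"].to_numpy())

    def migration_of(self, size: float) -> float:
        """Invert the calibration: migration distance of a given size."""
        if not self.size[-1] <= size <= self.size[0]:
            raise ValueError(
                f"size {size:.0f} beyond ladder resolution "
                f"[{self.size[-1]:.0f}, {self.size[0]:.0f}]"
            )
        # np.interp needs increasing x; log-size decreases with migration
        return float(
            np.interp(np.log(size), np.log(self.size[::-1]), self.migration[::-1])
        )


def hansenula_ladder() -> LadderCalibration:
    """A Hansenula wingei chromosome ladder (sizes per the Bio-Rad standard)
    with synthetic but realistically curved migration distances."""
    sizes = np.array([3_130_000, 2_700_000, 2_350_000, 1_810_000, 1_660_000, 1_370_000, 1_050_000])
    # mobility compresses for the largest fragments
    migration = 80.0 * (np.log(3_300_000) - np.log(sizes)) ** 0.85
    return LadderCalibration(migration=migration, size=sizes)


@dataclass
class ChefMeasurement:
    """One measured band. Give either ``migration`` (+ ladder at conversion
    time) or a pre-calibrated ``size`` in bases."""

    unit_length: int
    migration: float | None = None
    size: float | None = None
    flank_left: int = 0
    flank_right: int = 0
    band_role: str = "primary"  # primary | minor
    strain: str | None = None

    def __post_init__(self) -> None:
        if (self.migration is None) == (self.size is None):
            raise ValueError("give exactly one of migration or size")
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if self.band_role not in ("primary", "minor"):
            raise ValueError("band_role must be 'primary' or 'minor'")


def calibrate_size(migration: float, ladder: LadderCalibration) -> float:
    """Band size (bases) from migration distance, log-linear between rungs.

    Exact at ladder rungs; errors outside the ladder range, where the gel
    no longer resolves size.
    """
    if not ladder.migration[0] <= migration <= ladder.migration[-1]:
        raise ValueError(
            f"migration {migration:.2f} beyond ladder resolution "
            f"[{ladder.migration[0]:.2f}, {ladder.migration[-1]:.2f}]"
        )
    log_size = np.interp(migration, ladder.migration, np.log(ladder.size))
    return float(np.exp(log_size))


def chef_copy_number(
    m: ChefMeasurement, ladder: LadderCalibration | None = None
) -> CopyNumberEstimate:
    """Copies in the array: (size - flanks) / unit_length.

    The value is reported rounded to the nearest integer (band sizes do not
    support sub-copy precision); the unrounded value is kept in provenance.
    """
    if m.size is not None:
        size = float(m.size)
    else:
        if ladder is None:
            raise ValueError("migration-based measurement needs a ladder")
        size = calibrate_size(m.migration, ladder)
    flanks = m.flank_left + m.flank_right
    if size <= flanks:
        raise ValueError(
            f"band size {size:.0f} <= flank total {flanks}: no array left after "
            "flank subtraction — measurement invalid"
        )
    raw = (size - flanks) / m.unit_length
    return CopyNumberEstimate(
        value=float(round(raw)),
        method="CHEF",
        provenance={
            "band_size": size,
            "flank_left": m.flank_left,
            "flank_right": m.flank_right,
            "unit_length": m.unit_length,
            "unrounded": raw,
            "band_role": m.band_role,
            "strain": m.strain,
        },
    )


def chef_replicates(values: Sequence[float]) -> dict:
    """Replicate summary: mean, sample SD, and CV% = 100 * sd / mean.

    The coefficient of variation uses the sample (n-1) standard deviation.
    A single replicate has no dispersion estimate: SD and CV are NaN.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    if vals.size < 2:
        sd = cv = float("nan")
    else:
        sd = float(vals.std(ddof=1))
        cv = 100.0 * sd / mean
    return {
        "n": int(vals.size),
        "mean": mean,
        "mean_rounded": int(round(mean)),
        "sd": sd,
        "cv_percent": cv,
    }
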