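"""Common result container for all estimation methods."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["CopyNumberEstimate"]


@dataclass
class CopyNumberEstimate:
    """A copy-number value (copies per haploid genome) with provenance.

    ``method`` labels the assay/estimator that produced the value: one of
    ``RR`` (relative read depth), ``GCC`` (GC-corrected read depth),
    ``ddPCR``, ``smMIP``, ``CHEF`` or ``FISH-relative``. ``interval`` is a
    95% confidence interval where the method defines one (ddPCR); methods
    without a closed-form interval leave it ``None``. ``provenance`` is a
    free-form dict recording inputs (counts, seeds, file digests).
    """

    value: float
    method: str
    interval: Optional[tuple[float, float]] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("copy number cannot be negative")
        if self.interval is not None:
            lo, hi = self.interval
            if lo > hi:
                raise ValueError("interval bounds out of order")

    def contains(self, truth: float) -> bool:
        """True if ``truth`` lies inside the confidence interval."""
        if self.interval is None:
            raise ValueError(f"{self.method} estimate carries no interval")
        lo, hi = self.interval
        return lo <= truth <= hi
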