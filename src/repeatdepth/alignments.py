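"""Columnar container for mapped-read records plus SAM input/output.

Read-depth copy-number estimation only needs, per mapped record, the
reference it aligned to, the alignment span, and the strand. Holding those
as numpy arrays keeps counting and GC-profile fitting vectorized even for
millions of records; SAM round-tripping goes through pysam.

Counting conventions (deliberate, and relied on by the estimators):

* every mapped record counts — each mate of a pair is one record;
* unmapped records are excluded at parse time;
* duplicates are retained: in a tandem array, identical fragments are
  expected from independent molecules, so duplicate removal would bias the
  repeat count downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

__all__ = ["AlignmentTable", "read_alignments"]


@dataclass
class AlignmentTable:
    """Mapped records as parallel arrays (one entry per SAM record)."""

    ref_names: list[str]
    ref_id: np.ndarray  # int32, index into ref_names
    start: np.ndarray  # int64, 0-based leftmost aligned position
    end: np.ndarray  # int64, exclusive end of the aligned span
    is_reverse: np.ndarray  # bool
    mapq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.start)
        if self.mapq is None:
            self.mapq = np.full(n, 60, dtype=np.int16)
        for arr in (self.ref_id, self.end, self.is_reverse, self.mapq):
            if len(arr) != n:
                raise ValueError("alignment columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_records(self) -> int:
        return len(self.start)

    def subset(self, mask: np.ndarray) -> "AlignmentTable":
        return AlignmentTable(
            ref_names=self.ref_names,
            ref_id=self.ref_id[mask],
            start=self.start[mask],
            end=self.end[mask],
            is_reverse=self.is_reverse[mask],
            mapq=self.mapq[mask],
        )

    def ref_index(self, name: str) -> int:
        try:
            return self.ref_names.index(name)
        except ValueError:
            raise KeyError(f"unknown reference sequence {name!r}") from None


def read_alignments(sam_path: str | Path) -> AlignmentTable:
    """Parse a SAM/BAM file into an :class:`AlignmentTable`.

    Unmapped records are dropped; secondary/supplementary records are kept
    (a multi-mapper randomly assigned to one location arrives as a primary
    record and is counted once). Raises ``ValueError`` naming the offending
    line for records pysam cannot parse.
    """
    sam_path = str(sam_path)
    ref_ids, starts, ends, revs, mapqs = [], [], [], [], []
    lineno = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        ref_names = list(fh.references)
        name_to_id = {n: i for i, n in enumerate(ref_names)}
        try:
            for lineno, rec in enumerate(fh, start=1):
                if rec.is_unmapped:
                    continue
                ref_ids.append(name_to_id[rec.reference_name])
                starts.append(rec.reference_start)
                ends.append(rec.reference_end)
                revs.append(rec.is_reverse)
                mapqs.append(rec.mapping_quality)
        except (ValueError, OSError) as exc:
            raise ValueError(
                f"malformed SAM record near line {lineno} of {sam_path}: {exc}"
            ) from exc
    return AlignmentTable(
        ref_names=ref_names,
        ref_id=np.asarray(ref_ids, dtype=np.int32),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        is_reverse=np.asarray(revs, dtype=bool),
        mapq=np.asarray(mapqs, dtype=np.int16),
    )
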