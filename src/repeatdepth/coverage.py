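"""Read-depth copy-number estimation with optional GC-bias correction.

The relative-read (RR) estimate scales the fraction of mapped records
falling in the repeat region by genome length over repeat-unit length:

    c_RR = (N_repeat * G) / (N_total * L_r)

Counting rules: every mapped record counts (each mate independently),
duplicates are retained, no mapping-quality filter is applied, and a
record counts toward a region when its aligned span overlaps it by at
least one base. The counting region and the unit length are independent:
the numerator span may cover flanking partial units while the denominator
stays one unit.

The GC-corrected (GCC) estimate addresses library-preparation bias in
which fragment recovery depends on fragment GC content (pronounced for
tagmentation libraries). Read anchors (the fragment-facing end of each
record: start of a forward record, end of a reverse one) are modeled as
Poisson with a rate that depends only on the GC fraction of the W-base
window adjacent to the anchor. The per-GC-bin rate ``lambda_b`` is fitted
on background (non-repeat) positions, where true copy number is one, and
the repeat copy number MLE is

    c_GCC = N_repeat_anchors / (s * sum_{i in repeat} lambda(g_i))

with ``s`` a global normalization chosen so that a flat profile makes the
GCC estimate coincide with the anchor-based RR estimate (the constant then
cancels and no correction is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignments import AlignmentTable, read_alignments  # noqa: F401  (re-export)
from .reference import GenomicRegion, ReferenceModel
from .results import CopyNumberEstimate

__all__ = [
    "CountSummary",
    "GCBiasProfile",
    "read_alignments",
    "count_regions",
    "estimate_rr",
    "fit_gc_profile",
    "estimate_gcc",
    "estimate_control_regions",
    "downsample_estimates",
]


@dataclass
class CountSummary:
    """Total mapped records and per-region overlap counts."""

    total_mapped: int
    region_counts: dict[GenomicRegion, int]

    def __post_init__(self) -> None:
        for region, n in self.region_counts.items():
            if n > self.total_mapped:
                raise ValueError(
                    f"region {region.name}:{region.start}-{region.end} count {n} "
                    f"exceeds total mapped {self.total_mapped}"
                )


def count_regions(
    aln: AlignmentTable,
    ref: ReferenceModel,
    regions: list[GenomicRegion] | None = None,
    counting: str = "overlap",
) -> CountSummary:
    """Count records per region; ``total_mapped`` counts all records.

    ``counting`` chooses the membership rule: ``overlap`` (default; the
    aligned span overlaps the region by >= 1 base), ``start`` (the leftmost
    aligned position lies in the region) or ``anchor`` (the fragment-facing
    end — start of a forward record, last base of a reverse one — lies in
    the region, the rule used inside the GC-corrected likelihood).
    """
    if counting not in ("overlap", "start", "anchor"):
        raise ValueError("counting must be 'overlap', 'start' or 'anchor'")
    if regions is None:
        regions = [ref.repeat_region, *ref.control_regions]
    counts: dict[GenomicRegion, int] = {}
    for region in regions:
        rid = aln.ref_index(region.name)
        on_ref = aln.ref_id == rid
        if counting == "overlap":
            mask = on_ref & (aln.start < region.end) & (aln.end > region.start)
        else:
            pos = (
                aln.start
                if counting == "start"
                else np.where(aln.is_reverse, aln.end - 1, aln.start)
            )
            mask = on_ref & (pos >= region.start) & (pos < region.end)
        counts[region] = int(mask.sum())
    return CountSummary(total_mapped=len(aln), region_counts=counts)


def estimate_rr(
    counts: CountSummary,
    ref: ReferenceModel,
    region: GenomicRegion | None = None,
    unit_length: int | None = None,
) -> CopyNumberEstimate:
    """Relative-read copy number: (N_region * G) / (N_total * unit_length)."""
    if region is None:
        region = ref.repeat_region
    if unit_length is None:
        unit_length = ref.repeat_unit_length
    if counts.total_mapped == 0:
        raise ValueError("no mapped records: cannot estimate copy number")
    n_region = counts.region_counts[region]
    if n_region == 0:
        warnings.warn(
            f"no records overlap {region.name}:{region.start}-{region.end}; "
            "copy number reported as 0",
            stacklevel=2,
        )
    value = (n_region * ref.genome_length) / (counts.total_mapped * unit_length)
    return CopyNumberEstimate(
        value=value,
        method="RR",
        provenance={
            "n_region": n_region,
            "n_total": counts.total_mapped,
            "genome_length": ref.genome_length,
            "unit_length": unit_length,
        },
    )


@dataclass
class GCBiasProfile:
    """Per-GC-bin anchor rate fitted on background positions.

    ``rate[b]`` is anchors per eligible (position, strand) slot for windows
    whose GC falls in bin ``b``; bins with fewer than the requested minimum
    of eligible slots were merged with an adjacent bin and share its rate.
    Bins never observed in the background carry NaN.
    """

    window: int
    bin_edges: np.ndarray
    rate: np.ndarray
    eligible: np.ndarray  # eligible slots per bin (both strands)

    @property
    def n_bins(self) -> int:
        return len(self.rate)

    def is_flat(self) -> bool:
        r = self.rate[np.isfinite(self.rate)]
        return len(r) > 0 and np.allclose(r, r[0])

    def rate_at(self, gc: np.ndarray) -> np.ndarray:
        """Rates for GC values; empty bins borrow the nearest fitted bin."""
        idx = np.clip(np.digitize(gc, self.bin_edges) - 1, 0, self.n_bins - 1)
        rates = self.rate[idx]
        if np.any(~np.isfinite(rates)):
            good = np.flatnonzero(np.isfinite(self.rate))
            if len(good) == 0:
                raise ValueError("profile has no fitted bins")
            centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
            bad = ~np.isfinite(rates)
            nearest = good[np.argmin(np.abs(centers[idx[bad]][:, None] - centers[good][None, :]), axis=1)]
            rates = rates.copy()
            rates[bad] = self.rate[nearest]
        return rates


def _window_gc(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position GC fraction of the W-window starting there, plus an
    eligibility mask (window inside the sequence and free of non-ACGT)."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = ((codes == ord("G")) | (codes == ord("C"))).astype(np.int64)
    is_acgt = (
        (codes == ord("A")) | (codes == ord("C")) | (codes == ord("G")) | (codes == ord("T"))
    ).astype(np.int64)
    cs_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cs_ok = np.concatenate([[0], np.cumsum(is_acgt)])
    n = len(codes)
    n_win = n - window + 1
    if n_win <= 0:
        raise ValueError("sequence shorter than the GC window")
    gc = (cs_gc[window:] - cs_gc[:-window]) / window
    ok = (cs_ok[window:] - cs_ok[:-window]) == window
    assert len(gc) == n_win
    return gc, ok


def _anchor_positions(aln: AlignmentTable, window: int) -> np.ndarray:
    """Window-start position of each record's fragment-facing window:
    the record start for forward records, ``end - window`` for reverse."""
    return np.where(aln.is_reverse, aln.end - window, aln.start)


class _RefGCIndex:
    """Cached per-reference GC binning: window-GC bin of every position,
    background slot masks, per-bin eligible-slot counts, and the bin counts
    of the repeat unit in its periodic (tandem) context.

    The repeat's windows are taken on the tiled unit rather than the
    collapsed reference, because in the true genome the sequence following
    a unit is the next copy, not the flanking sequence.
    """

    def __init__(self, ref: ReferenceModel, window: int, n_bins: int) -> None:
        self.window = window
        self.n_bins = n_bins
        self.edges = np.linspace(0.0, 1.0, n_bins + 1)
        self.bins_pos: dict[str, np.ndarray] = {}
        self.fwd_mask: dict[str, np.ndarray] = {}
        self.rev_mask: dict[str, np.ndarray] = {}
        self.eligible = np.zeros(n_bins, dtype=np.int64)
        for name, seq in ref.sequences.items():
            gc, ok = _window_gc(seq, window)
            n_win = len(gc)
            self.bins_pos[name] = np.clip(
                np.digitize(gc, self.edges) - 1, 0, n_bins - 1
            ).astype(np.int16)
            # a forward anchor sits at its window start; a reverse anchor at
            # position j owns the window starting at j - window + 1
            fwd = ok.copy()
            rev = ok.copy()
            if ref.repeat_region.name == name:
                rs, re_ = ref.repeat_region.start, ref.repeat_region.end
                fwd[rs : min(re_, n_win)] = False
                rev[max(0, rs - window + 1) : min(re_ - window + 1, n_win)] = False
            self.fwd_mask[name] = fwd
            self.rev_mask[name] = rev
            self.eligible += np.bincount(self.bins_pos[name][fwd], minlength=n_bins)
            self.eligible += np.bincount(self.bins_pos[name][rev], minlength=n_bins)
        # periodic repeat windows: tile the repeat region so every offset has
        # a full window of tandem context
        region = ref.repeat_region
        unit = ref.sequences[region.name][region.start : region.end]
        tiles = -(-(len(unit) + window) // len(unit)) + 1
        gc_rep, ok_rep = _window_gc(unit * tiles, window)
        gc_rep, ok_rep = gc_rep[: len(unit)], ok_rep[: len(unit)]
        bins_rep = np.clip(np.digitize(gc_rep, self.edges) - 1, 0, n_bins - 1)
        self.repeat_bins = np.bincount(bins_rep[ok_rep], minlength=n_bins)
        self.repeat_slots = int(ok_rep.sum())  # per strand


def _gc_index(ref: ReferenceModel, window: int, n_bins: int) -> _RefGCIndex:
    cache = ref.__dict__.setdefault("_gc_index_cache", {})
    key = (window, n_bins)
    if key not in cache:
        cache[key] = _RefGCIndex(ref, window, n_bins)
    return cache[key]


def _merge_sparse_bins(
    anchors: np.ndarray, eligible: np.ndarray, min_positions: int
) -> np.ndarray:
    """Rates after merging bins with < min_positions eligible slots into an
    adjacent occupied bin (the better-populated neighbor)."""
    n = len(eligible)
    groups = list(range(n))  # group id per bin, contiguous runs

    def group_sizes():
        sizes: dict[int, int] = {}
        for b in range(n):
            sizes[groups[b]] = sizes.get(groups[b], 0) + int(eligible[b])
        return sizes

    while True:
        sizes = group_sizes()
        small = [g for g, s in sizes.items() if 0 < s < min_positions]
        if not small or len(sizes) <= 1:
            break
        g = min(small, key=lambda gg: sizes[gg])
        members = [b for b in range(n) if groups[b] == g]
        left = [groups[b] for b in range(members[0] - 1, -1, -1) if sizes.get(groups[b], 0) > 0]
        right = [groups[b] for b in range(members[-1] + 1, n) if sizes.get(groups[b], 0) > 0]
        neighbors = []
        if left:
            neighbors.append(left[0])
        if right:
            neighbors.append(right[0])
        neighbors = [x for x in neighbors if x != g]
        if not neighbors:
            break
        target = max(neighbors, key=lambda gg: sizes[gg])
        for b in members:
            groups[b] = target
    rate = np.full(n, np.nan)
    sizes = group_sizes()
    for g in set(groups):
        members = [b for b in range(n) if groups[b] == g]
        tot_e = sum(int(eligible[b]) for b in members)
        if tot_e > 0:
            tot_a = sum(int(anchors[b]) for b in members)
            for b in members:
                if eligible[b] > 0:
                    rate[b] = tot_a / tot_e
    return rate


def fit_gc_profile(
    aln: AlignmentTable,
    ref: ReferenceModel,
    window: int = 300,
    n_bins: int = 100,
    min_positions: int = 100,
) -> GCBiasProfile:
    """Fit the per-GC-bin anchor rate on background (non-repeat) positions.

    Background is the genome minus the repeat region; positions whose
    window contains non-ACGT bases are ineligible. Both strands contribute:
    each eligible position provides one forward and one reverse anchor
    slot. Warns when every eligible position lands in a single bin, in
    which case the correction degenerates to RR.
    """
    if not ref.sequences:
        raise ValueError("GC fitting needs reference sequences")
    idx = _gc_index(ref, window, n_bins)
    anchors = np.zeros(n_bins, dtype=np.int64)
    for name in ref.sequences:
        if name not in aln.ref_names:
            continue
        on_ref = aln.ref_id == aln.ref_index(name)
        ws = _anchor_positions(aln, window)[on_ref]
        rev = aln.is_reverse[on_ref]
        n_win = len(idx.bins_pos[name])
        valid = (ws >= 0) & (ws < n_win)
        ws, rev = ws[valid], rev[valid]
        slot_ok = np.where(rev, idx.rev_mask[name][ws], idx.fwd_mask[name][ws])
        anchors += np.bincount(idx.bins_pos[name][ws[slot_ok]], minlength=n_bins)

    if anchors.sum() == 0:
        warnings.warn("no background anchors: all rates zero", stacklevel=2)
        rate = np.where(idx.eligible > 0, 0.0, np.nan)
    else:
        if int((idx.eligible > 0).sum()) <= 1:
            warnings.warn(
                "all eligible positions fall in one GC bin; "
                "GC correction degenerates to the RR estimate",
                stacklevel=2,
            )
        rate = _merge_sparse_bins(anchors, idx.eligible, min_positions)
    return GCBiasProfile(
        window=window, bin_edges=idx.edges, rate=rate, eligible=idx.eligible
    )


def estimate_gcc(
    aln: AlignmentTable, ref: ReferenceModel, profile: GCBiasProfile
) -> CopyNumberEstimate:
    """GC-corrected copy number from a fitted bias profile.

    The anchor-based relative-read value is multiplied by the ratio of the
    genome-mean to the repeat-mean per-slot anchor rate:

        c_GCC = (N_rep_anchors * G) / (N_tot * L_r) * (mean_genome / mean_repeat)

    Repeat windows are evaluated in the unit's periodic (tandem) context;
    repeat GC bins never seen in the background borrow the nearest fitted
    bin's rate. Under a flat profile the ratio is exactly 1 and the value
    coincides with the anchor-counted RR estimate.
    """
    if not ref.sequences:
        raise ValueError("GC correction needs reference sequences")
    region = ref.repeat_region
    idx = _gc_index(ref, profile.window, profile.n_bins)

    rate = profile.rate.copy()
    need = (idx.repeat_bins > 0) & ~np.isfinite(rate)
    if np.any(need):
        centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
        rate[need] = profile.rate_at(centers[need])
    rate_bg = np.where(np.isfinite(profile.rate), profile.rate, 0.0)

    sum_repeat = float(np.dot(idx.repeat_bins, np.where(np.isfinite(rate), rate, 0.0)))
    if sum_repeat <= 0 or idx.repeat_slots == 0:
        raise ValueError("bias profile sums to zero over the repeat region")
    mean_repeat = sum_repeat / idx.repeat_slots
    sum_background = float(np.dot(idx.eligible, rate_bg))
    n_slots = int(idx.eligible.sum()) + 2 * idx.repeat_slots
    mean_genome = (sum_background + 2.0 * sum_repeat) / n_slots
    if mean_genome <= 0:
        raise ValueError("bias profile sums to zero over the genome")

    on_ref = aln.ref_id == aln.ref_index(region.name)
    anchor = np.where(aln.is_reverse, aln.end - 1, aln.start)
    n_rep = int(((anchor >= region.start) & (anchor < region.end) & on_ref).sum())
    n_tot = len(aln)
    if n_tot == 0:
        raise ValueError("no mapped records")
    rr_anchor = (n_rep * ref.genome_length) / (n_tot * ref.repeat_unit_length)
    # a flat profile carries no information: the correction is identically 1
    # (computing it would only add summation roundoff)
    correction = 1.0 if profile.is_flat() else mean_genome / mean_repeat
    value = rr_anchor * correction
    return CopyNumberEstimate(
        value=value,
        method="GCC",
        provenance={
            "n_repeat_anchors": n_rep,
            "n_total": n_tot,
            "window": profile.window,
            "n_bins": profile.n_bins,
            "anchor_rr": rr_anchor,
            "correction_factor": correction,
        },
    )


def estimate_control_regions(
    aln: AlignmentTable, ref: ReferenceModel, counting: str = "anchor"
) -> tuple[list[CopyNumberEstimate], float]:
    """RR estimate of every single-copy control region (unit length = region
    length) plus their mean — the per-sample coverage-inflation statistic.

    Control regions are single copy, so the mean sits near 1.0 for a
    well-behaved library; systematic departure flags global count
    distortion of the kind that also inflates the repeat estimate. Anchor
    counting is the default here: overlap counting carries a fixed
    +2(read_length-1)/region_length edge offset, irrelevant for
    multi-kilobase regions but distorting when regions approach read
    length.
    """
    if not ref.control_regions:
        return [], float("nan")
    counts = count_regions(aln, ref, regions=list(ref.control_regions), counting=counting)
    estimates = [
        estimate_rr(counts, ref, region=region, unit_length=region.length)
        for region in ref.control_regions
    ]
    mean = float(np.mean([e.value for e in estimates]))
    return estimates, mean


def downsample_estimates(
    aln: AlignmentTable,
    fraction: float,
    n_reps: int,
    seed: int,
    ref: ReferenceModel,
    method: str = "rr",
    gc_window: int = 300,
    gc_bins: int = 100,
) -> dict:
    """Record-level Bernoulli downsampling stability analysis.

    Each replicate keeps every record independently with probability
    ``fraction`` and re-estimates copy number (refitting the GC profile on
    the downsampled records when ``method='gcc'``). Returns the replicate
    estimates, the full-data estimate, the maximum percent deviation from
    it, and the replicate CV%.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if method not in ("rr", "gcc"):
        raise ValueError("method must be 'rr' or 'gcc'")

    def _estimate(table: AlignmentTable) -> float:
        if method == "rr":
            counts = count_regions(table, ref, regions=[ref.repeat_region])
            return estimate_rr(counts, ref).value
        profile = fit_gc_profile(table, ref, window=gc_window, n_bins=gc_bins)
        return estimate_gcc(table, ref, profile).value

    full = _estimate(aln)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_reps):
        if fraction == 1.0:
            values.append(full)
            continue
        mask = rng.random(len(aln)) < fraction
        values.append(_estimate(aln.subset(mask)))
    values_arr = np.asarray(values)
    max_dev = float(100.0 * np.max(np.abs(values_arr - full)) / full) if full > 0 else float("nan")
    cv = (
        float(100.0 * values_arr.std(ddof=1) / values_arr.mean())
        if n_reps > 1 and values_arr.mean() > 0
        else float("nan")
    )
    return {
        "estimates": values,
        "full_estimate": full,
        "max_percent_deviation": max_dev,
        "cv_percent": cv,
        "fraction": fraction,
        "method": method,
    }
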