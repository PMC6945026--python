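"""Synthetic data for every stage of the copy-number pipeline.

The generator emulates, at desk scale, the study design around a large
tandem-repeat array: a toy genome whose reference carries a single
collapsed repeat unit while the true genome carries ``c`` tandem copies;
paired short reads drawn from the true (expanded) genome with an optional
unimodal fragment-GC acceptance bias standing in for tagmentation
(Tn5/Nextera) chemistry; Poisson droplet partitioning for ddPCR; smMIP
capture with per-probe efficiencies, UMI barcodes and a co-captured
normalization plasmid; pulsed-field gel band measurements through a ladder
model; and 3-D image stacks with Gaussian nuclear FISH foci whose
integrated intensity is proportional to copy number.

Everything is seeded and deterministic: the same :class:`SimConfig` yields
byte-identical outputs, and every simulated record carries ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .alignments import AlignmentTable
from .chef import ChefMeasurement, LadderCalibration, hansenula_ladder
from .reference import GenomicRegion, ReferenceModel
from .targeted import DropletAssay

__all__ = [
    "SimConfig",
    "ReadSimulation",
    "FishStack",
    "build_reference",
    "simulate_reads",
    "simulate_droplets",
    "simulate_smmip_reads",
    "simulate_chef_measurement",
    "simulate_fish_stack",
]

_CHROM = "chr_sim"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


def _default_probes() -> dict[str, float]:
    # two repeat-targeting probes and four single-copy loci, as in a
    # typical smMIP panel with a normalization plasmid
    return {
        "rdna_1": 1.0,
        "rdna_2": 1.0,
        "sc_1": 1.0,
        "sc_2": 1.0,
        "sc_3": 1.0,
        "sc_4": 1.0,
    }


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Geometry defaults keep the repeat array a small fraction of the genome
    (as for real rDNA loci: a few percent at high copy number), so the
    relative-read estimator's structural bias from extra repeat reads in
    the denominator stays below ~1% even at 412 copies.
    """

    seed: int = 0
    true_copy_number: float = 150.0
    genome_length: int = 8_000_000  # collapsed reference length (bp)
    repeat_unit_length: int = 200
    repeat_gc: float = 0.42
    background_gc: float = 0.50
    gc_bias_mode: str = "none"  # none | unimodal
    gc_bias_center: float = 0.50
    gc_bias_width: float = 0.10
    fragment_mean: int = 300
    fragment_sd: int = 20
    read_length: int = 75
    n_read_pairs: int = 500_000
    plasmid_to_genome_molar_ratio: float = 19.0
    probe_efficiencies: dict[str, float] = field(default_factory=_default_probes)
    capture_events_per_copy: float = 100.0
    smmip_duplicate_rate: float = 2.0
    smmip_ambiguous_rate: float = 0.0
    droplet_count: int = 20_000
    droplet_volume: float = 0.85  # nL

    def __post_init__(self) -> None:
        if self.true_copy_number < 1:
            raise ValueError("true_copy_number must be >= 1")
        if self.repeat_unit_length < self.read_length:
            raise ValueError("repeat_unit_length must be >= read_length")
        if self.fragment_mean <= self.read_length:
            raise ValueError("fragment_mean must exceed read_length")
        if self.genome_length < 10 * self.repeat_unit_length:
            raise ValueError("genome_length must be >= 10 * repeat_unit_length")
        if self.gc_bias_mode not in ("none", "unimodal"):
            raise ValueError("gc_bias_mode must be 'none' or 'unimodal'")
        if not 0.0 <= self.gc_bias_center <= 1.0:
            raise ValueError("gc_bias_center must lie in [0, 1]")
        if self.gc_bias_width <= 0:
            raise ValueError("gc_bias_width must be positive")
        for name, frac in (("repeat_gc", self.repeat_gc), ("background_gc", self.background_gc)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.plasmid_to_genome_molar_ratio <= 0:
            raise ValueError("plasmid_to_genome_molar_ratio must be positive")
        if not self.probe_efficiencies:
            raise ValueError("probe set must not be empty")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per simulation stage."""
        return np.random.default_rng([self.seed, stream])


def _exact_gc_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Byte array (ACGT codes) with G+C count fixed to round(gc * length)."""
    n_gc = int(round(gc * length))
    n_at = length - n_gc
    codes = np.empty(length, dtype=np.uint8)
    codes[: n_gc // 2] = ord("G")
    codes[n_gc // 2 : n_gc] = ord("C")
    codes[n_gc : n_gc + n_at // 2] = ord("A")
    codes[n_gc + n_at // 2 :] = ord("T")
    rng.shuffle(codes)
    return codes


N_CONTROL_REGIONS = 29


def build_reference(config: SimConfig) -> ReferenceModel:
    """Toy single-chromosome reference with one collapsed repeat unit.

    The repeat unit (GC composition settable independently of background)
    is spliced in at one third of the genome; 29 disjoint single-copy
    control regions of the unit length are recorded downstream of it for
    the coverage-inflation audit.
    """
    G, L = config.genome_length, config.repeat_unit_length
    rng = config.rng(0)
    seq = _exact_gc_sequence(G, config.background_gc, rng)
    rep_start = G // 3
    seq[rep_start : rep_start + L] = _exact_gc_sequence(L, config.repeat_gc, rng)
    repeat_region = GenomicRegion(_CHROM, rep_start, rep_start + L)

    margin = max(2_000, 2 * config.fragment_mean)
    lo = rep_start + L + margin
    hi = G - margin - L
    span = hi - lo
    if span < N_CONTROL_REGIONS * L:
        raise ValueError(
            "genome too small to place control regions: need "
            f"{N_CONTROL_REGIONS * L} bp downstream of the repeat, have {max(span, 0)}"
        )
    step = span // N_CONTROL_REGIONS
    controls = [
        GenomicRegion(_CHROM, lo + i * step, lo + i * step + L)
        for i in range(N_CONTROL_REGIONS)
    ]
    return ReferenceModel(
        genome_length=G,
        repeat_region=repeat_region,
        repeat_unit_length=L,
        control_regions=controls,
        sequences={_CHROM: seq.tobytes().decode("ascii")},
    )


def _truncated_normal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=n - filled)).astype(np.int64)
        draw = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
    return out


@dataclass
class SimTruth:
    """Ground truth for one read simulation (one entry per record)."""

    true_copy_number: float
    expanded_start: np.ndarray  # record start in the expanded genome
    copy_index: np.ndarray  # repeat copy of origin, -1 for background
    pair_id: np.ndarray
    fragment_gc: np.ndarray  # per record, GC fraction of its fragment


@dataclass
class ReadSimulation:
    """Paired-read simulation output: collapsed-coordinate truth alignments
    plus per-record ground truth. Records are interleaved (mate1, mate2)."""

    config: SimConfig
    reference: ReferenceModel
    alignments: AlignmentTable
    truth: SimTruth
    multi_mapping: np.ndarray  # record wholly inside the repeat array

    @property
    def n_records(self) -> int:
        return len(self.alignments)

    def _expanded_sequence(self) -> np.ndarray:
        cfg, ref = self.config, self.reference
        seq = np.frombuffer(ref.sequences[_CHROM].encode("ascii"), dtype=np.uint8)
        rs, re_ = ref.repeat_region.start, ref.repeat_region.end
        L = ref.repeat_unit_length
        n_full = int(math.floor(cfg.true_copy_number))
        partial = int(round((cfg.true_copy_number - n_full) * L))
        unit = seq[rs:re_]
        return np.concatenate([seq[:rs], np.tile(unit, n_full), unit[:partial], seq[re_:]])

    def write_sam(self, path: str | Path) -> None:
        """Truth alignments as SAM (collapsed reference coordinates)."""
        ref = self.reference
        aln, truth = self.alignments, self.truth
        R = self.config.read_length
        expanded = self._expanded_sequence()
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": _CHROM, "LN": ref.genome_length}],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i in range(len(aln)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"sim_pair_{truth.pair_id[i]}"
                raw = expanded[truth.expanded_start[i] : truth.expanded_start[i] + R]
                if aln.is_reverse[i]:
                    raw = _COMPLEMENT[raw[::-1]]
                rec.query_sequence = raw.tobytes().decode("ascii")
                rec.query_qualities = pysam.qualitystring_to_array("I" * R)
                rec.reference_id = 0
                rec.reference_start = int(aln.start[i])
                rec.mapping_quality = int(aln.mapq[i])
                rec.cigarstring = f"{R}M"
                rec.is_paired = True
                rec.is_proper_pair = True
                rec.is_reverse = bool(aln.is_reverse[i])
                rec.mate_is_reverse = not rec.is_reverse
                rec.is_read1 = not bool(aln.is_reverse[i])
                rec.is_read2 = bool(aln.is_reverse[i])
                mate = i + 1 if i % 2 == 0 else i - 1
                rec.next_reference_id = 0
                rec.next_reference_start = int(aln.start[mate])
                out.write(rec)

    def write_fastq(self, path_r1: str | Path, path_r2: str | Path) -> None:
        aln, truth = self.alignments, self.truth
        R = self.config.read_length
        expanded = self._expanded_sequence()
        qual = "I" * R
        with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
            for i in range(0, len(aln), 2):
                pid = truth.pair_id[i]
                s1 = expanded[truth.expanded_start[i] : truth.expanded_start[i] + R]
                s2 = expanded[truth.expanded_start[i + 1] : truth.expanded_start[i + 1] + R]
                s2 = _COMPLEMENT[s2[::-1]]
                f1.write(f"@sim_pair_{pid}/1\n{s1.tobytes().decode()}\n+\n{qual}\n")
                f2.write(f"@sim_pair_{pid}/2\n{s2.tobytes().decode()}\n+\n{qual}\n")


def simulate_reads(ref: ReferenceModel, config: SimConfig) -> ReadSimulation:
    """Draw GC-bias-weighted paired fragments from the expanded genome.

    Fragments start uniformly on the expanded genome (repeat unit tiled
    ``true_copy_number`` times); lengths are truncated normal; under
    ``gc_bias_mode='unimodal'`` a fragment of GC fraction ``g`` is accepted
    with probability ``exp(-(g - center)^2 / (2 width^2))``. Each fragment
    yields a forward mate at its left end and a reverse mate at its right
    end. Truth alignments map every record to collapsed-reference
    coordinates; records wholly inside the repeat array are flagged
    multi-mapping and placed within the single collapsed unit.
    """
    cfg = config
    G, L, R = ref.genome_length, ref.repeat_unit_length, cfg.read_length
    rs, re_ = ref.repeat_region.start, ref.repeat_region.end
    seq = np.frombuffer(ref.sequences[ref.repeat_region.name].encode("ascii"), dtype=np.uint8)
    is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(np.uint8)

    n_full = int(math.floor(cfg.true_copy_number))
    partial = int(round((cfg.true_copy_number - n_full) * L))
    unit_gc = is_gc[rs:re_]
    expanded_gc = np.concatenate(
        [is_gc[:rs], np.tile(unit_gc, n_full), unit_gc[:partial], is_gc[re_:]]
    )
    array_len = n_full * L + partial
    E = len(expanded_gc)
    delta = array_len - L
    cs = np.concatenate([[0], np.cumsum(expanded_gc, dtype=np.int64)])

    rng = cfg.rng(1)
    n_target = cfg.n_read_pairs
    frag_start_parts, frag_len_parts, frag_gc_parts = [], [], []
    n_accepted, n_drawn = 0, 0
    lo_len, hi_len = 2 * R, min(2_000, E)
    while n_accepted < n_target:
        batch = max(int((n_target - n_accepted) * 1.4) + 1_000, 10_000)
        lens = _truncated_normal_lengths(rng, batch, cfg.fragment_mean, cfg.fragment_sd, lo_len, hi_len)
        starts = np.floor(rng.random(batch) * (E - lens + 1)).astype(np.int64)
        gcs = (cs[starts + lens] - cs[starts]) / lens
        if cfg.gc_bias_mode == "unimodal":
            w = np.exp(-((gcs - cfg.gc_bias_center) ** 2) / (2.0 * cfg.gc_bias_width**2))
            keep = rng.random(batch) < w
        else:
            keep = np.ones(batch, dtype=bool)
        n_drawn += batch
        frag_start_parts.append(starts[keep])
        frag_len_parts.append(lens[keep])
        frag_gc_parts.append(gcs[keep])
        n_accepted += int(keep.sum())
        if n_drawn >= 200 * n_target + 100_000 and n_accepted == 0:
            raise RuntimeError(
                "degenerate GC bias: no fragment accepted after "
                f"{n_drawn} draws (center={cfg.gc_bias_center}, width={cfg.gc_bias_width})"
            )

    fs = np.concatenate(frag_start_parts)[:n_target]
    fl = np.concatenate(frag_len_parts)[:n_target]
    fgc = np.concatenate(frag_gc_parts)[:n_target]
    fe = fs + fl

    # interleave mates: even records forward (fragment left end), odd reverse
    n_rec = 2 * n_target
    exp_start = np.empty(n_rec, dtype=np.int64)
    exp_start[0::2] = fs
    exp_start[1::2] = fe - R
    is_rev = np.zeros(n_rec, dtype=bool)
    is_rev[1::2] = True
    pair_id = np.repeat(np.arange(n_target, dtype=np.int64), 2)
    frag_gc_rec = np.repeat(fgc, 2)

    # Collapse by the fragment-facing anchor (start of a forward record, last
    # aligned base of a reverse one): a multi-mapper's placement within the
    # single collapsed unit is chosen so its anchor keeps its within-unit
    # offset. Records near copy junctions may then overhang the unit ends,
    # as junction-spanning alignments do on a collapsed reference.
    anchor = np.where(is_rev, exp_start + R - 1, exp_start)
    anchor_in_array = (anchor >= rs) & (anchor < rs + array_len)
    coll_anchor = np.where(
        anchor_in_array,
        rs + (anchor - rs) % L,
        np.where(anchor >= rs + array_len, anchor - delta, anchor),
    )
    collapsed = np.where(is_rev, coll_anchor - R + 1, coll_anchor)
    fully_in_array = (exp_start >= rs) & (exp_start + R <= rs + array_len)
    copy_index = np.where(anchor_in_array, (anchor - rs) // L, -1)

    aln = AlignmentTable(
        ref_names=[ref.repeat_region.name],
        ref_id=np.zeros(n_rec, dtype=np.int32),
        start=collapsed,
        end=collapsed + R,
        is_reverse=is_rev,
        mapq=np.where(fully_in_array, 0, 60).astype(np.int16),
    )
    truth = SimTruth(
        true_copy_number=cfg.true_copy_number,
        expanded_start=exp_start,
        copy_index=copy_index.astype(np.int64),
        pair_id=pair_id,
        fragment_gc=frag_gc_rec,
    )
    return ReadSimulation(
        config=cfg,
        reference=ref,
        alignments=aln,
        truth=truth,
        multi_mapping=fully_in_array,
    )


def simulate_droplets(
    c_target: float,
    c_reference: float,
    config: SimConfig,
    reference_copies_per_genome: float = 1.0,
) -> tuple[DropletAssay, pd.DataFrame]:
    """Poisson droplet partitioning for a paired target/reference reaction.

    ``c_target``/``c_reference`` are concentrations in copies per nL; each
    droplet of volume ``v`` receives independent Poisson(c*v) molecules per
    channel and reads positive when it holds at least one. Returns the
    assay counts and the per-droplet true occupancies.
    """
    if config.droplet_count <= 0:
        raise ValueError("droplet_count must be positive")
    if c_target < 0 or c_reference < 0:
        raise ValueError("concentrations must be non-negative")
    rng = config.rng(2)
    n, v = config.droplet_count, config.droplet_volume
    occ_t = rng.poisson(c_target * v, size=n)
    occ_r = rng.poisson(c_reference * v, size=n)
    assay = DropletAssay(
        n_droplets=n,
        positives_target=int((occ_t > 0).sum()),
        positives_reference=int((occ_r > 0).sum()),
        droplet_volume=v,
        reference_copies_per_genome=reference_copies_per_genome,
    )
    truth = pd.DataFrame({"target_molecules": occ_t, "reference_molecules": occ_r})
    return assay, truth


_UMI_LENGTH = 12


def simulate_smmip_reads(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """smMIP capture read table with a co-captured normalization plasmid.

    Per probe, unique capture events are Poisson with mean
    ``efficiency * template_copies * capture_events_per_copy`` where
    template copies are ``true_copy_number`` (genomic, repeat probes), 1
    (genomic, single-copy probes) and the plasmid:genome molar ratio
    (plasmid templates, both probe classes). Every event gets a random
    12-bp UMI and >= 1 reads sharing it; the read's allele is 'G' for
    genomic templates and 'P' for plasmid, with an optional ambiguous-read
    rate emitting 'N'. Returns ``(reads, truth)`` where truth holds the
    true event counts per probe and source.
    """
    rng = config.rng(3)
    cfg = config
    rows_probe, rows_umi, rows_allele = [], [], []
    truth_rows = []
    for probe_id, eff in cfg.probe_efficiencies.items():
        is_rdna = str(probe_id).startswith("rdna")
        for source, copies in (
            ("genomic", cfg.true_copy_number if is_rdna else 1.0),
            ("plasmid", cfg.plasmid_to_genome_molar_ratio),
        ):
            n_events = int(rng.poisson(eff * copies * cfg.capture_events_per_copy))
            truth_rows.append(
                {"probe_id": probe_id, "source": source, "true_events": n_events}
            )
            if n_events == 0:
                continue
            umi_codes = _BASES[rng.integers(0, 4, size=(n_events, _UMI_LENGTH))]
            umis = [u.tobytes().decode("ascii") for u in umi_codes]
            n_reads = 1 + rng.poisson(cfg.smmip_duplicate_rate, size=n_events)
            rep_umis = np.repeat(np.asarray(umis, dtype=object), n_reads)
            alleles = np.full(len(rep_umis), "G" if source == "genomic" else "P", dtype=object)
            if cfg.smmip_ambiguous_rate > 0:
                amb = rng.random(len(alleles)) < cfg.smmip_ambiguous_rate
                alleles[amb] = "N"
            rows_probe.append(np.full(len(rep_umis), probe_id, dtype=object))
            rows_umi.append(rep_umis)
            rows_allele.append(alleles)
    if not rows_probe:
        reads = pd.DataFrame(columns=["probe_id", "umi", "allele"])
    else:
        reads = pd.DataFrame(
            {
                "probe_id": np.concatenate(rows_probe),
                "umi": np.concatenate(rows_umi),
                "allele": np.concatenate(rows_allele),
            }
        )
        # shuffle rows so downstream code cannot rely on generation order
        reads = reads.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
            drop=True
        )
    return reads, pd.DataFrame(truth_rows)


def simulate_chef_measurement(
    true_copies: float,
    unit_length: int,
    flank_left: int = 0,
    flank_right: int = 0,
    ladder: LadderCalibration | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> list[ChefMeasurement]:
    """Gel band measurements for an array of ``true_copies`` units.

    The true band size ``copies*unit + flanks`` acquires multiplicative
    measurement noise (Gaussian on log size, ``noise_sd`` in log-units) and
    is pushed through the inverse ladder map to a migration distance, which
    is what a gel image actually provides.
    """
    if ladder is None:
        ladder = hansenula_ladder()
    rng = np.random.default_rng([seed, 4])
    true_size = true_copies * unit_length + flank_left + flank_right
    out = []
    for _ in range(n_replicates):
        size = float(np.exp(np.log(true_size) + rng.normal(0.0, noise_sd))) if noise_sd > 0 else true_size
        out.append(
            ChefMeasurement(
                unit_length=unit_length,
                migration=ladder.migration_of(size),
                flank_left=flank_left,
                flank_right=flank_right,
            )
        )
    return out


@dataclass
class FishStack:
    """Two-channel 3-D stack (DAPI nuclei + FISH foci) with ground truth."""

    dapi: np.ndarray  # (z, y, x) float32
    fish: np.ndarray
    cells: pd.DataFrame  # cell, center, n_foci, total_intensity
    foci: pd.DataFrame  # cell, z, y, x, intensity


def simulate_fish_stack(
    n_cells: int,
    copy_number: float,
    intensity_per_copy: float = 20.0,
    p_two_foci: float = 0.76,
    psf_sigma: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    cell_box: tuple[int, int, int] = (16, 40, 40),
    foci_min_separation: float = 8.0,
) -> FishStack:
    """Render dissociated cells on a grid, one nucleus per grid box.

    Each cell draws 1 or 2 foci (P(two) = ``p_two_foci``, matching the
    one-or-two nucleolar foci seen in embryonic cells); the per-cell total
    FISH intensity is ``intensity_per_copy * copy_number`` split randomly
    across its foci, each rendered as a 3-D Gaussian (kernel normalized to
    unit sum, so integrated intensity is exact) plus additive Gaussian
    noise. The DAPI channel renders nuclei as filled ellipsoids.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng([seed, 5])
    bz, by, bx = cell_box
    ncols = int(math.ceil(math.sqrt(n_cells)))
    nrows = int(math.ceil(n_cells / ncols))
    shape = (bz, nrows * by, ncols * bx)
    dapi = np.zeros(shape, dtype=np.float32)
    fish = np.zeros(shape, dtype=np.float32)

    rad_z, rad_y, rad_x = 0.28 * bz, 0.30 * by, 0.30 * bx
    zz = np.arange(bz)[:, None, None]
    yy = np.arange(by)[None, :, None]
    xx = np.arange(bx)[None, None, :]

    cells_rows, foci_rows = [], []
    total = intensity_per_copy * copy_number
    kr = int(math.ceil(4 * psf_sigma))
    kz, ky, kx = np.meshgrid(
        np.arange(-kr, kr + 1), np.arange(-kr, kr + 1), np.arange(-kr, kr + 1), indexing="ij"
    )
    kernel = np.exp(-(kz**2 + ky**2 + kx**2) / (2.0 * psf_sigma**2))
    kernel /= kernel.sum()

    for cell in range(n_cells):
        row, col = divmod(cell, ncols)
        oy, ox = row * by, col * bx
        cz = bz / 2.0
        cy = by / 2.0 + rng.uniform(-2, 2)
        cx = bx / 2.0 + rng.uniform(-2, 2)
        mask = (
            ((zz - cz) / rad_z) ** 2 + ((yy - cy) / rad_y) ** 2 + ((xx - cx) / rad_x) ** 2
        ) <= 1.0
        dapi[:, oy : oy + by, ox : ox + bx][mask] += 100.0

        k = 2 if rng.random() < p_two_foci else 1
        if k == 1:
            fractions = [1.0]
        else:
            f = rng.uniform(0.3, 0.7)
            fractions = [f, 1.0 - f]
        centers = []
        for frac in fractions:
            for _ in range(50):
                dz = rng.uniform(-0.5, 0.5) * rad_z
                dy = rng.uniform(-0.6, 0.6) * rad_y
                dx = rng.uniform(-0.6, 0.6) * rad_x
                pos = (cz + dz, cy + dy, cx + dx)
                if all(
                    math.dist(pos, prev) >= foci_min_separation for prev in centers
                ):
                    break
            centers.append(pos)
            pz, py, px = (int(round(p)) for p in pos)
            z0, z1 = max(0, pz - kr), min(bz, pz + kr + 1)
            y0, y1 = max(0, py - kr), min(by, py + kr + 1)
            x0, x1 = max(0, px - kr), min(bx, px + kr + 1)
            sub = kernel[
                z0 - (pz - kr) : z1 - (pz - kr),
                y0 - (py - kr) : y1 - (py - kr),
                x0 - (px - kr) : x1 - (px - kr),
            ]
            fish[z0:z1, oy + y0 : oy + y1, ox + x0 : ox + x1] += frac * total * sub
            foci_rows.append(
                {
                    "cell": cell,
                    "z": pz,
                    "y": oy + py,
                    "x": ox + px,
                    "intensity": frac * total,
                }
            )
        cells_rows.append(
            {
                "cell": cell,
                "center_z": cz,
                "center_y": oy + cy,
                "center_x": ox + cx,
                "n_foci": k,
                "total_intensity": total,
            }
        )

    if noise_sd > 0:
        fish += rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
        dapi += rng.normal(0.0, 2.0, size=shape).astype(np.float32)
    return FishStack(
        dapi=dapi,
        fish=fish,
        cells=pd.DataFrame(cells_rows),
        foci=pd.DataFrame(foci_rows),
    )
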