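# Methods

This note records the models behind each estimator, the synthetic-data
generator's assumptions, the numerical choices that were genuinely open,
and what the test suite does and does not establish about real data.

## Read-depth estimation

### Relative read (RR)

`c_RR = (N_rep · G)/(N_tot · L_r)` over mapped records. Counting rules:
each mate is one record, duplicates retained, no mapping-quality filter.
Region membership supports three rules — `overlap` (≥ 1 base of the
aligned span; the default, matching samtools regional-view semantics),
`start` (leftmost coordinate containment), and `anchor` (containment of
the fragment-facing end: the start of a forward record, the last aligned
base of a reverse one). The counting region and the unit length are
independent parameters, because the natural counting span of an array
locus (flanking partial units included) can exceed one unit; the bundled
*C. elegans* constants use a 10,735 bp span over a 7,197 bp unit and a
100,286,070 bp genome.

Two systematic terms are worth knowing. First, RR divides by the collapsed
genome length while the true genome carries `(c−1)·L_r` extra repeat bases
in the denominator's read pool, giving a relative downward bias of
`(c−1)L_r/(G+(c−1)L_r)` — about 3% for a 400-copy worm array and ~1% at
the synthetic defaults. Second, overlap counting adds `≈ 2(R−1)/L` extra
counts from reads straddling region edges; negligible for multi-kilobase
regions, which is why the control-region audit (regions of unit length,
possibly short) uses anchor counting instead.

### GC correction (GCC)

Fragment recovery in tagmentation libraries depends on fragment GC. The
model: each record's anchor occurs as Poisson with rate `λ(g)` where `g`
is the GC fraction of the `W`-base window adjacent to the anchor (forward:
window starting at the record start; reverse: window ending at the record
end — both approximate the fragment when `W` is near the fragment length).
`λ` is fitted per GC bin on background (non-repeat) positions, where copy
number is one: `λ_b` = anchors at background slots in bin `b` / eligible
slots in bin `b`, with each position contributing one forward and one
reverse slot and windows containing non-ACGT bases excluded.

The corrected estimate is

    c_GCC = RR_anchor × (mean genome rate / mean repeat rate)

where the repeat-mean weights `λ_b` by the repeat's window-GC distribution
and the genome-mean by all slots. Two details:

* **Periodic repeat windows.** Inside a tandem array the sequence
  following a unit is the next copy, not the flank, so repeat window GCs
  are computed on the tiled unit. On the collapsed reference this matters
  within `W` of the unit's 3′ end — a 4% sliver at worm scale but the
  whole unit at the synthetic scale.
* **Flat-profile reduction.** A constant profile carries no information;
  the correction is identically 1 and `c_GCC` equals the anchor-counted RR
  exactly (the ratio is short-circuited rather than computed, to avoid
  summation roundoff breaking the exact identity).

Defaults: `W = 300` (matched to the fragment scale so window GC proxies
fragment GC), 100 bins of width 0.01 over [0, 1], bins with fewer than 100
eligible slots merged into their better-populated neighbor, and repeat
bins never seen in background borrowing the nearest fitted bin. The 1%
bin width matters: the acceptance weight varies severalfold across a 5%
bin near the profile's flanks, and the resulting within-bin mismatch
between where background and repeat positions sit leaves a residual bias
of up to ~15%; at 1% width it is below 1% while bins stay well populated
on genomes of a few megabases and up.

The audit (`estimate_control_regions`) applies RR to single-copy regions
(unit length = region length); its mean sits near 1.0 for a well-behaved
library. `downsample_estimates` re-estimates on record-level Bernoulli
subsamples to separate coverage noise from library-preparation error.

## ddPCR

Positive fraction `p = k/n` inverts through the Poisson zero class,
`λ = −ln(1−p)/v` copies per nL (droplet volume default 0.85 nL, the
industry-standard droplet size, always explicit). The 95% CI uses the
delta method on the binomial: `se(λ) = sqrt(p/(n(1−p)))/v`. Saturated
reactions (`k = n`) are an error — the zero class is empty and the assay
must be diluted. Copies per genome = concentration ratio × reference
copies per genome, with relative variances added (channel independence).

## smMIP

One capture event = one distinct (probe, UMI) pair. Source assignment uses
the diagnostic allele; reads of an event vote, the recognized majority
wins, exact ties and unrecognized-only events are dropped and tallied.
Per single-copy probe `j`, `P_j = plasmid_j/genomic_j` estimates plasmids
per genome; per repeat probe `m`, `c_m = (genomic_m/plasmid_m)·P`. Both
counts of each ratio share the probe, so capture efficiency cancels
exactly. Probes combine by median (robust to one failed probe;
configurable to mean — the choice only matters with discordant probes).
Note the plasmids-per-genome ratio must be plasmid over genomic; the
inverse is not consistent with the final correction.

## CHEF

Ladder calibration interpolates piecewise-linearly in (migration,
log size) — mobility is far closer to log-linear than linear — and is
exact at rungs; migrations outside the ladder error out ("beyond ladder
resolution"). Copies = (size − flank_left − flank_right)/unit, reported
rounded to an integer with the unrounded value retained. Workflow
conventions: the yeast BamHI digest subtracts 8,800 + 30,900 bp flanks;
the worm workflow divides total band size by 7,197 bp with no flank
subtraction (the SwaI flank constant ships for users who want it).
Replicate summaries use the sample (n−1) SD for CV; population SD does
not reproduce the benchmark tables' observed CV range. Minor bands are
converted independently and never averaged into the primary estimate
unless a strain is explicitly flagged as a doublet.

## FISH

Nuclei: global Otsu threshold + 3-D connected components, voxel-count
floor 50, optional watershed splitting of touching nuclei. Foci: local
maxima above `median + k_mad·MAD` (raw MAD, `k_mad = 5`) of the nucleus's
own voxels; integration over a sphere of radius 4·psf_sigma (≥ 99.8% of a
Gaussian spot's mass, so truncation loss stays under the 1% contract; a
3-sigma radius would lose 2.9%). Background is the median of nucleus
voxels *outside* all spot spheres — the plain nuclear median includes
spot tails and would subtract signal proportional to spot brightness,
breaking intensity linearity. Per-cell totals feed strain medians and
their Pearson/Spearman correlation against reference copy numbers; the
readout is relative, with absolute calibration only as a linear rescale
against a user-supplied reference strain. No cell-cycle correction is
applied (unsynchronized cells are pooled, assuming the stage distribution
does not differ between strains).

## Synthetic data

The generator produces every pipeline input with ground truth and is
deterministic per `SimConfig` (independent numbered RNG streams per
stage).

* **Genome**: one chromosome with exact-composition shuffled sequence
  (background GC 0.50, repeat unit GC 0.42 by default — displaced from
  background as real rDNA is from its genome), a single recorded unit,
  and 29 single-copy control regions of unit length downstream.
* **Reads**: fragments uniform on the expanded genome (unit tiled
  `true_copy_number` times, fractional final copy supported), lengths
  truncated normal (default 300 ± 20, bounds [2·read, 2000]), 75 bp mates
  at both fragment ends. Unimodal bias accepts a fragment of GC `g` with
  probability `exp(−(g−center)²/2·width²)` (center 0.50, width 0.10) — a
  standard stand-in for tagmentation bias, whose true shape is not
  published; the narrow fragment-length spread keeps window GC a faithful
  proxy for fragment GC, the quantity the bias acts on. Multi-mapping
  (array-internal) records collapse to the single reference unit
  preserving the within-unit offset of their fragment-facing anchor, so
  junction-spanning alignments overhang the unit ends exactly as they do
  on a real collapsed reference; such records carry MAPQ 0.
* **Default geometry** (8 Mb genome, 200 bp unit): chosen so the RR
  structural bias stays ≈ 1% at 412 copies while 20-seed × 500k-pair
  recovery runs in seconds per simulation. Unit length below real rDNA
  scale is compensated by the periodic-window treatment above.
* **Droplets**: independent Poisson occupancy per channel, positive ⇔ ≥ 1
  molecule. The standard two-channel benchmark uses per-droplet means 3.0
  (target) and 0.02 (reference) — both channels quantifiable at 20,000
  droplets at a 150:1 ratio.
* **smMIP**: events Poisson with mean efficiency × template copies ×
  events-per-copy; templates are `c` (genomic repeat), 1 (genomic
  single-copy), and the molar ratio (plasmid, default 19 — one part
  genomic DNA to 19 plasmid). Random 12-mer UMIs can collide; colliding
  templates merge on dedup (a real smMIP undercount mechanism).
* **CHEF**: band size `copies·unit + flanks` with Gaussian noise on log
  size, pushed through the inverse ladder map; the bundled ladder uses
  the *H. wingei* chromosome sizes with a realistically curved synthetic
  migration profile.
* **FISH**: nuclei as filled ellipsoids on a grid; 1 or 2 foci per cell
  (P(two) = 0.76, giving the observed ≈ 1.76 foci/cell), total intensity
  `intensity_per_copy × copies` split 30–70% across foci, rendered as
  sum-normalized 3-D Gaussians (σ = 1.5 voxels) plus additive noise.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing errors and quality scores, PCR
duplication chemistry, mappability/alignment ambiguity beyond the single
collapsed locus, real tagmentation's empirical bias shape, droplet
volume variation and rain, probe cross-hybridization, optical aberrations
and chromatic shift, and diploid/heterozygous arrays (single-band
assumption throughout). The benchmark tables are measured data and carry
the real between-replicate error; the synthetic tests verify mechanism,
not field performance.

## Problem sizes

The acceptance-style checks use 20 seeds × 500k read pairs per copy
number for read-depth recovery (minutes on one CPU), 100 seeds × 20,000
droplets for interval coverage, and six strains × 100 cells for the FISH
correlation; `scripts/acceptance.py` re-runs the same computations at 12
seeds × 250k pairs, sizes at which all reported means are stable to well
under a percentage point.

## Known limitations

* GCC accuracy depends on background support across the repeat's GC
  range; a repeat whose GC lies outside the background distribution's
  tails falls back to nearest-bin rates and degrades gracefully rather
  than failing.
* The ddPCR interval is a normal approximation; it undercovers slightly
  below ~300 positive droplets in a channel.
* FISH focus detection assumes diffraction-limited, well-separated spots;
  foci closer than the detection separation merge and undercount (the
  integrated intensity remains approximately conserved).
* CHEF conversion inherits ladder accuracy and cannot resolve bands
  beyond the ladder range; sub-unit precision is not meaningful and
  values are reported as whole copies.
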