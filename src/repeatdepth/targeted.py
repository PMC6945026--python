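"""Targeted copy-number assays: ddPCR and smMIP.

Droplet digital PCR partitions a reaction into ~20,000 nanoliter droplets.
Template molecules distribute into droplets as a Poisson process, so the
fraction of *negative* droplets estimates the Poisson zero class and the
template concentration follows as ``lambda = -ln(1 - p) / v`` for positive
fraction ``p`` and droplet volume ``v``. Running the repeat target and a
single-copy reference gene (e.g. TUB1) in the same reaction turns the two
concentrations into copies per genome.

Single-molecule molecular inversion probes (smMIPs) capture ~100-150 bp of
target, tagging every capture event with a random 12-bp unique molecular
identifier (UMI) so events can be counted once after sequencing. Capture
efficiency varies per probe; a spiked normalization plasmid carrying one
variant-marked copy of every target cancels that efficiency within each
probe, because genomic and plasmid templates compete for the same probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import CopyNumberEstimate

__all__ = [
    "DropletAssay",
    "CaptureTable",
    "ddpcr_lambda",
    "ddpcr_copy_number",
    "smmip_dedup",
    "smmip_estimate",
]

#: Default droplet volume in nL (QX200-class instruments).
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass
class DropletAssay:
    """Positive/total droplet counts for a paired target/reference ddPCR run."""

    n_droplets: int
    positives_target: int
    positives_reference: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_NL
    reference_copies_per_genome: float = 1.0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        for k in (self.positives_target, self.positives_reference):
            if not 0 <= k <= self.n_droplets:
                raise ValueError("positive count outside [0, n_droplets]")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive")


def ddpcr_lambda(k: int, n: int, v: float = DEFAULT_DROPLET_VOLUME_NL):
    """Template concentration (copies/nL) from ``k`` positive of ``n`` droplets.

    Returns ``(lam, (lo, hi))`` where the 95% CI comes from the normal
    approximation on the positive fraction propagated through
    ``-ln(1-p)``: se(lam) = sqrt(p / (n (1-p))) / v.

    Raises on ``n == 0`` and on saturation (``k == n``), where the zero
    class is empty and the concentration is unbounded.
    """
    if n <= 0:
        raise ValueError("need at least one droplet")
    if not 0 <= k <= n:
        raise ValueError("positive count outside [0, n]")
    if k == n:
        raise ValueError("all droplets positive: reaction saturated, dilute and rerun")
    if v <= 0:
        raise ValueError("droplet volume must be positive")
    p = k / n
    lam = -math.log1p(-p) / v
    se = math.sqrt(p / (n * (1.0 - p))) / v
    return lam, (max(0.0, lam - 1.96 * se), lam + 1.96 * se)


def ddpcr_copy_number(assay: DropletAssay) -> CopyNumberEstimate:
    """Copies per genome as the ratio of target to reference concentration.

    The interval propagates the two channel CIs assuming independence:
    relative variances add.
    """
    if assay.positives_reference == 0:
        raise ValueError("no positive reference droplets: cannot normalize")
    lam_t, ci_t = ddpcr_lambda(assay.positives_target, assay.n_droplets, assay.droplet_volume)
    lam_r, ci_r = ddpcr_lambda(assay.positives_reference, assay.n_droplets, assay.droplet_volume)
    ratio = lam_t / lam_r * assay.reference_copies_per_genome
    se_t = (ci_t[1] - lam_t) / 1.96
    se_r = (ci_r[1] - lam_r) / 1.96
    rel_se = math.sqrt((se_t / lam_t) ** 2 + (se_r / lam_r) ** 2) if lam_t > 0 else 0.0
    half = 1.96 * rel_se * ratio
    return CopyNumberEstimate(
        value=ratio,
        method="ddPCR",
        interval=(max(0.0, ratio - half), ratio + half),
        provenance={
            "positives_target": assay.positives_target,
            "positives_reference": assay.positives_reference,
            "n_droplets": assay.n_droplets,
            "lambda_target": lam_t,
            "lambda_reference": lam_r,
        },
    )


@dataclass
class CaptureTable:
    """Deduplicated smMIP capture events per probe, split by template source.

    ``counts`` has one row per probe with columns ``probe_id``,
    ``target_class`` (``rdna`` or ``single_copy``), ``genomic_events``,
    ``plasmid_events``. ``n_ambiguous`` records reads whose diagnostic
    allele matched neither source and were excluded.
    """

    counts: pd.DataFrame
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        required = {"probe_id", "target_class", "genomic_events", "plasmid_events"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"capture table missing columns: {sorted(missing)}")


def _class_from_probe_id(probe_id: str) -> str:
    return "rdna" if str(probe_id).startswith("rdna") else "single_copy"


def smmip_dedup(
    reads: pd.DataFrame,
    genomic_alleles: frozenset | set = frozenset({"G"}),
    plasmid_alleles: frozenset | set = frozenset({"P"}),
    probe_classes: dict[str, str] | None = None,
) -> CaptureTable:
    """Collapse an smMIP read table to unique capture events.

    ``reads`` needs columns ``probe_id``, ``umi``, ``allele``. One event is
    one distinct ``(probe_id, umi)`` pair — the UMI is the per-capture
    barcode, so reads sharing it at the same probe are PCR/sequencing
    copies of one capture. The diagnostic allele assigns each event to the
    genomic or plasmid template; events whose reads carry only unrecognized
    alleles are dropped and tallied in ``n_ambiguous``. When reads of one
    event disagree (a recognizable mixture), the majority recognized
    allele wins; exact ties drop the event as ambiguous.

    ``probe_classes`` maps probe id to ``rdna``/``single_copy``; by default
    the class is inferred from an ``rdna``/``sc`` probe-id prefix.
    """
    required = {"probe_id", "umi", "allele"}
    if reads.empty and not required <= set(reads.columns):
        raise ValueError("empty smMIP read table without required columns")
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"smMIP read table missing columns: {sorted(missing)}")

    df = reads[["probe_id", "umi", "allele"]].copy()
    df["source"] = np.where(
        df["allele"].isin(list(genomic_alleles)),
        "genomic",
        np.where(df["allele"].isin(list(plasmid_alleles)), "plasmid", "ambiguous"),
    )
    # votes per event: count recognized alleles per (probe, umi)
    votes = (
        df.pivot_table(
            index=["probe_id", "umi"],
            columns="source",
            values="allele",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=["genomic", "plasmid", "ambiguous"], fill_value=0)
        .reset_index()
    )
    g, p = votes["genomic"].to_numpy(), votes["plasmid"].to_numpy()
    call = np.where(g > p, "genomic", np.where(p > g, "plasmid", "ambiguous"))
    votes["call"] = call
    n_ambiguous = int((votes["call"] == "ambiguous").sum())
    events = votes[votes["call"] != "ambiguous"]

    all_probes = sorted(df["probe_id"].unique())
    table = (
        events.pivot_table(
            index="probe_id", columns="call", values="umi", aggfunc="count", fill_value=0
        )
        .reindex(index=all_probes, columns=["genomic", "plasmid"], fill_value=0)
        .reset_index()
        .rename(columns={"genomic": "genomic_events", "plasmid": "plasmid_events"})
    )
    if probe_classes is None:
        table["target_class"] = [_class_from_probe_id(p) for p in table["probe_id"]]
    else:
        table["target_class"] = [probe_classes[p] for p in table["probe_id"]]
    table = table[["probe_id", "target_class", "genomic_events", "plasmid_events"]]
    return CaptureTable(counts=table, n_ambiguous=n_ambiguous)


def smmip_estimate(
    table: CaptureTable,
    plasmid_copies_per_target: float = 1.0,
    aggregate: str = "median",
) -> CopyNumberEstimate:
    """Repeat copies per genome from plasmid-normalized capture counts.

    Per single-copy probe *j*, ``P_j = plasmid_j / genomic_j`` estimates
    plasmids per genome (the genomic template is at one copy). Per repeat
    probe *m*, ``c_m = (genomic_m / plasmid_m) * P``. Because both counts of
    each ratio come from the same probe, per-probe capture efficiency
    cancels exactly. Probes are combined by ``aggregate`` (``median`` for
    robustness to a failed probe, or ``mean``).
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    agg = np.median if aggregate == "median" else np.mean
    counts = table.counts
    sc = counts[counts["target_class"] == "single_copy"]
    rd = counts[counts["target_class"] == "rdna"]
    if sc.empty or rd.empty:
        raise ValueError("need at least one single-copy and one repeat probe")

    sc_ok = sc[(sc["genomic_events"] > 0) & (sc["plasmid_events"] > 0)]
    if sc_ok.empty:
        raise ValueError("no single-copy probe with events from both sources")
    plasmids_per_genome = float(
        agg(sc_ok["plasmid_events"].to_numpy() / sc_ok["genomic_events"].to_numpy())
    )

    rd_ok = rd[rd["plasmid_events"] > 0]
    if rd_ok.empty:
        raise ValueError("no repeat probe with plasmid events")
    per_probe = (
        rd_ok["genomic_events"].to_numpy() / rd_ok["plasmid_events"].to_numpy()
    ) * plasmids_per_genome / plasmid_copies_per_target
    value = float(agg(per_probe))
    return CopyNumberEstimate(
        value=value,
        method="smMIP",
        provenance={
            "plasmids_per_genome": plasmids_per_genome,
            "n_single_copy_probes": int(len(sc_ok)),
            "n_repeat_probes": int(len(rd_ok)),
            "per_probe_estimates": [float(x) for x in per_probe],
            "n_ambiguous_dropped": table.n_ambiguous,
            "aggregate": aggregate,
        },
    )
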