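"""FISH focus detection and integrated-intensity quantification.

A hybridization probe tiled across a tandem array produces nuclear foci
whose integrated (background-subtracted) intensity scales with the number
of repeat units under the probe — a *relative* copy-number readout at
single-cell resolution. The pipeline: segment nuclei from the DAPI
channel, detect intra-nuclear foci as 3-D local maxima above a robust
background threshold, integrate each focus over a fixed-radius sphere, and
compare per-cell totals across strains (optionally rescaling to absolute
copies against a reference strain of known copy number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

__all__ = [
    "FociTable",
    "segment_nuclei",
    "detect_foci",
    "strain_intensity_summary",
    "calibrate_absolute",
]


@dataclass
class FociTable:
    """Detected foci (one row each: cell, centroid, integrated intensity,
    size) plus per-cell focus counts."""

    foci: pd.DataFrame  # cell, z, y, x, intensity, size_voxels
    cells: pd.DataFrame  # cell, n_foci

    def per_cell_totals(self) -> pd.Series:
        """Total background-subtracted focus intensity per cell (cells with
        no detected focus contribute 0)."""
        totals = self.foci.groupby("cell")["intensity"].sum()
        return totals.reindex(self.cells["cell"], fill_value=0.0)


def segment_nuclei(
    dapi: np.ndarray,
    threshold: float | None = None,
    min_voxels: int = 50,
    split_touching: bool = False,
    min_seed_distance: int = 10,
) -> np.ndarray:
    """Label nuclei in a DAPI stack.

    Global Otsu threshold (overridable) + 3-D connected components;
    components below ``min_voxels`` are discarded. With ``split_touching``,
    merged components are re-split by marker-controlled watershed on the
    distance transform, with markers at distance-map maxima at least
    ``min_seed_distance`` voxels apart.
    """
    dapi = np.asarray(dapi)
    if dapi.size == 0 or np.allclose(dapi.max(), dapi.min()):
        return np.zeros(dapi.shape, dtype=np.int32)
    if threshold is None:
        threshold = threshold_otsu(dapi)
    mask = dapi > threshold
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    if split_touching:
        dist = ndimage.distance_transform_edt(mask)
        seeds = peak_local_max(
            dist, min_distance=min_seed_distance, labels=mask, exclude_border=False
        )
        markers = np.zeros(dapi.shape, dtype=np.int32)
        for i, s in enumerate(seeds, start=1):
            markers[tuple(s)] = i
        labels = watershed(-dist, markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)
    # drop small components and relabel contiguously
    out = np.zeros(dapi.shape, dtype=np.int32)
    next_id = 1
    for lab in range(1, int(labels.max()) + 1):
        comp = labels == lab
        if comp.sum() >= min_voxels:
            out[comp] = next_id
            next_id += 1
    return out


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    zz, yy, xx = np.meshgrid(
        np.arange(-r, r + 1), np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij"
    )
    keep = zz**2 + yy**2 + xx**2 <= radius**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def detect_foci(
    fish: np.ndarray,
    nuclei: np.ndarray,
    k_mad: float = 5.0,
    spot_radius: float = 6.0,
    min_separation: int | None = None,
) -> FociTable:
    """Detect and integrate FISH foci within segmented nuclei.

    Candidates are 3-D local maxima above ``median + k_mad * MAD`` of the
    voxels of their own nucleus (raw median absolute deviation). Each
    focus's integrated intensity is the sum of voxel values in a sphere of
    ``spot_radius`` (clipped at stack borders) minus the nuclear median
    background times the voxel count; ``size_voxels`` counts sphere voxels
    above half the peak (above background). Negative integrals are floored
    at zero. The default radius of four PSF sigmas captures > 99.8% of a
    Gaussian spot's mass, keeping truncation loss well under 1%.
    """
    fish = np.asarray(fish, dtype=float)
    n_cells = int(nuclei.max())
    cols = ["cell", "z", "y", "x", "intensity", "size_voxels"]
    if n_cells == 0:
        warnings.warn("no nuclei to search for foci", stacklevel=2)
        return FociTable(foci=pd.DataFrame(columns=cols), cells=pd.DataFrame(columns=["cell", "n_foci"]))
    if min_separation is None:
        min_separation = max(2, int(np.ceil(spot_radius / 1.5)))
    offsets = _sphere_offsets(spot_radius)
    shape = np.array(fish.shape)

    foci_rows = []
    cell_rows = []
    objects = ndimage.find_objects(nuclei)
    for cell in range(1, n_cells + 1):
        sl = objects[cell - 1]
        if sl is None:
            cell_rows.append({"cell": cell, "n_foci": 0})
            continue
        sub_img = fish[sl]
        sub_lab = nuclei[sl] == cell
        vals = sub_img[sub_lab]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        thr = med + k_mad * mad
        peaks = peak_local_max(
            sub_img,
            min_distance=min_separation,
            threshold_abs=thr,
            labels=sub_lab.astype(np.int32),
            exclude_border=False,
        )
        n_found = 0
        origin = np.array([s.start for s in sl])
        # local background from nucleus voxels outside every spot sphere —
        # the plain nuclear median includes spot tails and would subtract
        # signal proportional to spot brightness
        if len(peaks):
            spot_mask = np.zeros(sub_img.shape, dtype=bool)
            sub_shape = np.array(sub_img.shape)
            for pk in peaks:
                coords = pk[None, :] + offsets
                ok = np.all((coords >= 0) & (coords < sub_shape[None, :]), axis=1)
                spot_mask[tuple(coords[ok].T)] = True
            outside = sub_img[sub_lab & ~spot_mask]
            bg = float(np.median(outside)) if outside.size >= 20 else med
        else:
            bg = med
        for pk in peaks:
            center = origin + pk
            coords = center[None, :] + offsets
            inside = np.all((coords >= 0) & (coords < shape[None, :]), axis=1)
            cz, cy, cx = coords[inside].T
            voxels = fish[cz, cy, cx]
            integrated = float(voxels.sum() - bg * len(voxels))
            peak_val = float(fish[tuple(center)]) - bg
            half = bg + 0.5 * peak_val
            size = int((voxels > half).sum())
            foci_rows.append(
                {
                    "cell": cell,
                    "z": int(center[0]),
                    "y": int(center[1]),
                    "x": int(center[2]),
                    "intensity": max(0.0, integrated),
                    "size_voxels": size,
                }
            )
            n_found += 1
        cell_rows.append({"cell": cell, "n_foci": n_found})
    return FociTable(
        foci=pd.DataFrame(foci_rows, columns=cols),
        cells=pd.DataFrame(cell_rows, columns=["cell", "n_foci"]),
    )


def strain_intensity_summary(
    tables: dict[str, FociTable],
    reference_copies: dict[str, float] | None = None,
) -> dict:
    """Cross-strain summary of per-cell total focus intensity.

    Returns a per-strain table (cells, mean foci/cell, median and mean of
    per-cell totals, quartiles) and, when reference copy numbers are
    supplied for >= 2 strains, the Pearson and Spearman correlations of
    strain median intensity against reference copies (NaN when undefined,
    e.g. constant input).
    """
    rows = []
    for strain, table in tables.items():
        totals = table.per_cell_totals()
        rows.append(
            {
                "strain": strain,
                "n_cells": int(len(table.cells)),
                "mean_foci_per_cell": float(table.cells["n_foci"].mean())
                if len(table.cells)
                else float("nan"),
                "median_total_intensity": float(totals.median()),
                "mean_total_intensity": float(totals.mean()),
                "q25_total_intensity": float(totals.quantile(0.25)),
                "q75_total_intensity": float(totals.quantile(0.75)),
            }
        )
    summary = pd.DataFrame(rows)
    out = {"per_strain": summary, "pearson": float("nan"), "spearman": float("nan")}
    if reference_copies:
        matched = summary[summary["strain"].isin(reference_copies)]
        if len(matched) >= 2:
            x = np.array([reference_copies[s] for s in matched["strain"]])
            y = matched["median_total_intensity"].to_numpy()
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                out["pearson"] = float(sps.pearsonr(x, y).statistic)
                out["spearman"] = float(sps.spearmanr(x, y).statistic)
    return out


def calibrate_absolute(
    tables: dict[str, FociTable],
    reference_strain: str,
    reference_copies: float,
) -> pd.DataFrame:
    """Linear rescale of median intensities to absolute copies via one
    reference strain of known copy number (intensity is proportional to
    copies, so a single anchor fixes the scale)."""
    if reference_strain not in tables:
        raise KeyError(f"reference strain {reference_strain!r} not in tables")
    ref_median = tables[reference_strain].per_cell_totals().median()
    if ref_median <= 0:
        raise ValueError("reference strain has no measurable signal")
    scale = reference_copies / ref_median
    rows = [
        {
            "strain": strain,
            "median_total_intensity": float(t.per_cell_totals().median()),
            "estimated_copies": float(t.per_cell_totals().median() * scale),
        }
        for strain, t in tables.items()
    ]
    return pd.DataFrame(rows)
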