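"""Method-comparison statistics and the bundled benchmark tables.

Two benchmark tables ship with the package: replicate copy-number
estimates for eight C. elegans wild isolates (CHEF gel plus Nextera WGS at
two input masses, relative-read and GC-corrected) and for a panel of
S. cerevisiae strains (CHEF replicates, re-sequenced GC-corrected WGS, and
ddPCR triplicates). CHEF replicate means serve as the reference value per
strain — pulsed-field sizing against chromosomal ladders is the one method
calibrated by molecules of known size. The error statistic throughout is

    percent_error = 100 * |estimate - reference| / reference

computed against the *unrounded* CHEF replicate mean. One strain (B30)
lacks CHEF replicates in the table and carries a known copy number of 35,
used as its fixed reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BenchmarkTable",
    "ErrorSummary",
    "percent_error",
    "cv_percent",
    "pearson",
    "welch_t",
    "load_table1",
    "load_table2",
    "error_summary",
    "chef_replicate_summary",
    "reproduce_benchmark_tables",
]

#: Fixed reference copies for strains without CHEF replicates in the table.
REFERENCE_OVERRIDES = {"B30": 35.0}


def percent_error(estimate: float, reference: float) -> float:
    """100 * |estimate - reference| / reference. Reference must be > 0."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * abs(estimate - reference) / reference


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, 100 * sample SD / mean (NaN for n < 2)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        return float("nan")
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * vals.std(ddof=1) / mean)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either input is constant."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test: returns (statistic, p)."""
    res = sps.ttest_ind(list(values_a), list(values_b), equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BenchmarkTable:
    """Long-format replicate estimates plus per-strain reference values.

    ``data`` columns: strain, method, replicate, value (missing replicates
    simply absent). ``reference`` maps strain to its reference copy number
    (unrounded CHEF replicate mean, or a fixed override).
    """

    data: pd.DataFrame
    reference: dict[str, float]
    name: str = ""

    def methods(self) -> list[str]:
        return sorted(self.data["method"].unique())

    def values(self, method: str, strain: str | None = None) -> pd.DataFrame:
        sel = self.data[self.data["method"] == method]
        if strain is not None:
            sel = sel[sel["strain"] == strain]
        return sel


def _melt_methods(df: pd.DataFrame, method_reps: dict[str, list[str]]) -> pd.DataFrame:
    rows = []
    for _, row in df.iterrows():
        for method, cols in method_reps.items():
            for i, col in enumerate(cols, start=1):
                v = row.get(col)
                if pd.notna(v):
                    rows.append(
                        {"strain": row["strain"], "method": method, "replicate": i, "value": float(v)}
                    )
    return pd.DataFrame(rows)


def _chef_reference(df: pd.DataFrame, chef_cols: list[str]) -> dict[str, float]:
    ref = {}
    for _, row in df.iterrows():
        vals = [row[c] for c in chef_cols if pd.notna(row[c])]
        if vals:
            ref[row["strain"]] = float(np.mean(vals))
        elif row["strain"] in REFERENCE_OVERRIDES:
            ref[row["strain"]] = REFERENCE_OVERRIDES[row["strain"]]
    return ref


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("repeatdepth.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> BenchmarkTable:
    """Eight C. elegans wild isolates: CHEF triplicates and Nextera WGS
    (10/50 ng input, relative-read and GC-corrected, three replicates)."""
    df = _fixture("table1_celegans.csv")
    chef_cols = ["chef_rep1", "chef_rep2", "chef_rep3"]
    methods = {"chef": chef_cols}
    for method in ("rr_10ng", "gcc_10ng", "rr_50ng", "gcc_50ng"):
        methods[method] = [f"{method}_rep{i}" for i in (1, 2, 3)]
    return BenchmarkTable(
        data=_melt_methods(df, methods),
        reference=_chef_reference(df, chef_cols),
        name="table1_celegans",
    )


def load_table2() -> BenchmarkTable:
    """S. cerevisiae panel: CHEF replicates, re-sequenced GC-corrected WGS,
    and ddPCR triplicates, with strain roles (control vs wild isolate)."""
    df = _fixture("table2_scerevisiae.csv")
    chef_cols = ["chef_rep1", "chef_rep2", "chef_rep3"]
    methods = {
        "chef": chef_cols,
        "reseq_gcc": ["reseq_gcc"],
        "ddpcr": ["ddpcr_rep1", "ddpcr_rep2", "ddpcr_rep3"],
    }
    data = _melt_methods(df, methods)
    roles = dict(zip(df["strain"], df["role"]))
    data["role"] = data["strain"].map(roles)
    return BenchmarkTable(
        data=data,
        reference=_chef_reference(df, chef_cols),
        name="table2_scerevisiae",
    )


@dataclass
class ErrorSummary:
    """Per-measurement percent errors against the strain reference, with
    aggregates. ``rounded()`` gives the whole-percent presentation values;
    the raw errors stay available for recomputation."""

    method: str
    per_measurement: pd.DataFrame  # strain, replicate, value, reference, percent_error

    @property
    def errors(self) -> np.ndarray:
        return self.per_measurement["percent_error"].to_numpy()

    @property
    def mean(self) -> float:
        return float(self.errors.mean())

    @property
    def min(self) -> float:
        return float(self.errors.min())

    @property
    def max(self) -> float:
        return float(self.errors.max())

    @property
    def median(self) -> float:
        return float(np.median(self.errors))

    def rounded(self) -> dict:
        return {
            "mean": int(round(self.mean)),
            "min": int(round(self.min)),
            "max": int(round(self.max)),
            "median": int(round(self.median)),
            "n": int(len(self.per_measurement)),
        }


def error_summary(
    table: BenchmarkTable, method: str, strains: Sequence[str] | None = None
) -> ErrorSummary:
    """Percent errors of every replicate of ``method`` vs strain references.

    Strains without a resolvable reference are skipped with a warning;
    ``strains`` restricts the computation (e.g. wild isolates only).
    """
    sel = table.values(method)
    if strains is not None:
        sel = sel[sel["strain"].isin(list(strains))]
    if sel.empty:
        raise ValueError(f"no measurements for method {method!r}")
    rows = []
    for _, row in sel.iterrows():
        ref = table.reference.get(row["strain"])
        if ref is None:
            warnings.warn(
                f"strain {row['strain']} has no reference value; skipped", stacklevel=2
            )
            continue
        rows.append(
            {
                "strain": row["strain"],
                "replicate": row["replicate"],
                "value": row["value"],
                "reference": ref,
                "percent_error": percent_error(row["value"], ref),
            }
        )
    return ErrorSummary(method=method, per_measurement=pd.DataFrame(rows))


def chef_replicate_summary(table: BenchmarkTable) -> pd.DataFrame:
    """Per-strain CHEF replicate mean and CV% (strains with >= 2 reps)."""
    rows = []
    for strain, grp in table.values("chef").groupby("strain", sort=True):
        vals = grp["value"].to_numpy()
        rows.append(
            {
                "strain": strain,
                "n": len(vals),
                "mean": float(vals.mean()),
                "mean_rounded": int(round(vals.mean())),
                "cv_percent": cv_percent(vals),
            }
        )
    return pd.DataFrame(rows)


def reproduce_benchmark_tables() -> dict:
    """Recompute every headline benchmark figure from the bundled tables.

    Returns a deterministic report: each entry has the recomputed value,
    the expected presentation value, and a pass flag (comparison at the
    presentation rounding). ``all_pass`` summarizes.
    """
    t1, t2 = load_table1(), load_table2()
    report: dict[str, dict] = {}

    def check(name: str, value: float, expected: float, rounded: bool = True) -> None:
        shown = int(round(value)) if rounded else value
        report[name] = {
            "value": float(value),
            "presentation": shown,
            "expected": expected,
            "pass": bool(shown == expected),
        }

    # WGS error summaries, 8 strains x 3 replicates each
    for method, expected in (
        ("rr_10ng", 18),
        ("rr_50ng", 58),
        ("gcc_10ng", 15),
        ("gcc_50ng", 29),
    ):
        check(f"wgs_{method}_mean_pct_error", error_summary(t1, method).mean, expected)

    # CHEF replicate concordance
    chef = chef_replicate_summary(t1)
    cvs = chef["cv_percent"].to_numpy()
    check("chef_cv_min_pct", cvs.min(), 3)
    check("chef_cv_max_pct", cvs.max(), 15)
    check("chef_cv_median_pct", float(np.median(cvs)), 6)
    check("chef_mean_MY1", float(chef.loc[chef["strain"] == "MY1", "mean"].iloc[0]), 412)
    check("chef_mean_JU775", float(chef.loc[chef["strain"] == "JU775", "mean"].iloc[0]), 70)

    # ddPCR vs CHEF references
    dd = error_summary(t2, "ddpcr")
    check("ddpcr_mean_pct_error", dd.mean, 22)
    check("ddpcr_max_pct_error", dd.max, 41)

    # re-sequenced GC-corrected WGS over the 14 wild strains
    wild = sorted(t2.data.loc[t2.data["role"] == "wild", "strain"].unique())
    reseq = error_summary(t2, "reseq_gcc", strains=wild)
    check("reseq_gcc_mean_pct_error", reseq.mean, 18)
    report["reseq_gcc_n_strains"] = {
        "value": float(len(reseq.per_measurement)),
        "presentation": len(reseq.per_measurement),
        "expected": 14,
        "pass": len(reseq.per_measurement) == 14,
    }

    report["all_pass"] = all(
        entry["pass"] for name, entry in report.items() if isinstance(entry, dict)
    )
    return report
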