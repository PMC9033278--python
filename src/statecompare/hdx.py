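"""Peptide-level differential hydrogen-deuterium exchange (HDX-MS) analysis.

Relative deuterium uptake is measured per peptide over a ladder of exposure
times in two states (e.g. wild-type vs a pocket-entrance mutant).  The summed
difference in uptake across all timepoints, tested against a global
pooled-variance confidence threshold (Wood's-plot style), classifies each
peptide as deprotected (more uptake in state B), protected, or unchanged;
significant peptides are then mapped onto contiguous residue regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeptideUptakeTable",
    "CoverageStats",
    "DifferentialResult",
    "UptakeFormatError",
    "load_uptake_table",
    "coverage_stats",
    "differential_uptake",
    "uptake_curves",
    "map_regions",
]

REQUIRED_COLUMNS = ["peptide", "start", "end", "state", "exposure_min",
                    "replicate", "uptake_Da"]


class UptakeFormatError(ValueError):
    """Raised for malformed uptake tables."""


@dataclass
class PeptideUptakeTable:
    """Peptide x exposure x replicate uptake rows for one (or more) states."""

    data: pd.DataFrame
    protein_length: int

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise UptakeFormatError(f"missing columns: {missing}")
        if len(df) == 0:
            raise UptakeFormatError("empty uptake table")
        if (df["start"] < 1).any():
            raise UptakeFormatError("residue numbering is 1-based: start >= 1 required")
        if (df["end"] < df["start"]).any():
            raise UptakeFormatError("peptide end < start")
        if (df["end"] > self.protein_length).any():
            raise UptakeFormatError("peptide extends beyond protein_length")
        if (df["uptake_Da"] < 0).any():
            raise UptakeFormatError("negative uptake")
        dup = df.duplicated(subset=["peptide", "start", "end", "state",
                                    "exposure_min", "replicate"])
        if dup.any():
            raise UptakeFormatError(
                f"duplicate replicate ids for {df[dup].iloc[0]['peptide']!r}")
        self.data = df.sort_values(["start", "end", "exposure_min", "replicate"],
                                   kind="mergesort").reset_index(drop=True)

    @property
    def peptides(self) -> pd.DataFrame:
        return (self.data[["peptide", "start", "end"]]
                .drop_duplicates().reset_index(drop=True))

    @property
    def exposures(self) -> np.ndarray:
        return np.sort(self.data["exposure_min"].unique())

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class CoverageStats:
    depth: np.ndarray          # per-residue peptide depth over the range
    residue_range: tuple[int, int]
    coverage_percent: float
    redundancy: float
    uncovered: list[int]


@dataclass
class DifferentialResult:
    """Wood's-plot style summed-difference result for state B vs state A."""

    table: pd.DataFrame        # peptide, start, end, delta_<t>..., summed_delta, threshold, class
    threshold: float           # global |summed_delta| significance threshold, Da
    alpha: float
    timepoints: np.ndarray
    method: str = "summed"

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["class"] != "not_significant"]

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------


def load_uptake_table(path, protein_length: int | None = None) -> PeptideUptakeTable:
    """Read an uptake CSV (peptide, start, end, state, exposure_min,
    replicate, uptake_Da); protein length defaults to the maximal end."""
    df = pd.read_csv(path)
    if protein_length is None:
        if "end" not in df.columns:
            raise UptakeFormatError("missing columns: ['end']")
        protein_length = int(df["end"].max())
    return PeptideUptakeTable(data=df, protein_length=protein_length)


def coverage_stats(table: PeptideUptakeTable,
                   residue_range: tuple[int, int] | None = None) -> CoverageStats:
    """Per-residue depth of peptide coverage over a residue range.

    A residue counts as covered when at least one peptide spans it;
    redundancy is the mean depth over the range (uncovered residues count 0).
    """
    if residue_range is None:
        residue_range = (1, table.protein_length)
    lo, hi = residue_range
    if not (1 <= lo <= hi <= table.protein_length):
        raise ValueError(f"residue range {residue_range} outside 1..{table.protein_length}")
    peptides = table.peptides
    if peptides.empty:
        raise UptakeFormatError("no peptides in table")
    depth = np.zeros(hi - lo + 1, dtype=int)
    for _, p in peptides.iterrows():
        a, b = max(int(p["start"]), lo), min(int(p["end"]), hi)
        if a <= b:
            depth[a - lo:b - lo + 1] += 1
    covered = depth > 0
    return CoverageStats(
        depth=depth,
        residue_range=(lo, hi),
        coverage_percent=100.0 * covered.sum() / depth.size,
        redundancy=float(depth.mean()),
        uncovered=[lo + i for i in np.nonzero(~covered)[0]],
    )


# ---------------------------------------------------------------------------


def _condition_stats(table: PeptideUptakeTable) -> pd.DataFrame:
    g = table.data.groupby(["peptide", "start", "end", "exposure_min"])["uptake_Da"]
    out = g.agg(mean="mean", var="var", n="count").reset_index()
    out["var"] = out["var"].fillna(0.0)
    return out


def differential_uptake(
    table_a: PeptideUptakeTable,
    table_b: PeptideUptakeTable,
    alpha: float = 0.01,
    method: str = "summed",
) -> DifferentialResult:
    """Summed-difference significance analysis of state B versus state A.

    Per peptide and exposure, delta_t = mean_B - mean_A; the statistic is
    summed_delta = sum_t delta_t.  The global threshold pools the replicate
    variances per timepoint across all peptides:

        threshold = t_crit(1 - alpha/2, n_A + n_B - 2)
                    * sqrt( sum_t ( s2_A,t / n_A + s2_B,t / n_B ) )

    ``method='hybrid'`` additionally requires at least one per-timepoint
    Welch test with p < alpha for a peptide to be called significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sa, sb = _condition_stats(table_a), _condition_stats(table_b)
    key = ["peptide", "start", "end"]
    pa = set(map(tuple, sa[key].drop_duplicates().itertuples(index=False)))
    pb = set(map(tuple, sb[key].drop_duplicates().itertuples(index=False)))
    if pa != pb:
        only_a, only_b = sorted(pa - pb), sorted(pb - pa)
        raise ValueError(
            f"peptide sets differ between states (A-only: {only_a[:5]}, "
            f"B-only: {only_b[:5]})")
    ta, tb = np.sort(sa["exposure_min"].unique()), np.sort(sb["exposure_min"].unique())
    if not np.array_equal(ta, tb):
        raise ValueError(f"exposure sets differ: {ta} vs {tb}")

    merged = sa.merge(sb, on=key + ["exposure_min"], suffixes=("_a", "_b"))
    merged["delta"] = merged["mean_b"] - merged["mean_a"]

    n_a = int(merged["n_a"].min())
    n_b = int(merged["n_b"].min())
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 replicates per condition for statistics")

    # pooled per-timepoint variances across peptides (df-weighted)
    pooled = merged.groupby("exposure_min").apply(
        lambda g: pd.Series({
            "s2_a": np.average(g["var_a"], weights=np.maximum(g["n_a"] - 1, 1)),
            "s2_b": np.average(g["var_b"], weights=np.maximum(g["n_b"] - 1, 1)),
            "n_a": g["n_a"].min(), "n_b": g["n_b"].min(),
        }), include_groups=False)
    se_sum = math.sqrt(float((pooled["s2_a"] / pooled["n_a"]
                              + pooled["s2_b"] / pooled["n_b"]).sum()))
    df_crit = n_a + n_b - 2
    tcrit = float(stats.t.ppf(1 - alpha / 2, df_crit))
    threshold = tcrit * se_sum

    wide = merged.pivot_table(index=key, columns="exposure_min", values="delta")
    wide = wide.reindex(columns=ta)
    summed = wide.sum(axis=1)

    out = wide.reset_index()
    out.columns = key + [f"delta_{t:g}min" for t in ta]
    out["summed_delta"] = summed.values
    out["threshold"] = threshold

    sig = np.abs(out["summed_delta"]) > threshold
    if method == "hybrid":
        welch_ok = _welch_any(merged, key, ta, alpha)
        out = out.merge(welch_ok, on=key, how="left")
        sig = sig & out.pop("welch_any").values
    elif method != "summed":
        raise ValueError(f"unknown method {method!r}")
    out["class"] = np.where(~sig, "not_significant",
                            np.where(out["summed_delta"] > 0, "deprotected", "protected"))
    out = out.sort_values(["start", "end"]).reset_index(drop=True)
    return DifferentialResult(table=out, threshold=threshold, alpha=alpha,
                              timepoints=ta, method=method)


def _welch_any(merged: pd.DataFrame, key: list[str], timepoints, alpha: float) -> pd.DataFrame:
    rows = []
    for k, g in merged.groupby(key):
        any_sig = False
        for _, r in g.iterrows():
            va, vb = max(r["var_a"], 1e-12), max(r["var_b"], 1e-12)
            na, nb = int(r["n_a"]), int(r["n_b"])
            se2 = va / na + vb / nb
            t = r["delta"] / math.sqrt(se2)
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = 2 * stats.t.sf(abs(t), df)
            if p < alpha:
                any_sig = True
                break
        rows.append((*k, any_sig))
    return pd.DataFrame(rows, columns=key + ["welch_any"])


def uptake_curves(table: PeptideUptakeTable, peptide: str) -> pd.DataFrame:
    """Mean +/- sd uptake versus exposure for one peptide."""
    sub = table.data[table.data["peptide"] == peptide]
    if sub.empty:
        raise KeyError(f"peptide {peptide!r} not in table")
    out = (sub.groupby("exposure_min")["uptake_Da"]
           .agg(mean="mean", sd="std", n="count").reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    return out


# ---------------------------------------------------------------------------


def map_regions(result: DifferentialResult,
                protein_length: int | None = None) -> dict:
    """Residue-level consensus classes and Wood's-plot segments.

    The consensus is conservative: a residue is classed deprotected (or
    protected) only when *every* peptide covering it is significant with
    that same sign.  Any covering non-significant peptide -- the evidence
    that the change does not localise to this residue -- or any overlapping
    contradictory peptide demotes the residue to not_significant.  With an
    overlapping digest this vetoes the bleed-over of long straddling
    peptides and resolves region boundaries to roughly the inter-cut-site
    spacing.  Contiguous same-class runs are emitted as regions.  Returns
    {'residue_classes': DataFrame, 'regions': DataFrame,
    'woods_segments': list of dicts}.
    """
    tbl = result.table
    if protein_length is None:
        protein_length = int(tbl["end"].max()) if len(tbl) else 0
    votes = {cls: np.zeros(protein_length + 1, dtype=int)
             for cls in ("deprotected", "protected", "not_significant")}
    for _, row in tbl.iterrows():
        votes[row["class"]][int(row["start"]):int(row["end"]) + 1] += 1
    classes = []
    for r in range(1, protein_length + 1):
        d, p, ns = (votes["deprotected"][r], votes["protected"][r],
                    votes["not_significant"][r])
        if d > 0 and p == 0 and ns == 0:
            classes.append("deprotected")
        elif p > 0 and d == 0 and ns == 0:
            classes.append("protected")
        else:
            classes.append("not_significant")
    residue_df = pd.DataFrame({"residue": np.arange(1, protein_length + 1),
                               "class": classes})
    regions = []
    r = 1
    while r <= protein_length:
        cls = classes[r - 1]
        if cls == "not_significant":
            r += 1
            continue
        r2 = r
        while r2 < protein_length and classes[r2] == cls:
            r2 += 1
        regions.append((r, r2, cls))
        r = r2 + 1
    regions_df = pd.DataFrame(regions, columns=["start", "end", "class"])
    segments = [
        {"start": int(row["start"]), "end": int(row["end"]),
         "summed_delta": float(row["summed_delta"]),
         "threshold": float(row["threshold"]), "class": row["class"]}
        for _, row in tbl.iterrows()
    ]
    return {"residue_classes": residue_df, "regions": regions_df,
            "woods_segments": segments}
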