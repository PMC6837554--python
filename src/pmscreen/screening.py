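"""Two-tier classification of the CHX / α-arrestin screen.

Tier 1 asks which PM proteins the cycloheximide treatment affects: the
WT+CHX vs mock-treated-WT comparison is analyzed and each protein called
DECREASED, INCREASED or UNCHANGED. Tier 2 asks, for every tier-1-affected
protein and every α-arrestin deletion, whether the deletion stabilizes the
protein at the PM (artΔ+CHX/WT+CHX significantly above 1 → STABILIZED,
read as an internalization defect), depletes it (significantly below 1 →
DEPLETED), or leaves it unaffected. The arrestin→candidate-target map then
lists, per arrestin, the tier-1 DECREASED proteins it STABILIZED — the
screen's interpretation of a direct endocytic adaptor–cargo relationship.

Tier-2 calls are evaluated for all tier-1-affected proteins (the published
per-arrestin table includes the INCREASED ones too), but the target map is
restricted to DECREASED ∧ STABILIZED.
"""

from __future__ import annotations

import os

import pandas as pd

from . import ratio_stats
from .ratio_stats import DECREASED, INCREASED, UNCHANGED, StatsConfig

__all__ = [
    "STABILIZED",
    "DEPLETED",
    "UNAFFECTED",
    "tier1_screen",
    "tier2_dependence",
    "build_target_map",
    "run_screen",
    "tier1_from_tables",
    "tier2_from_tables",
]

STABILIZED = "STABILIZED"
DEPLETED = "DEPLETED"
UNAFFECTED = "UNAFFECTED"

_CALL_TO_DEPENDENCE = {INCREASED: STABILIZED, DECREASED: DEPLETED, UNCHANGED: UNAFFECTED}


def tier1_screen(pooled: pd.DataFrame, config: StatsConfig | None = None) -> pd.DataFrame:
    """Build tier-1 screen records from pooled results of the CHX-vs-control
    comparison.

    Returns one row per protein with ``protein_id, tier1_ratio, tier1_call``,
    sorted by effect size with the greatest decrease first (ascending ratio,
    the published ordering). ``attrs["counts"]`` carries the per-call tally.
    """
    records = pooled[["protein_id", "pooled_ratio", "call"]].rename(
        columns={"pooled_ratio": "tier1_ratio", "call": "tier1_call"}
    )
    records = records.sort_values("tier1_ratio", kind="mergesort").reset_index(drop=True)
    counts = records["tier1_call"].value_counts().to_dict()
    records.attrs["counts"] = {k: int(counts.get(k, 0))
                               for k in (DECREASED, INCREASED, UNCHANGED)}
    return records


def tier2_dependence(records: pd.DataFrame, arrestin_pooled: dict,
                     config: StatsConfig | None = None) -> pd.DataFrame:
    """Attach per-arrestin dependence calls to tier-1 screen records.

    *arrestin_pooled* maps an arrestin label to the pooled-results frame of
    its artΔ+CHX vs WT+CHX comparison. For each tier-1-affected protein and
    each arrestin, the dependence call is STABILIZED for an INCREASED call
    on that comparison, DEPLETED for DECREASED, UNAFFECTED otherwise; a
    protein absent from a comparison is UNAFFECTED and flagged not
    quantified (ratio left as NaN). Tier-1 UNCHANGED proteins carry no
    dependence entries (NaN in every arrestin column).
    """
    out = records.copy()
    affected = out["tier1_call"] != UNCHANGED
    for arrestin, pooled in arrestin_pooled.items():
        by_protein = pooled.set_index("protein_id")
        ratios, calls = [], []
        for protein, is_affected in zip(out["protein_id"], affected):
            if not is_affected:
                ratios.append(float("nan"))
                calls.append(None)
                continue
            if protein not in by_protein.index:
                ratios.append(float("nan"))
                calls.append(f"{UNAFFECTED}(not quantified)")
                continue
            row = by_protein.loc[protein]
            ratios.append(float(row["pooled_ratio"]))
            calls.append(_CALL_TO_DEPENDENCE[row["call"]])
        out[f"{arrestin}_ratio"] = ratios
        out[f"{arrestin}_call"] = calls
    out.attrs["arrestins"] = list(arrestin_pooled)
    return out


def build_target_map(records: pd.DataFrame) -> dict:
    """Arrestin → candidate endocytic targets.

    For each arrestin, the tier-1 DECREASED proteins called STABILIZED in
    its deletion; a protein may appear under several arrestins. Arrestins
    with no candidates map to empty lists.
    """
    arrestins = records.attrs.get("arrestins")
    if arrestins is None:
        arrestins = [c.removesuffix("_call") for c in records.columns
                     if c.endswith("_call") and c != "tier1_call"]
    target_map = {a: [] for a in arrestins}
    decreased = records[records["tier1_call"] == DECREASED]
    for arrestin in arrestins:
        col = f"{arrestin}_call"
        hits = decreased.loc[decreased[col] == STABILIZED, "protein_id"]
        target_map[arrestin] = list(hits)
    return target_map


def _arrestin_label(test: str, reference: str) -> str:
    """Strip the treatment suffix and deletion marker from a test-condition
    label, e.g. 'art2Δ+CHX' vs 'WT+CHX' → 'art2'."""
    label = test
    if "+" in label:
        label = label.split("+", 1)[0]
    return label.removesuffix("Δ").removesuffix("d")


def run_screen(dataset_path, config: StatsConfig | None = None, outdir=None,
               tier1_comparison: tuple[str, str] = ("WT+CHX", "WT_ctrl")):
    """End-to-end screen: read a peptide dataset, run the ratio statistics,
    classify tiers 1 and 2, and build the target map.

    The tier-1 comparison is identified by its (test, reference) labels;
    every comparison whose reference equals the tier-1 test condition is
    treated as an arrestin deletion. Returns ``(records, target_map,
    results)``; when *outdir* is given, writes ``table1.tsv``,
    ``table2.tsv`` and ``targets.tsv`` there.
    """
    config = config or StatsConfig()
    peptides = ratio_stats.read_dataset(dataset_path)
    results = ratio_stats.analyze_dataset(peptides, config)

    t1_test, t1_ref = tier1_comparison
    tier1_pool = results[(results["test"] == t1_test) & (results["reference"] == t1_ref)]
    if tier1_pool.empty:
        raise ValueError(
            f"dataset has no ({t1_test}, {t1_ref}) comparison; tier 1 undefined"
        )
    records = tier1_screen(tier1_pool, config)

    arrestin_pooled = {}
    for (test, ref), comp_df in results.groupby(["test", "reference"], sort=True):
        if ref == t1_test:
            arrestin_pooled[_arrestin_label(test, ref)] = comp_df
    records = tier2_dependence(records, arrestin_pooled, config)
    target_map = build_target_map(records)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        t1 = records[["protein_id", "tier1_ratio", "tier1_call"]]
        t1.to_csv(os.path.join(str(outdir), "table1.tsv"), sep="\t", index=False)
        records.to_csv(os.path.join(str(outdir), "table2.tsv"), sep="\t", index=False)
        with open(os.path.join(str(outdir), "targets.tsv"), "w", encoding="utf-8") as fh:
            fh.write("arrestin\tproteins\n")
            for arrestin in sorted(target_map):
                fh.write(f"{arrestin}\t{','.join(target_map[arrestin])}\n")
    return records, target_map, results


# ---------------------------------------------------------------------------
# Fixture mode: drive the classifier from the packaged published tables.
# Raw MS data are unavailable, so significance comes from the tables'
# recorded flags rather than recomputed p-values.
# ---------------------------------------------------------------------------

_FLAG_TO_CALL = {"down": DECREASED, "up": INCREASED, "none": UNCHANGED}
_FLAG_TO_DEPENDENCE = {"up": STABILIZED, "down": DEPLETED, "none": UNAFFECTED}


def tier1_from_tables(table1: pd.DataFrame) -> pd.DataFrame:
    """Tier-1 records from a packaged CHX-effect table (ratio + flag)."""
    records = pd.DataFrame({
        "protein_id": table1["name"],
        "tier1_ratio": table1["ratio_chx_vs_ctrl"].astype(float),
        "tier1_call": table1["flag"].map(_FLAG_TO_CALL),
    })
    records = records.sort_values("tier1_ratio", kind="mergesort").reset_index(drop=True)
    counts = records["tier1_call"].value_counts().to_dict()
    records.attrs["counts"] = {k: int(counts.get(k, 0))
                               for k in (DECREASED, INCREASED, UNCHANGED)}
    return records


def tier2_from_tables(records: pd.DataFrame, table2: pd.DataFrame) -> pd.DataFrame:
    """Attach dependence calls from a packaged per-arrestin table.

    Cell flags map up → STABILIZED, down → DEPLETED, none → UNAFFECTED;
    only tier-1-affected proteins receive entries.
    """
    arrestins = [c.removesuffix("_ratio") for c in table2.columns if c.endswith("_ratio")]
    by_name = table2.set_index("name")
    out = records.copy()
    affected = out["tier1_call"] != UNCHANGED
    for arrestin in arrestins:
        ratios, calls = [], []
        for protein, is_affected in zip(out["protein_id"], affected):
            if not is_affected or protein not in by_name.index:
                ratios.append(float("nan"))
                calls.append(None)
                continue
            row = by_name.loc[protein]
            ratios.append(float(row[f"{arrestin}_ratio"]))
            calls.append(_FLAG_TO_DEPENDENCE[row[f"{arrestin}_flag"]])
        out[f"{arrestin}_ratio"] = ratios
        out[f"{arrestin}_call"] = calls
    out.attrs["arrestins"] = arrestins
    return out
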