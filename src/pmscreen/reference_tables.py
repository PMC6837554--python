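"""Packaged published reference tables for the CHX / α-arrestin PM screen.

Two tables are shipped as plain TSV inside the package:

``table1.tsv``
    The 33 plasma-membrane proteins whose abundance changes upon a 90-min
    cycloheximide (CHX) treatment of a wild-type strain: UniProtKB accession,
    protein symbol, the WT+CHX/WT ctrl geometric-mean fold-change ratio
    (6 biological replicates), and a significance flag. Every row of the
    published table is significant at p < 0.05 (24 decreased, 9 increased),
    so the flag is ``down`` for ratios < 1 and ``up`` for ratios > 1.

``table2.tsv``
    The same 33 proteins against the 12 α-arrestin deletions: for each
    arrestin (art1..art10, bul1, bul2) the artΔ+CHX/WT+CHX geometric-mean
    ratio (3 biological replicates) and a significance flag in
    ``{up, down, none}``. The published table encodes significance as cell
    color; the machine-readable source available for transcription preserves
    the ratios but not the colors, so flags are recorded only for the cells
    whose significance the running text states explicitly (Thi7 in art2Δ and
    art9Δ, Ptr2 in bul1Δ, Can1 in art1Δ, Hxt1/Hxt3 in art4Δ, Gas1 and Ras2
    in art9Δ and bul2Δ). Rows described as significant without naming the
    cells are listed in :data:`TABLE2_AMBIGUOUS_ROWS`.

File integrity is guarded by SHA-256 checksums recorded at packaging time.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = [
    "ARRESTINS",
    "TABLE2_AMBIGUOUS_ROWS",
    "load_table1",
    "load_table2",
    "summarize_counts",
    "lookup_ratio",
    "export_tables",
]

#: Arrestin column labels, in the published column order.
ARRESTINS = (
    "art1", "art2", "art3", "art4", "art5", "art6",
    "art7", "art8", "art9", "art10", "bul1", "bul2",
)

#: Protein symbols whose rows the text calls significant in one or more
#: arrestin deletions without naming the cells; their flags are ``none``.
TABLE2_AMBIGUOUS_ROWS = ("FKS1", "HXT4", "HXT7", "PMA1")

_CHECKSUMS = {
    "table1.tsv": "bb9bdc640f8107c390c97f52fdf910a12cb89c8acbf2a5b12a52bfea2e11a7ad",
    "table2.tsv": "fec481547a632a1227bd3d2ac6ed4360b189064d2f6a180dd6a27c2445d0e285",
}


class ChecksumError(RuntimeError):
    """Packaged table content does not match its recorded checksum."""


def _read_packaged(filename: str) -> pd.DataFrame:
    ref = resources.files("pmscreen.data").joinpath(filename)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise ChecksumError(
            f"{filename}: checksum {digest} does not match the recorded "
            f"value {_CHECKSUMS[filename]}; packaged data corrupted"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype={"accession": str, "name": str})


def load_table1() -> pd.DataFrame:
    """Return the CHX-effect table (33 rows).

    Columns: ``accession``, ``name``, ``ratio_chx_vs_ctrl`` (float),
    ``flag`` (``up``/``down``; every published row is significant).
    """
    df = _read_packaged("table1.tsv")
    if len(df) != 33:
        raise ChecksumError(f"table1 expected 33 rows, found {len(df)}")
    return df


def load_table2() -> pd.DataFrame:
    """Return the α-arrestin-deletion table (33 rows × 12 arrestins).

    Columns: ``accession``, ``name``, then for each arrestin label ``a`` in
    :data:`ARRESTINS` a ``{a}_ratio`` float column and a ``{a}_flag`` column
    in ``{up, down, none}`` (see the module docstring for flag provenance).
    """
    df = _read_packaged("table2.tsv")
    if len(df) != 33:
        raise ChecksumError(f"table2 expected 33 rows, found {len(df)}")
    return df


def summarize_counts(table1: pd.DataFrame) -> tuple[int, int, int]:
    """Count (decreased, increased, total) rows of a table-1-style frame.

    Decreased means ratio < 1, increased ratio > 1; a ratio of exactly 1
    counts toward the total only.
    """
    ratios = table1["ratio_chx_vs_ctrl"]
    return int((ratios < 1).sum()), int((ratios > 1).sum()), int(len(ratios))


def lookup_ratio(table: pd.DataFrame, protein: str, column: str | None = None) -> float:
    """Look up a printed ratio by protein symbol or accession.

    For table 1 pass ``column=None`` (or ``"ratio_chx_vs_ctrl"``); for
    table 2 pass an arrestin label from :data:`ARRESTINS`.
    """
    mask = (table["name"] == protein) | (table["accession"] == protein)
    if not mask.any():
        valid = ", ".join(table["name"])
        raise KeyError(f"unknown protein {protein!r}; valid names: {valid}")
    row = table.loc[mask].iloc[0]
    if column is None or column == "ratio_chx_vs_ctrl":
        if "ratio_chx_vs_ctrl" not in table.columns:
            raise KeyError(
                "this table has per-arrestin columns; pass one of: "
                + ", ".join(ARRESTINS)
            )
        return float(row["ratio_chx_vs_ctrl"])
    key = column.removesuffix("Δ").removesuffix("_ratio")
    if key not in ARRESTINS:
        raise KeyError(f"unknown column {column!r}; valid columns: {', '.join(ARRESTINS)}")
    return float(row[f"{key}_ratio"])


def export_tables(outdir) -> list[str]:
    """Write both packaged tables as TSV files into *outdir*; return paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for name, loader in (("table1.tsv", load_table1), ("table2.tsv", load_table2)):
        path = os.path.join(str(outdir), name)
        loader().to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
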