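"""Statistical core of the PM-proteome screen.

The quantity of interest is a protein's abundance ratio between a test and a
reference condition, estimated from per-peptide reporter ratios over several
biological replicates. The pipeline is:

1. Per replicate: the protein ratio is the geometric mean of its peptide
   ratios, and a two-sided one-sample t-test of the log2 peptide ratios
   against 0 supplies a per-replicate p-value (requires at least
   ``min_peptides`` peptides).
2. Across replicates: the pooled ratio is the geometric ("logarithmic")
   mean of the replicate ratios. Each replicate's two-sided p-value is
   converted to a signed z-score, ``z_i = sign(log r_i) * Phi^-1(1 - p_i/2)``,
   and combined with the weighted Stouffer–Liptak statistic

       Z = sum(w_i * z_i) / sqrt(sum(w_i**2)),   w_i = peptide count,

   which is standard normal under the null; the pooled two-sided p-value is
   ``2 * (1 - Phi(|Z|))``.
3. Bonferroni correction over the proteins tested within one comparison,
   then a direction call: DECREASED / INCREASED when the adjusted p-value is
   below ``alpha`` and the pooled ratio is below / above 1, else UNCHANGED.

All tabular data are pandas DataFrames. Peptide tables use the columns
``protein_id, test, reference, replicate, peptide, ratio``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsConfig",
    "DECREASED",
    "INCREASED",
    "UNCHANGED",
    "PEPTIDE_COLUMNS",
    "read_dataset",
    "replicate_protein_ratio",
    "pool_replicates",
    "bonferroni_adjust",
    "classify_change",
    "analyze_dataset",
    "write_results",
]

DECREASED = "DECREASED"
INCREASED = "INCREASED"
UNCHANGED = "UNCHANGED"

PEPTIDE_COLUMNS = ("protein_id", "test", "reference", "replicate", "peptide", "ratio")

# p-values are floored before the normal quantile so an underflowed t-test
# p of 0.0 maps to a large finite z rather than +inf.
_P_FLOOR = 1e-300


@dataclass
class StatsConfig:
    """Tuning knobs of the screen statistics.

    alpha
        Family-wise significance level for the direction call (default 0.05).
    min_peptides
        Minimum peptides for a replicate to yield a p-value (default 2); the
        stand-in for the upstream identification stringency.
    min_replicates
        Minimum replicates carrying p-values for a protein to be tested
        (default 2); proteins below it are reported but not tested.
    bonferroni_family_size
        ``"per_comparison"`` (family = proteins tested in that comparison)
        or an explicit integer family size.
    z_normalization
        ``"stouffer"`` divides the weighted z sum by sqrt(sum w**2), keeping
        the statistic standard normal under the null (the default and the
        endorsed reading); ``"mean"`` divides by sum w, a plain weighted
        average that is not a calibrated z and is provided for comparison
        only.
    """

    alpha: float = 0.05
    min_peptides: int = 2
    min_replicates: int = 2
    bonferroni_family_size: int | str = "per_comparison"
    z_normalization: str = "stouffer"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.z_normalization not in ("stouffer", "mean"):
            raise ValueError("z_normalization must be 'stouffer' or 'mean'")
        if not (self.bonferroni_family_size == "per_comparison"
                or (isinstance(self.bonferroni_family_size, int)
                    and self.bonferroni_family_size >= 1)):
            raise ValueError("bonferroni_family_size must be 'per_comparison' or int >= 1")


def read_dataset(path) -> pd.DataFrame:
    """Read a peptide-ratio TSV written by the synthetic generator.

    Validates the header and that every ratio is finite and positive;
    errors name the offending column or line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "test": str, "reference": str})
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise ValueError(f"{path}: dataset contains no records")
    ratios = pd.to_numeric(df["ratio"], errors="coerce")
    bad = ~np.isfinite(ratios) | (ratios <= 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(
            f"{path}: line {line}: ratio must be a finite positive number, "
            f"got {df['ratio'].iloc[int(df.index[bad][0])]!r}"
        )
    df["ratio"] = ratios
    return df[list(PEPTIDE_COLUMNS)]


def _check_ratios(ratios: np.ndarray) -> np.ndarray:
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("no peptide ratios supplied")
    if not np.all(np.isfinite(ratios) & (ratios > 0)):
        raise ValueError("peptide ratios must be finite and > 0")
    return ratios


def replicate_protein_ratio(peptide_ratios, config: StatsConfig | None = None) -> dict:
    """Summarize one (protein, comparison, replicate) from its peptide ratios.

    Returns a dict with ``ratio`` (geometric mean of the peptide ratios),
    ``n_peptides`` and ``p_value`` (two-sided one-sample t-test of the log2
    ratios against 0; ``None`` when fewer than ``min_peptides`` peptides).
    A replicate whose log2 ratios are all exactly 0 has p = 1; zero variance
    away from 0 gives p = 0 (the t statistic diverges).
    """
    config = config or StatsConfig()
    ratios = _check_ratios(peptide_ratios)
    log2r = np.log2(ratios)
    out = {
        "ratio": float(2.0 ** log2r.mean()),
        "n_peptides": int(ratios.size),
        "p_value": None,
    }
    if ratios.size >= config.min_peptides:
        if np.ptp(log2r) == 0.0:
            out["p_value"] = 1.0 if log2r[0] == 0.0 else 0.0
        else:
            n = log2r.size
            t_stat = log2r.mean() / (log2r.std(ddof=1) / math.sqrt(n))
            out["p_value"] = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return out


def _signed_z(ratio: float, p: float) -> float:
    """Signed z-score of a replicate: magnitude from the two-sided p, sign
    from the direction of the replicate's log ratio."""
    z = float(stats.norm.isf(max(p, _P_FLOOR) / 2.0))
    return float(np.sign(np.log(ratio))) * z


def pool_replicates(replicate_results, config: StatsConfig | None = None) -> dict:
    """Pool one protein's replicate results within one comparison.

    *replicate_results* is an iterable of dicts as returned by
    :func:`replicate_protein_ratio`. Returns a dict with ``pooled_ratio``
    (geometric mean of the replicate ratios), ``combined_z``, ``pooled_p``,
    ``n_replicates`` (replicates contributing p-values) and ``tested``.
    Proteins with fewer than ``min_replicates`` usable replicates keep their
    pooled ratio but are flagged ``tested=False`` with z and p set to None.
    """
    config = config or StatsConfig()
    results = list(replicate_results)
    if not results:
        raise ValueError("no replicate results supplied")
    log_ratios = np.log([r["ratio"] for r in results])
    pooled_ratio = float(np.exp(log_ratios.mean()))

    usable = [r for r in results if r["p_value"] is not None]
    out = {
        "pooled_ratio": pooled_ratio,
        "combined_z": None,
        "pooled_p": None,
        "n_replicates": len(usable),
        "tested": False,
    }
    if len(usable) < config.min_replicates:
        return out
    z = np.array([_signed_z(r["ratio"], r["p_value"]) for r in usable])
    w = np.array([r["n_peptides"] for r in usable], dtype=float)
    denom = np.sqrt((w**2).sum()) if config.z_normalization == "stouffer" else w.sum()
    combined_z = float((w * z).sum() / denom)
    out["combined_z"] = combined_z
    out["pooled_p"] = float(2.0 * stats.norm.sf(abs(combined_z)))
    out["tested"] = True
    return out


def bonferroni_adjust(pooled: pd.DataFrame, config: StatsConfig | None = None) -> pd.DataFrame:
    """Add ``adjusted_p`` to a pooled-results frame for one comparison.

    The family size m is the number of tested proteins in the comparison
    (or the explicit integer from the config); ``adjusted_p = min(1, m * p)``.
    """
    config = config or StatsConfig()
    pooled = pooled.copy()
    tested = pooled["tested"].astype(bool)
    if config.bonferroni_family_size == "per_comparison":
        m = int(tested.sum())
    else:
        m = int(config.bonferroni_family_size)
    m = max(m, 1)
    adjusted = np.minimum(1.0, m * pooled["pooled_p"].astype(float))
    pooled["adjusted_p"] = np.where(tested, adjusted, np.nan)
    pooled.attrs["bonferroni_m"] = m
    return pooled


def classify_change(pooled_ratio: float, adjusted_p: float,
                    config: StatsConfig | None = None) -> str:
    """Direction call for one protein.

    DECREASED / INCREASED when adjusted_p < alpha and the pooled ratio is
    below / above 1; UNCHANGED otherwise, including the degenerate pooled
    ratio of exactly 1 (direction undefined).
    """
    config = config or StatsConfig()
    if adjusted_p is None or not np.isfinite(adjusted_p):
        return UNCHANGED
    if adjusted_p < config.alpha:
        if pooled_ratio < 1.0:
            return DECREASED
        if pooled_ratio > 1.0:
            return INCREASED
    return UNCHANGED


def analyze_dataset(peptides: pd.DataFrame, config: StatsConfig | None = None) -> pd.DataFrame:
    """Run the full per-protein analysis on a peptide-ratio table.

    Returns one row per (protein, comparison) with columns ``protein_id,
    test, reference, pooled_ratio, combined_z, pooled_p, adjusted_p, call,
    n_replicates, tested``, Bonferroni-corrected within each comparison.
    """
    config = config or StatsConfig()
    rows = []
    for (test, ref), comp_df in peptides.groupby(["test", "reference"], sort=True):
        for protein, prot_df in comp_df.groupby("protein_id", sort=True):
            reps = [
                replicate_protein_ratio(rep_df["ratio"].to_numpy(), config)
                for _, rep_df in prot_df.groupby("replicate", sort=True)
            ]
            pooled = pool_replicates(reps, config)
            rows.append({"protein_id": protein, "test": test, "reference": ref, **pooled})
    out = pd.DataFrame(rows)
    adjusted = []
    for (_, _), comp_df in out.groupby(["test", "reference"], sort=True):
        adjusted.append(bonferroni_adjust(comp_df, config))
    out = pd.concat(adjusted).sort_index()
    out["call"] = [
        classify_change(r, p, config) if t else UNCHANGED
        for r, p, t in zip(out["pooled_ratio"], out["adjusted_p"], out["tested"])
    ]
    return out


def write_results(results: pd.DataFrame, path) -> None:
    """Write an analysis results frame as TSV (full float precision)."""
    cols = ["protein_id", "test", "reference", "pooled_ratio", "combined_z",
            "pooled_p", "adjusted_p", "call", "n_replicates"]
    results[cols].to_csv(path, sep="\t", index=False)
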