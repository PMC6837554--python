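"""Synthetic peptide-level ratio data matching the screen's design.

No raw mass-spectrometry data are publicly deposited for this screen, so
every downstream statistic is exercised on simulated peptide ratio tables
with known ground truth. The generator emulates the stated experimental
design — one WT+CHX vs mock-treated WT comparison with 6 biological
replicates and twelve artΔ+CHX vs WT+CHX comparisons with 3 replicates
each — and an explicit noise model:

* each (protein, comparison, replicate) draws a replicate offset
  ~ Normal(0, replicate_effect_sd²) on the log2 scale (shared biological /
  labeling variation within a replicate);
* each peptide then draws log2(ratio) ~ Normal(log2(true fold change) +
  offset, peptide_noise_sd²), i.e. multiplicative log-normal peptide noise.

Ratios are simulated directly; reporter-channel effects such as isotope
impurity or ratio compression are deliberately not modeled. Randomness is
a single top-level seed from which an independent substream is derived per
(protein, comparison, replicate), so adding proteins or comparisons never
perturbs existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratio_stats import PEPTIDE_COLUMNS

__all__ = [
    "ScreenDesign",
    "GroundTruth",
    "DEFAULT_PEPTIDE_COUNTS",
    "default_design",
    "uniform_truth",
    "simulate_peptide_ratios",
    "write_dataset",
]

#: Condition labels of the default design.
WT_CHX = "WT+CHX"
WT_CTRL = "WT_ctrl"
ARRESTIN_LABELS = (
    "art1", "art2", "art3", "art4", "art5", "art6",
    "art7", "art8", "art9", "art10", "bul1", "bul2",
)

# Fixed default peptides-per-protein table for the 33 screen proteins,
# spanning 1–40 so that the peptide-count weighting and the
# minimum-evidence filter are both exercised. Deterministic by design.
DEFAULT_PEPTIDE_COUNTS = (
    12, 3, 25, 2, 8, 40, 5, 1, 17, 6, 30, 4, 10, 2, 22, 7, 14,
    3, 35, 9, 11, 2, 19, 5, 28, 6, 16, 4, 13, 8, 21, 1, 24,
)


@dataclass
class ScreenDesign:
    """Experimental layout: which comparisons, how many replicates, which
    proteins with how many peptides each."""

    comparisons: list  # list of (test, reference) label pairs
    replicates_per_comparison: dict  # (test, reference) -> int >= 1
    proteins: list  # protein identifiers
    peptides_per_protein: dict  # protein -> int >= 1

    def __post_init__(self) -> None:
        comps = [tuple(c) for c in self.comparisons]
        if len(set(comps)) != len(comps):
            raise ValueError("comparison labels must be unique")
        self.comparisons = comps
        self.replicates_per_comparison = {
            tuple(k): int(v) for k, v in self.replicates_per_comparison.items()
        }
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("protein identifiers must be unique")
        for comp in self.comparisons:
            n = self.replicates_per_comparison.get(comp)
            if n is None or n < 1:
                raise ValueError(f"comparison {comp} needs >= 1 replicate")
        for prot in self.proteins:
            k = self.peptides_per_protein.get(prot)
            if k is None or k < 1:
                raise ValueError(f"protein {prot} needs >= 1 peptide")


@dataclass
class GroundTruth:
    """The simulated truth: per-(protein, comparison) fold change plus the
    two noise scales of the log-normal model (both on the log2 scale)."""

    true_fold_change: dict  # (protein, (test, reference)) -> float > 0
    peptide_noise_sd: float = 0.5
    replicate_effect_sd: float = 0.1

    def __post_init__(self) -> None:
        self.true_fold_change = {
            (p, tuple(c)): float(f) for (p, c), f in self.true_fold_change.items()
        }
        for key, f in self.true_fold_change.items():
            if not f > 0:
                raise ValueError(f"true fold change for {key} must be > 0, got {f}")
        if not self.peptide_noise_sd > 0:
            raise ValueError("peptide_noise_sd must be > 0")
        if self.replicate_effect_sd < 0:
            raise ValueError("replicate_effect_sd must be >= 0")


def default_design() -> ScreenDesign:
    """The screen's stated design: (WT+CHX, WT_ctrl) at 6 replicates plus
    twelve (artNΔ+CHX, WT+CHX) comparisons at 3 replicates, over the 33
    proteins of the published CHX-effect table with the fixed default
    peptide-count table. Deterministic; no randomness."""
    from .reference_tables import load_table1

    comparisons = [(WT_CHX, WT_CTRL)]
    replicates = {(WT_CHX, WT_CTRL): 6}
    for art in ARRESTIN_LABELS:
        comp = (f"{art}Δ+CHX", WT_CHX)
        comparisons.append(comp)
        replicates[comp] = 3
    proteins = list(load_table1()["name"])
    peptides = dict(zip(proteins, DEFAULT_PEPTIDE_COUNTS))
    return ScreenDesign(comparisons, replicates, proteins, peptides)


def uniform_truth(design: ScreenDesign, fold_change: float = 1.0,
                  peptide_noise_sd: float = 0.5,
                  replicate_effect_sd: float = 0.1) -> GroundTruth:
    """Ground truth with the same fold change for every (protein, comparison);
    convenient for null and power simulations."""
    fc = {(p, comp): fold_change for p in design.proteins for comp in design.comparisons}
    return GroundTruth(fc, peptide_noise_sd, replicate_effect_sd)


def planted_truth(design: ScreenDesign, planted: dict,
                  tier1_fold: float = 0.2, stabilized_fold: float = 5.0,
                  peptide_noise_sd: float = 0.5,
                  replicate_effect_sd: float = 0.1,
                  tier1_comparison: tuple | None = None) -> GroundTruth:
    """Ground truth for a screen with planted arrestin-dependent proteins.

    *planted* maps a protein to its cognate arrestin label. A planted
    protein has fold change *tier1_fold* in the tier-1 comparison (CHX
    depletes it in the wild type) and *stabilized_fold* in its cognate
    arrestin's comparison (the deletion blocks its internalization); every
    other (protein, comparison) is null (fold 1). The cognate comparison is
    the one whose test label, stripped of any "+treatment" suffix and a
    trailing deletion marker, equals the arrestin label; the tier-1
    comparison defaults to the design's first.
    """
    tier1 = tuple(tier1_comparison) if tier1_comparison else design.comparisons[0]
    fc = {}
    for protein in design.proteins:
        for comp in design.comparisons:
            fold = 1.0
            if protein in planted:
                if comp == tier1:
                    fold = tier1_fold
                elif comp[0].split("+")[0].removesuffix("Δ") == planted[protein]:
                    fold = stabilized_fold
            fc[(protein, comp)] = fold
    return GroundTruth(fc, peptide_noise_sd, replicate_effect_sd)


def _substream(seed: int, protein, comparison, replicate: int) -> np.random.Generator:
    """Independent, order-insensitive RNG substream per experimental cell.

    The stream key hashes the labels with CRC-32, so draws for one cell do
    not depend on how many other proteins or comparisons exist.
    """
    def h(text: str) -> int:
        return zlib.crc32(text.encode("utf-8"))

    key = [int(seed), h(str(protein)), h(comparison[0]), h(comparison[1]), int(replicate)]
    return np.random.default_rng(key)


def simulate_peptide_ratios(design: ScreenDesign, truth: GroundTruth,
                            seed: int) -> pd.DataFrame:
    """Simulate a full peptide-ratio table for *design* under *truth*.

    Returns a DataFrame with the standard peptide columns. Identical
    (design, truth, seed) triples give bit-identical output. A missing
    truth entry raises KeyError naming the (protein, comparison).
    """
    records = []
    for comp in design.comparisons:
        n_rep = design.replicates_per_comparison[comp]
        for protein in design.proteins:
            try:
                fc = truth.true_fold_change[(protein, comp)]
            except KeyError:
                raise KeyError(
                    f"ground truth has no fold change for protein {protein!r} "
                    f"in comparison {comp}"
                ) from None
            n_pep = design.peptides_per_protein[protein]
            for rep in range(1, n_rep + 1):
                rng = _substream(seed, protein, comp, rep)
                offset = rng.normal(0.0, truth.replicate_effect_sd)
                log2r = rng.normal(np.log2(fc) + offset, truth.peptide_noise_sd, size=n_pep)
                for pep, lr in enumerate(log2r, start=1):
                    records.append((protein, comp[0], comp[1], rep, pep, float(2.0 ** lr)))
    return pd.DataFrame(records, columns=list(PEPTIDE_COLUMNS))


def write_dataset(peptide_ratios: pd.DataFrame, path) -> None:
    """Write a peptide-ratio table as UTF-8 TSV (header + one row per
    peptide). Round-trips losslessly through ``ratio_stats.read_dataset``.
    An empty table is rejected rather than written."""
    if peptide_ratios is None or len(peptide_ratios) == 0:
        raise ValueError("refusing to write an empty peptide-ratio dataset")
    missing = [c for c in PEPTIDE_COLUMNS if c not in peptide_ratios.columns]
    if missing:
        raise ValueError(f"dataset missing column(s): {', '.join(missing)}")
    peptide_ratios[list(PEPTIDE_COLUMNS)].to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )
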