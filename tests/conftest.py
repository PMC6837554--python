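import itertools

import pytest

from pmscreen.synthetic_proteomics import (
    DEFAULT_PEPTIDE_COUNTS,
    ARRESTIN_LABELS,
    WT_CHX,
    WT_CTRL,
    ScreenDesign,
)


@pytest.fixture(scope="session")
def table1():
    from pmscreen.reference_tables import load_table1

    return load_table1()


@pytest.fixture(scope="session")
def table2():
    from pmscreen.reference_tables import load_table2

    return load_table2()


def make_screen_design(n_proteins=20, arrestins=ARRESTIN_LABELS,
                       wt_replicates=6, art_replicates=3):
    """A compact screen design mirroring the published layout: one
    CHX-vs-control comparison plus one comparison per arrestin deletion."""
    proteins = [f"P{i:02d}" for i in range(n_proteins)]
    counts = dict(zip(
        proteins, itertools.islice(itertools.cycle(DEFAULT_PEPTIDE_COUNTS), n_proteins)
    ))
    comparisons = [(WT_CHX, WT_CTRL)]
    replicates = {(WT_CHX, WT_CTRL): wt_replicates}
    for art in arrestins:
        comp = (f"{art}Δ+CHX", WT_CHX)
        comparisons.append(comp)
        replicates[comp] = art_replicates
    return ScreenDesign(comparisons, replicates, proteins, counts)
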