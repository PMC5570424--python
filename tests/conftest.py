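import numpy as np
import pandas as pd
import pytest

from poolscreen import (
    PlantedEffect,
    ShRNALibrary,
    ShRNAReagent,
    build_default_library,
    build_library,
)
from poolscreen.stats import ContrastSpec, FoldChangeList
from poolscreen.library import Fraction


@pytest.fixture(scope="session")
def default_library() -> ShRNALibrary:
    """The full-scale simulated library (12,998 reagents / 648 genes)."""
    return build_default_library(seed=11)


@pytest.fixture(scope="session")
def small_library() -> ShRNALibrary:
    """A reduced library (40 genes x 5 reagents) for fast unit tests."""
    return build_library([5] * 40, seed=3)


@pytest.fixture
def tiny_library() -> ShRNALibrary:
    return ShRNALibrary(
        [
            ShRNAReagent("r1", "GENEA", "A" * 18),
            ShRNAReagent("r2", "GENEA", "C" * 18),
            ShRNAReagent("r3", "GENEB", "G" * 18),
        ]
    )


@pytest.fixture
def make_fc():
    """Factory for hand-built fold-change lists: values + gene labels."""

    def _make(log2fc, genes, ids=None):
        n = len(log2fc)
        if ids is None:
            ids = [f"sh{i:03d}" for i in range(n)]
        table = pd.DataFrame(
            {"gene": list(genes), "log2fc": np.asarray(log2fc, dtype=float)},
            index=pd.Index(ids, name="reagent_id"),
        )
        contrast = ContrastSpec("test", Fraction.M2POS, Fraction.INPUT)
        return FoldChangeList(contrast, table, pseudocount=1.0)

    return _make


def planted_panel(genes_mediator, genes_suppressor, genes_essential,
                  strengths=(0.7, 0.75, 0.8, 0.85, 0.9)):
    """The standard planted-effect panel: M2 mediators, M2 suppressors and
    essential genes at strengths spanning 0.7-0.9."""
    eff = []
    for g, s in zip(genes_mediator, strengths):
        eff.append(PlantedEffect(g, "M2", "mediator", s))
    for g, s in zip(genes_suppressor, strengths):
        eff.append(PlantedEffect(g, "M2", "suppressor", s))
    for g, s in zip(genes_essential, strengths):
        eff.append(PlantedEffect(g, "viability", "essential", s))
    return eff
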