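"""Top-N hit selection, contingency classification and essential-gene
filtering.

The screen's analysis plan crosses five comparisons — M1+ vs input, M1+ vs
M1-, M2+ vs input, M2+ vs M2-, and M2+ vs M1+ — with the two analysis modes,
yielding ten polarization analysis modules, plus one viability module
(viable monocytes vs input, depletion mode) that flags essential genes.

Because RSA p-values only rank genes within one comparison, hits are called
by taking the top N (default 10, ~1.5% of 648 genes) of each module.  Genes
are then classified by inferred normal function: reagents *over*-represented
in a phenotype-positive fraction mean the gene normally suppresses that
phenotype; *under*-represented means it mediates it.  The M2+ vs M1+
comparison speaks to both phenotypes at once with opposite roles (depleted
in M2+ relative to M1+ = M2 mediator = M1 suppressor).  Genes appearing in
two or more modules are higher-confidence hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .library import Fraction
from .stats import ContrastSpec, Mode

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 10


@dataclass(frozen=True)
class AnalysisModule:
    """One (contrast, mode) analysis of the screen."""

    contrast: ContrastSpec
    mode: Mode

    @property
    def name(self) -> str:
        return f"{self.contrast.name}.{self.mode}"


CONTRAST_M1_VS_INPUT = ContrastSpec("M1pos_vs_input", Fraction.M1POS, Fraction.INPUT)
CONTRAST_M1_VS_M1NEG = ContrastSpec("M1pos_vs_M1neg", Fraction.M1POS, Fraction.M1NEG)
CONTRAST_M2_VS_INPUT = ContrastSpec("M2pos_vs_input", Fraction.M2POS, Fraction.INPUT)
CONTRAST_M2_VS_M2NEG = ContrastSpec("M2pos_vs_M2neg", Fraction.M2POS, Fraction.M2NEG)
CONTRAST_M2_VS_M1 = ContrastSpec("M2pos_vs_M1pos", Fraction.M2POS, Fraction.M1POS)
CONTRAST_VIABILITY = ContrastSpec("viable_vs_input", Fraction.VIABLE_MO, Fraction.INPUT)

POLARIZATION_CONTRASTS = [
    CONTRAST_M1_VS_INPUT,
    CONTRAST_M1_VS_M1NEG,
    CONTRAST_M2_VS_INPUT,
    CONTRAST_M2_VS_M2NEG,
    CONTRAST_M2_VS_M1,
]


def default_plan() -> list[AnalysisModule]:
    """The ten polarization analysis modules (5 contrasts x 2 modes)."""
    return [
        AnalysisModule(c, m)
        for c in POLARIZATION_CONTRASTS
        for m in ("mediator", "suppressor")
    ]


VIABILITY_MODULE = AnalysisModule(CONTRAST_VIABILITY, "mediator")

#: (phenotype, role) credits earned by a top-N appearance in each module.
#: The numerator of every polarization contrast is a phenotype-positive
#: fraction, so suppressor mode (enriched in the positive fraction) credits
#: that phenotype's suppressors, mediator mode its mediators.  The
#: M2pos-vs-M1pos contrast additionally credits the opposite role of M1.
_ROLE_CREDITS: dict[tuple[str, Mode], list[tuple[str, str]]] = {
    ("M1pos_vs_input", "mediator"): [("M1", "mediator")],
    ("M1pos_vs_input", "suppressor"): [("M1", "suppressor")],
    ("M1pos_vs_M1neg", "mediator"): [("M1", "mediator")],
    ("M1pos_vs_M1neg", "suppressor"): [("M1", "suppressor")],
    ("M2pos_vs_input", "mediator"): [("M2", "mediator")],
    ("M2pos_vs_input", "suppressor"): [("M2", "suppressor")],
    ("M2pos_vs_M2neg", "mediator"): [("M2", "mediator")],
    ("M2pos_vs_M2neg", "suppressor"): [("M2", "suppressor")],
    ("M2pos_vs_M1pos", "mediator"): [("M2", "mediator"), ("M1", "suppressor")],
    ("M2pos_vs_M1pos", "suppressor"): [("M2", "suppressor"), ("M1", "mediator")],
}

CONTINGENCY_COLUMNS = [
    "m1_mediator", "m1_suppressor", "m2_mediator", "m2_suppressor",
]


def call_top_hits(scores: pd.DataFrame, top_n: int = DEFAULT_TOP_N) -> pd.DataFrame:
    """First ``top_n`` rows of a sorted gene-score table.

    The table is already deterministically ordered (p-value, effect-size
    quartile, gene symbol), so the hit list always has exactly ``top_n``
    entries.  The cutoff fraction 100*top_n/n_genes is attached as
    ``DataFrame.attrs['cutoff_pct']`` rounded to one decimal.
    """
    n_genes = len(scores)
    if top_n > n_genes:
        raise ValidationError(
            f"top_n={top_n} exceeds the {n_genes} scored genes"
        )
    hits = scores.head(top_n).reset_index(drop=True)
    hits.attrs["cutoff_pct"] = round(100.0 * top_n / n_genes, 1) if n_genes else 0.0
    return hits


def cutoff_percent(top_n: int, n_genes: int) -> float:
    """Hit-list cutoff as a percentage of genes tested, 1 decimal."""
    return round(100.0 * top_n / n_genes, 1)


def build_contingency(
    hits_by_module: dict[AnalysisModule, pd.DataFrame]
) -> pd.DataFrame:
    """Tally, per gene, how many comparisons placed it in the top N under
    each (phenotype, role), over the full ten-module polarization plan.

    Confidence is ``high`` when the gene appears in two or more distinct
    modules; the one contrast that credits two (phenotype, role) cells at
    once still counts as a single appearance.  Genes absent from every hit
    list are not reported.
    """
    plan_names = {m.name for m in default_plan()}
    have = {m.name for m in hits_by_module}
    missing = sorted(plan_names - have)
    if missing:
        raise ValidationError(
            f"analysis plan incomplete; missing module(s): {missing}"
        )
    counts: dict[str, dict[str, int]] = {}
    appearances: dict[str, int] = {}
    for module, hits in hits_by_module.items():
        key = (module.contrast.name, module.mode)
        if key not in _ROLE_CREDITS:
            continue  # e.g. the viability module
        for gene in hits["gene"]:
            appearances[gene] = appearances.get(gene, 0) + 1
            row = counts.setdefault(gene, dict.fromkeys(CONTINGENCY_COLUMNS, 0))
            for phenotype, role in _ROLE_CREDITS[key]:
                row[f"{phenotype.lower()}_{role}"] += 1
    records = []
    for gene in sorted(counts):
        rec = {"gene": gene, **counts[gene]}
        rec["n_modules"] = appearances[gene]
        rec["confidence"] = "high" if appearances[gene] >= 2 else "low"
        records.append(rec)
    return pd.DataFrame(
        records,
        columns=["gene", *CONTINGENCY_COLUMNS, "n_modules", "confidence"],
    )


def call_essential_genes(
    viability_scores: pd.DataFrame, top_n: int = DEFAULT_TOP_N
) -> list[str]:
    """Top-N genes by depletion RSA in the viable-monocytes vs input
    comparison: reagents lost over culture mark genes required for
    viability/growth."""
    if top_n == 0:
        return []
    return list(call_top_hits(viability_scores, top_n)["gene"])


def filter_hits_excluding_essential(
    contingency: pd.DataFrame,
    essential: list[str],
    high_confidence_only: bool = False,
) -> pd.DataFrame:
    """Remove essential genes (and optionally low-confidence hits) from the
    contingency table; removals are logged for provenance."""
    removed = [g for g in contingency["gene"] if g in set(essential)]
    if removed:
        logger.info("excluding %d essential gene(s) from shortlist: %s",
                    len(removed), removed)
    out = contingency[~contingency["gene"].isin(set(essential))]
    if high_confidence_only:
        out = out[out["confidence"] == "high"]
    return out.reset_index(drop=True)
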