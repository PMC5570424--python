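"""End-to-end screen analysis: normalize -> fold changes -> RSA -> hits ->
contingency -> essential filter, over the full analysis plan."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .hits import (
    DEFAULT_TOP_N,
    VIABILITY_MODULE,
    AnalysisModule,
    build_contingency,
    call_essential_genes,
    call_top_hits,
    cutoff_percent,
    default_plan,
    filter_hits_excluding_essential,
)
from .library import CountMatrix, ShRNALibrary
from .stats import (
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_SCALE,
    normalize_counts,
    score_all_genes,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """All artifacts of one full screen analysis."""

    scores: dict[AnalysisModule, pd.DataFrame]
    hits: dict[AnalysisModule, pd.DataFrame]
    contingency: pd.DataFrame
    essential: list[str]
    shortlist: pd.DataFrame
    skipped: list[AnalysisModule] = field(default_factory=list)
    top_n: int = DEFAULT_TOP_N
    n_genes: int = 0

    @property
    def n_polarization_modules(self) -> int:
        viability = {VIABILITY_MODULE.name}
        return sum(1 for m in self.scores if m.name not in viability)

    @property
    def cutoff_pct(self) -> float:
        return cutoff_percent(self.top_n, self.n_genes)

    def summary(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "top_n": self.top_n,
            "cutoff_pct": self.cutoff_pct,
            "polarization_modules": self.n_polarization_modules,
            "skipped_modules": [m.name for m in self.skipped],
            "n_hit_genes": int(len(self.contingency)),
            "n_high_confidence": int((self.contingency["confidence"] == "high").sum())
            if len(self.contingency) else 0,
            "n_essential": len(self.essential),
            "n_shortlist": int(len(self.shortlist)),
        }


def run_analysis(
    matrix: CountMatrix,
    library: ShRNALibrary,
    scale: float = DEFAULT_SCALE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    top_n: int = DEFAULT_TOP_N,
    allow_partial: bool = False,
    high_confidence_only: bool = True,
) -> AnalysisResult:
    """Run the full analysis plan on a raw count matrix.

    Without ``allow_partial`` every fraction required by the ten polarization
    modules plus the viability module must be present; with it, modules whose
    fractions are missing are skipped (and listed on the result).
    """
    norm = normalize_counts(matrix, scale)
    fractions = matrix.fractions()
    plan = default_plan() + [VIABILITY_MODULE]

    runnable, skipped = [], []
    for module in plan:
        need = {module.contrast.numerator, module.contrast.reference}
        (runnable if need <= fractions else skipped).append(module)
    if skipped and not allow_partial:
        raise ValidationError(
            "missing fractions for module(s) "
            f"{[m.name for m in skipped]}; rerun with allow_partial to skip"
        )
    for m in skipped:
        logger.warning("skipping module %s: fraction data missing", m.name)

    scores: dict[AnalysisModule, pd.DataFrame] = {}
    hits: dict[AnalysisModule, pd.DataFrame] = {}
    for module in runnable:
        df = score_all_genes(norm, module.contrast, module.mode, library,
                             pseudocount)
        scores[module] = df
        hits[module] = call_top_hits(df, top_n)
        logger.info("module %s: %d genes scored, top %d called",
                    module.name, len(df), top_n)

    polar_hits = {m: h for m, h in hits.items() if m.name != VIABILITY_MODULE.name}
    if len(polar_hits) == len(default_plan()):
        contingency = build_contingency(polar_hits)
    else:
        contingency = pd.DataFrame(
            columns=["gene", "m1_mediator", "m1_suppressor", "m2_mediator",
                     "m2_suppressor", "n_modules", "confidence"]
        )
        logger.warning("partial plan: contingency table not built")

    if VIABILITY_MODULE in scores:
        essential = call_essential_genes(scores[VIABILITY_MODULE], top_n)
    else:
        essential = []
    shortlist = filter_hits_excluding_essential(
        contingency, essential, high_confidence_only=high_confidence_only
    )
    return AnalysisResult(
        scores=scores,
        hits=hits,
        contingency=contingency,
        essential=essential,
        shortlist=shortlist,
        skipped=skipped,
        top_n=top_n,
        n_genes=library.n_genes,
    )
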