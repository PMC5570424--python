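"""Forward model of a FACS-sorted pooled shRNA screen.

The generator emulates the experiment end to end: a plasmid pool with
log-normal abundance skew, lentiviral transduction at one reagent per cell,
per-reagent knockdown efficacy, an untreated viability arm (essential-gene
dropout), two polarization arms in which each cell sorts into the
phenotype-positive or -negative fraction with a probability shifted by any
planted gene effect, biological-replicate noise, and multinomial read
sampling at a fixed sequencing depth.

Planted effects act through ``strength * efficacy``: a weak-knockdown shRNA
produces a proportionally weak phenotype, which is exactly the within-gene
rank structure the RSA statistic exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError
from .library import (
    BARCODE_LENGTH,
    CountMatrix,
    Fraction,
    SampleMeta,
    ShRNALibrary,
    ShRNAReagent,
    hamming_from_codes,
)

import pandas as pd

#: library composition: 648 genes at ~20 reagents/gene totalling 12,998.
#: 610 x 20 + 38 x 21 is the minimal-spread composition with that total.
DEFAULT_N_GENES = 648
DEFAULT_N_REAGENTS = 12_998
_N_GENES_21 = 38

#: reduced sequencing depth for desk-scale runs; gene-level scoring is
#: depth-robust above ~150 reads/reagent.
DESK_DEPTH = 2_000_000

Phenotype = Literal["M1", "M2", "viability"]
Role = Literal["mediator", "suppressor", "essential"]


@dataclass(frozen=True)
class PlantedEffect:
    """A gene effect planted into the simulation.

    ``strength`` in [0, 1] scales the per-reagent knockdown efficacy; a
    strength-0 effect behaves exactly as a null gene.  ``essential`` role is
    only meaningful for the viability phenotype (and vice versa).
    """

    gene: str
    phenotype: Phenotype
    role: Role
    strength: float

    def __post_init__(self):
        if not 0.0 <= self.strength <= 1.0:
            raise ValidationError(
                f"effect on {self.gene!r}: strength must be in [0, 1]"
            )
        if (self.role == "essential") != (self.phenotype == "viability"):
            raise ValidationError(
                f"effect on {self.gene!r}: role 'essential' pairs only with "
                "phenotype 'viability'"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated screen.

    Defaults reproduce the screen's stated scale: a 12,998-reagent / 648-gene
    library, ~12 million reads per sample, two biological replicates (one for
    the M1-negative fraction), and an ~11% baseline positive-sort rate for the
    M2 arm (the DMSO-control positive-cell rate; the M1 baseline is a free
    parameter).
    """

    n_genes: int = DEFAULT_N_GENES
    efficacy_beta: tuple[float, float] = (5.0, 2.0)
    pool_sigma: float = 0.5
    p_M1: float = 0.30
    p_M2: float = 0.11
    dropout_rate: float = 0.05
    cells_per_reagent: float = 500.0
    depth: int = 12_000_000
    # calibrated so replicate log10-count R^2 >= 0.97 at default depth,
    # matching the screen's reported replicate reproducibility
    rep_sigma: float = 0.04
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("p_M1", "p_M2", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.rep_sigma < 0:
            raise ValidationError("rep_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class TruthTable:
    """Planted effects and per-reagent efficacies, for recovery evaluation."""

    effects: list[PlantedEffect]
    efficacies: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [e.gene for e in self.effects],
                "phenotype": [e.phenotype for e in self.effects],
                "role": [e.role for e in self.effects],
                "strength": [e.strength for e in self.effects],
            }
        )


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _random_distinct_barcodes(
    n: int, rng: np.random.Generator, min_dist: int = 3
) -> list[str]:
    """Random 18-mers with pairwise Hamming distance >= min_dist.

    Rejection sampling: with 4^18 possible 18-mers, fewer than a handful of
    the ~n^2/2 pairs land within distance 2, so nearly all candidates survive
    the first round.  Distances are computed on 2-bit-packed codes with XOR +
    popcount, chunked to bound memory.
    """
    k = BARCODE_LENGTH
    shifts = 2 * np.arange(k, dtype=np.int64)

    def draw(m: int) -> tuple[np.ndarray, np.ndarray]:
        mat = rng.integers(0, 4, size=(m, k))
        return mat, (mat.astype(np.int64) << shifts).sum(axis=1)

    mat, codes = draw(n)
    while True:
        bad = np.zeros(n, dtype=bool)
        block = 512
        for start in range(0, n, block):
            d = hamming_from_codes(codes[start : start + block, None], codes[None, :])
            ii, jj = np.nonzero(d < min_dist)
            for i, j in zip(ii, jj):
                if start + int(i) < int(j):  # greedy: keep first of each pair
                    bad[int(j)] = True
        if not bad.any():
            break
        m = int(bad.sum())
        mat[bad], codes[bad] = draw(m)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(bases[row]).decode() for row in mat]


def build_library(
    reagent_plan: Sequence[int], seed: int = 0, min_dist: int = 3
) -> ShRNALibrary:
    """Build a simulated library from a per-gene reagent-count plan, with
    random pairwise-distant 18-nt barcodes.  Deterministic given the seed."""
    total = int(sum(reagent_plan))
    rng = np.random.default_rng(seed)
    barcodes = _random_distinct_barcodes(total, rng, min_dist=min_dist)
    reagents = []
    b = 0
    for g, n_sh in enumerate(reagent_plan):
        gene = f"G{g + 1:04d}"
        for j in range(n_sh):
            reagents.append(
                ShRNAReagent(f"{gene}_sh{j + 1:02d}", gene, barcodes[b])
            )
            b += 1
    return ShRNALibrary(reagents)


def default_reagent_plan() -> list[int]:
    """648 genes at 12,998 reagents total: 38 genes with 21 reagents, 610
    with 20 — the minimal-spread composition with mean ~= 20/gene."""
    return [21] * _N_GENES_21 + [20] * (DEFAULT_N_GENES - _N_GENES_21)


def build_default_library(seed: int = 0) -> ShRNALibrary:
    """The default simulated library: 648 genes, 12,998 reagents, random
    18-nt barcodes at pairwise Hamming distance >= 3."""
    return build_library(default_reagent_plan(), seed=seed)


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

def sort_probability(
    p0: float, role: Role | None, strength: float, efficacy: float
) -> float:
    """Probability a cell carrying a reagent sorts into the positive fraction.

    Nulls sort at the baseline rate p0.  Knocking down a phenotype mediator
    lowers the rate by the factor (1 - strength*efficacy); knocking down a
    suppressor moves it the complementary distance toward 1.
    """
    knock = strength * efficacy
    if role is None or knock == 0.0:
        return p0
    if role == "mediator":
        return p0 * (1.0 - knock)
    if role == "suppressor":
        return p0 + knock * (1.0 - p0)
    raise ValidationError(f"role {role!r} has no sorting semantics")


def survival_probability(
    dropout_rate: float, strength: float, efficacy: float
) -> float:
    """Survival probability in the untreated viability arm; essential-gene
    knockdown multiplies baseline survival by (1 - strength*efficacy)."""
    return (1.0 - dropout_rate) * (1.0 - strength * efficacy)


def _effect_vectors(
    library: ShRNALibrary, effects: Sequence[PlantedEffect]
) -> dict[Phenotype, tuple[np.ndarray, np.ndarray]]:
    """Per-phenotype (strength, is_suppressor) vectors over reagents."""
    n = len(library)
    gene_rows: dict[str, list[int]] = {}
    for i, rg in enumerate(library.reagents):
        gene_rows.setdefault(rg.gene, []).append(i)
    out: dict[Phenotype, tuple[np.ndarray, np.ndarray]] = {}
    seen: set[tuple[str, str]] = set()
    for ph in ("M1", "M2", "viability"):
        out[ph] = (np.zeros(n), np.zeros(n, dtype=bool))
    for e in effects:
        if e.gene not in library.gene_index:
            raise ValidationError(f"planted gene {e.gene!r} absent from library")
        key = (e.gene, e.phenotype)
        if key in seen:
            raise ValidationError(
                f"gene {e.gene!r} has more than one effect on phenotype "
                f"{e.phenotype!r}"
            )
        seen.add(key)
        strength, supp = out[e.phenotype]
        rows = gene_rows[e.gene]
        strength[rows] = e.strength
        supp[rows] = e.role == "suppressor"
    return out


def simulate_screen(
    library: ShRNALibrary,
    config: SimulationConfig,
    effects: Sequence[PlantedEffect] = (),
) -> tuple[CountMatrix, TruthTable]:
    """Simulate the sorted screen and return a raw count matrix plus the
    truth table of planted effects and drawn efficacies.

    Samples emitted: plasmid (single), then input, viable_Mo, M1pos, M2pos
    and M2neg with ``n_replicates`` biological replicates each, and M1neg
    with a single replicate (matching the screen design).  Every sample
    column is a multinomial draw of ``depth`` reads.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = len(library)

    # (1) plasmid pool abundance skew
    abundance = rng.lognormal(0.0, config.pool_sigma, n)
    abundance /= abundance.sum()

    # (2) transduced input population
    cells = rng.poisson(config.cells_per_reagent * n * abundance)

    # (3) knockdown efficacy per reagent
    a, b = config.efficacy_beta
    efficacy = rng.beta(a, b, n)

    ev = _effect_vectors(library, effects)

    # (4) viability arm
    s_v, _ = ev["viability"]
    surv_p = (1.0 - config.dropout_rate) * (1.0 - s_v * efficacy)
    viable = rng.binomial(cells, surv_p)

    # (5) polarization arms: positive/negative sort is mutually exclusive
    def arm(p0: float, ph: Phenotype) -> tuple[np.ndarray, np.ndarray]:
        strength, supp = ev[ph]
        knock = strength * efficacy
        p = np.where(supp, p0 + knock * (1.0 - p0), p0 * (1.0 - knock))
        pos = rng.binomial(cells, p)
        return pos, cells - pos

    m1pos, m1neg = arm(config.p_M1, "M1")
    m2pos, m2neg = arm(config.p_M2, "M2")

    # (6)+(7) replicate noise and multinomial read sampling
    def sequence(base: np.ndarray, with_rep_noise: bool = True) -> np.ndarray:
        w = base.astype(float)
        if with_rep_noise and config.rep_sigma > 0:
            w = w * rng.lognormal(0.0, config.rep_sigma, n)
        total = w.sum()
        if total <= 0:
            raise ValidationError("a sample has zero total abundance")
        return rng.multinomial(config.depth, w / total)

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []

    def emit(fraction: Fraction, base: np.ndarray, n_reps: int,
             rep_noise: bool = True) -> None:
        for rep in range(1, n_reps + 1):
            sid = f"{fraction.value}_r{rep}"
            columns[sid] = sequence(base, rep_noise)
            samples.append(SampleMeta(sid, fraction, rep))

    emit(Fraction.PLASMID, abundance, 1, rep_noise=False)
    emit(Fraction.INPUT, cells, config.n_replicates)
    emit(Fraction.VIABLE_MO, viable, config.n_replicates)
    emit(Fraction.M1POS, m1pos, config.n_replicates)
    emit(Fraction.M1NEG, m1neg, 1)  # single biological replicate by design
    emit(Fraction.M2POS, m2pos, config.n_replicates)
    emit(Fraction.M2NEG, m2neg, config.n_replicates)

    values = pd.DataFrame(columns, index=pd.Index(library.reagent_ids,
                                                  name="reagent_id"))
    matrix = CountMatrix(values=values, samples=samples, normalized=False)
    truth = TruthTable(
        effects=list(effects),
        efficacies=dict(zip(library.reagent_ids, efficacy)),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

#: read layout constants shared with barcode_quant
DEFAULT_ANCHOR = "ACCG"
READ_LENGTH = 50
_FILLER = ("ACGT" * (READ_LENGTH // 4 + 1))


def emit_fastq(
    matrix: CountMatrix,
    library: ShRNALibrary,
    out_dir: str | Path,
    anchor: str = DEFAULT_ANCHOR,
    error_rate: float = 0.0,
    seed: int = 0,
    compress: bool = False,
) -> dict[str, Path]:
    """Write one FASTQ file per sample, one read per counted barcode event.

    Read structure: 5' anchor + 18-nt barcode + constant filler, total length
    50, constant quality 'I'.  Per-base substitution errors are applied at
    ``error_rate``.  Reads are emitted grouped by library reagent order, so an
    error-free emission is exactly reproducible from the count matrix.
    """
    if matrix.normalized:
        raise ValidationError("FASTQ emission requires a raw (integer) matrix")
    if not 0.0 <= error_rate < 1.0:
        raise ValidationError("error_rate must be in [0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    code = {b: i for i, b in enumerate("ACGT")}

    templates = np.empty((len(library), READ_LENGTH), dtype=np.int8)
    for i, rg in enumerate(library.reagents):
        read = (anchor + rg.barcode + _FILLER)[:READ_LENGTH]
        templates[i] = [code[c] for c in read]

    qual = "I" * READ_LENGTH
    paths: dict[str, Path] = {}
    import gzip

    for sid in matrix.sample_ids:
        counts = matrix.values[sid].to_numpy()
        fname = out_dir / (f"{sid}.fastq.gz" if compress else f"{sid}.fastq")
        opener = gzip.open if compress else open
        with opener(fname, "wt") as fh:
            serial = 0
            for i in np.nonzero(counts)[0]:
                c = int(counts[i])
                reads = np.tile(templates[i], (c, 1))
                if error_rate > 0:
                    err = rng.random((c, READ_LENGTH)) < error_rate
                    # substitute with a uniformly chosen *different* base
                    shift = rng.integers(1, 4, size=err.sum())
                    reads[err] = (reads[err] + shift) % 4
                for row in reads:
                    seq = bytes(base_map[row]).decode()
                    fh.write(f"@{sid}:{serial}\n{seq}\n+\n{qual}\n")
                    serial += 1
        paths[sid] = fname
    return paths
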