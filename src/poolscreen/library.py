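"""Data model and I/O for the shRNA reagent library, sample sheets and count
matrices.

A pooled screen library maps each shRNA reagent to the gene it targets and to
a unique 18-nt DNA barcode used to count reagent abundance by amplicon
sequencing.  Count matrices hold reagents x samples read counts, either raw
(non-negative integers straight from barcode counting) or depth-normalized
(each sample column scaled to a common total, canonically 12 million reads).

All on-disk formats are UTF-8 tab-delimited text with a mandatory header;
lines starting with '#' are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

BARCODE_LENGTH = 18
_BASES = frozenset("ACGT")

#: relative tolerance on normalized column sums
NORM_RTOL = 1e-9


class Fraction(str, Enum):
    """Cell fractions collected in the sorted polarization screen."""

    PLASMID = "plasmid"
    INPUT = "input"
    VIABLE_MO = "viable_Mo"
    M1POS = "M1pos"
    M1NEG = "M1neg"
    M2POS = "M2pos"
    M2NEG = "M2neg"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ShRNAReagent:
    """One shRNA reagent: unique id, targeted gene symbol, 18-nt barcode."""

    reagent_id: str
    gene: str
    barcode: str

    def __post_init__(self):
        if len(self.barcode) != BARCODE_LENGTH:
            raise ValidationError(
                f"reagent {self.reagent_id!r}: barcode {self.barcode!r} has "
                f"length {len(self.barcode)}, expected {BARCODE_LENGTH}"
            )
        if not set(self.barcode) <= _BASES:
            raise ValidationError(
                f"reagent {self.reagent_id!r}: barcode {self.barcode!r} "
                "contains characters outside ACGT"
            )


class ShRNALibrary:
    """Ordered collection of reagents with gene and barcode indexes.

    Uniqueness of ``reagent_id`` and ``barcode`` is enforced at construction;
    row order is preserved (it defines count-matrix row order).
    """

    def __init__(self, reagents: Sequence[ShRNAReagent]):
        self.reagents: list[ShRNAReagent] = list(reagents)
        if not self.reagents:
            raise ValidationError("library must contain at least one reagent")
        self._by_id: dict[str, ShRNAReagent] = {}
        self._by_barcode: dict[str, str] = {}
        self.gene_index: dict[str, list[str]] = {}
        for row, rg in enumerate(self.reagents):
            if rg.reagent_id in self._by_id:
                raise ValidationError(
                    f"duplicate reagent_id {rg.reagent_id!r} at row {row}"
                )
            if rg.barcode in self._by_barcode:
                raise ValidationError(
                    f"duplicate barcode {rg.barcode!r} shared by reagents "
                    f"{self._by_barcode[rg.barcode]!r} and {rg.reagent_id!r} "
                    f"(row {row})"
                )
            self._by_id[rg.reagent_id] = rg
            self._by_barcode[rg.barcode] = rg.reagent_id
            self.gene_index.setdefault(rg.gene, []).append(rg.reagent_id)
        # caches filled lazily by close_pair_report()
        self._close_pairs: dict[int, list[tuple[str, str, int]]] = {}

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.reagents)

    def __eq__(self, other) -> bool:
        return isinstance(other, ShRNALibrary) and self.reagents == other.reagents

    def __contains__(self, reagent_id: str) -> bool:
        return reagent_id in self._by_id

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def genes(self) -> list[str]:
        return list(self.gene_index)

    @property
    def reagent_ids(self) -> list[str]:
        return [r.reagent_id for r in self.reagents]

    @property
    def barcodes(self) -> list[str]:
        return [r.barcode for r in self.reagents]

    def reagent(self, reagent_id: str) -> ShRNAReagent:
        return self._by_id[reagent_id]

    def gene_of(self, reagent_id: str) -> str:
        return self._by_id[reagent_id].gene

    # -- barcode-space diagnostics ------------------------------------------------
    def barcode_codes(self) -> np.ndarray:
        """Barcodes packed 2 bits/base into int64, one per reagent."""
        return pack_barcodes(self.barcodes)

    def close_pair_report(self, max_dist: int = 2) -> list[tuple[str, str, int]]:
        """All reagent pairs whose barcodes are within Hamming distance
        ``max_dist`` of each other.

        Barcode-correction during FASTQ deconvolution is only safe when this
        report is empty at ``max_dist=2`` (any observed 18-mer then has at most
        one whitelist barcode within distance 1).  Cached per library.
        """
        if max_dist not in self._close_pairs:
            codes = self.barcode_codes()
            ids = self.reagent_ids
            pairs = []
            for i, j, d in _close_code_pairs(codes, max_dist):
                pairs.append((ids[i], ids[j], d))
            self._close_pairs[max_dist] = pairs
        return self._close_pairs[max_dist]


def pack_barcodes(barcodes: Iterable[str]) -> np.ndarray:
    """Pack ACGT strings into int64 codes, 2 bits per base."""
    lut = np.full(128, -1, dtype=np.int64)
    for v, b in enumerate("ACGT"):
        lut[ord(b)] = v
    arr = np.frombuffer("".join(barcodes).encode(), dtype=np.uint8)
    vals = lut[arr]
    if (vals < 0).any():
        raise ValidationError("barcode contains characters outside ACGT")
    k = BARCODE_LENGTH
    vals = vals.reshape(-1, k)
    shifts = 2 * np.arange(k, dtype=np.int64)
    return (vals << shifts).sum(axis=1)


_ODD_BITS = np.int64(0x5555555555555555)


def hamming_from_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise (broadcast) Hamming distance between packed barcodes."""
    z = np.bitwise_xor(a, b)
    return np.bitwise_count((z | (z >> 1)) & _ODD_BITS)


def _close_code_pairs(codes: np.ndarray, max_dist: int, block: int = 512):
    """Yield (i, j, dist) for i<j with Hamming distance <= max_dist."""
    n = codes.size
    for start in range(0, n, block):
        chunk = codes[start : start + block]
        d = hamming_from_codes(chunk[:, None], codes[None, :])
        ii, jj = np.nonzero(d <= max_dist)
        for i, j in zip(ii, jj):
            gi = start + int(i)
            if gi < int(j):
                yield gi, int(j), int(d[i, j])


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: which sorted fraction, which biological replicate."""

    sample_id: str
    fraction: Fraction
    replicate: int

    def __post_init__(self):
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


def validate_sample_sheet(samples: Sequence[SampleMeta]) -> None:
    seen_ids: set[str] = set()
    seen_pairs: set[tuple[Fraction, int]] = set()
    for s in samples:
        if s.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        pair = (s.fraction, s.replicate)
        if pair in seen_pairs:
            raise ValidationError(
                f"duplicate (fraction, replicate) pair "
                f"({s.fraction.value}, {s.replicate})"
            )
        seen_ids.add(s.sample_id)
        seen_pairs.add(pair)


@dataclass
class CountMatrix:
    """Reagents x samples count grid with sample metadata.

    ``values`` is indexed by reagent_id (library row order) with one column per
    sample_id.  Raw matrices hold non-negative integers; normalized matrices
    hold non-negative reals whose columns each sum to ``scale``.  When a matrix
    was normalized in-memory, ``raw_totals`` keeps the pre-normalization column
    sums so downstream pseudocounts can be propagated on the same footing.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    normalized: bool = False
    scale: float | None = None
    raw_totals: pd.Series | None = None

    def __post_init__(self):
        validate_sample_sheet(self.samples)
        meta_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != meta_ids:
            raise ValidationError(
                "count matrix columns do not match sample metadata order"
            )
        if (np.asarray(self.values.values) < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.normalized:
            vals = self.values.values
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.allclose(vals, np.round(vals)):
                    raise ValidationError("raw counts must be integers")
                self.values = self.values.round().astype(np.int64)
        else:
            if self.scale is None:
                raise ValidationError("normalized matrix requires a scale")
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, self.scale, rtol=NORM_RTOL, atol=0):
                bad = sums.index[~np.isclose(sums, self.scale, rtol=NORM_RTOL)]
                raise ValidationError(
                    f"normalized columns do not sum to scale: {list(bad)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_for(self, fraction: Fraction) -> list[str]:
        return [s.sample_id for s in self.samples if s.fraction == fraction]

    def fractions(self) -> set[Fraction]:
        return {s.fraction for s in self.samples}

    def with_values(self, values: pd.DataFrame, **kw) -> "CountMatrix":
        args = dict(
            values=values,
            samples=self.samples,
            normalized=self.normalized,
            scale=self.scale,
            raw_totals=self.raw_totals,
        )
        args.update(kw)
        return CountMatrix(**args)


# ---------------------------------------------------------------------------
# Tab-delimited I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )
    return df


def read_library(path: str | Path) -> ShRNALibrary:
    """Read a library TSV with columns reagent_id, gene, barcode."""
    df = _read_tsv(path, ["reagent_id", "gene", "barcode"])
    reagents = [
        ShRNAReagent(str(r.reagent_id), str(r.gene), str(r.barcode))
        for r in df.itertuples(index=False)
    ]
    return ShRNALibrary(reagents)


def write_library(library: ShRNALibrary, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "reagent_id": library.reagent_ids,
            "gene": [r.gene for r in library.reagents],
            "barcode": library.barcodes,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a sample sheet TSV with columns sample_id, fraction, replicate."""
    df = _read_tsv(path, ["sample_id", "fraction", "replicate"])
    samples = []
    for r in df.itertuples(index=False):
        try:
            frac = Fraction(str(r.fraction))
        except ValueError:
            raise ValidationError(
                f"{path}: unknown fraction {r.fraction!r} for sample "
                f"{r.sample_id!r}; expected one of "
                f"{[f.value for f in Fraction]}"
            ) from None
        samples.append(SampleMeta(str(r.sample_id), frac, int(r.replicate)))
    validate_sample_sheet(samples)
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "fraction": [s.fraction.value for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path,
    library: ShRNALibrary,
    sheet: Sequence[SampleMeta],
    normalized: bool = False,
    scale: float | None = None,
) -> CountMatrix:
    """Read a counts TSV (first column reagent_id, one column per sample).

    Rows are re-aligned to library order.  Library reagents missing from the
    file get all-zero rows (with a logged warning); reagent ids not in the
    library are an error, as are samples absent from the sample sheet.
    """
    df = _read_tsv(path, ["reagent_id"])
    sheet = list(sheet)
    sheet_ids = {s.sample_id: s for s in sheet}
    file_samples = [c for c in df.columns if c != "reagent_id"]
    unknown_samples = [s for s in file_samples if s not in sheet_ids]
    if unknown_samples:
        raise ValidationError(
            f"{path}: sample(s) {unknown_samples} absent from the sample sheet"
        )
    df = df.set_index("reagent_id")
    unknown = [r for r in df.index if r not in library]
    if unknown:
        raise ValidationError(
            f"{path}: unknown reagent_id(s) not in library: {unknown[:10]}"
        )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate reagent_id rows: {dups[:10]}")

    vals = df.astype(float)
    if not normalized:
        arr = vals.values
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            bad = vals.index[((arr < 0) | ~np.isclose(arr, np.round(arr))).any(axis=1)]
            raise ValidationError(
                f"{path}: negative or non-integer raw counts for reagent(s) "
                f"{list(bad[:10])}"
            )

    missing = [r for r in library.reagent_ids if r not in df.index]
    if missing:
        logger.warning(
            "%s: %d library reagent(s) missing from counts file; "
            "filled with zeros", path, len(missing)
        )
    full = vals.reindex(library.reagent_ids, fill_value=0.0)
    if not normalized:
        full = full.round().astype(np.int64)
    samples = [sheet_ids[s] for s in file_samples]
    return CountMatrix(
        values=full[file_samples],
        samples=samples,
        normalized=normalized,
        scale=scale,
    )


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write a counts TSV.  Raw matrices round-trip exactly; normalized values
    are serialized with 15 significant digits (column sums preserved well
    within the 1e-9 relative tolerance)."""
    if not matrix.samples:
        raise ValidationError("cannot write a count matrix with no samples")
    out = matrix.values.copy()
    out.insert(0, "reagent_id", out.index)
    if matrix.normalized:
        out.to_csv(path, sep="\t", index=False, float_format="%.15g")
    else:
        out.to_csv(path, sep="\t", index=False)
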