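"""Barcode deconvolution: count library barcodes in FASTQ reads.

Reads carry a fixed-position 18-nt barcode after a short constant anchor.
Matching is exact-first; optionally a read with a single substitution is
rescued when exactly one whitelist barcode lies at Hamming distance 1
(substitution-only correction — indels are not modeled on fixed-offset
amplicon reads).  Correction is only enabled after verifying that no two
whitelist barcodes are within distance 2 of each other, which guarantees
every correction is unique.  Ambiguous reads are discarded, never
fractionally assigned.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError, ValidationError
from .library import BARCODE_LENGTH, ShRNALibrary

_BASES = "ACGT"


@dataclass(frozen=True)
class ReadLayout:
    """Where the barcode sits in a read: a 5' constant anchor followed by the
    18-nt barcode at ``barcode_offset``."""

    anchor: str = "ACCG"
    barcode_offset: int | None = None  # defaults to len(anchor)
    barcode_length: int = BARCODE_LENGTH

    def __post_init__(self):
        if self.barcode_length != BARCODE_LENGTH:
            raise ValidationError(
                f"barcode_length must be {BARCODE_LENGTH}"
            )
        if self.barcode_offset is None:
            object.__setattr__(self, "barcode_offset", len(self.anchor))


@dataclass
class QuantStats:
    """Read accounting for one sample; categories partition total_reads."""

    total_reads: int = 0
    anchor_fail: int = 0
    exact_match: int = 0
    corrected_match: int = 0
    ambiguous: int = 0
    unmatched: int = 0

    def check(self) -> None:
        parts = (
            self.anchor_fail + self.exact_match + self.corrected_match
            + self.ambiguous + self.unmatched
        )
        if parts != self.total_reads:
            raise AssertionError("QuantStats categories do not sum to total")


class BarcodeMatcher:
    """Indexed whitelist lookup with optional unique Hamming-1 correction."""

    def __init__(self, library: ShRNALibrary, max_mismatch: int = 0):
        if max_mismatch not in (0, 1):
            raise ValidationError("max_mismatch must be 0 or 1")
        self.max_mismatch = max_mismatch
        self._exact = {r.barcode: r.reagent_id for r in library.reagents}
        if max_mismatch == 1:
            close = library.close_pair_report(max_dist=2)
            if close:
                raise ValidationError(
                    "Hamming-1 correction unsafe: "
                    f"{len(close)} whitelist barcode pair(s) within distance 2, "
                    f"e.g. {close[0][0]!r} vs {close[0][1]!r} (d={close[0][2]})"
                )

    def match(self, observed: str) -> str | None:
        """Return the matching reagent_id, 'ambiguous', or None."""
        if len(observed) != BARCODE_LENGTH:
            return None
        hit = self._exact.get(observed)
        if hit is not None:
            return hit
        if self.max_mismatch == 0:
            return None
        found: str | None = None
        obs = list(observed)
        for pos in range(BARCODE_LENGTH):
            orig = obs[pos]
            for base in _BASES:
                if base == orig:
                    continue
                obs[pos] = base
                hit = self._exact.get("".join(obs))
                if hit is not None:
                    if found is not None and hit != found:
                        obs[pos] = orig
                        return "ambiguous"
                    found = hit
            obs[pos] = orig
        return found


def match_barcode(
    observed: str, library: ShRNALibrary, max_mismatch: int = 0
) -> str | None:
    """One-shot barcode match (see :class:`BarcodeMatcher`).  For per-read
    loops build the matcher once instead."""
    return BarcodeMatcher(library, max_mismatch).match(observed)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_fastq(
    fastq: str | Path,
    library: ShRNALibrary,
    layout: ReadLayout = ReadLayout(),
    max_mismatch: int = 0,
) -> tuple[pd.Series, QuantStats]:
    """Count library barcodes in one FASTQ file.

    Returns a per-reagent count column (library row order) and read-level
    accounting.  Reads with any mismatch in the anchor are not barcode-matched
    (counted as ``anchor_fail``); malformed barcodes count as unmatched.
    """
    matcher = BarcodeMatcher(library, max_mismatch)
    counts: dict[str, int] = dict.fromkeys(library.reagent_ids, 0)
    stats = QuantStats()
    off = layout.barcode_offset
    end = off + layout.barcode_length
    anchor = layout.anchor
    alen = len(anchor)

    with _open_maybe_gzip(fastq) as fh:
        record_index = 0
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                record_index += 1
                stats.total_reads += 1
                if len(seq) < end or seq[:alen] != anchor:
                    stats.anchor_fail += 1
                    continue
                hit = matcher.match(seq[off:end])
                if hit is None:
                    stats.unmatched += 1
                elif hit == "ambiguous":
                    stats.ambiguous += 1
                else:
                    counts[hit] += 1
                    if seq[off:end] == library.reagent(hit).barcode:
                        stats.exact_match += 1
                    else:
                        stats.corrected_match += 1
        except ValueError as exc:
            raise FastqParseError(
                f"{fastq}: malformed FASTQ at record {record_index + 1}: {exc}",
                record_index=record_index + 1,
            ) from exc

    stats.check()
    return pd.Series(counts, name=Path(fastq).stem), stats


def stats_frame(stats_by_sample: dict[str, QuantStats]) -> pd.DataFrame:
    """Tabulate per-sample read accounting for reporting."""
    rows = []
    for sid, st in stats_by_sample.items():
        rows.append(
            {
                "sample_id": sid,
                "total_reads": st.total_reads,
                "anchor_fail": st.anchor_fail,
                "exact_match": st.exact_match,
                "corrected_match": st.corrected_match,
                "ambiguous": st.ambiguous,
                "unmatched": st.unmatched,
            }
        )
    return pd.DataFrame(rows)
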