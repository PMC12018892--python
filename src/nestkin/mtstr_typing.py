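"""mtDNA control-region AT-repeat (mtSTR) haplotype barcoding.

The 3' end of the green-turtle mtDNA control region carries four tandem
AT-dinucleotide repeat loci.  A haplotype is the ordered quadruple of repeat
counts, written as a four-number barcode such as ``6-8-8-4``.  Because the
marker is maternally inherited, the barcode labels a matriline.  Individuals
can be heteroplasmic (carry a minor variant); the major haplotype is called
from relative peak heights, locus by locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MtStrHaplotype",
    "SegmentationError",
    "AmbiguousPeakError",
    "segment_at_loci",
    "count_repeats",
    "barcode",
    "parse_barcode",
    "type_sequence",
    "call_major_haplotype",
    "read_fasta_barcodes",
    "inventory_overlap",
]


class SegmentationError(ValueError):
    """The amplicon does not contain the expected number of AT-repeat runs."""


class AmbiguousPeakError(ValueError):
    """Two candidate repeat counts at a locus have exactly equal peak heights."""


@dataclass(frozen=True)
class MtStrHaplotype:
    """Four AT-repeat counts, with optional heteroplasmic minor variant."""

    repeat_counts: tuple[int, int, int, int]
    heteroplasmic: bool = False
    minor_counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.repeat_counts) != 4 or any(c < 0 for c in self.repeat_counts):
            raise ValueError("repeat_counts must be four non-negative integers")
        if self.heteroplasmic:
            if self.minor_counts is None or self.minor_counts == self.repeat_counts:
                raise ValueError(
                    "heteroplasmic haplotype requires minor_counts differing at >=1 locus"
                )

    @property
    def barcode(self) -> str:
        return barcode(self.repeat_counts)

    @property
    def minor_barcode(self) -> str | None:
        return None if self.minor_counts is None else barcode(self.minor_counts)


_AT_RUN = re.compile(r"(?:AT)+")


def segment_at_loci(
    sequence: str, min_run: int = 3, n_loci: int = 4
) -> list[tuple[int, int]]:
    """Locate the four AT-repeat loci in a control-region amplicon.

    A locus is a maximal run of the ``AT`` dimer at least ``min_run`` dimers
    long; runs are returned 5'->3' as 0-based half-open spans.  The input is
    taken as the forward strand as sequenced (no reverse-complement search).

    Raises
    ------
    SegmentationError
        If the number of qualifying runs differs from ``n_loci``.
    """
    seq = sequence.upper().replace("U", "T")
    spans = [
        (m.start(), m.end())
        for m in _AT_RUN.finditer(seq)
        if (m.end() - m.start()) // 2 >= min_run
    ]
    if len(spans) != n_loci:
        found = [(s, e, (e - s) // 2) for s, e in spans]
        raise SegmentationError(
            f"expected {n_loci} AT-repeat runs of >= {min_run} dimers, found "
            f"{len(spans)}: {found}"
        )
    return spans


def count_repeats(sequence: str, min_run: int = 3, n_loci: int = 4) -> tuple[int, ...]:
    """Repeat count (number of AT dimers) at each locus, 5'->3'."""
    return tuple((e - s) // 2 for s, e in segment_at_loci(sequence, min_run, n_loci))


def barcode(counts: Iterable[int]) -> str:
    """Hyphen-joined decimal barcode, e.g. ``(6, 8, 8, 4) -> "6-8-8-4"``."""
    return "-".join(str(int(c)) for c in counts)


def parse_barcode(code: str) -> tuple[int, ...]:
    return tuple(int(x) for x in code.split("-"))


def type_sequence(sequence: str, min_run: int = 3) -> MtStrHaplotype:
    """Barcode a single consensus amplicon sequence (no heteroplasmy call)."""
    counts = count_repeats(sequence, min_run=min_run)
    return MtStrHaplotype(repeat_counts=counts)  # type: ignore[arg-type]


def call_major_haplotype(
    peaks: Mapping[int, Mapping[int, float]], noise_floor: float = 0.2
) -> MtStrHaplotype:
    """Resolve heteroplasmy from per-locus peak heights.

    Parameters
    ----------
    peaks:
        Locus index (0..3, or any four sortable keys) -> {repeat count ->
        peak height}.  Heights must be positive.
    noise_floor:
        A secondary peak counts as a heteroplasmic minor allele when its
        height is at least this fraction of the major peak's height.

    The major count per locus is the height argmax.  An exact height tie is
    an error rather than an arbitrary call.
    """
    loci = sorted(peaks)
    if len(loci) != 4:
        raise ValueError(f"expected peak tables for 4 loci, got {len(loci)}")
    major: list[int] = []
    minor: list[int] = []
    heteroplasmic = False
    for locus in loci:
        table = peaks[locus]
        if not table or any(h <= 0 for h in table.values()):
            raise ValueError(f"locus {locus}: peak heights must be positive")
        ranked = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
        top_count, top_h = ranked[0]
        if len(ranked) > 1 and ranked[1][1] == top_h:
            raise AmbiguousPeakError(
                f"locus {locus}: counts {top_count} and {ranked[1][0]} tie at height {top_h}"
            )
        major.append(top_count)
        if len(ranked) > 1 and ranked[1][1] >= noise_floor * top_h:
            heteroplasmic = True
            minor.append(ranked[1][0])
        else:
            minor.append(top_count)
    return MtStrHaplotype(
        repeat_counts=tuple(major),  # type: ignore[arg-type]
        heteroplasmic=heteroplasmic,
        minor_counts=tuple(minor) if heteroplasmic else None,  # type: ignore[arg-type]
    )


def read_fasta_barcodes(path: str | Path, min_run: int = 3) -> pd.DataFrame:
    """Barcode every record of a FASTA of control-region amplicons.

    Returns a frame with columns ``sample_id``, ``barcode``; a record that
    cannot be segmented raises :class:`SegmentationError` naming the record.
    """
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            counts = count_repeats(str(rec.seq), min_run=min_run)
        except SegmentationError as exc:
            raise SegmentationError(f"record {rec.id}: {exc}") from exc
        rows.append({"sample_id": rec.id, "barcode": barcode(counts)})
    return pd.DataFrame(rows, columns=["sample_id", "barcode"])


def inventory_overlap(inventory: Mapping[str, Iterable[str]]) -> dict:
    """Set algebra over per-category barcode inventories.

    Returns per-category totals, all pairwise and higher-order intersection
    sizes, the union size, and each category's share of the union as a
    percentage rounded to the nearest integer.
    """
    sets = {k: set(v) for k, v in inventory.items()}
    if not sets:
        raise ValueError("inventory must contain at least one category")
    union: set[str] = set().union(*sets.values())
    inter: dict[str, int] = {}
    cats = sorted(sets)
    for r in range(2, len(cats) + 1):
        for combo in combinations(cats, r):
            common = set.intersection(*(sets[c] for c in combo))
            inter["&".join(combo)] = len(common)
    pct = {
        k: int(round(100.0 * len(s) / len(union))) if union else 0
        for k, s in sets.items()
    }
    return {
        "category_sizes": {k: len(s) for k, s in sets.items()},
        "intersections": inter,
        "union_size": len(union),
        "percent_of_union": pct,
    }
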