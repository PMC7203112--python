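"""Motif-arrangement grammar and sequence/genome scanning.

Homeodomain transcription factors recognise short core motifs (e.g. TAAT,
TGAA) whose *arrangement* — tandem direct repeats, inverted (tail-to-tail)
or everted (head-to-head) pairs, with or without spacer nucleotides —
strongly modulates binding affinity because appropriately arranged copies
allow two protein monomers to dimerise on the DNA. This module defines the
grammar of such arrangements, expands an arrangement into its composite
probe sequence, and scans sequences or whole genomes for occurrences.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Layout",
    "MotifPattern",
    "ArrangementSpec",
    "MotifSite",
    "reverse_complement",
    "expand_arrangement",
    "arrangement_pattern",
    "scan_sequence",
    "scan_genome",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")


class Layout(str, Enum):
    """Relative orientation of motif copies in a composite element."""

    SINGLE = "single"
    DIRECT_REPEAT = "direct_repeat"
    INVERTED_TAIL_TO_TAIL = "inverted_tail_to_tail"
    EVERTED_HEAD_TO_HEAD = "everted_head_to_head"


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement. N maps to N.

    >>> reverse_complement("TGAA")
    'TTCA'
    """
    seq = seq.upper()
    if not _DNA_N.issuperset(seq):
        bad = sorted(set(seq) - _DNA_N)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A core recognition motif, e.g. the atypical homeodomain core TGAA."""

    name: str
    core: str

    def __post_init__(self):
        object.__setattr__(self, "core", self.core.upper())
        if len(self.core) < 2:
            raise ValueError("motif core must be at least 2 nt")
        if not _DNA.issuperset(self.core):
            raise ValueError(f"motif core {self.core!r} must use only A/C/G/T")


@dataclass(frozen=True)
class ArrangementSpec:
    """A motif plus its repeat layout (orientation, copy number, spacer).

    ``spacer_fill`` is the concrete base used when *expanding* the composite
    into a probe sequence; scanning always treats spacer positions as the
    wildcard N. The default fill C is absent from the cores TGAA/TAAT, which
    limits accidental creation of extra motif copies in planted probes.
    """

    motif: MotifPattern
    layout: Layout = Layout.SINGLE
    copies: int = 1
    spacer_nt: int = 0
    spacer_fill: str = "C"
    name: str | None = None

    def __post_init__(self):
        layout = Layout(self.layout)
        object.__setattr__(self, "layout", layout)
        if layout is Layout.SINGLE and self.copies != 1:
            raise ValueError("layout 'single' requires copies == 1")
        if layout in (Layout.INVERTED_TAIL_TO_TAIL, Layout.EVERTED_HEAD_TO_HEAD) and self.copies != 2:
            raise ValueError(f"layout {layout.value!r} requires copies == 2")
        if layout is Layout.DIRECT_REPEAT and self.copies < 2:
            raise ValueError("direct_repeat requires copies >= 2")
        if self.spacer_nt < 0:
            raise ValueError("spacer_nt must be >= 0")
        fill = self.spacer_fill.upper()
        object.__setattr__(self, "spacer_fill", fill)
        if len(fill) != 1 or fill not in _DNA_N:
            raise ValueError("spacer_fill must be a single base A/C/G/T or N")
        if self.name is None:
            label = self.motif.name
            if layout is not Layout.SINGLE:
                label = f"{self.copies}x{self.motif.name}_{layout.value}"
                if self.spacer_nt:
                    label += f"_sp{self.spacer_nt}"
            object.__setattr__(self, "name", label)

    @property
    def composite_length(self) -> int:
        return self.copies * len(self.motif.core) + (self.copies - 1) * self.spacer_nt


@dataclass(frozen=True)
class MotifSite:
    """One genomic occurrence of an arrangement (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    matched_seq: str
    class_label: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if len(self.matched_seq) != self.end - self.start:
            raise ValueError("matched_seq length must equal end - start")


def arrangement_pattern(spec: ArrangementSpec, fill: str | None = None) -> str:
    """Composite sequence of an arrangement with the given spacer fill.

    With ``fill=None`` the spec's own ``spacer_fill`` is used; pass ``"N"``
    to obtain the scanning pattern where spacer positions match any base.
    """
    fill = (fill or spec.spacer_fill).upper()
    core = spec.motif.core
    spacer = fill * spec.spacer_nt
    layout = spec.layout
    if layout is Layout.SINGLE:
        return core
    if layout is Layout.DIRECT_REPEAT:
        return spacer.join([core] * spec.copies)
    if layout is Layout.INVERTED_TAIL_TO_TAIL:
        return core + spacer + reverse_complement(core)
    if layout is Layout.EVERTED_HEAD_TO_HEAD:
        return reverse_complement(core) + spacer + core
    raise AssertionError(f"unhandled layout {layout}")


def expand_arrangement(spec: ArrangementSpec) -> str:
    """Concrete composite probe sequence for an arrangement.

    >>> expand_arrangement(ArrangementSpec(MotifPattern("TGAA", "TGAA"),
    ...                                    Layout.DIRECT_REPEAT, copies=2))
    'TGAATGAA'
    """
    if spec.spacer_nt > 0 and spec.spacer_fill == "N":
        raise ValueError("expanding a spaced arrangement requires a concrete spacer_fill")
    return arrangement_pattern(spec)


def _compile(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + pattern.replace("N", "[ACGT]") + "))")


def scan_sequence(
    seq: str,
    spec: ArrangementSpec,
    both_strands: bool = True,
    chrom: str = "seq",
) -> list[MotifSite]:
    """All occurrences of an arrangement in one sequence.

    Spacer positions match any base. Minus-strand hits are positions where
    the reverse complement of the composite matches; a palindromic composite
    (pattern equal to its own reverse complement) is scanned once so each
    interval is reported a single time.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    seq = seq.upper()
    pattern = arrangement_pattern(spec, fill="N")
    rc_pattern = reverse_complement(pattern)
    sites: list[MotifSite] = []
    for m in _compile(pattern).finditer(seq):
        s = m.start()
        e = s + len(pattern)
        sites.append(MotifSite(chrom, s, e, "+", seq[s:e], spec.name))
    if both_strands and rc_pattern != pattern:
        for m in _compile(rc_pattern).finditer(seq):
            s = m.start()
            e = s + len(pattern)
            sites.append(MotifSite(chrom, s, e, "-", seq[s:e], spec.name))
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


def scan_genome(
    genome: Mapping[str, str] | str | Path,
    specs: Iterable[ArrangementSpec],
) -> pd.DataFrame:
    """Scan every record of a genome for every arrangement.

    Parameters
    ----------
    genome
        Mapping of record name to sequence, or a path to a FASTA file.
    specs
        Arrangements to scan for; each site carries the spec's label.

    Returns
    -------
    DataFrame with columns chrom, start, end, class_label, score, strand,
    matched_seq, sorted by (chrom, start, class_label).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one ArrangementSpec is required")
    labels = [s.name for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate arrangement labels")
    if not isinstance(genome, Mapping):
        from .io import read_fasta

        genome = read_fasta(genome)
    rows = []
    for chrom, seq in genome.items():
        for spec in specs:
            for site in scan_sequence(seq, spec, chrom=chrom):
                rows.append(
                    (site.chrom, site.start, site.end, site.class_label, 0, site.strand, site.matched_seq)
                )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "class_label", "score", "strand", "matched_seq"]
    )
    return df.sort_values(["chrom", "start", "class_label"], kind="mergesort").reset_index(drop=True)
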