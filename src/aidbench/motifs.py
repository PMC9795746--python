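"""Hotspot-motif counting and CDR-vs-FR enrichment in immunoglobulin V regions.

AID (activation-induced cytidine deaminase) preferentially deaminates dC in
WRC motifs (W = A/T, R = A/G).  Because deamination acts on both DNA strands,
strand coverage is obtained by counting an explicit word list that is closed
under reverse complement: the 4 WRC trimers plus their GYW reverse
complements, and the 4 WGCW tetramers (which contain overlapping WRC/GYW
hotspots on the two strands and are reverse-complement closed as a set).

The enrichment statistic for a species is the mean motifs-per-nucleotide
index over CDR1 and CDR2 divided by the mean index over FR1, FR2 and FR3.
CDR3 is excluded because it is created by V(D)J recombination rather than
inherited in the germline V gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotatedIgV",
    "MotifSet",
    "EnrichmentResult",
    "builtin_motif_sets",
    "count_motifs",
    "normalized_index",
    "species_enrichment",
    "gc_content",
    "reverse_complement",
    "CDR_REGIONS",
    "FR_REGIONS",
]

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Regions entering the numerator / denominator of the enrichment ratio.
CDR_REGIONS = ("CDR1", "CDR2")
FR_REGIONS = ("FR1", "FR2", "FR3")

# WRC hotspot trimers and their GYW reverse complements, enumerated literally.
_WRC_GYW_WORDS = ("TGC", "TAC", "AGC", "AAC", "GCA", "GTA", "GCT", "GTT")
# WGCW tetramers: overlapping AID hotspots on both strands.
_WGCW_WORDS = ("AGCA", "AGCT", "TGCA", "TGCT")


@dataclass(frozen=True)
class MotifSet:
    """An explicit list of equal-length DNA words counted on the forward strand."""

    name: str
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("MotifSet requires at least one word")
        lengths = {len(w) for w in self.words}
        if len(lengths) != 1:
            raise ValueError(f"motif words must have equal length, got {sorted(lengths)}")
        if len(set(self.words)) != len(self.words):
            raise ValueError("motif words must be unique")
        for w in self.words:
            if not set(w) <= _DNA:
                raise ValueError(f"motif word {w!r} contains non-ACGT characters")

    @property
    def word_length(self) -> int:
        return len(self.words[0])


@dataclass
class AnnotatedIgV:
    """One immunoglobulin V-region nucleotide sequence with its FR/CDR map.

    ``regions`` maps region names (FR1, CDR1, FR2, CDR2, FR3 and optionally
    CDR3) to 0-based half-open ``(start, end)`` intervals into ``sequence``.
    """

    seq_id: str
    sequence: str
    regions: dict[str, tuple[int, int]]
    species_id: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        seen: list[tuple[int, int]] = []
        for name, (start, end) in self.regions.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"{self.seq_id}: region {name} interval [{start}, {end}) "
                    f"outside sequence of length {len(self.sequence)}"
                )
            for s2, e2 in seen:
                if start < e2 and s2 < end:
                    raise ValueError(f"{self.seq_id}: region {name} overlaps another region")
            seen.append((start, end))

    def segment(self, region: str) -> str:
        start, end = self.regions[region]
        return self.sequence[start:end]


@dataclass
class EnrichmentResult:
    """Per-region motif indices and the CDR/FR enrichment ratio for one species."""

    species_id: str
    motif_set_name: str
    per_region_index: dict[str, float]
    cdr_mean_index: float
    fr_mean_index: float
    enrichment_ratio: float | None  # None when fr_mean_index == 0
    n_sequences: int
    nucleotides_analyzed: dict[str, int] = field(default_factory=dict)


def builtin_motif_sets() -> dict[str, MotifSet]:
    """The two built-in hotspot word lists: WRC/GYW trimers and WGCW tetramers."""
    return {
        "WRC_GYW": MotifSet("WRC_GYW", _WRC_GYW_WORDS),
        "WGCW": MotifSet("WGCW", _WGCW_WORDS),
    }


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    sequence = sequence.upper()
    if not set(sequence) <= _DNA:
        bad = sorted(set(sequence) - _DNA)
        raise ValueError(f"invalid DNA characters: {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


def count_motifs(sequence: str, motifs: MotifSet) -> int:
    """Count motif occurrences by sliding a window over the forward strand.

    All overlapping occurrences are counted.  Windows containing characters
    outside A/C/G/T (e.g. N) are skipped; sequences shorter than the word
    length yield 0.
    """
    sequence = sequence.upper()
    k = motifs.word_length
    words = set(motifs.words)
    return sum(1 for i in range(len(sequence) - k + 1) if sequence[i : i + k] in words)


def normalized_index(segment: str, motifs: MotifSet) -> float:
    """Motifs per nucleotide: ``count_motifs(segment) / len(segment)``."""
    if not segment:
        raise ValueError("normalized index undefined for an empty segment")
    return count_motifs(segment, motifs) / len(segment)


def gc_content(sequences: str | Iterable[str]) -> float:
    """Fraction of G+C over all counted bases of one or more sequences."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = total = 0
    for seq in sequences:
        seq = seq.upper()
        gc += seq.count("G") + seq.count("C")
        total += sum(seq.count(b) for b in "ACGT")
    if total == 0:
        raise ValueError("no countable bases")
    return gc / total


def species_enrichment(
    seqs: Sequence[AnnotatedIgV],
    motifs: MotifSet,
    exclude: frozenset[str] | set[str] = frozenset({"CDR3"}),
    species_id: str | None = None,
    pooled: bool = False,
) -> EnrichmentResult:
    """CDR-vs-FR hotspot enrichment for one species' V-region set.

    For each sequence the motifs-per-nucleotide index of every annotated
    region is computed; per-region indices are then averaged across
    sequences (default), or counts and lengths are pooled per region when
    ``pooled=True``.  The ratio is mean(CDR1, CDR2) / mean(FR1, FR2, FR3).
    Regions in ``exclude`` (CDR3 by default) never contribute.

    Sequences missing any required region are skipped with a warning; an
    error is raised if no sequence is usable.
    """
    required = [r for r in CDR_REGIONS + FR_REGIONS if r not in exclude]
    usable: list[AnnotatedIgV] = []
    for seq in seqs:
        missing = [r for r in required if r not in seq.regions]
        if missing:
            logger.warning("skipping %s: missing regions %s", seq.seq_id, missing)
        else:
            usable.append(seq)
    if not usable:
        raise ValueError("no sequence carries all required regions")

    per_region_index: dict[str, float] = {}
    nucleotides: dict[str, int] = {}
    for region in required:
        counts = [count_motifs(s.segment(region), motifs) for s in usable]
        lengths = [len(s.segment(region)) for s in usable]
        nucleotides[region] = sum(lengths)
        if pooled:
            per_region_index[region] = sum(counts) / sum(lengths)
        else:
            per_region_index[region] = sum(
                c / n for c, n in zip(counts, lengths)
            ) / len(usable)

    cdr_mean = sum(per_region_index[r] for r in CDR_REGIONS if r in per_region_index) / sum(
        1 for r in CDR_REGIONS if r in per_region_index
    )
    fr_mean = sum(per_region_index[r] for r in FR_REGIONS) / len(FR_REGIONS)
    ratio = cdr_mean / fr_mean if fr_mean > 0 else None
    if ratio is None:
        logger.warning("FR mean index is zero; enrichment ratio undefined")

    if species_id is None:
        ids = {s.species_id for s in usable if s.species_id}
        species_id = ids.pop() if len(ids) == 1 else ""
    return EnrichmentResult(
        species_id=species_id,
        motif_set_name=motifs.name,
        per_region_index=per_region_index,
        cdr_mean_index=cdr_mean,
        fr_mean_index=fr_mean,
        enrichment_ratio=ratio,
        n_sequences=len(usable),
        nucleotides_analyzed=nucleotides,
    )
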