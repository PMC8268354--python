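"""Gene-structure representation, validation and windowed divergence.

A gene model is an exon/intron length table, optionally backed by genomic
sequence (from the transcription start) and a CDS interval on the transcript.
The module validates canonical GT..AG splice sites, translates coding
sequence, locates polyadenylation signals, and counts divergence events
(substitutions plus gap runs, an indel counted as a single event) in a fixed
window of a pairwise alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

GAP = "-"


@dataclass
class GeneModel:
    """Exon/intron structure with optional sequence and coding bounds.

    ``sequence`` runs from the transcription start over the full genomic
    span; ``cds`` is a 1-based inclusive interval on the spliced transcript.
    """

    name: str
    exon_lengths: list[int]
    intron_lengths: list[int] = field(default_factory=list)
    sequence: Optional[str] = None
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            raise ValueError("a gene model needs at least one exon")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError("all exon and intron lengths must be positive")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != genomic_length(self):
                raise ValueError(
                    f"sequence length {len(self.sequence)} does not match the "
                    f"genomic length {genomic_length(self)}"
                )
        if self.cds is not None:
            start, end = self.cds
            if not 1 <= start <= end <= transcript_length(self):
                raise ValueError("cds interval must lie within the transcript")

    def intron_interval(self, i: int) -> tuple[int, int]:
        """1-based inclusive genomic interval of intron ``i`` (0-based index)."""
        pos = 0
        for j, exon in enumerate(self.exon_lengths[:-1]):
            pos += exon
            if j == i:
                return pos + 1, pos + self.intron_lengths[i]
            pos += self.intron_lengths[j]
        raise IndexError(f"no intron {i}")

    def transcript_sequence(self) -> str:
        if self.sequence is None:
            raise ValueError("gene model carries no sequence")
        parts, pos = [], 0
        for j, exon in enumerate(self.exon_lengths):
            parts.append(self.sequence[pos : pos + exon])
            pos += exon
            if j < len(self.intron_lengths):
                pos += self.intron_lengths[j]
        return "".join(parts)


def genomic_length(model: GeneModel) -> int:
    """Total genomic span: sum of all exon and intron lengths."""
    return sum(model.exon_lengths) + sum(model.intron_lengths)


def transcript_length(model: GeneModel) -> int:
    """Spliced transcript length: sum of exon lengths."""
    return sum(model.exon_lengths)


@dataclass
class SpliceReport:
    intron_flags: list[tuple[int, str, str, bool]]  # (index, donor, acceptor, ok)
    passed: bool


def validate_splice_sites(model: GeneModel) -> SpliceReport:
    """Check that every intron starts with GT and ends with AG (case-insensitive)."""
    if model.sequence is None:
        raise ValueError("splice-site validation requires the genomic sequence")
    flags = []
    for i in range(len(model.intron_lengths)):
        start, end = model.intron_interval(i)
        intron = model.sequence[start - 1 : end]
        donor, acceptor = intron[:2], intron[-2:]
        flags.append((i, donor, acceptor, donor == "GT" and acceptor == "AG"))
    return SpliceReport(flags, all(ok for *_, ok in flags))


class TranslationError(ValueError):
    pass


def translate_cds(transcript: str, cds: tuple[int, int]) -> str:
    """Translate a CDS interval (1-based inclusive, on the transcript).

    The CDS must start with ATG, be a whole number of codons, and end with a
    stop codon; the stop is not included in the returned peptide, so a CDS of
    3(n+1) bases encodes n residues.
    """
    start, end = cds
    seq = transcript.upper()[start - 1 : end]
    if len(seq) != end - start + 1:
        raise TranslationError("cds interval extends past the transcript")
    if len(seq) % 3 != 0:
        raise TranslationError(f"cds length {len(seq)} is not a multiple of 3")
    if not seq.startswith("ATG"):
        raise TranslationError("cds must begin with ATG")
    protein = str(Seq(seq).translate())
    if not protein.endswith("*"):
        raise TranslationError("cds must end in a stop codon")
    body = protein[:-1]
    if "*" in body:
        raise TranslationError(f"internal stop at codon {body.index('*') + 1}")
    return body


def find_polya_signals(sequence: str, motif: str = "AATAAA") -> list[int]:
    """All (possibly overlapping) 1-based start positions of ``motif``."""
    if not motif:
        raise ValueError("motif must be non-empty")
    seq, motif = sequence.upper(), motif.upper()
    hits, start = [], seq.find(motif)
    while start != -1:
        hits.append(start + 1)
        start = seq.find(motif, start + 1)
    return hits


@dataclass
class AlignedPair:
    """Two gapped sequences of equal length with a column window.

    ``window`` is a 1-based inclusive interval on alignment columns.
    """

    seq_a: str
    seq_b: str
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        start, end = self.window
        if not 1 <= start <= end <= len(self.seq_a):
            raise ValueError("window lies outside the alignment")
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()


def window_divergence(pair: AlignedPair) -> float:
    """Divergence fraction over the window: events / window width.

    An event is either a substitution column (both sequences carry a base and
    they differ) or one maximal contiguous gap run in either sequence — an
    indel counts as a single event regardless of its length.  Columns where
    both sequences are gapped (padding from a larger alignment) count nothing
    and terminate any open run.
    """
    start, end = pair.window
    events = 0
    open_run = None  # which sequence is currently gapped: "a" | "b" | None
    for col in range(start - 1, end):
        a, b = pair.seq_a[col], pair.seq_b[col]
        gap_a, gap_b = a == GAP, b == GAP
        if gap_a and gap_b:
            open_run = None
            continue
        if gap_a or gap_b:
            side = "a" if gap_a else "b"
            if side != open_run:
                events += 1
                open_run = side
        else:
            open_run = None
            if a != b:
                events += 1
    return events / (end - start + 1)


def global_align(seq_a: str, seq_b: str) -> AlignedPair:
    """Utility global aligner (match +1, mismatch -1, linear gap -2).

    Provided as plumbing for users without a pre-computed alignment; the
    divergence operation itself works on supplied alignments.
    """
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(alignment[0]), str(alignment[1])
    return AlignedPair(a, b, (1, len(a)))
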