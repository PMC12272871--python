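"""3'-terminal analysis: tag-anchored segment extraction, size distribution,
per-size top sequences, terminus classification and run-off fidelity.

The internal tag sits a fixed distance upstream of the template 3'
terminus, so under perfect run-off the segment between the tag and the 3'
adaptor has exactly ``tag_end_offset`` nt and equals the template suffix.
Shorter segments are interrupted transcripts; longer or divergent ones
come from non-templated additions or fold-back self-templated synthesis.
The headline statistic is the run-off fidelity: the frequency of the
expected segment size multiplied by the fraction of at-size segments that
exactly match the template — which is algebraically the joint frequency
of (correct size AND correct sequence) among all extracted records.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence

from .core import (
    ANCHOR3,
    TAG,
    FrequencyTable,
    Read,
    SizeDistribution,
    TemplateSpec,
)
from .selftemplating import match_self_templated


@dataclass(frozen=True)
class ThreePrimeRecord:
    read_id: str
    segment: str  # bases strictly between tag end and adaptor start
    multi_tag: bool = False

    @property
    def size(self) -> int:
        return len(self.segment)


@dataclass(frozen=True)
class ThreePrimeLabel:
    """One of ``correct_runoff``, ``templated_truncation`` (with the
    negative terminus offset), ``nontemplated_addition``,
    ``self_templated`` (both with the extension recorded verbatim) or
    ``unrelated``."""

    category: str
    offset: Optional[int] = None
    extension: str = ""


@dataclass
class FidelityReport:
    enzyme: str
    n_reads_in: int
    n_extracted: int
    modal_size: int
    freq_at_expected_size: float
    correct_ratio_at_expected_size: float
    runoff_fidelity: float

    def to_dict(self) -> dict:
        return asdict(self)


def extract_three_prime(
    read: Read,
    tag: str = TAG,
    adaptor: str = ANCHOR3,
    max_mismatches: int = 0,
) -> Optional[ThreePrimeRecord]:
    """Segment between the leftmost tag and the following 3' adaptor.

    The adaptor search starts at the tag end, so adaptor-like sequence
    upstream of the tag can never clip the segment. Returns None when
    either anchor is absent; a zero-length segment (tag immediately
    followed by adaptor) is valid. Matching is exact by default;
    ``max_mismatches`` allows a Hamming tolerance on both anchors.
    """
    from .core import find_first_hamming

    tpos = find_first_hamming(read.seq, tag, max_mismatches)
    if tpos is None:
        return None
    seg_start = tpos + len(tag)
    apos = find_first_hamming(read.seq[seg_start:], adaptor, max_mismatches)
    if apos is None:
        return None
    apos += seg_start
    multi = read.seq.find(tag, tpos + 1) >= 0
    return ThreePrimeRecord(read.id, read.seq[seg_start:apos], multi_tag=multi)


def size_distribution(records: Iterable[ThreePrimeRecord]) -> SizeDistribution:
    counts: dict = {}
    n = 0
    for r in records:
        counts[r.size] = counts.get(r.size, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("no extracted 3' records")
    return SizeDistribution(counts=counts, n_analyzed=n)


def top_sequences_at_size(
    records: Iterable[ThreePrimeRecord], size: int, n: int = 5
) -> FrequencyTable:
    """Top-``n`` segment sequences among records of exactly ``size`` nt.

    Frequencies are relative to the records at that size; an empty table
    is returned when no record has the requested size.
    """
    at_size = [r.segment for r in records if r.size == size]
    if not at_size:
        return FrequencyTable(rows=[], n_analyzed=0)
    return FrequencyTable.from_sequences(at_size).top(n)


def classify_three_prime(
    segment: str,
    template: TemplateSpec,
    min_duplex: int = 3,
    min_match: int = 3,
) -> ThreePrimeLabel:
    """Classify one extracted 3' segment against the template suffix.

    With T the expected ``tag_end_offset``-nt suffix after the tag: an
    exact match is a correct run-off; a proper prefix is a templated
    truncation; a prefix plus a non-empty extension is self-templated
    when the extension is the fold-back prediction for the transcript
    truncated at that point, a non-templated addition when the templated
    part runs to the template terminus, and unrelated otherwise.
    """
    T = template.terminal_segment
    if segment == T:
        return ThreePrimeLabel("correct_runoff", offset=0)
    k = 0
    m = min(len(segment), len(T))
    while k < m and segment[k] == T[k]:
        k += 1
    if len(segment) < len(T) and k == len(segment):
        return ThreePrimeLabel("templated_truncation", offset=len(segment) - len(T))
    ext = segment[k:]
    truncated = template.transcript[: len(template.transcript) - (len(T) - k)]
    if len(ext) >= min_match and match_self_templated(
        ext, truncated, min_duplex=min_duplex, min_match=min_match
    ):
        return ThreePrimeLabel("self_templated", offset=k - len(T), extension=ext)
    if k == len(T):
        return ThreePrimeLabel("nontemplated_addition", offset=0, extension=ext)
    return ThreePrimeLabel("unrelated", extension=ext)


def runoff_fidelity(
    dist: SizeDistribution, correct_ratio, expected_size: int
):
    """Frequency at the expected size times the correct-sequence ratio.

    Accepts exact ``Fraction`` inputs (and then returns one), so the
    factorized statistic can be compared exactly with the direct joint
    frequency it factorizes.
    """
    return dist.frequency(expected_size) * correct_ratio


def direct_runoff_fraction(
    records: Sequence[ThreePrimeRecord], template: TemplateSpec
) -> Fraction:
    """Joint frequency of (expected size AND exact template suffix)."""
    if not records:
        raise ValueError("no extracted 3' records")
    T = template.terminal_segment
    correct = sum(1 for r in records if r.segment == T)
    return Fraction(correct, len(records))


def correct_ratio_at_size(
    records: Sequence[ThreePrimeRecord], template: TemplateSpec, size: int
) -> Fraction:
    """Fraction of at-size segments classified as correct run-off."""
    at_size = [r for r in records if r.size == size]
    if not at_size:
        return Fraction(0)
    T = template.terminal_segment
    correct = sum(
        1
        for r in at_size
        if classify_three_prime(r.segment, template).category == "correct_runoff"
    )
    return Fraction(correct, len(at_size))


def compute_fidelity_report(
    records: Sequence[ThreePrimeRecord],
    template: TemplateSpec,
    enzyme: str = "",
    n_reads_in: Optional[int] = None,
    expected_size: Optional[int] = None,
) -> FidelityReport:
    if expected_size is None:
        expected_size = template.tag_end_offset
    dist = size_distribution(records)
    ratio = correct_ratio_at_size(records, template, expected_size)
    fid = runoff_fidelity(dist, ratio, expected_size)
    return FidelityReport(
        enzyme=enzyme,
        n_reads_in=n_reads_in if n_reads_in is not None else len(records),
        n_extracted=len(records),
        modal_size=dist.modal_size,
        freq_at_expected_size=float(dist.frequency(expected_size)),
        correct_ratio_at_expected_size=float(ratio),
        runoff_fidelity=float(fid),
    )
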