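"""Shared sequence utilities, coordinate conventions and file I/O.

All sequences are held in the DNA alphabet {A,C,G,T}, uppercase, in
transcript sense; RNA input (printed adaptor oligos) is normalized with
U->T on ingest. Coordinates are 0-based, half-open throughout.

The single sanctioned signed convention for transcript 3' ends is the
*terminus offset*: -k means the transcript 3' end lies k nt upstream of
the template 3' terminus (so the tag-to-end segment is ``tag_end_offset
- k`` nt long); +k means k nt beyond the terminus; 0 is a perfect
run-off end.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

#: Signed distance of a transcript 3' end from the template terminus
#: (see module docstring); kept as a plain int under this alias.
TerminusOffset = int

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: 5' adaptor oligo ligated to the transcript 5' end (printed as RNA).
ADAPTOR5_RNA = "CCAGGCUUAUGGCAGUCACA"
#: 3' adaptor oligo ligated to the transcript 3' end (printed as RNA).
ADAPTOR3_RNA = "CACGAGCGUUUUCCCACCUA"
#: Anchor used to locate the 5' adaptor/read junction.
ANCHOR5 = "ATGGCAGTCACA"
#: Anchor used to locate the 3' adaptor within a read.
ANCHOR3 = "CACGAGCGTTTT"
#: Internal tag placed a fixed distance upstream of the template 3' end.
TAG = "ACTATTGCTTTCACG"


class AlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


def as_dna(s: str) -> str:
    """Validate and upper-case a DNA string over {A,C,G,T}."""
    s = s.upper()
    if not DNA_ALPHABET.issuperset(s):
        bad = sorted(set(s) - DNA_ALPHABET)
        raise AlphabetError(f"non-ACGT characters: {bad!r}")
    return s


def normalize_rna(s: str) -> str:
    """Convert an RNA or DNA string to the internal DNA alphabet (U->T)."""
    s = s.upper().replace("U", "T")
    return as_dna(s)


def revcomp(s: str) -> str:
    """Watson-Crick reverse complement of a DNA string."""
    s = as_dna(s)
    return s.translate(_COMPLEMENT)[::-1]


def complement_base(b: str) -> str:
    return b.translate(_COMPLEMENT)


def find_first(haystack: str, needle: str) -> Optional[int]:
    """Leftmost exact occurrence of ``needle`` in ``haystack``, or None."""
    if not needle:
        raise ValueError("needle must be non-empty")
    pos = haystack.find(needle)
    return None if pos < 0 else pos


def find_first_hamming(
    haystack: str, needle: str, max_mismatches: int = 0
) -> Optional[int]:
    """Leftmost occurrence of ``needle`` within Hamming distance
    ``max_mismatches``; falls back to exact search when the tolerance is 0."""
    if max_mismatches == 0:
        return find_first(haystack, needle)
    if not needle:
        raise ValueError("needle must be non-empty")
    n = len(needle)
    for i in range(len(haystack) - n + 1):
        mm = 0
        for a, b in zip(haystack[i : i + n], needle):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return i
    return None


def percent_identity(aligned_a: str, aligned_b: str, gap: str = "-") -> float:
    """Percent identity between two rows of a pairwise alignment.

    Columns gapped in *both* rows are excluded from the denominator;
    a gap aligned to a base counts as a mismatch.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    matches = 0
    columns = 0
    for a, b in zip(aligned_a, aligned_b):
        if a == gap and b == gap:
            continue
        columns += 1
        if a == b and a != gap:
            matches += 1
    if columns == 0:
        raise ValueError("alignment has no scorable columns")
    return 100.0 * matches / columns


# ---------------------------------------------------------------------------
# Template specification


@dataclass(frozen=True)
class TemplateSpec:
    """The transcribed template and its landmarks.

    ``sense`` is the template sense strand (promoter region followed by
    the transcribed body); ``plus_one_index`` is the 0-based position of
    the +1 base within ``sense``. The expected run-off transcript is
    ``sense[plus_one_index:]``. ``tag_end_offset`` is the number of
    transcript nucleotides following the internal tag, i.e. the expected
    size of the 3'-terminal segment under perfect run-off.
    """

    name: str
    promoter: str
    plus_one_index: int
    sense: str
    tag: str = TAG
    tag_end_offset: int = 50

    def __post_init__(self):
        object.__setattr__(self, "sense", as_dna(self.sense))
        object.__setattr__(self, "promoter", as_dna(self.promoter))
        object.__setattr__(self, "tag", as_dna(self.tag))
        t = self.transcript
        if t.count(self.tag) != 1:
            raise ValueError("tag must occur exactly once in the transcript")
        tag_start = t.index(self.tag)
        expected = len(t) - (tag_start + len(self.tag))
        if expected != self.tag_end_offset:
            raise ValueError(
                f"tag_end_offset={self.tag_end_offset} but {expected} nt follow the tag"
            )
        if self.promoter and self.promoter not in self.sense[: self.plus_one_index]:
            raise ValueError("promoter not found upstream of the +1 site")

    @property
    def transcript(self) -> str:
        """Expected full run-off transcript (transcript sense, DNA alphabet)."""
        return self.sense[self.plus_one_index :]

    @property
    def tag_start(self) -> int:
        """0-based start of the tag within the transcript."""
        return self.transcript.index(self.tag)

    @property
    def terminal_segment(self) -> str:
        """Template suffix downstream of the tag (the expected 3' segment)."""
        return self.transcript[self.tag_start + len(self.tag) :]

    def upstream_window(self, offset: int, width: int) -> Optional[str]:
        """``width`` sense bases starting ``offset`` nt from the +1 site."""
        start = self.plus_one_index + offset
        if start < 0 or start + width > len(self.sense):
            return None
        return self.sense[start : start + width]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "promoter": self.promoter,
            "plus_one_index": self.plus_one_index,
            "sense": self.sense,
            "tag": self.tag,
            "tag_end_offset": self.tag_end_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateSpec":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TemplateSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Reads and FASTQ/FASTA I/O


@dataclass
class Read:
    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self):
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError("quality string length must match sequence length")


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Iterate reads from a FASTQ file (optionally gzipped)."""
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield Read(rec.id, str(rec.seq), qual)


def write_fastq(reads: Iterable[Read], path) -> int:
    """Write reads to FASTQ (gzipped if the path ends in .gz). Returns count."""
    n = 0
    with _open_text(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def read_fasta(path) -> dict:
    """Read a FASTA file into an ``{id: sequence}`` dict (DNA alphabet)."""
    with _open_text(path, "r") as fh:
        return {rec.id: as_dna(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with _open_text(path, "w") as fh:
        for name, seq in seqs.items():
            SeqIO.write(SeqRecord(Seq(seq), id=name, description=""), fh, "fasta")


# ---------------------------------------------------------------------------
# Normalized count tables


@dataclass
class FrequencyTable:
    """Exact-sequence counts normalized to the number of analyzed items.

    Rows are sorted by count descending, ties broken lexicographically,
    which makes top-N views deterministic. Frequencies are exact
    rationals; they sum to 1 by construction.
    """

    rows: list  # of (sequence, count, Fraction)
    n_analyzed: int

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "FrequencyTable":
        counts: dict = {}
        n = 0
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
            n += 1
        if n == 0:
            raise ValueError("cannot tabulate an empty collection")
        rows = [
            (s, c, Fraction(c, n))
            for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return cls(rows=rows, n_analyzed=n)

    def top(self, n: int) -> "FrequencyTable":
        return FrequencyTable(rows=self.rows[:n], n_analyzed=self.n_analyzed)

    def frequency_of(self, seq: str) -> Fraction:
        for s, _, f in self.rows:
            if s == seq:
                return f
        return Fraction(0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(s, c, float(f)) for s, c, f in self.rows],
            columns=["sequence", "count", "frequency"],
        )


@dataclass
class SizeDistribution:
    """Counts of 3'-segment sizes normalized to the analyzed records."""

    counts: dict  # size -> count
    n_analyzed: int = field(default=0)

    def __post_init__(self):
        if self.n_analyzed == 0:
            self.n_analyzed = sum(self.counts.values())
        if self.n_analyzed <= 0:
            raise ValueError("empty size distribution")

    def frequency(self, size: int) -> Fraction:
        return Fraction(self.counts.get(size, 0), self.n_analyzed)

    @property
    def modal_size(self) -> int:
        # ties broken toward the smaller size for determinism
        return min(self.counts, key=lambda s: (-self.counts[s], s))

    def to_frame(self):
        import pandas as pd

        rows = [
            (s, c, c / self.n_analyzed) for s, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["size", "count", "frequency"])
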