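"""Promoter-candidate filtering downstream of a motif predictor.

Candidate promoter motifs (e.g. from an external phage-promoter
predictor) are filtered with a simple genomic heuristic: keep motifs
that occur multiple times in the genome and lie upstream of at least one
annotated ORF start on the same strand, then rank by how many upstream
placements each has. The motif scan is exact and counts overlapping
occurrences on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .core import as_dna, revcomp

Hit = Tuple[int, str]  # (0-based leftmost position in genome, strand)


@dataclass(frozen=True)
class PromoterCandidate:
    seq: str
    hits: Tuple[Hit, ...]
    n_hits: int
    n_upstream: int

    def __post_init__(self):
        assert self.n_hits == len(self.hits)
        assert self.n_upstream <= self.n_hits


def _find_all(haystack: str, needle: str) -> List[int]:
    out, start = [], 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return out
        out.append(pos)
        start = pos + 1  # overlapping occurrences count


def scan_genome(
    candidate: str, genome: str, both_strands: bool = True
) -> List[Hit]:
    """All exact occurrences of the candidate motif, with strand."""
    candidate = as_dna(candidate)
    if len(candidate) < 8:
        raise ValueError("candidate motif shorter than 8 nt")
    genome = as_dna(genome)
    hits: List[Hit] = [(p, "+") for p in _find_all(genome, candidate)]
    if both_strands:
        hits += [(p, "-") for p in _find_all(genome, revcomp(candidate))]
    hits.sort()
    return hits


def _is_upstream(hit: Hit, motif_len: int, orf: Tuple[int, str], window: int) -> bool:
    """Same-strand hit whose 3' end lies within ``window`` nt of the ORF start."""
    pos, strand = hit
    orf_pos, orf_strand = orf
    if strand != orf_strand:
        return False
    if strand == "+":
        gap = orf_pos - (pos + motif_len)
    else:
        gap = pos - 1 - orf_pos
    return 0 <= gap < window


def select_candidates(
    candidates: Sequence[str],
    genome: str,
    orf_starts: Sequence[Tuple[int, str]],
    min_hits: int = 2,
    upstream_window: int = 100,
    both_strands: bool = True,
) -> List[PromoterCandidate]:
    """Filter and rank candidate motifs by the genomic heuristic.

    Keeps candidates with at least ``min_hits`` genomic occurrences and
    at least one occurrence upstream of an ORF start; ranks by upstream
    count descending, then total hits descending, then sequence. The
    result is invariant under the input order of candidates.
    """
    kept = []
    for cand in sorted(set(as_dna(c) for c in candidates)):
        hits = scan_genome(cand, genome, both_strands=both_strands)
        n_up = sum(
            1
            for h in hits
            if any(_is_upstream(h, len(cand), orf, upstream_window) for orf in orf_starts)
        )
        if len(hits) >= min_hits and n_up >= 1:
            kept.append(
                PromoterCandidate(
                    seq=cand, hits=tuple(hits), n_hits=len(hits), n_upstream=n_up
                )
            )
    kept.sort(key=lambda c: (-c.n_upstream, -c.n_hits, c.seq))
    return kept
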