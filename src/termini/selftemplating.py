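"""Fold-back self-templated extension and hairpin detection.

Single-subunit phage RNA polymerases (T7 in particular) can re-initiate
from the 3' end of their own transcript when it anneals intramolecularly:
the RNA folds back, the 3' suffix pairs with an upstream region, and the
polymerase copies the RNA itself, appending the reverse complement of the
region 5' of the annealing site. This produces 3' termini longer than a
run-off product and composed of sequence found only on the complementary
strand of the template. The same stem-loop structures are implicated in
premature termination: a stable hairpin just upstream of the template
terminus can stall a weakly processive polymerase.

Hairpins are found by exact reverse-complement stem search rather than
free-energy minimization: the mechanism only requires that a paired stem
exists, exact stems are unambiguous, and the module stays dependency-free.
G.T wobble pairs are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .core import as_dna, complement_base, revcomp


@dataclass(frozen=True)
class HairpinSite:
    """An exact stem-loop: arms of ``stem_len`` separated by ``loop_len``.

    Coordinates are 0-based in the supplied sequence; ``terminus_offset``
    is the signed distance of the stem's 3'-most base from the sequence
    3' end (0 = stem ends on the last base, -10 = ten bases early).
    """

    stem5_start: int
    stem_len: int
    loop_len: int
    terminus_offset: int

    @property
    def span(self) -> int:
        return 2 * self.stem_len + self.loop_len


@dataclass(frozen=True)
class FoldBack:
    """A fold-back annealing event and the extension it templates.

    The transcript 3' suffix of ``duplex_len`` bases pairs exactly
    (reverse complement) with the window starting at ``anneal_start``;
    the predicted extension is the reverse complement of everything 5'
    of that window, truncated at the cap from its 5'-proximal side (the
    bases synthesized first are kept).
    """

    anneal_start: int
    duplex_len: int
    extension: str
    capped: bool


def _pairs(a: str, b: str) -> bool:
    return b == complement_base(a)


def find_hairpins(
    seq: str, min_stem: int = 4, loop_min: int = 3, loop_max: int = 8
) -> List[HairpinSite]:
    """All maximal exact reverse-complement hairpins with loop in bounds.

    A hairpin is maximal if its stem cannot be extended by one more pair
    outward (within the sequence) or inward (keeping the loop at least
    ``loop_min``). Results are sorted by stem length descending, then
    5' arm position.
    """
    seq = as_dna(seq)
    n = len(seq)
    found = set()
    for loop_len in range(loop_min, loop_max + 1):
        for loop_start in range(1, n - loop_len):
            # expand the stem outward from the loop
            i = loop_start - 1
            j = loop_start + loop_len
            stem = 0
            while i >= 0 and j < n and _pairs(seq[i], seq[j]):
                stem += 1
                i -= 1
                j += 1
            if stem < min_stem:
                continue
            i += 1  # 5' arm start
            found.add((i, stem, loop_len))
    out = []
    for i, s, L in found:
        # inward extension would be found again with loop L-2; keep only
        # stems that are maximal for their own loop placement
        if L - 2 >= loop_min and _pairs(seq[i + s], seq[i + s + L - 1]):
            continue
        end = i + 2 * s + L  # one past the 3'-most stem base
        out.append(
            HairpinSite(
                stem5_start=i, stem_len=s, loop_len=L, terminus_offset=end - n
            )
        )
    out.sort(key=lambda h: (-h.stem_len, h.stem5_start, h.loop_len))
    return out


def fold_back_extend(
    transcript: str, min_duplex: int = 3, max_extension: Optional[int] = None
) -> Optional[FoldBack]:
    """Predict the self-templated extension of a transcript 3' end.

    Finds the longest 3' suffix (>= ``min_duplex``) that is the exact
    reverse complement of an internal window ending strictly before the
    suffix; ties between windows are broken toward the 3'-most window
    (physically the tightest fold-back loop). Returns None when no such
    annealing site exists.
    """
    t = as_dna(transcript)
    n = len(t)
    for d in range(n // 2, min_duplex - 1, -1):
        suffix = t[n - d :]
        target = revcomp(suffix)
        # window must end at or before the suffix start
        best = t.rfind(target, 0, n - d)
        if best >= 0:
            ext_full = revcomp(t[:best])
            capped = max_extension is not None and len(ext_full) > max_extension
            ext = ext_full[:max_extension] if capped else ext_full
            return FoldBack(
                anneal_start=best, duplex_len=d, extension=ext, capped=capped
            )
    return None


def match_self_templated(
    observed_ext: str,
    truncated_transcript: str,
    min_duplex: int = 3,
    min_match: int = 3,
) -> bool:
    """Whether an observed 3' extension is explained by fold-back synthesis.

    True iff the extension is an exact prefix (length >= ``min_match``)
    of the extension predicted by :func:`fold_back_extend` applied to the
    truncated transcript.
    """
    if not observed_ext:
        raise ValueError("observed extension must be non-empty")
    if len(observed_ext) < min_match:
        return False
    fb = fold_back_extend(truncated_transcript, min_duplex=min_duplex)
    if fb is None:
        return False
    return fb.extension.startswith(as_dna(observed_ext))
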