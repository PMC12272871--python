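# Methods

## Coordinate conventions and read parsing

All sequences are kept in the DNA alphabet, transcript sense, uppercase;
printed RNA oligos are normalized with U→T on ingest. Coordinates are
0-based, half-open. The one signed convention is the **terminus
offset**: −k means a transcript 3′ end k nt upstream of the template
terminus (segment size `tag_end_offset − k`), +k means k nt beyond it,
0 a perfect run-off end.

A template is described by `TemplateSpec`: the sense strand (promoter
region + transcribed body), the +1 index, the internal tag and
`tag_end_offset` — the number of transcript bases following the tag,
i.e. the expected 3′-segment size (default 50). Invariants (tag unique
in the transcript, offset arithmetic consistent, the transcript starts
at +1) are checked at construction.

Read parsing is anchored on exact, leftmost matches of the printed
adaptor/tag subsequences (5′ anchor `ATGGCAGTCACA`, internal tag
`ACTATTGCTTTCACG`, 3′ anchor `CACGAGCGTTTT`); no mismatch tolerance is
applied by default because the analysis being reproduced used exact
containment. The 3′-adaptor search starts at the tag end, so
adaptor-like sequence upstream can never clip a segment. Reads failing
an anchor are skipped and counted; the filter counts
(reads in / 5′-anchored / tag+adaptor-anchored) are mandatory pipeline
output so every discard is auditable.

## 5′ classification

The 20-nt window after the 5′ anchor is classified with a total,
deterministic precedence: exact +1 match; templated shifted start within
±10 nt of +1 (smaller |offset| first, upstream before downstream);
stripping a homopolymer run of 1–10 leading bases that leaves an exact
+1 match (non-templated addition, the polymerase's extra-G slippage);
otherwise unrelated. Requiring the stripped run to be a homopolymer
avoids double explanations — a window is attributed to exactly one
mechanism — and mixed 5′ additions deliberately fall to `unrelated`.
The +1 site is estimated as the sense-strand position of the most
frequent window; if that window does not occur on the template the
estimate is flagged (position `None`) rather than forced.

## 3′ classification and the fidelity statistic

With T the expected 50-nt template suffix after the tag, a segment is:
`correct_runoff` (equals T); `templated_truncation` (proper prefix of
T, offset recorded); `self_templated` when the part after the longest
common prefix with T is an exact prefix (≥ 3 nt) of the fold-back
prediction for the transcript truncated at that point;
`nontemplated_addition` when the templated part runs to the terminus
and a short unexplained extension follows; else `unrelated`.

Frequencies are exact rationals (`fractions.Fraction`), so the run-off
fidelity — frequency at the expected size × correct-sequence ratio at
that size — equals the direct joint frequency of (correct size ∧
correct sequence) *exactly*, not to within floating-point rounding; the
test suite asserts the identity with `==`. Table tie-breaks are count
descending then lexicographic; size-distribution modal ties go to the
smaller size.

## Fold-back model

Self-templating is modelled as: the transcript 3′ suffix (longest
suffix ≥ 3 nt that is the exact reverse complement of an internal
window ending at or before the suffix start) anneals intramolecularly,
and synthesis restarts copying the RNA, appending the reverse
complement of everything 5′ of the annealing window, truncated at a cap
from the 5′-proximal side (the bases synthesized first are kept). Ties
between annealing windows are broken toward the 3′-most window — the
physically tightest fold-back loop. Hairpins are found as maximal exact
reverse-complement stems (default stem ≥ 4, loop 3–8), G·T wobble pairs
excluded. Free-energy folding is intentionally not used: the mechanism
only needs the existence and position of a paired stem, exact stems are
unambiguous and testable against brute-force enumeration, and the
module stays dependency-free. Whether a real extension stops because of
polymerase drop-off or read length is not modelled; the cap parameter
encodes it agnostically.

## Synthetic data generator

Each read is drawn as: degraded? → start offset → extra 5′ Gs → end
mode → substitution errors (default rate 0). Degraded reads are uniform
internal fragments (≥ 20 nt) of the full run-off transcript, emulating
RNA degradation during transcription and library preparation; they
receive adaptors like any molecule, so they enter the extraction
denominators just as real degradation products would. Extra 5′ Gs are
applied only to reads starting exactly at +1 (initiation slippage at
the +1 G); this keeps generator truth and classifier output in strict
one-to-one correspondence, which the closure tests assert at 100%.
End modes: correct run-off; premature stop at a terminus offset;
non-templated 3′ addition to the run-off product (default one
uniformly-drawn base); self-templated — truncate at a stop site
(−10, the designed hairpin) and append the fold-back prediction up to a
cap. Reads are emitted as FASTQ (constant qualities) with a truth TSV;
the same seed gives byte-identical files. Sampling order is documented
so seeds are portable across implementations at the statistical level;
bitwise reproducibility is guaranteed only within this implementation.

### The packaged template

The default template is a deterministic pseudo-random 250-nt transcript
(per-enzyme +1 base: G for T7/KpnP/Ro45Iw, A for CD23823) engineered to
contain: the tag ending exactly 50 nt from the 3′ end; and a designed
exact hairpin (stem 6, loop 4) whose stem ends at terminus offset −10.
A transcript truncated there folds back at the designed stem, and the
12-nt-capped extension yields a 52-nt 3′ segment — 40 + 12 — the size
arithmetic of the self-templated peak. Construction is validated
(unique tag, unique 20-mers, no internal adaptor anchors, the fold-back
site is the designed stem, the extension diverges from the template
immediately) and deterministically retried with derived seeds until all
constraints hold, so the packaged sequence is fixed. T7's promoter is
the canonical consensus; the other three promoters are synthetic
stand-ins of the same length (only the few bases upstream of +1 matter,
as context for shifted starts).

### Presets

Per-enzyme presets encode the published terminal statistics as *true*
mixture parameters: +1-start frequency (T7 28%, KpnP 22%, Ro45Iw 46%,
CD23823 60%), T7's ~9% extra-G fraction, run-off fidelity (0.93%,
5.2%, 2.6%, 29%), correct-sequence ratio at 50 nt (22.5%, 88.2%,
83.3%, 97.4%) and modal segment size (52, 51, 40, 50 nt). Degradation
is not quantified in the source observations; it is fixed at 5% and the
remaining unexplained mass is spread over a fixed set of minor
premature-stop sites. Because degraded fragments contaminate every
estimator in computable ways (a tag-containing fragment looks like a
templated truncation; one ending exactly at the template terminus is
indistinguishable from a correct run-off; one starting at position 0
reproduces the +1 window), the preset builder solves the mixture
weights in closed form against the exact fragment distribution so the
*theoretical* pipeline estimates equal the published values, and the
pipeline must recover them within binomial sampling error. Incorrect
sequences at the expected size — needed for correct ratios below 100% —
are modelled as self-templated products whose cap lands the segment
exactly at 50 nt (stop at −10 plus a 10-nt fold-back prefix); the
dominant published product of each enzyme (T7: 52-nt fold-back; KpnP:
+1-nt addition; Ro45Iw: −10 hairpin stop; CD23823: run-off) carries the
enzyme's characteristic peak. Preset construction self-checks that the
theoretical size distribution peaks at the published modal size.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — start
heterogeneity, slippage Gs, hairpin stops, 3′ additions, fold-back
extensions, degradation, exact adaptor ligation. It does not model PCR
or ligation bias, quality-score-dependent errors, RppH treatment, or
DNA terminus-initiated transcription. Passing recovery tests therefore
shows the pipeline measures these modes correctly when reads follow the
stated protocol; it does not validate robustness to library-preparation
artefacts absent from the model.

## Promoter-candidate filter

Candidates (from any upstream motif predictor) are kept when they occur
at least `min_hits` (default 2) times in the genome — overlapping
occurrences counted, both strands by default — and at least one
same-strand occurrence has its 3′ end within `upstream_window` (default
100 nt) of an ORF start; ranking is by upstream count, then total hits,
then sequence, making the output invariant to input order. The source
heuristic states neither threshold; both defaults are documented and
configurable.

## Problem sizes and numerical choices

Recovery tests and the acceptance script simulate 100,000 reads per
enzyme (binomial 3-SD bands on each estimator's effective denominator);
structural checks use 1,000 reads; oracle-equivalence suites use 1,000
random sequences of length ≤ 60 against brute-force enumeration.
`percent_identity` excludes doubly-gapped columns from its denominator
and scores gap-vs-base as mismatch; published inter-enzyme identity
ranges depend on a specific aligner configuration and are not asserted.

## Known limitations

Exact-match anchoring slightly undercounts reads under nonzero
sequencing error (an optional Hamming tolerance exists for the anchors
but defaults to 0, matching the reproduced analysis). The hairpin
detector ignores wobble pairing and loop thermodynamics, so it finds a
superset/subset of thermodynamic hairpins depending on stem strictness.
Self-templated classification requires the extension to match the
single best fold-back prediction; secondary annealing sites are not
searched.
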