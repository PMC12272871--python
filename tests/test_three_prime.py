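"""3'-segment extraction, size distribution, classification and fidelity."""

import random
from fractions import Fraction

import pytest

from termini import (
    Read,
    classify_three_prime,
    compute_fidelity_report,
    correct_ratio_at_size,
    direct_runoff_fraction,
    extract_three_prime,
    runoff_fidelity,
    size_distribution,
    top_sequences_at_size,
)
from termini.core import ANCHOR3, TAG
from termini.selftemplating import fold_back_extend
from termini.three_prime import ThreePrimeRecord


def _read(seq, rid="r1"):
    return Read(rid, seq)


def test_extract_segment_between_tag_and_adaptor(t7_template):
    seg = t7_template.terminal_segment
    rec = extract_three_prime(_read("AAAA" + TAG + seg + ANCHOR3 + "TTTT"))
    assert rec.segment == seg and rec.size == 50


def test_extract_empty_segment():
    rec = extract_three_prime(_read("AA" + TAG + ANCHOR3 + "GG"))
    assert rec.segment == "" and rec.size == 0


def test_extract_none_without_adaptor():
    assert extract_three_prime(_read("AA" + TAG + "ACGT" * 5)) is None


def test_extract_none_without_tag():
    assert extract_three_prime(_read("ACGT" * 10 + ANCHOR3)) is None


def test_extract_adaptor_search_starts_at_tag_end():
    # an adaptor occurrence upstream of the tag must not clip the segment
    seq = ANCHOR3 + TAG + "AAAA" + ANCHOR3
    assert extract_three_prime(_read(seq)).segment == "AAAA"


def test_extract_flags_multiple_tags():
    rec = extract_three_prime(_read(TAG + "AA" + TAG + "CC" + ANCHOR3))
    assert rec.multi_tag
    assert rec.segment == "AA" + TAG + "CC"


def test_size_distribution_all_expected():
    recs = [ThreePrimeRecord(f"r{i}", "A" * 50) for i in range(4)]
    d = size_distribution(recs)
    assert d.frequency(50) == 1 and d.modal_size == 50


def test_size_distribution_rejects_empty():
    with pytest.raises(ValueError):
        size_distribution([])


def test_top_sequences_at_size():
    recs = [ThreePrimeRecord(f"a{i}", "AAA") for i in range(3)]
    recs += [ThreePrimeRecord("c0", "CCC"), ThreePrimeRecord("d0", "TTTT")]
    t = top_sequences_at_size(recs, 3)
    assert [(s, float(f)) for s, _, f in t.rows] == [("AAA", 0.75), ("CCC", 0.25)]
    assert top_sequences_at_size(recs, 7).rows == []


def test_classify_correct_runoff(t7_template):
    lab = classify_three_prime(t7_template.terminal_segment, t7_template)
    assert lab.category == "correct_runoff"


def test_classify_nta(t7_template):
    lab = classify_three_prime(t7_template.terminal_segment + "A", t7_template)
    assert (lab.category, lab.extension) == ("nontemplated_addition", "A")


def test_classify_templated_truncation(t7_template):
    lab = classify_three_prime(t7_template.terminal_segment[:40], t7_template)
    assert (lab.category, lab.offset) == ("templated_truncation", -10)


def test_classify_self_templated_from_designed_hairpin(t7_template):
    t = t7_template.transcript
    fb = fold_back_extend(t[: len(t) - 10], max_extension=12)
    segment = t7_template.terminal_segment[:40] + fb.extension
    lab = classify_three_prime(segment, t7_template)
    assert (lab.category, lab.extension) == ("self_templated", fb.extension)


def test_classify_internal_mismatch_is_unrelated(t7_template):
    seg = list(t7_template.terminal_segment)
    seg[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg[20]]
    assert classify_three_prime("".join(seg), t7_template).category == "unrelated"


@pytest.mark.parametrize("freq,ratio,expected", [(1, 1, 1), (Fraction(1, 2), Fraction(1, 2), Fraction(1, 4))])
def test_runoff_fidelity_values(freq, ratio, expected):
    from termini.core import SizeDistribution

    d = SizeDistribution(counts={50: int(2 * freq), 40: int(2 * (1 - freq))})
    assert runoff_fidelity(d, ratio, 50) == expected


def _random_records(rng, template, n):
    T = template.terminal_segment
    out = []
    for i in range(n):
        kind = rng.randrange(4)
        if kind == 0:
            seg = T
        elif kind == 1:
            seg = T[: rng.randrange(len(T))]
        elif kind == 2:
            seg = T + rng.choice("ACGT")
        else:
            seg = "".join(rng.choice("ACGT") for _ in range(rng.randrange(30, 55)))
        out.append(ThreePrimeRecord(f"r{i}", seg))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_fidelity_product_identity_is_exact(t7_template, seed):
    """The factorized statistic equals the direct joint frequency exactly."""
    rng = random.Random(seed)
    records = _random_records(rng, t7_template, 200)
    dist = size_distribution(records)
    ratio = correct_ratio_at_size(records, t7_template, 50)
    assert runoff_fidelity(dist, ratio, 50) == direct_runoff_fraction(records, t7_template)


def test_fidelity_monotonic_in_correct_reads(t7_template):
    rng = random.Random(7)
    records = _random_records(rng, t7_template, 100)
    before = direct_runoff_fraction(records, t7_template)
    records.append(ThreePrimeRecord("extra", t7_template.terminal_segment))
    dist = size_distribution(records)
    ratio = correct_ratio_at_size(records, t7_template, 50)
    assert runoff_fidelity(dist, ratio, 50) >= before


def test_fidelity_report_fields(t7_template):
    T = t7_template.terminal_segment
    records = [ThreePrimeRecord(f"r{i}", T) for i in range(3)]
    records.append(ThreePrimeRecord("x", T[:40]))
    rep = compute_fidelity_report(records, t7_template, enzyme="T7", n_reads_in=5)
    assert rep.n_extracted == 4 and rep.n_reads_in == 5
    assert rep.modal_size == 50
    assert rep.freq_at_expected_size == pytest.approx(0.75)
    assert rep.correct_ratio_at_expected_size == 1.0
    assert rep.runoff_fidelity == pytest.approx(0.75)
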