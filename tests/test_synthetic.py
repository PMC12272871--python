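"""Generator: template engineering, mixtures, ground-truth consistency."""

import math

import numpy as np
import pytest

from termini import (
    NTA,
    GeneratorConfig,
    PrematureStop,
    Runoff,
    SelfTemplated,
    TemplateSpec,
    build_template,
    classify_five_prime,
    classify_three_prime,
    default_template,
    extract_five_prime,
    extract_three_prime,
    ligate_and_emit,
    preset,
    simulate_reads,
    simulate_transcripts,
)
from termini.core import TAG
from termini.synthetic import DEGRADATION_PROB, fragment_statistics

BODY_RNG = np.random.default_rng(123)
BODY = "".join(BODY_RNG.choice(list("ACGT"), size=250))
PROMOTER = "TAATACGACTCACTATA"


def test_build_template_places_tag_at_minus_fifty():
    spec = build_template(BODY, PROMOTER, tag_end_offset=50)
    t = spec.transcript
    assert len(t) == 250
    assert t.index(TAG) + len(TAG) == 200
    assert len(spec.terminal_segment) == 50


def test_build_template_tag_at_five_prime_boundary():
    spec = build_template(BODY, PROMOTER, tag_end_offset=len(BODY))
    assert spec.transcript.startswith(TAG)
    assert spec.tag_end_offset == len(BODY)


def test_build_template_rejects_tag_collision():
    with pytest.raises(ValueError):
        build_template(BODY[:100] + TAG + BODY[100:], PROMOTER)


def test_build_template_rejects_offset_overflow():
    with pytest.raises(ValueError):
        build_template(BODY, PROMOTER, tag_end_offset=245)


@pytest.mark.parametrize("enzyme,plus1", [("T7", "G"), ("KpnP", "G"), ("Ro45Iw", "G"), ("CD23823", "A")])
def test_default_template_plus_one_base(enzyme, plus1):
    spec = default_template(enzyme)
    assert spec.transcript[0] == plus1
    assert len(spec.transcript) == 250
    assert spec.tag_end_offset == 50


def test_template_spec_validates_tag_uniqueness():
    with pytest.raises(ValueError):
        TemplateSpec("bad", PROMOTER, len(PROMOTER), PROMOTER + TAG + "A" * 20 + TAG + "A" * 50)


def test_degenerate_runoff_mixture_reproduces_template(t7_template):
    cfg = GeneratorConfig(depth=50, seed=1)
    for seq, lab in simulate_transcripts(t7_template, cfg):
        assert seq == t7_template.transcript
        assert (lab.end_mode, lab.end_offset, lab.start_offset) == ("runoff", 0, 0)


def test_nta_mixture_appends_single_base(t7_template):
    cfg = GeneratorConfig(
        depth=30, seed=2,
        end_modes={NTA(length_probs=((1, 1.0),), base_probs=(("C", 1.0),)): 1.0},
    )
    for seq, lab in simulate_transcripts(t7_template, cfg):
        assert seq == t7_template.transcript + "C"
        assert (lab.end_mode, lab.extension) == ("nta", "C")


def test_premature_stop_at_minus_ten_gives_forty_nt_segments(t7_template):
    cfg = GeneratorConfig(depth=30, seed=3, end_modes={PrematureStop(-10): 1.0})
    reads, labels = simulate_reads(t7_template, cfg)
    for rd in reads:
        rec = extract_three_prime(rd)
        assert rec is not None and rec.size == 40


def test_self_templated_product_is_40_plus_12(t7_template):
    cfg = GeneratorConfig(
        depth=10, seed=4, end_modes={SelfTemplated(stop_offset=-10, cap=12): 1.0}
    )
    reads, labels = simulate_reads(t7_template, cfg)
    for rd, lab in zip(reads, labels):
        rec = extract_three_prime(rd)
        assert rec.size == 52
        assert lab.end_mode == "self_templated" and len(lab.extension) == 12


def test_ligate_and_emit_empty(tmp_path):
    fq, tsv = tmp_path / "e.fq", tmp_path / "e.tsv"
    n = ligate_and_emit([], default_template("T7"), fq, tsv)
    assert n == 0
    assert fq.read_text() == ""
    assert tsv.read_text().strip() == "read_id\tstart_offset\tn_extra_5g\tend_mode\tend_offset\textension"


def test_ligate_and_emit_structure_and_determinism(tmp_path, t7_template):
    cfg = GeneratorConfig(depth=50, seed=9)
    pairs = simulate_transcripts(t7_template, cfg)
    f1, f2 = tmp_path / "a.fq", tmp_path / "b.fq"
    ligate_and_emit(pairs, t7_template, f1, tmp_path / "a.tsv")
    ligate_and_emit(
        simulate_transcripts(t7_template, GeneratorConfig(depth=50, seed=9)),
        t7_template, f2, tmp_path / "b.tsv",
    )
    assert f1.read_bytes() == f2.read_bytes()
    first = f1.read_text().splitlines()[1]
    assert "ATGGCAGTCACA" + t7_template.transcript + "CACGAGCGTTTT" in first


def test_probability_maps_validated():
    with pytest.raises(ValueError):
        GeneratorConfig(depth=10, seed=0, start_offset_probs={0: 0.5, 1: 0.4})
    with pytest.raises(ValueError):
        GeneratorConfig(depth=0, seed=0)


# ---------------------------------------------------------------------------
# presets encode the published per-enzyme statistics


def test_cd23823_preset_theoretical_plus_one_frequency_is_60_percent():
    tpl = default_template("CD23823")
    cfg = preset("CD23823", template=tpl)
    _, _, delta0 = fragment_statistics(tpl)
    d = cfg.degradation_prob
    a = cfg.start_offset_probs[0]
    g = 1 - cfg.extra5g_probs.get(0, 1.0)
    assert (1 - d) * a * (1 - g) + d * delta0 == pytest.approx(0.60, abs=1e-12)


def test_t7_preset_theoretical_extra_g_fraction_is_9_percent():
    tpl = default_template("T7")
    cfg = preset("T7", template=tpl)
    d = cfg.degradation_prob
    a = cfg.start_offset_probs[0]
    g = 1 - cfg.extra5g_probs[0]
    assert (1 - d) * a * g == pytest.approx(0.09, abs=1e-12)


def test_kpnp_preset_dominant_mode_is_single_nta():
    cfg = preset("KpnP")
    dominant = max(cfg.end_modes, key=cfg.end_modes.get)
    assert isinstance(dominant, NTA)
    assert dict(dominant.length_probs) == {1: 1.0}


def test_preset_end_modes_sum_to_one():
    for e in ("T7", "KpnP", "Ro45Iw", "CD23823"):
        cfg = preset(e)
        assert math.isclose(sum(cfg.end_modes.values()), 1.0, abs_tol=1e-9)
        assert all(p >= 0 for p in cfg.end_modes.values())
        assert cfg.degradation_prob == DEGRADATION_PROB


def test_mode_frequencies_converge_to_configuration(t7_template):
    cfg = GeneratorConfig(
        depth=20000, seed=5,
        end_modes={Runoff(): 0.3, PrematureStop(-10): 0.5, NTA(): 0.2},
    )
    _, labels = simulate_reads(t7_template, cfg)
    n = len(labels)
    for mode, p in [("runoff", 0.3), ("premature_stop", 0.5), ("nta", 0.2)]:
        obs = sum(1 for l in labels if l.end_mode == mode) / n
        assert abs(obs - p) < 3 * math.sqrt(p * (1 - p) / n)


def test_same_seed_same_output(t7_template):
    cfg = preset("T7", depth=500, seed=42, template=t7_template)
    a = simulate_transcripts(t7_template, cfg)
    b = simulate_transcripts(t7_template, cfg)
    assert [(s, vars(l)) for s, l in a] == [(s, vars(l)) for s, l in b]


# ---------------------------------------------------------------------------
# generator/classifier closure: truth labels are recovered exactly


def closure_config(depth=2000, seed=6):
    return GeneratorConfig(
        depth=depth, seed=seed,
        start_offset_probs={0: 0.6, -1: 0.1, -2: 0.05, 1: 0.15, 3: 0.1},
        extra5g_probs={0: 0.8, 1: 0.12, 2: 0.05, 3: 0.03},
        end_modes={
            Runoff(): 0.4,
            PrematureStop(-10): 0.2,
            NTA(): 0.15,
            SelfTemplated(stop_offset=-10, cap=12): 0.15,
            SelfTemplated(stop_offset=-10, cap=10): 0.1,
        },
        degradation_prob=0.0,
        seq_error_rate=0.0,
    )


END_MODE_TO_CATEGORY = {
    "runoff": "correct_runoff",
    "premature_stop": "templated_truncation",
    "nta": "nontemplated_addition",
    "self_templated": "self_templated",
}


def test_classification_recovers_truth_labels(t7_template):
    reads, labels = simulate_reads(t7_template, closure_config())
    for rd, lab in zip(reads, labels):
        five = extract_five_prime(rd)
        assert five is not None
        flab = classify_five_prime(five.window, t7_template)
        if lab.n_extra_5g > 0:
            assert flab.category == "nontemplated_5prime"
            assert (flab.n_extra, flab.base) == (lab.n_extra_5g, "G")
        elif lab.start_offset == 0:
            assert flab.category == "starts_at_plus1"
        else:
            assert (flab.category, flab.offset) == ("shifted_start", lab.start_offset)
        three = extract_three_prime(rd)
        assert three is not None
        tlab = classify_three_prime(three.segment, t7_template)
        assert tlab.category == END_MODE_TO_CATEGORY[lab.end_mode]
        if lab.end_mode in ("nta", "self_templated"):
            assert tlab.extension == lab.extension
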