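import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import votefuse as vf
from votefuse.genotype_prep import (
    MarkerEncoding,
    encode_table,
    fit_normalization,
    pairwise_r2,
)
from votefuse.io_model import ValidationError

from conftest import toy_calls, toy_labels


# ---------------------------------------------------------------------------
# risk allele and dosage encoding
# ---------------------------------------------------------------------------

def test_risk_allele_is_case_majority_allele():
    calls = toy_calls(["AA", "AT", "AA", "TT", "TT"])
    labels = toy_labels(["s0", "s1", "s2"], ["s3", "s4"])
    assert vf.determine_risk_allele(calls, labels) == ("A", "T")


def test_risk_allele_tie_broken_by_control_minor_then_lexicographic():
    # case allele frequencies exactly 0.5; controls carry more T, so A is
    # the control-minor allele and becomes the risk allele
    calls = toy_calls(["AT", "AT", "TT", "TT", "AT"])
    labels = toy_labels(["s0", "s1"], ["s2", "s3", "s4"])
    assert vf.determine_risk_allele(calls, labels) == ("A", "T")
    # fully symmetric tie: lexicographic
    calls = toy_calls(["AT", "AT", "AT", "AT"])
    labels = toy_labels(["s0", "s1"], ["s2", "s3"])
    assert vf.determine_risk_allele(calls, labels) == ("A", "T")


def test_risk_allele_monomorphic_cases_uses_cohort_for_other():
    calls = toy_calls(["AA", "AA", "AT", "TT"])
    labels = toy_labels(["s0", "s1"], ["s2", "s3"])
    assert vf.determine_risk_allele(calls, labels) == ("A", "T")


def test_all_case_calls_missing_is_unencodable():
    calls = toy_calls([None, None, "AT", "AA"])
    labels = toy_labels(["s0", "s1"], ["s2", "s3"])
    with pytest.raises(ValidationError, match="unencodable"):
        vf.determine_risk_allele(calls, labels)


@pytest.mark.parametrize(
    "call,expected", [("AA", 2), ("AT", 1), ("TT", 0), (None, None)]
)
def test_dosage_encoding(call, expected):
    enc = MarkerEncoding("m1", "A", "T")
    assert vf.encode_numeric(call, enc) == expected


def test_foreign_allele_errors_with_marker_name():
    enc = MarkerEncoding("m1", "A", "T")
    with pytest.raises(ValidationError, match="m1"):
        vf.encode_numeric("AG", enc)


@given(g=st.integers(min_value=0, max_value=2))
@settings(deadline=None)
def test_encoding_label_equivariance(g):
    """Swapping risk/other allele maps dosage g to 2-g."""
    call = "A" * g + "T" * (2 - g)
    call = "".join(sorted(call))
    enc = MarkerEncoding("m", "A", "T")
    enc_swapped = MarkerEncoding("m", "T", "A")
    assert vf.encode_numeric(call, enc) == 2 - vf.encode_numeric(call, enc_swapped)


# ---------------------------------------------------------------------------
# EIGENSTRAT normalization (hand oracle)
# ---------------------------------------------------------------------------

def _fit(mid, values):
    enc = MarkerEncoding(mid, "A", "T")
    return fit_normalization(pd.Series(values, dtype=float), enc)


def test_normalization_hand_oracle_0121():
    # g=[0,1,2,1]: mean 1, p=(1+4)/(2+8)=0.5, scale 0.5 -> [-2,0,2,0]
    enc = _fit("m", [0, 1, 2, 1])
    assert enc.train_mean == pytest.approx(1.0)
    assert enc.train_allele_freq == pytest.approx(0.5)
    assert enc.scale == pytest.approx(0.5)
    assert [enc.normalize(g) for g in (0, 1, 2, 1)] == pytest.approx([-2, 0, 2, 0])


def test_normalization_hand_oracle_02():
    enc = _fit("m", [0, 2])
    assert enc.train_mean == pytest.approx(1.0)
    assert enc.train_allele_freq == pytest.approx(0.5)
    assert [enc.normalize(g) for g in (0, 2)] == pytest.approx([-2, 2])


def test_normalization_monomorphic_training_flagged():
    # g=[2,2,2,2]: posterior p=9/10, centered values all 0, flagged constant
    enc = _fit("m", [2, 2, 2, 2])
    assert enc.train_allele_freq == pytest.approx(0.9)
    assert enc.constant_in_training
    assert enc.normalize(2) == pytest.approx(0.0)


def test_apply_normalization_missing_to_zero_and_test_reuse():
    calls = pd.DataFrame(
        {"m": ["AA", "AT", "TT", "AT", None]},
        index=[f"s{i}" for i in range(5)], dtype=object,
    )
    table = vf.RawGenotypeTable(calls)
    labels = toy_labels(["s0", "s1"], ["s2", "s3", "s4"])
    encodings, dropped = vf.fit_encodings(table, labels)
    assert not dropped
    mat = vf.apply_normalization(table, encodings)
    # missing entry is exactly 0.0 and masked
    assert mat.values.loc["s4", "m"] == 0.0
    assert mat.missing_mask.loc["s4", "m"]
    # g = train mean maps to 0; test-set g=2 with mean 1, scale 0.5 -> 2.0
    enc = encodings["m"]
    assert enc.normalize(enc.train_mean) == 0.0
    test_calls = pd.DataFrame({"m": ["AA"]}, index=["t1"], dtype=object)
    mat2 = vf.apply_normalization(vf.RawGenotypeTable(test_calls), encodings)
    assert mat2.values.loc["t1", "m"] == pytest.approx(
        (2 - enc.train_mean) / enc.scale
    )


def test_apply_normalization_unknown_marker_errors():
    calls = pd.DataFrame({"mX": ["AA"]}, index=["s0"], dtype=object)
    with pytest.raises(ValidationError, match="mX"):
        vf.apply_normalization(vf.RawGenotypeTable(calls), {})


def test_normalized_training_mean_near_zero(sim_default, prep_default):
    """No-missing columns center exactly; missing columns within the bound
    missing_count * |mean| / scale / n."""
    vals = prep_default.geno_train
    table = sim_default.train.genotype
    n = len(vals)
    for m in vals.columns:
        enc = prep_default.encodings[m]
        n_miss = int(table.calls[m].isna().sum())
        bound = n_miss * abs(enc.train_mean) / enc.scale / n + 1e-9
        assert abs(vals[m].mean()) <= bound


# ---------------------------------------------------------------------------
# pairwise r2 (EM) and LD pruning
# ---------------------------------------------------------------------------

def _counts_r2(ga, gb):
    """Closed-form r2 from haplotype counts for tables without double hets."""
    ga, gb = np.asarray(ga), np.asarray(gb)
    assert not ((ga == 1) & (gb == 1)).any()
    haps = []
    for a, b in zip(ga, gb):
        copies_a = [1] * a + [0] * (2 - a)
        copies_b = [1] * b + [0] * (2 - b)
        if a == 1:
            copies_a = [1, 0]
        if b == 1:
            copies_b = [1, 0] if a != 0 else [1, 0]
        haps += list(zip(copies_a, copies_b))
    haps = np.array(haps)
    pa, pb = haps[:, 0].mean(), haps[:, 1].mean()
    f11 = (haps[:, 0] & haps[:, 1]).mean()
    d = f11 - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def _calls_from_dosage(g, alleles="AT"):
    lut = {0: alleles[1] * 2, 1: "".join(sorted(alleles)), 2: alleles[0] * 2}
    return toy_calls([lut[int(x)] for x in g])


def test_r2_marker_against_itself_is_one():
    g = [0, 1, 2, 0, 1, 2, 1, 0]
    a = _calls_from_dosage(g)
    assert pairwise_r2(a, a) == pytest.approx(1.0)


def test_r2_double_homozygote_blocks_are_perfect_ld():
    g = [2] * 50 + [0] * 50
    a = _calls_from_dosage(g, "AT")
    b = _calls_from_dosage(g, "GC")
    assert pairwise_r2(a, b) == pytest.approx(1.0)


def test_r2_independent_markers_near_zero(rng):
    n = 2000
    a = _calls_from_dosage(rng.binomial(2, 0.4, n))
    b = _calls_from_dosage(rng.binomial(2, 0.6, n))
    assert pairwise_r2(a, b) < 0.05


def test_r2_em_matches_closed_form_without_double_hets(rng):
    # phase-unambiguous table: avoid simultaneous heterozygotes
    ga = rng.integers(0, 3, 200)
    gb = rng.integers(0, 3, 200)
    gb[(ga == 1) & (gb == 1)] = 2
    a, b = _calls_from_dosage(ga), _calls_from_dosage(gb)
    assert pairwise_r2(a, b) == pytest.approx(_counts_r2(ga, gb), abs=1e-8)


def test_r2_symmetric_and_allele_label_invariant(rng):
    ga = rng.binomial(2, 0.3, 120)
    gb = np.where(rng.random(120) < 0.8, ga, rng.binomial(2, 0.3, 120))
    a, b = _calls_from_dosage(ga), _calls_from_dosage(gb)
    r = pairwise_r2(a, b)
    assert pairwise_r2(b, a) == pytest.approx(r)
    # swap allele labels at marker b (dosage 2-g)
    b_swapped = _calls_from_dosage(2 - gb)
    assert pairwise_r2(a, b_swapped) == pytest.approx(r, abs=1e-9)


def test_r2_monomorphic_marker_warns_zero():
    a = _calls_from_dosage([2] * 10)
    b = _calls_from_dosage([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
    with pytest.warns(UserWarning, match="monomorphic"):
        assert pairwise_r2(a, b) == 0.0


def test_ld_prune_drops_lower_priority_duplicate(rng):
    g = rng.binomial(2, 0.5, 100)
    calls = pd.DataFrame(
        {"keep": _calls_from_dosage(g).values, "dup": _calls_from_dosage(g).values},
        index=[f"s{i}" for i in range(100)], dtype=object,
    )
    table = vf.RawGenotypeTable(calls)
    rep = vf.ld_prune(table, 0.8)
    assert rep.kept == ["keep"]
    assert rep.dropped[0][:2] == ("dup", "keep")
    assert rep.dropped[0][2] >= 0.8
    # priority order reverses the outcome
    rep2 = vf.ld_prune(table, 0.8, priority=["dup", "keep"])
    assert rep2.kept == ["dup"]


def test_ld_prune_keeps_independent_markers(rng):
    calls = pd.DataFrame(
        {f"m{i}": _calls_from_dosage(rng.binomial(2, 0.5, 150)).values
         for i in range(6)},
        index=[f"s{i}" for i in range(150)], dtype=object,
    )
    rep = vf.ld_prune(vf.RawGenotypeTable(calls), 0.8)
    assert rep.kept == [f"m{i}" for i in range(6)]
    assert rep.dropped == []


def test_ld_prune_respects_chromosomes(rng):
    g = rng.binomial(2, 0.5, 100)
    ids = [f"s{i}" for i in range(100)]
    calls = pd.DataFrame(
        {"a": _calls_from_dosage(g).values, "b": _calls_from_dosage(g).values},
        index=ids, dtype=object,
    )
    markers = {"a": vf.MarkerInfo("a", "1"), "b": vf.MarkerInfo("b", "2")}
    rep = vf.ld_prune(vf.RawGenotypeTable(calls, markers), 0.8)
    # identical calls but on different chromosomes: both kept
    assert rep.kept == ["a", "b"]


def test_encodings_json_round_trip(tmp_path, prep_default):
    path = tmp_path / "enc.json"
    from votefuse.genotype_prep import load_encodings, save_encodings

    save_encodings(prep_default.encodings, path)
    back = load_encodings(path)
    assert back == prep_default.encodings
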