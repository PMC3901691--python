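import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnabindpred import encode_all, normalize_pssm, parse_descriptor_name
from dnabindpred.features import (
    FAMILY_TABLE,
    N_DESCRIPTORS,
    encode_aac,
    encode_autocc,
    encode_ave_rsa,
    encode_pssm_averages,
    encode_pssm_percentiles,
    encode_ss_content,
    enumerate_feature_space,
    normalize_descriptor_name,
)
from dnabindpred.io import AA_ALPHABET, PSSMatrix

from conftest import random_triple


class TestFeatureSpaceCensus:
    def test_total_and_family_sizes(self, space):
        assert len(space) == N_DESCRIPTORS
        sizes = space.family_sizes()
        expected = {fam: n for fam, _, n in FAMILY_TABLE}
        assert sizes == expected
        assert sum(sizes.values()) == 1486

    def test_names_unique_and_parseable(self, space):
        assert len(set(space.names)) == 1486
        for d in space.descriptors:
            parsed = parse_descriptor_name(d.name)
            assert parsed.family == d.family
            assert parsed.category == d.category

    def test_enumeration_deterministic(self, space):
        again = enumerate_feature_space()
        assert again.names == space.names


class TestDescriptorGrammar:
    @pytest.mark.parametrize(
        "printed, family, category",
        [
            ("Pscore_AA_Q__P_75_", "Pscore_P", "PSSM"),
            ("AutoCC_AA_N_ _Lag_7_", "AutoCC_Lag", "PSSM"),
            ("AvePscore_AA_R_ _Res_R_", "AvePscore_AA_Res", "PSSM"),
            ("DIP_Res_DL_", "DIC_Res", "AAC"),  # published dipeptide alias
            ("AAC_Res_R__Ex_0.2_", "AAC_Res_Ex", "AAC"),
            ("AveRSA_Res_G_", "AveRSA_Res", "AveRSA"),
            ("Con_SS_H", "Con_SS", "SS_content"),
        ],
    )
    def test_printed_names_parse(self, printed, family, category):
        d = parse_descriptor_name(printed)
        assert d.family == family
        assert d.category == category

    def test_unparseable_name_raises(self):
        with pytest.raises(ValueError, match="NotAFeature"):
            parse_descriptor_name("NotAFeature_42")

    def test_normalization_idempotent(self):
        n = normalize_descriptor_name("AutoCC_AA_T__Lag_2_")
        assert n == "AutoCC_AA_T_Lag_2"
        assert normalize_descriptor_name(n) == n


class TestToyGoldenValues:
    def test_all_hand_computed_values(self, toy, space):
        vec = encode_all(toy["record"], toy["pssm"], toy["profile"], space)
        for name, expected in toy["expected"].items():
            assert vec[space.index[name]] == pytest.approx(expected, abs=1e-12), name


class TestLogisticNormalization:
    def test_known_values(self):
        raw = PSSMatrix("p", np.array([[0.0] * 20, [2.0] * 20, [-7.0] * 20, [-6.0] * 20]))
        norm = normalize_pssm(raw)
        assert norm.scores[0, 0] == pytest.approx(0.5)
        assert norm.scores[1, 0] == pytest.approx(0.88079707797788, abs=1e-10)
        assert norm.scores[2, 0] < norm.scores[3, 0]  # monotone
        assert np.all((norm.scores > 0) & (norm.scores < 1))

    def test_idempotent_flag(self):
        raw = PSSMatrix("p", np.zeros((3, 20)))
        norm = normalize_pssm(raw)
        assert normalize_pssm(norm) is norm


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_composition_identities(seed):
    """Partition/normalization identities hold on random fixtures."""
    rng = np.random.default_rng(seed)
    record, pssm, profile = random_triple(rng)
    L = len(record)

    con = encode_ss_content(profile)
    assert con.sum() == pytest.approx(1.0)

    aac_all = encode_aac(record, profile)
    aac, aac_ss = aac_all[:20], aac_all[20:80].reshape(20, 3)
    aac_ex = aac_all[80:180].reshape(20, 5)
    aac_bu = aac_all[180:280].reshape(20, 5)
    dic = aac_all[280:680]
    assert aac.sum() == pytest.approx(1.0)
    assert dic.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(aac_ss.sum(axis=1), aac, atol=1e-12)
    for j in range(5):
        np.testing.assert_allclose(aac_ex[:, j] + aac_bu[:, j], aac, atol=1e-12)

    ave = encode_ave_rsa(record, profile)
    assert np.all((ave >= 0) & (ave <= 1))

    norm = normalize_pssm(pssm)
    assert np.all((norm.scores > 0) & (norm.scores < 1))
    pct = encode_pssm_percentiles(norm).reshape(20, 5)
    np.testing.assert_array_equal(pct[:, 0], norm.scores.min(axis=0))
    np.testing.assert_array_equal(pct[:, 4], norm.scores.max(axis=0))
    assert np.all(np.diff(pct, axis=1) >= 0)  # non-decreasing in t

    acc = encode_autocc(norm)
    assert np.all((acc >= -1 - 1e-12) & (acc <= 1 + 1e-12))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), length=st.integers(2, 50))
def test_dipeptide_matches_bruteforce(seed, length):
    rng = np.random.default_rng(seed)
    record, _, profile = random_triple(rng, length=length)
    dic = encode_aac(record, profile)[280:680].reshape(20, 20)
    seq = record.sequence
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        counts[AA_ALPHABET.index(a), AA_ALPHABET.index(b)] += 1
    np.testing.assert_allclose(dic, counts / (length - 1), atol=1e-12)


def test_autocc_matches_bruteforce_formula():
    rng = np.random.default_rng(7)
    _, pssm, _ = random_triple(rng, length=25)
    norm = normalize_pssm(pssm)
    got = encode_autocc(norm).reshape(20, 10)
    S = norm.scores
    for j in range(20):
        col = S[:, j]
        mu = col.mean()
        denom = ((col - mu) ** 2).sum()
        for m in range(1, 11):
            num = sum((col[i] - mu) * (col[i + m] - mu) for i in range(len(col) - m))
            assert got[j, m - 1] == pytest.approx(num / denom, abs=1e-12)


def test_autocc_alternating_series_near_minus_one():
    scores = np.zeros((30, 20))
    scores[:, 0] = np.tile([3.0, -3.0], 15)
    norm = normalize_pssm(PSSMatrix("p", scores))
    acc = encode_autocc(norm).reshape(20, 10)
    assert acc[0, 0] == pytest.approx(-29 / 30, abs=1e-12)


def test_autocc_lag_exceeding_length_warns_zero():
    rng = np.random.default_rng(8)
    _, pssm, _ = random_triple(rng, length=8)
    norm = normalize_pssm(pssm)
    with pytest.warns(UserWarning, match="lag"):
        acc = encode_autocc(norm).reshape(20, 10)
    assert np.all(acc[:, 8:] == 0)  # lags 9, 10 undefined at L=8


def test_percentile_nearest_rank_median():
    scores = np.zeros((3, 20))
    scores[:, 0] = [np.log(9), np.log(0.4 / 0.6), np.log(0.1 / 0.9)]  # expit: .9,.4,.1
    norm = normalize_pssm(PSSMatrix("p", scores))
    pct = encode_pssm_percentiles(norm).reshape(20, 5)
    np.testing.assert_allclose(pct[0], [0.1, 0.1, 0.4, 0.9, 0.9], atol=1e-12)


def test_pssm_average_conditioning(toy, space):
    """Residue-conditioned column averages agree with direct subsetting."""
    rng = np.random.default_rng(9)
    record, pssm, profile = random_triple(rng, length=40)
    norm = normalize_pssm(pssm)
    vals = encode_pssm_averages(record, norm)
    cond = vals[20:].reshape(20, 20)
    for x2, aa in enumerate(AA_ALPHABET):
        rows = [i for i, c in enumerate(record.sequence) if c == aa]
        for x in range(20):
            expected = norm.scores[rows, x].mean() if rows else 0.0
            assert cond[x, x2] == pytest.approx(expected, abs=1e-12)


class TestEncodeAll:
    def test_deterministic_and_finite(self, space):
        rng = np.random.default_rng(10)
        record, pssm, profile = random_triple(rng)
        v1 = encode_all(record, pssm, profile, space)
        v2 = encode_all(record, pssm, profile, space)
        np.testing.assert_array_equal(v1, v2)
        assert v1.shape == (1486,)
        assert np.all(np.isfinite(v1))

    def test_length_mismatch_names_protein(self, space):
        rng = np.random.default_rng(11)
        record, pssm, _ = random_triple(rng, length=30, pid="mismatched")
        _, _, profile = random_triple(rng, length=31)
        with pytest.raises(ValueError, match="mismatched"):
            encode_all(record, pssm, profile, space)
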