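"""Fragment scoring (s, m, p), CSI search, and feature-vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presyncodon.csi import build_csi
from presyncodon.genetics import STANDARD_AAS, STANDARD_CODE
from presyncodon.matching import (
    MatchConfig,
    NoMatchError,
    build_feature_vector,
    get_searcher,
    load_substitution_matrix,
    score_pair,
    search_csi,
    self_score,
)

fragments5 = st.text(alphabet=STANDARD_AAS, min_size=5, max_size=5)


class TestScores:
    @pytest.mark.parametrize(
        "fragment, expected",
        [("KKKKK", 25.0), ("WWWWW", 55.0)],  # BLOSUM62: K/K=5, W/W=11
    )
    def test_self_score(self, fragment, expected):
        assert self_score(fragment) == expected

    def test_hand_summed_pair(self):
        # K/K=5, A/G=0 under BLOSUM62 -> 5+0+5+0+5
        assert score_pair("KAKAK", "KGKGK") == 15.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_pair("KKK", "KKKK")

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            self_score("KKXKK")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(fragments5, fragments5)
    def test_symmetry(self, a, b):
        assert score_pair(a, b) == score_pair(b, a)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(fragments5)
    def test_self_pair_equals_self_score(self, fragment):
        assert score_pair(fragment, fragment) == self_score(fragment)


@pytest.fixture(scope="module")
def csi5(small_records):
    return build_csi(small_records, 5)


def _random_queries(csi, rng, n=50):
    """Mix of fragments present in the index and random novel ones."""
    present = sorted(csi.entries)
    queries = [present[i] for i in rng.integers(0, len(present), size=n // 2)]
    degenerate = sorted(STANDARD_CODE.degenerate_aas)
    while len(queries) < n:
        q = "".join(rng.choice(list(STANDARD_AAS), size=5))
        mid = degenerate[rng.integers(len(degenerate))]
        queries.append(q[:2] + mid + q[3:])
    return queries


def _brute_force_search(query, csi, cutoff):
    """Independent oracle: score every same-middle entry with score_pair."""
    matrix = load_substitution_matrix()
    m = self_score(query, matrix)
    middle = query[len(query) // 2]
    out = []
    for frag in csi.entries:
        if frag[len(frag) // 2] != middle:
            continue
        s = score_pair(query, frag, matrix)
        p = s / m
        passes = (s > 0) and (p >= 1.0 if cutoff >= 1.0 else p > cutoff)
        if passes:
            out.append((frag, s, p))
    out.sort(key=lambda t: (-t[2], t[0]))
    return out


class TestSearchCsi:
    def test_exact_fragment_found_at_cutoff_one(self, csi5):
        query = sorted(csi5.entries)[0]
        results = search_csi(query, csi5, MatchConfig(cutoff=1.0))
        assert [r.entry.fragment for r in results] == [query]
        assert results[0].p == 1.0

    def test_p_equals_one_only_for_exact_match(self, csi5):
        query = sorted(csi5.entries)[10]
        results = search_csi(query, csi5, MatchConfig(cutoff=0.7))
        for r in results:
            assert (r.p == 1.0) == (r.entry.fragment == query)

    def test_no_shared_middle_gives_empty_result(self):
        from presyncodon.corpus import CodingSequence
        from presyncodon.genetics import translate

        codons = ("ATG", "AAA", "AAA", "AAA", "TGG")
        gene = CodingSequence("g", codons, translate(codons))
        index = build_csi([gene], 5)  # only a K-middle entry
        assert search_csi("MMHMM", index, MatchConfig(cutoff=0.7)) == []

    def test_agrees_with_brute_force_oracle(self, csi5):
        rng = np.random.default_rng(17)
        for query in _random_queries(csi5, rng, n=50):
            for cutoff in (0.7, 0.9, 1.0):
                got = [
                    (r.entry.fragment, r.s, r.p)
                    for r in search_csi(query, csi5, MatchConfig(cutoff=cutoff))
                ]
                assert got == _brute_force_search(query, csi5, cutoff)

    def test_cutoff_monotonicity(self, csi5):
        rng = np.random.default_rng(23)
        for query in _random_queries(csi5, rng, n=20):
            at_07 = {r.entry.fragment for r in search_csi(query, csi5, MatchConfig(cutoff=0.7))}
            at_09 = {r.entry.fragment for r in search_csi(query, csi5, MatchConfig(cutoff=0.9))}
            assert at_09 <= at_07


class TestFeatureVector:
    def test_single_match_normalizes_distribution(self, csi5):
        from presyncodon.csi import CsiEntry
        from presyncodon.matching import MatchResult

        entry = CsiEntry("AAKAA", {"AAA": 3, "AAG": 1}, (0.5,) * 5, 4)
        fv = build_feature_vector([MatchResult(entry, 25.0, 25.0, 1.0)], "K", 5)
        assert fv[:2] == pytest.approx([0.75, 0.25])
        assert len(fv) == 2 + 5  # k + w

    def test_two_matches_average(self):
        from presyncodon.csi import CsiEntry
        from presyncodon.matching import MatchResult

        e1 = CsiEntry("AAKAA", {"AAA": 1}, (0.2,) * 5, 1)
        e2 = CsiEntry("CCKCC", {"AAG": 1}, (0.8,) * 5, 1)
        fv = build_feature_vector(
            [MatchResult(e1, 20.0, 25.0, 0.8), MatchResult(e2, 20.0, 25.0, 0.8)], "K", 5
        )
        assert fv[:2] == pytest.approx([0.5, 0.5])
        assert fv[2:] == pytest.approx([0.5] * 5)

    def test_zero_matches_signal_no_match(self):
        with pytest.raises(NoMatchError):
            build_feature_vector([], "K", 5)

    def test_feature_dimension_is_degeneracy_plus_window(self, csi5):
        searcher = get_searcher(csi5, MatchConfig(cutoff=1.0))
        for frag in sorted(csi5.entries)[:20]:
            fv = searcher.feature_vector(frag, 1.0)
            k = STANDARD_CODE.degeneracy(frag[2])
            assert fv.shape == (k + 5,)
            assert fv[:k].sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((fv >= 0) & (fv <= 1))

    def test_fast_path_equals_match_list_construction(self, csi5):
        rng = np.random.default_rng(29)
        searcher = get_searcher(csi5, MatchConfig(cutoff=0.7))
        for query in _random_queries(csi5, rng, n=20):
            matches = search_csi(query, csi5, MatchConfig(cutoff=0.7))
            fv = searcher.feature_vector(query, 0.7)
            if not matches:
                assert fv is None
                continue
            expected = build_feature_vector(matches, query[2], 5)
            assert fv == pytest.approx(expected)

    def test_mean_is_componentwise_bounded_by_inputs(self, csi5):
        rng = np.random.default_rng(31)
        for query in _random_queries(csi5, rng, n=10):
            matches = search_csi(query, csi5, MatchConfig(cutoff=0.7))
            if len(matches) < 2:
                continue
            fv = build_feature_vector(matches, query[2], 5)
            k = STANDARD_CODE.degeneracy(query[2])
            dists = np.stack([m.entry.middle_distribution() for m in matches])
            assert np.all(fv[:k] >= dists.min(axis=0) - 1e-12)
            assert np.all(fv[:k] <= dists.max(axis=0) + 1e-12)

    def test_match_config_validation(self):
        with pytest.raises(ValueError):
            MatchConfig(cutoff=0.0)
        with pytest.raises(ValueError):
            MatchConfig(cutoff=1.2)
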