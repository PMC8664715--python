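"""Connectivity scorers, permutation null, and database querying, checked
against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosecmap import (ContractViolation, GeneSignature, ParameterError,
                      SignatureDatabase, combined_score, permutation_null,
                      profile_top_sets, query_database, signed_jaccard,
                      wks_connectivity)
from dosecmap.connectivity import _ks_es

from conftest import make_profile


# ------------------------------------------------------------------ oracles

def oracle_signed_jaccard(qu, qd, su, sd):
    """First-principles re-derivation: per-element double loop counts."""
    def j(a, b):
        inter = sum(1 for x in a if x in b)
        union = len(set(list(a) + list(b)))
        return inter / union if union else 0.0
    return (j(qu, su) + j(qd, sd) - j(qu, sd) - j(qd, su)) / 2


def oracle_ks_es(hit_ranks, n):
    """Running-sum over every position of the ranking."""
    t = len(hit_ranks)
    hits = set(hit_ranks)
    best_a = -np.inf
    best_b = -np.inf
    seen = 0
    for pos in range(1, n + 1):
        if pos in hits:
            seen += 1
            best_a = max(best_a, seen / t - pos / n)
            best_b = max(best_b, pos / n - (seen - 1) / t)
    return best_a if best_a >= best_b else -best_b


class TestProfileTopSets:
    def test_direct_ordering(self):
        p = make_profile("ABCDE", [2, 1, 0, -1, -2])
        up, down = profile_top_sets(p, 2)
        assert up == {"A", "B"} and down == {"D", "E"}

    def test_tie_break_alphabetical_up_first(self):
        p = make_profile("ABCDEFGHIJ", [0.0] * 10)
        up, down = profile_top_sets(p, 1)
        assert up == {"A"} and down == {"B"}

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        genes = tuple(f"G{i:03d}" for i in range(100))
        v = rng.normal(size=100)
        p = make_profile(genes, v)
        up, down = profile_top_sets(p, 10)
        order = sorted(range(100), key=lambda i: (-v[i], genes[i]))
        assert up == set(genes[i] for i in order[:10])
        assert down == set(genes[i] for i in order[-10:])

    def test_n_top_too_large(self, tiny_profile):
        with pytest.raises(ParameterError):
            profile_top_sets(tiny_profile, 6)


class TestSignedJaccard:
    def test_perfect_concordance(self):
        assert signed_jaccard({"A", "B"}, {"C", "D"}, {"A", "B"}, {"C", "D"}) == 1.0

    def test_perfect_reversal(self):
        assert signed_jaccard({"A", "B"}, {"C", "D"}, {"C", "D"}, {"A", "B"}) == -1.0

    def test_partial_overlap_value(self):
        val = signed_jaccard({"A", "B"}, {"C", "D"}, {"A", "E"}, {"F", "G"})
        assert val == pytest.approx(1 / 6, abs=1e-15)

    def test_overlapping_halves_rejected(self):
        with pytest.raises(ContractViolation):
            signed_jaccard({"A"}, {"A"}, {"B"}, {"C"})
        with pytest.raises(ContractViolation):
            signed_jaccard({"A"}, {"B"}, {"C"}, {"C"})

    def test_exhaustive_small_universe(self):
        """All disjoint-pair set systems over a 4-gene universe."""
        genes = "ABCD"
        assignments = list(itertools.product([0, 1, 2], repeat=len(genes)))

        def sets_of(assign):
            up = {g for g, a in zip(genes, assign) if a == 1}
            dn = {g for g, a in zip(genes, assign) if a == 2}
            return up, dn
        for qa in assignments:
            qu, qd = sets_of(qa)
            for sa in assignments:
                su, sd = sets_of(sa)
                assert signed_jaccard(qu, qd, su, sd) == pytest.approx(
                    oracle_signed_jaccard(qu, qd, su, sd), abs=1e-12)

    def test_symmetry_and_antisymmetry_random(self):
        rng = np.random.default_rng(4)
        genes = np.array([f"G{i}" for i in range(12)])
        for _ in range(300):
            labels = rng.integers(0, 3, size=(2, 12))
            qu = set(genes[labels[0] == 1]); qd = set(genes[labels[0] == 2])
            su = set(genes[labels[1] == 1]); sd = set(genes[labels[1] == 2])
            s = signed_jaccard(qu, qd, su, sd)
            assert s == pytest.approx(signed_jaccard(su, sd, qu, qd), abs=1e-15)
            assert s == pytest.approx(-signed_jaccard(qu, qd, sd, su), abs=1e-15)
            assert -1.0 <= s <= 1.0


class TestWksConnectivity:
    def test_concordant_extremes(self):
        genes = tuple(f"G{i}" for i in range(1, 11))
        # descending z: G1 has the highest z, G10 the lowest
        p = make_profile(genes, np.arange(10, 0, -1, dtype=float))
        score = wks_connectivity({"G1", "G2"}, {"G9", "G10"}, p)
        assert score == pytest.approx(0.85, abs=1e-12)

    def test_reversed_ranking_negates(self):
        genes = tuple(f"G{i}" for i in range(1, 11))
        p = make_profile(genes, np.arange(1, 11, dtype=float))
        score = wks_connectivity({"G1", "G2"}, {"G9", "G10"}, p)
        assert score == pytest.approx(-0.85, abs=1e-12)

    def test_discordant_halves_score_zero(self):
        genes = tuple(f"G{i}" for i in range(1, 11))
        p = make_profile(genes, np.arange(10, 0, -1, dtype=float))
        # both query halves sit at the top: both ES positive -> null score
        assert wks_connectivity({"G1", "G2"}, {"G3", "G4"}, p) == 0.0

    def test_absent_gene_named_in_error(self, tiny_profile):
        with pytest.raises(ParameterError, match="ZZZ"):
            wks_connectivity({"ZZZ"}, {"A"}, tiny_profile)

    def test_es_matches_running_sum_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            t = int(rng.integers(1, min(n, 10) + 1))
            ranks = np.sort(rng.choice(np.arange(1, n + 1), size=t,
                                       replace=False))
            assert _ks_es(ranks, n) == pytest.approx(
                oracle_ks_es(list(ranks), n), abs=1e-12)

    def test_bounded_random(self):
        rng = np.random.default_rng(12)
        genes = tuple(f"G{i:02d}" for i in range(30))
        for _ in range(50):
            p = make_profile(genes, rng.normal(size=30))
            pick = rng.choice(30, size=8, replace=False)
            s = wks_connectivity({genes[i] for i in pick[:4]},
                                 {genes[i] for i in pick[4:]}, p)
            assert -1.0 <= s <= 1.0


class TestPermutationNull:
    def test_add_one_smoothing_floor(self, tiny_profile):
        # observed larger than any |null| -> p = 1/(n_perm+1)
        p, z = permutation_null(lambda a, b: 0.0, tiny_profile, (2, 2),
                                n_perm=999, seed=1, observed=5.0)
        # constant null is degenerate -> handled by the sd=0 rule
        assert (p, z) == (1.0, 0.0)
        scores = iter(np.linspace(-0.5, 0.5, 999))
        p, z = permutation_null(lambda a, b: next(scores), tiny_profile,
                                (2, 2), n_perm=999, seed=1, observed=5.0)
        assert p == pytest.approx(1 / 1000)

    def test_zero_observed_on_symmetric_null(self, tiny_profile):
        rng = np.random.default_rng(2)
        p, z = permutation_null(lambda a, b: rng.normal(), tiny_profile,
                                (2, 2), n_perm=999, seed=3, observed=0.0)
        assert p > 0.9
        assert abs(z) < 3 / np.sqrt(999)

    def test_n_perm_floor(self, tiny_profile):
        with pytest.raises(ParameterError):
            permutation_null(lambda a, b: 0.0, tiny_profile, (2, 2),
                             n_perm=50, seed=0, observed=0.0)

    def test_null_queries_are_disjoint_and_sized(self, tiny_profile):
        seen = []
        def spy(a, b):
            seen.append((a, b))
            return 0.0
        permutation_null(spy, tiny_profile, (3, 4), n_perm=99, seed=5,
                         observed=0.0)
        assert len(seen) == 99
        for a, b in seen:
            assert len(a) == 3 and len(b) == 4 and not a & b


class TestCombinedScore:
    @pytest.mark.parametrize("p,z,expected", [
        (0.01, 3.0, 6.0),
        (1.0, 5.0, 0.0),
        (0.001, -2.0, -6.0),
    ])
    def test_values(self, p, z, expected):
        assert combined_score(p, z) == pytest.approx(expected, abs=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ParameterError):
            combined_score(0.0, 1.0)


class TestQueryDatabase:
    def test_concordant_profile_saturates(self, tiny_universe):
        sig = GeneSignature(up=frozenset({"A", "B"}),
                            down=frozenset({"I", "J"}))
        v = np.array([3, 2.5, 0, 0, 0, 0, 0, 0, -2.5, -3.0])
        db = SignatureDatabase(universe=tiny_universe,
                               profiles=[make_profile(tiny_universe, v)])
        res = query_database(db, sig, n_top=2, n_perm=199, seed=0)[0]
        assert res.score == 1.0
        assert res.p == pytest.approx(1 / 200)
        assert res.combined > 0

    def test_results_deterministic_and_order_independent(self, tiny_db):
        sig = GeneSignature(up=frozenset({"A", "B"}),
                            down=frozenset({"I", "J"}))
        r1 = query_database(tiny_db, sig, n_top=2, n_perm=99, seed=42)
        r2 = query_database(tiny_db, sig, n_top=2, n_perm=99, seed=42)
        assert [(r.score, r.p, r.zstat) for r in r1] == \
               [(r.score, r.p, r.zstat) for r in r2]

    def test_signature_outside_universe_errors(self, tiny_db):
        sig = GeneSignature(up=frozenset({"XX"}), down=frozenset({"YY"}))
        with pytest.raises(ParameterError):
            query_database(tiny_db, sig)

    def test_wks_method_runs_and_is_bounded(self, tiny_db):
        sig = GeneSignature(up=frozenset({"A", "B"}),
                            down=frozenset({"I", "J"}))
        res = query_database(tiny_db, sig, method="wks", n_perm=99, seed=1)
        assert all(-1 <= r.score <= 1 for r in res)
        assert all(0 < r.p <= 1 for r in res)


@given(st.integers(0, 3 ** 8 - 1), st.integers(0, 3 ** 8 - 1))
@settings(max_examples=200, deadline=None)
def test_signed_jaccard_bounded_everywhere(qcode, scode):
    """Property: the score is always within [-1, 1]."""
    genes = "ABCDEFGH"
    def decode(code):
        up, dn = set(), set()
        for g in genes:
            code, r = divmod(code, 3)
            if r == 1:
                up.add(g)
            elif r == 2:
                dn.add(g)
        return up, dn
    qu, qd = decode(qcode)
    su, sd = decode(scode)
    assert -1.0 <= signed_jaccard(qu, qd, su, sd) <= 1.0
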