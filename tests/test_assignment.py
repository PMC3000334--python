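import math

import numpy as np
import pytest

from barcodiag.assignment import (
    assign,
    candidate_matrices,
    diagnostic_sites_seqs,
    loo_validate,
    prob_segsites,
    segregating_sites_seqs,
    watterson_a,
)
from barcodiag.seqio import Library
from barcodiag.simulate import SimConfig, simulate_library

from conftest import make_record


def coalescent_segsites(n, theta, reps, rng):
    """Monte-Carlo oracle: S is a sum of independent geometric counts, one
    per coalescent level i (success prob (i-1)/(theta+i-1))."""
    total = np.zeros(reps, dtype=np.int64)
    for i in range(2, n + 1):
        p = (i - 1) / (theta + i - 1)
        total += rng.geometric(p, size=reps) - 1
    return total


class TestSegregatingSites:
    def test_identical_sequences_have_none(self):
        assert segregating_sites_seqs(["ACGT" * 3] * 3) == 0

    def test_pairwise_differences_counted(self):
        assert segregating_sites_seqs(["AAAACCCC", "AAGACCTT"]) == 3

    def test_ambiguity_ignored_within_column(self):
        # column {A, N, G} still segregates (A vs G); column {A, N, N} does not
        assert segregating_sites_seqs(["AA", "NN", "GN"]) == 1

    def test_gap_columns_do_not_segregate(self):
        assert segregating_sites_seqs(["A-C", "A-C", "AGC"]) == 0


class TestProbSegsites:
    def test_pair_sample_geometric_form(self):
        assert prob_segsites(2, 1.0, 0) == pytest.approx(0.5, abs=1e-12)
        assert prob_segsites(2, 2.0, 1) == pytest.approx((1 / 3) * (2 / 3), abs=1e-12)

    def test_zero_theta_point_mass(self):
        assert prob_segsites(5, 0.0, 0) == 1.0
        assert prob_segsites(5, 0.0, 3) == 0.0

    @pytest.mark.parametrize("n,theta", [(2, 1.0), (5, 2.0), (10, 10.0)])
    def test_normalization(self, n, theta):
        total = sum(prob_segsites(n, theta, k) for k in range(600))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_coalescent_simulation(self, rng):
        reps = 200_000
        for n, theta in [(2, 0.5), (5, 2.0), (10, 10.0)]:
            sim = coalescent_segsites(n, theta, reps, rng)
            for k in range(0, 15):
                p_hat = float(np.mean(sim == k))
                p = prob_segsites(n, theta, k)
                sigma = math.sqrt(max(p * (1 - p), 1e-12) / reps)
                assert abs(p_hat - p) <= 4 * sigma + 1e-9

    def test_expectation_is_watterson(self):
        # E[S] = theta * a_n under the infinite-sites coalescent
        n, theta = 6, 3.0
        mean = sum(k * prob_segsites(n, theta, k) for k in range(1000))
        assert mean == pytest.approx(theta * watterson_a(n), rel=1e-9)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            prob_segsites(1, 1.0, 0)
        with pytest.raises(ValueError):
            prob_segsites(3, -1.0, 0)
        with pytest.raises(ValueError):
            prob_segsites(3, 1.0, -1)


class TestWatterson:
    def test_harmonic_normalizer(self):
        assert watterson_a(2) == 1.0
        assert watterson_a(4) == pytest.approx(1 + 0.5 + 1 / 3)
        assert watterson_a(1) == 0.0

    def test_estimator_unbiased_on_simulated_samples(self, rng):
        n, theta, reps = 20, 5.0, 1000
        s = coalescent_segsites(n, theta, reps, rng)
        theta_hats = s / watterson_a(n)
        se = theta_hats.std(ddof=1) / math.sqrt(reps)
        assert abs(theta_hats.mean() - theta) <= 4 * se


def _query(seq, qid="q"):
    return make_record(qid, seq, "query")


class TestAssign:
    def test_query_identical_to_monomorphic_candidate(self):
        base_a = "ACGT" * 25
        base_b = "TGCA" * 25
        cands = {
            "A": [base_a, base_a, base_a],
            "B": [base_b, base_b, base_b],
        }
        res = assign(_query(base_a), cands)
        assert res.assigned == "A"
        assert res.posterior > 0.99
        tab = res.table.set_index("taxon")
        assert tab.loc["A", "S_prime"] == 0
        assert tab.loc["B", "S_prime"] == 100  # every site becomes segregating

    def test_symmetric_candidates_tie_broken_lexicographically(self):
        # candidates with identical n, S and S' relative to the query
        base = "A" * 100
        ca = ["GG" + "A" * 98, "GG" + "A" * 97 + "T"]
        cb = ["A" * 98 + "GG", "T" + "A" * 97 + "GG"]
        res = assign(_query(base), {"B": cb, "A": ca})
        tab = res.table.set_index("taxon")
        assert tab.loc["A", "posterior"] == pytest.approx(0.5)
        assert tab.loc["B", "posterior"] == pytest.approx(0.5)
        assert res.assigned == "A"
        assert res.tied_with == ["B"]

    def test_posteriors_sum_to_one_and_reorder_invariant(self):
        rng = np.random.default_rng(5)
        seqs = {}
        for lab in "ABC":
            base = "".join(rng.choice(list("ACGT"), size=80))
            seqs[lab] = [base, base[:-1] + "A"]
        q = _query(seqs["B"][0])
        r1 = assign(q, seqs)
        r2 = assign(q, dict(reversed(list(seqs.items()))))
        assert r1.table["posterior"].sum() == pytest.approx(1.0, abs=1e-9)
        assert r1.assigned == r2.assigned == "B"
        assert r1.posterior == pytest.approx(r2.posterior)

    def test_supporting_sequence_never_lowers_posterior(self):
        rng = np.random.default_rng(9)
        base_a = "".join(rng.choice(list("ACGT"), size=60))
        base_b = "".join(rng.choice(list("ACGT"), size=60))
        q = _query(base_a[:-2] + "GG")
        cands = {"A": [base_a, base_a[:-1] + "T"], "B": [base_b, base_b]}
        before = assign(q, cands).table.set_index("taxon").loc["A", "posterior"]
        cands["A"] = cands["A"] + [q.sequence]
        after = assign(q, cands).table.set_index("taxon").loc["A", "posterior"]
        assert after >= before - 1e-12

    def test_query_gaps_dropped_for_s_prime(self):
        base = "ACGT" * 10
        cands = {"A": [base, base], "B": ["TTTT" * 10, "TTTT" * 10]}
        # query matches A over covered columns, gap elsewhere
        q = _query(base[:20] + "-" * 20)
        res = assign(q, cands)
        assert res.assigned == "A"
        assert res.table.set_index("taxon").loc["A", "S_prime"] == 0

    def test_singleton_candidate_flagged(self):
        base_a = "ACGT" * 20
        base_b = "TGCA" * 20
        res = assign(_query(base_b), {"A": [base_a, base_a, base_a[:-1] + "T"],
                                      "B": [base_b]})
        assert res.assigned == "B"
        assert any("singleton" in f for f in res.flags)

    def test_fewer_than_two_candidates_rejected(self):
        with pytest.raises(ValueError):
            assign(_query("ACGT"), {"A": ["ACGT"]})


class TestLOO:
    def test_distinct_species_all_assigned(self):
        a, b = "ACGT" * 30, "TGCA" * 30
        recs = [make_record(f"a{i}", a, "spA") for i in range(3)]
        recs += [make_record(f"b{i}", b, "spB") for i in range(3)]
        df = loo_validate(Library(recs), "species", seed=0)
        assert df["correct"].all()
        assert set(df["taxon"]) == {"spA", "spB"}

    def test_same_seed_same_queries(self, small_library):
        lib, _ = small_library
        d1 = loo_validate(lib, "species", seed=11)
        d2 = loo_validate(lib, "species", seed=11)
        assert list(d1["query_id"]) == list(d2["query_id"])

    def test_species_level_recovery_on_synthetic(self, small_library):
        lib, _ = small_library
        df = loo_validate(lib, "species", seed=3)
        assert df["correct"].all()

    def test_subspecies_posteriors_lower_than_species(self):
        # two subspecies separated by ~ the intraspecific scale are harder
        # to tell apart than the species are
        cfg = SimConfig(
            n_species=4, members_per_species=6, seed=21,
            subspecies_spec={0: (["east", "west"], [3, 3], 0.004)},
        )
        lib, _ = simulate_library(cfg)
        sp = loo_validate(lib, "species", seed=5)
        ssp = loo_validate(lib, "subspecies", seed=5)
        assert len(ssp) == 2  # the two subspecies with >= 3 members
        assert ssp["posterior"].mean() < sp["posterior"].mean()


class TestDiagnosticSites:
    def test_fixed_difference_is_diagnostic(self):
        assert diagnostic_sites_seqs(["AAAA", "AAAA"], ["GAAA", "GAAA"]) == 1

    def test_polymorphic_taxon_column_is_not(self):
        assert diagnostic_sites_seqs(["AC", "GC"], ["TC"]) == 0  # col 0 polymorphic, col 1 shared
        assert diagnostic_sites_seqs(["AC", "AC"], ["TC"]) == 1  # col 0 fixed and absent in others

    def test_state_shared_with_others_is_not(self):
        assert diagnostic_sites_seqs(["AAAA"], ["AAAA", "GGGG"]) == 0

    def test_distinct_haplotypes_can_have_zero_diagnostics(self):
        # taxon polymorphic at every column where it differs from the rest:
        # distinct haplotypes yet no pure diagnostic site
        taxon = ["ACAA", "GCAA"]
        others = ["ATAA", "GTCA"]
        # col 0: taxon {A,G} polymorphic; col 1: taxon fixed C, absent in others -> diagnostic
        assert diagnostic_sites_seqs(taxon, others) == 1
        taxon2 = ["ACAA", "GTAA"]
        assert diagnostic_sites_seqs(taxon2, others) == 0
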