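"""Informative-PSV calling, conflict testing and greedy graph pruning."""

import numpy as np
import pytest

from lcrcall.aggregate import aggregate_posterior
from lcrcall.model import ParalogousSite, PSVRecord, reference_compatible
from lcrcall.psv import (
    build_conflict_graph,
    conflict_test,
    prune_conflicts,
    psv_paralog_posterior,
    psv_prior,
)

from .oracles import (
    oracle_binom_tail,
    oracle_max_weight_independent_set,
    oracle_psv_posterior,
)


def make_psv(refs=("T", "C"), freqs=(0.95, 0.9), pos=100):
    site = ParalogousSite(
        copy_positions=tuple(
            (f"copy{i}", f"ctg{i}", pos) for i in range(len(refs))
        ),
        ref_alleles=tuple(refs),
    )
    return PSVRecord(site=site, freqs=tuple(freqs))


class TestPsvPrior:
    def test_reference_compatible(self):
        g = (("T", "T"), ("C", "C"))
        assert psv_prior(g, ("T", "C"), (0.95, 0.9), (2, 2)) == pytest.approx(
            0.95**2 * 0.9**2, rel=1e-12
        )

    def test_one_nonreference_allele(self):
        g = (("C", "T"), ("C", "C"))
        assert psv_prior(g, ("T", "C"), (0.95, 0.9), (2, 2)) == pytest.approx(
            0.95 * 0.05 * 0.9**2, rel=1e-12
        )

    def test_degenerate_frequency_limit(self):
        ref_g = (("T", "T"), ("C", "C"))
        other = (("C", "T"), ("C", "C"))
        assert psv_prior(ref_g, ("T", "C"), (1.0, 1.0), (2, 2)) == 1.0
        assert psv_prior(other, ("T", "C"), (1.0, 1.0), (2, 2)) == 0.0


class TestPsvPosterior:
    def test_total_posterior_sums_to_one(self, params):
        psv = make_psv()
        agg = aggregate_posterior([28, 32], ["C", "T"], 4, params)
        call = psv_paralog_posterior(psv, agg, (2, 2), params)
        assert sum(call.posteriors) == pytest.approx(1.0, abs=1e-9)

    def test_reference_pattern_is_informative(self, params):
        psv = make_psv(freqs=(0.95, 0.95))
        agg = aggregate_posterior([30, 30], ["C", "T"], 4, params)
        call = psv_paralog_posterior(psv, agg, (2, 2), params)
        assert call.informative
        assert call.map_genotype == (("T", "T"), ("C", "C"))

    def test_skewed_pattern_is_not_informative(self, params):
        # nearly all reads carry the copy-0 allele: gene-conversion signal
        psv = make_psv(freqs=(0.95, 0.95))
        agg = aggregate_posterior([2, 58], ["C", "T"], 4, params)
        call = psv_paralog_posterior(psv, agg, (2, 2), params)
        assert not call.informative
        assert not reference_compatible(call.map_genotype, ("T", "C"))

    def test_matches_bruteforce_oracle(self, params, rng):
        worst = 0.0
        for _ in range(200):
            refs = tuple(rng.choice(["A", "C", "G", "T"], size=2, replace=False))
            freqs = tuple(rng.uniform(0.5, 0.99, size=2))
            pscn = tuple(int(x) for x in rng.integers(1, 4, size=2))
            depths = [int(x) for x in rng.integers(0, 30, size=2)]
            psv = make_psv(refs=refs, freqs=freqs)
            alleles = sorted(set(refs), key=lambda a: (len(a), a))
            agg = aggregate_posterior(depths, alleles, sum(pscn), params)
            call = psv_paralog_posterior(psv, agg, pscn, params)
            oracle = oracle_psv_posterior(
                depths, refs, freqs, pscn, params.mean_read_len, params.epsilon
            )
            for g, p in zip(call.genotypes, call.posteriors):
                ref_val = oracle[g]
                if ref_val > 1e-300:
                    worst = max(worst, abs(p - ref_val) / ref_val)
        assert worst < 1e-9


class TestConflictTest:
    def test_pi_formula(self):
        p, _ = conflict_test(10, 0, 0.01)
        assert p == 1.0  # zero discordant reads can never conflict
        # pi = 2 eps - eps^2 enters the tail: check against the oracle
        p5, conflict = conflict_test(10, 5, 0.01)
        assert conflict and p5 < 1e-3
        assert p5 == pytest.approx(oracle_binom_tail(5, 10, 0.0199), rel=1e-10)

    def test_below_min_coverage_no_test(self):
        p, conflict = conflict_test(2, 2, 0.01)
        assert p is None and not conflict

    def test_matches_exact_oracle(self, rng):
        worst = 0.0
        for _ in range(300):
            n = int(rng.integers(3, 40))
            k = int(rng.integers(0, n + 1))
            eps = float(rng.uniform(0.001, 0.1))
            p, _ = conflict_test(n, k, eps)
            pi = 2 * eps - eps * eps
            worst = max(worst, abs(p - oracle_binom_tail(k, n, pi)))
        assert worst < 1e-12


class TestPruneConflicts:
    def test_edgeless_graph_keeps_everything(self):
        g = build_conflict_graph([1, 2, 3], {1: 0.9, 2: 0.8, 3: 0.99}, [])
        assert prune_conflicts(g) == [1, 2, 3]

    def test_single_edge_removes_low_frequency_node(self):
        g = build_conflict_graph(
            [10, 20], {10: 0.99, 20: 0.50}, [(10, 20, 1e-5)]
        )
        assert prune_conflicts(g) == [10]

    def test_random_graphs_vs_exhaustive_optimum(self, rng):
        """Greedy output is always a valid independent set; the total weight
        is compared against the exhaustive optimum and the gap reported."""
        ratios = []
        for _ in range(120):
            n = int(rng.integers(2, 13))
            nodes = list(range(n))
            weights = {v: float(rng.uniform(0.3, 0.999)) for v in nodes}
            edges = [
                (u, v, 1e-4)
                for u in nodes
                for v in nodes
                if u < v and rng.random() < 0.25
            ]
            g = build_conflict_graph(nodes, weights, edges)
            kept = prune_conflicts(g)
            kept_set = set(kept)
            for u, v, _ in edges:  # validity: no conflict edge survives
                assert not (u in kept_set and v in kept_set)
            opt, _ = oracle_max_weight_independent_set(
                nodes, weights, [(u, v) for u, v, _ in edges]
            )
            got = sum(weights[v] for v in kept)
            assert got <= opt + 1e-9
            ratios.append(got / opt if opt > 0 else 1.0)
        # the greedy heuristic should stay close to optimal on average
        assert np.mean(ratios) > 0.9
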