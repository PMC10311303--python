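"""Read-pair location model, paralog posteriors and the strand-bias FET."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from lcrcall.aggregate import GenotypingParams, aggregate_posterior
from lcrcall.model import ParalogousSite, PSVRecord
from lcrcall.paralog import (
    ReadPairObservation,
    fisher_exact_two_sided,
    locate_read_pair,
    novel_variant_prior,
    ps_genotype_likelihood,
    ps_genotype_posterior,
    strand_bias_filter,
)

from .oracles import oracle_fisher_two_sided, oracle_read_posterior

PSVS = {
    "w1": ("T", "C"),
    "w2": ("G", "A"),
    "gapped": ("A", None),
}


def pair(allele, links=(), anchor=None, pid="p1", strand=True):
    return ReadPairObservation(
        pair_id=pid, allele=allele, strand=strand,
        psv_alleles=tuple(links), anchor_copy=anchor,
    )


class TestLocateReadPair:
    def test_prior_only(self):
        pr = locate_read_pair(pair("A"), PSVS, (2, 2), 0.01)
        assert np.allclose(pr, [0.5, 0.5])

    def test_single_matching_psv(self):
        pr = locate_read_pair(pair("A", [("w1", "T")]), PSVS, (2, 2), 0.01)
        assert pr[0] == pytest.approx(0.99, abs=1e-12)

    def test_two_concordant_psvs(self):
        pr = locate_read_pair(
            pair("A", [("w1", "T"), ("w2", "G")]), PSVS, (2, 2), 0.01
        )
        expected = 0.99**2 / (0.99**2 + 0.01**2)
        assert pr[0] == pytest.approx(expected, rel=1e-12)

    def test_copy_number_prior_weighting(self):
        pr = locate_read_pair(pair("A"), PSVS, (3, 1), 0.01)
        assert np.allclose(pr, [0.75, 0.25])

    def test_missing_copy_penalty(self):
        # PSV absent from copy 1: P(a | r) = eps^2 there
        pr = locate_read_pair(pair("A", [("gapped", "A")]), PSVS, (2, 2), 0.01)
        expected = 0.99 / (0.99 + 0.01**2)
        assert pr[0] == pytest.approx(expected, rel=1e-12)

    def test_anchor_concentrates_mass(self):
        pr = locate_read_pair(pair("A", anchor=1), PSVS, (2, 2), 0.01)
        assert pr[1] == pytest.approx(0.99, abs=1e-12)

    def test_zero_copy_number_everywhere_is_an_error(self):
        with pytest.raises(ValueError):
            locate_read_pair(pair("A"), PSVS, (0, 0), 0.01)


class TestPairLikelihood:
    def test_located_het_copy(self):
        lik = ps_genotype_likelihood(
            np.array([1.0, 0.0]), "G", (("A", "G"), ("A", "A")), (2, 2), 0.01
        )
        assert lik == pytest.approx(0.5, abs=1e-12)

    def test_emission_independent_of_split_when_monomorphic(self):
        g = (("A", "A"), ("A", "A"))
        for pr in ([0.5, 0.5], [0.9, 0.1], [0.0, 1.0]):
            assert ps_genotype_likelihood(
                np.array(pr), "A", g, (2, 2), 0.01
            ) == pytest.approx(0.99, abs=1e-12)

    def test_mirror_symmetry(self):
        pr = np.array([0.5, 0.5])
        l1 = ps_genotype_likelihood(pr, "G", (("A", "G"), ("A", "A")), (2, 2), 0.01)
        l2 = ps_genotype_likelihood(pr, "G", (("A", "A"), ("A", "G")), (2, 2), 0.01)
        assert l1 == pytest.approx(l2, rel=1e-12)


class TestNovelPrior:
    def test_reference_genotype(self):
        g = (("A", "A"), ("A", "A"))
        assert novel_variant_prior(g, "A", 1e-3) == pytest.approx(0.999**2, rel=1e-12)

    def test_single_nonreference_copy(self):
        g = (("A", "G"), ("A", "A"))
        assert novel_variant_prior(g, "A", 1e-3) == pytest.approx(
            0.999 * 0.001, rel=1e-12
        )

    def test_hom_and_het_penalised_equally(self):
        het = (("A", "G"), ("A", "A"))
        hom = (("G", "G"), ("A", "A"))
        assert novel_variant_prior(het, "A", 1e-3) == novel_variant_prior(
            hom, "A", 1e-3
        )

    def test_zero_mutation_rate_limit(self):
        ref = (("A", "A"), ("A", "A"))
        alt = (("A", "G"), ("A", "A"))
        assert novel_variant_prior(ref, "A", 0.0) == 1.0
        assert novel_variant_prior(alt, "A", 0.0) == 0.0


class TestReadSetPosterior:
    def _posterior(self, params, depths, reads, pscn=(2, 2), refs=("A", "A")):
        alleles = ["A", "G"]
        agg = aggregate_posterior(depths, alleles, sum(pscn), params)
        return ps_genotype_posterior(
            agg, reads, pscn, params, PSVS, refs, psv_record=None
        )

    def test_linked_reads_resolve_copy(self, params):
        # copy 0 shows half A / half G, copy 1 only A: het on copy 0
        reads = (
            [pair("G", [("w1", "T")], pid=f"g{i}") for i in range(6)]
            + [pair("A", [("w1", "T")], pid=f"ra{i}") for i in range(6)]
            + [pair("A", [("w1", "C")], pid=f"a{i}") for i in range(12)]
        )
        post = self._posterior(params, [18, 6], reads)
        assert post.resolved
        assert post.map_genotype == (("A", "G"), ("A", "A"))

    def test_unlinked_reads_leave_mirror_symmetry(self, params):
        reads = [pair("G", pid=f"g{i}") for i in range(8)] + [
            pair("A", pid=f"a{i}") for i in range(8)
        ]
        post = self._posterior(params, [16, 8], reads)
        assert not post.resolved
        p1 = post.prob((("A", "G"), ("A", "A")))
        p2 = post.prob((("A", "A"), ("A", "G")))
        assert abs(p1 - p2) < 1e-9

    def test_read_order_invariance(self, params, rng):
        reads = [
            pair("G", [("w1", "T")], pid="a"),
            pair("A", [("w2", "A")], pid="b"),
            pair("A", pid="c"),
            pair("G", [("w1", "C")], pid="d"),
        ]
        post1 = self._posterior(params, [12, 6], reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        post2 = self._posterior(params, [12, 6], shuffled)
        for g in post1.genotypes:
            assert post1.prob(g) == pytest.approx(post2.prob(g), abs=1e-12)

    def test_matches_bruteforce_oracle(self, params, rng):
        worst = 0.0
        for _ in range(150):
            pscn = tuple(int(x) for x in rng.integers(1, 3, size=2))
            depths = [int(x) for x in rng.integers(1, 15, size=2)]
            n_reads = int(rng.integers(1, 12))
            reads = []
            oracle_reads = []
            for i in range(n_reads):
                allele = str(rng.choice(["A", "G"]))
                links = []
                if rng.random() < 0.6:
                    psv_id = str(rng.choice(["w1", "w2"]))
                    obs = str(rng.choice([a for a in PSVS[psv_id] if a]))
                    links.append((psv_id, obs))
                anchor = int(rng.integers(0, 2)) if rng.random() < 0.2 else None
                reads.append(pair(allele, links, anchor=anchor, pid=f"r{i}"))
                oracle_reads.append((allele, links, anchor))
            agg = aggregate_posterior(depths, ["A", "G"], sum(pscn), params)
            post = ps_genotype_posterior(
                agg, reads, pscn, params, PSVS, ("A", "A"), psv_record=None
            )
            oracle = oracle_read_posterior(
                depths, ["A", "G"], pscn, oracle_reads, PSVS, ("A", "A"),
                params.mean_read_len, params.epsilon, params.xi,
                floor=params.agg_posterior_floor,
            )
            for g, p in zip(post.genotypes, post.posteriors):
                ref_val = oracle[g]
                if ref_val > 1e-300:
                    worst = max(worst, abs(p - ref_val) / ref_val)
        assert worst < 1e-9

    def test_empty_read_set_is_unresolved(self, params):
        post = self._posterior(params, [16, 8], [])
        assert not post.resolved
        assert post.posteriors.sum() == pytest.approx(1.0, abs=1e-9)


class TestStrandBias:
    def test_balanced_table_passes(self):
        p, ok = strand_bias_filter(10, 10, 10, 10)
        assert p == pytest.approx(1.0) and ok

    def test_perfect_separation_fails(self):
        p, ok = strand_bias_filter(20, 0, 0, 20)
        assert p < 1e-9 and not ok

    def test_empty_table_passes(self):
        p, ok = strand_bias_filter(0, 0, 0, 0)
        assert p == 1.0 and ok

    def test_matches_exact_enumeration_oracle(self, rng):
        worst = 0.0
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 21, size=4))
            p = fisher_exact_two_sided(a, b, c, d)
            worst = max(worst, abs(p - oracle_fisher_two_sided(a, b, c, d)))
        assert worst < 1e-12

    def test_agrees_with_scipy(self, rng):
        """Independent cross-check against scipy's implementation."""
        worst = 0.0
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 26, size=4))
            ours = fisher_exact_two_sided(a, b, c, d)
            theirs = fisher_exact([[a, b], [c, d]]).pvalue
            worst = max(worst, abs(ours - theirs))
        assert worst < 1e-9
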