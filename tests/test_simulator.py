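"""Simulator: determinism, calibration of rates, read/haplotype consistency."""

import numpy as np
import pytest

from lcrcall.simulate import (
    SimConfig,
    simulate_locus,
    simulate_reads,
    simulate_sample,
)


def small_cfg(**kw):
    base = dict(
        seed=7, copy_length=3000, flank=300, depth=20.0,
        fragment_mean=400.0, fragment_sd=40.0, variant_rate=3e-3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_objects(self):
        runs = []
        for _ in range(2):
            cfg = small_cfg()
            locus = simulate_locus(cfg)
            sample = simulate_sample(locus)
            reads = simulate_reads(sample)
            runs.append(
                (
                    locus.contig_seqs,
                    [(p.site.rep_position, p.freqs) for p in locus.psvs],
                    [(t.position, t.ref, t.per_copy) for t in sample.truth],
                    [(r.name, r.copy_index, r.start, r.cigar, r.seq) for r in reads],
                )
            )
        assert runs[0] == runs[1]


class TestLocus:
    def test_psv_count_tracks_similarity(self):
        counts = [
            len(simulate_locus(small_cfg(seed=s, similarity=0.995)).psvs)
            for s in range(40)
        ]
        expect = 3000 * 0.005
        assert abs(np.mean(counts) - expect) < 4 * np.sqrt(expect / 40)

    def test_zero_psv_density_gives_identical_copies(self):
        locus = simulate_locus(small_cfg(similarity=1.0))
        assert locus.psvs == []
        s, e = locus.core
        assert locus.contig_seqs[0][s:e] == locus.contig_seqs[1][s:e]

    def test_copies_differ_exactly_at_psv_columns(self):
        locus = simulate_locus(small_cfg())
        s, e = locus.core
        a, b = locus.contig_seqs[0][s:e], locus.contig_seqs[1][s:e]
        diff = {i + s for i in range(len(a)) if a[i] != b[i]}
        assert diff == set(locus.psv_positions().tolist())

    def test_incompatible_similarity_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, similarity=0.5)


class TestSample:
    def test_variant_type_mix_and_heterozygosity(self):
        subs = ins = dels = het = hom = 0
        for s in range(12):
            cfg = small_cfg(
                seed=100 + s, copy_length=20_000, variant_rate=5e-3,
                similarity=0.999,
            )
            locus = simulate_locus(cfg)
            sample = simulate_sample(locus)
            for t in sample.truth:
                if t.at_psv:
                    continue
                ref, alt = t.alleles[0], t.alleles[1]
                if len(ref) == len(alt):
                    subs += 1
                elif len(ref) < len(alt):
                    ins += 1
                else:
                    dels += 1
                carriers = sum(
                    1 for a in t.per_hap.values() if a != ref
                )
                het += carriers == 1
                hom += carriers == 2
        total = subs + ins + dels
        assert total > 800
        assert abs(subs / total - 0.80) < 0.05
        assert abs(ins / total - 0.10) < 0.04
        assert abs(dels / total - 0.10) < 0.04
        assert abs(het / (het + hom) - 0.615) < 0.05

    def test_polymorphic_psv_realisation_rate(self):
        # f = 0.7 on every copy: non-reference alleles at rate 0.3 per
        # copy-chromosome
        flips = draws = 0
        for s in range(30):
            cfg = small_cfg(
                seed=200 + s, psv_freq_mix=((1.0, 0.7, 0.7),), variant_rate=0.0
            )
            locus = simulate_locus(cfg)
            sample = simulate_sample(locus)
            by_pos = {t.position: t for t in sample.truth if t.at_psv}
            for psv in locus.psvs:
                refs = psv.site.ref_alleles
                t = by_pos.get(psv.site.rep_position)
                for i in range(2):
                    for h in range(2):
                        draws += 1
                        if t is not None and t.per_hap[(i, h)] != refs[i]:
                            flips += 1
        assert draws > 1500
        assert abs(flips / draws - 0.3) < 4 * np.sqrt(0.3 * 0.7 / draws)

    def test_zero_variant_rate_fixed_psvs_gives_empty_truth(self):
        cfg = small_cfg(variant_rate=0.0, fixed_psv_freq=0.999999)
        sample = simulate_sample(simulate_locus(cfg))
        assert sample.truth == []

    def test_truth_reconstructs_haplotypes(self):
        cfg = small_cfg()
        locus = simulate_locus(cfg)
        sample = simulate_sample(locus)
        for hap in sample.haplotypes:
            contig = locus.contig_seqs[hap.copy_index]
            variants = []
            for t in sample.truth:
                allele = t.per_hap.get((hap.copy_index, hap.hap_index))
                ref = (
                    t.copy_refs[hap.copy_index] if t.copy_refs else t.ref
                )
                if allele is not None and allele != ref:
                    variants.append((t.position, ref, allele))
            expected = []
            cursor = 0
            for pos, ref, alt in sorted(variants):
                expected.append(contig[cursor:pos])
                expected.append(alt)
                cursor = pos + len(ref)
            expected.append(contig[cursor:])
            assert "".join(expected) == hap.seq


class TestReads:
    def test_error_free_reads_match_haplotypes(self):
        cfg = small_cfg(error_rate=0.0)
        locus = simulate_locus(cfg)
        sample = simulate_sample(locus)
        seqs = {}
        for hap in sample.haplotypes:
            seqs[(hap.copy_index, hap.hap_index)] = hap.seq
        reads = simulate_reads(sample)
        assert reads
        for r in reads[:500]:
            _, tc, th, _ = r.name.split(":")
            assert r.seq in seqs[(int(tc), int(th))]

    def test_mean_depth_near_target(self):
        # coverage accounting over whole contigs: fragments cannot hang off
        # the ends, so per-base coverage integrates to the target exactly
        pooled = []
        for s in range(3):
            cfg = small_cfg(seed=300 + s, depth=30.0)
            locus = simulate_locus(cfg)
            sample = simulate_sample(locus)
            reads = simulate_reads(sample)
            length = len(locus.contig_seqs[0])
            cov = np.zeros(length)
            for r in reads:
                ref = r.start
                for op, ln in r.cigar:
                    if op == "M":
                        hi = min(ref + ln, length)
                        cov[ref:hi] += 1
                        ref += ln
                    elif op == "D":
                        ref += ln
            pooled.append(cov.mean())
        target = 30.0 / 2 * 4  # depth/2 per haplotype, four haplotypes
        assert abs(np.mean(pooled) - target) / target < 0.05

    def test_psv_free_pairs_assigned_uniformly(self):
        cfg = small_cfg(error_rate=0.0, similarity=0.999)
        locus = simulate_locus(cfg)
        sample = simulate_sample(locus)
        reads = simulate_reads(sample)
        psv_pos = set(locus.psv_positions().tolist())
        core_s, core_e = locus.core
        by_pair = {}
        for r in reads:
            by_pair.setdefault(r.name, []).append(r)
        mismap = total = 0
        for name, group in by_pair.items():
            covered = set()
            flank = False
            for r in group:
                ref = r.start
                if r.start < core_s:
                    flank = True
                for op, ln in r.cigar:
                    if op in ("M", "D"):
                        covered.update(range(ref, ref + ln))
                        ref += ln
                if ref > core_e:
                    flank = True
            if flank or covered & psv_pos:
                continue
            total += 1
            mismap += group[0].copy_index != int(name.split(":")[1])
        assert total > 100
        assert abs(mismap / total - 0.5) < 4 * np.sqrt(0.25 / total)

    def test_zero_depth_yields_no_reads(self):
        cfg = small_cfg(depth=0.0)
        sample = simulate_sample(simulate_locus(cfg))
        assert simulate_reads(sample) == []
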