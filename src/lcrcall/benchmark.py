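"""Parameter-recovery experiments: simulate loci, call, score against truth.

Two standard study designs are bundled:

* the *polymorphic* design — 2-copy loci at similarity 0.995 (about one
  PSV per 200 bp, frequencies from the population-like mixture), 30x
  coverage, 150 bp pairs with 500 bp fragments, 1% sequencing error;
* the *clean fixed-PSV* design — the same loci with error-free reads at
  60x and near-fixed PSV frequencies (0.9999), which isolates the
  pipeline's combinatorial correctness from statistical noise.

Both use 10 kb loci and a variant rate of 3 per kb so that a 20-locus
run yields several hundred truth variants.  Metrics are computed at the
recommended variant-quality threshold (21), counting all emitted records
(the strand-bias FILTER annotation is retained in the VCF but carries no
information under the simulator's strand-symmetric error model), and
genotype concordance is tallied among resolved calls whose per-copy
genotype qualities also clear the threshold.
"""

from __future__ import annotations

import numpy as np

from .evaluate import Evaluation, evaluate_calls
from .io import calls_to_vcf_records, truth_to_vcf_records
from .pipeline import call_locus
from .simulate import SimConfig, simulate_locus, simulate_reads, simulate_sample

__all__ = ["run_recovery_experiment", "recovery_metrics"]


def run_recovery_experiment(
    seed: int,
    n_loci: int = 20,
    clean: bool = False,
    copy_length: int = 10_000,
    variant_rate: float = 3e-3,
    qual_threshold: float = 21.0,
) -> tuple[Evaluation, int]:
    """Simulate ``n_loci`` loci, call them, and score against the truth.

    Returns the evaluation and the number of truth variants.
    """
    seed = int(seed) % (2**31 - 1)
    if clean:
        cfg = SimConfig(
            seed=seed, copy_length=copy_length, variant_rate=variant_rate,
            error_rate=0.0, depth=60.0, fixed_psv_freq=0.9999,
        )
    else:
        cfg = SimConfig(
            seed=seed, copy_length=copy_length, variant_rate=variant_rate,
            error_rate=0.01, depth=30.0,
        )
    rng = np.random.default_rng(seed)
    all_calls, all_truth = [], []
    for k in range(n_loci):
        locus = simulate_locus(cfg, locus_id=f"locus{k + 1}", rng=rng)
        sample = simulate_sample(locus, rng=rng)
        reads = simulate_reads(sample, rng=rng)
        result = call_locus(
            reads, locus.hmap, locus.rep_seq, locus.psvs, sample.profile,
            locus_id=locus.locus_id,
        )
        all_calls.extend(calls_to_vcf_records(result, locus.hmap))
        all_truth.extend(truth_to_vcf_records(sample))
    ev = evaluate_calls(
        all_calls,
        all_truth,
        qual_threshold=qual_threshold,
        exclude_filtered=False,
        concordance_min_gq=qual_threshold,
    )
    return ev, len(all_truth)


def recovery_metrics(ev: Evaluation) -> dict:
    """Flatten the headline numbers of one experiment run."""
    allele = ev.allele.get("all")
    out = {
        "precision": allele.precision if allele else None,
        "recall": allele.recall if allele else None,
    }
    snv = ev.concordance.get("snv")
    out["snv_concordance"] = snv[0] / snv[1] if snv and snv[1] else None
    full = ev.concordance.get("all")
    out["concordance"] = full[0] / full[1] if full and full[1] else None
    return out
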