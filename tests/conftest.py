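"""Shared simulated datasets.

The heavier end-to-end fixtures (simulate genomes -> reads -> competitive
assignment -> windowed profiles) are session-scoped so several tests can
reuse one run.  Genome sizes (100-200 kb) and 30x per-copy coverage keep the
statistical behaviour of the full-genome analysis while staying quick.
"""

from dataclasses import dataclass

import pytest

from hybripop.synthetic import (
    HybridPlan,
    Segment,
    simulate_hybrid_genome,
    simulate_parental_pair,
    simulate_reads,
)
from hybripop.hybrid import assign_reads, coverage_profile, infer_copy_number

DIVERGENCE = 0.02  # default parental divergence used across simulated runs


@dataclass
class HybridRun:
    pair: object
    plan: object
    truth: object
    reads: list
    assignment: object
    profile: object
    subprofile: object


def make_hybrid_run(length, segments, het_rate_a=0.0, het_rate_b=0.0,
                    coverage=30.0, seed=0, total_ploidy=None,
                    divergence=DIVERGENCE, error_rate=0.001) -> HybridRun:
    pair = simulate_parental_pair(length, divergence, seed=seed)
    plan = HybridPlan([Segment(*s) for s in segments],
                      het_rate_a=het_rate_a, het_rate_b=het_rate_b,
                      total_ploidy=total_ploidy)
    truth = simulate_hybrid_genome(pair, plan, seed=seed + 1)
    reads = simulate_reads(truth, coverage=coverage, error_rate=error_rate,
                           seed=seed + 2)
    assignment = assign_reads(reads, pair.seq_a, pair.seq_b)
    profile = coverage_profile(assignment, total_ploidy=plan.total_ploidy)
    subprofile = infer_copy_number(profile)
    return HybridRun(pair, plan, truth, reads, assignment, profile, subprofile)


@pytest.fixture(scope="session")
def allodiploid_run():
    """1A:1B hybrid, 200 kb, no LOH, moderate planted heterozygosity."""
    return make_hybrid_run(
        200_000, [(0, 200_000, 1, 1, False)], het_rate_a=2.0, seed=100)


@pytest.fixture(scope="session")
def allotriploid_run():
    """2A:1B hybrid, 200 kb, heterozygous-diploid A parent with an 80-kb LOH
    tract; haploid B subgenome carries only sporadic substitutions."""
    return make_hybrid_run(
        200_000,
        [(0, 60_000, 2, 1, False),
         (60_000, 140_000, 2, 1, True),
         (140_000, 200_000, 2, 1, False)],
        het_rate_a=5.0, het_rate_b=0.09, seed=200)


@pytest.fixture(scope="session")
def allotetraploid_run():
    """2A:2B hybrid, 200 kb, with a segment where A is lost and B is 4n."""
    return make_hybrid_run(
        200_000,
        [(0, 150_000, 2, 2, False), (150_000, 200_000, 0, 4, False)],
        het_rate_a=2.0, seed=300, total_ploidy=4)


@pytest.fixture(scope="session")
def triploid_a_run():
    """Three A copies (auto-triploid against reference A), het on one copy:
    the 1/3-2/3 allele-balance scenario."""
    return make_hybrid_run(
        100_000, [(0, 100_000, 3, 0, False)], het_rate_a=5.0, seed=400)
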