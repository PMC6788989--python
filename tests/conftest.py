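"""Shared fixtures: small simulated datasets, record converters, and the
random phasing-instance generator used by the phase/acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from phasecall.formats import Region, VcfRecord
from phasecall.phase import Fragment, HaplotypePair
from phasecall.pipeline import CallerConfig, call_variants
from phasecall.simulate import SimConfig, simulate_dataset


def truth_to_records(truth) -> list:
    return [
        VcfRecord(truth.chrom, v.pos, v.ref, v.alt, v.genotype, True)
        for v in truth.variants
    ]


def calls_to_records(calls, chrom: str) -> list:
    return [
        VcfRecord(chrom, c.pos, c.ref_allele, c.alt_allele, c.genotype, True,
                  gq=c.gq, depth=c.depth, phase_set=c.phase_set,
                  filters=frozenset(c.filters))
        for c in calls
    ]


def make_phasing_instance(rng: np.random.Generator, n_sites: int,
                          n_frags: int, span_max: int = 6,
                          qual_range=(10.0, 30.0)):
    """A random diploid phasing instance with known truth.

    Sites are het with probability 1/2, otherwise hom-ref or hom-alt; each
    fragment reads a contiguous run of sites from one haplotype with
    per-site allele errors matching its phred quality.
    """
    kinds = rng.choice(3, size=n_sites, p=[0.25, 0.5, 0.25])  # 00, het, 11
    h1 = np.where(kinds == 2, 1, 0).astype(np.int8)
    h2 = h1.copy()
    het = kinds == 1
    flip = rng.integers(0, 2, size=n_sites).astype(np.int8)
    h1[het] = flip[het]
    h2[het] = 1 - flip[het]
    truth = HaplotypePair(h1, h2)
    fragments = []
    for f in range(n_frags):
        span = int(rng.integers(2, min(span_max, n_sites) + 1))
        start = int(rng.integers(0, n_sites - span + 1))
        sites = np.arange(start, start + span)
        hap = truth.h1 if rng.random() < 0.5 else truth.h2
        quals = rng.uniform(*qual_range, size=span)
        errs = 10.0 ** (-quals / 10.0)
        alleles = hap[sites].copy()
        wrong = rng.random(span) < errs
        alleles[wrong] = 1 - alleles[wrong]
        fragments.append(Fragment(f"frag{f}", sites, alleles, quals))
    return fragments, truth


@pytest.fixture(scope="session")
def small_sim():
    """200 kb at 30x with the standard CLR error profile."""
    cfg = SimConfig(region_length=200_000, coverage=30.0, seed=3)
    ref, reads, truth = simulate_dataset(cfg)
    return cfg, ref, reads, truth


@pytest.fixture(scope="session")
def small_sim_result(small_sim):
    cfg, ref, reads, truth = small_sim
    region = Region(cfg.chrom, 0, len(ref))
    return call_variants(ref, reads, region, CallerConfig()), region


@pytest.fixture(scope="session")
def zero_error_sim():
    """60 kb at 20x with no sequencing errors at all."""
    cfg = SimConfig(region_length=60_000, coverage=20.0, seed=5,
                    ins_rate=0.0, del_rate=0.0, sub_rate=0.0)
    ref, reads, truth = simulate_dataset(cfg)
    return cfg, ref, reads, truth


@pytest.fixture(scope="session")
def read_sample_sim():
    """~600 reads for error-rate recovery checks (rates 0.11/0.04/0.01)."""
    cfg = SimConfig(region_length=500_000, coverage=9.0, seed=17)
    ref, reads, truth = simulate_dataset(cfg)
    return cfg, ref, reads, truth
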