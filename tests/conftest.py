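"""Shared fixtures: record builders and small harmonized-pair sets."""

from __future__ import annotations

import numpy as np
import pytest

from mrkit.harmonize import HarmonizedPair
from mrkit.records import SumStatRecord


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-9,
    chrom="1",
    pos=1000,
    eaf=0.3,
    n=10_000.0,
) -> SumStatRecord:
    return SumStatRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        chrom=chrom,
        pos=pos,
        eaf=eaf,
        n=n,
    )


def make_pair(beta_exp, beta_out, se_out, se_exp=0.01, variant_id="rs1") -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=variant_id,
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        action="kept",
    )


def random_pairs(rng: np.random.Generator, n: int) -> list[HarmonizedPair]:
    """A random harmonized-pair instance for oracle comparisons."""
    bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
    by = rng.normal(0.1 * bx, 0.02)
    sy = rng.uniform(0.005, 0.05, n)
    sx = rng.uniform(0.005, 0.02, n)
    return [
        make_pair(bx[i], by[i], sy[i], se_exp=sx[i], variant_id=f"rs{i}") for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240527)
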