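"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
binomial tails by direct summation with math.comb, Fisher p-values by
exhaustive hypergeometric enumeration, codon effects from a hard-coded
genetic code.
"""

from __future__ import annotations

import math

import pytest

from editome.core_model import GeneModel
from editome.synthetic_data import (
    GeneratorConfig,
    generate_editome,
    generate_reference,
    simulate_counts,
)

# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def binom_tail_oracle(C: int, L: int, eps: float) -> float:
    """P[X >= L], X ~ Binomial(C, eps), by direct summation."""
    return sum(
        math.comb(C, i) * eps**i * (1 - eps) ** (C - i) for i in range(L, C + 1)
    )


def nondetection_series_oracle(C: int, level: float, eps: float) -> float:
    """The printed zero-detection series, summed term by term."""
    return sum(
        math.comb(C, i)
        * level**i * (1 - level) ** (C - i)
        * eps**i * (1 - eps) ** (C - i)
        for i in range(C + 1)
    )


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        if k < 0 or k > row1 or col1 - k < 0 or col1 - k > c + d:
            return 0.0
        return (
            math.comb(row1, k) * math.comb(n - row1, col1 - k)
            / math.comb(n, col1)
        )

    p_obs = pmf(a)
    return sum(
        p for k in range(0, min(row1, col1) + 1)
        if (p := pmf(k)) <= p_obs * (1 + 1e-9)
    )


# hard-coded standard genetic code (independent of Biopython)
_GENETIC_CODE = {}
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_B = "TCAG"
for _i, (_x, _y, _z) in enumerate(
    (x, y, z) for x in _B for y in _B for z in _B
):
    _GENETIC_CODE[_x + _y + _z] = _AA[_i]

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def codon_effect_oracle(cds: str):
    """Per-position effect of A→G for every A in a CDS string.

    Returns {offset: category} with category in N/S/stop_retained/stop_lost.
    """
    out = {}
    for i, base in enumerate(cds):
        if base != "A":
            continue
        ci, within = divmod(i, 3)
        ref = cds[ci * 3: ci * 3 + 3]
        alt = ref[:within] + "G" + ref[within + 1:]
        ref_aa, alt_aa = _GENETIC_CODE[ref], _GENETIC_CODE[alt]
        if ref_aa == "*":
            out[i] = "stop_retained" if alt_aa == "*" else "stop_lost"
        else:
            out[i] = "S" if ref_aa == alt_aa else "N"
    return out


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_gene():
    """A + strand single-exon gene with CDS ATGAAATGA."""
    genome = {"c": "TTT" + "ATGAAATGA" + "TTT"}
    gene = GeneModel("gA", "c", "+", exons=[(3, 12)], cds=[(3, 12)])
    return genome, gene


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic small synthetic dataset shared across tests."""
    cfg = GeneratorConfig(n_genes=12, seed=11, mean_coverage=30,
                          editing_rate=0.015)
    genome, genes = generate_reference(cfg)
    truth = generate_editome(genome, genes, cfg)
    counts = simulate_counts(truth)
    return cfg, genome, genes, truth, counts
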