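"""Local nucleotide-context model around editing sites.

The ±3 nt transcript-strand flanks of the editing sites define a position
frequency matrix and, after normalization, a position probability matrix
(PPM; the central A carries no information and is excluded).  A 7-mer
N−3..N+3 centered on A scores

    score = Σ_i log2( P_i(N_i) / 0.25 ),

the log-odds against a uniform background.  The score cutoff retaining the
top 90% of editing sites, applied to all A-centered background 7-mers of the
same genes, yields a context-matched background for the N/S comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._stats import quantile_type1, ratio_or_inf

logger = logging.getLogger(__name__)

__all__ = ["PositionProbabilityMatrix", "build_ppm", "score_7mer",
           "extract_flank", "scan_background_and_ns"]

BASES = "ACGT"
POSITIONS = (-3, -2, -1, 1, 2, 3)
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PositionProbabilityMatrix:
    """Per-position base probabilities at offsets −3..−1, +1..+3.

    ``probs``: (6, 4) array over POSITIONS × ACGT, rows summing to 1.
    ``counts``: the underlying frequency matrix.
    """

    probs: np.ndarray
    counts: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        if self.probs.shape != (len(POSITIONS), 4):
            raise ValueError("PPM must be 6 positions x 4 bases")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PPM rows must sum to 1")

    def prob(self, position: int, base: str) -> float:
        return float(self.probs[POSITIONS.index(position), _BASE_IDX[base]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(POSITIONS), columns=list(BASES))


def build_ppm(
    flanks: list[str], pseudocount: float = 0.0, min_sites: int = 10
) -> PositionProbabilityMatrix:
    """PPM from 7-mers centered on the edited A.

    Probabilities are (count + pseudocount) / (total + 4·pseudocount) per
    position.  The default pseudocount of 0 keeps the direct frequencies; a
    base never seen at a position then scores −inf.
    """
    if len(flanks) < min_sites:
        raise ValueError(
            f"insufficient sites for a PPM ({len(flanks)} < {min_sites})"
        )
    counts = np.zeros((len(POSITIONS), 4))
    for mer in flanks:
        mer = mer.upper()
        if len(mer) != 7 or mer[3] != "A":
            raise ValueError(f"flank {mer!r} is not a 7-mer centered on A")
        for row, off in enumerate(POSITIONS):
            base = mer[3 + off]
            if base not in _BASE_IDX:
                raise ValueError(f"ambiguous base {base!r} in {mer!r}")
            counts[row, _BASE_IDX[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    return PositionProbabilityMatrix(probs, counts, pseudocount)


def score_7mer(mer: str, ppm: PositionProbabilityMatrix) -> float:
    """Σ_i log2(P_i(N_i)/0.25); −inf when a zero-probability base occurs."""
    mer = mer.upper()
    if len(mer) != 7:
        raise ValueError(f"{mer!r} is not a 7-mer")
    if mer[3] != "A":
        raise ValueError(f"central base of {mer!r} is not A")
    score = 0.0
    for row, off in enumerate(POSITIONS):
        base = mer[3 + off]
        if base not in _BASE_IDX:
            raise ValueError(f"ambiguous base {base!r} in {mer!r}")
        p = ppm.probs[row, _BASE_IDX[base]]
        if p == 0.0:
            return float("-inf")
        score += np.log2(p / 0.25)
    return float(score)


def extract_flank(transcript: str, index: int) -> str | None:
    """±3 nt 7-mer around position ``index`` of a transcript-strand sequence.

    None when the site is within 3 nt of a transcript end (dropped upstream
    with a warning).
    """
    if index < 3 or index > len(transcript) - 4:
        return None
    return transcript[index - 3: index + 4].upper()


def scan_background_and_ns(
    site_scores: pd.DataFrame,
    background_scores: pd.DataFrame,
    quantile: float = 0.90,
):
    """Context-conditioned N/S comparison above a PPM score cutoff.

    ``site_scores``: editing sites with columns ``score`` and ``category``;
    ``background_scores``: all A-centered background 7-mers with the same
    columns.  The cutoff is the (1 − quantile) type-1 quantile of the editing
    site scores, so ⌈quantile·n⌉ of n sites score at or above it (ties at
    the cutoff are included).

    Returns a dict with the cutoff, the fraction of background 7-mers above
    it, the observed and expected N/S ratios among above-cutoff sites and
    the two-sided Fisher p.
    """
    if background_scores.empty:
        raise ValueError("empty background")
    cutoff = quantile_type1(site_scores["score"].to_numpy(), 1.0 - quantile)
    kept_sites = site_scores[site_scores["score"] >= cutoff]
    kept_bg = background_scores[background_scores["score"] >= cutoff]
    obs_n = int((kept_sites["category"] == "N").sum())
    obs_s = int((kept_sites["category"] == "S").sum())
    bg_n = int((kept_bg["category"] == "N").sum())
    bg_s = int((kept_bg["category"] == "S").sum())
    fisher_p = (
        fisher_exact([[obs_n, obs_s], [bg_n, bg_s]])[1]
        if min(obs_n + obs_s, bg_n + bg_s) > 0 else float("nan")
    )
    return {
        "cutoff": cutoff,
        "n_sites_retained": len(kept_sites),
        "background_fraction_above": len(kept_bg) / len(background_scores),
        "observed_ns": ratio_or_inf(obs_n, obs_s),
        "expected_ns": ratio_or_inf(bg_n, bg_s),
        "fisher_p": float(fisher_p),
    }
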