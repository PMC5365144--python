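"""Selection test on the editome: observed vs neutral N/S ratio.

An A→G edit at a CDS adenosine either changes the encoded amino acid (N) or
not (S).  If editing targets were placed neutrally, the N/S ratio among
edited sites would match the N/S ratio over *all* CDS adenosines of the same
genes (the neutral background).  An observed ratio above the background
indicates that nonsynonymous recoding is enriched beyond chance; the excess
is summarized by the adaptive fraction

    α = 1 − (N/S)_expected / (N/S)_observed,

the estimated proportion of N sites favored by selection.  Uncertainty comes
from a label bootstrap: the N+S site labels are resampled with replacement
and the ratio and α recomputed per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._stats import quantile_type1, ratio_or_inf
from .core_model import GeneModel, iter_cds_adenosines

logger = logging.getLogger(__name__)

__all__ = [
    "NeutralBackground", "SelectionResult", "DegenerateBackgroundError",
    "neutral_ns_expectation", "observed_ns_test", "ns_counts",
    "classify_pseb", "stratified_ns", "ns_by_level_cutoff",
    "expression_split", "adjusted_ns_comparison",
]


class DegenerateBackgroundError(ValueError):
    pass


@dataclass(frozen=True)
class NeutralBackground:
    """Counts of background CDS adenosines by effect of a hypothetical edit."""

    background_n: int
    background_s: int
    scope: str = "all edited genes"

    def __post_init__(self):
        if self.background_n <= 0 or self.background_s <= 0:
            raise DegenerateBackgroundError(
                f"degenerate background N={self.background_n} S={self.background_s}"
            )

    @property
    def expected_ratio(self) -> float:
        return self.background_n / self.background_s


@dataclass(frozen=True)
class SelectionResult:
    observed_n: int
    observed_s: int
    observed_ratio: float          # +inf when observed_s == 0
    expected_ratio: float
    fisher_p: float
    alpha: float
    ratio_ci: tuple[float, float] | None
    alpha_ci: tuple[float, float] | None
    degenerate: bool = False       # observed_s == 0: ratio unbounded, no CI


def neutral_ns_expectation(
    genes: list[GeneModel],
    genome: dict[str, str],
    conserved_adenosine_filter: set | None = None,
    scope: str | None = None,
) -> NeutralBackground:
    """Neutral N/S expectation from every CDS adenosine of the given genes.

    ``genes`` should already be restricted to genes carrying at least one
    editing event.  With a conserved-adenosine filter, only positions in the
    filter are tallied (the cross-species background).  Stop-codon positions
    (stop_retained / stop_lost) never enter the tallies.
    """
    n = s = 0
    for gene in genes:
        if not gene.is_coding:
            continue
        for pos, effect in iter_cds_adenosines(gene, genome):
            if (
                conserved_adenosine_filter is not None
                and (gene.chromosome, pos) not in conserved_adenosine_filter
            ):
                continue
            if effect.category == "N":
                n += 1
            elif effect.category == "S":
                s += 1
    label = scope or (
        "conserved adenosines" if conserved_adenosine_filter is not None
        else "all edited genes"
    )
    return NeutralBackground(n, s, scope=label)


def ns_counts(sites: pd.DataFrame, category_col: str = "effect") -> tuple[int, int]:
    """(N, S) counts from a site table's effect category column."""
    cats = sites[category_col]
    return int((cats == "N").sum()), int((cats == "S").sum())


def _bootstrap(observed_n, observed_s, expected, n_boot, rng):
    n_total = observed_n + observed_s
    k = rng.binomial(n_total, observed_n / n_total, size=n_boot)
    ratios = ratio_or_inf(k, n_total - k)
    with np.errstate(divide="ignore"):
        # expected/inf -> 0 so alpha -> 1; a zero ratio gives alpha -> -inf
        alphas = 1.0 - expected / ratios
    ratio_ci = (quantile_type1(ratios, 0.025), quantile_type1(ratios, 0.975))
    alpha_ci = (quantile_type1(alphas, 0.025), quantile_type1(alphas, 0.975))
    return ratio_ci, alpha_ci


def observed_ns_test(
    observed_n: int,
    observed_s: int,
    background: NeutralBackground,
    n_boot: int = 1000,
    seed: int | None = None,
) -> SelectionResult:
    """Selection test of observed (N, S) against a neutral background.

    The Fisher exact test is two-sided on the 2×2 table
    [[observed_N, observed_S], [background_N, background_S]].  The bootstrap
    resamples the N+S site labels with replacement ``n_boot`` times; ratio
    and α intervals are the 2.5%/97.5% type-1 quantiles of the replicate
    values, with zero-S replicates contributing +inf ratios that sort above
    all finite values.
    """
    expected = background.expected_ratio
    _, fisher_p = fisher_exact(
        [[observed_n, observed_s], [background.background_n, background.background_s]],
        alternative="two-sided",
    )
    if observed_s == 0:
        return SelectionResult(
            observed_n, observed_s, float("inf"), expected, float(fisher_p),
            alpha=1.0, ratio_ci=None, alpha_ci=None, degenerate=True,
        )
    observed_ratio = observed_n / observed_s
    alpha = 1.0 - expected / observed_ratio if observed_n else float("-inf")
    rng = np.random.default_rng(seed)
    ratio_ci, alpha_ci = _bootstrap(observed_n, observed_s, expected, n_boot, rng)
    return SelectionResult(
        observed_n, observed_s, observed_ratio, expected, float(fisher_p),
        alpha, ratio_ci, alpha_ci,
    )


def classify_pseb(
    gene_site_effects: pd.DataFrame,
    background: NeutralBackground,
    ratio_threshold: float = 5.0,
    n_boot: int = 1000,
    seed: int | None = None,
):
    """Split edited genes into PSEB and non-PSEB by per-gene editing N/S > 5.

    ``gene_site_effects`` needs one row per high-confidence CDS editing site
    with columns ``gene_id`` and ``category`` (N or S).  A gene with N ≥ 1
    and S = 0 has an unbounded ratio and qualifies.  Genes without CDS
    editing sites are absent from the input and therefore unclassified.

    Returns ``(pseb_genes, pooled_pseb_result, pooled_non_pseb_result)``.
    """
    df = gene_site_effects[gene_site_effects["category"].isin(["N", "S"])]
    per_gene = (
        df.assign(is_n=df["category"] == "N")
        .groupby("gene_id")["is_n"]
        .agg(n="sum", total="count")
    )
    per_gene["s"] = per_gene["total"] - per_gene["n"]
    ratio = ratio_or_inf(per_gene["n"].to_numpy(), per_gene["s"].to_numpy())
    pseb = set(per_gene.index[ratio > ratio_threshold])

    def _pooled(gene_set, offset):
        sub = df[df["gene_id"].isin(gene_set)]
        n, s = int((sub["category"] == "N").sum()), int((sub["category"] == "S").sum())
        local_seed = None if seed is None else seed + offset
        return observed_ns_test(n, s, background, n_boot=n_boot, seed=local_seed)

    non_pseb = set(per_gene.index) - pseb
    return sorted(pseb), _pooled(pseb, 0), _pooled(non_pseb, 1)


def stratified_ns(
    categories: pd.Series,
    strata: pd.Series,
    backgrounds: NeutralBackground | dict,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, SelectionResult]:
    """One selection test per stratum (X vs autosome, expression halves, ...).

    ``backgrounds`` is either one shared background or a mapping
    stratum → stratum-matched background.  Strata with no N+S sites are
    omitted with a warning; strata with S = 0 come back flagged degenerate.
    """
    results = {}
    for i, stratum in enumerate(sorted(pd.unique(strata.dropna()))):
        cats = categories[strata == stratum]
        n, s = int((cats == "N").sum()), int((cats == "S").sum())
        if n + s == 0:
            logger.warning("stratum %r has no N or S sites; omitted", stratum)
            continue
        bg = backgrounds[stratum] if isinstance(backgrounds, dict) else backgrounds
        local_seed = None if seed is None else seed + i
        results[stratum] = observed_ns_test(n, s, bg, n_boot=n_boot, seed=local_seed)
    return results


def ns_by_level_cutoff(
    sites: pd.DataFrame,
    background: NeutralBackground,
    cutoffs=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    level_col: str = "mean_level",
    category_col: str = "effect",
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed N/S ratio over the sites with editing level ≥ each cutoff."""
    rows = []
    for i, cutoff in enumerate(cutoffs):
        sub = sites[sites[level_col] >= cutoff]
        n, s = ns_counts(sub, category_col)
        if n + s == 0:
            logger.warning("level cutoff %.2f leaves no N or S sites; omitted", cutoff)
            continue
        res = observed_ns_test(
            n, s, background, n_boot=n_boot,
            seed=None if seed is None else seed + i,
        )
        rows.append({
            "cutoff": cutoff, "N": n, "S": s,
            "ratio": res.observed_ratio, "alpha": res.alpha,
            "fisher_p": res.fisher_p,
        })
    return pd.DataFrame(rows)


def expression_split(gene_rpkm: pd.Series) -> pd.Series:
    """Label genes 'Highly'/'Lowly' by the median of rank-ordered RPKM."""
    ranks = gene_rpkm.rank(method="first")
    return pd.Series(
        np.where(ranks > ranks.median(), "Highly", "Lowly"), index=gene_rpkm.index
    )


def adjusted_ns_comparison(
    n1: int, s1: int, expected1: float,
    n2: int, s2: int, expected2: float,
) -> float:
    """Fisher p for (N,S) of group 1 vs group 2 with unequal neutral backgrounds.

    The second group's S margin is rescaled by expected1/expected2 (rounded)
    so the two groups are compared against a common neutral yardstick; a
    stated convention for contrasts such as fixed vs polymorphic sites.
    """
    s2_adj = max(1, round(s2 * expected1 / expected2)) if s2 else 0
    _, p = fisher_exact([[n1, s1], [n2, s2_adj]], alternative="two-sided")
    return float(p)
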