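"""Covariate associations of editing density, structure enrichment,
library clustering and temperature-shift analyses.

Editing density in a set of background adenosines is the fraction that carry
editing events (optionally weighting each edited site by its level).  The
density is examined across rank bins of a covariate (expression, coverage,
transcript position, dN, phyloP), in paired 5'/3' half-gene contrasts, and
in conservation-matched coverage bins.  A permutation test measures
enrichment of editing sites in precomputed hairpin intervals, and libraries
are clustered by the Pearson correlation of their editing-level profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr, ttest_rel

from ._stats import empirical_p, quantile_type1

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedDensitySpec", "binned_density_correlation", "halfgene_paired_test",
    "matched_conservation_contrast", "structure_enrichment_test",
    "cluster_libraries", "temperature_shift_analysis", "rank_bins",
]


@dataclass(frozen=True)
class BinnedDensitySpec:
    covariate: str
    n_bins: int = 20
    weighting: str = "count"        # or "level_weighted"
    per_million: bool = False


def rank_bins(values: pd.Series, n_bins: int, tiebreak: pd.Series | None = None):
    """Equal-sized rank bins (0..n_bins−1) with deterministic tie-breaking.

    Ties are broken by the ``tiebreak`` key (typically genomic coordinate)
    and then input order, so binning is reproducible.
    """
    df = pd.DataFrame({"v": values.to_numpy()})
    if tiebreak is not None:
        df["t"] = tiebreak.to_numpy()
        order = np.lexsort((np.arange(len(df)), df["t"].to_numpy(), df["v"].to_numpy()))
    else:
        order = np.lexsort((np.arange(len(df)), df["v"].to_numpy()))
    bins = np.empty(len(df), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return pd.Series(bins, index=values.index)


def binned_density_correlation(
    background: pd.DataFrame,
    spec: BinnedDensitySpec | None = None,
    edited_col: str = "edited",
    level_col: str = "level",
    tiebreak_cols=("chrom", "pos"),
) -> dict:
    """Editing density per covariate bin and its Spearman trend.

    ``background`` has one row per background adenosine with the covariate
    column named by ``spec.covariate``, a boolean ``edited`` column and
    (for level weighting) a ``level`` column.  Density per bin is
    edited/total (or Σ level / total).  Returns per-bin table plus
    (rho, p) of density against bin index; a rho of 0 with ``tied=True`` is
    reported when the densities are all equal.
    """
    spec = spec or BinnedDensitySpec(covariate="covariate")
    tiebreak = None
    if all(c in background.columns for c in tiebreak_cols):
        tiebreak = background[list(tiebreak_cols)].apply(tuple, axis=1)
    bins = rank_bins(background[spec.covariate], spec.n_bins, tiebreak)
    rows = []
    for b in range(spec.n_bins):
        sub = background[bins == b]
        if sub.empty:
            logger.warning("bin %d empty; dropped", b)
            continue
        if spec.weighting == "level_weighted":
            numer = sub.loc[sub[edited_col], level_col].sum()
        else:
            numer = int(sub[edited_col].sum())
        density = numer / len(sub)
        rows.append({
            "bin": b,
            "covariate_median": float(sub[spec.covariate].median()),
            "n_adenosines": len(sub),
            "n_edited": int(sub[edited_col].sum()),
            "density": density,
            "density_per_million": density * 1e6,
        })
    table = pd.DataFrame(rows)
    dens = table["density"].to_numpy()
    if np.ptp(dens) == 0:
        rho, p, tied = 0.0, 1.0, True
    else:
        rho, p = spearmanr(table["bin"], dens)
        ranks = pd.Series(dens).rank()
        tied = (ranks.duplicated().sum() / len(ranks)) > 0.2
    return {"table": table, "rho": float(rho), "p": float(p), "tied": bool(tied)}


def halfgene_paired_test(half_densities: pd.DataFrame, min_bins: int = 3) -> dict:
    """Paired t-test of 5' (front) vs 3' (rear) editing densities across bins.

    ``half_densities``: per-bin frame with columns ``front`` and ``rear``
    (densities of the two gene halves in that bin); bins with a missing half
    are dropped with a log message.
    """
    df = half_densities.dropna(subset=["front", "rear"])
    n_dropped = len(half_densities) - len(df)
    if n_dropped:
        logger.info("dropped %d bins with an empty half", n_dropped)
    if len(df) < min_bins:
        raise ValueError(f"only {len(df)} usable bins (< {min_bins})")
    if np.allclose(df["front"], df["rear"]):
        t, p = 0.0, 1.0
    else:
        t, p = ttest_rel(df["rear"], df["front"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(df["front"] > 0, df["rear"] / df["front"], np.inf)
    return {
        "t": float(t), "p": float(p), "n_bins": len(df),
        "rear_front_ratio": pd.Series(ratio, index=df.index),
    }


def matched_conservation_contrast(
    background: pd.DataFrame,
    n_bins: int = 20,
    coverage_col: str = "coverage",
    conservation_col: str = "phylop",
    edited_col: str = "edited",
) -> dict:
    """Density of non-conserved relative to conserved sites at matched coverage.

    Background adenosines are rank-binned by coverage; within each bin a
    median split on the conservation score defines conserved / non-conserved
    halves whose densities are compared by a paired t-test across bins.
    """
    tiebreak = None
    if {"chrom", "pos"} <= set(background.columns):
        tiebreak = background[["chrom", "pos"]].apply(tuple, axis=1)
    bins = rank_bins(background[coverage_col], n_bins, tiebreak)
    rows = []
    for b in range(n_bins):
        sub = background[bins == b]
        if sub.empty:
            continue
        split = sub[conservation_col].median()
        conserved = sub[sub[conservation_col] >= split]
        nonconserved = sub[sub[conservation_col] < split]
        if conserved.empty or nonconserved.empty:
            logger.info("bin %d has an empty conservation half; dropped", b)
            continue
        d_cons = conserved[edited_col].mean()
        d_non = nonconserved[edited_col].mean()
        rows.append({
            "bin": b, "density_conserved": d_cons, "density_nonconserved": d_non,
            "ratio": d_non / d_cons if d_cons > 0 else np.nan,
        })
    table = pd.DataFrame(rows).dropna(subset=["density_conserved"])
    if np.allclose(table["density_nonconserved"], table["density_conserved"]):
        t, p = 0.0, 1.0
    else:
        t, p = ttest_rel(table["density_nonconserved"], table["density_conserved"])
    return {"table": table, "t": float(t), "p": float(p)}


def structure_enrichment_test(
    site_positions,
    hairpin_intervals: pd.DataFrame,
    background_positions,
    n_replicates: int = 1000,
    seed: int | None = None,
) -> dict:
    """Permutation enrichment of editing sites inside hairpin intervals.

    Each replicate samples |sites| positions with replacement from the
    background adenosines and counts hairpin overlaps; the empirical p for
    enrichment is the (r+1)/(n+1)-smoothed fraction of replicates with at
    least the observed count.  ``hairpin_intervals`` has BED-style columns
    chrom, start, end (0-based half-open).
    """
    rng = np.random.default_rng(seed)
    sites = list(site_positions)
    background = list(background_positions)
    in_hairpin = _interval_membership(hairpin_intervals)
    observed = sum(in_hairpin(c, p) for c, p in sites)
    bg_flags = np.array([in_hairpin(c, p) for c, p in background])
    idx = rng.integers(0, len(background), size=(n_replicates, len(sites)))
    null_counts = bg_flags[idx].sum(axis=1)
    return {
        "observed": int(observed),
        "null_median": float(quantile_type1(null_counts, 0.5)),
        "null_ci": (
            float(quantile_type1(null_counts, 0.025)),
            float(quantile_type1(null_counts, 0.975)),
        ),
        "p": empirical_p(int((null_counts >= observed).sum()), n_replicates),
    }


def _interval_membership(intervals: pd.DataFrame):
    by_chrom = {}
    for chrom, sub in intervals.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())

    def member(chrom, pos):
        if chrom not in by_chrom:
            return False
        starts, ends = by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        return bool(i >= 0 and pos < ends[i])

    return member


def cluster_libraries(level_matrix: pd.DataFrame) -> dict:
    """Hierarchical clustering of libraries by editing-level correlation.

    ``level_matrix``: complete site-by-library frame of editing levels
    (already restricted to sites covered in every library).  Distance is
    1 − Pearson r with average linkage; the dendrogram is returned in
    newick format.
    """
    if level_matrix.shape[1] < 2:
        raise ValueError("need at least two libraries")
    if level_matrix.shape[0] < 2:
        raise ValueError("need at least two sites")
    if level_matrix.isna().any().any():
        raise ValueError("level matrix contains missing values")
    corr = level_matrix.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    linkage = hierarchy.average(squareform(dist, checks=False))
    tree = hierarchy.to_tree(linkage)
    labels = list(level_matrix.columns)

    def newick(node):
        if node.is_leaf():
            return f"{labels[node.id]}:{node.dist:.6f}"
        left, right = newick(node.get_left()), newick(node.get_right())
        return f"({left},{right}):{node.dist:.6f}"

    return {
        "correlation": corr,
        "linkage": linkage,
        "newick": f"({newick(tree.get_left())},{newick(tree.get_right())});",
    }


def temperature_shift_analysis(
    shifts: pd.DataFrame,
    expression_lfc: pd.Series | None = None,
    other_species_shifts: pd.Series | None = None,
    rpkm: pd.Series | None = None,
    rpkm_cutoffs=(1, 3, 5, 10),
) -> dict:
    """Editing-level changes under a temperature shift, by functional category.

    ``shifts``: per-site frame with columns ``delta`` (level at the elevated
    temperature minus the control level), ``category`` and optionally
    ``gene_id``.  Optional inputs add the cross-species correlation of
    shifts (index-aligned per-site series from the second species) and the
    correlation of N-site shifts with host-gene expression log-fold-changes
    under the RPKM cutoff grid.
    """
    if shifts.empty:
        raise ValueError("no shared sites between conditions")
    silent = {"S", "UTR5", "UTR3", "intron"}
    groups = shifts.assign(
        group=np.where(shifts["category"] == "N", "N", "silent")
    )[lambda d: d["category"].isin(silent | {"N"})]
    summary = groups.groupby("group")["delta"].agg(
        mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count"
    )
    out = {"category_summary": summary}

    if other_species_shifts is not None:
        shared = shifts.join(other_species_shifts.rename("other"), how="inner")
        shared = shared.dropna(subset=["delta", "other"])
        if len(shared) >= 3 and np.ptp(shared["delta"]) > 0 and np.ptp(shared["other"]) > 0:
            r, p = pearsonr(shared["delta"], shared["other"])
            out["cross_species"] = {"r": float(r), "p": float(p), "n": len(shared)}
        else:
            out["cross_species"] = None

    if expression_lfc is not None and "gene_id" in shifts.columns:
        rows = []
        n_sites = shifts[shifts["category"] == "N"].copy()
        n_sites["lfc"] = n_sites["gene_id"].map(expression_lfc)
        for cutoff in rpkm_cutoffs:
            sub = n_sites.dropna(subset=["lfc"])
            if rpkm is not None:
                expressed = set(rpkm[rpkm >= cutoff].index)
                sub = sub[sub["gene_id"].isin(expressed)]
            if len(sub) < 3 or np.ptp(sub["delta"]) == 0 or np.ptp(sub["lfc"]) == 0:
                rows.append({"rpkm_cutoff": cutoff, "r": np.nan, "p": np.nan,
                             "n": len(sub)})
                continue
            r, p = pearsonr(sub["delta"], sub["lfc"])
            rows.append({"rpkm_cutoff": cutoff, "r": float(r), "p": float(p),
                         "n": len(sub)})
        out["expression_correlation"] = pd.DataFrame(rows)
    return out
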