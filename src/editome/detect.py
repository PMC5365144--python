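"""Editing-site detection from multi-library allele counts.

The statistical core: under the null, every A→G read at a site is a
sequencing error at the A→G-specific rate ε, so the per-library evidence is
the upper binomial tail P_k(E0) = P[X ≥ L_k], X ~ Binomial(C_k, ε).  Evidence
is combined multiplicatively across libraries, P(E0) = Π_k P_k(E0), giving
the joint probability P(E1) = 1 − P(E0) that the site is edited in at least
one library; the joint null probabilities are BH-adjusted across candidate
sites.  Sites are then placed in five exclusive confidence classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorModel", "DetectionConfig", "NotExpressedError",
    "per_library_error_prob", "joint_editing_prob", "fdr_adjust",
    "per_library_highconf_filter", "classify_sites", "library_summary",
    "estimate_fpr", "cluster_sites",
]


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing-error model: a platform error rate scaled to the A→G class.

    A platform error rate ε0 is spread over three possible miscalled bases;
    conditioning on sites whose mismatches are exclusively A→G rescales it to
    ε = (ε0/3) / (1 − (2/3)·ε0) ≈ 0.00167 at the default ε0 = 0.5%.
    """

    epsilon0: float = 0.005

    @property
    def scaled(self) -> float:
        return (self.epsilon0 / 3) / (1 - (2 / 3) * self.epsilon0)


@dataclass(frozen=True)
class ClassThresholds:
    fdr: float
    c_max_min: int
    c_total_min: int
    min_libraries: int = 2


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for the five-class assignment and the per-library filter."""

    class1: ClassThresholds = field(
        default_factory=lambda: ClassThresholds(fdr=0.001, c_max_min=10, c_total_min=40)
    )
    class2: ClassThresholds = field(
        default_factory=lambda: ClassThresholds(fdr=0.01, c_max_min=5, c_total_min=16)
    )
    class3_p_e1: float = 0.99
    # per-library high-confidence filter
    min_level: float = 0.01
    min_coverage: int = 5
    min_edited: int = 2
    max_p_e0: float = 1e-4
    error_model: ErrorModel = field(default_factory=ErrorModel)


class NotExpressedError(ValueError):
    """Raised when a site has zero coverage in every library."""


def per_library_error_prob(coverage, edited, epsilon: float):
    """P_k(E0): upper binomial tail P[X ≥ L_k] with X ~ Binomial(C_k, ε).

    Vectorized over coverage/edited.  Zero coverage gives 1 (no evidence).
    """
    C = np.asarray(coverage)
    L = np.asarray(edited)
    if np.any(L > C) or np.any(L < 0):
        raise ValueError("edited count outside [0, coverage]")
    out = binom.sf(L - 1, np.maximum(C, 1), epsilon)
    out = np.where(C == 0, 1.0, out)
    return float(out) if out.ndim == 0 else out


def _log_p_e0(coverage, edited, epsilon: float):
    C = np.asarray(coverage)
    L = np.asarray(edited)
    out = binom.logsf(L - 1, np.maximum(C, 1), epsilon)
    return np.where(C == 0, 0.0, out)


def joint_editing_prob(coverage, edited, epsilon: float) -> tuple[float, float]:
    """Joint (P(E0), P(E1)) for one site across libraries.

    Libraries with zero coverage contribute a factor of 1; if no library
    covers the site it is not expressed and no probability is defined.
    """
    C = np.asarray(coverage)
    if C.size == 0 or not np.any(C > 0):
        raise NotExpressedError("site has no covered library")
    log_p0 = _log_p_e0(C, edited, epsilon).sum()
    return float(np.exp(log_p0)), float(-np.expm1(log_p0))


def fdr_adjust(p_values, keys=None) -> np.ndarray:
    """Benjamini–Hochberg q-values (monotone step-up).

    ``keys`` (e.g. genomic coordinates) break ordering ties deterministically;
    BH q-values themselves are invariant to tie order, so this only pins the
    internal sort.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if keys is not None:
        order = sorted(range(p.size), key=lambda i: (p[i], keys[i]))
        order = np.asarray(order)
        q = np.empty_like(p)
        q[order] = multipletests(p[order], method="fdr_bh")[1]
        return q
    return multipletests(p, method="fdr_bh")[1]


def per_library_highconf_filter(
    coverage, edited, config: DetectionConfig | None = None
):
    """Per-library detection: level > 0.01, C ≥ 5, L ≥ 2 and P_k(E0) < 1e-4."""
    cfg = config or DetectionConfig()
    C = np.asarray(coverage, dtype=float)
    L = np.asarray(edited, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(C > 0, L / np.maximum(C, 1), np.nan)
    p0 = per_library_error_prob(coverage, edited, cfg.error_model.scaled)
    ok = (
        (level > cfg.min_level)
        & (C >= cfg.min_coverage)
        & (L >= cfg.min_edited)
        & (p0 < cfg.max_p_e0)
    )
    return bool(ok) if np.ndim(ok) == 0 else ok


def classify_sites(
    observations: pd.DataFrame,
    config: DetectionConfig | None = None,
    effects: pd.Series | dict | None = None,
    novel_sites: set | None = None,
) -> pd.DataFrame:
    """Assign every expressed candidate site to one of classes I–V.

    Parameters
    ----------
    observations
        Long frame with columns chrom, pos, library_id, coverage,
        edited_count (one row per site per library; 0-based positions).
    effects
        Optional mapping (chrom, pos) → functional category, copied onto the
        output.
    novel_sites
        Optional set of (chrom, pos) marked ``is_novel``.

    Returns a per-site frame (one row per expressed candidate) with the
    joint probability, q-value, coverage aggregates, detection count, class
    and mean editing level across covered libraries.  Unexpressed candidates
    are dropped (count logged).
    """
    cfg = config or DetectionConfig()
    eps = cfg.error_model.scaled
    obs = observations.copy()
    obs["detected"] = per_library_highconf_filter(
        obs["coverage"], obs["edited_count"], cfg
    )
    obs["_log_p0"] = _log_p_e0(obs["coverage"], obs["edited_count"], eps)
    with np.errstate(invalid="ignore"):
        obs["_level"] = obs["edited_count"] / obs["coverage"].where(obs["coverage"] > 0)

    g = obs.groupby(["chrom", "pos"], sort=True)
    sites = g.agg(
        C_max=("coverage", "max"),
        C_total=("coverage", "sum"),
        n_libraries_detected=("detected", "sum"),
        _log_p0=("_log_p0", "sum"),
        mean_level=("_level", "mean"),
        n_edited_total=("edited_count", "sum"),
    ).reset_index()

    n_unexpressed = int((sites["C_total"] == 0).sum())
    if n_unexpressed:
        logger.info("excluding %d candidate sites with no coverage", n_unexpressed)
    sites = sites[sites["C_total"] > 0].reset_index(drop=True)

    sites["joint_P_E0"] = np.exp(sites["_log_p0"])
    sites["joint_P_E1"] = -np.expm1(sites["_log_p0"])
    sites = sites.drop(columns="_log_p0")
    sites["q_value"] = fdr_adjust(
        sites["joint_P_E0"], keys=list(zip(sites["chrom"], sites["pos"]))
    )

    cls = np.full(len(sites), "V", dtype=object)
    c1, c2 = cfg.class1, cfg.class2
    is1 = (
        (sites["q_value"] <= c1.fdr)
        & (sites["C_max"] >= c1.c_max_min)
        & (sites["C_total"] >= c1.c_total_min)
        & (sites["n_libraries_detected"] >= c1.min_libraries)
    )
    is2 = (
        ~is1
        & (sites["q_value"] <= c2.fdr)
        & (sites["C_max"] >= c2.c_max_min)
        & (sites["C_total"] >= c2.c_total_min)
        & (sites["n_libraries_detected"] >= c2.min_libraries)
    )
    is3 = ~is1 & ~is2 & (sites["joint_P_E1"] > cfg.class3_p_e1)
    is4 = ~is1 & ~is2 & ~is3 & (sites["n_libraries_detected"] >= 1)
    cls[is1.to_numpy()] = "I"
    cls[is2.to_numpy()] = "II"
    cls[is3.to_numpy()] = "III"
    cls[is4.to_numpy()] = "IV"
    sites["site_class"] = cls

    keys = list(zip(sites["chrom"], sites["pos"]))
    if effects is not None:
        eff = dict(effects) if not isinstance(effects, dict) else effects
        sites["effect"] = [eff.get(k) for k in keys]
    if novel_sites is not None:
        sites["is_novel"] = [k in novel_sites for k in keys]
    return sites


def library_summary(
    sites: pd.DataFrame,
    observations: pd.DataFrame,
    config: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Per-library counts of high-confidence (Class I+II) sites and N/S tally.

    Mirrors the per-library layout of the headline site table: for each
    library, the number of Class I+II sites passing the per-library filter
    there, plus N and S counts when an ``effect`` column is present.
    """
    cfg = config or DetectionConfig()
    hc = sites[sites["site_class"].isin(["I", "II"])]
    hc_keys = set(zip(hc["chrom"], hc["pos"]))
    eff = (
        dict(zip(zip(hc["chrom"], hc["pos"]), hc["effect"]))
        if "effect" in hc.columns
        else {}
    )
    obs = observations.copy()
    obs["detected"] = per_library_highconf_filter(
        obs["coverage"], obs["edited_count"], cfg
    )
    rows = []
    for lib, sub in obs.groupby("library_id", sort=True):
        det = sub[sub["detected"]]
        keys = [k for k in zip(det["chrom"], det["pos"]) if k in hc_keys]
        cats = [eff.get(k) for k in keys]
        rows.append({
            "library_id": lib,
            "sites": len(keys),
            "N": sum(c == "N" for c in cats),
            "S": sum(c == "S" for c in cats),
        })
    return pd.DataFrame(rows)


def estimate_fpr(calls: set, wildtype_detected: set, mutant_detected: set):
    """Editing-null false-positive rate from a wild-type/mutant library pair.

    N1 = calls also detected in the wild type, N2 = those additionally showing
    the A→G signal in the editing-null mutant; rate = N2/N1.
    """
    shared = set(calls) & set(wildtype_detected)
    n1 = len(shared)
    n2 = len(shared & set(mutant_detected))
    if n1 == 0:
        logger.warning("no calls detected in the wild-type control; FPR undefined")
        return None, 0, 0
    return n2 / n1, n1, n2


def cluster_sites(sites, max_gap: int = 100) -> list[list[tuple[str, int]]]:
    """Single-linkage chains of sites closer than ``max_gap`` nt.

    Consecutive same-chromosome sites with distance < max_gap join one
    cluster; singletons are not reported.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in sites:
        by_chrom.setdefault(chrom, []).append(pos)
    clusters = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        current = [positions[0]] if positions else []
        for prev, pos in zip(positions, positions[1:]):
            if pos - prev < max_gap:
                current.append(pos)
            else:
                if len(current) > 1:
                    clusters.append([(chrom, p) for p in current])
                current = [pos]
        if len(current) > 1:
            clusters.append([(chrom, p) for p in current])
    return clusters
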