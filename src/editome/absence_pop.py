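"""Confident-absence calls and population analyses of editing.

Zero edited reads at a covered site is weak evidence of non-editing: the
edited molecules may simply not have been sampled, or their G signal erased
by error.  For an assumed true level l and depth C the per-library
probability of seeing no edited read is

    P_m(D0) = Σ_{i=0}^{C} C(C,i) · l^i (1−l)^{C−i} · ε^i (1−ε)^{C−i}
            = ((1−l)(1−ε) + l·ε)^C,

the closed form following from the binomial theorem.  Joint over libraries
with zero edited reads, P(D0) = Π_m P_m(D0); a small P(D0) supports genuine
absence.  This drives three calls: conservation gain/loss over a three
species tree ((mel, sim), pse), polymorphic editing across strains of one
species, and fixed editing across strains plus a same-sex outgroup.  A
genotype–level association test links polymorphic sites to nearby SNPs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import fdr_adjust, per_library_error_prob

logger = logging.getLogger(__name__)

__all__ = [
    "AbsenceConfig", "OrthologyMap",
    "nondetection_prob", "joint_nondetection_prob",
    "call_conservation_patterns", "call_polymorphic_sites", "call_fixed_sites",
    "snp_level_association", "genotype_association",
]

SITE_KEY = ["chrom", "pos"]


@dataclass(frozen=True)
class AbsenceConfig:
    epsilon: float = 0.00167
    #: "level_I": assumed level = mean across reliably detected strains;
    #: "level_II": that mean capped at 0.05
    level_mode: str = "level_I"
    #: BH FDR for confident-absence calls (None to use ``fixed_threshold``)
    absence_fdr: float | None = 0.05
    #: fixed joint P(D0) cutoff used instead of BH when ``absence_fdr`` is None
    fixed_threshold: float = 2e-4
    #: reliable per-strain detection for polymorphism candidates
    detection_p_e1: float = 0.999
    #: per-strain requirement for fixation calls
    fixation_p_e1: float = 0.95
    min_focal_level: float = 0.05
    min_ortholog_coverage: int = 200
    level_cap: float = 0.05


@dataclass
class OrthologyMap:
    """Site-to-site coordinate mapping between a focal and another species.

    ``table`` columns: chrom, pos (focal, 0-based), species, ortho_chrom,
    ortho_pos, provenance ∈ {g_align, c_align, both}, is_adenosine.
    """

    table: pd.DataFrame

    def __post_init__(self):
        for prov, sub in self.table.groupby("provenance"):
            for _, per_species in sub.groupby("species"):
                if per_species.duplicated(["ortho_chrom", "ortho_pos"]).any():
                    raise ValueError(f"{prov}: mapping not injective")

    def map_observations(self, species: str, obs: pd.DataFrame) -> pd.DataFrame:
        """Re-key another species' observations to focal coordinates.

        Non-adenosine targets are dropped with a warning.
        """
        sub = self.table[self.table["species"] == species]
        n_bad = int((~sub["is_adenosine"]).sum())
        if n_bad:
            logger.warning(
                "%s: %d orthologous positions are not adenosines; dropped",
                species, n_bad,
            )
        sub = sub[sub["is_adenosine"]]
        merged = obs.merge(
            sub[["chrom", "pos", "ortho_chrom", "ortho_pos"]].drop_duplicates(
                ["ortho_chrom", "ortho_pos"]
            ),
            left_on=["chrom", "pos"], right_on=["ortho_chrom", "ortho_pos"],
            suffixes=("_ortho", ""),
        )
        out = merged.drop(columns=["chrom_ortho", "pos_ortho", "ortho_chrom",
                                   "ortho_pos"], errors="ignore")
        return out


def nondetection_prob(coverage, level, epsilon: float):
    """P_m(D0): probability of zero edited reads at depth C and true level l."""
    C = np.asarray(coverage)
    l = np.asarray(level, dtype=float)
    if np.any((l < 0) | (l > 1)):
        raise ValueError("editing level outside [0, 1]")
    out = np.exp(_log_nondetection(C, l, epsilon))
    return float(out) if out.ndim == 0 else out


def _log_nondetection(C, l, epsilon):
    per_read = (1.0 - l) * (1.0 - epsilon) + l * epsilon
    with np.errstate(divide="ignore"):
        return np.where(per_read > 0, C * np.log(np.maximum(per_read, 1e-300)), -np.inf)


def joint_nondetection_prob(coverages, level, epsilon: float) -> float:
    """P(D0) = Π_m P_m(D0) over the libraries with zero edited reads."""
    C = np.asarray(coverages)
    l = np.broadcast_to(np.asarray(level, dtype=float), C.shape)
    if np.any((l < 0) | (l > 1)):
        raise ValueError("editing level outside [0, 1]")
    return float(np.exp(_log_nondetection(C, l, epsilon).sum()))


# ---------------------------------------------------------------------------
# conservation over ((mel, sim), pse)
# ---------------------------------------------------------------------------

def call_conservation_patterns(
    focal_sites: pd.DataFrame,
    species_observations: dict[str, pd.DataFrame],
    species_detected: dict[str, set],
    config: AbsenceConfig | None = None,
) -> pd.DataFrame:
    """Presence/absence calls and parsimony patterns over the species tree.

    Parameters
    ----------
    focal_sites
        Frame with chrom, pos and the focal species' editing ``level``.
        Sites below the focal-level floor (default 0.05) are dropped.
    species_observations
        species → observation frame *already re-keyed to focal coordinates*
        (see :meth:`OrthologyMap.map_observations`), columns chrom, pos,
        coverage, edited_count, one row per library.
    species_detected
        species → set of focal (chrom, pos) keys with editing detected.

    Per species a site is **present** if detected, **absent** if every
    covering library shows zero edited reads and the joint P(D0) — computed
    at the focal species' level — is significant (BH FDR, or the fixed
    cutoff when ``absence_fdr`` is None), otherwise **undetermined**.
    Sites with C_total below the ortholog-coverage floor in a species, or
    with no ortholog there, are undetermined.  Parsimony mapping: present in
    all three → ``conserved``; present in focal+sister, absent in outgroup →
    ``loss_outgroup`` (gain preceding the focal/sister split is equally
    parsimonious); absent in both others → ``gain_focal``; everything else
    → ``undetermined``.
    """
    cfg = config or AbsenceConfig()
    focal = focal_sites[focal_sites["level"] >= cfg.min_focal_level].copy()
    statuses: dict[str, list[str]] = {}
    pd0_rows = []  # (species, row index, p_d0) for BH

    for species, obs in species_observations.items():
        detected = species_detected.get(species, set())
        status = []
        for i, row in enumerate(focal.itertuples(index=False)):
            key = (row.chrom, row.pos)
            sub = obs[(obs["chrom"] == row.chrom) & (obs["pos"] == row.pos)]
            if key in detected:
                status.append("present")
                continue
            if sub.empty or sub["coverage"].sum() < cfg.min_ortholog_coverage:
                status.append("undetermined")
                continue
            if (sub["edited_count"] > 0).any():
                status.append("undetermined")  # trace signal, not confident either way
                continue
            p_d0 = joint_nondetection_prob(
                sub.loc[sub["coverage"] > 0, "coverage"].to_numpy(),
                row.level, cfg.epsilon,
            )
            pd0_rows.append((species, i, p_d0))
            status.append("pending")
        statuses[species] = status

    significant = _absence_significance([p for *_, p in pd0_rows], cfg)
    for (species, i, _), sig in zip(pd0_rows, significant):
        statuses[species][i] = "absent" if sig else "undetermined"

    out = focal.reset_index(drop=True)
    for species, status in statuses.items():
        out[f"status_{species}"] = status
    out["pattern"] = [
        _parsimony_pattern(out.loc[i, "status_sim"], out.loc[i, "status_pse"])
        if {"status_sim", "status_pse"} <= set(out.columns) else "undetermined"
        for i in range(len(out))
    ]
    return out


def _absence_significance(p_values, cfg: AbsenceConfig):
    if not p_values:
        return []
    if cfg.absence_fdr is not None:
        return fdr_adjust(p_values) <= cfg.absence_fdr
    return np.asarray(p_values) < cfg.fixed_threshold


def _parsimony_pattern(sim_status: str, pse_status: str) -> str:
    if sim_status == "present" and pse_status == "present":
        return "conserved"
    if sim_status == "present" and pse_status == "absent":
        return "loss_outgroup"
    if sim_status == "absent" and pse_status == "absent":
        return "gain_focal"
    return "undetermined"


# ---------------------------------------------------------------------------
# polymorphic / fixed editing across strains
# ---------------------------------------------------------------------------

def call_polymorphic_sites(
    strain_observations: pd.DataFrame,
    outgroup_edited: set,
    config: AbsenceConfig | None = None,
) -> pd.DataFrame:
    """Sites with editing reliably present in some strains and absent in others.

    ``strain_observations``: one sex's frame with columns chrom, pos, strain,
    coverage, edited_count.  Sites edited in the outgroup species are
    excluded first.  A candidate needs ≥1 strain with P_k(E1) above the
    detection threshold and ≥1 covered strain with zero edited reads; the
    assumed level in non-detected strains is the mean level of the reliably
    detected strains (Level I) or that mean capped at 0.05 (Level II).  The
    joint P(D0) over the zero-read strains is tested per ``absence_fdr`` /
    ``fixed_threshold``; both stringency calls are reported.
    """
    cfg = config or AbsenceConfig()
    obs = strain_observations.copy()
    obs["p_e1"] = 1.0 - per_library_error_prob(
        obs["coverage"], obs["edited_count"], cfg.epsilon
    )
    rows = []
    for (chrom, pos), sub in obs.groupby(SITE_KEY, sort=True):
        if (chrom, pos) in outgroup_edited:
            continue
        covered = sub[sub["coverage"] > 0]
        if covered.empty:
            continue
        detected = covered[covered["p_e1"] > cfg.detection_p_e1]
        zero = covered[covered["edited_count"] == 0]
        if detected.empty or zero.empty:
            continue
        mean_level = float(
            (detected["edited_count"] / detected["coverage"]).mean()
        )
        level_ii = min(mean_level, cfg.level_cap)
        C0 = zero["coverage"].to_numpy()
        rows.append({
            "chrom": chrom, "pos": pos,
            "n_strains_detected": len(detected),
            "n_strains_zero": len(zero),
            "detected_strains": ",".join(sorted(detected["strain"].astype(str))),
            "assumed_level_I": mean_level,
            "assumed_level_II": level_ii,
            "p_d0_level_I": joint_nondetection_prob(C0, mean_level, cfg.epsilon),
            "p_d0_level_II": joint_nondetection_prob(C0, level_ii, cfg.epsilon),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=SITE_KEY + ["polymorphic_level_I", "polymorphic_level_II"]
        )
    for level in ("I", "II"):
        out[f"polymorphic_level_{level}"] = _absence_significance(
            out[f"p_d0_level_{level}"].tolist(), cfg
        )
    return out


def call_fixed_sites(
    strain_observations: pd.DataFrame,
    outgroup_detected: set,
    config: AbsenceConfig | None = None,
) -> pd.DataFrame:
    """Sites edited in every strain and in the same-sex outgroup library.

    Fixed iff P_k(E1) > threshold (default 0.95) in *all* strains (a site
    with any uncovered strain is not callable) and the orthologous site is
    edited in the outgroup.
    """
    cfg = config or AbsenceConfig()
    obs = strain_observations.copy()
    n_strains = obs["strain"].nunique()
    obs["p_e1"] = 1.0 - per_library_error_prob(
        obs["coverage"], obs["edited_count"], cfg.epsilon
    )
    rows = []
    for (chrom, pos), sub in obs.groupby(SITE_KEY, sort=True):
        covered = sub[sub["coverage"] > 0]
        if covered["strain"].nunique() < n_strains:
            continue
        all_detected = bool((covered["p_e1"] > cfg.fixation_p_e1).all())
        rows.append({
            "chrom": chrom, "pos": pos,
            "min_p_e1": float(covered["p_e1"].min()),
            "outgroup_edited": (chrom, pos) in outgroup_detected,
            "fixed": all_detected and (chrom, pos) in outgroup_detected,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP association with editing levels
# ---------------------------------------------------------------------------

def genotype_association(levels, genotypes) -> tuple[float, float] | None:
    """Exact one-sided association of editing level with a biallelic SNP.

    Returns (Pearson r, p) where p is the fraction of all 2^n possible
    genotype assignments whose correlation with the levels is at least as
    extreme in the observed direction; monomorphic null assignments cannot
    exceed and are counted in the denominator.  Returns None for a
    monomorphic observed genotype or constant levels.
    """
    x = np.asarray(levels, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if np.ptp(g) == 0 or np.ptp(x) == 0:
        return None
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())

    def corr(gv):
        gc = gv - gv.mean()
        denom = np.sqrt((gc ** 2).sum()) * xs
        return (gc * xc).sum() / denom if denom > 0 else np.nan

    r_obs = corr(g)
    n = len(g)
    n_exceed = 0
    for bits in itertools.product((0.0, 1.0), repeat=n):
        r = corr(np.array(bits))
        if np.isnan(r):
            continue
        if (r_obs > 0 and r >= r_obs - 1e-12) or (r_obs < 0 and r <= r_obs + 1e-12):
            n_exceed += 1
    return float(r_obs), n_exceed / 2 ** n


def snp_level_association(
    levels_female: pd.DataFrame,
    levels_male: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_positions: pd.DataFrame,
    site_positions: pd.DataFrame,
    max_distance: int = 10_000,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """(site, SNP) pairs whose editing level tracks genotype in both sexes.

    ``levels_female``/``levels_male`` are site-by-strain level matrices for
    the sites polymorphic in both sexes (index: site id).  ``genotypes`` is
    a SNP-by-strain 0/1 matrix; ``snp_positions`` / ``site_positions`` map
    ids to (chrom, pos).  A pair is reported iff the effect direction is
    identical in both sexes and the exact one-sided p is below threshold in
    both.  Monomorphic SNPs are skipped.
    """
    strains = [c for c in levels_female.columns if c in genotypes.columns]
    snp_pos = snp_positions.set_index("snp_id")
    site_pos = site_positions.set_index("site_id")
    rows = []
    for site_id in levels_female.index:
        if site_id not in levels_male.index or site_id not in site_pos.index:
            continue
        chrom, pos = site_pos.loc[site_id, ["chrom", "pos"]]
        near = snp_pos[
            (snp_pos["chrom"] == chrom)
            & (abs(snp_pos["pos"] - pos) <= max_distance)
        ]
        for snp_id in near.index:
            if snp_id not in genotypes.index:
                continue
            g = genotypes.loc[snp_id, strains].to_numpy(float)
            res_f = genotype_association(
                levels_female.loc[site_id, strains].to_numpy(float), g
            )
            res_m = genotype_association(
                levels_male.loc[site_id, strains].to_numpy(float), g
            )
            if res_f is None or res_m is None:
                continue
            r_f, p_f = res_f
            r_m, p_m = res_m
            if np.sign(r_f) == np.sign(r_m) and p_f < p_threshold and p_m < p_threshold:
                rows.append({
                    "site_id": site_id, "snp_id": snp_id,
                    "distance": int(abs(near.loc[snp_id, "pos"] - pos)),
                    "r_female": r_f, "r_male": r_m,
                    "p_female": p_f, "p_male": p_m,
                })
    return pd.DataFrame(
        rows, columns=["site_id", "snp_id", "distance", "r_female", "r_male",
                       "p_female", "p_male"],
    )
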