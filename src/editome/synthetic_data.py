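"""Ground-truth editome generator.

Emulates the statistical structure the analysis assumes, end to end: random
gene models (UTR/CDS/intron on both strands), editing sites placed on
transcript-strand adenosines with beta-distributed true levels (N sites
drawn from a higher-mean beta than S sites), negative-binomial per-library
coverage, per-read A→G error applied symmetrically (an edited molecule can
lose its G by error, an unedited one can gain it), genomic SNPs to be
masked, multi-species presence patterns on a ((mel, sim), pse) tree, and a
five-strain population panel with planted polymorphic/fixed sites and
editing-QTL SNPs.

Every draw flows from a single seed, and the truth tables cover every
emitted count row, so recovery tests can score calls exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_model import (
    GeneModel,
    LibraryMeta,
    iter_cds_adenosines,
    write_fasta,
    write_gene_models,
    write_library_meta,
    write_site_observations,
    write_snp_vcf,
)

__all__ = [
    "GeneratorConfig", "SyntheticTruth", "PopulationPanel",
    "generate_reference", "generate_editome", "simulate_counts",
    "generate_population_panel", "write_dataset",
]

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic editome.

    Defaults emulate the brain-library marginals the analysis was designed
    around: median per-site coverage in the 5–9 range, nonsynonymous sites
    edited at higher mean levels (Beta(2,4), mean 1/3) than synonymous and
    non-coding sites (Beta(1.2,6), mean ≈0.17), eight libraries spanning two
    sexes and three temperature conditions, and an A→G-specific error rate
    of 0.00167 per read.
    """

    n_genes: int = 30
    cds_codon_range: tuple[int, int] = (100, 500)
    utr5_range: tuple[int, int] = (30, 120)
    utr3_range: tuple[int, int] = (60, 250)
    intron_prob: float = 0.5
    intron_range: tuple[int, int] = (60, 200)
    intergenic_range: tuple[int, int] = (200, 500)
    chromosomes: tuple[str, ...] = ("chr2L", "chrX")
    x_fraction: float = 0.2

    editing_rate: float = 0.02           # per transcript-strand adenosine
    #: extra rate multiplier on N adenosines; plants an adaptive fraction of
    #: 1 − 1/multiplier relative to the same genes' neutral background
    n_rate_multiplier: float = 1.0
    position_gradient: float = 0.0       # linear 5'→3' multiplier strength
    phylop_dependence: float = 0.0       # log-linear effect of the phyloP proxy
    pseb_fraction: float = 0.0           # fraction of genes with boosted N editing
    pseb_n_multiplier: float = 10.0
    pseb_s_multiplier: float = 0.1
    level_beta_n: tuple[float, float] = (2.0, 4.0)
    level_beta_other: tuple[float, float] = (1.2, 6.0)

    n_libraries: int = 8
    mean_coverage: float = 7.0
    dispersion: float = 0.35             # NB variance = m + dispersion * m^2
    epsilon_true: float = 0.00167
    temperature_effects: tuple[tuple[str, float], ...] = (
        ("25C", 0.0), ("30C_14h", 0.0), ("30C_48h", 0.0),
    )
    snp_rate: float = 0.0005             # per genomic base
    snp_allele_fraction: float = 0.5
    n_background_sites: int = 300        # unedited adenosines in count tables

    share_sim: float = 0.47              # presence probability on the sister species
    share_pse: float = 0.21              # presence probability on the outgroup

    # population panel
    n_strains: int = 5
    panel_mean_coverage: float = 50.0
    panel_coverage_floor: int = 0        # guaranteed minimum panel depth
    polymorphic_fraction: float = 0.4
    polymorphic_n_strains: tuple[int, int] = (1, 3)
    qtl_fraction: float = 0.6
    qtl_max_distance: int = 10_000

    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth: per-site categories, levels and presence patterns."""

    sites: pd.DataFrame          # chrom,pos,gene_id,category,edited,base_level,
                                 # present_sim,present_pse,pseb_gene,phylop,relpos
    snps: list[tuple[str, int]]
    libraries: list[LibraryMeta]
    config: GeneratorConfig

    @property
    def edited_sites(self) -> pd.DataFrame:
        return self.sites[self.sites["edited"]]


@dataclass
class PopulationPanel:
    counts_female: pd.DataFrame      # chrom,pos,strain,coverage,edited_count
    counts_male: pd.DataFrame
    outgroup_detected_female: set
    outgroup_detected_male: set
    genotypes: pd.DataFrame          # snp_id x strain 0/1
    snp_positions: pd.DataFrame      # snp_id, chrom, pos
    site_truth: pd.DataFrame         # chrom,pos,label in {polymorphic,fixed},
                                     # edited_strains, qtl_snp


# ---------------------------------------------------------------------------
# reference genome + gene models
# ---------------------------------------------------------------------------

def generate_reference(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random-codon genome and canonical gene models (both strands ~50/50)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pieces: dict[str, list[str]] = {c: [] for c in cfg.chromosomes}
    offsets = {c: 0 for c in cfg.chromosomes}
    genes: list[GeneModel] = []

    for i in range(cfg.n_genes):
        chrom = (
            cfg.chromosomes[-1]
            if rng.random() < cfg.x_fraction and len(cfg.chromosomes) > 1
            else cfg.chromosomes[0]
        )
        strand = "+" if rng.random() < 0.5 else "-"
        gene, pre_mrna = _build_gene(f"g{i:04d}", chrom, strand, offsets[chrom], cfg, rng)
        spacer = _random_seq(rng, rng.integers(*cfg.intergenic_range))
        pieces[chrom].extend([spacer, pre_mrna])
        offsets[chrom] += len(spacer)
        gene = _shift_gene(gene, len(spacer))
        offsets[chrom] += len(pre_mrna)
        genes.append(gene)

    for chrom in cfg.chromosomes:
        pieces[chrom].append(_random_seq(rng, rng.integers(*cfg.intergenic_range)))
    genome = {c: "".join(p) for c, p in pieces.items() if p}
    return genome, genes


def _random_seq(rng, length) -> str:
    return "".join(rng.choice(list("ACGT"), size=int(length)))


def _build_gene(gene_id, chrom, strand, offset, cfg, rng):
    n_codons = int(rng.integers(*cfg.cds_codon_range))
    cds = "ATG" + "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2)) + \
        str(rng.choice(_STOPS))
    utr5 = _random_seq(rng, rng.integers(*cfg.utr5_range))
    utr3 = _random_seq(rng, rng.integers(*cfg.utr3_range))
    transcript = utr5 + cds + utr3
    cs, ce = len(utr5), len(utr5) + len(cds)

    # optionally split the CDS with one intron (pre-mRNA coordinates)
    exon_ivs = [(0, len(transcript))]
    if rng.random() < cfg.intron_prob and len(cds) > 12:
        ip = int(rng.integers(cs + 3, ce - 3))
        intron = _random_seq(rng, rng.integers(*cfg.intron_range))
        transcript = transcript[:ip] + intron + transcript[ip:]
        exon_ivs = [(0, ip), (ip + len(intron), len(transcript))]
        cds_ivs = [(cs, ip), (ip + len(intron), ce + len(intron))]
    else:
        cds_ivs = [(cs, ce)]

    length = len(transcript)
    if strand == "+":
        genomic = transcript
        to_genomic = lambda a, b: (offset + a, offset + b)  # noqa: E731
    else:
        genomic = _revcomp(transcript)
        to_genomic = lambda a, b: (offset + length - b, offset + length - a)  # noqa: E731

    gene = GeneModel(
        gene_id, chrom, strand,
        exons=[to_genomic(a, b) for a, b in exon_ivs],
        cds=[to_genomic(a, b) for a, b in cds_ivs],
    )
    return gene, genomic


def _shift_gene(gene: GeneModel, delta: int) -> GeneModel:
    return GeneModel(
        gene.gene_id, gene.chromosome, gene.strand,
        exons=[(a + delta, b + delta) for a, b in gene.exons],
        cds=[(a + delta, b + delta) for a, b in gene.cds],
    )


# ---------------------------------------------------------------------------
# editome
# ---------------------------------------------------------------------------

def default_libraries(cfg: GeneratorConfig) -> list[LibraryMeta]:
    conditions = [c for c, _ in cfg.temperature_effects]
    libs = []
    for i in range(cfg.n_libraries):
        sex = "F" if i % 2 == 0 else "M"
        cond = conditions[(i // 2) % len(conditions)]
        libs.append(LibraryMeta(f"B{i + 1}", species="mel", sex=sex,
                                age_days="1-5", temperature_condition=cond))
    return libs


def _transcript_adenosines(gene: GeneModel, genome: dict[str, str]):
    """(pos, category, relative transcript position) for non-CDS adenosines."""
    chrom_seq = genome[gene.chromosome]
    target = "A" if gene.strand == "+" else "T"
    span = gene.span
    length = span[1] - span[0]
    out = []
    for pos in range(*span):
        if chrom_seq[pos] != target:
            continue
        region = gene.region_of(pos)
        if region in (None, "CDS"):
            continue
        rel = (pos - span[0]) / length
        if gene.strand == "-":
            rel = 1.0 - rel
        out.append((pos, region, rel))
    return out


def generate_editome(
    genome: dict[str, str],
    genes: list[GeneModel],
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> SyntheticTruth:
    """Place editing sites on transcript-strand adenosines with true levels."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    pseb_genes = {
        g.gene_id for g in genes
        if g.is_coding and rng.random() < cfg.pseb_fraction
    }

    rows = []
    for gene in genes:
        span = gene.span
        length = span[1] - span[0]
        gene_phylop = rng.normal()
        candidates = []
        for pos, effect in iter_cds_adenosines(gene, genome):
            rel = (pos - span[0]) / length
            if gene.strand == "-":
                rel = 1.0 - rel
            candidates.append((pos, effect.category, rel))
        candidates.extend(_transcript_adenosines(gene, genome))
        for pos, category, rel in candidates:
            phylop = gene_phylop + rng.normal(scale=0.5)
            rate = cfg.editing_rate
            rate *= 1.0 + cfg.position_gradient * (rel - 0.5)
            rate *= float(np.exp(cfg.phylop_dependence * phylop))
            if category == "N":
                rate *= cfg.n_rate_multiplier
            if gene.gene_id in pseb_genes:
                if category == "N":
                    rate *= cfg.pseb_n_multiplier
                elif category == "S":
                    rate *= cfg.pseb_s_multiplier
            edited = (
                category in ("N", "S", "UTR5", "UTR3", "intron")
                and rng.random() < min(rate, 1.0)
            )
            a, b = cfg.level_beta_n if category == "N" else cfg.level_beta_other
            level = float(rng.beta(a, b)) if edited else 0.0
            rows.append({
                "chrom": gene.chromosome, "pos": pos, "gene_id": gene.gene_id,
                "category": category, "relpos": rel, "phylop": phylop,
                "edited": edited, "base_level": level,
                "present_sim": edited and rng.random() < cfg.share_sim,
                "present_pse": edited and rng.random() < cfg.share_pse,
                "pseb_gene": gene.gene_id in pseb_genes,
            })
    sites = pd.DataFrame(rows)

    # background adenosines included in count tables, and genomic SNPs
    unedited_idx = sites.index[~sites["edited"]]
    n_bg = min(cfg.n_background_sites, len(unedited_idx))
    bg_pick = rng.choice(unedited_idx, size=n_bg, replace=False)
    sites["in_count_table"] = sites["edited"]
    sites.loc[bg_pick, "in_count_table"] = True

    snps = []
    for chrom, seq in genome.items():
        n_snps = rng.poisson(cfg.snp_rate * len(seq))
        for pos in sorted(rng.choice(len(seq), size=min(n_snps, len(seq)),
                                     replace=False)):
            snps.append((chrom, int(pos)))
    edited_keys = set(zip(sites.loc[sites["edited"], "chrom"],
                          sites.loc[sites["edited"], "pos"]))
    snps = [s for s in snps if s not in edited_keys]

    return SyntheticTruth(
        sites=sites, snps=snps, libraries=default_libraries(cfg), config=cfg,
    )


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb_coverage(rng, mean, dispersion, size):
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def _true_level(row, library: LibraryMeta, cfg: GeneratorConfig) -> float:
    if library.species == "mel":
        present = bool(row.edited)
    elif library.species == "sim":
        present = bool(row.present_sim)
    else:
        present = bool(row.present_pse)
    if not present:
        return 0.0
    delta = dict(cfg.temperature_effects).get(library.temperature_condition, 0.0)
    return float(np.clip(row.base_level + delta, 0.0, 1.0))


def simulate_counts(
    truth: SyntheticTruth,
    seed: int | None = None,
    libraries: list[LibraryMeta] | None = None,
    include_null_pair: bool = False,
) -> pd.DataFrame:
    """Per-library count tables (long format) from the truth editome.

    Per site and library, coverage is negative-binomial and the edited count
    binomial with per-read success l·(1−ε) + (1−l)·ε — error both erases and
    fabricates edited reads.  SNP positions are emitted with the configured
    allele fraction so an unmasked analysis would call them.  With
    ``include_null_pair``, two extra libraries are appended: ``wt_control``
    (normal levels) and ``editing_null`` (all true levels zero), the
    wild-type/mutant pair used for false-positive-rate estimation.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    libs = list(libraries if libraries is not None else truth.libraries)
    if include_null_pair:
        libs = libs + [
            LibraryMeta("wt_control", species="mel", strain="w1118"),
            LibraryMeta("editing_null", species="mel", strain="adar_null"),
        ]
    table = truth.sites[truth.sites["in_count_table"]]
    frames = []
    for lib in libs:
        C = _nb_coverage(rng, cfg.mean_coverage, cfg.dispersion, len(table))
        levels = np.array([
            0.0 if lib.library_id == "editing_null"
            else _true_level(row, lib, cfg)
            for row in table.itertuples(index=False)
        ])
        p = levels * (1 - cfg.epsilon_true) + (1 - levels) * cfg.epsilon_true
        L = rng.binomial(C, p)
        frames.append(pd.DataFrame({
            "chrom": table["chrom"].to_numpy(),
            "pos": table["pos"].to_numpy(),
            "library_id": lib.library_id,
            "coverage": C,
            "edited_count": L,
        }))
        if truth.snps:
            snp_chrom, snp_pos = zip(*truth.snps)
            C_snp = _nb_coverage(rng, cfg.mean_coverage, cfg.dispersion,
                                 len(truth.snps))
            L_snp = rng.binomial(C_snp, cfg.snp_allele_fraction)
            frames.append(pd.DataFrame({
                "chrom": snp_chrom, "pos": snp_pos,
                "library_id": lib.library_id,
                "coverage": C_snp, "edited_count": L_snp,
            }))
    out = pd.concat(frames, ignore_index=True)
    out["level"] = out["edited_count"] / out["coverage"].where(out["coverage"] > 0)
    return out


# ---------------------------------------------------------------------------
# population panel
# ---------------------------------------------------------------------------

def generate_population_panel(
    truth: SyntheticTruth, seed: int | None = None
) -> PopulationPanel:
    """Five-strain, two-sex panel with planted polymorphic/fixed editing.

    Polymorphic sites are edited (at their true level) in a random strain
    subset — identically in both sexes — and carry zero true editing
    elsewhere and in the outgroup; fixed sites are edited in every strain
    and in the outgroup.  A configurable fraction of polymorphic sites get a
    linked QTL SNP within 10 kb whose alternative allele marks exactly the
    edited strains.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    strains = [f"S{i + 1}" for i in range(cfg.n_strains)]
    edited = truth.edited_sites.reset_index(drop=True)

    labels, strain_sets, qtl_ids = [], [], []
    geno_rows, snp_rows = {}, []
    for i, row in enumerate(edited.itertuples(index=False)):
        if rng.random() < cfg.polymorphic_fraction:
            k = int(rng.integers(cfg.polymorphic_n_strains[0],
                                 cfg.polymorphic_n_strains[1] + 1))
            subset = sorted(rng.choice(strains, size=k, replace=False))
            labels.append("polymorphic")
            strain_sets.append(subset)
            if rng.random() < cfg.qtl_fraction:
                snp_id = f"qtl_{i}"
                offset = int(rng.integers(100, cfg.qtl_max_distance))
                snp_rows.append({"snp_id": snp_id, "chrom": row.chrom,
                                 "pos": row.pos + offset})
                geno_rows[snp_id] = [1 if s in subset else 0 for s in strains]
                qtl_ids.append(snp_id)
            else:
                qtl_ids.append(None)
        else:
            labels.append("fixed")
            strain_sets.append(list(strains))
            qtl_ids.append(None)

    # decoy SNPs uncorrelated with editing
    for j in range(len(edited)):
        if rng.random() < 0.3:
            snp_id = f"decoy_{j}"
            snp_rows.append({
                "snp_id": snp_id,
                "chrom": edited.loc[j, "chrom"],
                "pos": int(edited.loc[j, "pos"]) + int(rng.integers(100, cfg.qtl_max_distance)),
            })
            geno_rows[snp_id] = list(rng.integers(0, 2, size=len(strains)))

    def _sex_counts(sex_seed):
        sub_rng = np.random.default_rng(sex_seed)
        frames = []
        outgroup_detected = set()
        for i, row in enumerate(edited.itertuples(index=False)):
            lvl = row.base_level
            for strain in strains:
                on = strain in strain_sets[i]
                C = max(
                    int(_nb_coverage(sub_rng, cfg.panel_mean_coverage,
                                     cfg.dispersion, 1)[0]),
                    cfg.panel_coverage_floor,
                )
                p = (lvl if on else 0.0) * (1 - cfg.epsilon_true) \
                    + (1 - (lvl if on else 0.0)) * cfg.epsilon_true
                L = int(sub_rng.binomial(C, p))
                frames.append({"chrom": row.chrom, "pos": row.pos,
                               "strain": strain, "coverage": C,
                               "edited_count": L})
            if labels[i] == "fixed":
                outgroup_detected.add((row.chrom, row.pos))
        return pd.DataFrame(frames), outgroup_detected

    base = rng.integers(0, 2**31 - 1)
    counts_f, out_f = _sex_counts(base)
    counts_m, out_m = _sex_counts(base + 1)

    site_truth = pd.DataFrame({
        "chrom": edited["chrom"], "pos": edited["pos"],
        "category": edited["category"], "label": labels,
        "edited_strains": [",".join(s) for s in strain_sets],
        "qtl_snp": qtl_ids,
        "base_level": edited["base_level"],
    })
    snp_positions = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    genotypes = pd.DataFrame.from_dict(
        geno_rows, orient="index", columns=strains
    ) if geno_rows else pd.DataFrame(columns=strains)
    return PopulationPanel(
        counts_female=counts_f, counts_male=counts_m,
        outgroup_detected_female=out_f, outgroup_detected_male=out_m,
        genotypes=genotypes, snp_positions=snp_positions, site_truth=site_truth,
    )


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def write_dataset(
    genome: dict[str, str],
    genes: list[GeneModel],
    truth: SyntheticTruth,
    counts: pd.DataFrame,
    outdir,
) -> dict[str, str]:
    """Write FASTA/GFF3/VCF/count-table/meta/truth files; returns the paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa", "gff3": out / "genes.gff3",
        "vcf": out / "snps.vcf", "counts": out / "counts.tsv",
        "meta": out / "libraries.tsv", "truth": out / "truth.tsv",
    }
    write_fasta(genome, paths["fasta"])
    write_gene_models(genes, paths["gff3"])
    write_snp_vcf(truth.snps, genome, paths["vcf"])
    write_site_observations(counts, paths["counts"])
    write_library_meta(truth.libraries, paths["meta"])
    truth.sites.assign(pos=truth.sites["pos"] + 1).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return {k: str(v) for k, v in paths.items()}


def with_overrides(config: GeneratorConfig, **kwargs) -> GeneratorConfig:
    """Convenience: a copy of the config with fields replaced."""
    return replace(config, **kwargs)
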