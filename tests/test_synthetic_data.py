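"""Generator determinism, construct validity and marginal calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from editome.core_model import iter_cds_adenosines
from editome.detect import classify_sites
from editome.synthetic_data import (
    GeneratorConfig,
    generate_editome,
    generate_population_panel,
    generate_reference,
    simulate_counts,
    write_dataset,
)


class TestReference:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_genes=8, seed=21)
        g1, genes1 = generate_reference(cfg)
        g2, genes2 = generate_reference(cfg)
        assert g1 == g2
        assert [(g.gene_id, g.exons, g.cds) for g in genes1] == \
            [(g.gene_id, g.exons, g.cds) for g in genes2]

    def test_cds_validity(self, small_dataset):
        _, genome, genes, *_ = small_dataset
        stops = {"TAA", "TAG", "TGA"}
        for gene in genes:
            cds = gene.coding_sequence(genome)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            assert codons[-1] in stops
            assert not any(c in stops for c in codons[:-1])

    def test_both_strands_represented(self, small_dataset):
        _, _, genes, *_ = small_dataset
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}

    def test_base_composition_roughly_uniform(self):
        cfg = GeneratorConfig(n_genes=40, seed=33)
        genome, _ = generate_reference(cfg)
        seq = "".join(genome.values())
        counts = [seq.count(b) for b in "ACGT"]
        # CDS codon structure skews composition a little; chi-square on a
        # modest sample should not reject uniformity outright
        _, p = chisquare(np.array(counts) / 50)
        assert p > 0.001


class TestEditome:
    def test_sites_on_transcript_strand_adenosines(self, small_dataset):
        _, genome, genes, truth, _ = small_dataset
        by_gene = {g.gene_id: g for g in genes}
        for row in truth.edited_sites.itertuples(index=False):
            gene = by_gene[row.gene_id]
            base = genome[row.chrom][row.pos]
            assert base == ("A" if gene.strand == "+" else "T")

    def test_zero_rate_gives_empty_editome(self):
        cfg = GeneratorConfig(n_genes=5, seed=3, editing_rate=0.0)
        genome, genes = generate_reference(cfg)
        truth = generate_editome(genome, genes, cfg)
        assert truth.edited_sites.empty

    def test_full_sharing_conserves_every_site(self):
        cfg = GeneratorConfig(n_genes=5, seed=4, share_sim=1.0, share_pse=1.0)
        genome, genes = generate_reference(cfg)
        truth = generate_editome(genome, genes, cfg)
        edited = truth.edited_sites
        assert edited["present_sim"].all() and edited["present_pse"].all()

    def test_pseb_genes_have_elevated_ns_ratio(self):
        cfg = GeneratorConfig(n_genes=40, seed=5, editing_rate=0.02,
                              pseb_fraction=0.3)
        genome, genes = generate_reference(cfg)
        truth = generate_editome(genome, genes, cfg)
        cds = truth.edited_sites[truth.edited_sites["category"].isin(["N", "S"])]
        def ratio(sub):
            n, s = (sub["category"] == "N").sum(), (sub["category"] == "S").sum()
            return n / max(s, 1)
        assert ratio(cds[cds["pseb_gene"]]) > ratio(cds[~cds["pseb_gene"]])

    def test_categories_match_annotation(self, small_dataset):
        _, genome, genes, truth, _ = small_dataset
        by_gene = {g.gene_id: g for g in genes}
        cds_truth = truth.sites[truth.sites["category"].isin(["N", "S"])]
        for gene_id, sub in cds_truth.groupby("gene_id"):
            expected = dict(
                (pos, e.category)
                for pos, e in iter_cds_adenosines(by_gene[gene_id], genome)
            )
            for row in sub.itertuples(index=False):
                assert expected[row.pos] == row.category


class TestCounts:
    def test_truth_covers_every_count_row(self, small_dataset):
        _, _, _, truth, counts = small_dataset
        truth_keys = set(
            zip(truth.sites.loc[truth.sites["in_count_table"], "chrom"],
                truth.sites.loc[truth.sites["in_count_table"], "pos"])
        ) | set(truth.snps)
        assert set(zip(counts["chrom"], counts["pos"])) <= truth_keys

    def test_deterministic_under_seed(self, small_dataset):
        _, _, _, truth, _ = small_dataset
        a = simulate_counts(truth, seed=77)
        b = simulate_counts(truth, seed=77)
        pd.testing.assert_frame_equal(a, b)

    def test_full_level_zero_error_reproduces_coverage(self):
        cfg = GeneratorConfig(n_genes=5, seed=6, editing_rate=0.05,
                              epsilon_true=0.0,
                              level_beta_n=(10**6, 1), level_beta_other=(10**6, 1))
        genome, genes = generate_reference(cfg)
        truth = generate_editome(genome, genes, cfg)
        counts = simulate_counts(truth)
        edited_keys = set(zip(truth.edited_sites["chrom"], truth.edited_sites["pos"]))
        on = counts[[k in edited_keys for k in zip(counts["chrom"], counts["pos"])]]
        assert (on["edited_count"] == on["coverage"]).all()

    def test_null_library_has_only_error_reads(self, small_dataset):
        _, _, _, truth, _ = small_dataset
        counts = simulate_counts(truth, seed=5, include_null_pair=True)
        null = counts[counts["library_id"] == "editing_null"]
        snp_keys = set(truth.snps)
        null = null[[k not in snp_keys for k in zip(null["chrom"], null["pos"])]]
        # error-only edited reads: rate ~ eps, so the mean level is tiny
        assert null["edited_count"].sum() / max(null["coverage"].sum(), 1) < 0.01

    def test_default_coverage_marginals_match_study_conditions(self):
        """Defaults give a median per-site library coverage in the 5-9 band
        and N-site mean levels above S-site mean levels."""
        cfg = GeneratorConfig(n_genes=20, seed=8)
        genome, genes = generate_reference(cfg)
        truth = generate_editome(genome, genes, cfg)
        counts = simulate_counts(truth)
        med = counts.groupby("library_id")["coverage"].median()
        assert ((med >= 5) & (med <= 9)).all()
        edited = truth.edited_sites
        mean_n = edited.loc[edited["category"] == "N", "base_level"].mean()
        mean_s = edited.loc[edited["category"] == "S", "base_level"].mean()
        assert mean_n > mean_s


@pytest.fixture(scope="module")
def panel():
    cfg = GeneratorConfig(n_genes=15, seed=9, editing_rate=0.01,
                          panel_coverage_floor=50,
                          polymorphic_n_strains=(2, 2))
    genome, genes = generate_reference(cfg)
    truth = generate_editome(genome, genes, cfg)
    return truth, generate_population_panel(truth, seed=10)


class TestPopulationPanel:

    def test_polymorphic_sites_silent_in_off_strains(self, panel):
        truth, pp = panel
        poly = pp.site_truth[pp.site_truth["label"] == "polymorphic"]
        merged = pp.counts_female.merge(poly, on=["chrom", "pos"])
        off = merged[[
            s not in es.split(",")
            for s, es in zip(merged["strain"], merged["edited_strains"])
        ]]
        # off strains carry only error reads
        assert (off["edited_count"] / off["coverage"]).max() < 0.1

    def test_fixed_sites_require_outgroup(self, panel):
        truth, pp = panel
        fixed = pp.site_truth[pp.site_truth["label"] == "fixed"]
        keys = set(zip(fixed["chrom"], fixed["pos"]))
        assert keys <= pp.outgroup_detected_female
        poly = pp.site_truth[pp.site_truth["label"] == "polymorphic"]
        assert not (set(zip(poly["chrom"], poly["pos"]))
                    & pp.outgroup_detected_female)

    def test_qtl_genotypes_mark_edited_strains(self, panel):
        truth, pp = panel
        with_qtl = pp.site_truth.dropna(subset=["qtl_snp"])
        for row in with_qtl.itertuples(index=False):
            geno = pp.genotypes.loc[row.qtl_snp]
            edited = set(row.edited_strains.split(","))
            assert {s for s in geno.index if geno[s] == 1} == edited


class TestEmission:
    def test_written_files_reload_consistently(self, tmp_path, small_dataset):
        _, genome, genes, truth, counts = small_dataset
        from editome.core_model import (
            SNPMask, load_gene_models, load_site_observations, read_fasta,
        )
        paths = write_dataset(genome, genes, truth, counts, tmp_path / "d")
        assert read_fasta(paths["fasta"]) == genome
        assert len(load_gene_models(paths["gff3"])) == len(genes)
        mask = SNPMask.from_vcf(paths["vcf"])
        reloaded = load_site_observations(paths["counts"], mask=mask)
        # all masked rows removed, everything else preserved
        assert not any((c, p) in mask
                       for c, p in zip(reloaded["chrom"], reloaded["pos"]))
        kept = counts[[(c, p) not in mask
                       for c, p in zip(counts["chrom"], counts["pos"])]]
        assert len(reloaded) == len(kept)


class TestDetectionPower:
    def test_planted_sites_recovered_at_depth_30(self):
        """Coverage 30, planted level ~0.3, 8 libraries: nearly all planted
        sites reach Class I+II and no unplanted site does."""
        cfg = GeneratorConfig(n_genes=20, seed=13, editing_rate=0.02,
                              mean_coverage=30.0,
                              level_beta_n=(300, 700),
                              level_beta_other=(300, 700))
        genome, genes = generate_reference(cfg)
        truth = generate_editome(genome, genes, cfg)
        counts = simulate_counts(truth)
        snp_keys = set(truth.snps)
        counts = counts[[(c, p) not in snp_keys
                         for c, p in zip(counts["chrom"], counts["pos"])]]
        out = classify_sites(counts)
        hc = out[out["site_class"].isin(["I", "II"])]
        hc_keys = set(zip(hc["chrom"], hc["pos"]))
        planted = set(zip(truth.edited_sites["chrom"], truth.edited_sites["pos"]))
        assert len(hc_keys & planted) / len(planted) >= 0.95
        assert not hc_keys - planted
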