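"""Simulator tests: genome layout, turnover process, read and qPCR sampling."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

import histurn as h
from histurn.synthetic_chromatin import NAKED, NEW, OLD


# ---------------------------------------------------------------------------
# build_genome
# ---------------------------------------------------------------------------

class TestBuildGenome:
    def test_counts_by_construction(self):
        m = h.build_genome(4, (8, 4, 2, 0.5), 1, seed=0)
        genes = m.genes
        assert len(genes) == 4
        assert sorted(g.passage_rate for g in genes) == [0.5, 2, 4, 8]
        assert len(m.het_domains) == 1

    def test_strands_alternate_and_domains_disjoint(self, default_model):
        genes = sorted(default_model.genes, key=lambda g: g.start)
        assert [g.strand for g in genes[:4]] == ["+", "-", "+", "-"]
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    @pytest.mark.parametrize("n_genes", [0, 3, 5])
    def test_bad_gene_count_is_sizing_error(self, n_genes):
        with pytest.raises(h.SizingError):
            h.build_genome(n_genes, (8, 4, 2, 0.5), 1, seed=0)

    def test_chromosome_too_short_is_sizing_error(self):
        with pytest.raises(h.SizingError):
            h.build_genome(8, (8, 4, 2, 0.5), 0, seed=0, chrom_length=1000)

    def test_non_decreasing_rates_rejected(self):
        with pytest.raises(h.ConfigError):
            h.build_genome(4, (8, 8, 2, 0.5), 1, seed=0)

    def test_same_seed_identical_models(self):
        a = h.build_genome(16, (8, 4, 2, 0.5), 2, seed=7)
        b = h.build_genome(16, (8, 4, 2, 0.5), 2, seed=7)
        assert a == b
        c = h.build_genome(16, (8, 4, 2, 0.5), 2, seed=8)
        assert [d.passage_rate for d in a.genes] != [d.passage_rate for d in c.genes]


# ---------------------------------------------------------------------------
# simulate_turnover
# ---------------------------------------------------------------------------

class TestSimulateTurnover:
    def test_wild_type_keeps_initial_state(self, small_model, sim_cfg):
        state = h.simulate_turnover(small_model, h.get_genotype("WT"), sim_cfg)
        assert state.old_fraction() == 1.0
        assert all(n.occupancy == "OLD" for n in state)

    def test_no_transcription_is_stationary(self, small_model):
        cfg = h.SimConfig(seed=5, epochs=0.0)
        gt = h.get_genotype("spt6D")
        state = h.simulate_turnover(small_model, gt, cfg)
        assert state.old_fraction() == 1.0

    def test_eviction_matches_closed_form_binomial_ci(self):
        """r=0, p0=0.5, 3 forced passages: OLD fraction ~ Binomial(N, 0.125).

        The oracle is the closed form (1 - p0)^n with an exact binomial
        99% interval on the simulated nucleosome count.
        """
        model = h.build_genome(80, (8, 4, 2, 0.5), 0, seed=2)
        cfg = h.SimConfig(seed=13, p0=0.5, p_fill=0.0, p_fill_5prime=0.0)
        state = h.simulate_turnover(
            model, h.get_genotype("spt6D"), cfg, passages=3
        )
        n_total = sum(
            len(state.domain_state(d.id).dyads) for d in model.domains
        )
        n_old = round(state.old_fraction() * n_total)
        p_exact = (1 - 0.5) ** 3
        assert p_exact == 0.125
        lo = stats.binom.ppf(0.005, n_total, p_exact)
        hi = stats.binom.ppf(0.995, n_total, p_exact)
        assert lo <= n_old <= hi

    def test_methylation_never_added(self, small_model):
        """K4me2/K9me2 counts are non-increasing in forced passage count."""
        gt = h.get_genotype("spt6-K20")
        cfg = h.SimConfig(seed=3)

        def methyl_count(state):
            return sum(
                1 for n in state if n.marks & {"K4me2", "K9me2"}
            )

        initial = h.simulate_turnover(small_model, gt, cfg, passages=0)
        counts = [
            methyl_count(h.simulate_turnover(small_model, gt, cfg, passages=n))
            for n in (0, 2, 5, 10)
        ]
        assert counts[0] == methyl_count(initial)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_new_histones_carry_k56ac_only(self, small_model):
        cfg = h.SimConfig(seed=4)
        state = h.simulate_turnover(
            small_model, h.get_genotype("spt6D"), cfg, passages=4
        )
        for n in state:
            if n.occupancy == "NEW":
                assert n.marks == {"K56Ac"}
            elif n.occupancy == "NAKED":
                assert n.marks == set()

    def test_monotone_in_transcription(self, default_model):
        """Mean final OLD fraction per gene is non-increasing in stratum rate."""
        cfg_base = h.SimConfig()
        gt = h.get_genotype("spt6D")
        by_rate = {}
        for seed in range(200):
            state = h.simulate_turnover(
                default_model, gt, dataclasses.replace(cfg_base, seed=seed)
            )
            for g in default_model.genes:
                by_rate.setdefault(g.passage_rate, []).append(
                    state.old_fraction(g.id)
                )
        means = [np.mean(by_rate[r]) for r in sorted(by_rate, reverse=True)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_monotone_in_retention(self, default_model):
        """Mean K4me2 (OLD) density is non-decreasing in retention r."""
        genotypes = [
            h.get_genotype("spt6D"),      # r = 0
            h.get_genotype("spt6-K20"),   # r = 0.5
            h.get_genotype("WT"),         # r = 1
        ]
        means = []
        for gt in genotypes:
            vals = [
                h.simulate_turnover(
                    default_model, gt, h.SimConfig(seed=s), passages=4
                ).old_fraction()
                for s in range(30)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
        assert means[2] == 1.0

    def test_refill_compensates_and_is_k56ac_marked(self, small_model):
        """Occupancy with refilling exceeds occupancy without; the surplus is
        entirely NEW (K56Ac-marked) histones."""
        gt = h.get_genotype("spt6D")
        with_fill = h.simulate_turnover(
            small_model, gt, h.SimConfig(seed=9, p_fill=0.4, p_fill_5prime=0.1),
            passages=5,
        )
        no_fill = h.simulate_turnover(
            small_model, gt, h.SimConfig(seed=9, p_fill=0.0, p_fill_5prime=0.0),
            passages=5,
        )
        assert with_fill.occupied_fraction() > no_fill.occupied_fraction()
        assert no_fill.new_fraction() == 0.0
        assert with_fill.occupied_fraction() == pytest.approx(
            with_fill.old_fraction() + with_fill.new_fraction()
        )

    def test_clr4_inactive_removes_k9me2(self, small_model, sim_cfg):
        state = h.simulate_turnover(
            small_model, h.get_genotype("clr4D"), sim_cfg
        )
        assert all("K9me2" not in n.marks for n in state)


# ---------------------------------------------------------------------------
# sample_chip_reads
# ---------------------------------------------------------------------------

class TestSampleChipReads:
    def test_read_geometry_and_count(self, small_model, sim_cfg):
        state = h.simulate_turnover(small_model, h.get_genotype("WT"), sim_cfg)
        reads = h.sample_chip_reads(state, "input", sim_cfg, n_reads=1000)
        assert len(reads) == 1000
        assert all(r.end - r.start == sim_cfg.read_length for r in reads)

    def test_k9me2_unsampleable_in_clr4_mutant(self, small_model):
        cfg = h.SimConfig(seed=2, background_fraction=0.0)
        state = h.simulate_turnover(small_model, h.get_genotype("clr4D"), cfg)
        with pytest.raises(h.UnsampleableTargetError):
            h.sample_chip_reads(state, "K9me2", cfg, n_reads=100)

    def test_single_occupied_nucleosome_focuses_reads(self, small_model):
        cfg = h.SimConfig(seed=6, background_fraction=0.0)
        state = h.simulate_turnover(small_model, h.get_genotype("WT"), cfg)
        # strip the state down to one occupied nucleosome
        target_dyad = None
        for d in small_model.domains:
            ds = state.domain_state(d.id)
            ds.occupancy[:] = NAKED
        ds = state.domain_state(small_model.genes[3].id)
        ds.occupancy[4] = OLD
        target_dyad = int(ds.dyads[4])
        reads = h.sample_chip_reads(state, "H3", cfg, n_reads=500)
        mids = np.array([(r.start + r.end) // 2 for r in reads])
        assert np.all(np.abs(mids - target_dyad) <= cfg.fragment_length)

    def test_determinism_byte_for_byte(self, small_model, sim_cfg, tmp_path):
        state = h.simulate_turnover(small_model, h.get_genotype("spt6D"), sim_cfg)
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        h.write_reads_bed(h.sample_chip_reads(state, "H3", sim_cfg, n_reads=2000), a)
        h.write_reads_bed(h.sample_chip_reads(state, "H3", sim_cfg, n_reads=2000), b)
        assert a.read_bytes() == b.read_bytes()

    def test_mark_target_tracks_density(self, small_model):
        """K56Ac reads concentrate where NEW histones are (spt6D genes)."""
        cfg = h.SimConfig(seed=21, background_fraction=0.0)
        state = h.simulate_turnover(
            small_model, h.get_genotype("spt6D"), cfg, passages=5
        )
        reads = h.sample_chip_reads(state, "K56Ac", cfg, n_reads=2000)
        new_dyads = np.array(
            [n.dyad for n in state if n.occupancy == "NEW"]
        )
        for r in reads[:200]:
            mid = (r.start + r.end) // 2
            chrom_new = new_dyads  # both chromosomes share the dyad pool
            assert np.min(np.abs(chrom_new - mid)) <= cfg.fragment_length

    def test_sam_round_trip(self, small_model, sim_cfg, tmp_path):
        state = h.simulate_turnover(small_model, h.get_genotype("WT"), sim_cfg)
        reads = h.sample_chip_reads(state, "H3", sim_cfg, n_reads=200)
        path = tmp_path / "reads.sam"
        h.write_reads_sam(reads, small_model.chrom_sizes, path)
        back = h.read_alignments(path, "SAM", small_model.chrom_sizes)
        assert back == reads


# ---------------------------------------------------------------------------
# emit_qpcr_table
# ---------------------------------------------------------------------------

class TestQpcrTable:
    def test_zero_noise_replicates_equal(self, small_model):
        cfg = h.SimConfig(seed=1, noise_cv=0.0)
        state = h.simulate_turnover(small_model, h.get_genotype("WT"), cfg)
        g = small_model.genes[0]
        df = h.emit_qpcr_table(state, [("amp", g.chrom, g.start, g.end)], cfg)
        reps = df[[c for c in df if c.startswith("rep")]]
        assert (reps.nunique(axis=1) == 1).all()
        k4 = df[df["mark"] == "K4me2"].iloc[0]
        assert k4["rep1"] == pytest.approx(1.0 + cfg.background_fraction)

    def test_replicate_count_contract(self, small_model):
        cfg = h.SimConfig(seed=1, qpcr_replicates=3)
        state = h.simulate_turnover(small_model, h.get_genotype("WT"), cfg)
        df = h.emit_qpcr_table(state, [("amp", "chrI", 1000, 2000)], cfg)
        assert {"rep1", "rep2", "rep3"} <= set(df.columns)
        assert "rep4" not in df.columns

    def test_k9me2_is_pure_background_without_clr4(self, small_model):
        cfg = h.SimConfig(seed=1, noise_cv=0.0)
        state = h.simulate_turnover(small_model, h.get_genotype("clr4D"), cfg)
        het = small_model.het_domains[0]
        df = h.emit_qpcr_table(state, [("dg", het.chrom, het.start, het.end)], cfg)
        k9 = df[df["mark"] == "K9me2"].iloc[0]
        assert k9["rep1"] == pytest.approx(cfg.background_fraction)

    def test_empty_amplicon_list_rejected(self, small_model, sim_cfg):
        state = h.simulate_turnover(small_model, h.get_genotype("WT"), sim_cfg)
        with pytest.raises(h.ConfigError):
            h.emit_qpcr_table(state, [], sim_cfg)


def test_genotype_invariants_enforced():
    with pytest.raises(h.ConfigError):
        h.Genotype("WT", retention=0.5)
    with pytest.raises(h.ConfigError):
        h.Genotype("spt6-K20", retention=1.0)
    with pytest.raises(h.ConfigError):
        h.Genotype("x", retention=1.2)
    assert h.get_genotype("spt6Δ").name == "spt6D"


def test_sim_config_validation():
    with pytest.raises(h.ConfigError):
        h.SimConfig(p_fill=0.1, p_fill_5prime=0.2)
    with pytest.raises(h.ConfigError):
        h.SimConfig(read_length=300, fragment_length=250)
    with pytest.raises(h.ConfigError):
        h.SimConfig(p0=1.5)


def test_state_tsv_and_gff3_export(small_model, sim_cfg, tmp_path):
    state = h.simulate_turnover(small_model, h.get_genotype("spt6D"), sim_cfg)
    h.write_state_tsv(state, tmp_path / "state.tsv")
    lines = (tmp_path / "state.tsv").read_text().splitlines()
    assert lines[0] == "domain\tindex\tdyad\toccupancy\tmarks"
    h.write_gff3(small_model, tmp_path / "genes.gff3")
    genes = h.read_gff3(tmp_path / "genes.gff3", small_model.chrom_sizes)
    assert len(genes) == len(small_model.genes)
    assert genes[0].start == small_model.genes[0].start
    assert genes[0].end == small_model.genes[0].end
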