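import numpy as np
import pytest
from scipy import stats

from nbconform import fourc, imaging, splicing, synthetic
from nbconform.genome import GenomicInterval, ToyGenome
from nbconform.synthetic import (
    CellPopulationModel,
    ExpressionModel,
    JunctionModel,
    PlantedArchitecture,
)


class TestGenerateAnnotation:
    def test_degenerate_mixture_labels_everything(self, toy_genome):
        genes = synthetic.generate_genome_annotation(
            toy_genome, {"snoRNA": 1.0}, n_genes=50, seed=1
        )
        assert all(g.gene_class == "snoRNA" for g in genes)

    def test_same_seed_identical_annotation(self, toy_genome):
        a = synthetic.generate_genome_annotation(toy_genome, {"coding": 1.0}, seed=5)
        b = synthetic.generate_genome_annotation(toy_genome, {"coding": 1.0}, seed=5)
        assert a == b

    def test_genes_do_not_overlap_and_fit_genome(self, toy_genome):
        genes = synthetic.generate_genome_annotation(
            toy_genome, {"coding": 0.5, "snRNA": 0.5}, n_genes=150, seed=2
        )
        assert all(toy_genome.contains(g.interval) for g in genes)
        by_chrom: dict = {}
        for g in genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_class_counts_within_binomial_interval(self):
        genome = ToyGenome([("chr1", 20_000_000)])
        genes = synthetic.generate_genome_annotation(
            genome, {"snRNA": 0.1, "coding": 0.9}, n_genes=1_000, seed=3
        )
        n_snrna = sum(g.gene_class == "snRNA" for g in genes)
        lo, hi = stats.binom.interval(0.99, 1_000, 0.1)
        assert lo <= n_snrna <= hi

    def test_invalid_proportions_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            synthetic.generate_genome_annotation(toy_genome, {"coding": 0.7})


class TestSimulate4cReads:
    def test_exactly_n_reads_inside_genome(self, toy_genome):
        arch = synthetic.default_architecture(toy_genome)
        reads = synthetic.simulate_4c_reads(arch, toy_genome, 5_000, seed=1)
        assert len(reads) == 5_000
        assert all(toy_genome.contains(GenomicInterval(r.chrom, r.start, r.end))
                   for r in reads)

    def test_zero_reads_rejected(self, toy_genome):
        arch = synthetic.default_architecture(toy_genome)
        with pytest.raises(ValueError):
            synthetic.simulate_4c_reads(arch, toy_genome, 0)

    def test_flat_architecture_gives_uniform_bins(self):
        """No decay, no peaks, trans level 1: per-bin counts pass a
        chi-square goodness-of-fit test for uniformity at alpha = 0.01."""
        genome = ToyGenome([("chr1", 2_000_000), ("chr2", 1_000_000)])
        arch = PlantedArchitecture(
            bait=GenomicInterval("chr1", 900_000, 910_000),
            decay_exponent=0.0,
            trans_level=1.0,
        )
        reads = synthetic.simulate_4c_reads(arch, genome, 60_000, seed=6)
        # bin by read midpoint (overlap binning double-counts spanning reads)
        mids = np.array([(r.start + r.end) // 2 for r in reads])
        chrom = np.array([r.chrom for r in reads])
        counts = np.concatenate(
            [
                np.bincount(mids[chrom == "chr1"] // 50_000, minlength=40),
                np.bincount(mids[chrom == "chr2"] // 50_000, minlength=20),
            ]
        )
        assert stats.chisquare(counts).pvalue > 0.01

    def test_peak_bins_exceed_flanking_bins(self, toy_genome):
        arch = synthetic.default_architecture(toy_genome)
        reads = synthetic.simulate_4c_reads(arch, toy_genome, 100_000, seed=2)
        counts = fourc.bin_reads(reads, toy_genome)["chr1"].counts
        peak, factor = arch.cis_peaks[0]
        peak_bins = counts[peak.start // 10_000 : peak.end // 10_000]
        flank_left = counts[peak.start // 10_000 - 5 : peak.start // 10_000]
        flank_right = counts[peak.end // 10_000 : peak.end // 10_000 + 5]
        assert peak_bins.mean() > flank_left.mean()
        assert peak_bins.mean() > flank_right.mean()

    def test_same_seed_bitwise_identical(self, toy_genome):
        arch = synthetic.default_architecture(toy_genome)
        a = synthetic.simulate_4c_reads(arch, toy_genome, 2_000, seed=9)
        b = synthetic.simulate_4c_reads(arch, toy_genome, 2_000, seed=9)
        assert a == b

    def test_misplaced_peaks_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="cis"):
            PlantedArchitecture(
                bait=GenomicInterval("chr1", 0, 10_000),
                cis_peaks=[(GenomicInterval("chr2", 0, 10_000), 5.0)],
            ).validate(toy_genome)


class TestSimulateCellSpots:
    def test_full_dependence_classifies_every_cell(self):
        model = CellPopulationModel(n_cells=60, p_dep=1.0, p_indep=0.0)
        sims = synthetic.simulate_cell_spots(model, seed=4)
        tables = [s.table for s in sims]
        pct, _, n = imaging.interaction_frequency(
            tables, lambda label, bridging: label == "CB_dependent"
        )
        assert n == 60 and pct == 100.0

    def test_planted_labels_match_downstream_classification(self):
        model = CellPopulationModel(n_cells=400, p_dep=0.3, p_indep=0.2)
        sims = synthetic.simulate_cell_spots(model, seed=8)
        for sim in sims:
            recs = imaging.min_pairwise_distances(sim.table)
            labels = {
                imaging.classify_rnu1_spot(r["d_gene"], r["d_cb"], r["d_cb_vgoi"])[0]
                for r in recs
            }
            if sim.true_label == "dependent":
                assert "CB_dependent" in labels
            elif sim.true_label == "independent":
                assert "CB_independent" in labels and "CB_dependent" not in labels
            else:
                assert labels == {"none"}

    def test_all_spots_inside_nucleus(self):
        sims = synthetic.simulate_cell_spots(
            CellPopulationModel(n_cells=50, p_dep=0.4, p_indep=0.2), seed=3
        )
        for sim in sims:
            cx, cy = sim.centre
            for spots in sim.table.spots.values():
                for s in spots:
                    assert np.hypot(s.x - cx, s.y - cy) <= sim.radius

    def test_same_seed_identical_tables(self):
        model = CellPopulationModel(n_cells=20)
        a = synthetic.simulate_cell_spots(model, seed=11)
        b = synthetic.simulate_cell_spots(model, seed=11)
        assert [s.table for s in a] == [t.table for t in b]

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            CellPopulationModel(p_dep=0.8, p_indep=0.3).validate()


class TestRendering:
    def test_single_spot_detected_at_planted_pixel(self):
        table = imaging.CellSpotTable(
            "c", {"RNU1": [imaging.Spot("RNU1", 10.0, 12.0, 1.0)], "VGOI": [], "CB": []}
        )
        sim = synthetic.SimulatedCell(table, radius=14.0, centre=(15.0, 15.0),
                                      true_label="none")
        images = synthetic.render_cell(sim, poisson_noise=False)
        mask = images["DAPI"] > 50
        (spot,) = imaging.detect_spots(
            images["RNU1"], imaging.NucleusMask(1, mask, False), "RNU1",
            min_intensity=50,
        )
        assert (spot.x, spot.y) == (10.0, 12.0)


class TestSimulateExpression:
    def test_same_seed_identical_tables(self):
        model = ExpressionModel(n_genes=40)
        a = synthetic.simulate_expression_table(model, seed=2)
        b = synthetic.simulate_expression_table(model, seed=2)
        assert a["fpkm"].equals(b["fpkm"]) and a["counts"].equals(b["counts"])

    def test_missing_controls_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_expression_table(
                ExpressionModel(), conditions=["control_1", "kd"]
            )

    def test_null_effect_gives_near_zero_mean_lfc(self):
        model = ExpressionModel(n_genes=500, kd_effect=0.0, replicate_noise=0.5)
        tables = synthetic.simulate_expression_table(model, seed=5)
        from nbconform import expression as xp

        log2 = xp.log2_average_replicates(
            tables["fpkm"], tables["condition_map"], 0.01
        )
        lfc = log2["kd"] - log2["control_1"]
        assert abs(lfc.mean()) < 3 * lfc.std() / np.sqrt(len(lfc))


class TestSimulateJunctions:
    def _genes(self, n=50):
        genome = ToyGenome([("chr1", 10_000_000)])
        return synthetic.generate_genome_annotation(
            genome, {"coding": 1.0}, n_genes=n, gene_length_range=(3_000, 5_000), seed=1
        )

    def test_zero_rate_gives_zero_unannotated(self):
        model = JunctionModel(genes=self._genes(), unannot_rate={"control": 0.0, "kd": 0.0})
        tables = synthetic.simulate_junction_table(model, ["control", "kd"], seed=2)
        annotated = synthetic.annotated_junction_set(model)
        for junctions in tables.values():
            assert all(j.key in annotated for j in junctions)

    def test_planted_annotation_recovered_exactly(self):
        model = JunctionModel(genes=self._genes())
        tables = synthetic.simulate_junction_table(model, ["control", "kd"], seed=3)
        annotated = synthetic.annotated_junction_set(model)
        df = splicing.classify_annotated(tables["kd"], annotated)
        truth = df.apply(
            lambda row: (row["chrom"], row["donor"], row["acceptor"], row["strand"])
            in annotated,
            axis=1,
        )
        assert (df["annotated"] == truth).all()

    def test_junctions_lie_inside_their_gene(self):
        model = JunctionModel(genes=self._genes())
        tables = synthetic.simulate_junction_table(model, ["control", "kd"], seed=4)
        by_id = {g.gene_id: g.interval for g in model.genes}
        for junctions in tables.values():
            for j in junctions:
                iv = by_id[j.gene_id]
                assert iv.start <= j.donor < j.acceptor <= iv.end

    def test_doubled_rate_raises_unique_count_in_most_runs(self):
        """Monte-Carlo check: with the knockdown unannotated rate doubled,
        the knockdown-unique unannotated junction count exceeds the
        control-unique count in at least 95% of seeded runs."""
        genes = self._genes(200)
        model = JunctionModel(genes=genes, unannot_rate={"control": 0.1, "kd": 0.2})
        annotated = synthetic.annotated_junction_set(model)
        wins = 0
        n_runs = 200
        for seed in range(n_runs):
            tables = synthetic.simulate_junction_table(model, ["control", "kd"], seed=seed)
            uc, uk = splicing.unique_to_condition(
                [tables["control"]], [tables["kd"]]
            )
            uc = {k for k in uc if k not in annotated}
            uk = {k for k in uk if k not in annotated}
            wins += len(uk) > len(uc)
        assert wins / n_runs >= 0.95
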