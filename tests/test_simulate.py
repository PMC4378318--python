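"""Synthetic genome, chromatin model, and library generation."""

import numpy as np
import pytest

import redseq as rs
from redseq.simulate import NUCLEOSOME_CORE_BP


class TestSimulateGenome:
    def test_deterministic(self):
        g1 = rs.simulate_genome(42, 2000)
        g2 = rs.simulate_genome(42, 2000)
        assert g1 == g2
        assert rs.simulate_genome(43, 2000) != g1

    def test_gc_extremes(self):
        g = rs.simulate_genome(1, 1500, gc_fraction=1.0)
        assert set(g["chr1"]) <= {"G", "C"}
        g0 = rs.simulate_genome(1, 1500, gc_fraction=0.0)
        assert set(g0["chr1"]) <= {"A", "T"}

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            rs.simulate_genome(1, 2000, gc_fraction=1.5)

    def test_multi_chromosome_and_planting(self):
        g = rs.simulate_genome(
            5,
            {"chrA": 1200, "chrB": 1500},
            plant={"chrB": [(700, "GGTCC")]},
        )
        assert len(g["chrA"]) == 1200
        assert g["chrB"][700:705] == "GGTCC"
        with pytest.raises(ValueError):
            rs.simulate_genome(5, {"chrA": 1200}, plant={"chrA": [(1198, "GGTCC")]})

    def test_site_density_matches_iid_expectation(self):
        """GGNCC occurrences in 1 Mb of i.i.d. sequence fall within 3 sigma
        of the closed-form k-mer expectation (palindrome: forward only)."""
        gc = 0.42
        g = rs.simulate_genome(11, 1_000_000, gc_fraction=gc)
        index = rs.build_index(g, [rs.BUILTIN_ENZYMES["Sau96I"]])
        p_gc = gc / 2
        per_pos = p_gc**4  # sum over the 4 N-resolutions of G G n C C
        n_pos = 1_000_000 - 4
        expected = n_pos * per_pos
        sigma = np.sqrt(expected)  # Poisson-scale tolerance for weak overlap dependence
        assert abs(len(index) - expected) < 3 * sigma


class TestChromatinModel:
    @pytest.fixture
    def model(self):
        return rs.build_chromatin_model(
            {"chr1": 50_000}, seed=3, nfr_centers={"chr1": [10_000, 30_000]}
        )

    def test_cores_non_overlapping(self, model):
        starts = model.core_start["chr1"]
        assert (np.diff(starts) >= NUCLEOSOME_CORE_BP).all()

    def test_cores_avoid_nfrs(self, model):
        starts = model.core_start["chr1"]
        for s, e in model.nfr["chr1"]:
            inside = (starts + NUCLEOSOME_CORE_BP > s) & (starts < e)
            assert not inside.any()

    def test_linker_lengths_near_mean(self, model):
        starts = model.core_start["chr1"]
        linkers = np.diff(starts) - NUCLEOSOME_CORE_BP
        linkers = linkers[linkers < 100]  # exclude NFR jumps
        assert 20 < linkers.mean() < 40

    def test_regular_spacing_is_phased(self):
        m = rs.build_chromatin_model({"chr1": 20_000}, seed=1, regular_spacing=True)
        gaps = set(np.diff(m.core_start["chr1"]))
        assert gaps == {NUCLEOSOME_CORE_BP + 30}

    def test_accessibility_factors(self, model):
        starts = model.core_start["chr1"]
        canonical = starts[model.core_class["chr1"] == 0]
        # dead center of a canonical core
        a = model.accessibility("chr1", canonical[:5] + 70)
        assert np.allclose(a, model.occlusion)
        # NFR interior
        nfr_mid = (model.nfr["chr1"][0][0] + model.nfr["chr1"][0][1]) // 2
        assert model.accessibility("chr1", np.array([nfr_mid]))[0] == 1.0
        # unknown chromosome: fully accessible
        assert rs.ChromatinModel({}, {}, {}).accessibility("chrZ", np.array([5]))[0] == 1.0

    def test_variant_core_factor(self):
        m = rs.build_chromatin_model(
            {"chr1": 50_000}, seed=3, variant_fraction=1.0, variant_multiplier=5.0
        )
        starts = m.core_start["chr1"]
        a = m.accessibility("chr1", starts + 70)
        assert np.allclose(a, min(1.0, 5.0 * m.occlusion))


class TestCutProbabilities:
    @pytest.fixture
    def setup(self):
        genome = rs.simulate_genome(9, 60_000)
        index = rs.build_index(genome, [rs.BUILTIN_ENZYMES["Sau96I"]])
        model = rs.build_chromatin_model(
            {"chr1": 60_000}, seed=10, nfr_centers={"chr1": [30_000]}
        )
        return genome, index, model

    def test_naked_mode_ignores_chromatin(self, setup):
        _, index, model = setup
        cfg = rs.SimulationConfig(seed=1, p0=0.1, naked_dna=True)
        probs = rs.cut_probabilities(index, model, cfg)
        assert np.allclose(probs, 0.1)

    def test_chromatin_mode_products(self, setup):
        _, index, model = setup
        cfg = rs.SimulationConfig(seed=1, p0=0.1)
        probs = rs.cut_probabilities(index, model, cfg)
        cutpos = index.expected_end_plus()
        a = model.accessibility("chr1", cutpos)
        assert np.allclose(probs, 0.1 * a)
        # occluded sites at p0 * occlusion, open sites at p0
        assert set(np.round(np.unique(probs), 6)) <= {
            round(0.1 * model.occlusion, 6),
            round(0.1 * min(1, model.variant_multiplier * model.occlusion), 6),
            0.1,
        }

    def test_variant_weights_scale(self, setup):
        _, index, model = setup
        model.variant_weights = {"GGTCC": 2.0}
        cfg = rs.SimulationConfig(seed=1, p0=0.1, naked_dna=True)
        probs = rs.cut_probabilities(index, model, cfg)
        is_ggtcc = index.variant == "GGTCC"
        assert np.allclose(probs[is_ggtcc], 0.2)
        assert np.allclose(probs[~is_ggtcc], 0.1)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rs.SimulationConfig(seed=1, p0=0.0)
        with pytest.raises(ValueError):
            rs.SimulationConfig(seed=1, size_select=(300, 200))


class TestGenerateLibrary:
    @pytest.fixture
    def sim(self):
        genome = rs.simulate_genome(17, 80_000)
        index = rs.build_index(genome, [rs.BUILTIN_ENZYMES["Sau96I"]])
        model = rs.build_chromatin_model(
            {"chr1": 80_000}, seed=18, nfr_centers={"chr1": [20_000, 60_000]}
        )
        cfg = rs.SimulationConfig(seed=19, n_molecules=8000, p0=0.05)
        probs = rs.cut_probabilities(index, model, cfg)
        return genome, index, probs, cfg

    def test_same_seed_identical_output(self, sim):
        genome, index, probs, cfg = sim
        r1, t1 = rs.generate_library(genome, index, probs, cfg)
        r2, t2 = rs.generate_library(genome, index, probs, cfg)
        assert r1 == r2
        assert np.array_equal(t1.read_site, t2.read_site)

    def test_reads_carry_barcode_and_signature(self, sim):
        genome, index, probs, cfg = sim
        reads, truth = rs.generate_library(genome, index, probs, cfg)
        assert len(reads) > 100
        for r in reads[:200]:
            assert r.sequence.startswith(cfg.barcode)
            post = r.sequence[len(cfg.barcode) :]
            assert post[0] == "G" and post[2:4] == "CC"  # GNCC signature

    def test_every_read_traces_to_its_site(self, sim):
        genome, index, probs, cfg = sim
        _, truth = rs.generate_library(genome, index, probs, cfg, emit_fastq=False)
        plus = truth.read_strand == "+"
        assert np.array_equal(
            truth.read_five_prime[plus],
            index.expected_end_plus()[truth.read_site[plus]],
        )
        assert np.array_equal(
            truth.read_five_prime[~plus],
            index.expected_end_minus()[truth.read_site[~plus]],
        )

    def test_fragment_sizes_obey_selection(self, sim):
        """No emitted read can come from a cut-to-cut fragment shorter than
        the lower size bound: adjacent-cut spacing caps fragment length."""
        genome, index, probs, cfg = sim
        _, truth = rs.generate_library(genome, index, probs, cfg, emit_fastq=False)
        assert len(truth.read_site) == truth.site_counts(len(index)).sum()

    def test_zero_cuts_raises(self, sim):
        genome, index, _, cfg = sim
        tiny = rs.SimulationConfig(seed=1, n_molecules=1, p0=1e-9)
        with pytest.raises(ValueError):
            rs.generate_library(genome, index, np.full(len(index), 1e-12), tiny)

    def test_truth_outputs_roundtrip(self, sim, tmp_path):
        genome, index, probs, cfg = sim
        _, truth = rs.generate_library(genome, index, probs, cfg, emit_fastq=False)
        bed = tmp_path / "truth.bed"
        truth.write_read_bed(bed)
        table = rs.assign(rs.read_ends_from_bed(bed), index, library="bed")
        assert np.array_equal(table.raw, truth.site_counts(len(index)))


    def test_error_rate_degrades_signature(self, sim):
        genome, index, probs, _ = sim
        cfg = rs.SimulationConfig(
            seed=19, n_molecules=8000, p0=0.05, error_rate=0.2
        )
        reads, _ = rs.generate_library(genome, index, probs, cfg)
        rep = rs.signature_report(
            [rs.FastqRead(r.name, r.sequence[4:], r.quality[4:]) for r in reads],
            rs.BUILTIN_ENZYMES["Sau96I"],
        )
        assert 0.2 < rep.signature_fraction < 0.9  # noisy but not random

    def test_end_to_end_rpm_tracks_truth_probability(self):
        """Recovered per-site RPM correlates with the generating cleavage
        probability (Spearman > 0.9 at isolated sites)."""
        from scipy.stats import spearmanr

        genome = rs.simulate_genome(51, 300_000)
        index = rs.build_index(genome, [rs.BUILTIN_ENZYMES["Sau96I"]])
        # variant weights spread the truth probabilities: with only the three
        # occlusion levels, rank ties cap the achievable correlation
        model = rs.build_chromatin_model(
            {"chr1": 300_000}, seed=52,
            nfr_centers={"chr1": list(range(15_000, 290_000, 15_000))},
            variant_weights={"GGACC": 0.6, "GGCCC": 0.8, "GGGCC": 1.2, "GGTCC": 2.0},
        )
        cfg = rs.SimulationConfig(seed=53, n_molecules=200_000, p0=0.02)
        probs = rs.cut_probabilities(index, model, cfg)
        _, truth = rs.generate_library(genome, index, probs, cfg, emit_fastq=False)
        table = rs.normalize_rpm(
            rs.assign_arrays(
                truth.read_chrom, truth.read_strand, truth.read_five_prime, index
            )
        )
        # isolated sites only: close neighbors distort recovery via size selection
        pos = index.motif_start
        gap_ok = np.ones(len(index), dtype=bool)
        gap_ok[1:] &= np.diff(pos) > 400
        gap_ok[:-1] &= np.diff(pos) > 400
        rho = spearmanr(probs[gap_ok], table.rpm[gap_ok]).statistic
        assert rho > 0.9


class TestSampleCountTable:
    def test_total_and_determinism(self):
        probs = np.array([0.1, 0.2, 0.7])
        t1 = rs.sample_count_table(probs, 10_000, seed=5)
        t2 = rs.sample_count_table(probs, 10_000, seed=5)
        assert t1.total == 10_000
        assert np.array_equal(t1.raw, t2.raw)
        assert t1.raw[2] > t1.raw[0]

    def test_zero_probs_rejected(self):
        with pytest.raises(ValueError):
            rs.sample_count_table(np.zeros(3), 100, seed=1)


class TestEmergentBehaviors:
    def test_variant_weight_recovered_from_naked_library(self):
        """A 2x GGTCC efficiency weight reappears as ~2x mean RPM per site
        relative to the other motif variants in a naked-DNA library."""
        genome = rs.simulate_genome(61, 300_000)
        index = rs.build_index(genome, [rs.BUILTIN_ENZYMES["Sau96I"]])
        model = rs.ChromatinModel({}, {}, {}, variant_weights={"GGTCC": 2.0})
        cfg = rs.SimulationConfig(seed=62, n_molecules=30_000, p0=0.05, naked_dna=True)
        probs = rs.cut_probabilities(index, model, cfg)
        _, truth = rs.generate_library(genome, index, probs, cfg, emit_fastq=False)
        table = rs.normalize_rpm(rs.CutCountTable("naked", truth.site_counts(len(index))))
        summary = rs.variant_cut_frequency(table, index).set_index("variant")
        others = summary.loc[["GGACC", "GGCCC", "GGGCC"], "mean_rpm"].mean()
        ratio = summary.loc["GGTCC", "mean_rpm"] / others
        assert 1.6 < ratio < 2.4


    def test_naked_more_uniform_than_chromatin(self):
        """At equal depth the per-site RPM coefficient of variation is
        strictly smaller for naked DNA than for chromatin."""
        genome = rs.simulate_genome(31, 200_000)
        index = rs.build_index(genome, [rs.BUILTIN_ENZYMES["Sau96I"]])
        model = rs.build_chromatin_model({"chr1": 200_000}, seed=32)
        tables = {}
        for naked in (True, False):
            cfg = rs.SimulationConfig(
                seed=33, n_molecules=20_000, p0=0.05, naked_dna=naked
            )
            probs = rs.cut_probabilities(index, model, cfg)
            _, truth = rs.generate_library(genome, index, probs, cfg, emit_fastq=False)
            table = rs.normalize_rpm(
                rs.CutCountTable("x", truth.site_counts(len(index)))
            )
            tables[naked] = table.rpm
        cv = {k: v.std() / v.mean() for k, v in tables.items()}
        assert cv[True] < cv[False]

    def test_nfr_metaprofile_peaks_at_center(self):
        """Accessibility aggregated over planted NFR centers peaks centrally
        and, with regularly spaced cores, shows phased flanking structure."""
        genome = rs.simulate_genome(41, 400_000)
        index = rs.build_index(genome, [rs.BUILTIN_ENZYMES["Sau96I"]])
        centers = list(range(20_000, 400_000 - 20_000, 10_000))
        model = rs.build_chromatin_model(
            {"chr1": 400_000},
            seed=42,
            nfr_centers={"chr1": centers},
            regular_spacing=True,
        )
        cfg = rs.SimulationConfig(seed=43, n_molecules=60_000, p0=0.05)
        probs = rs.cut_probabilities(index, model, cfg)
        _, truth = rs.generate_library(genome, index, probs, cfg, emit_fastq=False)
        table = rs.normalize_rpm(rs.CutCountTable("chrom", truth.site_counts(len(index))))
        prof = rs.metaprofile(table, model.nfr_features(), index=index)
        v, off = prof.values, prof.offsets
        central = v[(off >= -100) & (off < 100)].mean()
        flanking = v[(off < -600) | (off >= 600)].mean()
        assert central > flanking
        # phasing: linker bins beat the neighboring core-interior bins
        assert central > v[(off >= -300) & (off < -200)].mean()
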