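"""Generator-level checks: composition, determinism, planted structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fmscreen import synthetic as sy
from fmscreen.seqs import revcomp


class TestGenGenomes:
    def test_gc_fraction_within_binomial_ci(self):
        (g,) = sy.gen_genomes(1, 100_000, gc=0.5, seed=1)
        gc = (g.count("G") + g.count("C")) / len(g)
        assert abs(gc - 0.5) < 0.01  # ~6 binomial SDs at n=1e5

    def test_zero_gc_gives_at_only(self):
        (g,) = sy.gen_genomes(1, 100, gc=0.0, seed=7)
        assert set(g) <= {"A", "T"}

    def test_deterministic_given_seed(self):
        assert sy.gen_genomes(2, 500, seed=3) == sy.gen_genomes(2, 500, seed=3)

    @pytest.mark.parametrize("n,length", [(0, 10), (1, 0), (-1, 5)])
    def test_nonpositive_sizes_rejected(self, n, length):
        with pytest.raises(ValueError):
            sy.gen_genomes(n, length)


class TestCloneLibrary:
    def test_planted_pair_shares_exact_substring(self):
        genomes = sy.gen_genomes(1, 120_000, seed=2)
        lib = sy.gen_clone_library(genomes, 2, 20_000, 1_000,
                                   planted_groups=[(2, 6_000)], seed=3)
        a, b = lib.inserts
        # orientation-normalize back to the source strand
        sa = a.sequence if a.source_strand == "+" else revcomp(a.sequence)
        sb = b.sequence if b.source_strand == "+" else revcomp(b.sequence)
        shared = sa[-6_000:]
        assert shared == sb[:6_000]

    def test_no_groups_gives_all_singletons(self):
        genomes = sy.gen_genomes(1, 200_000, seed=2)
        lib = sy.gen_clone_library(genomes, 5, 20_000, 1_000, seed=4)
        assert len(set(lib.truth_regions.values())) == 5

    def test_partition_block_count(self):
        genomes = sy.gen_genomes(1, 600_000, seed=2)
        lib = sy.gen_clone_library(genomes, 10, 20_000, 1_000,
                                   planted_groups=[(4, 8_000), (2, 6_000)], seed=5)
        # 2 planted groups + 4 singletons
        assert len(set(lib.truth_regions.values())) == 6
        assert len(lib.inserts) == 10

    def test_infeasible_allocation_raises(self):
        with pytest.raises(ValueError):
            sy.gen_clone_library(sy.gen_genomes(1, 10_000, seed=1), 5,
                                 20_000, 1_000, seed=1)


class TestPlateLayouts:
    def test_exact_fit_single_plate(self):
        cfg = sy.SimConfig()
        df = sy.gen_plate_layouts(342, cfg)
        assert df.plate_id.nunique() == 1
        assert (df.role == "clone").sum() == 342
        assert (df.role == "control").sum() == 42

    def test_overflow_by_one_spills_to_second_plate(self):
        df = sy.gen_plate_layouts(343, sy.SimConfig())
        assert df.plate_id.nunique() == 2
        # every plate carries the full control set
        assert (df[df.role == "control"].groupby("plate_id").size() == 42).all()

    def test_zero_clones_zero_plates(self):
        assert len(sy.gen_plate_layouts(0, sy.SimConfig())) == 0

    def test_controls_at_fixed_positions(self):
        cfg = sy.SimConfig()
        df = sy.gen_plate_layouts(342, cfg)
        ctl = df[df.role == "control"]
        expect = {(sy.ROW_LETTERS[r], c + 1) for r, c in cfg.control_positions()}
        assert set(zip(ctl.row, ctl.col)) == expect
        assert ctl.clone_id.isna().all()


class TestSimulateScreen:
    def test_zero_effect_actives_match_null(self):
        cfg = sy.SimConfig(active_effect=0.0, null_mean=10, null_sd=1,
                           toxic_fraction=0.0)
        layouts = sy.gen_plate_layouts(342, cfg)
        active = set(layouts.clone_id.dropna())  # all clones "active"
        wells = sy.simulate_screen(layouts, active, cfg, seed=11)
        clones = wells[wells.role == "clone"]
        assert abs(clones.readout.mean() - 10) < 3 * 1 / np.sqrt(len(clones))

    def test_effect_size_shifts_mean_by_planted_sds(self):
        cfg = sy.SimConfig(active_effect=8.0, null_mean=100.0, null_sd=1.0,
                           toxic_fraction=0.0)
        layouts = sy.gen_plate_layouts(342, cfg)
        active = set(sorted(layouts.clone_id.dropna())[:150])
        wells = sy.simulate_screen(layouts, active, cfg, seed=12)
        m = wells[wells.clone_id.isin(active)].readout.mean()
        assert abs(m - 108.0) < 0.5

    def test_replicate_cardinality(self):
        cfg = sy.SimConfig()
        layouts = sy.gen_plate_layouts(50, cfg)
        wells = sy.simulate_screen(layouts, set(), cfg, replicates=4, seed=1)
        per_well = wells.groupby(["plate_id", "row", "col"]).size()
        assert (per_well == 4).all()

    def test_sonar_emits_channel_pairs(self):
        cfg = sy.SimConfig(null_mean=1.0, null_sd=0.05)
        layouts = sy.gen_plate_layouts(50, cfg)
        wells = sy.simulate_screen(layouts, set(), cfg, assay="sonar", seed=2)
        assert wells.f420.notna().all() and wells.f485.notna().all()
        ratio = wells.f420 / wells.f485
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_unknown_assay_rejected(self):
        cfg = sy.SimConfig()
        layouts = sy.gen_plate_layouts(10, cfg)
        with pytest.raises(ValueError):
            sy.simulate_screen(layouts, set(), cfg, assay="luciferase")

    def test_deterministic_given_seed(self):
        cfg = sy.SimConfig()
        layouts = sy.gen_plate_layouts(100, cfg)
        a = sy.simulate_screen(layouts, set(), cfg, seed=9)
        b = sy.simulate_screen(layouts, set(), cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateCells:
    def test_zero_death_probability(self):
        cells = sy.simulate_cells(500, 0.0, 0.5, 1.0, seed=1)
        assert not cells.dead.any()

    def test_zero_puncta_rate(self):
        cells = sy.simulate_cells(500, 0.1, 0.5, 0.0, seed=2)
        assert (cells.puncta == 0).all()

    def test_gfp_fraction_within_binomial_ci(self):
        cells = sy.simulate_cells(10_000, 0.0, 0.3, 0.0, seed=3)
        assert abs(cells.gfp_positive.mean() - 0.30) < 0.02

    def test_dead_cells_carry_no_live_metrics(self):
        cells = sy.simulate_cells(2_000, 0.5, 1.0, 5.0, seed=4)
        dead = cells[cells.dead]
        assert not dead.gfp_positive.any()
        assert (dead.puncta == 0).all()

    def test_negative_cell_count_rejected(self):
        with pytest.raises(ValueError):
            sy.simulate_cells(-1, 0.1, 0.1, 1.0)


class TestTransposonPanel:
    def _panel(self, n_mutants=200, seed=5):
        insert, genes = sy.make_insert_with_operon(3, gene_len=999, seed=1)
        clone = sy.CloneInsert("T01", insert)
        cfg = sy.SimConfig(null_mean=0.05, null_sd=0.01)
        return genes, sy.gen_transposon_panel(clone, genes, 1, n_mutants, cfg,
                                              seed=seed)

    def test_inactive_iff_inside_effector_gene(self):
        genes, (mutants, _) = self._panel()
        gs, ge = genes[1]
        inside = (mutants.insertion_pos >= gs) & (mutants.insertion_pos < ge)
        assert (mutants.truth_inactive == inside).all()

    def test_inactive_count_tracks_gene_fraction(self):
        insert, genes = sy.make_insert_with_operon(1, gene_len=999, flank=4_500,
                                                   seed=2)
        clone = sy.CloneInsert("T02", insert)
        cfg = sy.SimConfig()
        mutants, _ = sy.gen_transposon_panel(clone, genes, 0, 200, cfg, seed=6)
        frac = 999 / (len(insert) - 200)
        expected = 200 * frac
        assert abs(mutants.truth_inactive.sum() - expected) <= 3 * np.sqrt(
            200 * frac * (1 - frac)) + 1

    def test_flanking_reads_are_3prime_of_insertion(self):
        genes, (mutants, reads) = self._panel(n_mutants=20)
        insert, _ = sy.make_insert_with_operon(3, gene_len=999, seed=1)
        fwd = rc = 0
        for row in mutants.itertuples():
            expect = insert[row.insertion_pos:row.insertion_pos + 200]
            got = reads[row.mutant_id]
            assert got in (expect, revcomp(expect))
            if got == expect:
                fwd += 1
            else:
                rc += 1
        assert fwd > 0 and rc > 0

    def test_zero_mutants_rejected(self):
        genes, _ = self._panel(n_mutants=1)
        insert, g = sy.make_insert_with_operon(3, seed=1)
        with pytest.raises(ValueError):
            sy.gen_transposon_panel(sy.CloneInsert("T", insert), g, 0, 0,
                                    sy.SimConfig())


class TestPatientCatalogs:
    def test_zero_mutation_plants_exact_copy(self):
        q = ["MKV" * 100]
        cats = sy.gen_patient_catalogs(1, q, {0: [(0, 0.0)]}, 2, seed=1)
        planted = [s for name, s in cats[0] if "hom" in name]
        assert planted == q

    def test_substitution_count_near_binomial_mean(self):
        rng = np.random.default_rng(8)
        query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        cats = sy.gen_patient_catalogs(1, [query], {0: [(0, 0.05)]}, 0, seed=2)
        (name, hom), = cats[0]
        n_sub = sum(a != b for a, b in zip(query, hom))
        assert abs(n_sub - 15) <= 8

    def test_no_planting_gives_decoys_only(self):
        cats = sy.gen_patient_catalogs(3, ["MKVLA" * 30], {}, 4, seed=3)
        assert all(all("decoy" in name for name, _ in cat) for cat in cats)
        assert all(len(cat) == 4 for cat in cats)

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            sy.gen_patient_catalogs(1, [], {}, 2)
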