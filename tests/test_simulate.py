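"""Synthetic study generator: kinetics, oxidation, rendering, determinism."""

import numpy as np
import pandas as pd
import pytest

from mbecflow import simulate as sim
from mbecflow.cytometry import DEFAULT_CHANNEL_MAP, merge_mb_channel
from mbecflow.spectra import default_model

NEU = sim.DEFAULT_POPULATIONS["neutrophil"]
MON = sim.DEFAULT_POPULATIONS["monocyte"]
MAC = sim.DEFAULT_POPULATIONS["macrophage"]
TCELL = sim.DEFAULT_POPULATIONS["T"]


class TestBacteriaPerCell:
    def test_zero_moi_or_time_gives_zero_counts(self):
        assert sim.simulate_bacteria_per_cell(NEU, 1.0, 0.0, n_cells=100).sum() == 0
        assert sim.simulate_bacteria_per_cell(NEU, 0.0, 10.0, n_cells=100).sum() == 0

    def test_nonphagocytic_cells_never_ingest(self):
        counts = sim.simulate_bacteria_per_cell(TCELL, 24.0, 100.0, n_cells=2000, seed=1)
        assert counts.sum() == 0

    def test_cytochalasin_b_suppresses_mean_50_fold(self):
        n = 10_000
        veh = sim.simulate_bacteria_per_cell(NEU, 1.0, 30.0, "none", seed=2, n_cells=n)
        cytb = sim.simulate_bacteria_per_cell(NEU, 1.0, 30.0, "cytochalasinB",
                                              seed=2, n_cells=n)
        lam = NEU.phagocytic_rate * 30.0 * (1.0 / 1.5)
        se = 3 * np.sqrt(lam * 0.02 / n)
        assert cytb.mean() / veh.mean() == pytest.approx(0.02, abs=se / lam + 0.005)

    def test_mean_nondecreasing_in_time_and_moi(self):
        times = [0.25, 0.5, 1.0, 2.0]
        mois = [1.0, 3.0, 10.0, 30.0]
        means = np.array([
            [sim.simulate_bacteria_per_cell(NEU, t, m, seed=7, n_cells=5000).mean()
             for m in mois] for t in times])
        assert np.all(np.diff(means, axis=0) > -0.05)
        assert np.all(np.diff(means, axis=1) > 0)

    def test_population_phagocytic_ordering(self):
        order = [NEU, MAC, MON, TCELL]
        means = [sim.simulate_bacteria_per_cell(p, 1.0, 10.0, seed=3, n_cells=5000).mean()
                 for p in order]
        assert means[0] > means[2] and means[1] > means[2] and means[3] == 0.0


class TestOxidation:
    def test_zero_rate_gives_zero_rho(self):
        times = [np.array([0.1, 0.5]), np.array([]), np.array([1.0])]
        rho = sim.simulate_oxidation(times, k_ox=0.0, time_h=2.0)
        np.testing.assert_array_equal(rho, 0.0)

    def test_infinite_rate_limit_saturates(self):
        rho = sim.simulate_oxidation([np.array([0.0])], k_ox=1e9, time_h=1.0)
        assert rho[0] == pytest.approx(1.0)

    def test_closed_form_per_bacterium(self):
        rho = sim.simulate_oxidation([np.array([0.0, 1.0])], k_ox=0.5, time_h=2.0)
        expected = np.mean(1 - np.exp(-0.5 * np.array([2.0, 1.0])))
        assert rho[0] == pytest.approx(expected)

    def test_affected_genotype_rho_zero_at_any_time(self):
        spec = sim.SampleSpec(sample_id="aff", time_h=3.0, moi=10.0,
                              genotype="CGD_affected",
                              n_events={"neutrophil": 2000}, seed=9)
        ev = sim.render_events(spec)
        assert (ev["rho"] == 0).all()

    def test_carrier_is_half_mosaic_with_intermediate_mean(self):
        mk = lambda g, s: sim.render_events(sim.SampleSpec(
            sample_id=g, time_h=3.0, moi=10.0, genotype=g,
            n_events={"neutrophil": 3000}, seed=s))
        healthy = mk("healthy", 21)
        carrier = mk("CGD_carrier", 21)
        eaten = carrier[carrier.bacteria_count > 0]
        zero_frac = (eaten["rho"] == 0).mean()
        assert zero_frac == pytest.approx(0.5, abs=0.05)
        ratio = carrier["rho"].mean() / healthy["rho"].mean()
        assert ratio == pytest.approx(0.5, abs=0.1)


class TestRenderEvents:
    def test_no_label_no_autofluorescence_no_noise_is_exactly_zero(self, model):
        pops = {"neutrophil": sim.CellPopulationSpec(
            name="neutrophil", phagocytic_rate=1.5, oxidation_rate=0.5,
            autofluorescence_density=0.0, fsc_mean=600, fsc_sd=50,
            ssc_mean=600, ssc_sd=50, marker_means={})}
        spec = sim.SampleSpec(sample_id="none", label="none", time_h=1.0,
                              n_events={"neutrophil": 100}, seed=0, noise_cv=0.0)
        ev = sim.render_events(spec, model=model, pops=pops)
        for c in sim.MB_CHANNELS:
            assert (ev[c] == 0).all()

    def test_same_seed_identical_tables(self):
        spec = sim.SampleSpec(sample_id="x", time_h=1.0, moi=10.0,
                              n_events=dict(sim.MIXED_LEUKOCYTES), seed=123)
        pd.testing.assert_frame_equal(sim.render_events(spec), sim.render_events(spec))

    def test_unknown_population_rejected(self):
        spec = sim.SampleSpec(sample_id="x", n_events={"dendritic": 10}, seed=0)
        with pytest.raises(KeyError):
            sim.render_events(spec)

    def test_blister_exceeds_matched_blood_neutrophil_mb(self, model):
        common = dict(time_h=24.0, moi=sim.INVIVO_MOI, label="MBEC",
                      n_events={"neutrophil": 2000}, seed=77, mode="conventional")
        blister = sim.render_events(sim.SampleSpec(sample_id="bl", compartment="blister",
                                                   **common), model=model)
        blood = sim.render_events(sim.SampleSpec(sample_id="bd", compartment="blood",
                                                 **common), model=model)
        cmap = DEFAULT_CHANNEL_MAP
        bl_med = merge_mb_channel(blister, cmap)[cmap.merged].median()
        bd_med = merge_mb_channel(blood, cmap)[cmap.merged].median()
        assert bl_med > bd_med

    def test_unlabeled_bacteria_leave_mb_at_autofluorescence(self, model):
        spec = sim.SampleSpec(sample_id="u", label="unlabeled_E_coli", time_h=1.0,
                              moi=30.0, n_events={"neutrophil": 2000}, seed=5)
        ev = sim.render_events(spec, model=model)
        af = sim.DEFAULT_POPULATIONS["neutrophil"].autofluorescence_density * 30.0
        assert ev["AF647"].mean() == pytest.approx(af, rel=0.05)

    def test_activation_markers_independent_of_label(self, model):
        """MBEC and unlabeled E. coli produce the same activation shifts."""
        mk = lambda label: sim.render_events(sim.SampleSpec(
            sample_id=label, label=label, time_h=1.0, moi=5.0,
            n_events={"neutrophil": 4000}, seed=31), model=model)
        mbec, unlab = mk("MBEC"), mk("unlabeled_E_coli")
        for marker in ("CD11b", "CD66b", "CD45", "CD62L"):
            ratio = np.log(mbec[marker]).mean() - np.log(unlab[marker]).mean()
            assert abs(ratio) < 0.05, marker

    def test_permeabilization_reduces_load_tenfold(self, model):
        mk = lambda pert, s: sim.render_events(sim.SampleSpec(
            sample_id=pert, label="MBEC", time_h=1.0, moi=30.0, perturbation=pert,
            n_events={"neutrophil": 3000}, seed=s, noise_cv=0.0), model=model)
        intact = mk("none", 41)
        perm = mk("permeabilization", 41)
        af = sim.DEFAULT_POPULATIONS["neutrophil"].autofluorescence_density * 30.0
        signal = lambda t: (t["AF647"] - af).clip(lower=0).mean()
        assert signal(perm) / signal(intact) == pytest.approx(0.1, abs=0.02)


class TestGenerateStudy:
    def test_exvivo_design_layout(self, exvivo_study):
        meta = exvivo_study["metadata"]
        labeled = meta[meta.sample_id.str.startswith("EX_MBEC")]
        assert sorted(labeled.time_h) == [0.0, 0.25, 0.5, 0.75, 1.0]
        assert (meta.label == "unlabeled_E_coli").any()
        assert set(labeled.fmo_control_id) == {"EX_FMO"}

    def test_invivo_design_has_38_blister_points_and_paired_blood(self, invivo_study):
        meta = invivo_study["metadata"]
        blisters = meta[(meta.compartment == "blister") & (meta.label == "MBEC")]
        assert len(blisters) == 38
        per_time = blisters.groupby("time_h").size()
        assert sorted(per_time.index) == [3.0, 5.0, 7.0, 9.0, 24.0]
        assert set(per_time) <= {7, 8}
        bloods = meta[(meta.compartment == "blood") & (meta.label == "MBEC")]
        assert len(bloods) == 38

    def test_truth_tables_byte_identical_for_same_seed(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        sim.generate_study("moi", a, seed=99)
        sim.generate_study("moi", b, seed=99)
        assert (a / "truth.csv").read_bytes() == (b / "truth.csv").read_bytes()
        assert (a / "metadata.csv").read_bytes() == (b / "metadata.csv").read_bytes()

    def test_zero_event_population_yields_valid_files(self, tmp_path):
        spec = sim.SampleSpec(sample_id="sparse", time_h=1.0, moi=10.0,
                              n_events={"neutrophil": 500, "T": 0}, seed=1)
        sim.generate_study([spec], tmp_path, seed=1)
        from mbecflow.fcsio import read_fcs
        table, _ = read_fcs(tmp_path / "sparse.fcs")
        assert len(table) == 500

    def test_truth_columns_never_in_fcs(self, exvivo_study):
        from mbecflow.fcsio import read_fcs
        meta = exvivo_study["metadata"]
        table, _ = read_fcs(exvivo_study["study_dir"] / meta.filename.iloc[0])
        for col in ("population", "bacteria_count", "rho"):
            assert col not in table.columns

    def test_ground_truth_monotone_in_time_and_moi(self, tmp_path):
        grid_t = [0.25, 0.5, 1.0, 2.0]
        grid_m = [1.0, 3.0, 10.0, 30.0]
        means = np.zeros((4, 4))
        for i, t in enumerate(grid_t):
            for j, m in enumerate(grid_m):
                ev = sim.render_events(sim.SampleSpec(
                    sample_id=f"g{i}{j}", time_h=t, moi=m,
                    n_events={"neutrophil": 5000}, seed=50 + 10 * i + j))
                means[i, j] = ev.bacteria_count.mean()
        assert np.all(np.diff(means, axis=0) > 0)
        assert np.all(np.diff(means, axis=1) > 0)

    def test_endotoxin_track_decreases_with_time(self, invivo_study):
        meta = invivo_study["metadata"]
        bl = meta[(meta.compartment == "blister") & (meta.label == "MBEC")]
        endo = bl.groupby("time_h")["endotoxin_eu_ml"].mean().sort_index()
        assert np.all(np.diff(endo.to_numpy()) < 0)
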