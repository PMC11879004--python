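"""Event-level primitives: merging, MFI, FMO gating, red shift, scatter gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mbecflow import simulate as sim
from mbecflow.cytometry import (
    DEFAULT_CHANNEL_MAP,
    GRANULOCYTE_GATE,
    GateDefinition,
    classify_mb,
    fmo_threshold,
    geometric_mfi,
    merge_mb_channel,
    read_events,
    redshift_ratio,
    scatter_gate,
    spectral_to_conventional,
)
from mbecflow.spectra import predict_redshift_ratio

CMAP = DEFAULT_CHANNEL_MAP


def table_of(af647, af700, apccy7, **extra):
    return pd.DataFrame({"AF647": af647, "AF700": af700, "APC-Cy7": apccy7, **extra})


class TestMergeMbChannel:
    def test_per_event_sum(self):
        t = merge_mb_channel(table_of([100.0, 0.0], [50.0, 0.0], [25.0, 0.0]), CMAP)
        np.testing.assert_allclose(t[CMAP.merged], [175.0, 0.0])

    def test_negative_values_clipped_before_merge(self):
        t = merge_mb_channel(table_of([-5.0], [10.0], [20.0]), CMAP)
        assert t[CMAP.merged].iloc[0] == 30.0

    def test_missing_source_channel_named(self):
        with pytest.raises(KeyError, match="AF700"):
            merge_mb_channel(pd.DataFrame({"AF647": [1.0], "APC-Cy7": [1.0]}), CMAP)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_merged_mfi_dominates_components(self, seed):
        rng = np.random.default_rng(seed)
        t = table_of(*(rng.lognormal(2, 1, 100) for _ in range(3)))
        merged = merge_mb_channel(t, CMAP)
        m = geometric_mfi(merged[CMAP.merged])
        assert all(m >= geometric_mfi(t[c]) for c in CMAP.sources)

    def test_merge_commutes_with_row_subsetting(self):
        rng = np.random.default_rng(8)
        t = table_of(*(rng.lognormal(2, 1, 300) for _ in range(3)),
                     FSC=rng.uniform(0, 1000, 300), SSC=rng.uniform(0, 1000, 300))
        gate = GateDefinition("scatter_box", ("FSC", "SSC"), (200.0, 800.0, 100.0, 900.0))
        a = merge_mb_channel(scatter_gate(t, gate), CMAP)[CMAP.merged]
        b = scatter_gate(merge_mb_channel(t, CMAP), gate)[CMAP.merged]
        pd.testing.assert_series_equal(a, b)


class TestGeometricMfi:
    def test_known_values(self):
        assert geometric_mfi([10.0, 1000.0]) == pytest.approx(100.0)
        assert geometric_mfi([42.0, 42.0, 42.0]) == pytest.approx(42.0)

    def test_scale_equivariant_above_floor(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(3, 0.5, 500) + 2.0
        assert geometric_mfi(3 * v) == pytest.approx(3 * geometric_mfi(v), rel=1e-9)

    def test_empty_rejected_floor_warned(self):
        with pytest.raises(ValueError):
            geometric_mfi([])
        with pytest.warns(UserWarning):
            assert geometric_mfi([0.0, 0.5]) == 1.0


class TestFmoThreshold:
    def test_matches_analytic_lognormal_quantile(self):
        mu, sigma, n = 3.0, 0.5, 100_000
        rng = np.random.default_rng(12)
        control = pd.DataFrame({"MB_merged": rng.lognormal(mu, sigma, n)})
        gate = fmo_threshold(control, "MB_merged", percentile=99.5)
        analytic = float(stats.lognorm.ppf(0.995, s=sigma, scale=np.exp(mu)))
        # Monte-Carlo error of an empirical 99.5% quantile at n = 1e5
        q = 0.995
        dens = stats.lognorm.pdf(analytic, s=sigma, scale=np.exp(mu))
        se = np.sqrt(q * (1 - q) / n) / dens
        assert gate.threshold == pytest.approx(analytic, abs=4 * se)
        assert gate.provenance == "FMO-derived"

    def test_self_application_respects_percentile(self):
        rng = np.random.default_rng(4)
        control = pd.DataFrame({"MB_merged": rng.lognormal(2, 0.4, 20_000)})
        gate = fmo_threshold(control, "MB_merged", percentile=99.5)
        _, counts = classify_mb(control, gate)
        assert counts["MB_hi"] / len(control) <= 0.005 + 3 * np.sqrt(0.005 / 20_000)

    def test_percentile_100_is_the_maximum(self):
        control = pd.DataFrame({"MB_merged": np.linspace(1, 500, 500)})
        gate = fmo_threshold(control, "MB_merged", percentile=100)
        assert gate.threshold == 500.0

    def test_small_control_rejected(self):
        control = pd.DataFrame({"MB_merged": np.ones(150)})
        with pytest.raises(ValueError, match="200"):
            fmo_threshold(control, "MB_merged")


class TestClassifyMb:
    def test_partition_exhaustive_and_order_independent(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame({"MB_merged": rng.lognormal(3, 1, 1000)})
        gate = GateDefinition("threshold_1d", ("MB_merged",), (30.0,))
        _, counts = classify_mb(t, gate)
        assert counts["MB_hi"] + counts["MB_lo"] == 1000
        shuffled = t.sample(frac=1, random_state=0)
        _, counts2 = classify_mb(shuffled, gate)
        assert counts == counts2

    def test_empty_table_zero_counts(self):
        gate = GateDefinition("threshold_1d", ("MB_merged",), (30.0,))
        _, counts = classify_mb(pd.DataFrame({"MB_merged": []}), gate)
        assert counts == {"MB_hi": 0, "MB_lo": 0}


class TestRedshiftRatio:
    @pytest.mark.parametrize("rho", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_noise_free_rendering_matches_closed_form(self, model, rho):
        """End-to-end oracle: measured APC-Cy7:AF647 MFI ratio of noise-free
        events equals the spectral model's prediction."""
        t = merge_mb_channel(sim.render_fixed(model, rho, load=800, n_events=200), CMAP)
        assert redshift_ratio(t, CMAP) == pytest.approx(
            predict_redshift_ratio(model, rho), abs=1e-6)

    def test_monotone_in_rho_under_rendering(self, model):
        lo = redshift_ratio(sim.render_fixed(model, 0.2, 800, 100), CMAP)
        hi = redshift_ratio(sim.render_fixed(model, 0.8, 800, 100), CMAP)
        assert hi > lo

    def test_brightness_invariance(self, model):
        t = sim.render_fixed(model, 0.5, 800, 300, noise_cv=0.2, seed=6)
        ratio = redshift_ratio(t, CMAP)
        scaled = t * 7.0
        assert redshift_ratio(scaled, CMAP) == pytest.approx(ratio, rel=1e-9)

    def test_af647_at_floor_rejected(self):
        t = table_of([0.1, 0.2], [1.0, 1.0], [5.0, 5.0])
        with pytest.raises(ValueError, match="floor"):
            redshift_ratio(t, CMAP)


class TestScatterGate:
    def test_full_box_is_identity_disjoint_box_is_empty(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({"FSC": rng.uniform(0, 1000, 200),
                          "SSC": rng.uniform(0, 1000, 200)})
        full = GateDefinition("scatter_box", ("FSC", "SSC"), (0.0, 1e9, 0.0, 1e9))
        assert len(scatter_gate(t, full)) == 200
        disjoint = GateDefinition("scatter_box", ("FSC", "SSC"), (2e3, 3e3, 2e3, 3e3))
        with pytest.warns(UserWarning):
            assert scatter_gate(t, disjoint).empty

    def test_granulocyte_box_purity_on_default_blood(self, model):
        spec = sim.SampleSpec(sample_id="bd", compartment="blood", time_h=3.0,
                              moi=2.0, label="MBEC",
                              n_events=dict(sim.BLOOD_COUNTS), seed=15)
        ev = sim.render_events(spec, model=model)
        gated = scatter_gate(ev, GRANULOCYTE_GATE)
        purity = gated["population"].isin(["neutrophil", "eosinophil"]).mean()
        assert purity >= 0.90


class TestReadEvents:
    def test_round_trips_generated_study_counts(self, exvivo_study):
        meta = exvivo_study["metadata"]
        row = meta.iloc[0]
        t = read_events(exvivo_study["study_dir"] / row.filename)
        truth = pd.read_csv(exvivo_study["study_dir"] / "truth.csv")
        assert len(t) == (truth.sample_id == row.sample_id).sum()

    def test_missing_required_channel_named(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame({"AF647": [1.0]}).to_csv(p, index=False)
        with pytest.raises(KeyError, match="APC-Cy7"):
            read_events(p, required=("AF647", "APC-Cy7"))

    def test_spectral_to_conventional_recovers_band_sums(self, model):
        t = sim.render_fixed(model, 0.3, 500, 50, mode="spectral")
        conv = spectral_to_conventional(t, CMAP)
        # 10 nm bins tile the windows exactly except AF647 (655-685) and the
        # APC-Cy7 lower edge; overlap weighting keeps totals close
        direct = sim.render_fixed(model, 0.3, 500, 50, mode="conventional")
        for c in CMAP.sources:
            assert conv[c].mean() == pytest.approx(direct[c].mean(), rel=0.1)
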