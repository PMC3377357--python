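"""ODE core: algebraic blood/lung identities, mass balance, solver checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcmpbpk.errors import ConfigError
from bcmpbpk.kinetics import MetabolicParamsTwoPathway, MetabolicParamsTwoSite
from bcmpbpk.model import (
    ClosedChamberConfig,
    ModelState,
    arterial_concentration,
    make_rhs,
    mass_balance_residual,
    rhs,
    simulate,
    venous_concentration,
)
from bcmpbpk.physiology import TISSUES, ppm_to_mg_per_liter

QC, QP, PB = 5.3033008588991066, 9.015611460128481, 41.5


def equilibrium_chamber_mgl(cfg):
    """Closed-form no-metabolism partition equilibrium (air equivalents)."""
    d = cfg.derived
    a0 = ppm_to_mg_per_liter(cfg.c0_ppm, cfg.chemical.mw) * cfg.v_chamber
    body_air_volume = cfg.n_rats * cfg.chemical.p_blood_air * sum(
        d.volumes[t] * cfg.chemical.tissue_blood_partitions[t] for t in TISSUES
    )
    return a0 / (cfg.v_chamber + body_air_volume)


class TestBloodAlgebra:
    def test_equilibrium_fixed_point(self):
        c_ch = 2.0
        c_ven = PB * c_ch
        assert arterial_concentration(c_ven, c_ch, QC, QP, PB) == pytest.approx(
            c_ven, rel=1e-12
        )

    def test_zero_inputs(self):
        assert arterial_concentration(0.0, 0.0, QC, QP, PB) == 0.0

    def test_inhalation_only_worked_value(self):
        c_art = arterial_concentration(0.0, 1.0, QC, QP, PB)
        assert c_art == pytest.approx(QP / (QC + QP / PB), rel=1e-12)
        assert c_art == pytest.approx(1.6331, rel=1e-4)

    def test_venous_is_flow_weighted_tissue_outflow(self, cfg_two_pathway):
        d = cfg_two_pathway.derived
        parts = cfg_two_pathway.chemical.tissue_blood_partitions
        zeros = {t: 0.0 for t in TISSUES}
        assert venous_concentration(zeros, d.flows, parts, d.qc) == 0.0
        # full equilibrium at common blood concentration c
        c = 3.7
        eq = {t: parts[t] * c for t in TISSUES}
        assert venous_concentration(eq, d.flows, parts, d.qc) == pytest.approx(c, rel=1e-12)
        # single perfused tissue contributes its flow-weighted share
        one = dict(zeros, liver=parts["liver"] * 1.0)
        expected = d.flows["liver"] / d.qc
        assert venous_concentration(one, d.flows, parts, d.qc) == pytest.approx(
            expected, rel=1e-12
        )

    def test_mismatched_keys_rejected(self, cfg_two_pathway):
        d = cfg_two_pathway.derived
        parts = cfg_two_pathway.chemical.tissue_blood_partitions
        with pytest.raises(ValueError):
            venous_concentration({"liver": 1.0}, d.flows, parts, d.qc)


class TestRhs:
    def test_zero_state_zero_derivative(self, cfg_two_pathway):
        ds = rhs(0.0, ModelState.zero(), cfg_two_pathway)
        assert ds.to_vector() == pytest.approx(np.zeros(10), abs=0.0)

    @pytest.mark.parametrize("hypothesis", ["two_pathway", "two_site"])
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(state=st.lists(st.floats(0.0, 50.0), min_size=6, max_size=6))
    def test_total_mass_is_conserved_analytically(self, hypothesis, state):
        # d/dt of chamber + n*(tissue burden + metabolised) + leak is exactly 0
        met = (
            MetabolicParamsTwoPathway()
            if hypothesis == "two_pathway"
            else MetabolicParamsTwoSite()
        )
        cfg = ClosedChamberConfig(hypothesis=hypothesis, metabolic=met)
        y = np.zeros(10)
        y[:6] = state
        dy = make_rhs(cfg)(0.0, y)
        vols = cfg.derived.volumes
        vol_arr = np.array([vols[t] for t in TISSUES])
        d_total = (
            dy[0]
            + cfg.n_rats * (vol_arr @ dy[1:6] + dy[6] + dy[7])
            + dy[9]
        )
        scale = max(1.0, np.max(np.abs(dy)))
        assert abs(d_total) / scale < 1e-12

    def test_named_and_vector_rhs_agree(self, cfg_two_site):
        y = np.array([5.0, 1.0, 2.0, 0.5, 3.0, 0.2, 0.0, 0.0, 0.0, 0.0])
        named = rhs(0.0, ModelState.from_vector(y), cfg_two_site).to_vector()
        fast = make_rhs(cfg_two_site)(0.0, y)
        assert fast == pytest.approx(named, rel=1e-12)

    def test_wrong_metabolic_type_rejected(self):
        with pytest.raises(ConfigError):
            ClosedChamberConfig(hypothesis="two_site", metabolic=MetabolicParamsTwoPathway())
        with pytest.raises(ConfigError):
            ClosedChamberConfig(hypothesis="mm_only")


class TestSimulate:
    def test_zero_dose_gives_zero_trajectory(self, cfg_two_pathway):
        r = simulate(cfg_two_pathway.replace(c0_ppm=0.0), t_end=2.0)
        assert np.all(r.chamber_ppm == 0)
        assert all(np.all(v == 0) for v in r.c_tissue.values())

    @pytest.mark.parametrize("hypothesis", ["two_pathway", "two_site"])
    @pytest.mark.parametrize("c0", [200.0, 4000.0])
    def test_mass_balance_closes(self, hypothesis, c0):
        met = (
            MetabolicParamsTwoPathway()
            if hypothesis == "two_pathway"
            else MetabolicParamsTwoSite()
        )
        cfg = ClosedChamberConfig(c0_ppm=c0, hypothesis=hypothesis, metabolic=met)
        r = simulate(cfg)
        assert np.max(np.abs(mass_balance_residual(r))) < 1e-6

    def test_chamber_declines_monotonically(self, cfg_two_pathway):
        r = simulate(cfg_two_pathway)
        assert np.all(np.diff(r.chamber_ppm) <= 1e-9)
        assert np.all(r.chamber_ppm >= -1e-12)

    def test_no_metabolism_reaches_partition_equilibrium(self):
        # negligible saturable capacity, no GST, sealed chamber
        cfg = ClosedChamberConfig(
            c0_ppm=1000.0,
            k_loss=0.0,
            metabolic=MetabolicParamsTwoPathway(vmax=1e-12, km=0.35, kgst=0.0),
        )
        r = simulate(cfg, t_end=20.0)
        c_eq = equilibrium_chamber_mgl(cfg)
        assert r.chamber_mgl[-1] == pytest.approx(c_eq, rel=1e-6)

    def test_linear_kinetics_scale_with_dose(self):
        cfg = ClosedChamberConfig(
            c0_ppm=100.0,
            metabolic=MetabolicParamsTwoPathway(vmax=1e-12, km=0.35, kgst=4.7),
        )
        r1 = simulate(cfg)
        r2 = simulate(cfg.replace(c0_ppm=200.0))
        assert r2.chamber_mgl == pytest.approx(2 * r1.chamber_mgl, rel=1e-6)

    def test_two_site_without_effector_matches_two_pathway_without_gst(self):
        tp = ClosedChamberConfig(
            c0_ppm=500.0, metabolic=MetabolicParamsTwoPathway(3.8, 0.35, 0.0)
        )
        ts = ClosedChamberConfig(
            c0_ppm=500.0,
            hypothesis="two_site",
            metabolic=MetabolicParamsTwoSite(3.8, 0.35, 0.0),
        )
        ra, rb = simulate(tp), simulate(ts)
        assert rb.chamber_mgl == pytest.approx(ra.chamber_mgl, rel=1e-6)

    def test_saturation_reduces_fractional_metabolism(self):
        # Michaelis-Menten only: the fraction of the dose metabolised by a
        # fixed time falls as the starting concentration rises
        fractions = []
        for c0 in (200.0, 500.0, 1000.0, 2000.0, 4000.0):
            cfg = ClosedChamberConfig(
                c0_ppm=c0, metabolic=MetabolicParamsTwoPathway(3.8, 0.35, 0.0)
            )
            r = simulate(cfg, t_grid=np.array([2.0]))
            a0 = ppm_to_mg_per_liter(c0, cfg.chemical.mw) * cfg.v_chamber
            fractions.append(
                cfg.n_rats * (r.a_met_liver[-1] + r.a_met_kidney[-1]) / a0
            )
        assert np.all(np.diff(fractions) < 0)

    def test_stiff_solver_matches_fixed_step_rk4(self, cfg_two_pathway):
        # brute-force oracle: classical RK4 at dt = 1e-4 hr over 0.5 hr
        f = make_rhs(cfg_two_pathway)
        dt, n = 1e-4, 5000
        y = np.zeros(10)
        y[0] = (
            ppm_to_mg_per_liter(cfg_two_pathway.c0_ppm, cfg_two_pathway.chemical.mw)
            * cfg_two_pathway.v_chamber
        )
        keep = {}
        targets = {1000: 0.1, 3000: 0.3, 5000: 0.5}
        for i in range(n):
            t = i * dt
            k1 = f(t, y)
            k2 = f(t + dt / 2, y + dt / 2 * k1)
            k3 = f(t + dt / 2, y + dt / 2 * k2)
            k4 = f(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            if i + 1 in targets:
                keep[targets[i + 1]] = y[0] / cfg_two_pathway.v_chamber
        r = simulate(cfg_two_pathway, t_grid=np.array([0.1, 0.3, 0.5]))
        for j, t in enumerate((0.1, 0.3, 0.5)):
            assert r.chamber_mgl[j] == pytest.approx(keep[t], rel=1e-5)

    def test_invalid_time_grids_rejected(self, cfg_two_pathway):
        with pytest.raises(ValueError):
            simulate(cfg_two_pathway, t_grid=np.array([0.2, 0.1]))
        with pytest.raises(ValueError):
            simulate(cfg_two_pathway, t_grid=np.array([-0.1, 0.5]))
        with pytest.raises(ValueError):
            simulate(cfg_two_pathway, t_end=-1.0)

    def test_tidy_frame_has_contracted_columns(self, cfg_two_pathway):
        df = simulate(cfg_two_pathway, t_end=1.0).to_frame()
        assert list(df.columns) == [
            "time_hr", "chamber_ppm", "chamber_mgl", "c_adipose", "c_rapid",
            "c_slow", "c_liver", "c_kidney", "a_met_liver", "a_met_kidney",
            "a_met_linear", "a_lost",
        ]
        assert len(df) == 51
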