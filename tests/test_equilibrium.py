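import dataclasses

import numpy as np
import pytest
from scipy.optimize import fsolve

from bimodalbind.equilibrium import (
    FIG_PRESET_HALF_UM,
    FIG_PRESET_ONE_UM,
    EquilibriumParameters,
    hill_coefficient,
    load_parameters,
    robustness_scan,
    sharpness,
    solve_equilibrium,
    species_from_free,
    sweep_myc_total,
)

# --------------------------------------------------------------- oracles


def oracle_grid_refinement(params, rounds=40, grid_n=15):
    """Independent 2-D grid-refinement solve over (free Myc, free Smad).

    For each candidate (m, s) the free-DNA concentrations are obtained by
    vectorized 1-D bisection on the DNA conservation equations (an
    independent route from the closed-form elimination in the package), and
    the Myc/Smad conservation mismatch is minimized by repeatedly zooming
    the grid around the best cell.
    """
    p = params

    def dna_by_bisection(m, s):
        # h from: h*(1 + m/K1 + s^2/KtH) + 2 m^2 h^2 / (K1^2 K2) = DNAH_tot
        def h_lhs(h):
            tet = 2.0 * m**2 * h**2 / (p.K1**2 * p.K2) if p.tetramer_enabled else 0.0
            return h * (1.0 + m / p.K1 + s * s / p.Ktilde_H) + tet - p.DNAH_tot

        lo = np.zeros_like(m)
        hi = np.full_like(m, p.DNAH_tot)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            take_hi = h_lhs(mid) > 0
            hi = np.where(take_hi, mid, hi)
            lo = np.where(take_hi, lo, mid)
        h = 0.5 * (lo + hi)
        l = p.DNAL_tot / (1.0 + m / p.K_L + s * s / p.Ktilde_L)
        return h, l

    def mismatch(m, s):
        h, l = dna_by_bisection(m, s)
        md = m * h / p.K1
        tet = md**2 / p.K2 if p.tetramer_enabled else 0.0
        ml = m * l / p.K_L
        sh = s * s * h / p.Ktilde_H
        sl = s * s * l / p.Ktilde_L
        r1 = (m + md + 2 * tet + ml - p.Myc_tot) / max(p.Myc_tot, 1e-300)
        r2 = (s + 2 * sh + 2 * sl - p.Smad_tot) / max(p.Smad_tot, 1e-300)
        return np.maximum(np.abs(r1), np.abs(r2))

    lo_m, hi_m = np.log(max(p.Myc_tot, 1e-300)) - 40, np.log(max(p.Myc_tot, 1e-300)) + 0.1
    lo_s, hi_s = np.log(p.Smad_tot) - 40, np.log(p.Smad_tot) + 0.1
    for _ in range(rounds):
        gm = np.linspace(lo_m, hi_m, grid_n)
        gs = np.linspace(lo_s, hi_s, grid_n)
        M, S = np.meshgrid(np.exp(gm), np.exp(gs), indexing="ij")
        err = mismatch(M, S)
        i, j = np.unravel_index(np.argmin(err), err.shape)
        dm = gm[1] - gm[0]
        ds = gs[1] - gs[0]
        lo_m, hi_m = gm[i] - dm, gm[i] + dm
        lo_s, hi_s = gs[j] - ds, gs[j] + ds
    m, s = np.exp(0.5 * (lo_m + hi_m)), np.exp(0.5 * (lo_s + hi_s))
    return float(m), float(s)


RELATION_TOL = 1e-9


def assert_detailed_balance(st, p, tol=RELATION_TOL):
    """All five equilibrium relations reproduced from the solved state."""
    assert st.myc_free * st.dnah_free / st.myc_dnah == pytest.approx(p.K1, rel=tol)
    if p.tetramer_enabled:
        assert st.myc_dnah**2 / st.tetramer == pytest.approx(p.K2, rel=tol)
    assert st.myc_free * st.dnal_free / st.myc_dnal == pytest.approx(p.K_L, rel=tol)
    assert st.smad_free**2 * st.dnah_free / st.smad2_dnah == pytest.approx(
        p.Ktilde_H, rel=tol
    )
    assert st.smad_free**2 * st.dnal_free / st.smad2_dnal == pytest.approx(
        p.Ktilde_L, rel=tol
    )


# --------------------------------------------------------------- species


class TestSpeciesFromFree:
    def test_zero_free_concentrations(self):
        p = FIG_PRESET_HALF_UM
        st = species_from_free(0.0, 0.0, p)
        assert st.dnah_free == p.DNAH_tot
        assert st.dnal_free == p.DNAL_tot
        assert st.myc_dnah == st.tetramer == st.myc_dnal == 0.0
        assert st.smad2_dnah == st.smad2_dnal == 0.0

    def test_half_saturation_without_tetramer(self):
        p = dataclasses.replace(FIG_PRESET_HALF_UM, tetramer_enabled=False)
        st = species_from_free(p.K1, 0.0, p)
        assert st.dnah_free == pytest.approx(p.DNAH_tot / 2, rel=1e-12)
        assert st.myc_dnah == pytest.approx(p.DNAH_tot / 2, rel=1e-12)

    def test_relations_reproduced_at_random_points(self):
        rng = np.random.default_rng(0)
        p = FIG_PRESET_HALF_UM
        for _ in range(50):
            m = 10 ** rng.uniform(-10, -5)
            s = 10 ** rng.uniform(-10, -5)
            st = species_from_free(m, s, p)
            assert st.myc_free * st.dnah_free / st.myc_dnah == pytest.approx(p.K1, rel=1e-12)
            assert st.myc_dnah**2 / st.tetramer == pytest.approx(p.K2, rel=1e-12)
            assert st.myc_free * st.dnal_free / st.myc_dnal == pytest.approx(p.K_L, rel=1e-12)
            assert st.smad_free**2 * st.dnah_free / st.smad2_dnah == pytest.approx(
                p.Ktilde_H, rel=1e-12
            )
            # DNAH conservation identity of the quadratic closed form
            assert st.dnah_free + st.myc_dnah + 2 * st.tetramer + st.smad2_dnah == pytest.approx(
                p.DNAH_tot, rel=1e-12
            )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            species_from_free(-1e-9, 0.0, FIG_PRESET_HALF_UM)


# --------------------------------------------------------------- solver


class TestSolveEquilibrium:
    def test_no_myc_reduces_to_smad_only_bisection(self):
        p = dataclasses.replace(FIG_PRESET_HALF_UM, Myc_tot=0.0)
        st = solve_equilibrium(p)
        assert st.myc_dnah == st.tetramer == st.myc_dnal == 0.0
        # 1-D oracle: bisect Smad conservation alone
        from scipy.optimize import brentq

        def f(s):
            h = p.DNAH_tot / (1 + s * s / p.Ktilde_H)
            l = p.DNAL_tot / (1 + s * s / p.Ktilde_L)
            return s + 2 * s * s * h / p.Ktilde_H + 2 * s * s * l / p.Ktilde_L - p.Smad_tot

        s_oracle = brentq(f, 0, p.Smad_tot, xtol=1e-30, rtol=8.9e-16)
        assert st.smad_free == pytest.approx(s_oracle, rel=1e-9)

    def test_no_smad_no_tetramer_closed_form(self):
        p = dataclasses.replace(
            FIG_PRESET_HALF_UM, Smad_tot=0.0, Myc_tot=3e-7, tetramer_enabled=False
        )
        st = solve_equilibrium(p)
        # independent residual check through fsolve on the raw 2-site system
        def resid(v):
            m = v[0]
            h = p.DNAH_tot / (1 + m / p.K1)
            l = p.DNAL_tot / (1 + m / p.K_L)
            return [m + m * h / p.K1 + m * l / p.K_L - p.Myc_tot]

        m_oracle = fsolve(resid, [p.Myc_tot / 2], xtol=1e-14)[0]
        assert st.myc_free == pytest.approx(m_oracle, rel=1e-9)
        assert st.smad_free == 0.0

    def test_conservation_residuals_tiny(self):
        st = solve_equilibrium(FIG_PRESET_HALF_UM)
        assert max(abs(r) for r in st.residuals) < 1e-9

    def test_matches_grid_refinement_oracle(self):
        for myc_tot in (3e-8, 3e-7, 1e-6, 5e-6):
            p = dataclasses.replace(FIG_PRESET_HALF_UM, Myc_tot=myc_tot)
            st = solve_equilibrium(p)
            m_o, s_o = oracle_grid_refinement(p)
            assert st.myc_free == pytest.approx(m_o, rel=1e-6)
            assert st.smad_free == pytest.approx(s_o, rel=1e-6)

    def test_uniqueness_from_random_initializations(self):
        p = dataclasses.replace(FIG_PRESET_HALF_UM, Myc_tot=4e-7)
        ref = solve_equilibrium(p)

        def resid(logv):
            m, s = np.exp(logv)
            st = species_from_free(m, s, p)
            return [
                st.myc_free + st.myc_dnah + 2 * st.tetramer + st.myc_dnal - p.Myc_tot,
                st.smad_free + 2 * st.smad2_dnah + 2 * st.smad2_dnal - p.Smad_tot,
            ]

        rng = np.random.default_rng(1)
        found = []
        for _ in range(100):
            x0 = np.log([10 ** rng.uniform(-12, -6), 10 ** rng.uniform(-12, -6)])
            sol, info, ok, _ = fsolve(resid, x0, full_output=True, xtol=1e-13)
            if ok == 1:
                found.append(np.exp(sol))
        assert len(found) >= 10  # fsolve from far-off starts often fails; enough converge
        for m, s in found:
            assert m == pytest.approx(ref.myc_free, rel=1e-8)
            assert s == pytest.approx(ref.smad_free, rel=1e-8)

    def test_detailed_balance_at_presets(self):
        for preset in (FIG_PRESET_HALF_UM, FIG_PRESET_ONE_UM):
            st = solve_equilibrium(preset)
            assert_detailed_balance(st, preset)


# --------------------------------------------------------------- sweep


class TestSweep:
    def test_monotone_species_along_grid(self):
        sw = sweep_myc_total(FIG_PRESET_HALF_UM, n_points=80)
        tet = sw.species("tetramer")
        smad2 = sw.species("smad2_dnah")
        assert np.all(np.diff(tet) >= -1e-12 * tet.max())
        assert np.all(np.diff(smad2) <= 1e-12 * smad2.max())

    def test_cooperative_transition_is_sharper(self):
        for preset in (FIG_PRESET_HALF_UM, FIG_PRESET_ONE_UM):
            s_on = sharpness(preset, n_points=120)
            s_off = sharpness(
                dataclasses.replace(preset, tetramer_enabled=False), n_points=120
            )
            assert s_on > s_off

    def test_single_point_grid(self):
        sw = sweep_myc_total(FIG_PRESET_HALF_UM, grid=[1e-6])
        assert np.isnan(sw.sharpness_smad2_dnah)
        assert len(sw.states) == 1
        assert max(abs(r) for r in sw.states[0].residuals) < 1e-9

    def test_high_myc_limit_displaces_smad_from_dnah(self):
        lo = solve_equilibrium(dataclasses.replace(FIG_PRESET_HALF_UM, Myc_tot=1e-9))
        hi = solve_equilibrium(dataclasses.replace(FIG_PRESET_HALF_UM, Myc_tot=1e-3))
        assert hi.smad2_dnah < 1e-2 * lo.smad2_dnah

    def test_weak_tetramer_limit_converges_to_heterodimer_model(self):
        p_on = dataclasses.replace(FIG_PRESET_HALF_UM, K2=1e6, Myc_tot=5e-7)
        p_off = dataclasses.replace(
            FIG_PRESET_HALF_UM, tetramer_enabled=False, Myc_tot=5e-7
        )
        st_on, st_off = solve_equilibrium(p_on), solve_equilibrium(p_off)
        for field in ("myc_free", "smad_free", "myc_dnah", "smad2_dnah"):
            assert getattr(st_on, field) == pytest.approx(
                getattr(st_off, field), rel=1e-4
            )

    def test_hill_coefficient_signature_of_cooperativity(self):
        n_on = hill_coefficient(FIG_PRESET_HALF_UM, n_points=150)
        n_off = hill_coefficient(
            dataclasses.replace(FIG_PRESET_HALF_UM, tetramer_enabled=False), n_points=150
        )
        assert n_on > 1.2
        assert n_off <= 1.05

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_myc_total(FIG_PRESET_HALF_UM, grid=[1e-6, 1e-7])


# --------------------------------------------------------------- scan / io


class TestRobustnessScan:
    def test_identity_row_reproduces_base_sweep(self):
        df = robustness_scan(FIG_PRESET_HALF_UM, factors=(10.0,), n_points=40)
        base = df[df.parameter == "base"].iloc[0]
        assert base.sharpness_on == pytest.approx(
            sharpness(FIG_PRESET_HALF_UM, n_points=40)
        )
        assert base.factor == 1.0

    def test_scan_covers_all_constants_both_directions(self):
        df = robustness_scan(FIG_PRESET_HALF_UM, factors=(0.1, 10.0), n_points=30)
        assert len(df) == 1 + 5 * 2
        assert df.cooperative_sharper.dtype == bool

    def test_symmetric_smad_constants_equalize_dna_classes(self):
        p = dataclasses.replace(
            FIG_PRESET_HALF_UM,
            Ktilde_L=FIG_PRESET_HALF_UM.Ktilde_H,
            K_L=FIG_PRESET_HALF_UM.K1,
            tetramer_enabled=False,
        )
        st = solve_equilibrium(p)
        assert st.dnah_free == pytest.approx(st.dnal_free, rel=1e-9)
        assert st.smad2_dnah == pytest.approx(st.smad2_dnal, rel=1e-9)


class TestParameters:
    def test_overall_tetramer_constant_derived(self):
        p = FIG_PRESET_HALF_UM
        assert p.K_H == pytest.approx(p.K1**2 * p.K2)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumParameters(K1=0)
        with pytest.raises(ValueError):
            EquilibriumParameters(Myc_tot=-1e-9)

    def test_yaml_units_parsed(self, tmp_path):
        cfg = tmp_path / "p.yaml"
        cfg.write_text(
            "K1: 145 nM\nK2: 90 nM\nK_L: 0.5 uM\n"
            "Ktilde_H: 1e-14 M2\nKtilde_L: 2.5e-14 M2\n"
            "Myc_tot: 1 uM\nSmad_tot: 1 uM\n"
            "DNAH_tot: 0.5 uM\nDNAL_tot: 0.5 uM\ntetramer_enabled: true\n"
        )
        p = load_parameters(cfg)
        ref = FIG_PRESET_HALF_UM
        for f in ("K1", "K2", "K_L", "Ktilde_H", "Ktilde_L", "Myc_tot",
                  "Smad_tot", "DNAH_tot", "DNAL_tot"):
            assert getattr(p, f) == pytest.approx(getattr(ref, f), rel=1e-12)
        assert p.tetramer_enabled

    def test_unknown_unit_rejected(self, tmp_path):
        cfg = tmp_path / "p.yaml"
        cfg.write_text("K1: 145 furlongs\n")
        with pytest.raises(ValueError):
            load_parameters(cfg)
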