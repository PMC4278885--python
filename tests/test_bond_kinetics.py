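import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfassay.bond_kinetics import (
    BellBond,
    ForceRamp,
    SerialProbe,
    bell_rate,
    bond_from_characteristic_force,
    default_ramp,
    first_rupture_prob,
    most_probable_rupture_force,
    sensitivity_curve,
    simulate_ruptures_kmc,
)


class TestBellBond:
    def test_valid(self):
        b = BellBond(k0=1e-4, dx=1.0, label="x")
        assert b.breakable

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k0": -1.0, "dx": 1.0},
            {"k0": 1.0, "dx": -0.1},
            {"k0": 1.0, "dx": 1.0, "label": ""},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            BellBond(**{"label": "x", **kwargs})


class TestForceRamp:
    def test_speed_times_stiffness(self):
        ramp = ForceRamp(retraction_speed=1.0, effective_stiffness=100.0)
        assert ramp.loading_rate == pytest.approx(1.0e5)

    def test_default_ramp_matches_stated_regime(self):
        assert default_ramp().loading_rate == pytest.approx(1.0e5)

    def test_inconsistent_rate_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ForceRamp(
                loading_rate=5.0e4, retraction_speed=1.0, effective_stiffness=100.0
            )

    def test_speed_without_stiffness_rejected(self):
        with pytest.raises(ValueError):
            ForceRamp(retraction_speed=1.0)

    def test_nonpositive_kt_rejected(self):
        with pytest.raises(ValueError):
            ForceRamp(loading_rate=1e5, kT=0.0)


class TestBellRate:
    def test_zero_force_limit(self):
        assert bell_rate(BellBond(1e-4, 1.0), 0.0) == pytest.approx(1e-4)

    def test_force_insensitive_bond(self):
        assert bell_rate(BellBond(1e-4, 0.0), 100.0) == pytest.approx(1e-4)

    def test_hand_evaluated_exponential(self):
        # k0 * e^(F*dx/kT) with F*dx/kT = 41.1/4.11 = 10
        assert bell_rate(BellBond(1e-4, 1.0), 41.1, kT=4.11) == pytest.approx(
            1e-4 * math.e**10, rel=1e-12
        )

    def test_monotone_in_force(self):
        b = BellBond(1e-4, 1.0)
        forces = np.linspace(0, 100, 50)
        rates = [bell_rate(b, f) for f in forces]
        assert all(r2 >= r1 for r1, r2 in zip(rates, rates[1:]))

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            bell_rate(BellBond(1e-4, 1.0), -1.0)

    def test_nonpositive_kt_rejected(self):
        with pytest.raises(ValueError):
            bell_rate(BellBond(1e-4, 1.0), 1.0, kT=0.0)


class TestFirstRuptureProb:
    def test_identical_bonds_give_half(self, identical_probe, ramp):
        assert first_rupture_prob(identical_probe, ramp) == pytest.approx(
            0.5, abs=1e-6
        )

    def test_equal_dx_closed_form(self, ramp):
        # with equal dx the hazards stay proportional at every force, so
        # p = k0_ref / (k0_ref + k0_prot) for any loading rate
        probe = SerialProbe(
            protein_bond=BellBond(1e-4, 1.0, "prot"),
            reference_bond=BellBond(2e-4, 1.0, "ref"),
        )
        assert first_rupture_prob(probe, ramp) == pytest.approx(2 / 3, abs=1e-9)

    def test_both_unbreakable_rejected(self, ramp):
        probe = SerialProbe(BellBond(0.0, 1.0), BellBond(0.0, 1.0))
        with pytest.raises(ValueError, match="no rupture possible"):
            first_rupture_prob(probe, ramp)

    def test_unbreakable_reference_never_breaks(self, ramp):
        probe = SerialProbe(
            protein_bond=BellBond(1e-4, 1.0), reference_bond=BellBond(0.0, 1.0)
        )
        assert first_rupture_prob(probe, ramp) == 0.0

    def test_unbreakable_protein_always_reference(self, ramp):
        probe = SerialProbe(
            protein_bond=BellBond(0.0, 1.0), reference_bond=BellBond(1e-4, 1.0)
        )
        assert first_rupture_prob(probe, ramp) == pytest.approx(1.0, abs=1e-9)

    def test_unequal_dx_matches_kmc(self, ramp):
        probe = SerialProbe(
            protein_bond=BellBond(5e-3, 0.7, "prot"),
            reference_bond=BellBond(1e-4, 1.3, "ref"),
        )
        p = first_rupture_prob(probe, ramp)
        n = 100_000
        stats = simulate_ruptures_kmc(probe, ramp, n, seed=7)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(stats.fraction_reference_broken - p) < 3 * se

    @given(
        k0_ref=st.floats(1e-6, 1e-1),
        k0_prot=st.floats(1e-6, 1e-1),
        dx=st.floats(0.2, 2.0),
        rate=st.floats(1e3, 1e7),
    )
    @settings(max_examples=25, deadline=None)
    def test_equal_dx_closed_form_property(self, k0_ref, k0_prot, dx, rate):
        ramp = ForceRamp(loading_rate=rate)
        probe = SerialProbe(
            protein_bond=BellBond(k0_prot, dx),
            reference_bond=BellBond(k0_ref, dx),
        )
        expected = k0_ref / (k0_ref + k0_prot)
        assert first_rupture_prob(probe, ramp) == pytest.approx(expected, abs=1e-9)

    @given(
        k0_ref=st.floats(1e-6, 1e-1),
        k0_prot=st.floats(1e-6, 1e-1),
        dx_ref=st.floats(0.2, 2.0),
        dx_prot=st.floats(0.2, 2.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_swap_symmetry_and_range(self, k0_ref, k0_prot, dx_ref, dx_prot):
        ramp = default_ramp()
        probe = SerialProbe(
            protein_bond=BellBond(k0_prot, dx_prot),
            reference_bond=BellBond(k0_ref, dx_ref),
        )
        p = first_rupture_prob(probe, ramp)
        q = first_rupture_prob(probe.swapped(), ramp)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-6)


class TestSimulateRupturesKmc:
    def test_unbreakable_reference_all_protein(self, ramp):
        probe = SerialProbe(
            protein_bond=BellBond(1e-4, 1.0), reference_bond=BellBond(0.0, 1.0)
        )
        stats = simulate_ruptures_kmc(probe, ramp, 1000, seed=1)
        assert stats.n_protein_broken == 1000
        assert stats.n_reference_broken == 0

    def test_identical_bonds_near_half(self, identical_probe, ramp):
        n = 100_000
        stats = simulate_ruptures_kmc(identical_probe, ramp, n, seed=3)
        assert abs(stats.fraction_reference_broken - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_reproducible_for_seed(self, identical_probe, ramp):
        a = simulate_ruptures_kmc(identical_probe, ramp, 1000, seed=5)
        b = simulate_ruptures_kmc(identical_probe, ramp, 1000, seed=5)
        assert a == b

    def test_different_seeds_differ(self, identical_probe, ramp):
        a = simulate_ruptures_kmc(identical_probe, ramp, 10_000, seed=5)
        b = simulate_ruptures_kmc(identical_probe, ramp, 10_000, seed=6)
        assert a.n_reference_broken != b.n_reference_broken

    def test_zero_trials_rejected(self, identical_probe, ramp):
        with pytest.raises(ValueError):
            simulate_ruptures_kmc(identical_probe, ramp, 0, seed=1)

    def test_both_unbreakable_rejected(self, ramp):
        probe = SerialProbe(BellBond(0.0, 1.0), BellBond(0.0, 1.0))
        with pytest.raises(ValueError, match="no rupture possible"):
            simulate_ruptures_kmc(probe, ramp, 10, seed=1)

    def test_mean_rupture_force_sane(self, ramp):
        # single-bond case: empirical mean should land near the analytic
        # most probable force (distribution is skewed, allow a wide band)
        bond = BellBond(1e-4, 1.0)
        probe = SerialProbe(BellBond(0.0, 1.0), bond)
        stats = simulate_ruptures_kmc(probe, ramp, 50_000, seed=11)
        f_star = most_probable_rupture_force(bond, ramp)
        assert abs(stats.mean_rupture_force - f_star) < 0.1 * f_star


class TestMostProbableRuptureForce:
    def test_hand_evaluated_closed_form(self, ramp):
        # (kT/dx) * ln(r*dx/(k0*kT)) = 4.11 * ln(1e5/(1e-4*4.11))
        expected = 4.11 * math.log(1e5 * 1.0 / (1e-4 * 4.11))
        f = most_probable_rupture_force(BellBond(1e-4, 1.0), ramp)
        assert f == pytest.approx(expected, rel=1e-12)
        assert f == pytest.approx(79.4, abs=0.1)

    def test_monotone_in_loading_rate(self):
        bond = BellBond(1e-4, 1.0)
        f1 = most_probable_rupture_force(bond, ForceRamp(loading_rate=1e5))
        f2 = most_probable_rupture_force(bond, ForceRamp(loading_rate=2e5))
        assert f2 > f1

    def test_floored_at_zero(self):
        # absurdly weak bond: log argument < 1
        f = most_probable_rupture_force(
            BellBond(1e9, 1.0), ForceRamp(loading_rate=1e3)
        )
        assert f == 0.0

    def test_degenerate_bond_rejected(self, ramp):
        with pytest.raises(ValueError):
            most_probable_rupture_force(BellBond(0.0, 1.0), ramp)
        with pytest.raises(ValueError):
            most_probable_rupture_force(BellBond(1e-4, 0.0), ramp)


class TestBondFromCharacteristicForce:
    def test_hand_evaluated_k0(self, ramp):
        # k0 = (r*dx/kT) * exp(-F*dx/kT) at F=65, dx=1, r=1e5, kT=4.11
        expected = (1e5 / 4.11) * math.exp(-65.0 / 4.11)
        bond = bond_from_characteristic_force(65.0, ramp, dx=1.0)
        assert bond.k0 == pytest.approx(expected, rel=1e-12)
        assert bond.k0 == pytest.approx(3.3e-3, rel=0.01)

    @given(force=st.floats(5.0, 100.0), dx=st.floats(0.2, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, force, dx):
        ramp = default_ramp()
        bond = bond_from_characteristic_force(force, ramp, dx=dx)
        assert most_probable_rupture_force(bond, ramp) == pytest.approx(
            force, rel=1e-9
        )

    def test_larger_force_gives_smaller_k0(self, ramp):
        k0s = [
            bond_from_characteristic_force(f, ramp, dx=1.0).k0
            for f in (20.0, 40.0, 60.0, 80.0)
        ]
        assert all(b < a for a, b in zip(k0s, k0s[1:]))

    @pytest.mark.parametrize("force,dx", [(0.0, 1.0), (-5.0, 1.0), (65.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, ramp, force, dx):
        with pytest.raises(ValueError):
            bond_from_characteristic_force(force, ramp, dx=dx)


class TestSensitivityCurve:
    def test_balanced_probe_crosses_half(self, ramp):
        ref = bond_from_characteristic_force(65.0, ramp, dx=1.0)
        curve = sensitivity_curve(ref, [65.0], ramp, dx=1.0)
        _, nf, _ = curve[0]
        assert nf == pytest.approx(0.5, abs=1e-6)

    def test_strong_protein_limit(self, ramp):
        ref = bond_from_characteristic_force(65.0, ramp, dx=1.0)
        curve = sensitivity_curve(ref, [120.0], ramp, dx=1.0)
        assert curve[0][1] > 0.999

    def test_monotone_and_peak_slope_near_half(self, ramp):
        ref = bond_from_characteristic_force(65.0, ramp, dx=1.0)
        grid = np.linspace(45.0, 85.0, 41)
        curve = sensitivity_curve(ref, grid, ramp, dx=1.0)
        nf = np.array([c[1] for c in curve])
        slope = np.array([c[2] for c in curve])
        assert np.all(np.diff(nf) >= -1e-12)
        peak = int(np.argmax(np.abs(slope)))
        nearest_half = int(np.argmin(np.abs(nf - 0.5)))
        assert abs(peak - nearest_half) <= 1

    def test_slope_larger_at_half_than_at_09(self, ramp):
        ref = bond_from_characteristic_force(65.0, ramp, dx=1.0)
        grid = np.linspace(45.0, 85.0, 81)
        curve = sensitivity_curve(ref, grid, ramp, dx=1.0)
        nf = np.array([c[1] for c in curve])
        slope = np.abs([c[2] for c in curve])
        at_half = slope[np.argmin(np.abs(nf - 0.5))]
        at_09 = slope[np.argmin(np.abs(nf - 0.9))]
        assert at_half > at_09

    def test_empty_grid_rejected(self, ramp):
        with pytest.raises(ValueError):
            sensitivity_curve(BellBond(1e-4, 1.0), [], ramp)

    def test_unsorted_grid_rejected(self, ramp):
        with pytest.raises(ValueError):
            sensitivity_curve(BellBond(1e-4, 1.0), [70.0, 60.0], ramp)


class TestStrengtheningReference:
    def test_stronger_reference_never_raises_nf(self, ramp):
        protein = bond_from_characteristic_force(70.0, ramp, dx=1.0)
        nfs = []
        for ref_force in (55.0, 65.0, 75.0, 85.0):
            ref = bond_from_characteristic_force(ref_force, ramp, dx=1.0)
            nfs.append(first_rupture_prob(SerialProbe(protein, ref), ramp))
        assert all(b < a for a, b in zip(nfs, nfs[1:]))
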