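import numpy as np
import pytest

from shiftfold.binding import fraction_bound
from shiftfold.io import AtomRef, PeptideSequence
from shiftfold.simulate import (NOEPeakTable, NOERow, SimulationConfig,
                                make_epitope_profile, make_ideal_helix,
                                simulate_noesy, simulate_plate,
                                simulate_titration)


@pytest.fixture(scope="module")
def noiseless():
    return SimulationConfig(shift_noise=0.0, noe_noise=0.0, plate_noise=0.0,
                            seed=7)


class TestNOESY:
    def test_intensities_follow_inverse_sixth_power(self, ideal_helix,
                                                    noiseless):
        peaks = simulate_noesy(ideal_helix, noiseless)
        topo = ideal_helix.topology
        d = ideal_helix.distances()
        for row in peaks.rows:
            r = d[topo.index_of(row.atom_i), topo.index_of(row.atom_j)]
            assert row.intensity == pytest.approx((1.78 / r) ** 6, rel=1e-12)

    def test_half_reference_distance_gives_sixtyfour(self):
        # r = r_ref/2 -> intensity 2^6; r = 2 r_ref -> 1/64
        assert (1.78 / 0.89) ** 6 == pytest.approx(64.0)

    def test_reference_pair_is_geminal_phe_methylene(self, ideal_helix,
                                                     noiseless):
        peaks = simulate_noesy(ideal_helix, noiseless)
        ref = peaks.reference
        names = sorted((ref.atom_i.atom_name, ref.atom_j.atom_name))
        assert names == ["HB2", "HB3"]
        assert ref.atom_i.residue_index == 65

    def test_sequential_amide_pairs_all_present(self, ideal_helix, noiseless):
        peaks = simulate_noesy(ideal_helix, noiseless)
        got = {frozenset((r.atom_i, r.atom_j)) for r in peaks.rows}
        for res in range(63, 73):
            pair = frozenset((AtomRef(res, "H"), AtomRef(res + 1, "H")))
            assert pair in got, f"missing sequential HN-HN {res}"

    def test_intensity_strictly_decreasing_in_distance(self, ideal_helix,
                                                       noiseless):
        peaks = simulate_noesy(ideal_helix, noiseless)
        topo = ideal_helix.topology
        d = ideal_helix.distances()
        rows = sorted(peaks.rows, key=lambda r: d[topo.index_of(r.atom_i),
                                                  topo.index_of(r.atom_j)])
        intens = [r.intensity for r in rows]
        assert all(a >= b for a, b in zip(intens, intens[1:]))

    def test_requires_protons(self, noiseless):
        with pytest.raises(ValueError):
            NOEPeakTable(rows=[NOERow(AtomRef(1, "HA"), AtomRef(2, "HA"),
                                      -1.0, True)])


class TestTitration:
    def test_zero_ratio_equals_free_state(self, noiseless):
        prof = make_epitope_profile(seed=3)
        tables = simulate_titration(noiseless, prof)
        assert tables[0].entries == prof.free_table.entries

    def test_saturation_limit_reaches_bound_shifts(self):
        cfg = SimulationConfig(shift_noise=0.0, ratios=(0.0, 1e5), seed=3)
        prof = make_epitope_profile(seed=3, n_residues=10)
        tables = simulate_titration(cfg, prof)
        for e0, e1 in zip(tables[0].entries, tables[-1].entries):
            dh, dn = prof.bound_shifts[e0.residue_index]
            assert e1.h_shift - e0.h_shift == pytest.approx(dh, abs=1e-3 * abs(dh) + 1e-7)
            assert e1.n_shift - e0.n_shift == pytest.approx(dn, abs=1e-3 * abs(dn) + 1e-7)

    def test_displacement_matches_mass_balance(self, noiseless):
        # P = 55 uM, K_D = 60 uM, 1:1 -> f_bound ~ 0.3671
        prof = make_epitope_profile(seed=5, n_residues=6, epitope_size=2)
        tables = simulate_titration(noiseless, prof)
        fb = fraction_bound(55e-6, 55e-6, 60e-6)
        assert fb == pytest.approx(0.3671, abs=2e-4)
        t1 = next(t for t in tables if t.ratio_label == 1.0)
        for e0, e1 in zip(tables[0].entries, t1.entries):
            dh, _ = prof.bound_shifts[e0.residue_index]
            assert e1.h_shift - e0.h_shift == pytest.approx(fb * dh, abs=1e-12)

    def test_missing_zero_ratio_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(ratios=(0.5, 1.0))

    def test_fraction_bound_monotone_in_ratio(self, noiseless):
        p = noiseless.protein_conc
        fb = [fraction_bound(p, r * p, noiseless.true_kd)
              for r in noiseless.ratios]
        assert all(0 <= f <= 1 for f in fb)
        assert all(a <= b for a, b in zip(fb, fb[1:]))

    def test_seeding_reproducible(self):
        prof = make_epitope_profile(seed=9, n_residues=12)
        a = simulate_titration(SimulationConfig(seed=11), prof)
        b = simulate_titration(SimulationConfig(seed=11), prof)
        c = simulate_titration(SimulationConfig(seed=12), prof)
        assert a[1].entries == b[1].entries
        assert a[1].entries != c[1].entries


class TestPlate:
    def test_midpoint_identity(self, noiseless):
        m1, m2, m3, m4 = noiseless.plate_params
        plate = simulate_plate(noiseless, concentrations=[m3] * 3 +
                               [m3 / 4, m3 / 2, 2 * m3, 4 * m3])
        mid = [r.signal for r in plate.rows if r.concentration == m3]
        assert mid[0] == pytest.approx((m1 + m2) / 2, rel=1e-12)

    def test_zero_concentration_gives_baseline(self, noiseless):
        plate = simulate_plate(noiseless,
                               concentrations=[0.0, 1e-7, 1e-6, 1e-5, 1e-4])
        assert plate.rows[0].signal == pytest.approx(
            noiseless.plate_params[1], rel=1e-12)

    def test_two_seeds_same_noiseless_component(self):
        a = simulate_plate(SimulationConfig(seed=1))
        b = simulate_plate(SimulationConfig(seed=2))
        clean = simulate_plate(SimulationConfig(seed=1, plate_noise=0.0))
        assert [r.signal for r in a.rows] != [r.signal for r in b.rows]
        resid_a = np.array([x.signal - c.signal
                            for x, c in zip(a.rows, clean.rows)])
        assert np.abs(resid_a).max() < 5 * 9.0  # noise only

    def test_all_zero_concentrations_rejected(self, noiseless):
        with pytest.raises(ValueError):
            simulate_plate(noiseless, concentrations=np.zeros(6))

    def test_descending_mode_uses_competition_parameters(self, noiseless):
        plate = simulate_plate(noiseless, descending=True)
        by_conc = sorted(plate.rows, key=lambda r: r.concentration)
        assert by_conc[0].signal > by_conc[-1].signal


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"true_kd": 0.0},
        {"protein_conc": -1.0},
        {"ratios": (0.0, 2.0, 1.0)},
        {"shift_noise": -0.1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
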