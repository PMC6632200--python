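"""Window currents, deactivation, IV assembly and reversal potentials."""

import numpy as np
import pytest

from cationsite.errors import ConfigurationError, NormalizationError
from cationsite.tevc import (
    CurrentSweep, Recording, SweepProtocol, build_iv, deactivation_pct,
    estimate_vrev, fit_vrev_semilog, nernst_slope, read_recording,
    window_currents, write_recording)

RATE = 2000.0


def sweep_from(samples, voltage=-145.0):
    return CurrentSweep(step_voltage=voltage, samples=np.asarray(samples),
                        sample_rate=RATE)


def linear_recording(g, vrev, solution="Na30K1", cell="cell1", gain=1.0,
                     protocol=SweepProtocol()):
    sweeps = {}
    n = int(protocol.pulse_duration * RATE)
    for v in protocol.voltages:
        i = gain * g * (v - vrev)
        sweeps[float(v)] = sweep_from(np.full(n, i), voltage=float(v))
    return Recording(solution=solution, na_mm=30, k_mm=1, sweeps=sweeps,
                     cell_id=cell)


def test_protocol_voltage_ladder():
    p = SweepProtocol()
    assert p.voltages[0] == 20.0
    assert p.voltages[-1] == -160.0
    assert len(p.voltages) == 13


def test_constant_sweep_windows_all_equal():
    s = sweep_from(np.full(2000, -1.0))
    ib, ie, ia = window_currents(s)
    assert ib == ie == ia == -1.0


def test_linear_ramp_window_limits():
    t = np.arange(20000) / 20000.0
    s = CurrentSweep(step_voltage=-145, samples=-t, sample_rate=20000.0)
    ib, ie, ia = window_currents(s, settle=0.0, window=0.001)
    assert ib == pytest.approx(0.0, abs=1e-3)
    assert ie == pytest.approx(-1.0, abs=1e-3)
    assert ia == pytest.approx(-0.5, abs=1e-3)


def test_exponential_sweep_matches_analytic_window_means():
    from cationsite.synthetic import analytic_deactivation_pct

    f, tau = 0.12, 0.2
    t = np.arange(2000) / RATE
    s = sweep_from(-2.0 * ((1 - f) + f * np.exp(-t / tau)))
    ib, ie, _ = window_currents(s)
    got = deactivation_pct(ib, ie)
    assert got == pytest.approx(
        analytic_deactivation_pct(f, tau, sample_rate=RATE), abs=1e-9)
    # and the continuous-time closed form agrees to ~0.1%
    assert got == pytest.approx(analytic_deactivation_pct(f, tau), rel=2e-3)


def test_window_too_fine_for_sample_rate_errors():
    s = sweep_from(np.full(10, -1.0))  # 5 ms of data at 2 kHz
    with pytest.raises(ConfigurationError):
        window_currents(s, settle=0.0, window=0.0001)


def test_deactivation_percentage_arithmetic():
    assert deactivation_pct(-2.0, -1.76) == pytest.approx(12.0)
    assert deactivation_pct(-1.0, -1.0) == 0.0
    assert deactivation_pct(0.0, 0.0) is None


def test_deactivation_invariant_under_positive_gain():
    t = np.arange(2000) / RATE
    base = -1.5 * (0.9 + 0.1 * np.exp(-t / 0.15))
    for gain in (0.1, 1.0, 7.3):
        ib, ie, _ = window_currents(sweep_from(gain * base))
        assert deactivation_pct(ib, ie) == pytest.approx(
            deactivation_pct(*window_currents(sweep_from(base))[:2]))


def test_iv_normalized_reference_point_is_unity():
    rec = linear_recording(g=0.05, vrev=-45.0)
    iv = build_iv([rec], normalize_to=("Na30K1", -145.0))
    at_ref = iv[(iv.solution == "Na30K1") & (iv.voltage_mV == -145.0)]
    assert abs(at_ref["mean"].iloc[0]) == pytest.approx(1.0)


def test_identical_cells_have_zero_sd():
    recs = [linear_recording(0.05, -45.0, cell="c1"),
            linear_recording(0.05, -45.0, cell="c2")]
    iv = build_iv(recs)
    assert (iv["sd"] == 0.0).all()
    assert (iv["n"] == 2).all()


def test_normalization_invariant_to_per_cell_gain():
    recs = [linear_recording(0.05, -45.0, cell="c1", gain=1.0),
            linear_recording(0.05, -45.0, cell="c2", gain=3.7)]
    iv = build_iv(recs)
    assert (iv["sd"] < 1e-12).all()


def test_linear_iv_matches_closed_form_pointwise():
    g, vrev = 0.05, -45.0
    rec = linear_recording(g, vrev)
    iv = build_iv([rec])
    scale = abs(g * (-145.0 - vrev))
    for _, row in iv.iterrows():
        assert row["mean"] == pytest.approx(g * (row["voltage_mV"] - vrev) / scale)


def test_missing_reference_solution_raises():
    rec = linear_recording(0.05, -45.0, solution="Na30K0")
    with pytest.raises(NormalizationError):
        build_iv([rec], normalize_to=("Na30K1", -145.0))


def test_vrev_interpolation_and_exact_zero():
    assert estimate_vrev([-60, -45], [-0.5, 0.5]) == pytest.approx(-52.5)
    assert estimate_vrev([-60, -45, -30], [-1.0, 0.0, 1.0]) == pytest.approx(-45.0)


def test_vrev_absent_without_sign_change():
    with pytest.warns(UserWarning, match="no zero crossing"):
        assert estimate_vrev([-60, -45], [-2.0, -1.0]) is None


def test_vrev_multiple_crossings_prefers_least_negative():
    with pytest.warns(UserWarning, match="multiple"):
        v = estimate_vrev([-90, -75, -60, -45], [-1.0, 0.5, -0.5, 1.0])
    assert v == pytest.approx(-55.0)  # crossings at -80, -67.5 and -55


def test_vrev_on_smooth_nonlinear_iv_within_half_mv():
    # GHK-flavoured curve with a known zero at -52.0 mV, 15 mV spacing
    true_vrev = -52.0
    v = np.arange(-160.0, 21.0, 15.0)
    i = 0.04 * (v - true_vrev) * (1 + 0.004 * (v - true_vrev))
    got = estimate_vrev(v, i)
    assert got == pytest.approx(true_vrev, abs=0.5)


def test_semilog_fit_exact_and_two_point():
    pts = [(0.3, 58 * np.log10(0.3) - 20), (3.0, 58 * np.log10(3.0) - 20),
           (30.0, 58 * np.log10(30.0) - 20)]
    fit = fit_vrev_semilog(pts)
    assert fit.slope == pytest.approx(58.0)
    assert fit.intercept == pytest.approx(-20.0)
    assert np.allclose(fit.residuals, 0.0)
    two = fit_vrev_semilog([(0.3, -95.0), (30.0, -50.0)])
    assert two.slope == pytest.approx(22.5)


def test_semilog_fit_recovers_slope_under_noise(rng):
    conc = np.array([0.3, 1.0, 3.0, 10.0, 30.0, 100.0])
    vrev = 45.0 * np.log10(conc) - 70.0 + rng.normal(0, 1.0, conc.size)
    fit = fit_vrev_semilog(list(zip(conc, vrev)))
    assert fit.slope == pytest.approx(45.0, abs=2.0)


def test_nernst_slope_at_room_temperature():
    assert nernst_slope(22.0) == pytest.approx(58.56, abs=0.01)
    fit = fit_vrev_semilog([(0.3, -95.0), (30.0, -50.0)], temperature_c=22.0)
    assert fit.ideal_slope == pytest.approx(58.56, abs=0.01)


def test_semilog_rejects_nonpositive_or_degenerate():
    with pytest.raises(ConfigurationError):
        fit_vrev_semilog([(0.0, -90.0), (30.0, -50.0)])
    with pytest.raises(ConfigurationError):
        fit_vrev_semilog([(30.0, -50.0), (30.0, -49.0)])


def test_recording_csv_manifest_roundtrip(tmp_path):
    rec = linear_recording(0.05, -45.0)
    mpath = write_recording(rec, tmp_path, SweepProtocol())
    back, proto = read_recording(mpath)
    assert back.solution == rec.solution
    assert proto.n_steps == 13
    for v, s in rec.sweeps.items():
        np.testing.assert_allclose(back.sweeps[v].samples, s.samples, atol=1e-6)
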