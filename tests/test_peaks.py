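import numpy as np
import pytest

from infantmmr.config import default_config
from infantmmr.containers import DEVIANT, STANDARD
from infantmmr.erp import bootstrap_erp, compute_mmr
from infantmmr.peaks import (detect_component_peak, make_vertex_waveform,
                             measure_all_components, vertex_series)
from infantmmr.simulate import (ComponentSpec, build_component_template,
                                default_cohort_spec)
from infantmmr.validation import naive_peak_pick

CHANNELS = ("F5", "Fz", "F6", "C5", "Cz", "C6", "P5", "Pz", "P6", "M1", "M2")
TIMES = -200.0 + np.arange(250) * 4.0  # 250 Hz epoch


def const_channels(values):
    """(11, T) array with constant per-channel values."""
    out = np.zeros((11, 250))
    for ch, v in values.items():
        out[CHANNELS.index(ch)] = v
    return out


class TestVertexWaveform:
    def test_hand_arithmetic(self):
        data = const_channels({"Fz": 4.0, "Cz": 2.0, "M1": 2.0, "M2": 0.0})
        assert np.allclose(vertex_series(data, CHANNELS), 2.0)

    def test_mastoid_free_case_and_reference_invariance(self):
        data = const_channels({"Fz": 3.0, "Cz": 3.0})
        assert np.allclose(vertex_series(data, CHANNELS), 3.0)
        shifted = data + 7.5  # common offset on every channel
        assert np.allclose(vertex_series(shifted, CHANNELS),
                           vertex_series(data, CHANNELS))

    def test_missing_mastoid_is_fatal_with_hint(self):
        names = tuple(c for c in CHANNELS if c != "M1")
        with pytest.raises(ValueError, match="M1"):
            vertex_series(np.zeros((10, 250)), names)


def gauss(lat, amp, width=20.0):
    return amp * np.exp(-((TIMES - lat) ** 2) / (2 * width ** 2))


class TestDetectComponentPeak:
    def test_single_bump_latency_within_one_sample(self):
        pk = detect_component_peak(gauss(202.0, 3.0), TIMES, "P1",
                                   (100.0, 300.0), +1)
        assert pk.found and abs(pk.latency_ms - 202.0) <= 4.0
        assert pk.amplitude_uv == pytest.approx(3.0, abs=0.02)  # 4 ms sampling

    def test_two_bumps_50ms_apart_one_survivor(self):
        wave = gauss(180.0, 3.0) + gauss(230.0, 5.0)
        pk = detect_component_peak(wave, TIMES, "P1", (100.0, 300.0), +1,
                                   min_dist_ms=80.0)
        assert pk.found and abs(pk.latency_ms - 230.0) <= 8.0

    def test_monotone_ramp_not_found(self):
        ramp = np.linspace(0, 10, len(TIMES))
        pk = detect_component_peak(ramp, TIMES, "P1", (100.0, 300.0), +1)
        assert not pk.found and np.isnan(pk.latency_ms)

    def test_negative_polarity_constraint(self):
        # local minimum with positive value is not a valid N1
        wave = 5.0 + gauss(300.0, -2.0)
        pk = detect_component_peak(wave, TIMES, "N1", (200.0, 450.0), -1)
        assert not pk.found
        wave2 = gauss(300.0, -4.0)
        pk2 = detect_component_peak(wave2, TIMES, "N1", (200.0, 450.0), -1)
        assert pk2.found and pk2.amplitude_uv <= 0

    def test_scaling_invariance_of_latency_linearity_of_amplitude(self):
        wave = gauss(150.0, 2.0) + gauss(260.0, 4.0) + 0.3 * np.sin(TIMES / 40)
        a = detect_component_peak(wave, TIMES, "P1", (100.0, 300.0), +1)
        b = detect_component_peak(3.0 * wave, TIMES, "P1", (100.0, 300.0), +1)
        assert a.latency_ms == b.latency_ms
        assert b.amplitude_uv == pytest.approx(3 * a.amplitude_uv)

    def test_matches_exhaustive_search_on_random_waveforms(self):
        rng = np.random.default_rng(11)
        n_checked = 0
        for _ in range(150):
            wave = np.zeros_like(TIMES)
            for _ in range(rng.integers(2, 7)):
                wave += gauss(rng.uniform(-200, 800), rng.uniform(-6, 6),
                              rng.uniform(20, 80))
            pol = int(rng.choice([-1, 1]))
            got = detect_component_peak(wave, TIMES, "P1", (100.0, 300.0), pol,
                                        80.0, (-200.0, 0.0))
            found, lat, amp = naive_peak_pick(wave, TIMES, (100.0, 300.0), pol,
                                              80.0, (-200.0, 0.0))
            assert got.found == found
            if found:
                assert got.latency_ms == lat
                assert got.amplitude_uv == pytest.approx(amp)
            n_checked += 1
        assert n_checked == 150


class TestMeasureAllComponents:
    def _noiseless_estimates(self, epochs_factory):
        cohort = default_cohort_spec()
        tpl_std = sum(
            build_component_template(spec, 250.0, (-200.0, 799.0))
            for spec in cohort.components.values())
        tpl_mmr = build_component_template(cohort.mmr["native"], 250.0,
                                           (-200.0, 799.0))
        std = np.tile(tpl_std, (6, 1, 1))
        dev = np.tile(tpl_std + tpl_mmr, (6, 1, 1))
        ep = epochs_factory(np.concatenate([std, dev]), rate=250.0,
                            labels=[STANDARD] * 6 + [DEVIANT] * 6,
                            channel_names=CHANNELS)
        s = bootstrap_erp(ep, np.arange(6), 49, seed=0)
        d = bootstrap_erp(ep, np.arange(6, 12), 49, seed=1)
        return s, d, compute_mmr(d, s), cohort

    def test_noiseless_subject_recovers_injected_latencies(self, epochs_factory):
        s, d, mmr, cohort = self._noiseless_estimates(epochs_factory)
        table = measure_all_components(s, d, mmr, default_config())
        assert len(table) == 7 and table["found"].all()
        # overlapping Gaussian tails shift composite extrema slightly from the
        # injected latencies; the analytic truth is the extremum of the summed
        # vertex waveform within each window
        from infantmmr.config import COMPONENT_WINDOWS
        truth_wave = {"standard": make_vertex_waveform(s),
                      "deviant": make_vertex_waveform(d),
                      "difference": make_vertex_waveform(mmr)}
        pol = {"P1": +1, "N1": -1, "P2": +1, "MMR": +1}
        times = s.times_ms
        for _, row in table.iterrows():
            w = truth_wave[row["waveform_kind"]]
            lo, hi = COMPONENT_WINDOWS[row["component"]]
            mask = (times >= lo) & (times <= hi)
            idx = np.flatnonzero(mask)
            ext = idx[np.argmax(pol[row["component"]] * w[idx])]
            assert abs(row["latency_ms"] - times[ext]) <= 4.0
        # well-isolated components sit at their injected latencies
        p1 = table[(table.component == "P1")
                   & (table.waveform_kind == "standard")].iloc[0]
        assert abs(p1["latency_ms"] - 200.0) <= 4.0
        mmr_lat = table[table.component == "MMR"].iloc[0]["latency_ms"]
        assert abs(mmr_lat - 300.0) <= 8.0
        n1 = table[table["component"] == "N1"]
        assert (n1["amplitude_uv"] <= 0).all()
        mmr_row = table[table["component"] == "MMR"].iloc[0]
        assert mmr_row["waveform_kind"] == "difference"
        assert mmr_row["amplitude_uv"] > 0  # injected positive MMR
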