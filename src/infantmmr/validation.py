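"""Desk-scale validation experiments with independent naive oracles.

Every function here recomputes a pipeline property from scratch: paradigm
statistics of the event generator, artifact rejection against a trial-by-
trial reference implementation, bootstrap CI coverage, FDR control under the
global null, peak-picker equivalence with exhaustive search, center-of-mass
parameter recovery, and mixed-model calibration (type-I error and power).
The naive oracles are deliberately simple loop implementations, independent
of the vectorized production code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kurtosis as _kurtosis

from .config import default_config
from .containers import DEVIANT, STANDARD, EpochSet
from .erp import bootstrap_erp, compute_mmr, ttest_fdr_series
from .matching import match_preceding_standard
from .montage import build_default_montage
from .peaks import detect_component_peak, make_vertex_waveform
from .preprocessing import (bandpass_filter, preprocess, reject_artifacts,
                            spatial_pca_denoise)
from .simulate import (default_cohort_spec, derive_seed, generate_event_sequence,
                       simulate_measures_table, synthesize_subject_session)
from .stats import fit_factorial_lme
from .topography import (amplitudes_at_latency, component_weights,
                         compute_center_of_mass, compute_displacement)

__all__ = [
    "naive_rejection_mask", "naive_peak_pick", "sequence_stats",
    "rejection_oracle_agreement", "pca_identity_error",
    "filter_pulse_peak_shift", "bootstrap_coverage",
    "fdr_null_discovery_rate", "peak_oracle_agreement", "com_recovery",
    "lme_interaction_type1", "lme_session_power",
]


# ---------------------------------------------------------------------------
# naive reference implementations


def naive_rejection_mask(data: np.ndarray, volt_thresh: float,
                         step_thresh: float, kurt_sd: float) -> np.ndarray:
    """Trial-by-trial loop over the three rejection rules."""
    n_trials, n_ch, _ = data.shape
    kurt = np.empty((n_trials, n_ch))
    for i in range(n_trials):
        for c in range(n_ch):
            kurt[i, c] = _kurtosis(data[i, c], fisher=True, bias=True)
    mask = np.zeros(n_trials, dtype=bool)
    for i in range(n_trials):
        rejected = False
        for c in range(n_ch):
            x = data[i, c]
            if np.any(np.abs(x) > volt_thresh):
                rejected = True
            if np.any(np.abs(np.diff(x)) > step_thresh):
                rejected = True
            mu = kurt[:, c].mean()
            sd = kurt[:, c].std(ddof=1)
            if sd > 0 and abs(kurt[i, c] - mu) / sd > kurt_sd:
                rejected = True
        mask[i] = rejected
    return mask


def _naive_prominence(x: np.ndarray, peak: int) -> float:
    """Peak prominence by direct contour search (matches the usual
    definition: height above the higher of the two interval minima toward
    the nearest higher samples or signal edges)."""
    h = x[peak]
    i = peak
    lmin = h
    while i > 0:
        i -= 1
        if x[i] > h:
            break
        lmin = min(lmin, x[i])
    i = peak
    rmin = h
    n = len(x)
    while i < n - 1:
        i += 1
        if x[i] > h:
            break
        rmin = min(rmin, x[i])
    return h - max(lmin, rmin)


def naive_peak_pick(wave: np.ndarray, times_ms: np.ndarray,
                    window_ms: tuple[float, float], polarity: int,
                    min_dist_ms: float, noise_window_ms: tuple[float, float]
                    ) -> tuple[bool, float, float]:
    """Exhaustive reference peak pick: enumerate all candidate extrema,
    apply prominence-ordered minimum-distance thinning, then score each
    survivor as prominence x SNR and take the best (earliest on ties)."""
    x = polarity * np.asarray(wave, float)
    cands = [i for i in range(1, len(x) - 1)
             if x[i - 1] < x[i] > x[i + 1]
             and window_ms[0] <= times_ms[i] <= window_ms[1]
             and x[i] >= 0]
    if not cands:
        return False, np.nan, np.nan
    prom = {i: _naive_prominence(x, i) for i in cands}
    order = sorted(cands, key=lambda i: (-prom[i], times_ms[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(times_ms[i] - times_ms[j]) >= min_dist_ms for j in kept):
            kept.append(i)
    base = (times_ms >= noise_window_ms[0]) & (times_ms <= noise_window_ms[1])
    noise_sd = np.asarray(wave, float)[base].std()
    best, best_score, best_t = None, -np.inf, np.inf
    for i in kept:
        snr = abs(wave[i]) / noise_sd if noise_sd > 0 else np.inf
        score = prom[i] * snr
        if score > best_score or (score == best_score and times_ms[i] < best_t):
            best, best_score, best_t = i, score, times_ms[i]
    return True, float(times_ms[best]), float(wave[best])


# ---------------------------------------------------------------------------
# calibration experiments


def sequence_stats(n_sequences: int = 1000, n_trials: int = 600,
                   deviant_prob: float = 0.15, seed: int = 0) -> dict:
    """Violation count and mean deviant count over many generated sequences."""
    violations = 0
    counts = []
    for k in range(n_sequences):
        ev = generate_event_sequence(n_trials, deviant_prob, 1200.0, 400.0,
                                     seed=derive_seed(seed, "seq", k))
        dev = ev.labels == DEVIANT
        violations += int(np.sum(dev[:-1] & dev[1:]))
        counts.append(int(dev.sum()))
    return {"n_sequences": n_sequences,
            "consecutive_violations": violations,
            "mean_deviant_count": float(np.mean(counts))}


def _synthetic_epochs_with_violations(n_trials: int, seed: int) -> EpochSet:
    rng = np.random.default_rng(seed)
    n_ch, n_t = 11, 1000
    from scipy.ndimage import gaussian_filter1d
    data = gaussian_filter1d(rng.normal(size=(n_trials, n_ch, n_t)), 5.0, axis=2)
    data *= 10.0 / data.std()  # band-limited background, SD 10 uV
    # ~30% of trials carry one injected violation
    kinds = rng.choice(4, size=n_trials, p=[0.7, 0.1, 0.1, 0.1])
    for i in range(n_trials):
        c = int(rng.integers(n_ch))
        pos = int(rng.integers(100, n_t - 100))
        if kinds[i] == 1:     # extreme voltage
            data[i, c, pos] += rng.choice([-1, 1]) * rng.uniform(180, 400)
        elif kinds[i] == 2:   # step between consecutive samples
            data[i, c, pos:] += rng.choice([-1, 1]) * rng.uniform(60, 120)
        elif kinds[i] == 3:   # heavy-tailed burst
            spikes = rng.integers(pos, pos + 50, size=12)
            data[i, c, spikes] += rng.choice([-1, 1], size=12) * rng.uniform(40, 80, size=12)
    labels = np.array([STANDARD] * n_trials, dtype=object)
    return EpochSet(data=data, window_ms=(-200.0, 799.0), sampling_rate=1000.0,
                    trial_labels=labels, trial_onsets=np.arange(n_trials) * 1600,
                    channel_names=tuple(f"ch{i}" for i in range(n_ch)))


def rejection_oracle_agreement(n_trials: int = 500, seed: int = 0) -> dict:
    """Compare the production rejection mask with the naive per-rule oracle."""
    cfg = default_config()
    epochs = _synthetic_epochs_with_violations(n_trials, seed)
    out = reject_artifacts(epochs, cfg.reject.volt_thresh_uv,
                           cfg.reject.step_thresh_uv, cfg.reject.kurt_sd)
    ref = naive_rejection_mask(epochs.data, cfg.reject.volt_thresh_uv,
                               cfg.reject.step_thresh_uv, cfg.reject.kurt_sd)
    agree = float(np.mean(out.rejection_mask == ref))
    return {"n_trials": n_trials, "agreement": agree,
            "n_rejected": int(out.rejection_mask.sum())}


def pca_identity_error(seed: int = 0) -> float:
    """Max |output - input| for spatial PCA with all variance retained."""
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, 5.0, size=(40, 11, 250))
    epochs = EpochSet(data=data, window_ms=(-200.0, 799.0), sampling_rate=250.0,
                      trial_labels=np.array([STANDARD] * 40, dtype=object),
                      trial_onsets=np.arange(40) * 1600,
                      channel_names=tuple(f"ch{i}" for i in range(11)))
    from .preprocessing import baseline_correct
    epochs = baseline_correct(epochs)
    out = spatial_pca_denoise(epochs, var_retained=1.0)
    return float(np.max(np.abs(out.data - epochs.data)))


def filter_pulse_peak_shift(seed: int = 0) -> int:
    """Peak-sample displacement of a symmetric pulse under the zero-phase
    bandpass filter (should be 0)."""
    from .containers import ContinuousRecording
    montage = build_default_montage()
    n = 20000
    t = np.arange(n)
    pulse = np.exp(-((t - 10000) ** 2) / (2 * 150.0 ** 2))
    data = np.tile(pulse, (montage.n_channels, 1)) * 50.0
    rec = ContinuousRecording(data, 1000.0, montage)
    filtered = bandpass_filter(rec, 1.0, 18.0, 4)
    return int(np.argmax(filtered.data[0]) - np.argmax(data[0]))


def bootstrap_coverage(n_replicates: int = 200, n_trials: int = 50,
                       n_boot: int = 600, seed: int = 0) -> dict:
    """Fraction of channel/time points where the 95% bootstrap CI covers the
    known population mean, over replicate Gaussian datasets."""
    rng = np.random.default_rng(seed)
    n_t = 60
    true = np.sin(np.linspace(0.0, 3.0, n_t))
    covered = []
    for rep in range(n_replicates):
        data = true + rng.standard_normal((n_trials, 1, n_t))
        epochs = EpochSet(data=data, window_ms=(0.0, float(n_t - 1)),
                          sampling_rate=1000.0,
                          trial_labels=np.array([STANDARD] * n_trials, dtype=object),
                          trial_onsets=np.arange(n_trials),
                          channel_names=("Cz",))
        est = bootstrap_erp(epochs, np.arange(n_trials), n_boot=n_boot,
                            seed=derive_seed(seed, "boot", rep))
        covered.append(np.mean((est.ci_low <= true) & (true <= est.ci_high)))
    return {"n_replicates": n_replicates, "coverage": float(np.mean(covered))}


def fdr_null_discovery_rate(n_replicates: int = 500, n_trials: int = 30,
                            n_timepoints: int = 100, seed: int = 0) -> dict:
    """Fraction of global-null replicates with any q <= 0.05 discovery."""
    rng = np.random.default_rng(seed)
    any_disc = 0
    for _ in range(n_replicates):
        a = rng.standard_normal((n_trials, n_timepoints))
        b = rng.standard_normal((n_trials, n_timepoints))
        _, _, sig = ttest_fdr_series(a, b, q_level=0.05)
        any_disc += bool(sig.any())
    return {"n_replicates": n_replicates, "rate": any_disc / n_replicates}


def _random_smooth_wave(rng: np.random.Generator, times_ms: np.ndarray) -> np.ndarray:
    wave = np.zeros_like(times_ms)
    for _ in range(rng.integers(2, 7)):
        lat = rng.uniform(times_ms[0], times_ms[-1])
        width = rng.uniform(20.0, 80.0)
        amp = rng.uniform(-6.0, 6.0)
        wave += amp * np.exp(-((times_ms - lat) ** 2) / (2 * width ** 2))
    return wave


def peak_oracle_agreement(n_waveforms: int = 1000, seed: int = 0) -> dict:
    """Constrained picking vs exhaustive search on random smooth waveforms,
    plus the 80 ms rule on two bumps 50 ms apart."""
    rng = np.random.default_rng(seed)
    times = -200.0 + np.arange(250) * 4.0  # 250 Hz epoch
    window, min_dist, noise_win = (100.0, 300.0), 80.0, (-200.0, 0.0)
    n_agree = 0
    for _ in range(n_waveforms):
        wave = _random_smooth_wave(rng, times)
        pol = int(rng.choice([-1, 1]))
        got = detect_component_peak(wave, times, "P1", window, pol, min_dist,
                                    noise_win)
        found, lat, amp = naive_peak_pick(wave, times, window, pol, min_dist,
                                          noise_win)
        if got.found == found and (
                not found or (lat == got.latency_ms
                              and np.isclose(amp, got.amplitude_uv))):
            n_agree += 1
    # two positive bumps 50 ms apart (3 and 5 uV): the 80 ms rule must keep one
    two = (3.0 * np.exp(-((times - 180.0) ** 2) / (2 * 20.0 ** 2))
           + 5.0 * np.exp(-((times - 230.0) ** 2) / (2 * 20.0 ** 2))
           + 0.05 * np.sin(times / 50.0))
    pick = detect_component_peak(two, times, "P1", window, +1, min_dist, noise_win)
    return {"n_waveforms": n_waveforms, "agreement": n_agree / n_waveforms,
            "two_bump_single_pick_latency_ms": pick.latency_ms}


def _subject_std_estimates(cohort, sessions, n_subjects, cfg, seed, n_boot):
    """Process subject x session recordings and collect peaks + mean ERPs."""
    results = {}
    for s in range(n_subjects):
        subject = f"S{s + 1:03d}"
        for session in sessions:
            rec, events = synthesize_subject_session(cohort, subject, session,
                                                     "native")
            epochs = preprocess(rec, events, cfg)
            pairs = match_preceding_standard(epochs)
            est = bootstrap_erp(epochs, pairs.standard_indices, n_boot,
                                seed=derive_seed(seed, "b", subject, session))
            wave = make_vertex_waveform(est)
            pk = detect_component_peak(wave, est.times_ms, "P1",
                                       (100.0, 300.0), +1, 80.0, (-200.0, 0.0))
            results.setdefault(session, []).append((pk, est))
    return results


def com_recovery(drift: np.ndarray | None = None, noise_sd: float = 1.0,
                 n_subjects: int = 20, n_trials: int = 400, n_boot: int = 60,
                 seed: int = 0) -> dict:
    """Recover an injected P1 centroid drift (T1 -> T3) from a simulated
    cohort via the full preprocess/bootstrap/peak/weights/CoM chain."""
    montage = build_default_montage()
    cfg = default_config()
    cfg.bootstrap.n_boot = n_boot
    from dataclasses import replace
    com_shift = {} if drift is None else {"P1": {"T3": np.asarray(drift, float)}}
    cohort = default_cohort_spec(
        com_shift=com_shift, noise_sd_uv=noise_sd, artifact_rate=0.0,
        amplitude_sd_uv=2.0, latency_jitter_sd_ms=5.0,
        latency_shift_ms={"T1": 0.0, "T2": 0.0, "T3": 0.0},
        seed=derive_seed(seed, "com"))
    cohort = replace(cohort, paradigm=replace(cohort.paradigm, n_trials=n_trials))
    results = _subject_std_estimates(cohort, ("T1", "T3"), n_subjects, cfg,
                                     seed, n_boot)
    coms = {}
    for session, items in results.items():
        lats = [pk.latency_ms for pk, _ in items if pk.found]
        group_latency = float(np.mean(lats))
        amps = []
        for _, est in items:
            a = amplitudes_at_latency(est.mean, est.times_ms, group_latency)
            full = np.full(montage.n_channels, np.nan)
            for i, ch in enumerate(est.channel_names):
                full[montage.index(ch)] = a[i]
            amps.append(full)
        weights = component_weights(np.array(amps))
        coms[session] = compute_center_of_mass(weights, montage, "P1", session,
                                               "native")
    disp = compute_displacement(coms["T1"], coms["T3"])
    return {"n_subjects": n_subjects, "magnitude": disp.magnitude,
            "dx": disp.dx, "dy": disp.dy, "dz": disp.dz,
            "category": disp.category}


def lme_interaction_type1(n_replicates: int = 200, n_subjects: int = 40,
                          alpha: float = 0.05, seed: int = 0) -> dict:
    """Session x Language interaction rejection rate under the null."""
    rejections = 0
    for rep in range(n_replicates):
        table = simulate_measures_table(n_subjects,
                                        seed=derive_seed(seed, "null", rep),
                                        subject_sd=15.0, resid_sd=15.0)
        results = fit_factorial_lme(table, "value")
        inter = next(r for r in results if r.term == "Session:Language")
        rejections += inter.p < alpha
    return {"n_replicates": n_replicates, "rate": rejections / n_replicates}


def lme_session_power(n_replicates: int = 100, n_subjects: int = 40,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Detection rate of a -30 ms/session latency decrease (subject SD 15 ms)."""
    detected = 0
    for rep in range(n_replicates):
        table = simulate_measures_table(
            n_subjects, seed=derive_seed(seed, "power", rep),
            grand_mean=200.0,
            session_effect={"T1": 0.0, "T2": -30.0, "T3": -60.0},
            subject_sd=15.0, resid_sd=15.0)
        results = fit_factorial_lme(table, "value")
        session = next(r for r in results if r.term == "Session")
        detected += session.p < alpha
    return {"n_replicates": n_replicates, "rate": detected / n_replicates}
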