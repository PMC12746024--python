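"""Synthetic oddball EEG cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
85%/15% standard/deviant sequences in which deviants never occur twice in a
row, Gaussian-bump P1/N1/P2 morphology inside the canonical search windows,
an additive mismatch component so that deviant - standard equals the injected
MMR exactly, 1/f background noise, session-dependent latency decreases and
topographic centroid drifts, subject-level random intercepts, and injectable
artifacts sized to trip the rejection rules.

Because component shapes are Gaussian, peak latency/amplitude and the
amplitude-weighted scalp centroid of every injected effect are analytically
known, which is what makes downstream parameter-recovery tests possible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .config import COMPONENT_WINDOWS, ParadigmConfig
from .containers import DEVIANT, STANDARD, ContinuousRecording, EventSequence
from .io import write_events, write_recording
from .montage import ElectrodeMontage, build_default_montage

__all__ = [
    "ComponentSpec", "CohortSpec", "derive_seed", "generate_event_sequence",
    "build_component_template", "shift_topography", "pink_noise",
    "synthesize_subject_session", "synthesize_cohort", "default_cohort_spec",
    "simulate_measures_table",
]

SESSIONS = ("T1", "T2", "T3")
LANGUAGES = ("native", "nonnative")


def derive_seed(master: int, *parts) -> int:
    """Stable sub-seed below 2**31 from a master seed and a key path."""
    key = "|".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: a Gaussian bump with a fixed scalp topography.

    ``topography`` holds nonnegative per-channel weights summing to 1;
    ``amplitude_uv`` is signed (N1 negative).  The latency must lie inside
    the component's canonical search window.
    """

    label: str
    latency_ms: float
    amplitude_uv: float
    width_ms: float
    topography: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_WINDOWS:
            raise ValueError(f"unknown component label {self.label!r}")
        lo, hi = COMPONENT_WINDOWS[self.label]
        if not lo <= self.latency_ms <= hi:
            raise ValueError(
                f"{self.label} latency {self.latency_ms} ms outside search "
                f"window [{lo}, {hi}]"
            )
        if not self.width_ms > 0:
            raise ValueError("width_ms must be positive")
        topo = np.asarray(self.topography, dtype=float)
        if topo.ndim != 1 or np.any(topo < -1e-12):
            raise ValueError("topography must be a 1-D nonnegative weight vector")
        if abs(topo.sum() - 1.0) > 1e-9:
            raise ValueError("topography weights must sum to 1")
        topo = np.clip(topo, 0.0, None)
        topo.setflags(write=False)
        object.__setattr__(self, "topography", topo)


# default scalp weight patterns (channel order F5 Fz F6 C5 Cz C6 P5 Pz P6 M1 M2)
_DEFAULT_TOPOS = {
    "P1": [0.08, 0.16, 0.08, 0.10, 0.20, 0.10, 0.05, 0.12, 0.05, 0.03, 0.03],
    "N1": [0.10, 0.18, 0.10, 0.09, 0.20, 0.09, 0.04, 0.10, 0.04, 0.03, 0.03],
    "P2": [0.06, 0.14, 0.06, 0.10, 0.24, 0.10, 0.05, 0.13, 0.05, 0.035, 0.035],
    "MMR": [0.10, 0.18, 0.10, 0.09, 0.20, 0.09, 0.04, 0.10, 0.04, 0.03, 0.03],
}


@dataclass
class CohortSpec:
    """Ground-truth description of a simulated longitudinal cohort.

    Deviant responses are standard responses plus one additive MMR component
    per language, so the true difference waveform equals the MMR template by
    construction.  ``latency_shift_ms`` and ``com_shift`` describe per-session
    maturation: a common latency shift of the obligatory components and a
    per-component displacement of the topographic centroid relative to T1.
    """

    components: dict  # label -> ComponentSpec (standard response, T1 baseline)
    mmr: dict         # language -> ComponentSpec
    latency_shift_ms: dict = field(default_factory=lambda: {"T1": 0.0, "T2": -30.0, "T3": -60.0})
    com_shift: dict = field(default_factory=dict)  # label -> session -> 3-vector
    n_per_session: dict = field(default_factory=lambda: {"T1": 59, "T2": 72, "T3": 46})
    n_subjects_pool: int = 83
    noise_sd_uv: float = 15.0
    artifact_rate: float = 0.05
    amplitude_sd_uv: float = 8.0
    latency_jitter_sd_ms: float = 15.0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")
        for lang, spec in self.mmr.items():
            if spec.label != "MMR":
                raise ValueError(f"mmr[{lang!r}] must be an MMR component")


def default_cohort_spec(montage: ElectrodeMontage | None = None, **overrides) -> CohortSpec:
    """Study-shaped defaults: session counts 59/72/46 from a pool of 83,
    P1/N1/P2 morphology, a ~2 uV frontocentral MMR, 30 ms/session latency
    decrease, and paper-scale topographic drifts (P1 posterior-left-inferior,
    N1/MMR net anterior by T3)."""
    if montage is None:
        montage = build_default_montage()

    def comp(label, lat, amp, width):
        return ComponentSpec(label, lat, amp, width,
                             np.asarray(_DEFAULT_TOPOS[label], dtype=float))

    # amplitudes are in uV *before* the sum-to-one topography weights; the
    # frontocentral patterns give a vertex-montage gain of ~0.15, so these
    # values yield vertex peaks of roughly +6 (P1), -4 (N1), +5 (P2) and a
    # 1-2 uV MMR, the infant CAEP scale
    components = {
        "P1": comp("P1", 200.0, 40.0, 40.0),
        "N1": comp("N1", 350.0, -25.0, 45.0),
        "P2": comp("P2", 620.0, 35.0, 60.0),
    }
    mmr = {
        "native": comp("MMR", 300.0, 12.0, 60.0),
        "nonnative": comp("MMR", 300.0, 9.0, 60.0),
    }
    com_shift = {
        "P1": {"T2": np.array([-0.014, -0.027, -0.024]),
               "T3": np.array([-0.028, -0.054, -0.048])},
        "N1": {"T2": np.array([0.0, -0.035, 0.0]),
               "T3": np.array([0.0, 0.058, 0.0])},
        "MMR": {"T2": np.array([0.0, -0.018, 0.0]),
                "T3": np.array([0.0, 0.060, 0.0])},
    }
    spec = CohortSpec(components=components, mmr=mmr, com_shift=com_shift)
    return replace(spec, **overrides) if overrides else spec


def generate_event_sequence(
    n_trials: int,
    deviant_prob: float,
    isi_ms: float,
    stim_ms: float,
    seed: int,
    sampling_rate: float = 1000.0,
    start_sample: int = 2000,
) -> EventSequence:
    """Oddball label sequence with no successive deviants.

    After a deviant the next label is forced standard; otherwise a deviant is
    drawn with probability p' = p/(1-p), which makes the stationary deviant
    fraction equal ``deviant_prob``.  The first event is always standard.
    Onsets are spaced by stimulus duration + ISI.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if not 0 < deviant_prob < 0.5:
        raise ValueError("deviant_prob must be in (0, 0.5): the no-successive-"
                         "deviants constraint is unsatisfiable at higher rates")
    p_prime = deviant_prob / (1.0 - deviant_prob)
    rng = np.random.default_rng(seed)
    draws = rng.random(n_trials)
    labels = np.empty(n_trials, dtype=object)
    labels[0] = STANDARD
    for i in range(1, n_trials):
        if labels[i - 1] == DEVIANT:
            labels[i] = STANDARD
        else:
            labels[i] = DEVIANT if draws[i] < p_prime else STANDARD
    soa = int(round((stim_ms + isi_ms) * sampling_rate / 1000.0))
    onsets = start_sample + np.arange(n_trials) * soa
    return EventSequence(onsets, labels)


def build_component_template(
    spec: ComponentSpec,
    sampling_rate: float,
    epoch_window_ms: tuple[float, float],
    latency_shift_ms: float = 0.0,
    amplitude_offset_uv: float = 0.0,
    topography: np.ndarray | None = None,
) -> np.ndarray:
    """Channels x time Gaussian bump: amp * topo[c] * exp(-(t-lat)^2 / 2w^2)."""
    tmin, tmax = epoch_window_ms
    n_t = int(round((tmax - tmin + 1) * sampling_rate / 1000.0))
    t = tmin + np.arange(n_t) * 1000.0 / sampling_rate
    topo = spec.topography if topography is None else np.asarray(topography, float)
    lat = spec.latency_ms + latency_shift_ms
    amp = spec.amplitude_uv + amplitude_offset_uv
    bump = np.exp(-((t - lat) ** 2) / (2.0 * spec.width_ms ** 2))
    return amp * np.outer(topo, bump)


def shift_topography(
    weights: np.ndarray,
    montage: ElectrodeMontage,
    delta: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Redistribute nonnegative channel weights so the amplitude-weighted
    centroid moves by ``delta`` (normalized units).

    Solves min ||w - w0||^2 subject to w >= 0, sum(w) = 1 and C^T w = target
    via a heavily weighted least-squares stack; raises if the target centroid
    is infeasible (outside the montage's convex hull).
    """
    w0 = np.asarray(weights, dtype=float)
    w0 = w0 / w0.sum()
    coords = montage.coordinates
    target = coords.T @ w0 + np.asarray(delta, dtype=float)
    lam = 1e4
    A = np.vstack([np.eye(len(w0)),
                   lam * np.ones((1, len(w0))),
                   lam * coords.T])
    b = np.concatenate([w0, [lam], lam * target])
    res = lsq_linear(A, b, bounds=(0.0, np.inf), tol=1e-14)
    w = res.x / res.x.sum()
    achieved = coords.T @ w
    if np.linalg.norm(achieved - target) > max(tol, 1e-3):
        raise ValueError(
            f"requested centroid shift {np.asarray(delta)} is infeasible for "
            f"this montage (residual {np.linalg.norm(achieved - target):.2e})"
        )
    return w


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               sd_uv, sampling_rate: float) -> np.ndarray:
    """1/f-spectrum Gaussian noise via FFT shaping.

    ``sd_uv`` may be a scalar or a per-channel array of target SDs.
    """
    sd_uv = np.broadcast_to(np.asarray(sd_uv, float), (n_channels,))
    if np.all(sd_uv == 0):
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    noise = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    noise *= sd_uv[:, None] / noise.std(axis=1, keepdims=True)
    return noise


def _session_topography(spec: ComponentSpec, montage: ElectrodeMontage,
                        com_shift: dict, session: str) -> np.ndarray:
    delta = com_shift.get(spec.label, {}).get(session)
    if delta is None or not np.any(np.asarray(delta)):
        return spec.topography
    return shift_topography(spec.topography, montage, delta)


def _inject_artifact(data: np.ndarray, onset: int, n_pre: int, n_post: int,
                     rng: np.random.Generator, sampling_rate: float) -> None:
    """Inject one artifact inside the epoch span of an event, in place.

    Flavors: a large smooth voltage excursion, an abrupt sustained offset
    (step-like), or a high-kurtosis spike burst.  All are sized so the epoch
    still violates at least one rejection rule after 1-18 Hz filtering.
    """
    n_ch, n_samples = data.shape
    kind = rng.integers(3)
    ch = int(rng.integers(n_ch))
    # keep the artifact's support well inside the epoch so filter smearing
    # cannot leak it into a neighboring epoch
    lo = onset - n_pre + int(0.15 * sampling_rate)
    hi = onset + n_post - int(0.15 * sampling_rate)
    center = int(rng.integers(lo, hi))
    t = np.arange(n_samples)
    if kind == 0:  # voltage excursion > 150 uV
        amp = rng.uniform(400.0, 600.0) * rng.choice([-1.0, 1.0])
        width = 0.05 * sampling_rate
        span = slice(max(0, center - int(4 * width)), min(n_samples, center + int(4 * width)))
        data[ch, span] += amp * np.exp(-((t[span] - center) ** 2) / (2 * width ** 2))
    elif kind == 1:  # step-like: abrupt sustained offset
        amp = rng.uniform(1500.0, 2500.0) * rng.choice([-1.0, 1.0])
        dur = int(0.12 * sampling_rate)
        data[ch, center:center + dur] += amp
    else:  # high-kurtosis burst of alternating spikes
        amp = rng.uniform(500.0, 800.0)
        for k in range(8):
            pos = center + int(k * 0.012 * sampling_rate)
            if pos < n_samples:
                data[ch, pos:pos + 3] += amp * (-1.0) ** k


def synthesize_subject_session(
    cohort: CohortSpec,
    subject: str,
    session: str,
    language: str,
    montage: ElectrodeMontage | None = None,
    seed: int | None = None,
) -> tuple[ContinuousRecording, EventSequence]:
    """One continuous recording: template train + 1/f noise + artifacts.

    Subject random effects (amplitude intercepts and a latency offset) are
    derived from the subject id alone, so they are stable across sessions.
    """
    if montage is None:
        montage = build_default_montage()
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    if language not in cohort.mmr:
        raise ValueError(f"unknown language {language!r}")
    if seed is None:
        seed = derive_seed(cohort.seed, "recording", subject, session, language)
    rng = np.random.default_rng(seed)
    subj_rng = np.random.default_rng(derive_seed(cohort.seed, "subject", subject))
    amp_offsets = {lbl: subj_rng.normal(0.0, cohort.amplitude_sd_uv)
                   for lbl in ("P1", "N1", "P2", "MMR")}
    lat_offset = subj_rng.normal(0.0, cohort.latency_jitter_sd_ms)

    par = cohort.paradigm
    fs = cohort.sampling_rate
    events = generate_event_sequence(
        par.n_trials, par.deviant_prob, par.isi_ms, par.stim_ms,
        seed=derive_seed(seed, "events"), sampling_rate=fs,
    )
    n_pre = int(round(0.200 * fs))
    n_post = int(round(0.800 * fs))
    n_samples = int(events.onsets[-1] + n_post + 2 * fs)

    window = (-200.0, 799.0)
    shift = cohort.latency_shift_ms.get(session, 0.0) + lat_offset
    std_template = np.zeros((montage.n_channels,
                             int(round((window[1] - window[0] + 1) * fs / 1000.0))))
    for lbl, spec in cohort.components.items():
        topo = _session_topography(spec, montage, cohort.com_shift, session)
        std_template += build_component_template(
            spec, fs, window, latency_shift_ms=shift,
            amplitude_offset_uv=amp_offsets[lbl] * np.sign(spec.amplitude_uv),
            topography=topo)
    mmr_spec = cohort.mmr[language]
    mmr_topo = _session_topography(mmr_spec, montage, cohort.com_shift, session)
    mmr_template = build_component_template(
        mmr_spec, fs, window, latency_shift_ms=shift,
        amplitude_offset_uv=amp_offsets["MMR"] * np.sign(mmr_spec.amplitude_uv),
        topography=mmr_topo)
    dev_template = std_template + mmr_template

    # mild per-channel noise heterogeneity (~10% lognormal), as in real caps
    sd_per_ch = cohort.noise_sd_uv * np.exp(rng.normal(0.0, 0.1,
                                                       montage.n_channels))
    data = pink_noise(rng, montage.n_channels, n_samples, sd_per_ch, fs)
    n_t = std_template.shape[1]
    for onset, label in zip(events.onsets, events.labels):
        template = dev_template if label == DEVIANT else std_template
        start = onset - n_pre
        data[:, start:start + n_t] += template
    if cohort.artifact_rate > 0:
        hit = rng.random(len(events)) < cohort.artifact_rate
        for onset in events.onsets[hit]:
            _inject_artifact(data, int(onset), n_pre, n_post, rng, fs)

    rec = ContinuousRecording(
        data, fs, montage,
        metadata={"subject": subject, "session": session, "language": language,
                  "seed": int(seed)},
    )
    return rec, events


def synthesize_cohort(
    cohort: CohortSpec,
    out_dir: str | Path,
    montage: ElectrodeMontage | None = None,
) -> pd.DataFrame:
    """Write one recording per subject x attended-session x language.

    Accelerated-longitudinal attendance: per session, the required number of
    subjects is drawn from a fixed pool, so not every subject attends every
    session; per-session manifest counts match ``n_per_session`` exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if montage is None:
        montage = build_default_montage()
    pool = [f"S{i + 1:03d}" for i in range(cohort.n_subjects_pool)]
    rows = []
    for session in SESSIONS:
        n = cohort.n_per_session.get(session, 0)
        if n > len(pool):
            raise ValueError(f"session {session} needs {n} subjects but pool has {len(pool)}")
        att_rng = np.random.default_rng(derive_seed(cohort.seed, "attendance", session))
        attendees = sorted(att_rng.choice(pool, size=n, replace=False).tolist())
        for subject in attendees:
            for language in LANGUAGES:
                seed = derive_seed(cohort.seed, "recording", subject, session, language)
                rec, events = synthesize_subject_session(
                    cohort, subject, session, language, montage, seed=seed)
                stem = f"sub-{subject}_ses-{session}_lang-{language}"
                rec_path = out_dir / f"{stem}.h5"
                ev_path = out_dir / f"{stem}_events.tsv"
                write_recording(rec, rec_path)
                write_events(events, ev_path)
                rows.append({
                    "subject": subject, "session": session, "language": language,
                    "recording": rec_path.name, "events": ev_path.name,
                    "seed": seed,
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def simulate_measures_table(
    n_subjects: int,
    seed: int,
    grand_mean: float = 0.0,
    session_effect: dict | None = None,
    language_effect: float = 0.0,
    interaction: dict | None = None,
    subject_sd: float = 15.0,
    resid_sd: float = 15.0,
    measure: str = "value",
) -> pd.DataFrame:
    """Subject x session x language measures drawn from the mixed model
    y = mu + session + language + interaction + subject-intercept + noise.

    Used for statistical calibration at desk scale without simulating EEG.
    ``session_effect`` maps session -> additive shift; ``interaction`` maps
    (session, language) -> shift; ``language_effect`` is added for the
    nonnative condition.
    """
    rng = np.random.default_rng(seed)
    session_effect = session_effect or {}
    interaction = interaction or {}
    rows = []
    intercepts = rng.normal(0.0, subject_sd, size=n_subjects)
    for i in range(n_subjects):
        subject = f"S{i + 1:03d}"
        for session in SESSIONS:
            for language in LANGUAGES:
                y = (grand_mean
                     + session_effect.get(session, 0.0)
                     + (language_effect if language == "nonnative" else 0.0)
                     + interaction.get((session, language), 0.0)
                     + intercepts[i]
                     + rng.normal(0.0, resid_sd))
                rows.append({"subject": subject, "session": session,
                             "language": language, measure: y})
    return pd.DataFrame(rows)
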