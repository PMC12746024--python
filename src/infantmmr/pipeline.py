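"""End-to-end orchestration: simulate -> preprocess -> match -> ERP -> peaks
-> topography -> statistics, with deterministic seeding and provenance.

Every stage seed is derived by stable hashing of (master seed, subject,
session, language, stage), so results are reproducible bit-for-bit from one
config and master seed, and adding subjects does not perturb existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import Config, default_config, load_config
from .containers import DEVIANT, STANDARD
from .erp import (bayes_factor_series, bootstrap_erp, compute_mmr,
                  ttest_fdr_series, window_peak_bf)
from .matching import match_preceding_standard, match_random_subset
from .montage import build_default_montage
from .peaks import make_vertex_waveform, measure_all_components, vertex_series
from .preprocessing import preprocess
from .io import read_recording
from .simulate import (CohortSpec, default_cohort_spec, derive_seed,
                       synthesize_cohort)
from .stats import (analyze_log_bf, fit_factorial_lme, summarize_descriptives)
from .topography import (amplitudes_at_latency, component_weights,
                         compute_center_of_mass, topography_report)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_all", "process_recording"]

_FLOAT_FMT = "%.6g"


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    software_version: str
    stages: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add_stage(self, name: str, inputs: list[str], outputs: list[str],
                  seed: int | None = None) -> None:
        self.stages.append({"stage": name, "inputs": inputs, "outputs": outputs,
                            "seed": seed})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _config_hash(cfg: Config) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_recording(rec, events, cfg: Config, seed: int) -> dict:
    """Preprocess one recording and compute its ERP-level results."""
    epochs = preprocess(rec, events, cfg)
    if cfg.matching.strategy == "random":
        pairs = match_random_subset(epochs, seed=derive_seed(seed, "match"))
    else:
        pairs = match_preceding_standard(epochs)
    n_boot = cfg.bootstrap.n_boot
    std_est = bootstrap_erp(epochs, pairs.standard_indices, n_boot,
                            seed=derive_seed(seed, "boot", "standard"))
    dev_est = bootstrap_erp(epochs, pairs.deviant_indices, n_boot,
                            seed=derive_seed(seed, "boot", "deviant"))
    mmr = compute_mmr(dev_est, std_est)
    std_trials = vertex_series(epochs.data[pairs.standard_indices], epochs.channel_names)
    dev_trials = vertex_series(epochs.data[pairs.deviant_indices], epochs.channel_names)
    mmr.bf10 = bayes_factor_series(std_trials, dev_trials, cfg.bayes.cauchy_scale)
    mmr.p_raw, mmr.q_fdr, mmr.significant = ttest_fdr_series(
        std_trials, dev_trials, cfg.fdr.q_level)
    mmr_window = tuple(cfg.peaks.windows.get("MMR", (150.0, 450.0)))
    mmr.window_peak_bf = window_peak_bf(mmr.bf10, mmr.times_ms, mmr_window)
    peaks = measure_all_components(std_est, dev_est, mmr, cfg)
    return {"epochs": epochs, "pairs": pairs, "std_est": std_est,
            "dev_est": dev_est, "mmr": mmr, "peaks": peaks,
            "bf_max": mmr.window_peak_bf}


def _peak_measures(peaks: pd.DataFrame, subject: str, session: str,
                   language: str) -> list[dict]:
    rows = []
    for _, r in peaks.iterrows():
        if not r["found"]:
            logger.info("peak %s/%s not found for %s %s %s: excluded",
                        r["component"], r["waveform_kind"], subject, session, language)
            continue
        base = {"subject": subject, "session": session, "language": language,
                "component": r["component"], "waveform_kind": r["waveform_kind"]}
        rows.append({**base, "measure": "latency", "value": r["latency_ms"]})
        rows.append({**base, "measure": "amplitude", "value": r["amplitude_uv"]})
    return rows


def _compute_topography(subject_results: list[dict], cfg: Config) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-latency weighted CoM per component x condition x session, plus
    pooled-language 'combined' rows, and the displacement report."""
    montage = build_default_montage()
    frame = pd.DataFrame([
        {"session": r["session"], "language": r["language"], "res": r}
        for r in subject_results
    ])
    com_specs = [("P1", "standard"), ("N1", "standard"), ("P2", "standard"),
                 ("MMR", "difference")]
    coms = {}
    com_rows = []
    sessions = sorted(frame["session"].unique())
    for component, kind in com_specs:
        for condition in ("native", "nonnative", "combined"):
            for session in sessions:
                sel = frame[frame["session"] == session]
                if condition != "combined":
                    sel = sel[sel["language"] == condition]
                lats, amp_rows = [], []
                for r in sel["res"]:
                    pk = r["peaks"]
                    row = pk[(pk["component"] == component)
                             & (pk["waveform_kind"] == kind) & pk["found"]]
                    if len(row):
                        lats.append(float(row["latency_ms"].iloc[0]))
                if not lats:
                    continue
                group_latency = float(np.mean(lats))
                for r in sel["res"]:
                    est = r["mmr"] if kind == "difference" else r["std_est"]
                    wave = est.difference if kind == "difference" else est.mean
                    amps = amplitudes_at_latency(wave, est.times_ms, group_latency)
                    full = np.full(montage.n_channels, np.nan)
                    for i, ch in enumerate(est.channel_names):
                        full[montage.index(ch)] = amps[i]
                    amp_rows.append(full)
                weights = component_weights(np.array(amp_rows))
                if weights.sum() <= 0:
                    continue
                com = compute_center_of_mass(weights, montage, component,
                                             session, condition)
                coms[(component, condition, session)] = com
                com_rows.append({
                    "component": component, "condition": condition,
                    "session": session, "group_latency_ms": group_latency,
                    "x": com.coords[0], "y": com.coords[1], "z": com.coords[2],
                    "weight_total": com.weight_total,
                })
    report = topography_report(coms)
    return pd.DataFrame(com_rows), report


def run_all(config: Config | str | Path | None, out_dir: str | Path,
            seed: int = 0) -> RunManifest:
    """Run the whole pipeline for a (simulated) cohort into ``out_dir``.

    Result tables: peaks.csv, measures.csv, lme_results.csv (interaction
    summary shaped like the 14-test table), descriptives_*.csv, com.csv,
    com_displacement.csv, logbf_lme.csv, logbf_proportions.csv.
    """
    cfg = config if isinstance(config, Config) else (
        load_config(config) if config is not None else default_config())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(cfg), seed, __version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    # stage 1: simulate
    sim_dir = out_dir / "sim"
    cohort = default_cohort_spec(
        n_per_session=dict(cfg.cohort.n_per_session),
        n_subjects_pool=cfg.cohort.n_subjects_pool,
        noise_sd_uv=cfg.cohort.noise_sd_uv,
        artifact_rate=cfg.cohort.artifact_rate,
        amplitude_sd_uv=cfg.cohort.amplitude_sd_uv,
        latency_jitter_sd_ms=cfg.cohort.latency_jitter_sd_ms,
        paradigm=cfg.paradigm,
        seed=derive_seed(seed, "simulate"),
    )
    sim_manifest = synthesize_cohort(cohort, sim_dir)
    manifest.add_stage("simulate", [], [str(sim_dir / "manifest.csv")],
                       seed=cohort.seed)

    # stage 2: per-recording analysis
    subject_results = []
    peak_rows, bf_rows = [], []
    for _, row in sim_manifest.iterrows():
        ctx = f"{row['subject']} {row['session']} {row['language']}"
        try:
            rec, events = read_recording(sim_dir / row["recording"],
                                         sim_dir / row["events"])
            sub_seed = derive_seed(seed, "analyze", row["subject"],
                                   row["session"], row["language"])
            res = process_recording(rec, events, cfg, sub_seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'analyze' failed for {ctx}: {exc}") from exc
        res.update(subject=row["subject"], session=row["session"],
                   language=row["language"])
        subject_results.append(res)
        peak_rows.extend(_peak_measures(res["peaks"], row["subject"],
                                        row["session"], row["language"]))
        bf_rows.append({"subject": row["subject"], "session": row["session"],
                        "language": row["language"], "bf_max": res["bf_max"]})
    measures = pd.DataFrame(peak_rows)
    bf_table = pd.DataFrame(bf_rows)
    measures.to_csv(out_dir / "measures.csv", index=False, float_format=_FLOAT_FMT)
    bf_table.to_csv(out_dir / "bf_max.csv", index=False, float_format=_FLOAT_FMT)
    manifest.add_stage("analyze", [str(sim_dir)],
                       [str(out_dir / "measures.csv"), str(out_dir / "bf_max.csv")])

    # stage 3: topography
    com_table, com_report = _compute_topography(subject_results, cfg)
    com_table.to_csv(out_dir / "com.csv", index=False, float_format=_FLOAT_FMT)
    com_report.to_csv(out_dir / "com_displacement.csv", index=False,
                      float_format=_FLOAT_FMT)
    manifest.add_stage("topography", [str(out_dir / "measures.csv")],
                       [str(out_dir / "com.csv"),
                        str(out_dir / "com_displacement.csv")])

    # stage 4: factorial statistics (14 measures) + descriptives + log-BF
    lme_rows = []
    specs = [("MMR", m, "difference") for m in ("amplitude", "latency")]
    specs += [(c, m, w) for c in ("P1", "N1", "P2")
              for m in ("latency", "amplitude") for w in ("deviant", "standard")]
    for component, measure, waveform in specs:
        sub = measures[(measures["component"] == component)
                       & (measures["measure"] == measure)
                       & (measures["waveform_kind"] == waveform)]
        try:
            results = fit_factorial_lme(sub, "value")
        except ValueError as exc:
            logger.warning("LME skipped for %s %s %s: %s", component, measure,
                           waveform, exc)
            continue
        for r in results:
            lme_rows.append({
                "peak": component, "measure": measure.capitalize(),
                "waveform": waveform.capitalize(), "term": r.term,
                "F": round(r.F, 4), "df1": r.df1, "df2": round(r.df2, 1),
                "p": round(r.p, 4), "eta_p2": round(r.eta_p2, 3),
                "sig": "*" if r.p < cfg.stats.alpha else "",
            })
    pd.DataFrame(lme_rows).to_csv(out_dir / "lme_results.csv", index=False,
                                  float_format=_FLOAT_FMT)

    for measure in ("amplitude", "latency"):
        sub = measures[(measures["component"] == "MMR")
                       & (measures["measure"] == measure)]
        if len(sub):
            desc = summarize_descriptives(sub, "value")
            desc.to_csv(out_dir / f"descriptives_mmr_{measure}.csv", index=False,
                        float_format=_FLOAT_FMT)

    try:
        logbf_results, props = analyze_log_bf(bf_table, strong=cfg.bayes.strong)
        pd.DataFrame([{
            "term": r.term, "F": round(r.F, 4), "df1": r.df1,
            "df2": round(r.df2, 1), "p": round(r.p, 4),
            "eta_p2": round(r.eta_p2, 3),
        } for r in logbf_results]).to_csv(out_dir / "logbf_lme.csv", index=False,
                                          float_format=_FLOAT_FMT)
        props.to_csv(out_dir / "logbf_proportions.csv", index=False,
                     float_format=_FLOAT_FMT)
    except ValueError as exc:
        logger.warning("log-BF analysis skipped: %s", exc)
    manifest.add_stage("stats", [str(out_dir / "measures.csv")],
                       [str(out_dir / "lme_results.csv")])

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "run_manifest.json")
    return manifest
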