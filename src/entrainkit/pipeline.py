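"""End-to-end orchestration: simulate -> preprocess -> entrain -> time-course -> stats.

A run is described by a single TOML config with per-module sections; the
master seed deterministically spawns per-subject seeds so any subject can
be recomputed in isolation.  Every run writes a manifest with SHA-256
hashes of the config and of each output, making reruns verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .entrainment import scalp_average, surrogate_null, word_precision_index, z_itc, compute_itc
from .preprocess import PreprocConfig, preprocess
from .stream import Lexicon, generate_stream, write_events
from .synth import fxs_preset, make_cohort, tdc_preset
from .stats import group_report
from .timecourse import fit_timecourse, pseudovalue_series

logger = logging.getLogger("entrainkit")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_full_pipeline",
           "subject_summaries"]


class ConfigError(ValueError):
    """Aggregated configuration errors, one message per offending field."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "results/run"
    # stream
    repetitions_per_word: int = 200
    syllable_duration: float = 0.300
    # cohort
    n_tdc: int = 31
    n_fxs: int = 17
    n_channels: int = 32
    sampling_rate: float = 1000.0
    # entrainment
    n_surrogates: int = 100
    jitter: float = 0.9
    # preprocessing
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    # time-course
    first_half_only: bool = True


_SECTIONS = {
    "run": {"seed", "out_dir"},
    "stream": {"repetitions_per_word", "syllable_duration"},
    "cohort": {"n_tdc", "n_fxs", "n_channels", "sampling_rate"},
    "entrainment": {"n_surrogates", "jitter"},
    "preproc": {"notch_hz", "bandpass", "ab_threshold", "epoch_duration",
                "every_k_words", "filter_order", "notch_quality",
                "exclude_channels"},
    "timecourse": {"first_half_only"},
}


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run config, aggregating all errors."""
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)

    errors: list[str] = []
    flat: dict = {}
    preproc_kwargs: dict = {}
    for section, content in raw.items():
        if section not in _SECTIONS:
            errors.append(f"unknown section [{section}]")
            continue
        for key, value in content.items():
            if key not in _SECTIONS[section]:
                errors.append(f"unknown key {section}.{key}")
            elif section == "preproc":
                preproc_kwargs[key] = (
                    tuple(value) if isinstance(value, list) else value
                )
            else:
                flat[key] = value

    def check(cond: bool, msg: str) -> None:
        if not cond:
            errors.append(msg)

    check(flat.get("syllable_duration", 0.3) > 0,
          "stream.syllable_duration: must be > 0")
    check(flat.get("repetitions_per_word", 200) >= 1,
          "stream.repetitions_per_word: must be >= 1")
    check(flat.get("n_tdc", 31) >= 0, "cohort.n_tdc: must be >= 0")
    check(flat.get("n_fxs", 17) >= 0, "cohort.n_fxs: must be >= 0")
    fs = flat.get("sampling_rate", 1000.0)
    check(fs >= 250, "cohort.sampling_rate: must be >= 250 Hz")
    check(flat.get("n_surrogates", 100) >= 2,
          "entrainment.n_surrogates: must be >= 2")
    check(flat.get("jitter", 0.9) >= 0, "entrainment.jitter: must be >= 0")

    bandpass = preproc_kwargs.get("bandpass", (0.5, 20.0))
    if not (0 < bandpass[0] < bandpass[1]):
        errors.append("preproc.bandpass: must satisfy 0 < low < high")
    elif bandpass[1] >= fs / 2:
        errors.append(
            f"preproc.bandpass: high edge {bandpass[1]} Hz >= Nyquist {fs / 2} Hz"
        )
    if preproc_kwargs.get("ab_threshold", 50.0) <= 0:
        errors.append("preproc.ab_threshold: must be > 0")

    if errors:
        raise ConfigError(errors)
    return RunConfig(preproc=PreprocConfig(**preproc_kwargs), **flat)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def subject_summaries(cohort, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-subject zITC/WPI summaries and pseudovalue tables for a cohort.

    Returns (summaries, pseudovalue table, per-group zITC spectra).
    """
    rng = np.random.default_rng(config.seed + 1)
    surrogate_seeds = rng.integers(0, 2**31 - 1, size=len(cohort))
    rows, pv_frames = [], []
    spectra: dict[str, list[np.ndarray]] = {}
    for i, subj in enumerate(cohort):
        t0 = time.perf_counter()
        cleaned, epochs = preprocess(
            subj.recording, subj.stream, config.preproc, subject_id=subj.subject_id
        )
        observed = compute_itc(epochs)
        null = surrogate_null(
            cleaned,
            epochs.onsets,
            config.preproc,
            n_surrogates=config.n_surrogates,
            jitter=config.jitter,
            seed=int(surrogate_seeds[i]),
        )
        z = z_itc(observed, null, subj.stream, cleaned.channel_labels)
        wpi = word_precision_index(z)
        rows.append(
            {
                "subject": subj.subject_id,
                "group": subj.group,
                "zitc_word": scalp_average(z, z.word_bin),
                "zitc_syllable": scalp_average(z, z.syllable_bin),
                "wpi": wpi.wpi,
                "n_epochs": epochs.n_epochs,
            }
        )
        spectra.setdefault(subj.group, []).append(np.nanmean(z.values, axis=0))
        for freq in ("word", "syllable"):
            series = pseudovalue_series(
                epochs, freq, subj.stream.word_rate, subj.stream.syllable_rate
            )
            pv_frames.append(
                series.to_frame(group=subj.group,
                                stream_duration=subj.stream.duration)
            )
        logger.info(
            "subject %s (%s): entrainment stage done in %.2fs",
            subj.subject_id, subj.group, time.perf_counter() - t0,
        )
    summaries = pd.DataFrame(rows)
    pv_table = pd.concat(pv_frames, ignore_index=True)
    spectra_arr = {g: np.vstack(v) for g, v in spectra.items()}
    return summaries, pv_table, spectra_arr


def run_full_pipeline(config: RunConfig) -> dict:
    """Run simulate -> preprocess -> entrain -> time-course -> stats.

    Writes events.tsv, subject_summaries.csv, pseudovalues.csv,
    group_stats.json, timecourse_fit.json and manifest.json under
    ``config.out_dir`` and returns the result bundle as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lexicon = Lexicon(syllable_duration=config.syllable_duration)
    stream = generate_stream(lexicon, config.repetitions_per_word,
                             seed=config.seed)
    events_path = write_events(stream, out / "events.tsv")
    logger.info("stream: %d tokens, %.1f s", stream.n_tokens, stream.duration)

    preset_kwargs = dict(n_channels=config.n_channels,
                         sampling_rate=config.sampling_rate)
    cohort = make_cohort(
        config.n_tdc, config.n_fxs, stream,
        tdc_params=tdc_preset(**preset_kwargs),
        fxs_params=fxs_preset(**preset_kwargs),
        seed=config.seed,
    )
    summaries, pv_table, _ = subject_summaries(cohort, config)

    report = group_report(summaries)
    word_pv = pv_table[pv_table["frequency"] == "word"]
    tc_fit = fit_timecourse(word_pv, first_half_only=config.first_half_only)
    tc_dict = dataclasses.asdict(tc_fit)

    summaries_path = out / "subject_summaries.csv"
    summaries.to_csv(summaries_path, index=False)
    pv_path = out / "pseudovalues.csv"
    pv_table.to_csv(pv_path, index=False)
    stats_path = out / "group_stats.json"
    stats_path.write_text(json.dumps(report, indent=2))
    tc_path = out / "timecourse_fit.json"
    tc_path.write_text(json.dumps(tc_dict, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": {
            p.name: _sha256(p)
            for p in (events_path, summaries_path, pv_path, stats_path, tc_path)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"summaries": summaries, "pseudovalues": pv_table,
            "group_stats": report, "timecourse": tc_dict,
            "manifest": manifest}
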