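"""Synthetic two-condition EEG-like datasets.

The generator emulates the layout of a five-channel concealed-information
lie-detection study: 27 subjects x 2 conditions (lie / truth) x
5 channels (AF3, T7, PZ, T8, AF4) x 25 trials of 3 s at 128 Hz.

Signal model per trial and channel:

    x(t) = alpha oscillation + theta oscillation + 1/f (pink) noise

with subject-level jitter on oscillation frequencies and amplitudes
(``subject_sd``) so that subjects are internally consistent but mutually
different — the property that makes leave-one-subject-out harder than
within-subject cross-validation.  In the "lie" condition, channels in
``informative_channels`` receive additional broadband white noise whose
variance is ``effect_size`` times the baseline signal variance.  The
class contrast is therefore carried by signal *complexity* (extra
broadband irregularity raises entropy) rather than by a simple gain
change: the amplitude-adaptive tolerance (r proportional to the
standard deviation) strongly damps sensitivity to overall amplitude,
so the entropy features must pick up the structural difference.

All randomness flows through a single seeded generator; regenerating
with the same config is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fuzzent.io import (
    LIE,
    MONTAGE,
    TRUTH,
    Recording,
    TrialSet,
    save_manifest,
    write_recording,
)

__all__ = ["SimConfig", "SubjectParams", "generate_trial", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study-layout and effect parameters of the synthetic generator."""

    n_subjects: int = 27
    n_trials_per_condition: int = 25
    trial_seconds: float = 3.0
    fs: float = 128.0
    channels: tuple[str, ...] = MONTAGE
    informative_channels: tuple[str, ...] = ("PZ", "T7")
    #: variance of the extra lie-condition broadband noise, as a fraction
    #: of the baseline signal variance on the informative channels
    effect_size: float = 0.4
    #: relative sd of subject-level jitter on oscillation frequency/amplitude
    subject_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.informative_channels) <= set(self.channels):
            raise ValueError(
                f"informative channels {self.informative_channels} not all in "
                f"montage {self.channels}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if min(self.n_subjects, self.n_trials_per_condition) < 1:
            raise ValueError("subject and trial counts must be positive")
        if self.trial_seconds <= 0 or self.fs <= 0:
            raise ValueError("trial_seconds and fs must be positive")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_seconds * self.fs))


@dataclass(frozen=True)
class SubjectParams:
    """Subject-level signal parameters drawn once per subject."""

    alpha_freq: float
    theta_freq: float
    alpha_amp: float
    theta_amp: float
    noise_amp: float
    channel_gain: dict[str, float]


def _draw_subject(cfg: SimConfig, rng: np.random.Generator) -> SubjectParams:
    jitter = lambda base: base * float(
        np.clip(1.0 + cfg.subject_sd * rng.standard_normal(), 0.3, 2.5)
    )
    return SubjectParams(
        alpha_freq=float(np.clip(jitter(10.0), 8.0, 13.0)),
        theta_freq=float(np.clip(jitter(5.5), 4.0, 8.0)),
        alpha_amp=jitter(1.0),
        theta_amp=jitter(0.6),
        noise_amp=jitter(0.7),
        channel_gain={ch: jitter(1.0) for ch in cfg.channels},
    )


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC component
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_trial(
    cond: str,
    channel: str,
    subject_params: SubjectParams,
    rng: np.random.Generator,
    cfg: SimConfig,
) -> np.ndarray:
    """One trial of one channel under the given condition.

    Baseline: two band-limited oscillations with per-trial random phases
    plus pink noise.  "lie" trials on informative channels add white
    noise with variance ``effect_size`` times the baseline variance;
    non-informative channels are identically distributed across
    conditions.
    """
    if cond not in ("lie", "truth"):
        raise ValueError(f"condition must be 'lie' or 'truth', got {cond!r}")
    p = subject_params
    n = cfg.samples_per_trial
    t = np.arange(n) / cfg.fs
    gain = p.channel_gain[channel]
    phase_a, phase_t = rng.uniform(0, 2 * np.pi, size=2)
    osc = p.alpha_amp * np.sin(2 * np.pi * p.alpha_freq * t + phase_a)
    osc += p.theta_amp * np.sin(2 * np.pi * p.theta_freq * t + phase_t)
    x = gain * (osc + p.noise_amp * _pink_noise(n, rng))
    if cond == "lie" and channel in cfg.informative_channels and cfg.effect_size > 0:
        extra_sd = np.sqrt(cfg.effect_size) * x.std()
        x = x + extra_sd * rng.standard_normal(n)
    return x


def generate_dataset(cfg: SimConfig | None = None) -> dict[str, TrialSet]:
    """Generate the full multi-subject dataset in memory.

    Returns a mapping ``subject_id -> TrialSet`` where each TrialSet
    holds the lie block followed by the truth block
    (``2 * n_trials_per_condition`` balanced trials).
    """
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    dataset: dict[str, TrialSet] = {}
    for s in range(1, cfg.n_subjects + 1):
        subject_id = f"S{s:02d}"
        params = _draw_subject(cfg, rng)
        trials = np.empty(
            (2 * cfg.n_trials_per_condition, len(cfg.channels), cfg.samples_per_trial)
        )
        labels = np.empty(2 * cfg.n_trials_per_condition, dtype=int)
        for c, cond in enumerate(("lie", "truth")):
            for trial in range(cfg.n_trials_per_condition):
                row = c * cfg.n_trials_per_condition + trial
                labels[row] = LIE if cond == "lie" else TRUTH
                for ch_i, ch in enumerate(cfg.channels):
                    trials[row, ch_i] = generate_trial(cond, ch, params, rng, cfg)
        dataset[subject_id] = TrialSet(trials, labels, cfg.fs, cfg.channels, subject_id)
    return dataset


def write_dataset(
    dataset: dict[str, TrialSet], outdir: str | Path, cfg: SimConfig | None = None
) -> Path:
    """Write the dataset as per-subject-per-condition CSVs plus a manifest.

    Each condition's trials are concatenated back into one continuous
    recording (the on-disk layout of the emulated study); the manifest
    records paths, sampling rate, channels, trial structure and marks
    the data as preprocessed (the generator has no DC offset or
    out-of-band noise to remove).
    """
    if cfg is None:
        cfg = SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects: dict[str, dict[str, str]] = {}
    for subject_id, ts in dataset.items():
        entry: dict[str, str] = {}
        for cond, label in (("lie", LIE), ("truth", TRUTH)):
            mask = ts.labels == label
            # (n_cond_trials, n_ch, n_samp) -> continuous (samples, channels)
            cont = np.transpose(ts.trials[mask], (0, 2, 1)).reshape(-1, len(ts.channels))
            rel = f"{subject_id}_{cond}.csv"
            write_recording(
                Recording(cont, ts.fs, ts.channels, subject_id, cond), outdir / rel
            )
            entry[cond] = rel
        subjects[subject_id] = entry
    manifest = {
        "fs": cfg.fs,
        "channels": list(cfg.channels),
        "trial_seconds": cfg.trial_seconds,
        "n_trials_per_condition": cfg.n_trials_per_condition,
        "preprocessed": True,
        "seed": cfg.seed,
        "subjects": subjects,
    }
    path = outdir / "manifest.json"
    save_manifest(manifest, path)
    return path
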