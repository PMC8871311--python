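"""Seeded synthetic EEG emulating the two dataset dialects.

Background activity is 1/f-shaped ("pink") noise plus an alpha-band
(8–12 Hz) sinusoid with per-channel random phase.  Ictal stretches add a
3 Hz spike-and-wave train (fundamental plus two harmonics at halving
amplitudes) whose RMS is ``ictal_gain`` times the nominal background RMS;
at gain 0 the two classes are distributionally identical, which makes
class separability a controllable dial for end-to-end checks.  No
physiological-realism or artifact (eye-blink/EMG) claims are made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._edf import write_edf
from .errors import BoundsError
from .io_formats import BONN_FS, CHBMIT_FS, EEGRecord

CHBMIT_CHANNELS = ("F3-C3", "C3-P3", "F4-C4", "C4-P4")


@dataclass
class SynthConfig:
    """Parameters of the generator; amplitudes in microvolts."""

    fs: float = CHBMIT_FS
    n_channels: int = 4
    duration_s: float = 120.0
    seed: int = 0
    pink_scale: float = 20.0
    alpha_amp: float = 10.0
    ictal_gain: float = 3.0
    spike_hz: float = 3.0
    n_harmonics: int = 2
    ictal_intervals: tuple[tuple[float, float], ...] = ()
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pink_scale < 0 or self.alpha_amp < 0 or self.ictal_gain < 0:
            raise BoundsError("amplitudes and gain must be non-negative")
        for start_s, end_s in self.ictal_intervals:
            if not (0 <= start_s < end_s <= self.duration_s):
                raise BoundsError(
                    f"ictal interval ({start_s}, {end_s}) outside 0..{self.duration_s} s"
                )
        if not self.channel_labels:
            labels = [
                CHBMIT_CHANNELS[i] if i < len(CHBMIT_CHANNELS) else f"ch{i + 1}"
                for i in range(self.n_channels)
            ]
            self.channel_labels = tuple(labels)

    @property
    def background_rms(self) -> float:
        """Nominal RMS of pink + alpha background (sinusoid RMS = amp/sqrt(2))."""
        return float(np.sqrt(self.pink_scale**2 + self.alpha_amp**2 / 2))


def pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-shaped noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _spike_wave(cfg: SynthConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Harmonic spike-and-wave train with unit-free amplitude set by the gain."""
    amps = np.array([0.5**h for h in range(cfg.n_harmonics + 1)])
    # scale so the summed-harmonic RMS equals gain x background RMS
    rms_unit = np.sqrt(np.sum(amps**2) / 2)
    target = cfg.ictal_gain * cfg.background_rms
    wave = np.zeros_like(t)
    for h, a in enumerate(amps):
        phase = rng.uniform(0, 2 * np.pi)
        wave += a * np.sin(2 * np.pi * cfg.spike_hz * (h + 1) * t + phase)
    return wave * (target / rms_unit if rms_unit > 0 else 0.0)


def generate_record(cfg: SynthConfig) -> EEGRecord:
    """Deterministic (seeded) multi-channel record with optional ictal stretches."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    data = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        alpha_f = rng.uniform(8.0, 12.0)
        alpha_phase = rng.uniform(0, 2 * np.pi)
        channel = cfg.pink_scale * pink_noise(rng, n) + cfg.alpha_amp * np.sin(
            2 * np.pi * alpha_f * t + alpha_phase
        )
        # dedicated stream so spike-phase draws never perturb the background,
        # keeping gain-0 records bitwise independent of the interval list
        spike_rng = np.random.default_rng([cfg.seed, 1000 + ch])
        for start_s, end_s in cfg.ictal_intervals:
            i0, i1 = round(start_s * cfg.fs), round(end_s * cfg.fs)
            channel[i0:i1] += _spike_wave(cfg, t[i0:i1], spike_rng)
        data[ch] = channel
    annotations = [(s, e, "ictal") for s, e in cfg.ictal_intervals]
    return EEGRecord(data, fs=cfg.fs, channel_labels=list(cfg.channel_labels),
                     annotations=annotations)


def generate_single_channel_samples(
    cfg: SynthConfig, n_samples: int, ictal: bool, rng: np.random.Generator
) -> np.ndarray:
    """One single-channel stretch; whole-stretch spike-wave when ictal."""
    t = np.arange(n_samples) / cfg.fs
    alpha_f = rng.uniform(8.0, 12.0)
    alpha_phase = rng.uniform(0, 2 * np.pi)
    x = cfg.pink_scale * pink_noise(rng, n_samples) + cfg.alpha_amp * np.sin(
        2 * np.pi * alpha_f * t + alpha_phase
    )
    if ictal:
        x += _spike_wave(cfg, t, rng)
    return x


def generate_labeled_segments(
    cfg: SynthConfig, n_per_class: int, n_samples: int = 512
) -> list:
    """In-memory single-channel segments, one independent draw per segment.

    Unlike :func:`generate_bonn_like_corpus`, every segment gets its own
    alpha frequency/phase and noise realization, so rows are statistically
    independent — the right setting for chance-level (gain 0) checks, where
    shared per-file structure would otherwise leak class labels through a
    row-level train/test split.
    """
    from .io_formats import ICTAL, NON_ICTAL, Segment

    segments = []
    for class_idx, (label, ictal) in enumerate([(NON_ICTAL, False), (ICTAL, True)]):
        for k in range(n_per_class):
            rng = np.random.default_rng([cfg.seed, class_idx, k])
            x = generate_single_channel_samples(cfg, n_samples, ictal, rng)
            segments.append(Segment(x, cfg.fs, label, source_id=f"synth-{label}-{k}"))
    return segments


def generate_bonn_like_corpus(
    cfg: SynthConfig,
    n_files: int,
    out_dir: str | Path,
    samples_per_file: int = 4096,
) -> dict[str, list[Path]]:
    """Write ``n_files`` ASCII files per class (one integer sample per line).

    Non-ictal files (Z prefix) carry background only; ictal files (S prefix)
    are spike-wave dominated throughout.  Regeneration with the same seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[Path]] = {"non_ictal": [], "ictal": []}
    for class_idx, (prefix, key, ictal) in enumerate(
        [("Z", "non_ictal", False), ("S", "ictal", True)]
    ):
        for k in range(n_files):
            rng = np.random.default_rng([cfg.seed, class_idx, k])
            x = generate_single_channel_samples(cfg, samples_per_file, ictal, rng)
            path = out_dir / f"{prefix}{k + 1:03d}.txt"
            np.savetxt(path, np.rint(x).astype(int), fmt="%d")
            paths[key].append(path)
    return paths


def generate_chbmit_like_corpus(
    cfg: SynthConfig,
    n_seizure_records: int,
    n_background_records: int,
    out_dir: str | Path,
    ictal_interval: tuple[float, float] = (30.0, 80.0),
) -> Path:
    """Write EDF records plus an annotations JSON; returns the JSON path.

    Seizure records contain one ictal interval each; background records none.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index: dict[str, list[list[float]]] = {}
    for k in range(n_seizure_records):
        rec_cfg = _reseed(cfg, [cfg.seed, 10, k], ictal_intervals=(ictal_interval,))
        name = f"seiz{k + 1:03d}.edf"
        write_edf(generate_record(rec_cfg), out_dir / name)
        index[name] = [list(ictal_interval)]
    for k in range(n_background_records):
        rec_cfg = _reseed(cfg, [cfg.seed, 11, k], ictal_intervals=())
        name = f"bkg{k + 1:03d}.edf"
        write_edf(generate_record(rec_cfg), out_dir / name)
        index[name] = []
    ann_path = out_dir / "annotations.json"
    ann_path.write_text(json.dumps(index, indent=1))
    return ann_path


def _reseed(cfg: SynthConfig, seed_seq, **overrides) -> SynthConfig:
    # derive a scalar sub-seed so nested configs remain plain integers
    sub = int(np.random.SeedSequence(seed_seq).generate_state(1)[0] % (2**31))
    kwargs = {**cfg.__dict__, "seed": sub, **overrides}
    kwargs.pop("channel_labels", None)
    return SynthConfig(**kwargs)
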