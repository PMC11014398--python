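"""Synthetic audio pools standing in for the real source corpora.

Four parametric signal families are generated: speech-like clips (harmonic
stack on a drifting fundamental, formant-shaped, syllabically amplitude
modulated), background event textures (~40 classes of colored noise and
impulsive events), bird-like frequency-modulated whistles, and long ambient
soundscape beds.  The families are deliberately spectrally separable —
speech energy concentrates below 1 kHz, bird energy in 2-8 kHz — so a small
CNN can learn the detection task at desk scale.

All generators are pure functions of their arguments and a seed; each call
draws from its own ``numpy.random.Generator``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import InvalidArgumentError

__all__ = [
    "AudioClip",
    "FixturePools",
    "PoolConfig",
    "synth_speech_like",
    "synth_background",
    "synth_bird_like",
    "synth_soundscape",
    "apply_distance",
    "build_fixture_pools",
    "write_wav",
    "read_wav",
    "N_BACKGROUND_CLASSES",
]

N_BACKGROUND_CLASSES = 40

ClipKind = Literal["speech", "background", "bird", "soundscape", "mixed"]
Register = Literal["low_pitch", "high_pitch"]

_REGISTER_F0 = {"low_pitch": (85.0, 180.0), "high_pitch": (165.0, 300.0)}


@dataclass
class AudioClip:
    """A bounded-amplitude mono waveform."""

    samples: np.ndarray
    sample_rate: int
    kind: ClipKind
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("AudioClip samples must be 1-D")
        if self.samples.size < 1:
            raise InvalidArgumentError("AudioClip must contain at least one sample")
        peak = float(np.abs(self.samples).max())
        if peak > 1.0 + 1e-6:
            raise InvalidArgumentError(f"AudioClip samples exceed [-1, 1] (peak {peak:.3f})")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples.astype(np.float64) ** 2)))


@dataclass
class FixturePools:
    speech: list[AudioClip]
    background: list[AudioClip]
    bird: list[AudioClip]
    soundscape: list[AudioClip]

    def validate(self) -> None:
        lows = sum(1 for c in self.speech if c.meta.get("register") == "low_pitch")
        highs = sum(1 for c in self.speech if c.meta.get("register") == "high_pitch")
        if lows != highs:
            raise InvalidArgumentError(f"speech registers unbalanced: {lows} low vs {highs} high")


def _n_samples(duration_s: float, sample_rate: int) -> int:
    if duration_s <= 0:
        raise InvalidArgumentError(f"duration must be positive, got {duration_s}")
    n = int(round(duration_s * sample_rate))
    return max(n, 1)


def _normalize_peak(x: np.ndarray, peak: float = 0.9) -> np.ndarray:
    m = np.abs(x).max()
    if m > 0:
        x = x * (peak / m)
    return x.astype(np.float32)


def _colored_noise(n: int, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ f^(-slope), unit peak-ish scale."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec *= freqs ** (-slope / 2.0)
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def synth_speech_like(duration_s: float, register: Register, seed: int) -> AudioClip:
    """Voiced, speech-like clip: harmonic stack on a drifting fundamental.

    The fundamental wanders inside the register's range (low 85-180 Hz,
    high 165-300 Hz), harmonics are shaped by 2-3 resonant formant-like
    peaks, and the whole signal is amplitude modulated at a 2-8 Hz syllabic
    rate with silent gaps between bursts.
    """
    if register not in _REGISTER_F0:
        raise InvalidArgumentError(f"unknown register {register!r}")
    sr = 16_000
    n = _n_samples(duration_s, sr)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sr

    lo, hi = _REGISTER_F0[register]
    f0_center = rng.uniform(lo * 1.1, hi * 0.9)
    drift = (hi - lo) * 0.15 * np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * t + rng.uniform(0, 2 * np.pi))
    jitter = _colored_noise(n, 2.0, rng) * 2.0
    f0 = np.clip(f0_center + drift + jitter, lo, hi)
    phase = 2 * np.pi * np.cumsum(f0) / sr

    n_formants = rng.integers(2, 4)
    formant_centers = np.sort(rng.uniform(300, 2800, size=n_formants))
    formant_bw = rng.uniform(120, 260, size=n_formants)

    voiced = np.zeros(n)
    n_harm = int(4000 / f0_center)
    for h in range(1, n_harm + 1):
        fh = f0_center * h
        # resonant envelope: sum of Lorentzian formant peaks + 1/h rolloff
        env = sum(
            bw**2 / ((fh - fc) ** 2 + bw**2) for fc, bw in zip(formant_centers, formant_bw)
        )
        amp = (0.25 + env) / h
        voiced += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))

    syllable_rate = rng.uniform(2.0, 8.0)
    am = 0.5 * (1 + np.sin(2 * np.pi * syllable_rate * t + rng.uniform(0, 2 * np.pi)))
    gate = np.clip((am - 0.25) / 0.5, 0.0, 1.0) ** 2  # silent gaps between syllables
    out = _normalize_peak(voiced * gate)
    return AudioClip(out, sr, "speech", seed, {"register": register, "f0_center": float(f0_center)})


def synth_background(duration_s: float = 5.0, class_id: int = 1, seed: int = 0) -> AudioClip:
    """Background event texture for one of the configured classes.

    Classes map to colored-noise spectral slopes; every third class also
    carries impulsive events (clicks/knocks) so the pool spans both
    stationary and transient textures.  Default duration 5 s.
    """
    if not 1 <= class_id <= N_BACKGROUND_CLASSES:
        raise InvalidArgumentError(
            f"class_id must be in 1..{N_BACKGROUND_CLASSES}, got {class_id}"
        )
    sr = 16_000
    n = _n_samples(duration_s, sr)
    rng = np.random.default_rng(np.random.SeedSequence([seed, class_id]))
    slope = 2.0 * (class_id - 1) / (N_BACKGROUND_CLASSES - 1)  # white .. brown
    out = _colored_noise(n, slope, rng)
    if class_id % 3 == 0:
        n_events = rng.integers(2, 8)
        for _ in range(n_events):
            pos = rng.integers(0, max(n - sr // 10, 1))
            width = rng.integers(sr // 200, sr // 20)
            burst = rng.standard_normal(width) * np.hanning(width) * rng.uniform(2, 6)
            out[pos : pos + width] += burst[: max(0, n - pos)]
    return AudioClip(_normalize_peak(out), sr, "background", seed, {"class_id": class_id})


def synth_bird_like(duration_s: float, species_id: int, seed: int) -> AudioClip:
    """Frequency-modulated whistle bouts in the 2-8 kHz band.

    The FM pattern (carrier center, modulation depth/rate, bout timing) is a
    deterministic function of the species id, giving each species a
    distinct chirp signature.
    """
    sr = 16_000
    n = _n_samples(duration_s, sr)
    rng = np.random.default_rng(np.random.SeedSequence([seed, species_id]))
    srng = np.random.default_rng(species_id)  # species-level signature
    t = np.arange(n) / sr

    center = srng.uniform(2800.0, 6800.0)
    fm_rate = srng.uniform(3.0, 30.0)
    fm_depth = srng.uniform(200.0, min(900.0, center - 2100, 7900 - center))
    bout_rate = srng.uniform(1.5, 5.0)

    inst_freq = center + fm_depth * np.sin(2 * np.pi * fm_rate * t + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(inst_freq) / sr
    carrier = np.sin(phase)
    bout = 0.5 * (1 + signal.square(2 * np.pi * bout_rate * t + rng.uniform(0, 2 * np.pi), duty=0.45))
    bout = signal.sosfiltfilt(signal.butter(2, 40.0, fs=sr, output="sos"), bout)
    bout = np.clip(bout, 0.0, 1.0)
    out = _normalize_peak(carrier * bout)
    return AudioClip(out, sr, "bird", seed, {"species_id": species_id})


def synth_soundscape(
    duration_s: float = 55.0,
    sample_rate: int = 44_100,
    seed: int = 0,
    flavor: str = "forest",
) -> AudioClip:
    """Low-level ambient bed: wind/rain-like colored noise with sparse distant events.

    Defaults mirror the source recordings: 55 s at 44.1 kHz.  ``flavor``
    selects a spectral slope family (``forest`` is darker, ``grassland``
    windier/brighter).
    """
    if flavor not in ("forest", "grassland"):
        raise InvalidArgumentError(f"unknown soundscape flavor {flavor!r}")
    n = _n_samples(duration_s, sample_rate)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, {"forest": 0, "grassland": 1}[flavor]])
    )
    slope = 1.8 if flavor == "forest" else 1.2
    bed = _colored_noise(n, slope, rng) * 0.05
    # sparse distant events (faint thumps / rustles)
    n_events = rng.integers(0, max(2, int(duration_s / 8)) + 1)
    for _ in range(n_events):
        pos = rng.integers(0, max(n - sample_rate, 1))
        width = rng.integers(sample_rate // 10, sample_rate // 2)
        env = np.hanning(width)
        ev = _colored_noise(width, 1.0, rng) * env * 0.04
        seg = min(width, n - pos)
        bed[pos : pos + seg] += ev[:seg]
    out = np.clip(bed, -1.0, 1.0).astype(np.float32)
    return AudioClip(out, sample_rate, "soundscape", seed, {"flavor": flavor})


def apply_distance(clip: AudioClip, distance_m: float) -> AudioClip:
    """Propagation proxy: inverse-distance gain plus distance-dependent low-pass.

    Gain follows the 1/r law referenced to 1 m; high-frequency loss (an air
    absorption proxy) is a first-order Butterworth low-pass whose cutoff
    decreases with distance.  Output is re-bounded to [-1, 1].
    """
    if distance_m < 1.0:
        raise InvalidArgumentError(f"distance_m must be >= 1, got {distance_m}")
    x = clip.samples.astype(np.float64) / distance_m
    nyq = clip.sample_rate / 2
    cutoff = min(0.95 * nyq, 7200.0 / np.sqrt(distance_m))
    sos = signal.butter(1, cutoff, fs=clip.sample_rate, output="sos")
    x = signal.sosfilt(sos, x)
    x = np.clip(x, -1.0, 1.0)
    return AudioClip(
        x.astype(np.float32),
        clip.sample_rate,
        clip.kind,
        clip.seed,
        {**clip.meta, "distance_m": float(distance_m)},
    )


# ---------------------------------------------------------------------------
# WAV I/O (16-bit PCM mono)
# ---------------------------------------------------------------------------


def write_wav(path: Path | str, clip: AudioClip) -> None:
    data = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(data * 32767.0).astype(np.int16)
    wavfile.write(str(path), clip.sample_rate, pcm)


def read_wav(path: Path | str, kind: ClipKind = "mixed") -> AudioClip:
    try:
        sr, pcm = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt container
        raise IOError(f"failed to read WAV file {path}: {exc}") from exc
    if pcm.ndim != 1:
        raise IOError(f"expected mono WAV, got shape {pcm.shape} in {path}")
    if pcm.dtype == np.int16:
        samples = pcm.astype(np.float32) / 32767.0
    else:
        samples = pcm.astype(np.float32)
    return AudioClip(np.clip(samples, -1, 1), int(sr), kind)


# ---------------------------------------------------------------------------
# pool builder
# ---------------------------------------------------------------------------


@dataclass
class PoolConfig:
    n_speech: int = 40
    n_background: int = 40
    n_bird: int = 20
    n_soundscape: int = 4
    n_background_classes: int = N_BACKGROUND_CLASSES
    speech_duration_s: float = 3.0
    background_duration_s: float = 5.0
    bird_duration_s: float = 3.0
    soundscape_duration_s: float = 55.0
    soundscape_rate: int = 44_100

    def __post_init__(self):
        if self.n_speech % 2:
            raise InvalidArgumentError("n_speech must be even for a 1:1 register balance")


def build_fixture_pools(
    config: PoolConfig, seed: int, outdir: Path | str | None = None
) -> FixturePools:
    """Generate all pools; optionally persist WAVs plus a manifest CSV.

    The speech pool is exactly balanced between the two pitch registers.
    Rerunning with the same config and seed reproduces identical audio.
    """
    ss = np.random.SeedSequence(seed)
    base = int(ss.generate_state(1)[0])

    speech = []
    for i in range(config.n_speech):
        register = "low_pitch" if i < config.n_speech // 2 else "high_pitch"
        speech.append(synth_speech_like(config.speech_duration_s, register, base + i))
    background = [
        synth_background(
            config.background_duration_s,
            class_id=(i % config.n_background_classes) + 1,
            seed=base + 10_000 + i,
        )
        for i in range(config.n_background)
    ]
    bird = [
        synth_bird_like(config.bird_duration_s, species_id=(i % 12) + 1, seed=base + 20_000 + i)
        for i in range(config.n_bird)
    ]
    soundscape = [
        synth_soundscape(config.soundscape_duration_s, config.soundscape_rate, base + 30_000 + i)
        for i in range(config.n_soundscape)
    ]
    pools = FixturePools(speech, background, bird, soundscape)
    pools.validate()

    if outdir is not None:
        outdir = Path(outdir)
        try:
            outdir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise IOError(f"cannot create pool directory {outdir}: {exc}") from exc
        rows = []
        for pool_name, clips in (
            ("speech", speech),
            ("background", background),
            ("bird", bird),
            ("soundscape", soundscape),
        ):
            for i, clip in enumerate(clips):
                path = outdir / f"{pool_name}_{i:04d}.wav"
                write_wav(path, clip)
                rows.append(
                    {
                        "path": str(path),
                        "kind": clip.kind,
                        "register_or_class": clip.meta.get("register")
                        or clip.meta.get("class_id")
                        or clip.meta.get("species_id")
                        or "",
                        "duration_s": round(clip.duration_s, 6),
                        "sample_rate": clip.sample_rate,
                        "seed": clip.seed,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "pool_manifest.csv", index=False)
    return pools


def manifest_checksum(path: Path | str) -> str:
    """SHA-256 of a manifest file's bytes (determinism checks)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
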