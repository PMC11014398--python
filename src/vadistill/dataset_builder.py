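"""Soundscape preprocessing: segmentation, SNR mixing, dataset and playback builds.

Long ambient recordings are cut into non-overlapping 3-s segments at 16 kHz,
then augmented with speech / background / bird events at controlled SNRs to
produce a balanced, labeled clip collection with train/val/test splits, plus
a playback-style evaluation set crossing distances, voice types and
environments.

All builders are pure functions of (pools, config, seed): rerunning with the
same arguments reproduces the audio and manifests bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidArgumentError
from .fixtures import AudioClip, FixturePools, apply_distance, write_wav

__all__ = [
    "MixRecord",
    "DatasetManifest",
    "PlaybackRecord",
    "segment_soundscape",
    "mix_at_snr",
    "build_dataset",
    "split_dataset",
    "build_playback_set",
    "DEFAULT_SNR_RANGE_DB",
]

SEGMENT_SAMPLES = 48_000
TARGET_RATE = 16_000
DEFAULT_SNR_RANGE_DB = (-6.0, 18.0)

DISTANCES_M = (1.0, 5.0, 10.0, 20.0)
VOICE_TYPES = ("male", "female", "child")
ENVIRONMENTS = ("forest", "grassland")


@dataclass
class MixRecord:
    path: str
    label: int
    snr_db: float | None
    components: list[tuple[str, int, float]]  # (source kind, source index, gain)
    seed: int
    split: str = "none"

    def __post_init__(self):
        has_speech = any(kind == "speech" for kind, _, _ in self.components)
        if bool(self.label) != has_speech:
            raise InvalidArgumentError("label must be 1 iff a speech component is present")
        if (self.snr_db is not None) != bool(self.label):
            raise InvalidArgumentError("snr_db must be present iff label = 1")


@dataclass
class DatasetManifest:
    records: list[MixRecord]

    @property
    def class_balance(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.label for r in self.records) / len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [r.path for r in self.records],
                "label": [r.label for r in self.records],
                "split": [r.split for r in self.records],
                "snr_db": [r.snr_db for r in self.records],
                "components": [
                    ";".join(f"{k}:{i}:{g:.6g}" for k, i, g in r.components)
                    for r in self.records
                ],
                "seed": [r.seed for r in self.records],
            }
        )

    def save(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: Path | str) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        records = []
        for row in df.itertuples(index=False):
            components = []
            if row.components:
                for part in str(row.components).split(";"):
                    kind, idx, gain = part.split(":")
                    components.append((kind, int(idx), float(gain)))
            snr = None if pd.isna(row.snr_db) else float(row.snr_db)
            records.append(
                MixRecord(row.path, int(row.label), snr, components, int(row.seed), row.split)
            )
        return cls(records)


@dataclass
class PlaybackRecord:
    path: str
    label: int
    distance_m: float
    voice_type: str
    environment: str
    seed: int
    speech_rms: float | None = None  # RMS of the attenuated speech component (label 1)


def segment_soundscape(
    clip: AudioClip, segment_s: float = 3.0, target_rate: int = TARGET_RATE
) -> list[AudioClip]:
    """Cut a recording into consecutive non-overlapping segments at ``target_rate``.

    The clip is resampled first (polyphase; the single resampler used across
    the package), then split into half-open windows of exactly
    ``segment_s * target_rate`` samples; any trailing remainder is dropped.
    A clip shorter than one segment yields an empty list.
    """
    if clip.sample_rate != target_rate:
        from math import gcd

        g = gcd(target_rate, clip.sample_rate)
        x = signal.resample_poly(
            clip.samples.astype(np.float64), target_rate // g, clip.sample_rate // g
        )
        x = np.clip(x, -1.0, 1.0)
    else:
        x = clip.samples.astype(np.float64)
    seg_len = int(round(segment_s * target_rate))
    n_segments = x.size // seg_len
    return [
        AudioClip(
            x[i * seg_len : (i + 1) * seg_len].astype(np.float32),
            target_rate,
            clip.kind,
            clip.seed,
            {**clip.meta, "segment_index": i},
        )
        for i in range(n_segments)
    ]


def mix_at_snr(
    base: AudioClip, event: AudioClip, snr_db: float, rng: np.random.Generator
) -> AudioClip:
    """Mix ``event`` into ``base`` at the requested event-to-base SNR.

    The event is scaled so ``10*log10(rms_event^2 / rms_base^2) = snr_db``,
    placed at a random offset fully inside the base, and summed.  The output
    is peak-normalized only if the sum exceeds 1 in magnitude.
    """
    if base.sample_rate != event.sample_rate:
        raise InvalidArgumentError("mix_at_snr requires equal sample rates")
    base_rms = base.rms()
    if base_rms == 0.0:
        raise InvalidArgumentError("cannot mix into a silent base (RMS 0)")
    ev = event.samples.astype(np.float64)
    if ev.size > base.samples.size:
        ev = ev[: base.samples.size]
    ev_rms = np.sqrt(np.mean(ev**2))
    if ev_rms == 0.0:
        raise InvalidArgumentError("event has zero RMS")
    gain = (base_rms / ev_rms) * 10.0 ** (snr_db / 20.0)
    out = base.samples.astype(np.float64).copy()
    offset = int(rng.integers(0, base.samples.size - ev.size + 1))
    out[offset : offset + ev.size] += gain * ev
    peak = np.abs(out).max()
    if peak > 1.0:
        out /= peak
    return AudioClip(
        out.astype(np.float32),
        base.sample_rate,
        "mixed",
        base.seed,
        {"offset": offset, "gain": float(gain)},
    )


def _segment_pool(pools: FixturePools) -> list[AudioClip]:
    segments: list[AudioClip] = []
    for clip in pools.soundscape:
        segments.extend(segment_soundscape(clip))
    if not segments:
        raise InvalidArgumentError("soundscape pool yields no 3-s segments")
    return segments


def _event_at_rate(clip: AudioClip) -> AudioClip:
    if clip.sample_rate == TARGET_RATE:
        return clip
    segs = segment_soundscape(clip, clip.duration_s, TARGET_RATE)
    return segs[0] if segs else clip


def build_dataset(
    pools: FixturePools,
    n_total: int = 20_000,
    balance: float = 0.5,
    snr_range_db: tuple[float, float] = DEFAULT_SNR_RANGE_DB,
    seed: int = 0,
    outdir: Path | str = "dataset",
    p_extra_event: float = 0.5,
) -> DatasetManifest:
    """Emit ``n_total`` labeled 3-s clips mixed from the fixture pools.

    Label-1 clips carry exactly one speech event at an SNR drawn uniformly
    from ``snr_range_db`` (plus, with probability ``p_extra_event``, one
    background or bird event); label-0 clips carry one or two background /
    bird events only.  The label split equals ``balance`` exactly.
    """
    if not pools.speech or not pools.background or not pools.soundscape:
        raise InvalidArgumentError("fixture pools must be non-empty")
    n_pos_f = n_total * balance
    if abs(n_pos_f - round(n_pos_f)) > 1e-9:
        raise InvalidArgumentError(
            f"n_total * balance must be integral, got {n_total} * {balance}"
        )
    n_pos = int(round(n_pos_f))
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create dataset directory {outdir}: {exc}") from exc

    bases = _segment_pool(pools)
    speech = [_event_at_rate(c) for c in pools.speech]
    noise_events = [_event_at_rate(c) for c in pools.background] + [
        _event_at_rate(c) for c in pools.bird
    ]
    noise_kinds = ["background"] * len(pools.background) + ["bird"] * len(pools.bird)

    rng = np.random.default_rng(seed)
    records: list[MixRecord] = []
    labels = np.array([1] * n_pos + [0] * (n_total - n_pos))
    for i in range(n_total):
        label = int(labels[i])
        clip_seed = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(clip_seed)
        base = bases[int(crng.integers(0, len(bases)))]
        mixed = base
        components: list[tuple[str, int, float]] = []
        snr: float | None = None
        if label:
            snr = float(crng.uniform(*snr_range_db))
            j = int(crng.integers(0, len(speech)))
            mixed = mix_at_snr(mixed, speech[j], snr, crng)
            components.append(("speech", j, mixed.meta["gain"]))
            extra = crng.random() < p_extra_event
            n_noise = 1 if extra else 0
        else:
            n_noise = int(crng.integers(1, 3))
        for _ in range(n_noise):
            j = int(crng.integers(0, len(noise_events)))
            noise_snr = float(crng.uniform(-3.0, 12.0))
            mixed = mix_at_snr(mixed, noise_events[j], noise_snr, crng)
            components.append((noise_kinds[j], j, mixed.meta["gain"]))
        path = outdir / f"clip_{i:06d}.wav"
        write_wav(path, mixed)
        records.append(MixRecord(str(path), label, snr, components, clip_seed))
    manifest = DatasetManifest(records)
    manifest.save(outdir / "manifest.csv")
    return manifest


def split_dataset(
    manifest: DatasetManifest,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetManifest:
    """Assign stratified-by-label train/val/test splits.

    Within each label stratum, val and test get ``round(n * ratio)`` records
    and the remainder goes to train.  Assignment order is randomized by
    ``seed``.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidArgumentError(f"split ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    records = [replace(r) for r in manifest.records]
    for label in (0, 1):
        idx = [i for i, r in enumerate(records) if r.label == label]
        if not idx:
            continue
        idx = list(rng.permutation(idx))
        n = len(idx)
        n_val = int(round(n * ratios[1]))
        n_test = int(round(n * ratios[2]))
        n_train = n - n_val - n_test
        for j, i in enumerate(idx):
            if j < n_train:
                records[i].split = "train"
            elif j < n_train + n_val:
                records[i].split = "val"
            else:
                records[i].split = "test"
    out = DatasetManifest(records)
    return out


def build_playback_set(
    pools: FixturePools,
    distances: Sequence[float] = DISTANCES_M,
    voice_types: Sequence[str] = VOICE_TYPES,
    environments: Sequence[str] = ENVIRONMENTS,
    n_per_cell: int = 5,
    seed: int = 0,
    outdir: Path | str = "playback",
) -> list[PlaybackRecord]:
    """Playback-style evaluation clips across distance/voice/environment cells.

    For every (distance, voice, environment) cell, ``n_per_cell`` speech
    clips are attenuated/filtered by :func:`apply_distance` and mixed over
    the environment's ambient bed, paired with ``n_per_cell`` matched
    non-speech clips (bed plus a distant background or bird event).
    """
    from .fixtures import synth_soundscape, synth_speech_like

    if n_per_cell < 1:
        raise InvalidArgumentError("n_per_cell must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    beds: dict[str, list[AudioClip]] = {}
    for env in environments:
        bed = synth_soundscape(30.0, TARGET_RATE, int(rng.integers(0, 2**31 - 1)), flavor=env)
        beds[env] = segment_soundscape(bed)

    low = [c for c in pools.speech if c.meta.get("register") == "low_pitch"]
    high = [c for c in pools.speech if c.meta.get("register") == "high_pitch"]
    if not low or not high:
        raise InvalidArgumentError("speech pool must contain both registers")
    noise_events = [_event_at_rate(c) for c in pools.background + pools.bird]

    def voice_clip(voice: str, crng: np.random.Generator) -> AudioClip:
        if voice == "male":
            return low[int(crng.integers(0, len(low)))]
        clip = high[int(crng.integers(0, len(high)))]
        if voice == "child":
            # child proxy: high register shifted up by resampling (f0 x1.25)
            x = signal.resample_poly(clip.samples.astype(np.float64), 4, 5)
            return AudioClip(
                np.clip(x, -1, 1).astype(np.float32), clip.sample_rate, "speech", clip.seed,
                {**clip.meta, "child_proxy": True},
            )
        return clip

    records: list[PlaybackRecord] = []
    i = 0
    for distance in distances:
        for voice in voice_types:
            for env in environments:
                for label in (1, 0):
                    for _ in range(n_per_cell):
                        clip_seed = int(rng.integers(0, 2**31 - 1))
                        crng = np.random.default_rng(clip_seed)
                        bed = beds[env][int(crng.integers(0, len(beds[env])))]
                        speech_rms = None
                        if label:
                            src = voice_clip(voice, crng)
                            att = apply_distance(src, distance)
                            speech_rms = att.rms()
                            mixed = AudioClip(
                                np.clip(
                                    bed.samples.astype(np.float64)
                                    + _fit_length(att.samples, SEGMENT_SAMPLES, crng),
                                    -1,
                                    1,
                                ).astype(np.float32),
                                TARGET_RATE,
                                "mixed",
                                clip_seed,
                            )
                        else:
                            ev = noise_events[int(crng.integers(0, len(noise_events)))]
                            far = apply_distance(ev, distance)
                            mixed = mix_at_snr(bed, far, float(crng.uniform(-3, 9)), crng)
                        path = outdir / f"playback_{i:05d}.wav"
                        write_wav(path, mixed)
                        records.append(
                            PlaybackRecord(
                                str(path), label, float(distance), voice, env, clip_seed, speech_rms
                            )
                        )
                        i += 1
    frame = pd.DataFrame([vars(r) for r in records])
    frame.to_csv(outdir / "playback_manifest.csv", index=False)
    return records


def _fit_length(x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Place x inside a zero vector of length n at a random offset (trim if longer)."""
    out = np.zeros(n)
    if x.size >= n:
        return x[:n].astype(np.float64)
    offset = int(rng.integers(0, n - x.size + 1))
    out[offset : offset + x.size] = x
    return out
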