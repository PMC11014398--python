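"""Log-Mel featurization: 3-s clips -> 128x128 normalized single-channel grids.

The transform is a centered magnitude STFT (1024-sample Hann window, hop
512, i.e. 64 ms with 50% overlap at 16 kHz), a 128-band Mel filterbank from
0 Hz to Nyquist, log(1 + S) compression of the power Mel energies, linear
interpolation of the 94 raw frames to exactly 128 time steps, and per-clip
z-scoring of each Mel bin along time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .dataset_builder import DatasetManifest
from .errors import InvalidArgumentError, InvalidStateError
from .fixtures import AudioClip, read_wav

__all__ = [
    "MelSpec",
    "MEL_PARAMS",
    "RAW_FRAMES",
    "mel_spectrogram",
    "normalize_per_bin",
    "featurize_manifest",
    "featurize_clips",
    "load_feature_archive",
    "mel_filterbank",
    "mel_center_frequencies",
]

MEL_PARAMS = {"sample_rate": 16_000, "n_fft": 1024, "hop": 512, "n_mels": 128}
# 48,000 samples with centered framing at hop 512 -> 1 + 48000 // 512 = 94 frames
RAW_FRAMES = 94
GRID = 128


@dataclass
class MelSpec:
    grid: np.ndarray
    params: dict = field(default_factory=lambda: dict(MEL_PARAMS))
    normalized: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.shape != (GRID, GRID):
            raise InvalidArgumentError(f"MelSpec grid must be {GRID}x{GRID}, got {self.grid.shape}")


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_center_frequencies(
    n_mels: int = 128, sample_rate: int = 16_000, fmin: float = 0.0
) -> np.ndarray:
    """Center frequencies (Hz) of the triangular Mel filters."""
    edges = _mel_to_hz(
        np.linspace(_hz_to_mel(fmin), _hz_to_mel(sample_rate / 2), n_mels + 2)
    )
    return edges[1:-1]


def mel_filterbank(
    n_mels: int = 128, n_fft: int = 1024, sample_rate: int = 16_000, fmin: float = 0.0
) -> np.ndarray:
    """Triangular Mel filterbank matrix of shape (n_mels, n_fft // 2 + 1)."""
    fft_freqs = np.linspace(0.0, sample_rate / 2, n_fft // 2 + 1)
    edges = _mel_to_hz(
        np.linspace(_hz_to_mel(fmin), _hz_to_mel(sample_rate / 2), n_mels + 2)
    )
    fb = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-9)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _stft_power(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Centered power spectrogram, frames = 1 + len(x) // hop ... truncated to RAW_FRAMES."""
    pad = n_fft // 2
    xp = np.pad(x, (pad, pad), mode="reflect")
    n_frames = 1 + (xp.size - n_fft) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = xp[idx] * np.hanning(n_fft)[None, :]
    spec = np.fft.rfft(frames, axis=1)
    return (np.abs(spec) ** 2).T  # (n_fft//2+1, n_frames)


def mel_spectrogram(clip: AudioClip) -> MelSpec:
    """Compute the un-normalized 128x128 log-Mel grid for a 3-s, 16 kHz clip."""
    if clip.sample_rate != MEL_PARAMS["sample_rate"]:
        raise InvalidArgumentError(
            f"expected {MEL_PARAMS['sample_rate']} Hz input, got {clip.sample_rate}"
        )
    if clip.samples.size != 48_000:
        raise InvalidArgumentError(f"expected 48,000 samples, got {clip.samples.size}")
    power = _stft_power(
        clip.samples.astype(np.float64), MEL_PARAMS["n_fft"], MEL_PARAMS["hop"]
    )
    fb = _filterbank_cached()
    mel = fb @ power  # (128, n_frames)
    mel = np.log1p(mel)
    n_frames = mel.shape[1]
    # linear time interpolation to exactly 128 frames
    src = np.arange(n_frames)
    dst = np.linspace(0, n_frames - 1, GRID)
    grid = np.empty((GRID, GRID), dtype=np.float64)
    for i in range(GRID):
        grid[i] = np.interp(dst, src, mel[i])
    return MelSpec(grid.astype(np.float32), dict(MEL_PARAMS), normalized=False)


_FB_CACHE: dict[tuple, np.ndarray] = {}


def _filterbank_cached() -> np.ndarray:
    key = (MEL_PARAMS["n_mels"], MEL_PARAMS["n_fft"], MEL_PARAMS["sample_rate"])
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(*key)
    return _FB_CACHE[key]


def normalize_per_bin(spec: MelSpec) -> MelSpec:
    """Z-score each Mel bin row along time; constant rows become zeros."""
    if spec.normalized:
        raise InvalidStateError("MelSpec is already normalized")
    grid = spec.grid.astype(np.float64)
    mu = grid.mean(axis=1, keepdims=True)
    sd = grid.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (grid - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return MelSpec(out.astype(np.float32), dict(spec.params), normalized=True)


def featurize_clip(clip: AudioClip) -> MelSpec:
    return normalize_per_bin(mel_spectrogram(clip))


def featurize_clips(clips: list[AudioClip]) -> np.ndarray:
    """Stack normalized grids into an (n, 1, 128, 128) float32 array."""
    return np.stack([featurize_clip(c).grid for c in clips])[:, None, :, :]


def featurize_manifest(manifest: DatasetManifest, outpath: Path | str) -> Path:
    """Featurize every manifest record into an HDF5 archive.

    Datasets: ``features`` (n, 1, 128, 128) float32, ``labels`` (n,) int8,
    ``split`` (n,) bytes, ``path`` (n,) bytes — ordered as the manifest.
    """
    outpath = Path(outpath)
    n = len(manifest.records)
    features = np.empty((n, 1, GRID, GRID), dtype=np.float32)
    labels = np.empty(n, dtype=np.int8)
    splits = []
    paths = []
    for i, record in enumerate(manifest.records):
        try:
            clip = read_wav(record.path)
        except FileNotFoundError as exc:
            raise IOError(f"missing audio file for record {i}: {record.path}") from exc
        except Exception as exc:
            raise IOError(f"unreadable audio file for record {i}: {record.path}: {exc}") from exc
        features[i, 0] = featurize_clip(clip).grid
        labels[i] = record.label
        splits.append(record.split)
        paths.append(record.path)
    with h5py.File(outpath, "w") as f:
        f.create_dataset("features", data=features)
        f.create_dataset("labels", data=labels)
        f.create_dataset("split", data=np.array(splits, dtype="S"))
        f.create_dataset("path", data=np.array(paths, dtype="S"))
    return outpath


def load_feature_archive(path: Path | str) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {
            "features": f["features"][...],
            "labels": f["labels"][...].astype(np.int64),
            "split": f["split"][...].astype("U"),
            "path": f["path"][...].astype("U"),
        }
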