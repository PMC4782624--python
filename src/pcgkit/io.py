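"""Reading, writing and amplitude-normalizing phonocardiogram audio.

Heart-sound recordings are carried through the pipeline as
:class:`AudioSignal` objects: a real-valued sample array plus its sampling
rate. Recording conditions (sensor coupling, thorax thickness, gain) make
raw amplitudes incomparable across subjects, so every analysis starts by
rescaling the waveform to peak amplitude +/-1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioSignal", "read_wav", "write_wav", "normalize"]

#: full scale of a 16-bit PCM sample; int -> float uses the symmetric
#: mapping of the representable range into [-1, 1).
_PCM16_SCALE = 32768.0


@dataclass
class AudioSignal:
    """A sampled phonocardiogram waveform.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence (dimensionless). Must be non-empty and finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str or None
        Optional class tag: ``"normal"``, ``"abnormal"`` or ``None``.
    source_id : str or None
        Free-text provenance (file name, generator spec, ...).
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite-valued")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def replace(self, **changes) -> "AudioSignal":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono PCM WAV file into an :class:`AudioSignal`.

    Integer PCM samples are scaled to floats: 16-bit by 1/32768, 32-bit by
    1/2^31; 8-bit unsigned is centred then scaled by 1/128. Float WAVs pass
    through unchanged. The sampling rate is taken from the file header.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For multi-channel files or unsupported encodings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path.name}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path.name}: unsupported WAV encoding {data.dtype}")
    return AudioSignal(samples=samples, fs=float(fs), source_id=path.name)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM mono WAV.

    Samples are expected in [-1, 1]; they are quantized by rounding
    ``x * 32768`` and clipping to the int16 range, so a read-back differs
    from the original by at most one quantization step (2^-15).
    """
    pcm = np.clip(np.rint(signal.samples * _PCM16_SCALE), -32768, 32767)
    wavfile.write(Path(path), int(round(signal.fs)), pcm.astype(np.int16))


def normalize(signal: AudioSignal) -> AudioSignal:
    """Scale a signal so its maximum absolute amplitude is exactly 1.

    Division by the global peak ``max(|x|)`` maps the waveform into
    [-1, 1] while preserving the sign pattern and relative shape. The
    operation is idempotent and invariant under positive rescaling of the
    input.

    Raises
    ------
    ValueError
        For an all-zero signal (no peak to normalize by).
    """
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    return signal.replace(samples=signal.samples / peak)
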