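"""Low-level acoustic descriptors for advertisement-call recordings.

Each recording (a mono waveform of a single calling male) is cut into
short frames — 40 ms windows advanced by 20 ms — and five descriptors are
computed from the per-frame RMS envelope and magnitude spectra:

* CVA — coefficient of variation of frame RMS amplitude: sd/mean of the
  envelope, a gain-invariant amplitude-modulation measure;
* DF  — dominant frequency: the frequency bin of maximal spectral
  amplitude, averaged over frames (Hz);
* SF  — spectral flux: Euclidean distance between consecutive magnitude
  spectra, averaged over frame pairs (the one gain-sensitive descriptor);
* SI  — spectral irregularity: summed squared amplitude differences
  between adjoining spectral peaks ("partials"), here normalized by the
  summed squared peak amplitudes so the measure is gain-invariant;
* TON — spectral flatness: geometric over arithmetic mean of the power
  spectrum in (0, 1]; near 0 for tonal, near 1 for noise-like spectra.

These are deliberately generic measures that apply to any vocalization —
from pulsatile toad trills to whistle-like calls — rather than
clade-specific characters such as pulse rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from sklearn.base import BaseEstimator

TRAIT_COLUMNS = ["cva", "logdf", "logsf", "logsi", "logton"]
FEATURE_NAMES = ["cva", "df", "sf", "si", "ton"]

#: frames with RMS below this are treated as silence for DF/SI/TON
SILENCE_RMS = 1e-6
#: relative power floor applied before the geometric mean in TON
TON_POWER_FLOOR = 1e-12
#: spectral peaks below this level (relative to frame max) are not partials
SI_PEAK_FLOOR_DB = -40.0


class AudioFormatError(ValueError):
    pass


class InputTooShortError(ValueError):
    pass


class UndefinedFeatureError(ValueError):
    pass


@dataclass
class Recording:
    """A mono waveform with provenance ids; samples nominally in [-1, 1]."""

    samples: np.ndarray
    sample_rate: float
    species_id: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Recording holds a 1-D (mono) sample array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class FrameSeries:
    """Per-frame RMS envelope and magnitude spectra of one recording."""

    frame_rms: np.ndarray          # (n_frames,)
    frame_spectra: np.ndarray      # (n_frames, n_bins) linear magnitude
    bin_freqs: np.ndarray          # (n_bins,) Hz
    window_ms: float
    hop_ms: float
    sample_rate: float

    @property
    def n_frames(self) -> int:
        return len(self.frame_rms)


def _normalize_pcm(data: np.ndarray) -> np.ndarray:
    if data.dtype == np.int16:
        return data / 32768.0
    if data.dtype == np.int32:
        return data / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(float) - 128.0) / 128.0
    if data.dtype in (np.float32, np.float64):
        return data.astype(float)
    raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")


def read_wav(path: str | Path, species_id: str = "", recording_id: str = "") -> Recording:
    """Read a PCM WAV file; multi-channel input is averaged to mono."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"cannot read {path.name}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path.name}: empty WAV file")
    samples = _normalize_pcm(data)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Recording(
        samples, float(rate), species_id, recording_id or path.stem
    )


def write_wav(path: str | Path, rec: Recording) -> None:
    x = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(str(path), int(rec.sample_rate), (x * 32767).astype(np.int16))


def compute_frames(
    rec: Recording, window_ms: float = 40.0, hop_ms: float = 20.0
) -> FrameSeries:
    """Frame a recording and compute per-frame RMS and Hann-windowed spectra.

    Frame count is floor((n_samples - win)/hop) + 1; the FFT size equals the
    window length (no zero padding), so bin spacing is sample_rate/win.
    """
    win = int(round(window_ms / 1000.0 * rec.sample_rate))
    hop = int(round(hop_ms / 1000.0 * rec.sample_rate))
    if win < 2 or hop < 1:
        raise ValueError("window/hop too small for this sample rate")
    n = len(rec.samples)
    if n < win:
        raise InputTooShortError(
            f"recording of {n} samples is shorter than one {win}-sample window"
        )
    n_frames = (n - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = rec.samples[idx]
    rms = np.sqrt((frames**2).mean(axis=1))
    window = np.hanning(win)
    spectra = np.abs(np.fft.rfft(frames * window, axis=1))
    bin_freqs = np.fft.rfftfreq(win, d=1.0 / rec.sample_rate)
    return FrameSeries(rms, spectra, bin_freqs, window_ms, hop_ms, rec.sample_rate)


def cva(fs: FrameSeries) -> float:
    """Coefficient of variation of the frame-RMS envelope (sd / mean)."""
    if fs.n_frames < 2:
        raise InputTooShortError("CVA needs at least two frames")
    m = fs.frame_rms.mean()
    if m <= 0:
        raise UndefinedFeatureError("CVA undefined: all-zero signal")
    return float(fs.frame_rms.std(ddof=0) / m)


def _voiced(fs: FrameSeries) -> np.ndarray:
    return fs.frame_rms >= SILENCE_RMS


def dominant_frequency(fs: FrameSeries) -> float:
    """Frequency of the maximal spectral bin, averaged over voiced frames."""
    voiced = _voiced(fs)
    if not voiced.any():
        raise UndefinedFeatureError("dominant frequency undefined on silence")
    peaks = fs.frame_spectra[voiced].argmax(axis=1)
    return float(fs.bin_freqs[peaks].mean())


def spectral_flux(fs: FrameSeries) -> float:
    """Mean Euclidean distance between consecutive magnitude spectra."""
    if fs.n_frames < 2:
        raise InputTooShortError("spectral flux needs at least two frames")
    d = np.diff(fs.frame_spectra, axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).mean())


def _frame_irregularity(spec: np.ndarray, normalized: bool) -> float | None:
    mx = spec.max()
    if mx <= 0:
        return None
    floor = mx * 10.0 ** (SI_PEAK_FLOOR_DB / 20.0)
    # interior local maxima above the floor are the "partials"
    interior = spec[1:-1]
    is_peak = (interior >= spec[:-2]) & (interior >= spec[2:]) & (interior >= floor)
    amps = interior[is_peak]
    if amps.size == 0:
        return None
    # trailing zero closes the sum, so a lone partial gives exactly 1
    num = float(np.sum(np.diff(np.append(amps, 0.0)) ** 2))
    if not normalized:
        return num
    return num / float(np.sum(amps**2))


def spectral_irregularity(fs: FrameSeries, normalized: bool = True) -> float:
    """Summed squared amplitude differences between adjoining partials.

    Partials are spectral peaks (interior local maxima within 40 dB of the
    frame maximum). With ``normalized`` (default) the sum is divided by the
    summed squared partial amplitudes, making SI gain-invariant; a lone
    partial then scores 1 and an equal-amplitude comb tends to 0.
    Silent frames are skipped.
    """
    vals = [
        v
        for spec, ok in zip(fs.frame_spectra, _voiced(fs))
        if ok and (v := _frame_irregularity(spec, normalized)) is not None
    ]
    if not vals:
        raise UndefinedFeatureError("spectral irregularity undefined: no voiced frames")
    return float(np.mean(vals))


def tonality(fs: FrameSeries) -> float:
    """Spectral flatness: geometric over arithmetic mean of the power spectrum.

    Values near 1 indicate a noise-like (flat) spectrum, values near 0 a
    spiky spectrum with strong partials. Power bins are floored at 1e-12 of
    the frame maximum before the geometric mean; silent frames are skipped.
    """
    voiced = _voiced(fs)
    if not voiced.any():
        raise UndefinedFeatureError("tonality undefined on silence")
    P = fs.frame_spectra[voiced] ** 2
    mx = P.max(axis=1, keepdims=True)
    P = np.maximum(P, mx * TON_POWER_FLOOR)
    geo = np.exp(np.log(P).mean(axis=1))
    arith = P.mean(axis=1)
    return float((geo / arith).mean())


class CallFeatureExtractor(BaseEstimator):
    """Transformer mapping recordings to the five-descriptor feature vector.

    Parameters
    ----------
    window_ms, hop_ms : analysis frame length and advance (defaults 40/20).
    si_normalized : divide SI by the summed squared partial amplitudes
        (gain-invariant variant; default True).
    """

    def __init__(
        self, window_ms: float = 40.0, hop_ms: float = 20.0, si_normalized: bool = True
    ):
        self.window_ms = window_ms
        self.hop_ms = hop_ms
        self.si_normalized = si_normalized

    def extract(self, rec: Recording) -> dict[str, float]:
        fs = compute_frames(rec, self.window_ms, self.hop_ms)
        return {
            "cva": cva(fs),
            "df": dominant_frequency(fs),
            "sf": spectral_flux(fs),
            "si": spectral_irregularity(fs, self.si_normalized),
            "ton": tonality(fs),
        }

    def fit(self, X: Iterable[Recording], y=None):  # stateless transformer
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Iterable[Recording]) -> pd.DataFrame:
        rows = []
        for rec in X:
            row = self.extract(rec)
            row["species_id"] = rec.species_id
            row["recording_id"] = rec.recording_id
            rows.append(row)
        return pd.DataFrame(rows, columns=["species_id", "recording_id", *FEATURE_NAMES])


def extract_features(
    rec: Recording, window_ms: float = 40.0, hop_ms: float = 20.0
) -> dict[str, float]:
    """Five descriptors of one recording (functional form)."""
    return CallFeatureExtractor(window_ms, hop_ms).extract(rec)


def species_trait_table(
    recordings: Sequence[Recording],
    metadata: pd.DataFrame,
    window_ms: float = 40.0,
    hop_ms: float = 20.0,
) -> pd.DataFrame:
    """Aggregate per-recording features to the species-level trait table.

    Feature means are averaged across a species' recordings on the linear
    scale; DF, SF, SI, TON and SVL are then log10-transformed (CVA, being a
    dimensionless coefficient of variation, is left untransformed).

    ``metadata`` needs columns ``species_id``, ``clade``, ``svl_mm``.
    Returns a DataFrame indexed by species_id with columns
    ``clade, cva, logdf, logsf, logsi, logton, logsvl``.
    """
    for col in ("species_id", "clade", "svl_mm"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    meta = metadata.set_index("species_id")
    missing_svl = meta.index[meta["svl_mm"].isna()].tolist()
    if missing_svl:
        raise ValueError(f"missing SVL for species: {missing_svl}")

    feats = CallFeatureExtractor(window_ms, hop_ms).fit([]).transform(recordings)
    by_species = feats.groupby("species_id")[FEATURE_NAMES].mean()

    orphan_meta = sorted(set(meta.index) - set(by_species.index))
    if orphan_meta:
        raise ValueError(f"species without recordings: {orphan_meta}")
    orphan_rec = sorted(set(by_species.index) - set(meta.index))
    if orphan_rec:
        raise ValueError(f"recordings without metadata: {orphan_rec}")

    out = pd.DataFrame(index=by_species.index)
    out["clade"] = meta.loc[out.index, "clade"]
    out["cva"] = by_species["cva"]
    for name in ("df", "sf", "si", "ton"):
        vals = by_species[name]
        if (vals <= 0).any():
            bad = vals.index[vals <= 0].tolist()
            raise ValueError(f"non-positive {name} cannot be log-transformed: {bad}")
        out[f"log{name}"] = np.log10(vals)
    out["logsvl"] = np.log10(meta.loc[out.index, "svl_mm"].astype(float))
    out.index.name = "species_id"
    return out


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.8g")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="species_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Species metadata TSV: ``species_id  clade  svl_mm  wav_paths``."""
    meta = pd.read_csv(path, sep="\t")
    required = {"species_id", "clade", "svl_mm"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta
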