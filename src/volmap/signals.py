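"""Conditioning of body-surface potential recordings.

Two fixed chains are provided.  Clinical recordings pass through a 50 Hz
comb (powerline fundamental plus its first three harmonics at 100/150/200
Hz), a 10th-order Butterworth low-pass at 40 Hz, and a baseline-wander
high-pass at 0.67 Hz.  Simulated recordings (already noise-calibrated) get
only a 10th-order Butterworth low-pass at 50 Hz.  All stages are applied
forward-backward (zero phase), since downstream activation timing is
phase-sensitive; quoted attenuations therefore double in dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.signal as sps

__all__ = [
    "BodySurfaceSignals",
    "condition_signals",
    "channel_qc",
    "read_signals_csv",
    "write_signals_csv",
    "read_signals_h5",
    "write_signals_h5",
]


@dataclass
class BodySurfaceSignals:
    """Electrode x sample potential matrix (mV) with sample rate and QC mask."""

    data: np.ndarray  # (M, T) mV
    sample_rate_hz: float
    excluded: np.ndarray | None = None  # bool mask of excluded channels

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.excluded is None:
            self.excluded = np.zeros(len(self.data), dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 temporal samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if np.isnan(self.data[~self.excluded]).any():
            raise ValueError("NaN in unmasked channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _comb_sos(fs: float, fundamental: float = 50.0, n_harmonics: int = 4,
              q: float = 35.0) -> np.ndarray:
    """Cascaded IIR notches at the powerline fundamental and harmonics."""
    sections = []
    for k in range(1, n_harmonics + 1):
        f0 = fundamental * k
        if f0 >= fs / 2:
            break
        b, a = sps.iirnotch(f0, q, fs=fs)
        sections.append(sps.tf2sos(b, a))
    return np.vstack(sections)


def condition_signals(sig: BodySurfaceSignals, mode: str = "clinical",
                      comb_q: float = 35.0) -> BodySurfaceSignals:
    """Apply the fixed conditioning chain; excluded channels pass untouched."""
    fs = sig.sample_rate_hz
    if mode == "clinical":
        cutoffs = (200.0, 40.0)
    elif mode == "simulated":
        cutoffs = (50.0,)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if max(cutoffs) >= fs / 2:
        raise ValueError("filter cutoff at or above Nyquist")

    x = sig.data
    active = ~sig.excluded
    y = x.copy()
    if mode == "clinical":
        stages = [
            _comb_sos(fs, q=comb_q),
            sps.butter(10, 40.0, btype="low", fs=fs, output="sos"),
            sps.butter(3, 0.67, btype="high", fs=fs, output="sos"),
        ]
    else:
        stages = [sps.butter(10, 50.0, btype="low", fs=fs, output="sos")]
    z = y[active]
    for sos in stages:
        z = sps.sosfiltfilt(sos, z, axis=1)
    y[active] = z
    return BodySurfaceSignals(y, fs, sig.excluded.copy())


def channel_qc(
    sig: BodySurfaceSignals,
    rms_z_threshold: float = 5.0,
    flatline_rms: float = 1e-9,
    max_fraction: float = 0.5,
    allow_majority: bool = False,
) -> np.ndarray:
    """Flag outlier channels by robust RMS z-score and flatline detection.

    Thresholds are configuration, not physiology: RMS z-scores are computed
    with median/MAD so one grossly noisy channel cannot inflate the scale.
    Refuses to flag more than ``max_fraction`` of channels unless
    ``allow_majority`` is set, and raises if every channel is flagged.
    """
    if sig.n_channels < 2:
        raise ValueError("need at least 2 channels for QC")
    rms = np.sqrt(np.mean(sig.data**2, axis=1))
    flat = sig.data.std(axis=1) < flatline_rms
    med = np.median(rms)
    mad = np.median(np.abs(rms - med))
    # robust scale with a relative floor so that a set of identical channels
    # (MAD = 0) neither divides by zero nor hides a gross outlier
    scale = max(1.4826 * mad, 1e-6 * max(med, 1e-12))
    z = np.abs(rms - med) / scale
    flagged = flat | (z > rms_z_threshold)
    if flagged.all():
        raise ValueError("all channels flagged by QC")
    if flagged.mean() > max_fraction and not allow_majority:
        # keep only the worst offenders up to the cap
        order = np.argsort(-np.where(flat, np.inf, z))
        cap = int(max_fraction * sig.n_channels)
        keep = np.zeros_like(flagged)
        keep[order[:cap]] = flagged[order[:cap]]
        flagged = keep
    return flagged


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_signals_csv(path, sig: BodySurfaceSignals):
    """Channels x samples CSV; header row carries electrode ids."""
    header = ",".join(f"e{i}" for i in range(sig.n_channels))
    with open(path, "w") as f:
        f.write(header + "\n")
        np.savetxt(f, sig.data.T, delimiter=",", fmt="%.9g")


def read_signals_csv(path, sample_rate_hz: float) -> BodySurfaceSignals:
    raw = Path(path).read_text().strip().splitlines()
    data = np.loadtxt(raw[1:], delimiter=",", ndmin=2).T
    return BodySurfaceSignals(data, sample_rate_hz)


def write_signals_h5(path, sig: BodySurfaceSignals, name="signals"):
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=sig.data)
        ds.attrs["sample_rate_hz"] = sig.sample_rate_hz
        ds.attrs["excluded"] = sig.excluded


def read_signals_h5(path, name="signals") -> BodySurfaceSignals:
    with h5py.File(path, "r") as f:
        ds = f[name]
        return BodySurfaceSignals(
            ds[()], float(ds.attrs["sample_rate_hz"]),
            np.asarray(ds.attrs["excluded"], dtype=bool),
        )
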