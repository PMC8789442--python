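"""Instantaneous phase and the phase synchronization index (PSI).

Two brain signals are phase-synchronized when their instantaneous phase
difference stays (nearly) constant even if their amplitudes are unrelated.
For 1:1 synchronization the index is the mean resultant length of the
per-sample phase-difference unit vectors::

    gamma = sqrt( <cos d(t)>^2 + <sin d(t)>^2 ),   d(t) = theta_x(t) - theta_y(t)

``gamma = 1`` means perfect phase locking; for independent phases it decays
toward 0 like ``sqrt(pi) / (2 sqrt(N))``.

Instantaneous phase is taken from the analytic signal (Hilbert transform),
which is well defined for narrowband inputs — hence the index is computed
per rank-matched pair of VMD modes of the two channels.  A small fraction
of samples is trimmed at both edges to discard Hilbert boundary artifacts,
which are not negligible on 2 s windows.

A static channel -> scalp-region lookup (forehead, left/right temporal,
occipital, hippocampus) ships with the package; channels within one region
share sources and thus exhibit the strongest synchronization contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .vmd import IMFSet

__all__ = [
    "PhaseSeries",
    "instantaneous_phase",
    "phase_sync_index",
    "imf_pair_psi",
    "load_region_map",
    "save_region_map",
    "default_region_map",
    "REGIONS",
]

REGIONS = (
    "forehead",
    "left_temporal",
    "right_temporal",
    "occipital",
    "hippocampus",
)

_REGION_RESOURCE = "channel_regions.txt"


@dataclass(frozen=True)
class PhaseSeries:
    """Wrapped instantaneous phase in (-pi, pi] with a provenance label."""

    phases: np.ndarray
    source: str = ""

    def __len__(self) -> int:
        return self.phases.size


def instantaneous_phase(
    signal: np.ndarray, trim_frac: float = 0.05, source: str = ""
) -> PhaseSeries:
    """Analytic-signal phase of a (narrowband) real signal.

    ``trim_frac`` of the samples are dropped at each end to suppress the
    Hilbert transform's edge ringing.

    Raises
    ------
    ValueError
        For inputs shorter than 16 samples, non-finite input, or an
        all-zero signal (whose phase is undefined).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("need a 1-D signal of at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if not np.any(x):
        raise ValueError("phase of the all-zero signal is undefined")
    if not 0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must be in [0, 0.5)")
    phase = np.angle(hilbert(x))
    n_trim = int(round(trim_frac * x.size))
    if n_trim:
        phase = phase[n_trim:-n_trim]
    return PhaseSeries(phases=phase, source=source)


def phase_sync_index(pa: PhaseSeries, pb: PhaseSeries) -> float:
    """Mean resultant length of the phase difference; in [0, 1].

    Symmetric in its arguments and invariant to adding a constant to either
    phase series.
    """
    a, b = pa.phases, pb.phases
    if a.size != b.size:
        raise ValueError(f"phase series length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty phase series")
    d = a - b
    return float(np.hypot(np.mean(np.cos(d)), np.mean(np.sin(d))))


def imf_pair_psi(
    imfs_a: IMFSet,
    imfs_b: IMFSet,
    n_pairs: int = 5,
    trim_frac: float = 0.05,
) -> np.ndarray:
    """PSI between rank-matched modes of two channels.

    Modes are paired by ascending-frequency rank; the top-frequency mode is
    excluded (with the default six-mode decomposition this computes the
    five pairs IMF1..IMF5 and skips IMF6, which is noise-dominated).
    Returns the indexes ordered low to high frequency.
    """
    if imfs_a.K != imfs_b.K:
        raise ValueError(f"mode-count mismatch: {imfs_a.K} vs {imfs_b.K}")
    if imfs_a.K < n_pairs + 1:
        raise ValueError(f"need at least {n_pairs + 1} modes, got {imfs_a.K}")
    out = np.empty(n_pairs)
    for k in range(n_pairs):
        pa = instantaneous_phase(imfs_a.modes[k], trim_frac, source=f"a/imf{k + 1}")
        pb = instantaneous_phase(imfs_b.modes[k], trim_frac, source=f"b/imf{k + 1}")
        out[k] = phase_sync_index(pa, pb)
    return out


# ---------------------------------------------------------------------------
# Region map (channel label -> scalp region), plain "KEY = value" text

def load_region_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed region-map line: {raw!r}")
        channel, region = (part.strip() for part in line.split("=", 1))
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r} for channel {channel}")
        mapping[channel.upper()] = region
    return mapping


def save_region_map(mapping: dict[str, str], path: str | Path) -> None:
    lines = [f"{ch.upper()} = {region}" for ch, region in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def default_region_map() -> dict[str, str]:
    """The shipped channel -> region lookup for the bipolar 10-20 montage."""
    with resources.as_file(
        resources.files("epivmd.data").joinpath(_REGION_RESOURCE)
    ) as p:
        return load_region_map(p)
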