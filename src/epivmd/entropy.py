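"""Sample entropy and its local-trend adjustment.

Sample entropy (SampEn) quantifies signal irregularity as the negative log
of the conditional probability that two sequences matching for ``m`` points
(within Chebyshev tolerance ``r``, self-matches excluded) also match for
``m + 1`` points.  It summarizes *global* complexity of a window but is
blind to how complexity evolves inside the window; seizure activity,
however, evolves gradually, so the trajectory of entropy across the window
carries class information of its own.

The adjusted ("improved") variant therefore splits the 2 s analysis window
into 8 equal segments, computes SampEn per segment, and nudges the whole-
window value by a channel-specific factor ``mu`` when the segment series
shows a sustained relative trend::

    SampEn_imp = SampEn + mu * alpha - mu * beta

where ``alpha = 1`` iff the segment entropies *increase* by >= 20 % on
three consecutive steps, and ``beta = 1`` iff they *decrease* by >= 20 % on
three consecutive steps.  ``mu`` is the absolute difference between the
channel's mean SampEn over ictal and interictal epochs; a per-channel
calibration table is shipped with the package and can be re-estimated from
user data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Epoch

__all__ = [
    "SampEnParams",
    "EntropyProfile",
    "ChannelEntropyStats",
    "sample_entropy",
    "segment_entropies",
    "detect_trend",
    "adjustment_factor",
    "improved_sample_entropy",
    "load_calibration",
    "save_calibration",
    "default_calibration",
    "default_adjustment_factors",
]

_CALIBRATION_RESOURCE = "channel_sampen_means.csv"


@dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension and tolerance for sample entropy.

    ``r`` is interpreted as a fraction of the signal's standard deviation
    when ``relative`` is true (the common convention, default ``0.2 * sd``),
    otherwise as an absolute tolerance in signal units.
    """

    m: int = 2
    r: float = 0.2
    relative: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not self.r > 0:
            raise ValueError("tolerance r must be positive")

    def resolve_r(self, x: np.ndarray) -> float:
        """Absolute tolerance for signal ``x``."""
        if not self.relative:
            return float(self.r)
        return float(self.r) * float(np.std(np.asarray(x, dtype=float)))

    def absolute(self, x: np.ndarray) -> "SampEnParams":
        """Parameters with ``r`` frozen to absolute units for signal ``x``."""
        return SampEnParams(m=self.m, r=self.resolve_r(x), relative=False)


@dataclass(frozen=True)
class EntropyProfile:
    """Whole-window entropy, per-segment entropies, trend flags, and the
    adjusted value ``adjusted = whole + mu*alpha - mu*beta``."""

    whole: float
    segments: np.ndarray
    alpha: int
    beta: int
    mu: float
    adjusted: float


@dataclass(frozen=True)
class ChannelEntropyStats:
    """Per-channel mean sample entropy of each class, used to derive the
    adjustment factor."""

    channel: str
    mean_epileptic: float
    mean_nonepileptic: float


def _max_resolvable(n: int, m: int) -> float:
    """Finite cap used when no template pair matches: the largest entropy
    resolvable with ``(n - m)`` templates, ``-ln(2 / ((n-m)(n-m-1)))``."""
    n_templ = n - m
    return -math.log(2.0 / (n_templ * (n_templ - 1)))


def sample_entropy(x: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy of a one-dimensional signal.

    Template vectors of length ``m`` and ``m + 1`` are compared under the
    Chebyshev (maximum absolute difference) distance with strict tolerance
    ``r``; self-matches are excluded, and both dimensions use the same
    ``N - m`` templates so the pair counts are directly comparable.  Returns
    ``-ln(A / B)`` where ``A`` and ``B`` are the match counts at dimensions
    ``m + 1`` and ``m``.

    If either count is zero (common on short segments) the finite cap
    ``-ln(2 / ((N-m)(N-m-1)))`` is returned instead of infinity, keeping
    downstream trend detection total.

    Raises
    ------
    ValueError
        If the input is shorter than ``m + 2`` samples or non-finite.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    n = x.size
    m = params.m
    if n < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    r = params.resolve_r(x)
    if not r > 0:
        raise ValueError("resolved tolerance r must be positive (constant input with relative r?)")

    n_templ = n - m
    # Chebyshev distances between all m-length templates, built by taking a
    # running elementwise max over lagged absolute-difference matrices.
    abs_diff = np.abs(x[:, None] - x[None, :])
    d_m = abs_diff[:n_templ, :n_templ].copy()
    for k in range(1, m):
        np.maximum(d_m, abs_diff[k : k + n_templ, k : k + n_templ], out=d_m)
    d_m1 = np.maximum(d_m, abs_diff[m : m + n_templ, m : m + n_templ])

    iu = np.triu_indices(n_templ, k=1)
    b = int(np.count_nonzero(d_m[iu] < r))
    a = int(np.count_nonzero(d_m1[iu] < r))
    if a == 0 or b == 0:
        return _max_resolvable(n, m)
    return -math.log(a / b)


def segment_entropies(
    epoch_samples: np.ndarray,
    n_segments: int = 8,
    params: SampEnParams = SampEnParams(),
) -> np.ndarray:
    """Sample entropy of each of ``n_segments`` contiguous equal blocks.

    A trailing remainder shorter than one block is discarded.  When ``r``
    is relative it is resolved *once* against the full input so segment
    values stay on a common scale (a segment-local tolerance would change
    the meaning of the inter-segment trend).
    """
    x = np.asarray(epoch_samples, dtype=float)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    block = x.size // n_segments
    if block < params.m + 2:
        raise ValueError(
            f"segments of {block} samples are too short for m = {params.m}"
        )
    abs_params = params.absolute(x)
    return np.array(
        [
            sample_entropy(x[i * block : (i + 1) * block], abs_params)
            for i in range(n_segments)
        ]
    )


def detect_trend(
    segments: np.ndarray,
    rel_change: float = 0.2,
    run_length: int = 3,
    direction: str = "ascending",
) -> int:
    """Binary flag: does the segment series contain ``run_length``
    consecutive steps each changing by at least ``rel_change`` relative to
    the step's starting value?

    For step ``i -> i+1`` the ascending condition is
    ``(s[i+1] - s[i]) / s[i] >= rel_change`` and the descending condition is
    ``(s[i] - s[i+1]) / s[i] >= rel_change``; a step starting at zero never
    qualifies.  Runs may start anywhere, and longer runs still yield 1.
    """
    s = np.asarray(segments, dtype=float)
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    if not np.all(np.isfinite(s)):
        raise ValueError("segment entropies must be finite")
    if s.size < run_length + 1:
        return 0
    prev, nxt = s[:-1], s[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (nxt - prev) / prev if direction == "ascending" else (prev - nxt) / prev
    ok = (prev != 0) & (rel >= rel_change)
    run = 0
    for flag in ok:
        run = run + 1 if flag else 0
        if run >= run_length:
            return 1
    return 0


def adjustment_factor(stats: ChannelEntropyStats) -> float:
    """Channel adjustment factor ``mu``: the absolute difference between the
    class-mean sample entropies of that channel."""
    mu = abs(stats.mean_nonepileptic - stats.mean_epileptic)
    if not np.isfinite(mu):
        raise ValueError("channel means must be finite")
    return float(mu)


def improved_sample_entropy(
    epoch: Epoch,
    mu: float,
    params: SampEnParams = SampEnParams(),
    n_segments: int = 8,
    rel_change: float = 0.2,
    run_length: int = 3,
) -> EntropyProfile:
    """Whole-window sample entropy adjusted by the local-trend rule.

    The input epoch is expected to be outlier-cleaned and amplitude-
    transformed already.  The relative tolerance (if any) is resolved once
    on the whole window and reused for the segments.
    """
    x = epoch.samples
    abs_params = params.absolute(x)
    whole = sample_entropy(x, abs_params)
    segs = segment_entropies(x, n_segments=n_segments, params=abs_params)
    alpha = detect_trend(segs, rel_change, run_length, "ascending")
    beta = detect_trend(segs, rel_change, run_length, "descending")
    adjusted = whole + mu * alpha - mu * beta
    return EntropyProfile(
        whole=whole, segments=segs, alpha=alpha, beta=beta, mu=float(mu),
        adjusted=adjusted,
    )


# ---------------------------------------------------------------------------
# Calibration table IO (channel, mean_epileptic, mean_nonepileptic)

def load_calibration(path: str | Path) -> dict[str, ChannelEntropyStats]:
    """Read a per-channel calibration CSV into a channel -> stats mapping."""
    df = pd.read_csv(path)
    required = {"channel", "mean_epileptic", "mean_nonepileptic"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration table must have columns {sorted(required)}")
    return {
        str(row.channel): ChannelEntropyStats(
            channel=str(row.channel),
            mean_epileptic=float(row.mean_epileptic),
            mean_nonepileptic=float(row.mean_nonepileptic),
        )
        for row in df.itertuples()
    }


def save_calibration(stats: dict[str, ChannelEntropyStats], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "channel": s.channel,
                "mean_epileptic": s.mean_epileptic,
                "mean_nonepileptic": s.mean_nonepileptic,
            }
            for s in stats.values()
        ]
    ).to_csv(path, index=False)


def default_calibration() -> dict[str, ChannelEntropyStats]:
    """The calibration table shipped with the package: published class-mean
    sample entropies for the 18 bipolar 10-20 montage channels of the
    CHB-MIT scalp EEG corpus."""
    with resources.as_file(
        resources.files("epivmd.data").joinpath(_CALIBRATION_RESOURCE)
    ) as p:
        return load_calibration(p)


def default_adjustment_factors() -> dict[str, float]:
    """Per-channel ``mu`` derived from the shipped calibration table."""
    return {ch: adjustment_factor(s) for ch, s in default_calibration().items()}
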