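"""Variational mode decomposition (VMD) and data-driven mode-count selection.

VMD decomposes a signal into ``K`` amplitude/frequency-modulated narrowband
modes ("IMFs") by minimizing the summed bandwidth of the modes — measured as
the H1 norm of each mode's analytic signal shifted to baseband — subject to
the modes (approximately) reconstructing the input.  The augmented-
Lagrangian saddle point is found by ADMM with closed-form spectral updates:

* mode update — a Wiener filter centered on the mode's current frequency::

      u_k(w) = (f(w) - sum_{i != k} u_i(w) + lam(w)/2) / (1 + 2*alpha*(w - w_k)^2)

* center-frequency update — the power-weighted mean frequency of the mode::

      w_k = integral(w * |u_k(w)|^2) / integral(|u_k(w)|^2)

* dual ascent on the reconstruction constraint with step ``tau``
  (``noise_slack``); ``tau = 0`` drops the hard constraint, which is the
  appropriate choice for noisy data.

The epoch is mirror-extended by half its length at each end before the
spectral updates and cropped afterwards to suppress boundary ringing.

Choosing ``K`` uses the center-frequency observation rule: decompose a set
of epochs for each candidate ``K``, average the rank-matched center
frequencies, and keep the largest ``K`` whose averaged frequencies are all
separated by a minimum relative spacing — beyond that point the extra mode
crowds an existing one (mode aliasing / over-decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocess import Epoch

__all__ = [
    "VMDConfig",
    "IMFSet",
    "vmd_decompose",
    "average_center_frequencies",
    "select_num_modes",
    "save_modes",
]


@dataclass(frozen=True)
class VMDConfig:
    """Decomposition parameters.

    Parameters
    ----------
    K : int
        Number of modes.
    bandwidth_penalty : float
        The variational weight ``alpha`` on mode bandwidth; larger values
        give narrower modes.
    noise_slack : float
        Dual-ascent step ``tau``.  ``0`` (default) tolerates residual noise;
        any positive value enforces exact reconstruction at convergence.
    tol : float
        Convergence threshold on the summed relative change of the mode
        spectra between iterations.
    max_iter : int
        Iteration cap; hitting it returns the current state flagged as
        unconverged rather than raising.
    init_mode : {"log", "uniform", "zero", "random"}
        Center-frequency initialization.  ``log`` (deterministic, default)
        spreads the frequencies geometrically over (0, fs/2), matching the
        roughly logarithmic organization of EEG rhythms — a linearly
        uniform start leaves low-frequency bands unclaimed on 1/f-type
        spectra; ``uniform`` spreads them evenly on a linear scale;
        ``random`` draws them using ``seed``.
    dc_mode : bool
        Pin the first mode's center frequency at 0 (for signals with a
        strong baseline drift).
    seed : int
        Only used by ``init_mode="random"``.
    """

    K: int = 6
    bandwidth_penalty: float = 20000.0
    noise_slack: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init_mode: str = "log"
    dc_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init_mode not in ("log", "uniform", "zero", "random"):
            raise ValueError("init_mode must be 'log', 'uniform', 'zero' or 'random'")

    def with_K(self, K: int) -> "VMDConfig":
        return VMDConfig(
            K=K,
            bandwidth_penalty=self.bandwidth_penalty,
            noise_slack=self.noise_slack,
            tol=self.tol,
            max_iter=self.max_iter,
            init_mode=self.init_mode,
            dc_mode=self.dc_mode,
            seed=self.seed,
        )


@dataclass(frozen=True)
class IMFSet:
    """Decomposition result: ``modes[k]`` is the k-th narrowband component
    (ascending center frequency), same length as the input epoch."""

    modes: np.ndarray          # shape (K, n_samples)
    center_freqs: np.ndarray   # Hz, strictly ascending
    residual_energy: float     # fraction of input energy not reconstructed
    converged: bool
    fs: float

    @property
    def K(self) -> int:
        return self.modes.shape[0]


def _init_omegas(config: VMDConfig, n_samples: int) -> np.ndarray:
    K = config.K
    if config.init_mode == "log":
        # geometric spread from two cycles per window up to 0.9 of Nyquist,
        # in normalized frequency
        return np.geomspace(2.0 / n_samples, 0.45, K)
    if config.init_mode == "uniform":
        # evenly spread over (0, 0.5) in normalized frequency
        return (np.arange(K) + 0.5) * (0.5 / K)
    if config.init_mode == "zero":
        return np.zeros(K)
    rng = np.random.default_rng(config.seed)
    return np.sort(0.5 * rng.random(K))


def vmd_decompose(epoch: Epoch, config: VMDConfig = VMDConfig()) -> IMFSet:
    """Decompose one epoch into ``config.K`` narrowband modes.

    Returns modes sorted by ascending center frequency.  Deterministic for
    ``init_mode`` in {"uniform", "zero"}.

    Raises
    ------
    ValueError
        For epochs shorter than 32 samples, non-finite input, or
        ``K > n_samples / 4`` (over-decomposition guard).
    """
    x = np.asarray(epoch.samples, dtype=float)
    n = x.size
    if n < 32:
        raise ValueError("epoch too short for VMD (need >= 32 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains non-finite samples")
    if config.K > n // 4:
        raise ValueError(f"K = {config.K} exceeds n/4 = {n // 4}: over-decomposition")

    K = config.K
    alpha = config.bandwidth_penalty
    tau = config.noise_slack

    # mirror extension by half the epoch at each end
    h = n // 2
    f = np.concatenate([x[:h][::-1], x, x[n - h :][::-1]])
    T = f.size
    half = T // 2

    freqs = np.arange(T) / T - 0.5  # normalized, after fftshift
    f_hat = np.fft.fftshift(np.fft.fft(f))
    f_hat_plus = f_hat.copy()
    f_hat_plus[:half] = 0.0

    omega = _init_omegas(config, n)
    if config.dc_mode:
        omega[0] = 0.0
    u_hat = np.zeros((K, T), dtype=complex)
    lam = np.zeros(T, dtype=complex)

    pos = slice(half, T)
    w_pos = freqs[pos]
    converged = False
    for _ in range(config.max_iter):
        u_prev = u_hat.copy()
        for k in range(K):
            others = u_hat.sum(axis=0) - u_hat[k]
            u_hat[k] = (f_hat_plus - others + lam / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2
            )
            if not (config.dc_mode and k == 0):
                power = np.abs(u_hat[k, pos]) ** 2
                total = power.sum()
                if total > 0:
                    omega[k] = float((w_pos * power).sum() / total)
        if tau > 0:
            lam = lam + tau * (f_hat_plus - u_hat.sum(axis=0))
        denom = np.sum(np.abs(u_prev) ** 2, axis=1)
        num = np.sum(np.abs(u_hat - u_prev) ** 2, axis=1)
        udiff = float(np.sum(num / (denom + np.finfo(float).eps)))
        if udiff < config.tol:
            converged = True
            break

    # Hermitian completion and inverse transform, then crop the mirrors
    u_full = np.zeros((K, T), dtype=complex)
    u_full[:, pos] = u_hat[:, pos]
    u_full[:, 1:half + 1] = np.conj(u_hat[:, -1:half - 1:-1])
    u_full[:, 0] = np.conj(u_full[:, -1])
    u_time = np.real(np.fft.ifft(np.fft.ifftshift(u_full, axes=1), axis=1))
    modes = u_time[:, h : h + n]

    order = np.argsort(omega)
    modes = modes[order]
    center_hz = omega[order] * epoch.fs

    energy = float(np.sum(x**2))
    if energy > 0:
        residual = float(np.sum((x - modes.sum(axis=0)) ** 2) / energy)
    else:
        residual = 0.0
    return IMFSet(
        modes=modes,
        center_freqs=center_hz,
        residual_energy=residual,
        converged=converged,
        fs=epoch.fs,
    )


def average_center_frequencies(
    epochs: Sequence[Epoch], config: VMDConfig = VMDConfig()
) -> np.ndarray:
    """Rank-matched average of the sorted center frequencies across epochs.

    All epochs must share a sampling rate; each is decomposed with the same
    configuration and the k-th lowest frequencies are averaged.
    """
    epochs = list(epochs)
    if not epochs:
        raise ValueError("need at least one epoch")
    fs = epochs[0].fs
    if any(e.fs != fs for e in epochs):
        raise ValueError("epochs must share a sampling rate")
    freqs = np.array([vmd_decompose(e, config).center_freqs for e in epochs])
    return freqs.mean(axis=0)


def select_num_modes(
    epochs: Sequence[Epoch],
    k_candidates: Iterable[int],
    config: VMDConfig = VMDConfig(),
    min_rel_spacing: float = 0.1,
) -> int:
    """Center-frequency-observation choice of the mode count.

    Candidates are scanned in ascending order.  For each ``K`` the averaged
    center frequencies must all be pairwise separated: ``(f[i+1] - f[i]) /
    f[i+1] >= min_rel_spacing`` for every adjacent pair.  The scan stops at
    the first candidate whose spacing collapses — at that point the extra
    mode is crowding an existing band (over-decomposition) — and the
    largest candidate seen before the collapse is returned.  If already the
    smallest candidate fails, it is returned with a warning.
    """
    candidates = sorted(set(int(k) for k in k_candidates))
    if not candidates:
        raise ValueError("k_candidates must be nonempty")
    best: int | None = None
    for k in candidates:
        avg = average_center_frequencies(epochs, config.with_K(k))
        if k == 1:
            spaced = True
        else:
            gaps = (avg[1:] - avg[:-1]) / avg[1:]
            spaced = bool(np.all(gaps >= min_rel_spacing))
        if not spaced:
            break
        best = k
    if best is None:
        warnings.warn(
            "no candidate K satisfies the center-frequency spacing criterion; "
            "returning the smallest candidate",
            RuntimeWarning,
            stacklevel=2,
        )
        return candidates[0]
    return best


def save_modes(imfs: IMFSet, path) -> None:
    """Dump modes as delimited text: a center-frequency header row, then one
    column per mode."""
    header = ",".join(f"{f:.6f}" for f in imfs.center_freqs)
    np.savetxt(path, imfs.modes.T, delimiter=",", header=header, comments="# center_freqs_hz: ")
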