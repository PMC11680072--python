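"""Signal decomposition: adaptive VMD, EMD recovery, and mode PSDs.

Stage 1 is canonical variational mode decomposition (VMD): the signal is
split into K band-limited modes by alternating Wiener-filter mode updates,
power-weighted center-frequency updates, and dual ascent with an optional
noise-tolerance slack. Stage 2 is a gradient-descent refinement of the modes
and an explicit residual-noise term under the objective

    Obj(s, n) = ||x − Σ_i s_i − n||² + Σ_i λ_i ||s_i||_p^p + γ ||n||_q^q

which trades reconstruction fidelity against mode/noise sparsity. Classical
EMD (cubic-spline envelope sifting) provides the first-IMF "recovered
signal", and a periodogram PSD summarizes each mode's frequency content.

Boundary handling is mirror extension for both the VMD spectra and the EMD
splines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DivergenceError, InputError, NoIMFError
from .signal import ECGSignal

# ---------------------------------------------------------------------------
# settings / containers
# ---------------------------------------------------------------------------


@dataclass
class VMDSettings:
    """Canonical VMD settings.

    K modes with bandwidth-constraint weight ``alpha`` (default 2000),
    convergence tolerance ``tol`` (default 1e-7) and Lagrangian noise slack
    ``noise_tolerance`` (default 0.0, i.e. exact reconstruction pressure).
    """

    K: int = 5
    alpha: float = 2000.0
    tol: float = 1e-7
    noise_tolerance: float = 0.0
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.K < 1:
            raise InputError("K must be >= 1")
        if self.alpha <= 0 or self.tol <= 0:
            raise InputError("alpha and tol must be positive")


@dataclass
class ModeSet:
    """Result of a (possibly refined) VMD decomposition.

    ``modes`` are ordered by ascending center frequency; ``residual`` is the
    bookkeeping remainder x − Σ modes, so modes + residual always sum to the
    decomposed input exactly.
    """

    modes: np.ndarray  # (K, N)
    residual: np.ndarray  # (N,)
    center_frequencies: np.ndarray  # Hz, ascending
    fs: float
    settings: VMDSettings
    converged: bool = True
    objective_trajectory: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.modes.shape[0]

    @property
    def source(self) -> np.ndarray:
        return self.modes.sum(axis=0) + self.residual

    def mode_energies(self) -> np.ndarray:
        """Per-mode energy Σ s_i(t)²."""
        return np.sum(self.modes**2, axis=1)


@dataclass
class AdaptiveVMDParams:
    """Gradient-refinement hyper-parameters (learning rate, penalties, norms)."""

    eta: float = 0.01
    lambda_i: float | np.ndarray = 1e-3
    gamma_reg: float = 1e-3
    p: int = 2
    q: int = 2
    iterations: int = 50
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise InputError("eta must be positive")
        if self.gamma_reg < 0 or np.any(np.asarray(self.lambda_i) < 0):
            raise InputError("regularization weights must be >= 0")
        if self.p not in (1, 2) or self.q not in (1, 2):
            raise InputError("norm orders p, q must be 1 or 2")


@dataclass
class IMFSet:
    """EMD result: intrinsic mode functions (highest frequency first) + residue."""

    imfs: list[np.ndarray] = field(default_factory=list)
    residue: np.ndarray | None = None
    fs: float = 1.0


# ---------------------------------------------------------------------------
# VMD
# ---------------------------------------------------------------------------


def vmd(signal: ECGSignal, settings: VMDSettings | None = None) -> ModeSet:
    """Decompose ``signal`` into K band-limited modes.

    Implements the alternating-direction spectral updates: each mode is a
    Wiener filter of the residual spectrum around its center frequency, the
    center frequency is the power-weighted mean of the mode spectrum, and a
    dual variable enforces reconstruction with slack ``noise_tolerance``.
    Modes come back sorted by ascending center frequency; the residual is
    the signal minus the mode sum.
    """
    settings = settings or VMDSettings()
    x = np.asarray(signal.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("signal contains non-finite samples")
    N = x.size
    if N < 2 * settings.K:
        raise InputError(f"signal length {N} too short for K={settings.K} modes")

    # pad odd-length inputs by one mirrored sample; trimmed again at the end
    trimmed = False
    if N % 2 == 1:
        x = np.append(x, x[-1])
        trimmed = True

    if np.ptp(x) == 0 and x[0] == 0:
        modes = np.zeros((settings.K, N))
        return ModeSet(
            modes=modes,
            residual=np.zeros(N),
            center_frequencies=np.zeros(settings.K),
            fs=signal.fs,
            settings=settings,
        )

    n = x.size
    half = n // 2
    # mirror extension to suppress boundary leakage
    f = np.concatenate([x[:half][::-1], x, x[half:][::-1]])
    T = f.size
    freqs = np.arange(T) / T - 0.5 - 1.0 / T

    f_hat = np.fft.fftshift(np.fft.fft(f))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: T // 2] = 0

    K, alpha, tau = settings.K, settings.alpha, settings.noise_tolerance
    u_hat = np.zeros((K, T), dtype=complex)
    omega = 0.5 / K * np.arange(K)  # uniform initialization in [0, 0.5)
    lam = np.zeros(T, dtype=complex)

    converged = False
    for _ in range(settings.max_iter):
        u_prev = u_hat.copy()
        sum_uk = u_hat.sum(axis=0)
        for k in range(K):
            sum_uk = sum_uk - u_hat[k]
            u_hat[k] = (f_hat_plus - sum_uk - lam / 2) / (
                1.0 + alpha * (freqs - omega[k]) ** 2
            )
            power = np.abs(u_hat[k, T // 2 :]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = float(freqs[T // 2 :] @ power / denom)
            sum_uk = sum_uk + u_hat[k]
        lam = lam + tau * (sum_uk - f_hat_plus)

        diff = u_hat - u_prev
        u_diff = np.sum(np.abs(diff) ** 2) / T
        norm = np.sum(np.abs(u_prev) ** 2) / T
        if norm > 0 and u_diff / norm < settings.tol:
            converged = True
            break

    # back to time domain: hermitian-complete each mode spectrum
    modes = np.zeros((K, n))
    for k in range(K):
        full = np.zeros(T, dtype=complex)
        full[T // 2 :] = u_hat[k, T // 2 :]
        full[1 : T // 2 + 1] = np.conj(u_hat[k, T // 2 :][::-1])
        m = np.real(np.fft.ifft(np.fft.ifftshift(full)))
        modes[k] = m[T // 4 : T // 4 + n]

    order = np.argsort(omega)
    modes = modes[order]
    cfs = np.clip(omega[order], 0.0, 0.5) * signal.fs

    if trimmed:
        modes = modes[:, :N]
        x = x[:N]
    residual = x - modes.sum(axis=0)
    return ModeSet(
        modes=modes,
        residual=residual,
        center_frequencies=cfs,
        fs=signal.fs,
        settings=settings,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# adaptive refinement
# ---------------------------------------------------------------------------


def _penalty(v: np.ndarray, order: int) -> float:
    return float(np.sum(np.abs(v))) if order == 1 else float(np.sum(v**2))


def _penalty_grad(v: np.ndarray, order: int) -> np.ndarray:
    return np.sign(v) if order == 1 else 2.0 * v


def _objective(
    x: np.ndarray, s: np.ndarray, n_t: np.ndarray, params: AdaptiveVMDParams
) -> float:
    r = x - s.sum(axis=0) - n_t
    lam = np.broadcast_to(np.asarray(params.lambda_i, dtype=float), (s.shape[0],))
    obj = float(np.sum(r**2))
    obj += float(sum(l * _penalty(si, params.p) for l, si in zip(lam, s)))
    obj += params.gamma_reg * _penalty(n_t, params.q)
    return obj


def adaptive_refine(modeset: ModeSet, params: AdaptiveVMDParams | None = None) -> ModeSet:
    """Gradient-descent refinement of modes and residual noise.

    Minimizes the penalized reconstruction objective by joint descent on
    every mode s_i and the noise term n. Stops after ``params.iterations``
    steps or when the objective decreases by less than ``params.tol``;
    aborts with :class:`DivergenceError` if the objective grows for five
    consecutive steps (the step size is too large). The returned ModeSet
    carries the objective trajectory.
    """
    params = params or AdaptiveVMDParams()
    x = modeset.source
    s = modeset.modes.copy()
    n_t = modeset.residual.copy()
    K = s.shape[0]
    lam = np.broadcast_to(np.asarray(params.lambda_i, dtype=float), (K,))

    traj = [_objective(x, s, n_t, params)]
    rises = 0
    for _ in range(params.iterations):
        r = x - s.sum(axis=0) - n_t
        grad_s = -2.0 * r[None, :] + lam[:, None] * _penalty_grad(s, params.p)
        grad_n = -2.0 * r + params.gamma_reg * _penalty_grad(n_t, params.q)
        s = s - params.eta * grad_s
        n_t = n_t - params.eta * grad_n
        obj = _objective(x, s, n_t, params)
        if obj > traj[-1]:
            rises += 1
            if rises >= 5:
                raise DivergenceError(
                    "objective increased 5 consecutive steps; reduce eta "
                    f"(eta={params.eta})"
                )
        else:
            rises = 0
        decreased_by = traj[-1] - obj
        traj.append(obj)
        if 0 <= decreased_by < params.tol:
            break

    order = np.argsort(modeset.center_frequencies)
    return ModeSet(
        modes=s[order],
        residual=x - s.sum(axis=0),
        center_frequencies=modeset.center_frequencies[order],
        fs=modeset.fs,
        settings=modeset.settings,
        converged=modeset.converged,
        objective_trajectory=np.asarray(traj),
    )


def reconstruct(modeset: ModeSet, include_modes: "list[int] | None" = None) -> ECGSignal:
    """Sum the selected modes (default: all). The residual — treated as
    noise — is excluded; that exclusion is the denoising step."""
    if include_modes is None:
        include_modes = list(range(modeset.K))
    if len(include_modes) == 0:
        raise InputError("include_modes must select at least one mode")
    idx = np.asarray(include_modes, dtype=int)
    if idx.min() < 0 or idx.max() >= modeset.K:
        raise InputError(f"mode indices out of range [0, {modeset.K})")
    y = modeset.modes[idx].sum(axis=0)
    return ECGSignal(y, fs=modeset.fs, label="vmd-reconstruction")


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau-tolerant)."""
    d = np.diff(x)
    # collapse flat segments by looking at the sign of the surrounding slopes
    nz = np.nonzero(d)[0]
    maxima, minima = [], []
    for a, b in zip(nz[:-1], nz[1:]):
        if d[a] > 0 and d[b] < 0:
            maxima.append((a + 1 + b) // 2)
        elif d[a] < 0 and d[b] > 0:
            minima.append((a + 1 + b) // 2)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.count_nonzero(np.diff(s))) if s.size else 0


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema, mirror-extended at the ends."""
    n = x.size
    t = np.arange(n)
    if idx.size >= 2:
        # mirror up to two extrema beyond each boundary
        k = min(2, idx.size)
        left_t = -idx[:k][::-1]
        left_v = x[idx[:k]][::-1]
        right_t = 2 * (n - 1) - idx[-k:][::-1]
        right_v = x[idx[-k:]][::-1]
        tt = np.concatenate([left_t, idx, right_t])
        vv = np.concatenate([left_v, x[idx], right_v])
        tt, keep = np.unique(tt, return_index=True)
        vv = vv[keep]
        if tt.size >= 4:
            return CubicSpline(tt, vv)(t)
        return np.interp(t, tt, vv)
    raise ValueError("not enough extrema for an envelope")


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def emd(
    signal: ECGSignal | np.ndarray,
    fs: float | None = None,
    max_imfs: int = 10,
    sd_threshold: float = 0.3,
    max_sifts: int = 100,
) -> IMFSet:
    """Classical empirical mode decomposition by envelope-mean sifting.

    Sifting of each candidate stops when the Cauchy SD criterion falls below
    ``sd_threshold`` *and* the extrema/zero-crossing counts differ by at
    most one; the decomposition stops when the residue is monotone or has
    fewer than two interior extrema. The subtractive construction makes
    Σ imfs + residue reproduce the input to machine precision.
    """
    if isinstance(signal, ECGSignal):
        x = signal.samples.copy()
        fs = signal.fs
    else:
        x = np.asarray(signal, dtype=float).copy()
        fs = fs or 1.0
    if x.size < 4:
        raise InputError("need at least 4 samples for EMD")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residue)
        if _is_monotone(residue) or maxima.size + minima.size < 2:
            break
        h = residue.copy()
        for _sift in range(max_sifts):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _envelope(h, maxima)
            lower = _envelope(h, minima)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            n_ext = _local_extrema(h)[0].size + _local_extrema(h)[1].size
            if sd < sd_threshold and abs(n_ext - _zero_crossings(h)) <= 1:
                break
        n_ext = _local_extrema(h)[0].size + _local_extrema(h)[1].size
        if abs(n_ext - _zero_crossings(h)) > 1:
            # candidate cannot be sifted into a proper IMF (typically the
            # final low-oscillation component): leave it in the residue
            break
        imfs.append(h)
        residue = residue - h
    return IMFSet(imfs=imfs, residue=residue, fs=fs)


def recover_first_imf(imfset: IMFSet) -> ECGSignal:
    """The first IMF — the highest-frequency component — as the recovered signal."""
    if not imfset.imfs:
        raise NoIMFError("decomposition produced no IMFs (monotone input?)")
    return ECGSignal(imfset.imfs[0], fs=imfset.fs, label="first-imf")


# ---------------------------------------------------------------------------
# PSD
# ---------------------------------------------------------------------------


def psd(sequence: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram: P[k] = |X[k]|² / (N·fs), doubled off-DC/Nyquist.

    Satisfies Parseval: Σ P·Δf equals the sequence mean square.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size < 8:
        raise InputError("need at least 8 samples for a PSD")
    N = x.size
    X = np.fft.rfft(x)
    power = np.abs(X) ** 2 / (N * fs)
    power[1:] *= 2.0
    if N % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(N, d=1.0 / fs)
    return freqs, power
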