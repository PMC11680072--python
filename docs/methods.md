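# Methods

This note documents the models, defaults, and numerical choices behind
`ecgcrypt`, and what the synthetic-data tests do and do not establish.

## Synthetic ECG model

Each beat is the sum of five Gaussian bumps — P, Q, R, S, T — placed at fixed
offsets from the R time. Defaults (amplitude, width σ [s], offset from R [s]):

| wave | amplitude | width | offset |
|------|-----------|-------|--------|
| P | 0.08 | 0.022 | −0.190 |
| Q | −0.055 | 0.010 | −0.032 |
| R | 0.32 | 0.011 | 0.000 |
| S | −0.075 | 0.011 | +0.032 |
| T | 0.14 | 0.060 | +0.300 |

These are typical resting lead-II proportions; the raw trace spans roughly
−0.15 to +0.35 units. The record shape defaults to 500 Hz × 20 s = 10,000
samples. RR intervals are 60/hr_mean plus i.i.d. Gaussian jitter of standard
deviation 60·hr_sd/hr_mean² (first-order propagation of a ±hr_sd bpm rate
jitter into interval units), truncated at 0.2 s; defaults hr_mean = 72,
hr_sd = 2 bpm — an unremarkable resting rhythm. Noise defaults are mild:
baseline wander 0.03 @ 0.33 Hz, powerline 0.01 @ 50 Hz, white σ = 0.01.

A Gaussian-bump beat was chosen over a dynamical (ODE) morphology because the
R-peak locations are then known *exactly*, giving an oracle for detector
tests. The generator does not emulate ectopy, motion artifacts, electrode
pops, respiratory modulation of amplitude, or inter-subject morphology
variation — a green detector test here says the detector works on clean to
moderately noisy regular rhythms, nothing more.

## Preprocessing

FIR windowed-sinc band-pass (Hamming, 501 taps at 500 Hz), built as
low-pass(f_high) − low-pass(f_low) and applied forward–backward
(`scipy.signal.filtfilt`), so the effective response is the squared magnitude
and the phase is exactly zero — fiducial points do not move. Defaults
0.5–40 Hz. After filtering: min–max scaling to [0, 1], then mean re-centering.
The normalize-then-center ordering is a deliberate choice: downstream
decomposition receives a zero-baseline signal bounded by [−1, 1]. Constant
inputs are rejected before filtering (the min–max step would be degenerate).

## Adaptive VMD

Stage 1 is canonical VMD: mirror-extend the signal, alternate
Wiener-filter mode updates
û_k ← (f̂ − Σ_{i≠k} û_i − λ̂/2)/(1 + α(ω − ω_k)²),
power-weighted center-frequency updates, and dual ascent with slack
`noise_tolerance` (default 0.0), until the relative spectral change drops
below `tol` (default 1e-7) or `max_iter` = 500. Defaults K = 5, α = 2000.
Modes are returned in ascending center-frequency order; the residual is
defined as input − Σ modes, so conservation is a bookkeeping identity
independent of convergence. Non-convergence is reported via a flag, not an
exception. A mode with zero spectral power keeps its previous center
frequency (zero signals yield all-zero modes at 0 Hz by convention).

Stage 2 refines modes and an explicit noise term by joint gradient descent on

Obj(s, n) = ‖x − Σ sᵢ − n‖² + Σ λᵢ‖sᵢ‖ₚᵖ + γ_reg‖n‖_q^q.

The penalties are implemented as p-th powers of the p-norms (p, q ∈ {1, 2})
so the default p = q = 2 objective is smooth and the descent provably
monotone for η below 1/(2(K+1)); default η = 0.01, λᵢ = γ_reg = 1e-3,
50 iterations, stop early when the decrease falls below 1e-12. Five
consecutive objective increases abort with a divergence error suggesting a
smaller η. The γ symbol is used both for this regularization weight
(`gamma_reg`) and for the half-life light intensity (`gamma0`/γ_t) in key
generation; the code keeps them strictly apart.

Reconstruction sums the refined modes; excluding the residual *is* the
denoising step. All modes are summed by default (a subset is selectable).

## EMD

Classical sifting: cubic-spline envelopes through maxima/minima with up to
two extrema mirrored beyond each boundary, subtract the mean envelope,
stop sifting when the Cauchy SD criterion < 0.3 *and* the extrema/
zero-crossing counts differ by ≤ 1 (capped at 100 sifts). If a candidate
cannot satisfy the IMF condition — typically the final low-oscillation
component — it is left in the residue rather than emitted, so every returned
IMF is a proper IMF and the subtractive construction keeps
Σ IMFs + residue = input at machine precision. Decomposition stops when the
residue is monotone or lacks two interior extrema.

## Features

- **R-peak detection**: energy-based QRS detector — 5–15 Hz zero-phase
  band-pass, derivative, square, 150 ms moving-window integral, adaptive
  threshold at 30% of the mean top-percentile integrator level, 200 ms
  refractory, then snap to the local band-passed maximum.
- **HRV**: sdnn = √(Σ(RRᵢ − meanRR)²/(N−1)); rmssd = √(Σ(RR_{i+1} − RRᵢ)²/(N−1))
  — note both use the N−1 normalizer; NN50 threshold 50 ms (strict >), pNN50
  = 100·nn50/(N−1); mean HR = 60/meanRR in bpm.
- **Moments**: sample std (N−1) by default, population variant by flag;
  skewness is Fisher–Pearson g1; kurtosis is *excess* by default (normal → 0).
  Constant input reports 0/0 with a degenerate flag.
- **Spectra**: DFT with the plain Σ convention (no forward 1/N). Frequency
  features default to the one-sided grid; a two-sided mode exists because the
  signed centroid/rolloff conventions differ across tools. Spectral entropy
  is in bits; rolloff fraction defaults to 0.85.
- **STFT**: Hann window, default 1 s with 50% hop; frame count is exactly
  ⌊(N − window)/hop⌋ + 1 (no padding), frame stamps at window centers.
- **ZCR**: sign in {+1, 0, −1}; a zero sample bridging opposite signs counts
  once; per-sample rate divides by N − 1.
- **Fusion**: fixed layout time(5) ‖ freq(5) ‖ timefreq(2) ‖ hrv(5) ‖ zcr(1) ‖
  mode_summary(2K+2) — per-VMD-mode (energy, center frequency) then first-IMF
  (energy, dominant frequency). Values are copied verbatim; every slot is
  recoverable bit-exactly.

In the assembled pipeline, time/frequency/time–frequency/ZCR features are
computed on the denoised reconstruction, HRV on R-peaks detected from the
preprocessed signal. If EMD yields no IMF the two first-IMF slots are zero.

## Key generation

- **Unique feature key**: each fused value is serialized as fixed-point with
  6 decimals, '|'-separated, and hashed with SHA-256. Any ≥ 1e-6 change in
  any slot changes the serialization and avalanches the digest (~50% of bits).
- **Kestrel search**: candidates hold m = 256 γ values in [0,1] plus a RandBit
  stream; the binarized form is (γ ≥ 0.5) XOR RandBits (the XOR realizes the
  "appended random bit generator" while keeping the bit length at m). Fitness
  is the Shannon entropy (bits/byte) of the packed bytes — the package's own
  choice, since key quality is ultimately judged by entropy. Note the ceiling
  for a 32-byte string is log₂32 = 5 bits/byte. Per round t the intensity
  γ_t = γ₀·e^(−φt) (φ = ln2/t½, default t½ = 1.0, γ₀ = 1.0) scales the
  flight-mode perturbation (uniform ±0.5·γ_t, probability 0.8); perch mode is
  a local ±0.05 tweak (probability 0.2); if φ > 1 (t½ < ln 2) candidates
  re-randomize each round ("trail is new", strict inequality at φ = 1). The
  search is elitist — the best candidate ever observed wins, ties to the
  lowest index — so the result is never worse than the initial population.
- **Final key**: SHA-256(unique key ‖ winner bytes), exactly the 256 bits a
  ChaCha20-family cipher needs. A 96-bit nonce is drawn from the same seeded
  generator and stored with the key; fresh-nonce-per-message is the policy.
  All randomness flows through one `numpy` PCG64 generator seeded by the user
  seed, so (fused vector, seed) determines the BioKey bit-for-bit.

## Cipher

ChaCha (20 or 12 rounds) and Salsa20 cores are implemented from the public
specifications with the block counter incrementing per 64-byte block,
vectorized across blocks with numpy (~150 MB/s single-core). The ChaCha20
core is pinned to the RFC 8439 test vectors; the Salsa20 quarter-round is
pinned to the published specification examples, with a frozen in-package
regression vector for the full keystream. "ChaCha" without a number is mapped
to 12 rounds. Nonces: 96-bit (ChaCha), 64-bit (Salsa20, the key's first
8 nonce bytes). The ciphertext container is
`magic ‖ version ‖ scheme id ‖ nonce ‖ counter ‖ length ‖ payload`.

**Security caveats**: pure stream XOR, no authentication or integrity; an
attacker can flip plaintext bits undetected. Key derivation from biometric
features is *not* error-tolerant — a different recording yields different
features and a different key by design; fuzzy extraction is out of scope. The
benchmark harness reports wall times only; they are hardware-dependent and
never asserted.

## Degenerate inputs and tie-breaks

Constant signals: rejected by preprocessing; flat signals yield no R peaks.
Monotone signals: zero IMFs, `recover_first_imf` raises. All-zero spectra and
spectrograms: rejected. VMD of an identically zero signal: zero modes at 0 Hz.
Kestrel fitness ties: lowest candidate index. Histogram binning: fixed 25 ms
width from the minimum interval.

## What the tests establish

All stage guarantees are demonstrated on synthetic fixtures with programmed
ground truth: exact beat grids, analytic tones, loop-oracle HRV, RFC test
vectors. They establish correctness of the computations and contracts, not
clinical performance on real recordings (no MIT-BIH or lab data is bundled),
and not cryptographic security of the key-derivation construction beyond the
entropy and avalanche properties measured.
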