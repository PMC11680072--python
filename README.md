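# ecgcrypt

Lightweight encryption keyed by a person's own heartbeat.

`ecgcrypt` implements an ECG-based encryption pipeline for resource-constrained
settings (wearables, internet-of-medical-things telemetry): a single-lead ECG is
denoised and decomposed, multi-domain features are fused into one vector, a
256-bit key is derived from that vector through a bio-inspired randomized
search, and data is encrypted with a ChaCha20-family stream cipher. A synthetic
ECG generator with known ground truth makes every stage testable without any
clinical recordings.

## The pipeline

1. **Preprocess** — zero-phase FIR band-pass (default 0.5–40 Hz, windowed-sinc
   built as h = h_LP − h_HP), min–max scaling F_norm = (F − F_min)/(F_max − F_min),
   mean re-centering.
2. **Adaptive VMD** — canonical variational mode decomposition
   x(t) = Σᵢ Sᵢ(t) + n(t) into K = 5 band-limited modes (α = 2000, tol = 1e-7),
   followed by gradient-descent refinement of the modes and residual noise under

   Obj(s, n) = ‖x − Σᵢ sᵢ − n‖² + Σᵢ λᵢ‖sᵢ‖ₚᵖ + γ‖n‖_q^q

   with updates sᵢ ← sᵢ − η ∂Obj/∂sᵢ, n ← n − η ∂Obj/∂n. The denoised signal is
   the sum of the refined modes. Classical EMD supplies the first IMF as the
   highest-frequency recovered component.
3. **Features** — time-domain moments (mean, std, RMS, skewness, kurtosis),
   DFT-based spectral features (dominant frequency, centroid, spread, entropy,
   rolloff), STFT time–frequency summaries, HRV metrics from detected R-peaks
   (SDNN, RMSSD, NN50, pNN50, mean HR), the zero-crossing rate, and per-mode
   energies/center frequencies — concatenated into one fused vector
   f_fused = [f_time ‖ f_freq ‖ f_timefreq ‖ f_hrv ‖ f_zcr ‖ f_modes].
4. **Key generation** — SHA-256 of a canonical fixed-point serialization of
   f_fused gives the unique feature key; a kestrel-style population search
   (200 candidates, flight p = 0.8 / perch p = 0.2, per-round intensity decay
   γ_t = γ₀·e^(−φt) with φ = ln2/t½) maximizes the Shannon entropy of a random
   bitstring; F_key = SHA-256(unique key ‖ winner bits) is the 256-bit cipher key.
5. **Cipher** — Cᵢ = Pᵢ ⊕ Kᵢ with ChaCha20 (RFC 8439-verified core), ChaCha12,
   or Salsa20 keystreams; decryption applies the identical keystream.

## Worked example

```
$ ecgcrypt simulate --seed 5 ecg.txt
wrote 10000 samples at 500 Hz to ecg.txt

$ ecgcrypt run --seed 5 --outdir demo ecg.txt
fused vector length: 30
winner fitness: 5.0000 bits/byte
features_csv: demo/features.csv
...
ciphertext: demo/ciphertext.bin

$ ecgcrypt decrypt demo/ciphertext.bin demo/key.bin recovered.txt
recovered 10000 samples -> recovered.txt
```

The fixture is a 20 s, 500 Hz synthetic lead-II ECG at 72 bpm with mild noise.
The run above fuses 30 features — e.g. HRV block
`sdnn 0.0211 s, rmssd 0.0268 s, nn50 1, pnn50 4.55 %, mean_hr 72.36 bpm`
(the detector recovered the programmed beats; the rates match the generator's
72 ± 2 bpm world) and five VMD center frequencies
`2.82, 6.20, 10.71, 15.28, 20.49 Hz` spanning the ECG band. `recovered.txt`
equals the input samples exactly: the stream cipher is an involution, and the
key is reproducible bit-for-bit from (features, seed). The winner fitness of
5.0 bits/byte is the maximum achievable Shannon entropy for a 32-byte
candidate (32 distinct bytes).

Subcommands: `simulate`, `preprocess`, `decompose`, `features`, `keygen`,
`encrypt`, `decrypt`, `entropy`, `benchmark`, `run`.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the packaged fixture from the seed, runs the complete pipeline
(preprocess → adaptive VMD → feature fusion → key derivation → ChaCha20
encryption), verifies that decryption restores the exact input samples, and
writes the results JSON.

## Caveats

This is a research implementation. The cipher layer is unauthenticated stream
XOR (confidentiality only); nonces are fresh per message and must never be
reused with the same key. See `docs/methods.md` for model assumptions, defaults
and limitations.
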