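"""End-to-end orchestration: preprocess → decompose → features → key → cipher.

``run_pipeline`` executes the full chain on one ECG signal and writes every
artifact (feature CSV/JSON, key material, ciphertext container, run log)
under an output directory. Each run is fully reproducible from its emitted
run log plus the seed: every stage draws randomness only from the seed
recorded there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import features as feat
from .cipher import CipherMessage, decrypt, encrypt
from .decompose import (
    AdaptiveVMDParams,
    VMDSettings,
    adaptive_refine,
    emd,
    psd,
    reconstruct,
    recover_first_imf,
    vmd,
)
from .errors import EcgCryptError, NoIMFError
from .keygen import BioKey, KestrelParams, derive_biokey
from .preprocess import BandpassSpec, preprocess
from .signal import ECGSignal


@dataclass
class PipelineConfig:
    """All stage settings plus the output directory and master seed."""

    outdir: Path = Path("ecgcrypt-run")
    seed: int = 0
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    vmd: VMDSettings = field(default_factory=VMDSettings)
    adaptive: AdaptiveVMDParams = field(default_factory=AdaptiveVMDParams)
    stft_window: int | None = None  # default: 1 s at the signal's fs
    stft_hop: int | None = None
    kestrel: KestrelParams = field(default_factory=lambda: KestrelParams())
    scheme: str = "chacha20"
    energy_fraction: float = 0.85

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scheme": self.scheme,
            "bandpass": vars(self.bandpass),
            "vmd": vars(self.vmd),
            "adaptive": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in vars(self.adaptive).items()
            },
            "stft": {"window": self.stft_window, "hop": self.stft_hop},
            "kestrel": vars(self.kestrel),
            "energy_fraction": self.energy_fraction,
        }


def extract_features(
    preprocessed: ECGSignal,
    reconstructed: ECGSignal,
    modeset,
    config: PipelineConfig,
) -> feat.FeatureBundle:
    """Build the full FeatureBundle from the pipeline's intermediate signals.

    Time/frequency/time–frequency/ZCR features come from the reconstructed
    (denoised) signal; HRV comes from R-peaks detected on the preprocessed
    signal; the mode summary carries per-VMD-mode (energy, center
    frequency) and the first-IMF (energy, dominant frequency).
    """
    recon = reconstructed.samples
    fs = reconstructed.fs

    time_rec = feat.time_domain_features(recon)
    spectrum = feat.dft(recon, fs=fs)
    freq_rec = feat.frequency_features(spectrum, config.energy_fraction)
    grid = feat.stft(recon, window=config.stft_window, hop=config.stft_hop, fs=fs)
    tf_rec = feat.timefreq_features(grid)
    peaks = feat.detect_r_peaks(preprocessed)
    hrv_rec = feat.hrv_metrics(feat.rr_intervals(peaks, fs))
    zcr_rec = feat.zcr(recon, fs=fs)

    energies = modeset.mode_energies()
    summary: list[float] = []
    names: list[str] = []
    for i, (e, cf) in enumerate(zip(energies, modeset.center_frequencies)):
        summary += [float(e), float(cf)]
        names += [f"mode_summary.vmd{i}.energy", f"mode_summary.vmd{i}.center_frequency"]
    try:
        imf1 = recover_first_imf(emd(reconstructed))
        f_grid, p = psd(imf1.samples, fs)
        summary += [float(np.sum(imf1.samples**2)), float(f_grid[np.argmax(p)])]
    except NoIMFError:
        summary += [0.0, 0.0]
    names += ["mode_summary.imf1.energy", "mode_summary.imf1.dominant_frequency"]

    return feat.FeatureBundle(
        time={k: time_rec[k] for k in feat.TIME_KEYS},
        freq=freq_rec,
        timefreq=tf_rec,
        hrv=hrv_rec,
        zcr=zcr_rec,
        mode_summary=np.asarray(summary),
        mode_summary_names=names,
    )


@dataclass
class PipelineResult:
    """Everything a run produces, in memory plus the paths written."""

    bundle: feat.FeatureBundle
    biokey: BioKey
    message: CipherMessage
    paths: dict[str, Path]


def run_pipeline(signal: ECGSignal, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the whole encryption pipeline on ``signal``; write all artifacts.

    The plaintext protected by the cipher is the signal's raw sample bytes
    (float64 little-endian), so ``decrypt_artifacts`` can restore the exact
    input samples.
    """
    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "preprocess"
    try:
        clean = preprocess(signal, config.bandpass)
        stage = "decompose"
        modeset = adaptive_refine(vmd(clean, config.vmd), config.adaptive)
        recon = reconstruct(modeset)
        stage = "features"
        bundle = extract_features(clean, recon, modeset, config)
        fused = bundle.fused
        stage = "keygen"
        kparams = KestrelParams(**{**vars(config.kestrel), "seed": config.seed})
        biokey = derive_biokey(fused, kparams)
        stage = "encrypt"
        plaintext = signal.samples.astype("<f8").tobytes()
        message = encrypt(plaintext, biokey, config.scheme)
    except EcgCryptError as exc:
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc

    paths = {
        "features_csv": outdir / "features.csv",
        "features_json": outdir / "features.json",
        "key": outdir / "key.bin",
        "key_provenance": outdir / "key.json",
        "ciphertext": outdir / "ciphertext.bin",
        "runlog": outdir / "runlog.json",
    }
    names = bundle.layout()
    paths["features_csv"].write_text(
        ",".join(names) + "\n" + ",".join(f"{v:.12g}" for v in fused) + "\n"
    )
    paths["features_json"].write_text(json.dumps(bundle.to_dict(), indent=2))
    paths["key"].write_bytes(biokey.final_key + biokey.nonce)
    paths["key_provenance"].write_text(
        json.dumps(
            {
                "provenance": biokey.provenance,
                "unique_feature_key_hex": biokey.unique_feature_key.hex(),
                "fused_length": int(fused.size),
            },
            indent=2,
        )
    )
    paths["ciphertext"].write_bytes(message.to_bytes())
    paths["runlog"].write_text(
        json.dumps(
            {
                "config": config.to_dict(),
                "input": {"n_samples": len(signal), "fs": signal.fs, "label": signal.label},
                "vmd_center_frequencies_hz": modeset.center_frequencies.tolist(),
                "vmd_converged": bool(modeset.converged),
                "fused_length": int(fused.size),
            },
            indent=2,
        )
    )
    return PipelineResult(bundle=bundle, biokey=biokey, message=message, paths=paths)


def decrypt_artifacts(ciphertext_path: Path, key_path: Path, fs: float) -> ECGSignal:
    """Restore the original signal from a run's ciphertext + key files."""
    blob = Path(key_path).read_bytes()
    key, nonce = blob[:32], blob[32:44]

    class _Key:
        final_key = key

    _Key.nonce = nonce
    message = CipherMessage.from_bytes(Path(ciphertext_path).read_bytes())
    plaintext = decrypt(message, _Key)
    samples = np.frombuffer(plaintext, dtype="<f8")
    return ECGSignal(samples, fs=fs, label="decrypted")
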