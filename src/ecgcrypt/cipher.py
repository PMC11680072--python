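"""ChaCha20-family stream ciphers and the execution-time harness.

The cores (ChaCha with a configurable round count and Salsa20) are
implemented directly from the public algorithm specifications — the 16-word
state, quarter-round mixing, and per-64-byte-block counter — rather than
delegated to a crypto library, so that key generation and the per-scheme
cores can be timed uniformly. Block generation is vectorized across blocks
with numpy for throughput. Encryption is the pure stream XOR
C_i = P_i ⊕ K_i; decryption applies the identical keystream.

No authentication (AEAD) layer is provided: this is the raw stream model,
which protects confidentiality only. Never reuse a (key, nonce) pair.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .errors import InputError

SCHEMES = ("chacha20", "chacha12", "salsa20")
_SCHEME_IDS = {"chacha20": 1, "chacha12": 2, "salsa20": 3}
_IDS_SCHEME = {v: k for k, v in _SCHEME_IDS.items()}
_MAGIC = b"ECGC"
_NONCE_BYTES = {"chacha20": 12, "chacha12": 12, "salsa20": 8}

# "expand 32-byte k", as four little-endian words
_SIGMA = np.array([0x61707865, 0x3320646E, 0x79622D32, 0x6B206574], dtype=np.uint32)

_MAX_BLOCKS_PER_CHUNK = 1 << 14  # 1 MiB of keystream per vectorized batch


def _rotl(x: np.ndarray, n: int) -> np.ndarray:
    return (x << np.uint32(n)) | (x >> np.uint32(32 - n))


def _chacha_quarter(s: np.ndarray, a: int, b: int, c: int, d: int) -> None:
    s[a] += s[b]
    s[d] = _rotl(s[d] ^ s[a], 16)
    s[c] += s[d]
    s[b] = _rotl(s[b] ^ s[c], 12)
    s[a] += s[b]
    s[d] = _rotl(s[d] ^ s[a], 8)
    s[c] += s[d]
    s[b] = _rotl(s[b] ^ s[c], 7)


def _chacha_blocks(
    key_words: np.ndarray, nonce_words: np.ndarray, counters: np.ndarray, rounds: int
) -> np.ndarray:
    """ChaCha keystream blocks, one column per counter value. (16, n) uint32."""
    n = counters.size
    state = np.empty((16, n), dtype=np.uint32)
    state[0:4] = _SIGMA[:, None]
    state[4:12] = key_words[:, None]
    state[12] = counters
    state[13:16] = nonce_words[:, None]
    w = state.copy()
    for _ in range(rounds // 2):
        _chacha_quarter(w, 0, 4, 8, 12)
        _chacha_quarter(w, 1, 5, 9, 13)
        _chacha_quarter(w, 2, 6, 10, 14)
        _chacha_quarter(w, 3, 7, 11, 15)
        _chacha_quarter(w, 0, 5, 10, 15)
        _chacha_quarter(w, 1, 6, 11, 12)
        _chacha_quarter(w, 2, 7, 8, 13)
        _chacha_quarter(w, 3, 4, 9, 14)
    w += state
    return w


def _salsa_quarter(s: np.ndarray, a: int, b: int, c: int, d: int) -> None:
    s[b] ^= _rotl(s[a] + s[d], 7)
    s[c] ^= _rotl(s[b] + s[a], 9)
    s[d] ^= _rotl(s[c] + s[b], 13)
    s[a] ^= _rotl(s[d] + s[c], 18)


def _salsa_blocks(
    key_words: np.ndarray, nonce_words: np.ndarray, counters: np.ndarray
) -> np.ndarray:
    """Salsa20 keystream blocks; 64-bit block counter in words 8 (lo) and 9 (hi)."""
    n = counters.size
    state = np.empty((16, n), dtype=np.uint32)
    state[0] = _SIGMA[0]
    state[1:5] = key_words[0:4, None]
    state[5] = _SIGMA[1]
    state[6:8] = nonce_words[:, None]
    state[8] = (counters & 0xFFFFFFFF).astype(np.uint32)
    state[9] = (counters >> 32).astype(np.uint32)
    state[10] = _SIGMA[2]
    state[11:15] = key_words[4:8, None]
    state[15] = _SIGMA[3]
    w = state.copy()
    for _ in range(10):
        _salsa_quarter(w, 0, 4, 8, 12)
        _salsa_quarter(w, 5, 9, 13, 1)
        _salsa_quarter(w, 10, 14, 2, 6)
        _salsa_quarter(w, 15, 3, 7, 11)
        _salsa_quarter(w, 0, 1, 2, 3)
        _salsa_quarter(w, 5, 6, 7, 4)
        _salsa_quarter(w, 10, 11, 8, 9)
        _salsa_quarter(w, 15, 12, 13, 14)
    w += state
    return w


def keystream(
    scheme: str, key: bytes, nonce: bytes, counter: int = 0, length: int = 0
) -> bytes:
    """Generate ``length`` keystream bytes for the given scheme.

    The block counter starts at ``counter`` and increments once per 64-byte
    block, so keystream(c, 128) == keystream(c, 64) ‖ keystream(c+1, 64).
    """
    if scheme not in SCHEMES:
        raise InputError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if len(key) != 32:
        raise InputError(f"{scheme} requires a 32-byte key, got {len(key)}")
    expected_nonce = _NONCE_BYTES[scheme]
    if len(nonce) != expected_nonce:
        raise InputError(
            f"{scheme} requires a {expected_nonce}-byte nonce, got {len(nonce)}"
        )
    if counter < 0 or length < 0:
        raise InputError("counter and length must be non-negative")
    if length == 0:
        return b""

    key_words = np.frombuffer(key, dtype="<u4").astype(np.uint32)
    nonce_words = np.frombuffer(nonce, dtype="<u4").astype(np.uint32)
    n_blocks = -(-length // 64)
    out = bytearray()
    for start in range(0, n_blocks, _MAX_BLOCKS_PER_CHUNK):
        stop = min(start + _MAX_BLOCKS_PER_CHUNK, n_blocks)
        counters = counter + np.arange(start, stop, dtype=np.uint64)
        if scheme == "salsa20":
            blocks = _salsa_blocks(key_words, nonce_words, counters)
        else:
            rounds = 20 if scheme == "chacha20" else 12
            blocks = _chacha_blocks(
                key_words, nonce_words, (counters & 0xFFFFFFFF).astype(np.uint32), rounds
            )
        # (16, n) words -> per-block little-endian byte serialization
        out += blocks.T.astype("<u4").tobytes()
    return bytes(out[:length])


@dataclass
class CipherMessage:
    """An encrypted payload: scheme, nonce, starting counter, ciphertext."""

    scheme: str
    nonce: bytes
    counter: int
    ciphertext: bytes

    def to_bytes(self) -> bytes:
        """Container layout: magic ‖ version ‖ scheme id ‖ nonce len ‖ nonce ‖
        counter (8 LE) ‖ payload length (8 LE) ‖ payload."""
        return (
            _MAGIC
            + bytes([1, _SCHEME_IDS[self.scheme], len(self.nonce)])
            + self.nonce
            + self.counter.to_bytes(8, "little")
            + len(self.ciphertext).to_bytes(8, "little")
            + self.ciphertext
        )

    @classmethod
    def from_bytes(cls, blob: bytes) -> "CipherMessage":
        if blob[:4] != _MAGIC:
            raise InputError("not an ecgcrypt ciphertext container")
        if blob[4] != 1:
            raise InputError(f"unsupported container version {blob[4]}")
        scheme = _IDS_SCHEME.get(blob[5])
        if scheme is None:
            raise InputError(f"unknown scheme id {blob[5]}")
        nlen = blob[6]
        off = 7
        nonce = blob[off : off + nlen]
        off += nlen
        counter = int.from_bytes(blob[off : off + 8], "little")
        off += 8
        plen = int.from_bytes(blob[off : off + 8], "little")
        off += 8
        ciphertext = blob[off : off + plen]
        if len(ciphertext) != plen:
            raise InputError("truncated ciphertext container")
        return cls(scheme=scheme, nonce=nonce, counter=counter, ciphertext=ciphertext)


def encrypt(
    plaintext: bytes, biokey, scheme: str = "chacha20", counter: int = 0
) -> CipherMessage:
    """C_i = P_i ⊕ K_i with the bio-key's 256-bit key and stored nonce."""
    nonce = biokey.nonce[: _NONCE_BYTES.get(scheme, 12)]
    ks = keystream(scheme, biokey.final_key, nonce, counter, len(plaintext))
    ct = _xor(plaintext, ks)
    return CipherMessage(scheme=scheme, nonce=nonce, counter=counter, ciphertext=ct)


def decrypt(message: CipherMessage, biokey, scheme: str | None = None) -> bytes:
    """P_i = C_i ⊕ K_i; the same keystream undoes the XOR exactly."""
    if scheme is not None and scheme != message.scheme:
        raise InputError(
            f"scheme mismatch: message is {message.scheme!r}, requested {scheme!r}"
        )
    expected = _NONCE_BYTES[message.scheme]
    if len(message.nonce) != expected:
        raise InputError(
            f"nonce length {len(message.nonce)} invalid for {message.scheme}"
        )
    ks = keystream(
        message.scheme, biokey.final_key, message.nonce, message.counter,
        len(message.ciphertext),
    )
    return _xor(message.ciphertext, ks)


def _xor(a: bytes, b: bytes) -> bytes:
    return (
        np.bitwise_xor(np.frombuffer(a, dtype=np.uint8), np.frombuffer(b, dtype=np.uint8))
        .tobytes()
        if a
        else b""
    )


def benchmark(
    schemes=SCHEMES,
    message_sizes=(1024, 65536),
    repetitions: int = 5,
    keygen_fn=None,
) -> list[dict]:
    """Median wall times per scheme, mirroring the execution-time comparison.

    Columns: encryption, decryption, key generation, and their total, in
    seconds. Values are hardware-dependent and reported, never asserted.
    ``keygen_fn`` must return an object with ``final_key``/``nonce``; by
    default a small kestrel search over a fixed fused vector is timed.
    """
    if repetitions < 1:
        raise InputError("need at least one repetition")
    if keygen_fn is None:
        from .keygen import KestrelParams, derive_biokey

        params = KestrelParams(population_size=20, iterations=10, seed=0)
        fused = np.linspace(0.0, 1.0, 30)
        keygen_fn = lambda: derive_biokey(fused, params)  # noqa: E731

    rows = []
    for scheme in schemes:
        key_times, enc_times, dec_times = [], [], []
        for _ in range(repetitions):
            t0 = time.perf_counter()
            biokey = keygen_fn()
            key_times.append(time.perf_counter() - t0)
            for size in message_sizes:
                payload = bytes(i % 251 for i in range(size))
                t0 = time.perf_counter()
                msg = encrypt(payload, biokey, scheme)
                enc_times.append(time.perf_counter() - t0)
                t0 = time.perf_counter()
                decrypt(msg, biokey)
                dec_times.append(time.perf_counter() - t0)
        enc = float(np.median(enc_times))
        dec = float(np.median(dec_times))
        kg = float(np.median(key_times))
        rows.append(
            {
                "scheme": scheme,
                "encryption_s": enc,
                "decryption_s": dec,
                "keygen_s": kg,
                "total_s": enc + dec + kg,
            }
        )
    return rows


def format_benchmark(rows: list[dict]) -> str:
    """Plain-text table of the benchmark report."""
    header = f"{'Scheme':<10}{'Encryption':>14}{'Decryption':>14}{'Key gen':>14}{'Total':>14}"
    lines = [header, "-" * len(header)]
    for r in rows:
        lines.append(
            f"{r['scheme']:<10}"
            f"{r['encryption_s']:>13.6f}s{r['decryption_s']:>13.6f}s"
            f"{r['keygen_s']:>13.6f}s{r['total_s']:>13.6f}s"
        )
    return "\n".join(lines)
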