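"""Bio-inspired key generation from the fused ECG feature vector.

Two ingredients are combined into the final 256-bit key:

1. a *unique feature key* — a SHA-256 digest of a canonical fixed-point
   serialization of the fused feature vector (so the key is tied to the
   person's ECG features), and
2. a *random component* — the bitstring of the best candidate found by a
   kestrel-style population search whose exploration is modulated by a
   radioactive half-life intensity decay γ_t = γ₀·e^{−φt}, φ = ln2/t½.

Candidates fly (large perturbation, probability 0.8) or perch (small local
perturbation, probability 0.2); their perturbation scale decays with the
half-life intensity, and when the decay constant exceeds 1 ("trail is new")
a candidate abandons its trail and re-randomizes. Fitness is the Shannon
entropy (bits/byte) of the candidate's binarized bytes — the paper's stated
evaluation of key randomness. The search is elitist: the best candidate
ever seen (including the initial population) is returned, ties broken by
lowest candidate index.

All randomness flows through one seeded generator, so (fused vector, seed)
fully determines the final key.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

FLIGHT_SCALE = 0.5  # flight-mode perturbation half-range, scaled by gamma_t
PERCH_SCALE = 0.05  # perch-mode perturbation half-range


@dataclass
class KestrelParams:
    """Search hyper-parameters; flight/perch probabilities must sum to 1."""

    population_size: int = 200
    flight_prob: float = 0.8
    perch_prob: float = 0.2
    iterations: int = 50
    t_half: float = 1.0
    gamma0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.flight_prob + self.perch_prob - 1.0) > 1e-12:
            raise InputError("flight_prob + perch_prob must equal 1")
        if self.population_size < 2:
            raise InputError("population_size must be >= 2")
        if self.t_half <= 0:
            raise InputError("t_half must be positive")
        if not 0 < self.gamma0 <= 1:
            raise InputError("gamma0 must lie in (0, 1]")


@dataclass
class KestrelCandidate:
    """One candidate key: γ vector in [0,1]^m, RandBit stream, binarized bits."""

    gammas: np.ndarray
    rand_bits: np.ndarray
    bits: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.uint8))
    fitness: float = 0.0

    def rebinarize(self) -> None:
        """bits = (γ ≥ 0.5) XOR RandBit stream; fitness = entropy of the bytes."""
        base = (self.gammas >= 0.5).astype(np.uint8)
        self.bits = np.bitwise_xor(base, self.rand_bits)
        self.fitness = shannon_entropy(np.packbits(self.bits).tobytes())

    def key_bytes(self) -> bytes:
        return np.packbits(self.bits).tobytes()


@dataclass
class BioKey:
    """Final 256-bit key with its 96-bit nonce and provenance."""

    unique_feature_key: bytes  # 32 bytes
    random_component: bytes  # winning candidate bits, packed
    final_key: bytes  # 32 bytes
    nonce: bytes  # 12 bytes
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.final_key) != 32:
            raise InputError("final key must be exactly 256 bits")
        if len(self.nonce) != 12:
            raise InputError("nonce must be exactly 96 bits")


# ---------------------------------------------------------------------------
# half-life machinery
# ---------------------------------------------------------------------------


def decay_constant(t_half: float) -> float:
    """φ = ln(0.5)/(−t½) = ln2/t½."""
    if t_half <= 0:
        raise InputError("t_half must be positive")
    return math.log(2.0) / t_half


def half_life_decay(gamma0: float, t_half: float, t: float) -> float:
    """γ_t = γ₀·e^{−φt}; halves every t½."""
    if gamma0 <= 0:
        raise InputError("gamma0 must be positive")
    if t < 0:
        raise InputError("t must be non-negative")
    return gamma0 * math.exp(-decay_constant(t_half) * t)


def trail_is_new(phi: float) -> int:
    """1 iff the decay constant strictly exceeds 1, else 0."""
    if not math.isfinite(phi):
        raise InputError("phi must be finite")
    return 1 if phi > 1.0 else 0


# ---------------------------------------------------------------------------
# population search
# ---------------------------------------------------------------------------


def init_population(
    params: KestrelParams, m: int = 256, rng: np.random.Generator | None = None
) -> list[KestrelCandidate]:
    """Seeded initial population: uniform γ values plus a RandBit stream each."""
    if m < 8:
        raise InputError("need at least 8 bits per candidate")
    rng = rng or np.random.default_rng(params.seed)
    population = []
    for _ in range(params.population_size):
        cand = KestrelCandidate(
            gammas=rng.uniform(0.0, 1.0, size=m),
            rand_bits=rng.integers(0, 2, size=m, dtype=np.uint8),
        )
        cand.rebinarize()
        population.append(cand)
    return population


def kestrel_search(
    population: list[KestrelCandidate],
    params: KestrelParams,
    rng: np.random.Generator | None = None,
) -> KestrelCandidate:
    """Flight/perch search for the maximum-entropy candidate.

    Elitist: returns the best candidate observed across all rounds,
    including the starting population; ties go to the lowest index.
    """
    if not population:
        raise InputError("population must be non-empty")
    rng = rng or np.random.default_rng(params.seed + 1)
    phi = decay_constant(params.t_half)

    best = _copy(population[int(np.argmax([c.fitness for c in population]))])
    for t in range(1, params.iterations + 1):
        gamma_t = half_life_decay(params.gamma0, params.t_half, float(t))
        for cand in population:
            if trail_is_new(phi):
                cand.gammas = rng.uniform(0.0, 1.0, size=cand.gammas.size)
            elif rng.uniform() < params.flight_prob:
                step = rng.uniform(-FLIGHT_SCALE, FLIGHT_SCALE, size=cand.gammas.size)
                cand.gammas = np.clip(cand.gammas + gamma_t * step, 0.0, 1.0)
            else:
                step = rng.uniform(-PERCH_SCALE, PERCH_SCALE, size=cand.gammas.size)
                cand.gammas = np.clip(cand.gammas + step, 0.0, 1.0)
            cand.rebinarize()
            if cand.fitness > best.fitness:
                best = _copy(cand)
    return best


def _copy(cand: KestrelCandidate) -> KestrelCandidate:
    return KestrelCandidate(
        gammas=cand.gammas.copy(),
        rand_bits=cand.rand_bits.copy(),
        bits=cand.bits.copy(),
        fitness=cand.fitness,
    )


# ---------------------------------------------------------------------------
# key assembly
# ---------------------------------------------------------------------------


def serialize_features(fused: np.ndarray) -> bytes:
    """Canonical serialization: fixed-point 6 decimals, '|'-separated."""
    fused = np.asarray(fused, dtype=float)
    if fused.size == 0:
        raise InputError("fused vector is empty")
    if not np.all(np.isfinite(fused)):
        raise InputError("fused vector contains non-finite entries")
    return "|".join(f"{v:.6f}" for v in fused).encode("ascii")


def unique_feature_key(fused: np.ndarray) -> bytes:
    """256-bit SHA-256 digest of the canonical feature serialization."""
    return hashlib.sha256(serialize_features(fused)).digest()


def generate_final_key(
    unique_key: bytes,
    winner: KestrelCandidate,
    params: KestrelParams,
    rng: np.random.Generator | None = None,
) -> BioKey:
    """F_key = SHA-256(unique_key ‖ winner bits), with a fresh 96-bit nonce.

    Hashing the concatenation down to 256 bits yields exactly the key size
    the ChaCha20 family requires.
    """
    rng = rng or np.random.default_rng(params.seed + 2)
    random_component = winner.key_bytes()
    final = hashlib.sha256(unique_key + random_component).digest()
    nonce = rng.integers(0, 256, size=12, dtype=np.uint8).tobytes()
    return BioKey(
        unique_feature_key=unique_key,
        random_component=random_component,
        final_key=final,
        nonce=nonce,
        provenance={
            "population_size": params.population_size,
            "iterations": params.iterations,
            "t_half": params.t_half,
            "gamma0": params.gamma0,
            "seed": params.seed,
            "winner_fitness": winner.fitness,
        },
    )


def derive_biokey(
    fused: np.ndarray, params: KestrelParams | None = None, m: int = 256
) -> BioKey:
    """Full Algorithm: unique key → population → search → final key."""
    params = params or KestrelParams()
    rng = np.random.default_rng(params.seed)
    ufk = unique_feature_key(fused)
    population = init_population(params, m=m, rng=rng)
    winner = kestrel_search(population, params, rng=rng)
    return generate_final_key(ufk, winner, params, rng=rng)


# ---------------------------------------------------------------------------
# entropy estimators
# ---------------------------------------------------------------------------


def _byte_probs(data: bytes) -> np.ndarray:
    if len(data) == 0:
        raise InputError("empty input has no entropy")
    counts = np.bincount(np.frombuffer(data, dtype=np.uint8), minlength=256)
    return counts[counts > 0] / len(data)


def shannon_entropy(data: bytes) -> float:
    """−Σ p_i log₂ p_i over the empirical byte distribution (bits/byte)."""
    p = _byte_probs(data)
    return float(-np.sum(p * np.log2(p)))


def min_entropy(data: bytes) -> float:
    """−log₂ max_i p_i — worst-case guessing entropy (bits/byte)."""
    p = _byte_probs(data)
    return float(-np.log2(p.max()))
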