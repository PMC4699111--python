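"""Homomorphic-encryption backends over the plaintext ring ``A_t``.

Two interchangeable backends implement the same interface:

``exact``
    Identity "encryption" — a ciphertext is just a plaintext ring element.
    It satisfies all four homomorphic congruences with zero noise and is
    used as the oracle backend and for large plaintext-scale runs.

``rlwe``
    A genuine public-key ring-LWE scheme of the BGV family with the message
    in the least-significant residue modulo ``t``.  It supports circuits of
    multiplicative depth 1 plus a configurable number of homomorphic
    additions; every computation the outsourcing protocol performs is of
    exactly that shape (sums of contributor uploads, one multiplication per
    scalar product, sums of per-block products).

Fresh ciphertexts have two components ``(c0, c1)`` with
``c0 + c1·s = m + t·v (mod q)``; a product has three and is decrypted
against ``(1, s, s²)`` directly — no relinearisation keys are kept.
Attempting a second multiplication raises ``DepthBudgetError`` rather than
corrupting the result silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import sympy

from .ring import (
    ParameterError,
    RingElement,
    RingParams,
    negacyclic_convolve,
    ring_add,
    ring_mul,
)

__all__ = [
    "DepthBudgetError",
    "DecryptionError",
    "SecurityParams",
    "BackendParams",
    "KeyPair",
    "Ciphertext",
    "select_lattice_dimension",
    "make_backend",
    "ExactBackend",
    "RlweBackend",
]

DEFAULT_SIGMA = 3.2
DEFAULT_ADDITION_BUDGET = 1024


class DepthBudgetError(RuntimeError):
    """Circuit exceeds the multiplicative depth the backend supports."""


class DecryptionError(RuntimeError):
    """Key/ciphertext mismatch or unreadable ciphertext."""


@dataclass(frozen=True)
class SecurityParams:
    """Depth ``L`` of evaluable circuits and security level ``kappa`` in bits."""

    L: int
    kappa: int

    def __post_init__(self) -> None:
        if self.L < 1 or self.kappa < 1:
            raise ParameterError("L and kappa must be positive integers")


def select_lattice_dimension(security: SecurityParams) -> int:
    """Smallest power-of-two lattice dimension meeting the security bound.

    The scheme is secure at ``kappa`` bits for depth-``L`` circuits when
    ``n > (L(log2 n + 23) - 8.5)(kappa + 110) / 7.2``; the search walks the
    powers of two upward until the inequality holds.
    """
    n = 2
    while True:
        rhs = (security.L * (math.log2(n) + 23) - 8.5) * (security.kappa + 110) / 7.2
        if n > rhs:
            return n
        n *= 2


def _noise_budget(n: int, t: int, sigma: float, addition_budget: int) -> dict[str, int]:
    """Worst-case centered-phase magnitudes for the depth-1 circuit family.

    Noise samples are drawn from a rounded Gaussian truncated at
    ``B_e = ceil(6 sigma)`` and secrets/ephemerals are ternary, so a fresh
    phase ``m + t(e·u + e0 + e1·s)`` is bounded by
    ``t/2 + t·B_e·(2n + 1)``.  ``A`` pre-multiplication additions scale it
    by ``A``; one negacyclic multiplication squares it times ``n``; a
    plaintext multiplication scales it by ``n·t/2``; ``A`` post additions
    scale by ``A`` again.  The ciphertext modulus must exceed twice the
    final bound.
    """
    B_e = math.ceil(6 * sigma)
    fresh = t // 2 + t * B_e * (2 * n + 1)
    pre = addition_budget * fresh
    after_mult = n * pre * pre
    after_plain = pre * n * (t // 2)
    final = addition_budget * max(after_mult, after_plain)
    return {"B_e": B_e, "fresh": fresh, "final": final}


@dataclass(frozen=True)
class BackendParams:
    """Ring, security and RLWE noise parameters for one protocol run."""

    ring: RingParams
    security: SecurityParams = SecurityParams(L=6, kappa=80)
    sigma: float = DEFAULT_SIGMA
    addition_budget: int = DEFAULT_ADDITION_BUDGET
    q: Optional[int] = None  # derived from the noise bound when None
    validate: bool = True

    def __post_init__(self) -> None:
        budget = _noise_budget(
            self.ring.n, self.ring.t, self.sigma, self.addition_budget
        )
        if self.q is None:
            object.__setattr__(self, "q", int(sympy.nextprime(4 * budget["final"])))
        q = int(self.q)
        if q % 2 == 0 or math.gcd(q, self.ring.t) != 1:
            raise ParameterError("ciphertext modulus must be odd and coprime to t")
        if self.validate and q <= 2 * budget["final"]:
            raise ParameterError(
                f"ciphertext modulus q={q} below the worst-case noise bound "
                f"{2 * budget['final']} for depth 1 + {self.addition_budget} additions"
            )
        object.__setattr__(self, "q", q)

    @property
    def noise_bound(self) -> int:
        return _noise_budget(
            self.ring.n, self.ring.t, self.sigma, self.addition_budget
        )["final"]


@dataclass(frozen=True)
class KeyPair:
    pk: object
    sk: object
    params: BackendParams
    scheme: str


@dataclass(frozen=True)
class Ciphertext:
    """Opaque encrypted ring element; 2 components fresh, 3 after a product."""

    payload: tuple
    scheme: str
    n_components: int

    def __post_init__(self) -> None:
        if self.n_components not in (2, 3):
            raise ParameterError("ciphertext component count must be 2 or 3")


class _BaseBackend:
    """Shared plumbing: operation counters and parameter storage."""

    scheme: str

    def __init__(self, params: BackendParams, seed: int = 0) -> None:
        self.params = params
        self.seed = int(seed)
        self.counts = {"hadd": 0, "hmult": 0, "add_plain": 0, "mult_plain": 0}

    def reset_counts(self) -> None:
        for k in self.counts:
            self.counts[k] = 0

    @property
    def multiplication_count(self) -> int:
        return self.counts["hmult"] + self.counts["mult_plain"]

    def _check_plain(self, p: RingElement) -> None:
        if p.params != self.params.ring:
            raise ParameterError("plaintext ring parameters do not match backend")

    def _check_ct(self, c: Ciphertext) -> None:
        if c.scheme != self.scheme:
            raise DecryptionError(
                f"ciphertext from backend {c.scheme!r} used with {self.scheme!r}"
            )


class ExactBackend(_BaseBackend):
    """Identity-encryption oracle backend: ciphertext == plaintext element.

    Homomorphic operations are plain ring operations; component counts are
    tracked anyway so depth accounting matches the RLWE backend exactly.
    """

    scheme = "exact"

    def keygen(self, seed: Optional[int] = None) -> KeyPair:
        return KeyPair(pk="exact", sk="exact", params=self.params, scheme=self.scheme)

    def encrypt(self, pk, m: RingElement) -> Ciphertext:
        self._check_plain(m)
        return Ciphertext(payload=(m,), scheme=self.scheme, n_components=2)

    def decrypt(self, sk, c: Ciphertext) -> RingElement:
        self._check_ct(c)
        return c.payload[0]

    def hadd(self, c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
        self._check_ct(c1), self._check_ct(c2)
        self.counts["hadd"] += 1
        return Ciphertext(
            payload=(ring_add(c1.payload[0], c2.payload[0]),),
            scheme=self.scheme,
            n_components=max(c1.n_components, c2.n_components),
        )

    def hmult(self, c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
        self._check_ct(c1), self._check_ct(c2)
        if c1.n_components != 2 or c2.n_components != 2:
            raise DepthBudgetError(
                "depth-1 backend: cannot multiply an already-multiplied ciphertext"
            )
        self.counts["hmult"] += 1
        return Ciphertext(
            payload=(ring_mul(c1.payload[0], c2.payload[0]),),
            scheme=self.scheme,
            n_components=3,
        )

    def add_plain(self, c: Ciphertext, p: RingElement) -> Ciphertext:
        self._check_ct(c), self._check_plain(p)
        self.counts["add_plain"] += 1
        return Ciphertext(
            payload=(ring_add(c.payload[0], p),),
            scheme=self.scheme,
            n_components=c.n_components,
        )

    def mult_plain(self, c: Ciphertext, p: RingElement) -> Ciphertext:
        self._check_ct(c), self._check_plain(p)
        self.counts["mult_plain"] += 1
        return Ciphertext(
            payload=(ring_mul(c.payload[0], p),),
            scheme=self.scheme,
            n_components=c.n_components,
        )


# ---------------------------------------------------------------------------
# RLWE backend
# ---------------------------------------------------------------------------

def _pmod(values: Sequence[int], q: int) -> tuple[int, ...]:
    return tuple(int(v) % q for v in values)


def _padd(a: Sequence[int], b: Sequence[int], q: int) -> tuple[int, ...]:
    return tuple((x + y) % q for x, y in zip(a, b))


def _pneg(a: Sequence[int], q: int) -> tuple[int, ...]:
    return tuple((-x) % q for x in a)


def _pscale(a: Sequence[int], k: int, q: int) -> tuple[int, ...]:
    return tuple((x * k) % q for x in a)


class RlweBackend(_BaseBackend):
    """Public-key RLWE backend (BGV style, message in the mod-``t`` residue).

    Secret key: ternary ``s``.  Public key: ``(b, a)`` with
    ``b = -a·s + t·e``.  Encryption of ``m``: ternary ephemeral ``u``,
    rounded-Gaussian ``e0, e1`` and
    ``c = (b·u + t·e0 + m,  a·u + t·e1) mod q``, so the phase
    ``c0 + c1·s = m + t(e·u + e0 + e1·s)`` decrypts exactly while the total
    noise stays below ``q/2``.
    """

    scheme = "rlwe"

    def __init__(self, params: BackendParams, seed: int = 0) -> None:
        super().__init__(params, seed)
        self._enc_rng = np.random.default_rng(self.seed)
        self._B_e = math.ceil(6 * params.sigma)

    # -- sampling ---------------------------------------------------------
    def _ternary(self, rng) -> tuple[int, ...]:
        return tuple(int(x) for x in rng.integers(-1, 2, self.params.ring.n))

    def _noise(self, rng) -> tuple[int, ...]:
        e = np.rint(rng.normal(0.0, self.params.sigma, self.params.ring.n))
        e = np.clip(e, -self._B_e, self._B_e)
        return tuple(int(x) for x in e)

    def _uniform_mod_q(self, rng) -> tuple[int, ...]:
        # q exceeds 64 bits; draw 64 spare bits per coefficient so the
        # modular bias is < 2^-64
        q = self.params.q
        width = (q.bit_length() + 7) // 8 + 8
        raw = rng.bytes(width * self.params.ring.n)
        return tuple(
            int.from_bytes(raw[i * width : (i + 1) * width], "little") % q
            for i in range(self.params.ring.n)
        )

    def _mulq(self, a: Sequence[int], b: Sequence[int]) -> tuple[int, ...]:
        q = self.params.q
        return tuple(negacyclic_convolve(_pmod(a, q), _pmod(b, q), q))

    # -- key management ---------------------------------------------------
    def keygen(self, seed: Optional[int] = None) -> KeyPair:
        rng = np.random.default_rng(self.seed if seed is None else int(seed))
        q, t = self.params.q, self.params.ring.t
        if q <= 2 * self.params.noise_bound:
            raise ParameterError("configured q fails the keygen noise self-check")
        s = self._ternary(rng)
        a = self._uniform_mod_q(rng)
        e = self._noise(rng)
        b = _padd(_pneg(self._mulq(a, s), q), _pscale(e, t, q), q)
        s_sq = self._mulq(s, s)
        kp = KeyPair(pk=(b, a), sk=(s, s_sq), params=self.params, scheme=self.scheme)
        # roundtrip self-check on a random plaintext
        probe = RingElement.from_coeffs(
            rng.integers(-(t // 2), t // 2 + 1, self.params.ring.n).tolist(),
            self.params.ring,
        )
        if self.decrypt(kp.sk, self.encrypt(kp.pk, probe)) != probe:
            raise DecryptionError("keygen self-check failed: roundtrip mismatch")
        return kp

    def encrypt(self, pk, m: RingElement) -> Ciphertext:
        self._check_plain(m)
        b, a = pk
        q, t = self.params.q, self.params.ring.t
        rng = self._enc_rng
        u = self._ternary(rng)
        e0, e1 = self._noise(rng), self._noise(rng)
        m_q = _pmod(m.coeffs.tolist(), q)
        c0 = _padd(_padd(self._mulq(b, u), _pscale(e0, t, q), q), m_q, q)
        c1 = _padd(self._mulq(a, u), _pscale(e1, t, q), q)
        return Ciphertext(payload=(c0, c1), scheme=self.scheme, n_components=2)

    def decrypt(self, sk, c: Ciphertext) -> RingElement:
        self._check_ct(c)
        s, s_sq = sk
        q, t = self.params.q, self.params.ring.t
        phase = _padd(c.payload[0], self._mulq(c.payload[1], s), q)
        if len(c.payload) == 3:
            phase = _padd(phase, self._mulq(c.payload[2], s_sq), q)
        centered = [p - q if p > q // 2 else p for p in phase]
        return RingElement.from_coeffs([p % t for p in centered], self.params.ring)

    # -- homomorphic operations ------------------------------------------
    def _pad(self, c: Ciphertext, k: int) -> tuple:
        zero = (0,) * self.params.ring.n
        return c.payload + (zero,) * (k - len(c.payload))

    def hadd(self, c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
        self._check_ct(c1), self._check_ct(c2)
        self.counts["hadd"] += 1
        k = max(len(c1.payload), len(c2.payload))
        q = self.params.q
        payload = tuple(
            _padd(x, y, q) for x, y in zip(self._pad(c1, k), self._pad(c2, k))
        )
        return Ciphertext(
            payload=payload,
            scheme=self.scheme,
            n_components=max(c1.n_components, c2.n_components),
        )

    def hmult(self, c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
        self._check_ct(c1), self._check_ct(c2)
        if len(c1.payload) != 2 or len(c2.payload) != 2:
            raise DepthBudgetError(
                "depth-1 backend: cannot multiply an already-multiplied ciphertext"
            )
        self.counts["hmult"] += 1
        q = self.params.q
        (c0, c1_), (d0, d1) = c1.payload, c2.payload
        return Ciphertext(
            payload=(
                self._mulq(c0, d0),
                _padd(self._mulq(c0, d1), self._mulq(c1_, d0), q),
                self._mulq(c1_, d1),
            ),
            scheme=self.scheme,
            n_components=3,
        )

    def add_plain(self, c: Ciphertext, p: RingElement) -> Ciphertext:
        self._check_ct(c), self._check_plain(p)
        self.counts["add_plain"] += 1
        q = self.params.q
        payload = (_padd(c.payload[0], _pmod(p.coeffs.tolist(), q), q),) + c.payload[1:]
        return Ciphertext(payload=payload, scheme=self.scheme, n_components=c.n_components)

    def mult_plain(self, c: Ciphertext, p: RingElement) -> Ciphertext:
        self._check_ct(c), self._check_plain(p)
        self.counts["mult_plain"] += 1
        p_q = _pmod(p.coeffs.tolist(), self.params.q)
        payload = tuple(self._mulq(comp, p_q) for comp in c.payload)
        return Ciphertext(payload=payload, scheme=self.scheme, n_components=c.n_components)


_BACKENDS = {"exact": ExactBackend, "rlwe": RlweBackend}


def make_backend(name: str, params: BackendParams, seed: int = 0):
    """Instantiate a homomorphic backend by name (``exact`` or ``rlwe``)."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ParameterError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return cls(params, seed=seed)
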