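"""Exact arithmetic in the plaintext ring ``A_t = Z_t[x] / (x^n + 1)``.

This is the message space of the BGV-family homomorphic scheme used by the
rest of the package: integer polynomials of degree below ``n`` (a power of
two), with coefficients reduced modulo a prime ``t``.  Every coefficient is
kept in the *centered* interval ``(-t/2, t/2]`` after every operation, so
that signed dot products extracted from the constant term of a product can
be read off directly.

Multiplication is the negacyclic convolution (``x^n ≡ -1``), computed
exactly over the integers by Kronecker substitution on Python big integers
and only then reduced — there is no floating point anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import sympy

__all__ = [
    "ParameterError",
    "RingParams",
    "RingElement",
    "centered_mod",
    "ring_add",
    "ring_mul",
    "constant_term",
    "negacyclic_convolve",
]


class ParameterError(ValueError):
    """Invalid ring / scheme parameters."""


@lru_cache(maxsize=1024)
def _validate_plaintext_modulus(t: int) -> None:
    if not isinstance(t, (int, np.integer)) or t < 3 or not sympy.isprime(int(t)):
        raise ParameterError(f"plaintext modulus must be a prime >= 3, got {t!r}")


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def centered_mod(z: int, t: int) -> int:
    """Reduce ``z`` modulo the odd prime ``t`` into ``(-t/2, t/2]``."""
    _validate_plaintext_modulus(t)
    r = int(z) % t
    return r - t if r > t // 2 else r


def _centered_array(values: np.ndarray, t: int) -> np.ndarray:
    """Vectorised centered reduction; assumes int64-safe inputs."""
    r = np.mod(values, t)
    return np.where(r > t // 2, r - t, r).astype(np.int64)


@dataclass(frozen=True)
class RingParams:
    """Parameters of the ring ``A_t``: lattice dimension ``n`` and prime ``t``.

    ``n`` must be a power of two (degree of ``x^n + 1``); ``t`` an odd prime
    (the plaintext modulus).
    """

    n: int
    t: int

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 2 or not _is_power_of_two(int(self.n)):
            raise ParameterError(f"lattice dimension must be a power of two >= 2, got {self.n!r}")
        _validate_plaintext_modulus(self.t)
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "t", int(self.t))


@dataclass(frozen=True)
class RingElement:
    """An element of ``A_t`` as a centered coefficient vector of length ``n``."""

    coeffs: np.ndarray
    params: RingParams

    @classmethod
    def from_coeffs(cls, coeffs: Iterable[int], params: RingParams) -> "RingElement":
        """Build an element from arbitrary integer coefficients (reduced)."""
        raw = list(coeffs)
        if len(raw) != params.n:
            raise ParameterError(
                f"expected {params.n} coefficients, got {len(raw)}"
            )
        t = params.t
        reduced = np.array([centered_mod(int(c), t) for c in raw], dtype=np.int64)
        return cls(reduced, params)

    @classmethod
    def zero(cls, params: RingParams) -> "RingElement":
        return cls(np.zeros(params.n, dtype=np.int64), params)

    @classmethod
    def one(cls, params: RingParams) -> "RingElement":
        c = np.zeros(params.n, dtype=np.int64)
        c[0] = 1
        return cls(c, params)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=np.int64))

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "RingElement") -> "RingElement":
        _check_same_params(self, other)
        return RingElement(
            _centered_array(self.coeffs + other.coeffs, self.params.t), self.params
        )

    def __neg__(self) -> "RingElement":
        return RingElement(_centered_array(-self.coeffs, self.params.t), self.params)

    def __sub__(self, other: "RingElement") -> "RingElement":
        return self + (-other)

    def __mul__(self, other: "RingElement") -> "RingElement":
        _check_same_params(self, other)
        t = self.params.t
        a = np.mod(self.coeffs, t)
        b = np.mod(other.coeffs, t)
        prod = negacyclic_convolve(a.tolist(), b.tolist(), t)
        return RingElement(
            _centered_array(np.array(prod, dtype=np.int64), t), self.params
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingElement):
            return NotImplemented
        return self.params == other.params and bool(
            np.array_equal(self.coeffs, other.coeffs)
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash((self.params, self.coeffs.tobytes()))

    def is_zero(self) -> bool:
        return not self.coeffs.any()

    def to_list(self) -> list[int]:
        """Plain-int coefficient list (JSON-friendly)."""
        return [int(c) for c in self.coeffs]


def _check_same_params(a: RingElement, b: RingElement) -> None:
    if a.params != b.params:
        raise ParameterError(
            f"ring parameter mismatch: {a.params} vs {b.params}"
        )


def ring_add(a: RingElement, b: RingElement) -> RingElement:
    """Coefficient-wise sum in ``A_t``, re-centered."""
    return a + b


def ring_mul(a: RingElement, b: RingElement) -> RingElement:
    """Negacyclic product in ``A_t`` (``x^n ≡ -1``), re-centered."""
    return a * b


def constant_term(a: RingElement) -> int:
    """The coefficient of ``x^0`` — carries the scalar product after packing."""
    return int(a.coeffs[0])


def negacyclic_convolve(
    a: Sequence[int], b: Sequence[int], modulus: int
) -> list[int]:
    """Exact negacyclic convolution of two length-``n`` sequences mod ``modulus``.

    Inputs must be non-negative residues below ``modulus``; the output is a
    list of non-negative residues.  Implemented by Kronecker substitution:
    the polynomials are packed into big integers with a digit base wide
    enough that ``n * (modulus-1)^2`` never carries between digits, the big
    integers are multiplied once, and the ``2n`` digit slots are folded with
    the sign flip of ``x^n ≡ -1``.
    """
    n = len(a)
    if len(b) != n:
        raise ParameterError("negacyclic_convolve requires equal-length inputs")
    if not any(a) or not any(b):
        return [0] * n
    slot_bound = n * (modulus - 1) ** 2
    width = (slot_bound.bit_length() + 8) // 8  # bytes per digit, 1 spare bit
    A = int.from_bytes(
        b"".join(int(x).to_bytes(width, "little") for x in a), "little"
    )
    B = int.from_bytes(
        b"".join(int(x).to_bytes(width, "little") for x in b), "little"
    )
    raw = (A * B).to_bytes(2 * n * width, "little")
    digits = [
        int.from_bytes(raw[k * width : (k + 1) * width], "little")
        for k in range(2 * n)
    ]
    return [(digits[k] - digits[k + n]) % modulus for k in range(n)]
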