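"""Packing integer vectors into ring elements so that one ring
multiplication yields a scalar product.

A length-``ℓ`` vector ``u`` is *forward* packed as ``Σ u_i x^i`` and a
vector ``v`` is *backward* packed as ``-Σ v_j x^(n-j)``.  Because
``x^n ≡ -1`` in ``A_t``, the constant term of the ring product of the two
packings equals ``⟨u, v⟩`` whenever (1) every entry lies in
``(-t/2, t/2]``, (2) ``ℓ ≤ n`` and (3) the scalar product itself lies in
``(-t/2, t/2]``.  The remaining ``2ℓ - 2`` coefficients of the product are
cross terms and are never interpreted.

When a vector is longer than the packing capacity ``n`` it is split into
``ceil(ℓ/n)`` contiguous blocks of near-equal length; per-block constant
terms then sum to the full scalar product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ring import (
    ParameterError,
    RingElement,
    RingParams,
    centered_mod,
    constant_term,
    ring_mul,
)

__all__ = [
    "CapacityError",
    "RangeError",
    "PackedBlockSet",
    "pack_forward",
    "pack_backward",
    "extract_scalar_product",
    "partition_vector",
    "pack_blocks",
    "blocked_scalar_product",
]


class CapacityError(ParameterError):
    """Vector longer than the packing capacity ``n``."""


class RangeError(ParameterError):
    """Vector entry outside the representable interval ``(-t/2, t/2]``."""


def _check_entries(values: Sequence[int], params: RingParams, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.int64)
    if arr.ndim != 1 or arr.size < 1:
        raise ParameterError(f"{what}: expected a non-empty 1-d integer vector")
    if arr.size > params.n:
        raise CapacityError(
            f"{what}: length {arr.size} exceeds packing capacity n={params.n}"
        )
    half = params.t // 2
    bad = (arr > half) | (arr <= -half - 1)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise RangeError(
            f"{what}: entry {int(arr[i])} at index {i} outside (-t/2, t/2] for t={params.t}"
        )
    return arr


def pack_forward(values: Sequence[int], params: RingParams) -> RingElement:
    """Forward packing: coefficient ``i`` of the result is ``u_i``."""
    arr = _check_entries(values, params, "pack_forward")
    coeffs = np.zeros(params.n, dtype=np.int64)
    coeffs[: arr.size] = arr
    return RingElement(coeffs, params)


def pack_backward(values: Sequence[int], params: RingParams) -> RingElement:
    """Backward packing: ``-Σ v_j x^(n-j)`` reduced into the ring.

    The ``j = 0`` term is ``-v_0 x^n ≡ +v_0``, so the constant coefficient
    is ``+v_0`` and coefficient ``n - j`` is ``-v_j`` for ``1 ≤ j < ℓ``.
    """
    arr = _check_entries(values, params, "pack_backward")
    t = params.t
    coeffs = np.zeros(params.n, dtype=np.int64)
    coeffs[0] = arr[0]
    for j in range(1, arr.size):
        coeffs[params.n - j] = centered_mod(-int(arr[j]), t)
    return RingElement(coeffs, params)


def extract_scalar_product(product: RingElement) -> int:
    """Read ``⟨u, v⟩`` off the constant term of a fw·bw ring product."""
    return constant_term(product)


def partition_vector(values: Sequence[int], n: int) -> list[np.ndarray]:
    """Split a vector into ``ceil(ℓ/n)`` contiguous blocks of length ≤ n.

    Block lengths are as equal as possible (they differ by at most one) and
    concatenation of the blocks reproduces the input.
    """
    arr = np.asarray(values, dtype=np.int64)
    ell = arr.size
    if ell == 0:
        raise ParameterError("cannot partition an empty vector")
    n_blocks = -(-ell // n)  # ceil
    base, rem = divmod(ell, n_blocks)
    lengths = [base + 1] * rem + [base] * (n_blocks - rem)
    out, pos = [], 0
    for length in lengths:
        out.append(arr[pos : pos + length])
        pos += length
    return out


@dataclass(frozen=True)
class PackedBlockSet:
    """An ordered set of packed blocks covering one logical vector."""

    blocks: tuple[RingElement, ...]
    direction: str  # "forward" | "backward"
    block_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ParameterError(f"unknown packing direction {self.direction!r}")
        if len(self.blocks) != len(self.block_lengths):
            raise ParameterError("one block length per block required")


def pack_blocks(
    values: Sequence[int], direction: str, params: RingParams
) -> PackedBlockSet:
    """Partition ``values`` into blocks of length ≤ n and pack each one."""
    packer = {"forward": pack_forward, "backward": pack_backward}.get(direction)
    if packer is None:
        raise ParameterError(f"unknown packing direction {direction!r}")
    chunks = partition_vector(values, params.n)
    return PackedBlockSet(
        blocks=tuple(packer(chunk, params) for chunk in chunks),
        direction=direction,
        block_lengths=tuple(len(c) for c in chunks),
    )


def blocked_scalar_product(
    u_blocks: PackedBlockSet, v_blocks: PackedBlockSet
) -> int:
    """Scalar product of two block-packed vectors (plaintext path).

    Sums the per-block constant terms of the forward·backward ring products
    and re-centers modulo ``t``; exact as long as the total scalar product
    lies in ``(-t/2, t/2]``.
    """
    if u_blocks.direction != "forward" or v_blocks.direction != "backward":
        raise ParameterError(
            "blocked_scalar_product expects (forward, backward) packed operands"
        )
    if u_blocks.block_lengths != v_blocks.block_lengths:
        raise ParameterError(
            f"mismatched block structure: {u_blocks.block_lengths} vs {v_blocks.block_lengths}"
        )
    params = u_blocks.blocks[0].params
    total = sum(
        extract_scalar_product(ring_mul(ub, vb))
        for ub, vb in zip(u_blocks.blocks, v_blocks.blocks)
    )
    return centered_mod(total, params.t)
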