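"""Versioned binary containers for protocol file exchange.

Layout: magic ``HEGW``, format version byte, a little-endian u32 header
length, a UTF-8 JSON header describing the object tree, then a flat payload
of coefficient arrays.  Each array is stored as ``u32 count``, ``u16 byte
width``, then ``count`` fixed-width little-endian unsigned residues (mod q
for RLWE data, mod t for exact-backend/plaintext data).  The header indexes
into the payload by array position, so the format is stable across runs and
platforms.
"""

from __future__ import annotations

import json
import struct
from typing import BinaryIO

from .backends import BackendParams, Ciphertext, KeyPair, SecurityParams
from .pipeline import ProtocolConfig
from .protocol import (
    AggregatedStore,
    ContributorUpload,
    EncryptedAllelicStats,
    EncryptedBlockSet,
    EncryptedGenotypePairStats,
    SnpUpload,
)
from .ring import RingElement, RingParams

__all__ = [
    "save_public_key",
    "load_public_key",
    "save_secret_key",
    "load_secret_key",
    "save_upload",
    "load_upload",
    "save_store",
    "load_store",
    "save_allelic_stats",
    "load_allelic_stats",
    "save_pair_stats",
    "load_pair_stats",
]

_MAGIC = b"HEGW"
_VERSION = 1


class _Writer:
    def __init__(self) -> None:
        self.arrays: list[tuple[int, ...]] = []

    def add(self, coeffs) -> int:
        self.arrays.append(tuple(int(c) for c in coeffs))
        return len(self.arrays) - 1


def _poly_width(modulus: int) -> int:
    return max(1, (int(modulus).bit_length() + 7) // 8)


def _write_container(fh: BinaryIO, header: dict, writer: _Writer, modulus: int) -> None:
    header = dict(header)
    header["n_arrays"] = len(writer.arrays)
    blob = json.dumps(header, sort_keys=True).encode()
    fh.write(_MAGIC)
    fh.write(struct.pack("<BI", _VERSION, len(blob)))
    fh.write(blob)
    width = _poly_width(modulus)
    for arr in writer.arrays:
        fh.write(struct.pack("<IH", len(arr), width))
        for c in arr:
            fh.write(int(c % modulus).to_bytes(width, "little"))


def _read_container(fh: BinaryIO) -> tuple[dict, list[tuple[int, ...]]]:
    if fh.read(4) != _MAGIC:
        raise ValueError("not a hegwas container (bad magic)")
    version, hlen = struct.unpack("<BI", fh.read(5))
    if version != _VERSION:
        raise ValueError(f"unsupported container version {version}")
    header = json.loads(fh.read(hlen).decode())
    arrays = []
    for _ in range(header["n_arrays"]):
        count, width = struct.unpack("<IH", fh.read(6))
        raw = fh.read(count * width)
        arrays.append(
            tuple(
                int.from_bytes(raw[k * width : (k + 1) * width], "little")
                for k in range(count)
            )
        )
    return header, arrays


def _params_header(params: BackendParams) -> dict:
    return {
        "n": params.ring.n,
        "t": params.ring.t,
        "L": params.security.L,
        "kappa": params.security.kappa,
        "sigma": params.sigma,
        "addition_budget": params.addition_budget,
        "q": str(params.q),  # may exceed JSON-safe integer range
    }


def _params_from_header(h: dict) -> BackendParams:
    return BackendParams(
        ring=RingParams(n=h["n"], t=h["t"]),
        security=SecurityParams(L=h["L"], kappa=h["kappa"]),
        sigma=h["sigma"],
        addition_budget=h["addition_budget"],
        q=int(h["q"]),
    )


def _payload_modulus(scheme: str, params: BackendParams) -> int:
    return params.q if scheme == "rlwe" else params.ring.t


def _ct_to_header(ct: Ciphertext, writer: _Writer) -> dict:
    if ct.scheme == "rlwe":
        polys = [writer.add(comp) for comp in ct.payload]
    else:
        polys = [writer.add(ct.payload[0].coeffs.tolist())]
    return {"k": ct.n_components, "polys": polys}


def _ct_from_header(
    h: dict, arrays, scheme: str, params: BackendParams
) -> Ciphertext:
    if scheme == "rlwe":
        payload = tuple(arrays[i] for i in h["polys"])
    else:
        payload = (
            RingElement.from_coeffs(list(arrays[h["polys"][0]]), params.ring),
        )
    return Ciphertext(payload=payload, scheme=scheme, n_components=h["k"])


def _blockset_to_header(bs: EncryptedBlockSet, writer: _Writer) -> dict:
    return {
        "direction": bs.direction,
        "block_lengths": list(bs.block_lengths),
        "cts": [_ct_to_header(ct, writer) for ct in bs.cts],
    }


def _blockset_from_header(h, arrays, scheme, params) -> EncryptedBlockSet:
    return EncryptedBlockSet(
        cts=tuple(_ct_from_header(c, arrays, scheme, params) for c in h["cts"]),
        direction=h["direction"],
        block_lengths=tuple(h["block_lengths"]),
    )


# -- keys -------------------------------------------------------------------

def save_public_key(path, keys: KeyPair) -> None:
    writer = _Writer()
    header = {"kind": "public_key", "scheme": keys.scheme, "params": _params_header(keys.params)}
    if keys.scheme == "rlwe":
        b, a = keys.pk
        header["polys"] = [writer.add(b), writer.add(a)]
    with open(path, "wb") as fh:
        _write_container(fh, header, writer, _payload_modulus(keys.scheme, keys.params))


def load_public_key(path) -> KeyPair:
    with open(path, "rb") as fh:
        header, arrays = _read_container(fh)
    if header["kind"] != "public_key":
        raise ValueError(f"expected a public key container, got {header['kind']!r}")
    params = _params_from_header(header["params"])
    scheme = header["scheme"]
    pk = (
        (arrays[header["polys"][0]], arrays[header["polys"][1]])
        if scheme == "rlwe"
        else "exact"
    )
    return KeyPair(pk=pk, sk=None, params=params, scheme=scheme)


def save_secret_key(path, keys: KeyPair) -> None:
    writer = _Writer()
    header = {"kind": "secret_key", "scheme": keys.scheme, "params": _params_header(keys.params)}
    if keys.scheme == "rlwe":
        s, s_sq = keys.sk
        header["polys"] = [writer.add(s), writer.add(s_sq)]
    with open(path, "wb") as fh:
        _write_container(fh, header, writer, _payload_modulus(keys.scheme, keys.params))


def load_secret_key(path) -> KeyPair:
    with open(path, "rb") as fh:
        header, arrays = _read_container(fh)
    if header["kind"] != "secret_key":
        raise ValueError(f"expected a secret key container, got {header['kind']!r}")
    params = _params_from_header(header["params"])
    scheme = header["scheme"]
    if scheme == "rlwe":
        q = params.q
        s = tuple(c % q for c in arrays[header["polys"][0]])
        sk = (s, arrays[header["polys"][1]])
    else:
        sk = "exact"
    return KeyPair(pk=None, sk=sk, params=params, scheme=scheme)


# -- uploads / store --------------------------------------------------------

def _snp_upload_header(u: SnpUpload, writer: _Writer) -> dict:
    return {
        "fw_AA": _blockset_to_header(u.fw_AA, writer),
        "bw_AA": _blockset_to_header(u.bw_AA, writer),
        "fw_Aa": _blockset_to_header(u.fw_Aa, writer),
        "bw_Aa": _blockset_to_header(u.bw_Aa, writer),
    }


def _snp_upload_from_header(h, arrays, scheme, params) -> SnpUpload:
    return SnpUpload(
        **{
            key: _blockset_from_header(h[key], arrays, scheme, params)
            for key in ("fw_AA", "bw_AA", "fw_Aa", "bw_Aa")
        }
    )


def save_upload(path, upload: ContributorUpload, params: BackendParams, scheme: str) -> None:
    writer = _Writer()
    header = {
        "kind": "contributor_upload",
        "scheme": scheme,
        "params": _params_header(params),
        "q": upload.q,
        "M": upload.M,
        "snp_ids": list(upload.snp_ids),
        "block_lengths": list(upload.block_lengths),
        "snps": {s: _snp_upload_header(upload.snps[s], writer) for s in upload.snp_ids},
        "phenotype_bw": _blockset_to_header(upload.phenotype_bw, writer),
    }
    with open(path, "wb") as fh:
        _write_container(fh, header, writer, _payload_modulus(scheme, params))


def load_upload(path) -> tuple[ContributorUpload, BackendParams, str]:
    with open(path, "rb") as fh:
        header, arrays = _read_container(fh)
    if header["kind"] != "contributor_upload":
        raise ValueError(f"expected an upload container, got {header['kind']!r}")
    params = _params_from_header(header["params"])
    scheme = header["scheme"]
    upload = ContributorUpload(
        q=header["q"],
        M=header["M"],
        snp_ids=tuple(header["snp_ids"]),
        snps={
            s: _snp_upload_from_header(header["snps"][s], arrays, scheme, params)
            for s in header["snp_ids"]
        },
        phenotype_bw=_blockset_from_header(
            header["phenotype_bw"], arrays, scheme, params
        ),
        block_lengths=tuple(header["block_lengths"]),
    )
    return upload, params, scheme


def save_store(path, store: AggregatedStore, params: BackendParams, scheme: str) -> None:
    writer = _Writer()
    header = {
        "kind": "aggregated_store",
        "scheme": scheme,
        "params": _params_header(params),
        "M": store.M,
        "Q": store.Q,
        "snp_ids": list(store.snp_ids),
        "block_lengths": list(store.block_lengths),
        "snps": {s: _snp_upload_header(store.snps[s], writer) for s in store.snp_ids},
        "phenotype_bw": _blockset_to_header(store.phenotype_bw, writer),
    }
    with open(path, "wb") as fh:
        _write_container(fh, header, writer, _payload_modulus(scheme, params))


def load_store(path) -> tuple[AggregatedStore, BackendParams, str]:
    with open(path, "rb") as fh:
        header, arrays = _read_container(fh)
    if header["kind"] != "aggregated_store":
        raise ValueError(f"expected a store container, got {header['kind']!r}")
    params = _params_from_header(header["params"])
    scheme = header["scheme"]
    store = AggregatedStore(
        M=header["M"],
        Q=header["Q"],
        snp_ids=tuple(header["snp_ids"]),
        snps={
            s: _snp_upload_from_header(header["snps"][s], arrays, scheme, params)
            for s in header["snp_ids"]
        },
        phenotype_bw=_blockset_from_header(
            header["phenotype_bw"], arrays, scheme, params
        ),
        block_lengths=tuple(header["block_lengths"]),
    )
    return store, params, scheme


# -- encrypted statistics ---------------------------------------------------

def save_allelic_stats(
    path, stats: list[EncryptedAllelicStats], M: int, params: BackendParams, scheme: str
) -> None:
    writer = _Writer()
    header = {
        "kind": "allelic_stats",
        "scheme": scheme,
        "params": _params_header(params),
        "M": M,
        "stats": [
            {
                "snp": s.snp_id,
                "e_o1": _ct_to_header(s.e_o1, writer),
                "e_colA": _ct_to_header(s.e_colA, writer),
                "e_cases": _ct_to_header(s.e_cases, writer),
            }
            for s in stats
        ],
    }
    with open(path, "wb") as fh:
        _write_container(fh, header, writer, _payload_modulus(scheme, params))


def load_allelic_stats(path) -> tuple[list[EncryptedAllelicStats], int, BackendParams, str]:
    with open(path, "rb") as fh:
        header, arrays = _read_container(fh)
    if header["kind"] != "allelic_stats":
        raise ValueError(f"expected allelic stats, got {header['kind']!r}")
    params = _params_from_header(header["params"])
    scheme = header["scheme"]
    stats = [
        EncryptedAllelicStats(
            snp_id=s["snp"],
            e_o1=_ct_from_header(s["e_o1"], arrays, scheme, params),
            e_colA=_ct_from_header(s["e_colA"], arrays, scheme, params),
            e_cases=_ct_from_header(s["e_cases"], arrays, scheme, params),
        )
        for s in header["stats"]
    ]
    return stats, header["M"], params, scheme


def save_pair_stats(
    path,
    stats: list[EncryptedGenotypePairStats],
    M: int,
    params: BackendParams,
    scheme: str,
) -> None:
    writer = _Writer()
    header = {
        "kind": "pair_stats",
        "scheme": scheme,
        "params": _params_header(params),
        "M": M,
        "stats": [
            {
                "snp_i": s.snp_i,
                "snp_j": s.snp_j,
                "cts": [
                    _ct_to_header(ct, writer)
                    for ct in (s.e_s1, s.e_s2, s.e_s3, s.e_s4, s.e_s5, s.e_s6)
                ],
            }
            for s in stats
        ],
    }
    with open(path, "wb") as fh:
        _write_container(fh, header, writer, _payload_modulus(scheme, params))


def load_pair_stats(path) -> tuple[list[EncryptedGenotypePairStats], int, BackendParams, str]:
    with open(path, "rb") as fh:
        header, arrays = _read_container(fh)
    if header["kind"] != "pair_stats":
        raise ValueError(f"expected pair stats, got {header['kind']!r}")
    params = _params_from_header(header["params"])
    scheme = header["scheme"]
    stats = [
        EncryptedGenotypePairStats(
            s["snp_i"],
            s["snp_j"],
            *(_ct_from_header(c, arrays, scheme, params) for c in s["cts"]),
        )
        for s in header["stats"]
    ]
    return stats, header["M"], params, scheme
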