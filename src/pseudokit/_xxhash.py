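"""Pure-Python xxHash64.

xxHash is a non-cryptographic 64-bit hash; this module implements the XXH64
variant exactly as specified by the reference algorithm (stripe loop over
32-byte blocks, tail handling, final avalanche).  Only short inputs are hashed
in practice (identifier + salt), so speed of the pure-Python path is not a
concern.
"""

from __future__ import annotations

_MASK = 0xFFFFFFFFFFFFFFFF
_P1 = 11400714785074694791
_P2 = 14029467366897019727
_P3 = 1609587929392839161
_P4 = 9650029242287828579
_P5 = 2870177450012600261


def _rotl(x: int, r: int) -> int:
    return ((x << r) | (x >> (64 - r))) & _MASK


def _round(acc: int, lane: int) -> int:
    acc = (acc + lane * _P2) & _MASK
    return (_rotl(acc, 31) * _P1) & _MASK


def _merge_round(acc: int, val: int) -> int:
    acc ^= _round(0, val)
    return (acc * _P1 + _P4) & _MASK


def xxh64(data: bytes, seed: int = 0) -> int:
    """Return the XXH64 digest of ``data`` as an integer."""
    n = len(data)
    pos = 0
    if n >= 32:
        v1 = (seed + _P1 + _P2) & _MASK
        v2 = (seed + _P2) & _MASK
        v3 = seed & _MASK
        v4 = (seed - _P1) & _MASK
        limit = n - 32
        while pos <= limit:
            v1 = _round(v1, int.from_bytes(data[pos:pos + 8], "little"))
            v2 = _round(v2, int.from_bytes(data[pos + 8:pos + 16], "little"))
            v3 = _round(v3, int.from_bytes(data[pos + 16:pos + 24], "little"))
            v4 = _round(v4, int.from_bytes(data[pos + 24:pos + 32], "little"))
            pos += 32
        acc = (_rotl(v1, 1) + _rotl(v2, 7) + _rotl(v3, 12) + _rotl(v4, 18)) & _MASK
        acc = _merge_round(acc, v1)
        acc = _merge_round(acc, v2)
        acc = _merge_round(acc, v3)
        acc = _merge_round(acc, v4)
    else:
        acc = (seed + _P5) & _MASK

    acc = (acc + n) & _MASK

    while pos + 8 <= n:
        acc ^= _round(0, int.from_bytes(data[pos:pos + 8], "little"))
        acc = (_rotl(acc, 27) * _P1 + _P4) & _MASK
        pos += 8
    if pos + 4 <= n:
        acc ^= (int.from_bytes(data[pos:pos + 4], "little") * _P1) & _MASK
        acc = (_rotl(acc, 23) * _P2 + _P3) & _MASK
        pos += 4
    while pos < n:
        acc ^= (data[pos] * _P5) & _MASK
        acc = (_rotl(acc, 11) * _P1) & _MASK
        pos += 1

    acc ^= acc >> 33
    acc = (acc * _P2) & _MASK
    acc ^= acc >> 29
    acc = (acc * _P3) & _MASK
    acc ^= acc >> 32
    return acc


def xxh64_hexdigest(data: bytes, seed: int = 0) -> str:
    """XXH64 digest as 16 lowercase hex characters (big-endian, zero-padded)."""
    return format(xxh64(data, seed), "016x")
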