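"""Pure-Python BLAKE3 (regular hash mode, 256-bit output).

Implements the full chunk/tree construction of BLAKE3: 1024-byte chunks
compressed in 64-byte blocks with the 7-round ChaCha-derived permutation,
binary-tree parent combining, and the ROOT finalisation flag on the last
compression.  Keyed hashing and key derivation modes are omitted; extendable
output beyond 32 bytes is not needed here.

The implementation favours clarity (recursive tree) over throughput; inputs in
this package are short identifier strings.
"""

from __future__ import annotations

from typing import List, Tuple

_IV = (
    0x6A09E667, 0xBB67AE85, 0x3C6EF372, 0xA54FF53A,
    0x510E527F, 0x9B05688C, 0x1F83D9AB, 0x5BE0CD19,
)
_MSG_PERM = (2, 6, 3, 10, 7, 0, 4, 13, 1, 11, 12, 5, 9, 14, 15, 8)
_BLOCK_LEN = 64
_CHUNK_LEN = 1024
_CHUNK_START = 1
_CHUNK_END = 2
_PARENT = 4
_ROOT = 8
_M32 = 0xFFFFFFFF


def _rotr(x: int, r: int) -> int:
    return ((x >> r) | (x << (32 - r))) & _M32


def _g(v: List[int], a: int, b: int, c: int, d: int, mx: int, my: int) -> None:
    v[a] = (v[a] + v[b] + mx) & _M32
    v[d] = _rotr(v[d] ^ v[a], 16)
    v[c] = (v[c] + v[d]) & _M32
    v[b] = _rotr(v[b] ^ v[c], 12)
    v[a] = (v[a] + v[b] + my) & _M32
    v[d] = _rotr(v[d] ^ v[a], 8)
    v[c] = (v[c] + v[d]) & _M32
    v[b] = _rotr(v[b] ^ v[c], 7)


def _compress(cv: Tuple[int, ...], block: Tuple[int, ...], counter: int,
              block_len: int, flags: int) -> List[int]:
    v = [
        cv[0], cv[1], cv[2], cv[3], cv[4], cv[5], cv[6], cv[7],
        _IV[0], _IV[1], _IV[2], _IV[3],
        counter & _M32, (counter >> 32) & _M32, block_len, flags,
    ]
    m = list(block)
    for _ in range(7):
        _g(v, 0, 4, 8, 12, m[0], m[1])
        _g(v, 1, 5, 9, 13, m[2], m[3])
        _g(v, 2, 6, 10, 14, m[4], m[5])
        _g(v, 3, 7, 11, 15, m[6], m[7])
        _g(v, 0, 5, 10, 15, m[8], m[9])
        _g(v, 1, 6, 11, 12, m[10], m[11])
        _g(v, 2, 7, 8, 13, m[12], m[13])
        _g(v, 3, 4, 9, 14, m[14], m[15])
        m = [m[p] for p in _MSG_PERM]
    for i in range(8):
        v[i] ^= v[i + 8]
        v[i + 8] ^= cv[i]
    return v


def _words(block: bytes) -> Tuple[int, ...]:
    block = block.ljust(_BLOCK_LEN, b"\x00")
    return tuple(int.from_bytes(block[i:i + 4], "little") for i in range(0, 64, 4))


class _Output:
    """Deferred final compression so the ROOT flag can be applied lazily."""

    __slots__ = ("cv", "block", "counter", "block_len", "flags")

    def __init__(self, cv, block, counter, block_len, flags):
        self.cv = cv
        self.block = block
        self.counter = counter
        self.block_len = block_len
        self.flags = flags

    def chaining_value(self) -> Tuple[int, ...]:
        return tuple(_compress(self.cv, self.block, self.counter,
                               self.block_len, self.flags)[:8])

    def root_bytes(self) -> bytes:
        v = _compress(self.cv, self.block, self.counter,
                      self.block_len, self.flags | _ROOT)
        return b"".join(w.to_bytes(4, "little") for w in v[:8])


def _chunk_output(chunk: bytes, chunk_index: int) -> _Output:
    cv = _IV
    blocks = [chunk[i:i + _BLOCK_LEN] for i in range(0, len(chunk), _BLOCK_LEN)] or [b""]
    for i, blk in enumerate(blocks[:-1]):
        flags = _CHUNK_START if i == 0 else 0
        cv = tuple(_compress(cv, _words(blk), chunk_index, _BLOCK_LEN, flags)[:8])
    last = blocks[-1]
    flags = _CHUNK_END
    if len(blocks) == 1:
        flags |= _CHUNK_START
    return _Output(cv, _words(last), chunk_index, len(last), flags)


def _parent_output(left_cv: Tuple[int, ...], right_cv: Tuple[int, ...]) -> _Output:
    return _Output(_IV, left_cv + right_cv, 0, _BLOCK_LEN, _PARENT)


def _subtree_output(data: bytes, chunk_start: int) -> _Output:
    if len(data) <= _CHUNK_LEN:
        return _chunk_output(data, chunk_start)
    # left subtree gets the largest power-of-two number of chunks < total
    full_chunks = (len(data) - 1) // _CHUNK_LEN
    left_chunks = 1
    while left_chunks * 2 <= full_chunks:
        left_chunks *= 2
    split = left_chunks * _CHUNK_LEN
    left = _subtree_output(data[:split], chunk_start)
    right = _subtree_output(data[split:], chunk_start + left_chunks)
    return _parent_output(left.chaining_value(), right.chaining_value())


def blake3_digest(data: bytes) -> bytes:
    """32-byte BLAKE3 hash of ``data``."""
    return _subtree_output(data, 0).root_bytes()


def blake3_hexdigest(data: bytes) -> str:
    """BLAKE3 hash of ``data`` as 64 lowercase hex characters."""
    return blake3_digest(data).hex()
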