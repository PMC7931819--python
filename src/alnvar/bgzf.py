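"""BGZF block compression, virtual offsets, and a linear coordinate index.

BGZF is the blockwise gzip dialect used throughout high-throughput
sequencing: a file is a series of independent gzip members, each carrying
its own compressed size in a ``BC`` extra subfield, terminated by a fixed
28-byte empty block (the EOF sentinel).  Because every block is an
independent gzip member, a record inside the file can be addressed by a
*virtual offset* — the byte offset of its block plus the offset within the
block's uncompressed payload — and a coarse per-window index over those
virtual offsets gives random access to position-sorted record streams.
"""

from __future__ import annotations

import io
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Iterator

MAX_BLOCK_SIZE = 65536
WINDOW_SHIFT = 14  # 16 kb linear-index windows
WINDOW_SIZE = 1 << WINDOW_SHIFT
INDEX_MAGIC = b"SVLI1"

#: The canonical 28-byte empty BGZF block written at end of file.
EOF_SENTINEL = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)


class BgzfError(ValueError):
    """Malformed BGZF stream."""


class BgzfTruncationWarning(UserWarning):
    """Stream ended without the EOF sentinel block."""


def _block(payload: bytes, level: int) -> bytes:
    co = zlib.compressobj(level, zlib.DEFLATED, -15)
    cdata = co.compress(payload) + co.flush()
    bsize = len(cdata) + 25  # header 18 + crc 4 + isize 4 - 1
    if bsize >= MAX_BLOCK_SIZE:
        # incompressible payload: store with level 0 in halves
        half = len(payload) // 2
        if half == 0:
            raise BgzfError("single byte produced an oversized block")
        return _block(payload[:half], level) + _block(payload[half:], level)
    header = struct.pack(
        "<4BIBBH2sHH", 0x1F, 0x8B, 8, 4, 0, 0, 0xFF, 6, b"BC", 2, bsize
    )
    # header layout: magic, CM=deflate, FLG=FEXTRA, MTIME=0, XFL, OS=unknown,
    # XLEN=6, subfield id "BC", subfield length 2, BSIZE-1
    return (
        header
        + cdata
        + struct.pack("<II", zlib.crc32(payload) & 0xFFFFFFFF, len(payload))
    )


def compress(payload: bytes, block_size: int = MAX_BLOCK_SIZE, level: int = 6) -> bytes:
    """Compress ``payload`` into a BGZF stream (sentinel included).

    ``block_size`` caps each block's uncompressed payload; the default is
    the format's 64 KiB maximum.  An empty payload yields exactly the EOF
    sentinel block.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not 0 <= level <= 9:
        raise ValueError("compression level must be in 0..9")
    block_size = min(block_size, MAX_BLOCK_SIZE)
    out = bytearray()
    for i in range(0, len(payload), block_size):
        out += _block(payload[i : i + block_size], level)
    out += EOF_SENTINEL
    return bytes(out)


def _read_block(data: bytes, off: int) -> tuple[bytes, int]:
    """Decode one gzip member at byte ``off``; return (payload, next offset)."""
    if data[off : off + 2] != b"\x1f\x8b":
        raise BgzfError(f"not a gzip member at byte offset {off}")
    if len(data) < off + 12:
        raise BgzfError(f"truncated gzip header at byte offset {off}")
    flg = data[off + 3]
    if not flg & 4:
        raise BgzfError(f"gzip member at offset {off} lacks the BGZF extra field")
    xlen = struct.unpack_from("<H", data, off + 10)[0]
    extra = data[off + 12 : off + 12 + xlen]
    bsize = None
    p = 0
    while p + 4 <= len(extra):
        si, slen = extra[p : p + 2], struct.unpack_from("<H", extra, p + 2)[0]
        if si == b"BC" and slen == 2:
            bsize = struct.unpack_from("<H", extra, p + 4)[0] + 1
        p += 4 + slen
    if bsize is None:
        raise BgzfError(f"gzip member at offset {off} has no BC subfield")
    cstart = off + 12 + xlen
    cend = off + bsize - 8
    if cend + 8 > len(data):
        raise BgzfError(f"block at offset {off} extends past end of stream")
    try:
        payload = zlib.decompress(data[cstart:cend], -15)
    except zlib.error as exc:
        raise BgzfError(f"corrupt deflate data in block at offset {off}: {exc}") from exc
    crc, isize = struct.unpack_from("<II", data, cend)
    if isize != len(payload) or (zlib.crc32(payload) & 0xFFFFFFFF) != crc:
        raise BgzfError(f"checksum mismatch in block at offset {off}")
    return payload, off + bsize


def decompress(data: bytes) -> bytes:
    """Concatenated payload of all blocks; warns if the EOF sentinel is absent."""
    out = bytearray()
    off = 0
    saw_sentinel = False
    while off < len(data):
        start = off
        payload, off = _read_block(data, off)
        saw_sentinel = not payload and data[start:off] == EOF_SENTINEL
        out += payload
    if not saw_sentinel:
        warnings.warn(
            "BGZF stream ended without the EOF sentinel block; file may be truncated",
            BgzfTruncationWarning,
            stacklevel=2,
        )
    return bytes(out)


# ---------------------------------------------------------------------------
# virtual offsets

def pack_virtual_offset(coffset: int, uoffset: int) -> int:
    """Pack (compressed block offset, within-block offset) into one integer."""
    if not 0 <= uoffset < MAX_BLOCK_SIZE:
        raise ValueError(f"uoffset {uoffset} out of range [0, 65536)")
    if coffset < 0:
        raise ValueError("coffset must be non-negative")
    return (coffset << 16) | uoffset


def unpack_virtual_offset(voffset: int) -> tuple[int, int]:
    return voffset >> 16, voffset & 0xFFFF


# ---------------------------------------------------------------------------
# readers / writers with virtual-offset support

class BgzfWriter:
    """Streaming BGZF writer that reports the virtual offset of each write."""

    def __init__(self, fh: BinaryIO, block_size: int = MAX_BLOCK_SIZE, level: int = 6):
        self._fh = fh
        self._block_size = min(block_size, MAX_BLOCK_SIZE)
        self._level = level
        self._buf = bytearray()
        self._coffset = 0
        self._closed = False

    def tell(self) -> int:
        """Virtual offset at which the next byte will be written."""
        return pack_virtual_offset(self._coffset, len(self._buf))

    def write(self, data: bytes) -> int:
        self._buf += data
        while len(self._buf) >= self._block_size:
            self._flush_block(self._block_size)
        return len(data)

    def _flush_block(self, n: int) -> None:
        chunk = bytes(self._buf[:n])
        del self._buf[:n]
        raw = _block(chunk, self._level)
        self._fh.write(raw)
        self._coffset += len(raw)

    def close(self) -> None:
        if self._closed:
            return
        if self._buf:
            self._flush_block(len(self._buf))
        self._fh.write(EOF_SENTINEL)
        self._closed = True

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class BgzfReader:
    """Random-access reader over an in-memory BGZF stream.

    Supports ``seek`` to a virtual offset and line-oriented reads whose
    ``tell`` values are valid virtual offsets for indexing.
    """

    def __init__(self, data: bytes):
        self._data = data
        self._blocks: dict[int, bytes] = {}
        self._coffset = 0
        self._uoffset = 0
        self._payload = self._load(0)

    def _load(self, coffset: int) -> bytes:
        if coffset not in self._blocks:
            if coffset >= len(self._data):
                self._blocks[coffset] = b""
            else:
                payload, _ = _read_block(self._data, coffset)
                self._blocks[coffset] = payload
        return self._blocks[coffset]

    def tell(self) -> int:
        return pack_virtual_offset(self._coffset, self._uoffset)

    def seek(self, voffset: int) -> None:
        self._coffset, self._uoffset = unpack_virtual_offset(voffset)
        self._payload = self._load(self._coffset)

    def readline(self) -> bytes:
        out = bytearray()
        while True:
            if self._uoffset >= len(self._payload):
                if self._coffset >= len(self._data):
                    break
                _, nxt = _read_block(self._data, self._coffset)
                if nxt >= len(self._data):
                    break
                self._coffset, self._uoffset = nxt, 0
                self._payload = self._load(nxt)
                if not self._payload:  # sentinel or empty block
                    continue
            idx = self._payload.find(b"\n", self._uoffset)
            if idx == -1:
                out += self._payload[self._uoffset :]
                self._uoffset = len(self._payload)
                continue
            out += self._payload[self._uoffset : idx + 1]
            self._uoffset = idx + 1
            break
        return bytes(out)

    def __iter__(self) -> Iterator[bytes]:
        while True:
            line = self.readline()
            if not line:
                return
            yield line


# ---------------------------------------------------------------------------
# linear index

@dataclass
class LinearIndex:
    """Per-reference arrays mapping 16 kb windows to minimal virtual offsets.

    ``windows[rid][w]`` is the virtual offset of the first record (in file
    order) whose interval overlaps window ``w`` or any later window, so a
    region query may start scanning there and miss nothing.
    """

    windows: list[list[int]] = field(default_factory=list)

    def serialize(self) -> bytes:
        out = bytearray(INDEX_MAGIC)
        out += struct.pack("<I", len(self.windows))
        for arr in self.windows:
            out += struct.pack("<I", len(arr))
            for v in arr:
                out += struct.pack("<Q", v)
        return bytes(out)

    @classmethod
    def deserialize(cls, data: bytes) -> "LinearIndex":
        if data[:5] != INDEX_MAGIC:
            raise ValueError("not a linear index file (bad magic)")
        off = 5
        (nref,) = struct.unpack_from("<I", data, off)
        off += 4
        windows = []
        for _ in range(nref):
            (n,) = struct.unpack_from("<I", data, off)
            off += 4
            arr = list(struct.unpack_from(f"<{n}Q", data, off))
            off += 8 * n
            windows.append(arr)
        return cls(windows)

    def min_offset(self, rid: int, start: int) -> int | None:
        """Smallest virtual offset that can contain a record overlapping
        ``start`` or beyond, or None when no record can."""
        if rid >= len(self.windows):
            return None
        arr = self.windows[rid]
        w = start >> WINDOW_SHIFT
        if w >= len(arr):
            return None
        return arr[w]


class SortOrderError(ValueError):
    """Input records violate the required (ref id, start) sort order."""


def build_linear_index(
    records: Iterable[tuple[int, int, int, int]], n_refs: int | None = None
) -> LinearIndex:
    """Single-pass index construction from (rid, start, end, voffset) tuples.

    Records must arrive sorted by (rid, start) with voffsets in file order.
    """
    windows: list[list[int]] = [] if n_refs is None else [[] for _ in range(n_refs)]
    last = (-1, -1)
    for i, (rid, start, end, voff) in enumerate(records):
        if (rid, start) < last:
            raise SortOrderError(
                f"record {i} (rid={rid}, start={start}) breaks sort order after "
                f"rid={last[0]}, start={last[1]}"
            )
        last = (rid, start)
        while rid >= len(windows):
            windows.append([])
        arr = windows[rid]
        wend = max(end - 1, start) >> WINDOW_SHIFT
        while len(arr) <= wend:
            arr.append(voff)
    return LinearIndex(windows)
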