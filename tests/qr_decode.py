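"""Independent structural QR decoder used as a test oracle.

Written directly from the published symbology layout, separately from the
encoder in ``cellvr.qr``: it locates the symbol in a rendered PNG, reads
and BCH-validates the format information, rebuilds the function-pattern
map, unmasks the data region, de-interleaves the error-correction blocks,
verifies that every Reed-Solomon syndrome vanishes, and parses the
byte-mode bit stream.  Any structural inconsistency raises
:class:`QRDecodeError`.
"""

from __future__ import annotations

import io

import numpy as np


class QRDecodeError(Exception):
    pass


# GF(256), primitive polynomial 0x11d
_EXP = [0] * 512
_LOG = [0] * 256
_v = 1
for _i in range(255):
    _EXP[_i] = _v
    _LOG[_v] = _i
    _v = (_v << 1) ^ (0x11d if _v & 0x80 else 0)
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]

_BLOCKS = {
    "L": {1: (7, [(1, 19)]), 2: (10, [(1, 34)]), 3: (15, [(1, 55)]),
          4: (20, [(1, 80)]), 5: (26, [(1, 108)]), 6: (18, [(2, 68)]),
          7: (20, [(2, 78)]), 8: (24, [(2, 97)]), 9: (30, [(2, 116)]),
          10: (18, [(2, 68), (2, 69)])},
    "M": {1: (10, [(1, 16)]), 2: (16, [(1, 28)]), 3: (26, [(1, 44)]),
          4: (18, [(2, 32)]), 5: (24, [(2, 43)]), 6: (16, [(4, 27)]),
          7: (18, [(4, 31)]), 8: (22, [(2, 38), (2, 39)]),
          9: (22, [(3, 36), (2, 37)]), 10: (26, [(4, 43), (1, 44)])},
}
_ALIGN = {1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30],
          6: [6, 34], 7: [6, 22, 38], 8: [6, 24, 42], 9: [6, 26, 46],
          10: [6, 28, 52]}
_LEVEL_OF_BITS = {0b01: "L", 0b00: "M", 0b11: "Q", 0b10: "H"}

_MASKS = [
    lambda i, j: (i + j) % 2 == 0,
    lambda i, j: i % 2 == 0,
    lambda i, j: j % 3 == 0,
    lambda i, j: (i + j) % 3 == 0,
    lambda i, j: (i // 2 + j // 3) % 2 == 0,
    lambda i, j: (i * j) % 2 + (i * j) % 3 == 0,
    lambda i, j: ((i * j) % 2 + (i * j) % 3) % 2 == 0,
    lambda i, j: ((i + j) % 2 + (i * j) % 3) % 2 == 0,
]


def png_to_matrix(png_bytes: bytes) -> np.ndarray:
    """Recover the boolean module matrix from a rendered PNG."""
    from PIL import Image

    img = Image.open(io.BytesIO(png_bytes)).convert("L")
    pixels = np.asarray(img) < 128
    rows = np.flatnonzero(pixels.any(axis=1))
    cols = np.flatnonzero(pixels.any(axis=0))
    if rows.size == 0:
        raise QRDecodeError("blank image")
    sub = pixels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    extent = sub.shape[0]
    if sub.shape[1] != extent:
        raise QRDecodeError("symbol is not square")
    for version in range(1, 11):
        n = 17 + 4 * version
        if extent % n:
            continue
        scale = extent // n
        centers = scale // 2 + scale * np.arange(n)
        mat = sub[np.ix_(centers, centers)]
        # timing pattern must alternate, starting dark
        timing = mat[6, 8:n - 8]
        if (timing == (np.arange(8, n - 8) % 2 == 0)).all():
            return mat
    raise QRDecodeError("no consistent module grid found")


def _bch15_ok(word: int) -> bool:
    rem = word
    for shift in range(14, 9, -1):
        if rem & (1 << shift):
            rem ^= 0b10100110111 << (shift - 10)
    return rem == 0


def _read_format(mat: np.ndarray) -> tuple[str, int]:
    n = mat.shape[0]
    coords_a = ([(k, 8) for k in range(6)] + [(7, 8), (8, 8), (8, 7)]
                + [(8, 5 - k) for k in range(6)])
    coords_b = ([(8, n - 1 - k) for k in range(8)]
                + [(n - 7 + k, 8) for k in range(7)])
    words = []
    for coords in (coords_a, coords_b):
        word = 0
        for k, (r, c) in enumerate(coords):
            word |= int(mat[r, c]) << k
        words.append(word ^ 0b101010000010010)
    if words[0] != words[1]:
        raise QRDecodeError("format info copies disagree")
    if not _bch15_ok(words[0]):
        raise QRDecodeError("format info fails BCH check")
    data = words[0] >> 10
    level_bits = (data >> 3) & 0b11
    mask = data & 0b111
    return _LEVEL_OF_BITS[level_bits], mask


def _function_map(version: int) -> np.ndarray:
    n = 17 + 4 * version
    func = np.zeros((n, n), dtype=bool)
    for r0, c0 in ((0, 0), (0, n - 8), (n - 8, 0)):
        func[max(0, r0):r0 + 8, max(0, c0):c0 + 8] = True
    func[6, :] = True
    func[:, 6] = True
    for rc in _ALIGN[version]:
        for cc in _ALIGN[version]:
            overlaps_finder = ((rc < 9 and cc < 9)
                               or (rc < 9 and cc > n - 10)
                               or (rc > n - 10 and cc < 9))
            if not overlaps_finder:
                func[rc - 2:rc + 3, cc - 2:cc + 3] = True
    for k in range(9):
        func[8, k] = func[k, 8] = True
    for k in range(8):
        func[8, n - 1 - k] = func[n - 1 - k, 8] = True
    func[n - 8, 8] = True
    if version >= 7:
        func[0:6, n - 11:n - 8] = True
        func[n - 11:n - 8, 0:6] = True
    return func


def _read_codewords(mat: np.ndarray, mask: int) -> list[int]:
    n = mat.shape[0]
    version = (n - 17) // 4
    func = _function_map(version)
    mask_fn = _MASKS[mask]
    bits: list[int] = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for row in rows:
            for c in (col, col - 1):
                if not func[row, c]:
                    bits.append(int(mat[row, c]) ^ int(mask_fn(row, c)))
        upward = not upward
        col -= 2
    return [int("".join(map(str, bits[i:i + 8])), 2)
            for i in range(0, len(bits) - len(bits) % 8, 8)]


def _deinterleave(codewords: list[int], version: int,
                  level: str) -> list[int]:
    ec, groups = _BLOCKS[level][version]
    sizes = [dc for cnt, dc in groups for _ in range(cnt)]
    n_blocks = len(sizes)
    dblocks: list[list[int]] = [[] for _ in range(n_blocks)]
    pos = 0
    for i in range(max(sizes)):
        for b in range(n_blocks):
            if i < sizes[b]:
                dblocks[b].append(codewords[pos])
                pos += 1
    eblocks: list[list[int]] = [[] for _ in range(n_blocks)]
    for _ in range(ec):
        for b in range(n_blocks):
            eblocks[b].append(codewords[pos])
            pos += 1
    data: list[int] = []
    for blk, eblk in zip(dblocks, eblocks):
        full = blk + eblk
        for j in range(ec):  # syndromes of the received polynomial
            s = 0
            for cw in full:
                s = _EXP[(_LOG[s] + j) % 255] if s else 0
                s ^= cw
            if s:
                raise QRDecodeError(
                    f"nonzero Reed-Solomon syndrome {j}")
        data.extend(blk)
    return data


def _parse_byte_mode(data: list[int], version: int) -> bytes:
    bits = [(cw >> k) & 1 for cw in data for k in range(7, -1, -1)]

    def take(n: int) -> int:
        nonlocal bits
        value = int("".join(map(str, bits[:n])), 2)
        bits = bits[n:]
        return value

    mode = take(4)
    if mode != 0b0100:
        raise QRDecodeError(f"unsupported mode indicator {mode:04b}")
    count = take(16 if version >= 10 else 8)
    if count * 8 > len(bits):
        raise QRDecodeError("declared length exceeds available bits")
    return bytes(take(8) for _ in range(count))


def decode_qr_png(png_bytes: bytes) -> str:
    """Decode a byte-mode QR PNG back to its payload string."""
    mat = png_to_matrix(png_bytes)
    version = (mat.shape[0] - 17) // 4
    level, mask = _read_format(mat)
    codewords = _read_codewords(mat, mask)
    data = _deinterleave(codewords, version, level)
    return _parse_byte_mode(data, version).decode("utf-8")
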