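"""Byte-mode QR symbol generation (model 2, versions 1-10, EC level M).

Implemented in-package because handoff URLs must be turned into scannable
codes and no QR library is part of the runtime stack.  Covers everything a
standard scanner needs: Reed-Solomon error correction over GF(256)
(polynomial 0x11d), block interleaving, finder/alignment/timing function
patterns, BCH-protected format and version information, and data masking
with standard penalty-based mask selection.  Versions 1-10 carry up to 213
bytes at level M — ample for a handoff URL with a viewpoint query string.

The public surface is :func:`qr_matrix` (boolean module matrix, True =
dark) and :func:`qr_png` (rendered PNG bytes with a quiet zone).
"""

from __future__ import annotations

import io

import numpy as np

# ---------------------------------------------------------------------------
# GF(256) arithmetic, primitive polynomial x^8+x^4+x^3+x^2+1 (0x11d)

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11d
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def rs_generator(n_ec: int) -> list[int]:
    """Coefficients (highest degree first) of prod_{i<n_ec} (x - alpha^i)."""
    gen = [1]
    for i in range(n_ec):
        nxt = [0] * (len(gen) + 1)
        for j, c in enumerate(gen):
            nxt[j] ^= c  # times x
            nxt[j + 1] ^= _gf_mul(c, _EXP[i])
        gen = nxt
    return gen


def rs_ec_codewords(data: list[int], n_ec: int) -> list[int]:
    """Reed-Solomon check codewords for one block (polynomial remainder)."""
    gen = rs_generator(n_ec)
    rem = list(data) + [0] * n_ec
    for i in range(len(data)):
        factor = rem[i]
        if factor:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], factor)
    return rem[len(data):]


# ---------------------------------------------------------------------------
# capacity tables, versions 1-10

#: per version: error-correction codewords per block and
#: [(block count, data codewords per block), ...]
BLOCK_TABLE: dict[str, dict[int, tuple[int, list[tuple[int, int]]]]] = {
    "L": {1: (7, [(1, 19)]), 2: (10, [(1, 34)]), 3: (15, [(1, 55)]),
          4: (20, [(1, 80)]), 5: (26, [(1, 108)]), 6: (18, [(2, 68)]),
          7: (20, [(2, 78)]), 8: (24, [(2, 97)]), 9: (30, [(2, 116)]),
          10: (18, [(2, 68), (2, 69)])},
    "M": {1: (10, [(1, 16)]), 2: (16, [(1, 28)]), 3: (26, [(1, 44)]),
          4: (18, [(2, 32)]), 5: (24, [(2, 43)]), 6: (16, [(4, 27)]),
          7: (18, [(4, 31)]), 8: (22, [(2, 38), (2, 39)]),
          9: (22, [(3, 36), (2, 37)]), 10: (26, [(4, 43), (1, 44)])},
}

#: alignment pattern center coordinates per version
ALIGN_CENTERS = {1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30],
                 6: [6, 34], 7: [6, 22, 38], 8: [6, 24, 42],
                 9: [6, 26, 46], 10: [6, 28, 52]}

_EC_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}


def _data_capacity_bytes(version: int, level: str) -> int:
    ec, blocks = BLOCK_TABLE[level][version]
    data_cw = sum(cnt * dc for cnt, dc in blocks)
    count_bits = 16 if version >= 10 else 8
    return (data_cw * 8 - 4 - count_bits) // 8


def choose_version(payload_len: int, level: str = "M") -> int:
    for v in sorted(BLOCK_TABLE[level]):
        if _data_capacity_bytes(v, level) >= payload_len:
            return v
    raise ValueError(f"payload of {payload_len} bytes exceeds the "
                     f"{max(BLOCK_TABLE[level])}-version capacity at "
                     f"level {level}")


# ---------------------------------------------------------------------------
# bit stream -> final codeword sequence

def _build_codewords(payload: bytes, version: int, level: str) -> list[int]:
    count_bits = 16 if version >= 10 else 8
    bits: list[int] = []

    def put(value: int, n: int) -> None:
        for k in range(n - 1, -1, -1):
            bits.append((value >> k) & 1)

    put(0b0100, 4)  # byte mode
    put(len(payload), count_bits)
    for b in payload:
        put(b, 8)
    ec, blocks = BLOCK_TABLE[level][version]
    data_cw = sum(cnt * dc for cnt, dc in blocks)
    bits.extend([0] * min(4, data_cw * 8 - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    data = [int("".join(map(str, bits[i:i + 8])), 2)
            for i in range(0, len(bits), 8)]
    pad = (0xEC, 0x11)
    for i in range(data_cw - len(data)):
        data.append(pad[i % 2])

    # split into blocks, compute EC per block, interleave
    dblocks: list[list[int]] = []
    pos = 0
    for cnt, dc in blocks:
        for _ in range(cnt):
            dblocks.append(data[pos:pos + dc])
            pos += dc
    eblocks = [rs_ec_codewords(blk, ec) for blk in dblocks]
    out: list[int] = []
    for i in range(max(len(b) for b in dblocks)):
        for blk in dblocks:
            if i < len(blk):
                out.append(blk[i])
    for i in range(ec):
        for blk in eblocks:
            out.append(blk[i])
    return out


# ---------------------------------------------------------------------------
# matrix construction

def format_bits(level: str, mask: int) -> int:
    """15-bit format information word (BCH(15,5), XOR-masked)."""
    data = (_EC_BITS[level] << 3) | mask
    rem = data << 10
    for shift in range(14, 9, -1):
        if rem & (1 << shift):
            rem ^= 0b10100110111 << (shift - 10)
    return ((data << 10) | rem) ^ 0b101010000010010


def version_bits(version: int) -> int:
    """18-bit version information word (BCH(18,6)), versions >= 7."""
    rem = version << 12
    for shift in range(17, 11, -1):
        if rem & (1 << shift):
            rem ^= 0b1111100100101 << (shift - 12)
    return (version << 12) | rem


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


def _place_function_patterns(version: int):
    n = 17 + 4 * version
    dark = np.zeros((n, n), dtype=bool)
    func = np.zeros((n, n), dtype=bool)

    def finder(r0: int, c0: int) -> None:
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < n and 0 <= c < n):
                    continue
                func[r, c] = True
                inside = 0 <= dr <= 6 and 0 <= dc <= 6
                ring = dr in (0, 6) or dc in (0, 6)
                core = 2 <= dr <= 4 and 2 <= dc <= 4
                dark[r, c] = inside and (ring or core)

    finder(0, 0)
    finder(0, n - 7)
    finder(n - 7, 0)

    for k in range(8, n - 8):  # timing patterns
        func[6, k] = func[k, 6] = True
        dark[6, k] = dark[k, 6] = k % 2 == 0

    centers = ALIGN_CENTERS[version]
    for rc in centers:
        for cc in centers:
            overlaps_finder = ((rc < 9 and cc < 9)
                               or (rc < 9 and cc > n - 10)
                               or (rc > n - 10 and cc < 9))
            if overlaps_finder:
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    func[rc + dr, cc + dc] = True
                    dark[rc + dr, cc + dc] = (
                        max(abs(dr), abs(dc)) != 1)

    # reserve format info areas
    for k in range(9):
        func[8, k] = func[k, 8] = True
    for k in range(8):
        func[8, n - 1 - k] = func[n - 1 - k, 8] = True
    dark[n - 8, 8] = True  # the fixed dark module
    func[n - 8, 8] = True

    if version >= 7:  # reserve version info blocks
        for k in range(18):
            func[k // 3, n - 11 + k % 3] = True
            func[n - 11 + k % 3, k // 3] = True
    return dark, func


def _write_format(dark: np.ndarray, level: str, mask: int) -> None:
    n = dark.shape[0]
    fmt = format_bits(level, mask)

    def bit(k: int) -> bool:
        return bool((fmt >> k) & 1)

    coords_a = ([(k, 8) for k in range(6)] + [(7, 8), (8, 8), (8, 7)]
                + [(8, 5 - k) for k in range(6)])
    for k, (r, c) in enumerate(coords_a):
        dark[r, c] = bit(k)
    coords_b = ([(8, n - 1 - k) for k in range(8)]
                + [(n - 7 + k, 8) for k in range(7)])
    for k, (r, c) in enumerate(coords_b):
        dark[r, c] = bit(k)


def _write_version(dark: np.ndarray, version: int) -> None:
    if version < 7:
        return
    n = dark.shape[0]
    vb = version_bits(version)
    for k in range(18):
        b = bool((vb >> k) & 1)
        dark[k // 3, n - 11 + k % 3] = b
        dark[n - 11 + k % 3, k // 3] = b


def _data_coords(func: np.ndarray) -> list[tuple[int, int]]:
    """Module coordinates in placement order (zigzag from bottom right)."""
    n = func.shape[0]
    coords = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for row in rows:
            for c in (col, col - 1):
                if not func[row, c]:
                    coords.append((row, c))
        upward = not upward
        col -= 2
    return coords


def _penalty(dark: np.ndarray) -> int:
    n = dark.shape[0]
    score = 0
    for grid in (dark, dark.T):  # rule 1: runs of >= 5 same-color modules
        for row in grid:
            run = 1
            for a, b in zip(row, row[1:]):
                if a == b:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + run - 5
                    run = 1
            if run >= 5:
                score += 3 + run - 5
    blocks = (dark[:-1, :-1] == dark[1:, :-1]) \
        & (dark[:-1, :-1] == dark[:-1, 1:]) \
        & (dark[:-1, :-1] == dark[1:, 1:])
    score += 3 * int(blocks.sum())  # rule 2: 2x2 same-color blocks
    pattern = np.array([1, 0, 1, 1, 1, 0, 1], dtype=bool)
    pad = np.zeros(4, dtype=bool)
    for grid in (dark, dark.T):  # rule 3: finder-like 1011101 with 0000
        for row in grid:
            ext = np.concatenate([pad, row, pad])
            for s in range(len(ext) - 10):
                win = ext[s:s + 11]
                if (win[:4].sum() == 0 and (win[4:11] == pattern).all()) \
                        or ((win[0:7] == pattern).all()
                            and win[7:11].sum() == 0):
                    score += 40
    dark_pct = 100.0 * dark.sum() / dark.size  # rule 4: dark proportion
    score += 10 * int(abs(dark_pct - 50) // 5)
    return score


def qr_matrix(payload: bytes | str, level: str = "M",
              version: int | None = None) -> np.ndarray:
    """Boolean module matrix (True = dark) for a byte-mode payload."""
    if isinstance(payload, str):
        payload = payload.encode("utf-8")
    if version is None:
        version = choose_version(len(payload), level)
    elif _data_capacity_bytes(version, level) < len(payload):
        raise ValueError(f"payload does not fit version {version}-{level}")
    codewords = _build_codewords(payload, version, level)

    base_dark, func = _place_function_patterns(version)
    coords = _data_coords(func)
    bits = [(cw >> k) & 1 for cw in codewords for k in range(7, -1, -1)]
    bits += [0] * (len(coords) - len(bits))  # remainder bits

    best = None
    for mask_id, mask_fn in enumerate(_MASKS):
        dark = base_dark.copy()
        for (r, c), b in zip(coords, bits):
            dark[r, c] = bool(b) ^ mask_fn(r, c)
        _write_format(dark, level, mask_id)
        _write_version(dark, version)
        p = _penalty(dark)
        if best is None or p < best[0]:
            best = (p, dark)
    return best[1]


def qr_png(payload: bytes | str, level: str = "M", scale: int = 8,
           border: int = 4) -> bytes:
    """Render the QR symbol for ``payload`` as PNG bytes.

    ``border`` is the quiet zone in modules (the symbology requires 4).
    """
    from PIL import Image

    matrix = qr_matrix(payload, level=level)
    n = matrix.shape[0]
    canvas = np.full((n + 2 * border, n + 2 * border), 255, dtype=np.uint8)
    canvas[border:border + n, border:border + n] = \
        np.where(matrix, 0, 255).astype(np.uint8)
    img = Image.fromarray(np.kron(canvas,
                                  np.ones((scale, scale), dtype=np.uint8)),
                          mode="L")
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
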