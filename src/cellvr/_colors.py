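"""Fixed color resources: categorical palette and continuous colormap.

Both are literal tables so that packaged hex colors are reproducible across
platforms and library versions — no runtime dependency on a plotting stack.
"""

from __future__ import annotations

#: 20 visually distinct hues for categorical tracks (cycled past 20).
DEFAULT_PALETTE: list[str] = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
]

#: Control points (u, (r, g, b)) of the default perceptually-monotone
#: dark-violet -> teal -> yellow ramp; linear RGB interpolation between
#: anchors.  u is the normalized track position in [0, 1].
DEFAULT_COLORMAP_NAME = "ember"
_RAMP: list[tuple[float, tuple[int, int, int]]] = [
    (0.000, (68, 1, 84)),
    (0.125, (72, 40, 120)),
    (0.250, (62, 74, 137)),
    (0.375, (49, 104, 142)),
    (0.500, (38, 130, 142)),
    (0.625, (31, 158, 137)),
    (0.750, (53, 183, 121)),
    (0.875, (109, 205, 89)),
    (1.000, (253, 231, 37)),
]


def colormap_hex(u: float) -> str:
    """Hex color of the default ramp at normalized position ``u`` in [0, 1]."""
    u = min(1.0, max(0.0, float(u)))
    for (u0, c0), (u1, c1) in zip(_RAMP, _RAMP[1:]):
        if u <= u1:
            f = 0.0 if u1 == u0 else (u - u0) / (u1 - u0)
            rgb = tuple(round(a + f * (b - a)) for a, b in zip(c0, c1))
            return "#{:02x}{:02x}{:02x}".format(*rgb)
    return "#{:02x}{:02x}{:02x}".format(*_RAMP[-1][1])
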