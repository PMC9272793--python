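"""Color handling: hex parsing, color-vision-deficiency simulation, weighted RGB distance.

Palette dissimilarity is deliberately plain (weighted) Euclidean distance between
RGB channel triples on [0, 1], optionally computed after simulating how the palette
is perceived under protanomaly, deuteranomaly or tritanomaly. The optimizer only
needs a ranking of assignments, so no perceptually uniform space is involved;
channel weights let users bias the metric toward the channels they care about.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Color",
    "ChannelWeights",
    "CvdMode",
    "CVD_KINDS",
    "parse_hex",
    "cvd_matrix",
    "simulate_cvd",
    "color_distance",
    "distance_matrix",
]

_HEX_RE = re.compile(r"\A#(?:[0-9a-fA-F]{6}|[0-9a-fA-F]{3})\Z")


@dataclass(frozen=True)
class Color:
    """An RGB color with unitless channel intensities on [0, 1].

    ``source_hex`` keeps the original user string (byte-for-byte) so output
    mappings can echo exactly what the user supplied; it does not take part
    in equality.
    """

    r: float
    g: float
    b: float
    source_hex: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"channel {name}={v!r} outside [0, 1]")

    @property
    def rgb(self) -> np.ndarray:
        """Channels as a float array of shape (3,)."""
        return np.array([self.r, self.g, self.b], dtype=float)

    def to_hex(self) -> str:
        """Format as #RRGGBB (nearest 8-bit values, uppercase)."""
        return "#%02X%02X%02X" % tuple(
            int(round(c * 255)) for c in (self.r, self.g, self.b)
        )


def parse_hex(hex_string: str, index: int | None = None) -> Color:
    """Parse ``#RRGGBB`` (or ``#RGB`` shorthand) into a :class:`Color`.

    Channels are byte/255 exactly. ``index`` (if given) names the palette
    position in error messages.
    """
    where = "" if index is None else f" at palette index {index}"
    if not isinstance(hex_string, str):
        raise ValueError(f"palette entry {hex_string!r}{where} is not a string")
    s = hex_string.strip()
    if not _HEX_RE.match(s):
        raise ValueError(
            f"malformed hex color {hex_string!r}{where}: expected #RRGGBB or #RGB"
        )
    digits = s[1:]
    if len(digits) == 3:  # expand shorthand: #ABC -> #AABBCC
        digits = "".join(ch * 2 for ch in digits)
    r, g, b = (int(digits[i : i + 2], 16) / 255.0 for i in (0, 2, 4))
    return Color(r, g, b, source_hex=hex_string)


@dataclass(frozen=True)
class ChannelWeights:
    """Nonnegative per-channel weights for the RGB distance; default (1, 1, 1)."""

    w_r: float = 1.0
    w_g: float = 1.0
    w_b: float = 1.0

    def __post_init__(self) -> None:
        w = (self.w_r, self.w_g, self.w_b)
        if any(x < 0 for x in w):
            raise ValueError(f"channel weights must be nonnegative, got {w}")
        if not any(x > 0 for x in w):
            raise ValueError("at least one channel weight must be positive")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.w_r, self.w_g, self.w_b], dtype=float)


CVD_KINDS = ("none", "protan", "deutan", "tritan")


@dataclass(frozen=True)
class CvdMode:
    """Color-vision-deficiency simulation mode.

    ``severity`` runs from 0 (normal vision, identity transform) to 1
    (dichromacy). ``kind='none'`` disables the transform regardless of severity.
    """

    kind: str = "none"
    severity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in CVD_KINDS:
            raise ValueError(f"cvd kind must be one of {CVD_KINDS}, got {self.kind!r}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"cvd severity must be in [0, 1], got {self.severity}")


# Severity-parameterized CVD simulation matrices from Machado, Oliveira &
# Fernandes (2009), "A physiologically-based model for simulation of color
# vision deficiency", IEEE TVCG 15(6). Tabulated at severity steps of 0.1;
# intermediate severities are linearly interpolated between adjacent entries.
# The matrices act on *linear-light* RGB. Severity 0.0 is the identity.
_MACHADO: dict[str, np.ndarray] = {
    "protan": np.array(
        [
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            [[0.856167, 0.182038, -0.038205],
             [0.029342, 0.955115, 0.015544],
             [-0.002880, -0.001563, 1.004443]],
            [[0.734766, 0.334872, -0.069637],
             [0.051840, 0.919198, 0.028963],
             [-0.004928, -0.004209, 1.009137]],
            [[0.630323, 0.465641, -0.095964],
             [0.069181, 0.890046, 0.040773],
             [-0.006308, -0.007724, 1.014032]],
            [[0.539009, 0.579343, -0.118352],
             [0.082546, 0.866121, 0.051332],
             [-0.007136, -0.011959, 1.019095]],
            [[0.458064, 0.679578, -0.137642],
             [0.092785, 0.846313, 0.060902],
             [-0.007494, -0.016807, 1.024301]],
            [[0.385450, 0.769005, -0.154455],
             [0.100526, 0.829802, 0.069673],
             [-0.007442, -0.022190, 1.029632]],
            [[0.319627, 0.849633, -0.169261],
             [0.106241, 0.815969, 0.077790],
             [-0.007025, -0.028051, 1.035076]],
            [[0.259411, 0.923008, -0.182420],
             [0.110296, 0.804340, 0.085364],
             [-0.006276, -0.034346, 1.040622]],
            [[0.203876, 0.990338, -0.194214],
             [0.112975, 0.794542, 0.092514],
             [-0.005222, -0.041043, 1.046265]],
            [[0.152286, 1.052583, -0.204868],
             [0.114503, 0.786281, 0.099216],
             [-0.003882, -0.048116, 1.051998]],
        ]
    ),
    "deutan": np.array(
        [
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            [[0.866435, 0.177704, -0.044139],
             [0.049567, 0.939063, 0.011370],
             [-0.003453, 0.007233, 0.996220]],
            [[0.760729, 0.319078, -0.079807],
             [0.090568, 0.889315, 0.020117],
             [-0.006027, 0.013325, 0.992702]],
            [[0.675425, 0.433850, -0.109275],
             [0.125303, 0.847755, 0.026942],
             [-0.007950, 0.018572, 0.989378]],
            [[0.605511, 0.528560, -0.134071],
             [0.155318, 0.812366, 0.032316],
             [-0.009376, 0.023176, 0.986200]],
            [[0.547494, 0.607765, -0.155259],
             [0.181692, 0.781742, 0.036566],
             [-0.010410, 0.027275, 0.983136]],
            [[0.498864, 0.674741, -0.173604],
             [0.205199, 0.754872, 0.039929],
             [-0.011131, 0.030969, 0.980162]],
            [[0.457771, 0.731899, -0.189670],
             [0.226409, 0.731012, 0.042579],
             [-0.011595, 0.034333, 0.977261]],
            [[0.422823, 0.781057, -0.203881],
             [0.245752, 0.709602, 0.044646],
             [-0.011843, 0.037423, 0.974421]],
            [[0.392952, 0.823610, -0.216562],
             [0.263559, 0.690210, 0.046232],
             [-0.011910, 0.040281, 0.971630]],
            [[0.367322, 0.860646, -0.227968],
             [0.280085, 0.672501, 0.047413],
             [-0.011820, 0.042940, 0.968881]],
        ]
    ),
    "tritan": np.array(
        [
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            [[0.926670, 0.092514, -0.019184],
             [0.021191, 0.964503, 0.014306],
             [0.008437, 0.054813, 0.936750]],
            [[0.895720, 0.133330, -0.029050],
             [0.029997, 0.945400, 0.024603],
             [0.013027, 0.104707, 0.882266]],
            [[0.905871, 0.127791, -0.033662],
             [0.026856, 0.941251, 0.031893],
             [0.013410, 0.148296, 0.838294]],
            [[0.948035, 0.089490, -0.037526],
             [0.014364, 0.946792, 0.038844],
             [0.010853, 0.193991, 0.795156]],
            [[1.017277, 0.027029, -0.044306],
             [-0.006113, 0.958479, 0.047634],
             [0.006379, 0.248708, 0.744913]],
            [[1.104996, -0.046633, -0.058363],
             [-0.032137, 0.971635, 0.060503],
             [0.001336, 0.317922, 0.680742]],
            [[1.193214, -0.109812, -0.083402],
             [-0.058496, 0.979410, 0.079086],
             [-0.002346, 0.403492, 0.598854]],
            [[1.257728, -0.139648, -0.118081],
             [-0.078003, 0.975409, 0.102594],
             [-0.003316, 0.501214, 0.502102]],
            [[1.278864, -0.125333, -0.153531],
             [-0.084748, 0.957674, 0.127074],
             [-0.000989, 0.601151, 0.399838]],
            [[1.255528, -0.076749, -0.178779],
             [-0.078411, 0.930809, 0.147602],
             [0.004733, 0.691367, 0.303900]],
        ]
    ),
}


def cvd_matrix(kind: str, severity: float) -> np.ndarray:
    """Return the 3×3 linear-RGB simulation matrix for ``kind`` at ``severity``.

    Severities between tabulated 0.1 steps are linearly interpolated.
    """
    if kind == "none" or severity == 0.0:
        return np.eye(3)
    table = _MACHADO[kind]
    pos = severity * 10.0
    lo = int(math.floor(pos))
    hi = min(lo + 1, 10)
    frac = pos - lo
    return (1.0 - frac) * table[lo] + frac * table[hi]


def _srgb_decode(c: np.ndarray) -> np.ndarray:
    """sRGB gamma-encoded [0,1] -> linear light."""
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_encode(c: np.ndarray) -> np.ndarray:
    """Linear light -> sRGB gamma-encoded [0,1]."""
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def simulate_cvd(c: Color, mode: CvdMode) -> Color:
    """Simulate how ``c`` is perceived under the given deficiency.

    The matrix acts in linear-light RGB (sRGB decode -> matrix -> encode),
    and the result is clipped to [0, 1]. ``kind='none'`` or severity 0
    returns the input unchanged.
    """
    if mode.kind == "none" or mode.severity == 0.0:
        return c
    lin = _srgb_decode(c.rgb)
    sim = cvd_matrix(mode.kind, mode.severity) @ lin
    out = np.clip(_srgb_encode(np.clip(sim, 0.0, 1.0)), 0.0, 1.0)
    return Color(float(out[0]), float(out[1]), float(out[2]), source_hex=c.source_hex)


def color_distance(
    e: Color, f: Color, w: ChannelWeights | None = None
) -> float:
    """Weighted Euclidean distance between two colors' RGB triples.

    ``sqrt(w_r (e_r-f_r)^2 + w_g (e_g-f_g)^2 + w_b (e_b-f_b)^2)``. Colors are
    expected to be already CVD-transformed when a simulation mode is active.
    """
    wv = (w or ChannelWeights()).as_array
    d = e.rgb - f.rgb
    return float(np.sqrt(np.sum(wv * d * d)))


def distance_matrix(
    palette: Sequence[Color],
    w: ChannelWeights | None = None,
    mode: CvdMode | None = None,
) -> np.ndarray:
    """Pairwise dissimilarity matrix D for a palette.

    Applies the CVD transform (if a mode is active), then the weighted RGB
    distance to every pair. Symmetric, zero diagonal, entries >= 0. Duplicate
    palette colors are permitted but warned about: they force a zero
    off-diagonal entry that the optimizer can never spend on overlapping
    clusters.
    """
    if len(palette) == 0:
        raise ValueError("palette must contain at least one color")
    w = w or ChannelWeights()
    mode = mode or CvdMode()
    seen: dict[tuple[float, float, float], int] = {}
    for i, c in enumerate(palette):
        key = (c.r, c.g, c.b)
        if key in seen:
            warnings.warn(
                f"duplicate palette color {c.source_hex or key} at indices "
                f"{seen[key]} and {i}: their pairwise distance is 0",
                stacklevel=2,
            )
        else:
            seen[key] = i
    transformed = [simulate_cvd(c, mode) for c in palette]
    pts = np.array([c.rgb for c in transformed])  # (M, 3)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt(np.sum(w.as_array * diff * diff, axis=-1))
    np.fill_diagonal(d, 0.0)
    return d
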