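"""Published fire-salamander hip and knee RoM extrema (worked examples).

Each entry gives, per axis, the full ZYX Euler triple (FE, ABAD, LAR,
whole degrees) at the maximal and minimal pose about that axis, plus the
published whole-degree range, for ex vivo ligamentous trials (specimens
Sal06-Sal14) and one in vivo walking stride (Sal22).  Ranges were
computed on unrounded extrema before rounding, so a published range can
differ from (rounded max - rounded min) by one degree;
``range_is_exact`` marks the cells where the whole-degree arithmetic is
self-consistent.  These tables are the package's reference inputs for
re-deriving range arithmetic without the underlying capture data.
"""

from __future__ import annotations

from .sfp import EULER_COLUMN, RoMSummary, summary_from_extrema

# axis -> (triple_at_max, triple_at_min, published_range)
HIP_ROM = {
    "Sal10 ex vivo": {
        "FE": ((29, 6, -73), (-85, 24, -97), 114),
        "ABAD": ((-26, 57, -52), (-4, -70, -36), 128),
        "LAR": ((-42, -55, -13), (-60, 36, -147), 134),
    },
    "Sal12 ex vivo": {
        "FE": ((-3, -57, -42), (-95, 0, -62), 92),
        "ABAD": ((-56, 49, -115), (-26, -58, -30), 108),
        "LAR": ((-42, -46, -12), (-58, 11, -121), 110),
    },
    "Sal13 ex vivo": {
        "FE": ((43, -4, -80), (-88, 22, -111), 131),
        "ABAD": ((-15, 71, -49), (-48, -39, -70), 110),
        "LAR": ((3, 52, -12), (-9, 33, -143), 131),
    },
    "Sal14 ex vivo": {
        "FE": ((43, 35, -45), (-72, 6, -67), 115),
        "ABAD": ((2, 63, -98), (8, -43, -72), 106),
        "LAR": ((-13, 46, -20), (5, 5, -140), 120),
    },
    "Sal22 in vivo": {
        "FE": ((64, 22, -73), (-53, 10, -56), 117),
        "ABAD": ((55, 31, -64), (-11, -9, -39), 40),
        "LAR": ((-10, 3, -36), (31, -7, -133), 96),
    },
}

KNEE_ROM = {
    "Sal06 ex vivo": {
        "FE": ((133, 24, 5), (5, -3, 7), 128),
        "ABAD": ((133, 26, 5), (18, -27, 0), 53),
        "LAR": ((85, -6, 30), (8, -7, -35), 65),
    },
    "Sal08 ex vivo": {
        "FE": ((115, -34, 13), (16, -23, 18), 99),
        "ABAD": ((49, 16, -15), (95, -38, 14), 53),
        "LAR": ((54, -6, 33), (26, -5, -21), 54),
    },
    "Sal22 in vivo": {
        "FE": ((124, 17, -17), (10, -2, -7), 115),
        "ABAD": ((105, 22, -18), (31, -15, 7), 37),
        "LAR": ((48, -6, 9), (109, 22, -22), 32),
    },
}


def range_is_exact(joint: str, specimen: str, axis: str) -> bool:
    """Whether the published range equals (max - min) of the rounded extrema."""
    table = HIP_ROM if joint == "hip" else KNEE_ROM
    at_max, at_min, published = table[specimen][axis]
    col = EULER_COLUMN[axis]
    return at_max[col] - at_min[col] == published


def reference_summary(joint: str, specimen: str) -> RoMSummary:
    """Rebuild a :class:`RoMSummary` from the published extremal triples."""
    table = HIP_ROM if joint == "hip" else KNEE_ROM
    extrema = {axis: (vals[0], vals[1]) for axis, vals in table[specimen].items()}
    context = "in_vivo" if "in vivo" in specimen else "ex_vivo"
    return summary_from_extrema(
        extrema, meta={"specimen": specimen.split()[0], "joint": joint,
                       "context": context})


def published_range(joint: str, specimen: str, axis: str) -> int:
    table = HIP_ROM if joint == "hip" else KNEE_ROM
    return table[specimen][axis][2]
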