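"""Brute-force spherical point-in-polygon oracle for the acceptance script."""

import numpy as np


def spherical_winding_inside(p, boundary):
    """Winding-number membership test, independent of the gnomonic chart.

    Projects the polygon vertices onto the tangent plane at ``p`` and sums
    the signed turning angles: +/-2*pi when enclosed, 0 outside.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(boundary, dtype=float)
    w = v - np.outer(v @ p, p)
    norms = np.linalg.norm(w, axis=1)
    if np.any(norms < 1e-12):
        return True
    w = w / norms[:, None]
    total = 0.0
    for i in range(len(w)):
        a, b = w[i], w[(i + 1) % len(w)]
        dot = float(np.clip(a @ b, -1.0, 1.0))
        sign = np.sign(p @ np.cross(a, b))
        total += sign * np.arccos(dot)
    return abs(total) > np.pi
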