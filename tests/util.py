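"""Independent oracles shared by the test suite."""

import numpy as np


def spherical_winding_inside(p, boundary):
    """Brute-force point-in-spherical-polygon via the winding number.

    Projects the boundary vertices onto the tangent plane at ``p`` and
    accumulates the signed turning angle; a point enclosed by the polygon
    sees a total of +/-2*pi, an outside point 0.  Independent of the
    gnomonic-chart membership test it checks.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(boundary, dtype=float)
    w = v - np.outer(v @ p, p)
    norms = np.linalg.norm(w, axis=1)
    if np.any(norms < 1e-12):  # query coincides with a vertex: inside (closed)
        return True
    w = w / norms[:, None]
    total = 0.0
    for i in range(len(w)):
        a, b = w[i], w[(i + 1) % len(w)]
        dot = float(np.clip(a @ b, -1.0, 1.0))
        sign = np.sign(p @ np.cross(a, b))
        total += sign * np.arccos(dot)
    return abs(total) > np.pi


def random_rotations(rng, n):
    """Uniform-ish random rotation matrices via QR of Gaussian matrices."""
    out = []
    while len(out) < n:
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q = q @ np.diag(np.sign(np.diag(r)))
        if np.linalg.det(q) < 0:
            q[:, [0, 1]] = q[:, [1, 0]]
        out.append(q)
    return out
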