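"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most literal method available
(per-pixel double loops, term-by-term summation, repeated scalar
multiplication) so the package's vectorized paths are checked against
code that shares none of their structure.
"""

import numpy as np


def density_by_double_loop(mask, bounds):
    """rho'[k] by an explicit per-pixel scan over each layer's rows."""
    counts = []
    for y_t, y_b in bounds.entries:
        c = 0
        for y in range(y_t, y_b + 1):          # 1-based inclusive rows
            for x in range(mask.shape[1]):
                if mask[y - 1, x]:
                    c += 1
        counts.append(c)
    return counts


def depth_sum_by_double_loop(depth_profile, bounds):
    """Per-layer sum of the masked depth values, pixel by pixel."""
    sums = []
    for y_t, y_b in bounds.entries:
        s = 0.0
        for y in range(y_t, y_b + 1):
            for x in range(depth_profile.shape[1]):
                s += float(depth_profile[y - 1, x])
        sums.append(s)
    return sums


def poly_cm_by_term_summation(x):
    """Depth->cm polynomial as a naive sum of monomials (no Horner)."""
    coeffs = [1.2512e-10, -1.0370e-7, 3.5014e-5, -0.0061, 0.5775, -27.6342, 5.6759e2]
    degree = len(coeffs) - 1
    return sum(c * x ** (degree - i) for i, c in enumerate(coeffs))


def inverse_depth_elementwise(depth):
    top, bottom = max(depth), min(depth)
    if top == bottom:
        return [0.0] * len(depth)
    return [(d - top) / (bottom - top) for d in depth]


def product_fusion_by_repeated_multiplication(arrays):
    """omega[k] by scalar-at-a-time multiplication across views."""
    n = len(arrays[0])
    out = []
    for k in range(n):
        acc = 1.0
        for view in arrays:
            acc = acc * float(view[k])
        out.append(acc)
    return out


def connected_components_by_flood_fill(mask):
    """8-connected components via explicit BFS; returns list of pixel sets."""
    mask = np.asarray(mask)
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                queue = [(sy, sx)]
                seen[sy, sx] = True
                pixels = []
                while queue:
                    y, x = queue.pop()
                    pixels.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w
                                    and mask[ny, nx] and not seen[ny, nx]):
                                seen[ny, nx] = True
                                queue.append((ny, nx))
                components.append(pixels)
    return components
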