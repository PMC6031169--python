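"""Per-view layered feature model of the human depth profile.

The subject's bounding box is split into 2N+1 equal-height horizontal
layers L[k], k = -N (top) ... +N (bottom). Per layer the model computes

* rho'[k], rho[k] — foreground pixel count and its max-normalized
  density (silhouette area per layer),
* D'[k], D[k]    — mean foreground depth converted to real-range
  centimeters by a fitted degree-6 polynomial, max-normalized,
* D_i[k]         — inverse depth, a min-max flip of D that is high
  where the layer is nearest the camera; it reveals "hidden volume"
  (thighs when sitting, the bent back when stooping) that the
  silhouette alone cannot,
* Q[k] = D_i[k] * rho[k] — inverse-depth density,
* Z[k] = (1-alpha) Q[k] + alpha rho[k] — weighted depth density, a
  convex blend controlled by the learning rate alpha,

plus one global scalar, the proportion value P_v = W_h / H_h, which
separates horizontal postures (lying) from vertical ones.

Layer row ranges follow the 1-based inclusive convention
``y_T[k] = floor(H (k+N) / (2N+1)) + 1``, ``y_B[k] = floor(H (k+N+1) /
(2N+1))``, which partitions rows 1..H exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import HumanBlob

#: Coefficients of the depth-value -> centimeters regression polynomial,
#: highest degree first. Fitted for an 8-bit structured-light depth
#: sensor; valid input domain is the sensor's code range [0, 255].
DEPTH_CM_COEFFS = (
    1.2512e-10,
    -1.0370e-7,
    3.5014e-5,
    -0.0061,
    0.5775,
    -27.6342,
    5.6759e2,
)

DEFAULT_LAYERS = 3     # L = 2N+1; the model's optimum on real data
DEFAULT_ALPHA = 0.9


@dataclass(frozen=True)
class LayerBounds:
    """Row ranges of the 2N+1 layers, 1-based inclusive within the blob."""

    n: int
    height: int
    entries: tuple[tuple[int, int], ...]  # (y_T, y_B) for k = -N..N

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ks(self) -> range:
        return range(-self.n, self.n + 1)


@dataclass(frozen=True)
class LayerProfile:
    """All per-view layer features of one blob (arrays indexed k=-N..N)."""

    rho_raw: np.ndarray    # rho'[k], pixel counts
    rho: np.ndarray        # rho[k], in [0,1]
    depth_raw: np.ndarray  # D'[k], cm (0 for empty layers)
    depth: np.ndarray      # D[k], in [0,1]
    depth_inv: np.ndarray  # D_i[k], in [0,1]
    q: np.ndarray          # Q[k]
    z: np.ndarray          # Z[k]
    alpha: float
    proportion: float      # P_v = W_h / H_h

    @property
    def n(self) -> int:
        return (len(self.rho) - 1) // 2


def layer_bounds(height: int, n: int) -> LayerBounds:
    """Split ``height`` rows into 2N+1 contiguous equal layers.

    Raises if the blob has fewer rows than layers (some layer would be
    empty).
    """
    if height < 1 or n < 0:
        raise ValueError("need height >= 1 and n >= 0")
    layers = 2 * n + 1
    if height < layers:
        raise ValueError(f"too few rows: height {height} < {layers} layers")
    entries = []
    for k in range(-n, n + 1):
        y_t = height * (k + n) // layers + 1
        y_b = height * (k + n + 1) // layers
        entries.append((y_t, y_b))
    return LayerBounds(n=n, height=height, entries=tuple(entries))


def _max_normalize(values: np.ndarray) -> np.ndarray:
    top = values.max(initial=0.0)
    if top <= 0:
        return np.zeros_like(values, dtype=np.float64)
    return values / top


def layer_density(blob: HumanBlob, bounds: LayerBounds) -> tuple[np.ndarray, np.ndarray]:
    """Foreground pixel count per layer and its max-normalized density.

    Normalizing by the per-frame max makes densities comparable across
    views at different subject distances.
    """
    if bounds.height != blob.height:
        raise ValueError("bounds were built for a different blob height")
    row_counts = blob.mask.astype(np.int64).sum(axis=1)
    rho_raw = np.array(
        [row_counts[y_t - 1:y_b].sum() for y_t, y_b in bounds.entries],
        dtype=np.float64,
    )
    return rho_raw, _max_normalize(rho_raw)


def depth_to_cm(x) -> float | np.ndarray:
    """Convert an 8-bit depth value to real distance in centimeters.

    Evaluates the fitted degree-6 regression polynomial in double
    precision (Horner form). Inputs outside [0, 255] are outside the
    sensor's code range and raise.
    """
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("depth value outside the 8-bit sensor range [0, 255]")
    result = np.zeros_like(arr)
    for c in DEPTH_CM_COEFFS:
        result = result * arr + c
    return float(result) if np.isscalar(x) or arr.ndim == 0 else result


def layer_real_depth(
    blob: HumanBlob, bounds: LayerBounds, rho_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean foreground depth per layer, in cm, and its max-normalized form.

    The mean 8-bit depth of the layer's foreground pixels is converted
    via :func:`depth_to_cm`. Empty layers get D' = 0 (not NaN) so the
    normalization and the downstream fusion stay defined.
    """
    depth64 = blob.depth_profile.astype(np.float64)
    row_sums = depth64.sum(axis=1)
    depth_raw = np.zeros(len(bounds), dtype=np.float64)
    for i, (y_t, y_b) in enumerate(bounds.entries):
        if rho_raw[i] > 0:
            mean_code = row_sums[y_t - 1:y_b].sum() / rho_raw[i]
            depth_raw[i] = depth_to_cm(mean_code)
    return depth_raw, _max_normalize(depth_raw)


def inverse_depth(depth: np.ndarray) -> np.ndarray:
    """Min-max flip of the normalized depth: 1 = nearest layer, 0 = farthest.

    A flat profile (max = min) maps to all zeros — no layer stands out
    as nearer, so the inverse depth carries no signal.
    """
    d = np.asarray(depth, dtype=np.float64)
    top, bottom = d.max(), d.min()
    if top == bottom:
        return np.zeros_like(d)
    return (d - top) / (bottom - top)


def weighted_density(
    rho: np.ndarray,
    depth_inv: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    alpha_convention: str = "printed",
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-depth density Q and the alpha-blended depth density Z.

    ``printed`` convention: Z = (1-alpha) Q + alpha rho, so alpha is the
    weight on the plain density. The ``prose`` convention swaps the
    weights (alpha on Q); both appear in the field's usage and only the
    role of alpha differs.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha_convention not in ("printed", "prose"):
        raise ValueError(f"unknown alpha_convention {alpha_convention!r}")
    q = np.asarray(depth_inv, dtype=np.float64) * np.asarray(rho, dtype=np.float64)
    if alpha_convention == "printed":
        z = (1.0 - alpha) * q + alpha * np.asarray(rho, dtype=np.float64)
    else:
        z = alpha * q + (1.0 - alpha) * np.asarray(rho, dtype=np.float64)
    return q, z


def proportion_value(blob: HumanBlob) -> float:
    """Width/height ratio of the bounding box; > 1 means a horizontal posture."""
    if blob.height == 0:
        raise ValueError("blob height is zero")
    return blob.width / blob.height


def compute_profile(
    blob: HumanBlob,
    layers: int = DEFAULT_LAYERS,
    alpha: float = DEFAULT_ALPHA,
    alpha_convention: str = "printed",
) -> LayerProfile:
    """Run the full per-view feature chain on one blob."""
    if layers % 2 == 0 or layers < 1:
        raise ValueError("layer count must be odd and >= 1")
    n = (layers - 1) // 2
    bounds = layer_bounds(blob.height, n)
    rho_raw, rho = layer_density(blob, bounds)
    depth_raw, depth = layer_real_depth(blob, bounds, rho_raw)
    d_i = inverse_depth(depth)
    q, z = weighted_density(rho, d_i, alpha=alpha, alpha_convention=alpha_convention)
    return LayerProfile(
        rho_raw=rho_raw, rho=rho, depth_raw=depth_raw, depth=depth,
        depth_inv=d_i, q=q, z=z, alpha=alpha,
        proportion=proportion_value(blob),
    )
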