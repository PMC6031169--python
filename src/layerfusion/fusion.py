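"""Cross-view fusion of layer features into view-count-independent vectors.

Per-layer features from d synchronized, uncalibrated views are fused
by simple products: the mass of dimension omega[k] multiplies the
per-view densities rho_v[k], the weighted mass omega_bar[k] multiplies
the per-view weighted depth densities Z_v[k], and the proportion value
takes the maximum over views. The resulting feature vector has length
2N+2 regardless of the number of cameras:

    [layer -N ... layer +N, P_m]

with layer entries drawn from omega (the "nondepth" flavor) or
omega_bar (the "depth" flavor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

FLAVORS = ("nondepth", "depth")


@dataclass(frozen=True)
class FusedFeatures:
    omega: np.ndarray      # per-layer product of rho across views
    omega_bar: np.ndarray  # per-layer product of Z across views
    p_max: float           # max proportion value over views
    views_used: int

    def __post_init__(self) -> None:
        if self.views_used < 1:
            raise ValueError("fusion needs at least one view")
        if len(self.omega) != len(self.omega_bar):
            raise ValueError("omega/omega_bar length mismatch")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray  # length 2N+2: layers then P_m
    flavor: str
    label: Optional[str] = None


def _product(arrays: Sequence[np.ndarray], name: str) -> np.ndarray:
    if len(arrays) == 0:
        raise ValueError(f"{name}: need at least one view")
    stacked = [np.asarray(a, dtype=np.float64) for a in arrays]
    if any(a.shape != stacked[0].shape for a in stacked):
        raise ValueError(f"{name}: layer count differs between views")
    # multiply per-layer factors in sorted order so the fused value is
    # exactly invariant to the order the views arrive in
    ordered = np.sort(np.stack(stacked), axis=0)
    return np.multiply.reduce(ordered, axis=0)


def fuse_density(rho_per_view: Sequence[np.ndarray]) -> np.ndarray:
    """omega[k]: product of the layer densities over all views."""
    return _product(rho_per_view, "fuse_density")


def fuse_weighted(z_per_view: Sequence[np.ndarray]) -> np.ndarray:
    """omega_bar[k]: product of the weighted depth densities over all views."""
    return _product(z_per_view, "fuse_weighted")


def max_proportion(p_per_view: Sequence[float]) -> float:
    """P_m: the largest proportion value seen by any view."""
    if len(p_per_view) == 0:
        raise ValueError("max_proportion: need at least one view")
    return float(max(p_per_view))


def fuse(profiles) -> FusedFeatures:
    """Fuse the :class:`~layerfusion.features.LayerProfile` of each view.

    Views with no detected subject should be dropped by the caller
    before fusion (a missing view must not contribute annihilating
    zeros to every layer).
    """
    omega = fuse_density([p.rho for p in profiles])
    omega_bar = fuse_weighted([p.z for p in profiles])
    p_max = max_proportion([p.proportion for p in profiles])
    return FusedFeatures(
        omega=omega, omega_bar=omega_bar, p_max=p_max, views_used=len(profiles)
    )


def make_vector(
    fused: FusedFeatures, flavor: str = "depth", label: Optional[str] = None
) -> FeatureVector:
    """Concatenate [layer -N ... +N, P_m] into the classification vector."""
    if flavor not in FLAVORS:
        raise ValueError(f"flavor must be one of {FLAVORS}, got {flavor!r}")
    layer_part = fused.omega if flavor == "nondepth" else fused.omega_bar
    values = np.concatenate([layer_part, [fused.p_max]])
    return FeatureVector(values=values, flavor=flavor, label=label)
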