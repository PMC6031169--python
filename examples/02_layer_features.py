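"""Layered features of a single rendered depth silhouette.

Renders one 'stooping' frame, extracts the subject with the standard
chain (background model -> foreground -> denoise -> blob -> arm
rejection), and prints the per-layer features: the density rho[k]
shows where the silhouette's mass sits, the inverse depth D_i[k]
which layers are nearest the camera, and Z[k] blends the two with the
learning rate alpha.
"""

import numpy as np

from layerfusion import build_background_model, compute_profile, extract_blob
from layerfusion.synthetic import (
    BodyParams, Posture, SceneConfig, render_action, render_background,
)

config = SceneConfig(seed=0)
rng = np.random.default_rng(0)

model = build_background_model(render_background(config, rng, 40))
frame = render_action(
    "stooping", BodyParams(orientation_deg=90), 0.0, config, rng,
    dist_cm=400.0, x_center=80.0, n_frames=1, posture=Posture(),
)[0]

blob = extract_blob(frame, model)
profile = compute_profile(blob, layers=3, alpha=0.9)

print(f"blob bbox (x, y, w, h): {blob.bbox}")
print(f"proportion value P_v = W/H = {profile.proportion:.3f}")
print(f"{'layer':>6} {'rho':>6} {'D':>6} {'D_i':>6} {'Q':>6} {'Z':>6}")
for i, k in enumerate(range(-profile.n, profile.n + 1)):
    print(f"{k:>+6d} {profile.rho[i]:6.3f} {profile.depth[i]:6.3f} "
          f"{profile.depth_inv[i]:6.3f} {profile.q[i]:6.3f} {profile.z[i]:6.3f}")

print("\nstooping concentrates mass in the top layer (rho[-1] = 1) and")
print("the bent back is nearest the camera there (D_i[-1] = 1): that")
print("signature is what separates it from the other postures.")
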