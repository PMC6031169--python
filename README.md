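# layerfusion

Profile-based human action recognition from multiview depth images,
built for privacy-preserving health monitoring (e.g. detecting that an
elderly person is lying on the floor) where only coarse whole-body
posture is needed and no RGB appearance should be stored. The package
classifies four profile actions — **standing/walking, sitting,
stooping, lying** — from synchronized 8-bit depth streams of two or
more uncalibrated cameras, and ships a synthetic multiview depth-scene
generator so the entire pipeline can be exercised and tested without
any recorded dataset.

## The model

Each frame is segmented against a per-pixel background model learned
from the sequence's leading background-only frames; the largest
connected foreground component, with thin limbs stripped by a
morphological opening, gives the subject's bounding box, binary mask
`I_m` and masked depth profile `I_mo`. The box is split into `2N+1`
equal-height **layers** `L[k]`, `k = −N…N`, with 1-based inclusive row
bounds

    y_T[k] = ⌊H·(k+N)/(2N+1)⌋ + 1,    y_B[k] = ⌊H·(k+N+1)/(2N+1)⌋.

Per layer and view the model computes

* density `ρ[k]` — foreground pixel count, max-normalized over layers;
* real-range depth `D[k]` — mean 8-bit layer depth converted to
  centimeters by a fitted degree-6 regression polynomial `f_c′`, then
  max-normalized;
* inverse depth `D_i[k] = (D[k] − max D)/(min D − max D)` — high where
  the layer is nearest the camera, revealing "hidden volume" such as
  the thighs of a sitter seen front-on;
* weighted depth density `Z[k] = (1−α)·D_i[k]·ρ[k] + α·ρ[k]`;
* proportion value `P_v = W_h/H_h`, separating horizontal postures.

Across the `d` views the features fuse by per-layer products
`ω[k] = Π_v ρ_v[k]`, `ω̄[k] = Π_v Z_v[k]` and `P_m = max_v P_v`, giving
a feature vector `[ω̄−N … ω̄+N, P_m]` of fixed length `2N+2` that is
independent of the camera count. A single-hidden-layer
back-propagation network (20 units) or an RBF-kernel C-SVC classifies
the vectors; evaluation reports the 4×4 confusion matrix and per-class
precision `TP/(TP+FP)` with its macro average.

## Worked example

`examples/04_end_to_end.py` generates a two-camera synthetic corpus
(25 sequences per class, cameras 90° apart, 40 background frames per
sequence), extracts and fuses features at `L=3, α=0.9`, and trains the
network on a 70/30 sequence-level split:

```
generated 100 sequences (40 background + 1 action frame(s) each, 2 views)
extracted 100 fused feature vectors of length 4

confusion matrix (rows = true, labels ['standing_walking', 'sitting', 'stooping', 'lying']):
[[8 0 0 0]
 [0 7 0 0]
 [0 0 7 0]
 [0 0 0 8]]
    standing_walking: 100.00% precision
             sitting: 100.00% precision
            stooping: 100.00% precision
               lying: 100.00% precision
       macro average: 100.00%
```

Rows of the confusion matrix are true classes of the held-out
sequences; on this quiet corpus the four postures separate cleanly.
The other examples show the depth-code→cm conversion, the per-layer
feature signature of a single silhouette, and why fusing a second view
disambiguates a front-on sitter.

## Command line

The same chain is scriptable via the `layerfusion` CLI:

```bash
layerfusion simulate -n 25 --views 2 --angle 90 --seed 42 -o corpus/
layerfusion run corpus/manifest.yaml -o results/
layerfusion sweep corpus/manifest.yaml --layers 3,5,7 --alphas 0.0,0.5,0.9 -o sweep.csv
```

`extract`, `train` and `evaluate` expose the intermediate stages and
compose through CSV/JSON artifacts; every applied default is logged.

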