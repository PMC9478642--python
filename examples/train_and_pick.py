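"""Train the denoiser + segmenter on synthetic patches and pick bundles from
held-out synthetic micrographs.

Prints the picker's precision and recall against the scenes' ground truth:
a pick counts as correct when it lands within half a pick-step of an unused
ground-truth pick. Per-scene numbers fluctuate with the objects a scene
happens to contain; the aggregate is the meaningful figure.
"""

import numpy as np

from filbundle.neuralpick import evaluate_picks, train_picker
from filbundle.synthgen import (CTFParams, compose_scene, corrupt,
                                default_scene_objects, make_training_patches)

# a couple of minutes on one CPU; enlarge n_patches/epochs for better masks
patches = make_training_patches(n_patches=150, patch=256, snr=0.2, seed=0)
picker = train_picker(patches, seed=1)

rng = np.random.default_rng(99)
matched = n_picks = n_truth = 0
for i in range(3):
    clean, truth = compose_scene(default_scene_objects(rng),
                                 shape=(1024, 1024), rng=rng)
    noisy = corrupt(clean, CTFParams(defocus_um=float(rng.uniform(0.8, 2.5))),
                    snr=0.2, rng=rng)
    picks, mask = picker.pick(noisy)
    m = evaluate_picks(picks, truth.picks, truth.labels, step=50.0)
    print(f"scene {i}: {m['n_picks']} picks vs {m['n_truth']} truth, "
          f"precision {m['precision']:.2f}, recall {m['recall']:.2f}")
    matched += m["precision"] * m["n_picks"]
    n_picks += m["n_picks"]
    n_truth += m["n_truth"]

print(f"\noverall: precision {matched / n_picks:.2f}, recall {matched / n_truth:.2f}")
# precision/recall near 1 mean the segmentation isolates two-filament bundles
# from single filaments and larger assemblies at this noise level
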