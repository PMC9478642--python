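# filbundle

Tools for visualizing and quantifying cross-linker bridges between actin
filaments in cryo-EM. Bundled filaments break the assumptions of standard
helical reconstruction — a bundle is not one helix, and cross-linked pairs sit
embedded in larger assemblies — so this package implements the surrounding
machinery a bundle-structure study needs:

* **Synthetic training data**: decorated-filament volumes rendered from an
  atomic model under helical symmetry, two-filament bundle configurations
  sampled uniformly over interfilament distance, relative orientation
  (polarity, skew, splay) and projection view, composed into micrograph-scale
  scenes with CTF and noise, per-pixel class labels and ground-truth picks.
* **Learned picking**: a small patch denoiser and a sliding-window semantic
  segmenter (background / single filament / two-filament bundle /
  higher-order assembly) that convert micrographs into bundle particle picks
  via skeletonized centerlines.
* **Polarity typing**: projection matching of bundle class averages against a
  decorated single-filament reference to call parallel vs. antiparallel
  bridges, and composition of initial two-filament 3D models.
* **Bundle geometry**: the quantitative core. From per-particle multibody
  poses of the two filaments, it measures polarity, skew (out-of-plane tilt),
  splay (in-plane rotation), interfilament distance and bridge span, docks
  templates into maps, and summarizes per-particle distributions.

The common frame puts filament A's plus-end direction on **ẑ** and the
perpendicular component of the displacement to filament B's body center on
**x̂**; with **d̂** filament B's direction (flipped for antiparallel bundles so
both polarities measure deviation from their ideal),

```
splay = atan2(d̂·x̂, d̂·ẑ)        (in-plane, degrees, signed)
skew  = asin(d̂·ŷ)               (out-of-plane, degrees, signed)
d     = |Δ − (Δ·ẑ)ẑ|            (interfilament distance, Å)
```

This construction is the exact inverse of the simulator's `place_pair`, so
simulated configurations round-trip through measurement at machine precision.
Bridge span is the distance between the Cα centroids of the two actin
protomers anchoring the cross-linker (4 Å contact cutoff). See
`docs/methods.md` for conventions, assumptions and limitations.

## Worked example

Measuring a bundle configuration and summarizing a per-particle table
(`examples/bundle_geometry.py`):

```
$ python examples/bundle_geometry.py
configured: antiparallel skew 9.0 deg, splay 1.1 deg, d 148.9 A
measured:   antiparallel skew 9.000000 deg, splay 1.100000 deg, d 148.9000 A

n = 20000
skew  mean 9.07 deg, SD 14.14 deg
splay mean 1.10 deg, SD 12.50 deg
skew-splay Pearson r = 0.0034
```

The first two lines show the realise→measure round trip: a bundle placed with
9° skew, 1.1° splay and 148.9 Å axis separation is measured back exactly. The
summary block recovers the generating moments of a simulated antiparallel
per-particle table; the near-zero skew–splay correlation is the signature of
a cross-linker flexing independently in its two angular degrees of freedom.

Docking and bridge measurement (`examples/dock_and_measure_bridge.py`):

```
$ python examples/dock_and_measure_bridge.py
docking: rotation error 0.10 deg, translation error 0.04 A, correlation 0.817
bridge span: 98.0 A (distance between the Calpha centroids of the two anchor protomers)
```

A decorated-filament template perturbed by a few degrees/Å and buried in map
noise (snr 2) is recovered to ~0.1° / 0.05 Å; the synthetic bridge model's
span comes back at its constructed 98 Å.

Other examples: `simulate_scenes.py` (labeled datasets with reproducing
manifests), `train_and_pick.py` (train the networks, pick a held-out
micrograph, print precision/recall), `polarity_classification.py` (class
averages → polarity calls with confidences), `structural_measurements.py`
(superposition, hinge swings, linker gaps, filament-axis fits).

A thin CLI mirrors the library for pipeline use:

```
filbundle simulate --n-scenes 10 --seed 1 --out dataset/
filbundle train-denoiser --dataset dataset/ --out denoiser.joblib
filbundle train-segmenter --dataset dataset/ --denoiser denoiser.joblib --out segmenter.joblib
filbundle pick --segmenter segmenter.joblib --denoiser denoiser.joblib \
    --micrographs mic.mrc --out-star picks.star
filbundle classify-polarity --averages avg.mrc --reference-map filament.mrc --out-csv polarity.csv
filbundle geometry --poses multibody.star --bodies bodies.yaml --out-csv geometry.csv
filbundle summarize --in-csv geometry.csv --out-json summary.json
filbundle measure --model a.pdb --model-b b.pdb --op swing --align A:1-40 --measure A:41-80
```

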