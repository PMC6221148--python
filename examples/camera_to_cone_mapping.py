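"""Calibrate a UV camera against a visual system and check its accuracy.

A training library of smooth reflectances is photographed through the
simulated four-channel UV camera (gamma response, gray-standard
normalization), and a least-squares mapping from camera responses to
*H. erato* female cone catches is fitted. Held-out spectra then measure
how well photographs alone predict what the butterfly's receptors catch.
"""

import numpy as np

import mimicvis as mv
from mimicvis.synth import generate_training_library

grid = mv.DEFAULT_GRID
d65 = mv.standard_illuminant("D65", grid)
cams = mv.default_camera(grid)
target = mv.build_preset("erato-female-green", grid)
rng = np.random.default_rng(1)

library = generate_training_library(260, rng, grid)
train, held_out = library[:200], library[200:]
mapping = mv.fit_cone_mapping(train, d65, cams, target)

print("Per-receptor training RMS (normalized catch units):")
for name, rms in zip(target.channel_names, mapping.training_rms):
    print(f"  {name:4s} {rms:.4f}")

errors = []
for spec in held_out:
    photo = mv.linearize_normalize(mv.simulate_camera_response(spec, d65, cams))
    predicted = mv.apply_mapping(mapping, photo)
    truth = mv.catch_vector(spec, d65, target)
    errors.append(np.abs(predicted.q - truth.q) / truth.q)
print(f"\nHeld-out median relative catch error: {np.median(errors):.3f}")
print("Errors of a few percent mean calibrated photographs are a usable "
      "stand-in for spectrometry in the downstream JND analysis.")
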