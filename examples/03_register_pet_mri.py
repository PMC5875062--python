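"""Recover a known PET–MRI misalignment by affine registration.

Simulates an MRI and a PET of the same phantom, pushes the PET through a
random rigid pose, registers it back with the correlation-ratio cost, and
reports the landmark registration error (LRE) before and after.
"""

import numpy as np

from petstage import (
    PhantomConfig,
    RegistrationConfig,
    build_template,
    landmark_error,
    place_landmarks,
    register,
    simulate_mri,
    simulate_pet,
)
from petstage.phantom import sample_pose
from petstage.resampling import resample
from petstage.transforms import AffineTransform

config = PhantomConfig(grid_shape=(48,) * 3, spacing=(128.0 / 48,) * 3)
_, atlas = build_template(config)
mri = simulate_mri(atlas, config, seed=0)
pet = simulate_pet(atlas, "NC", "FDG", "baseline", config, seed=1)

rng = np.random.default_rng(3)
truth = sample_pose(config, "rigid", rng)
pet_moved = resample(pet, truth, reference=pet)

landmarks = place_landmarks(atlas)
moving_lms = landmarks.transformed(truth)

before = landmark_error(landmarks, moving_lms, AffineTransform.identity())
recovered = register(mri, pet_moved, RegistrationConfig(cost="correlation_ratio", model="rigid"))
after = landmark_error(landmarks, moving_lms, recovered)

print(f"misalignment LRE before registration: {before.mean:.2f} ± {before.sd:.2f} mm")
print(f"residual LRE after registration     : {after.mean:.2f} ± {after.sd:.2f} mm")
print(f"voxel size                          : {128.0 / 48:.2f} mm")
print("\nA residual well below one voxel means the pose was recovered.")
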