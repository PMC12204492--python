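"""Simulate one avoidance session and preprocess its traces.

Generates a session (10-s tone trials, 25-40 s ITIs, success/failure
outcomes), converts raw fluorescence to session-z-scored ΔF/F and slices a
tone-aligned trial tensor.
"""

import avoidpop as ap
from avoidpop.preprocess import build_trial_tensor, zscore_session

cfg = ap.SimConfig(n_neurons=30, n_trials=20, seed=1)
bundle, truth = ap.generate_session(cfg)
print(f"session: {bundle.n_neurons} neurons x {bundle.n_frames} frames "
      f"at {bundle.frame_rate_hz:g} Hz, {bundle.events.n_trials} trials "
      f"({(truth.outcomes == 'success').sum()} successes)")

z = zscore_session(bundle)
tensor = build_trial_tensor(bundle, z, "cs_onset", (-2.0, 3.0))
print(f"tone-aligned tensor: {tensor.data.shape} "
      "(neurons x trials x timepoints), window -2..+3 s")
print(f"z-trace per-neuron mean ~ {z.mean():.2e}, SD ~ {z.std(axis=1).mean():.3f}")
# each tensor value is fluorescence in units of session standard deviations,
# so +2 means the neuron is 2 SDs above its session-typical activity
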