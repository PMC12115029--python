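"""Condition one session: bandpass the EOG, low-pass the acceleration,
and excise motion artifacts flagged by the mean + 3 sd magnitude rule."""

import numpy as np

import eogstress as eog

session, truth = eog.render_session(eog.SynthConfig(seed=7), 0)
prep = eog.preprocess_session(session)

print(f"acceleration magnitude: mean {prep.mask.mean_mag:.3f} g, "
      f"sd {prep.mask.sd_mag:.3f} g -> threshold {prep.mask.threshold_value:.3f} g")
print(f"masked fraction: {prep.mask.masked_fraction:.4%} of samples")

flags = prep.mask.flags
fs = session.sampling_rate
hit = sum(
    bool(flags[int((t - 0.15) * fs): int((t + 0.15) * fs) + 1].any())
    for t in truth.true_artifact_times
)
print(f"injected motion events intersecting the mask: "
      f"{hit}/{len(truth.true_artifact_times)}")

drift_before = np.ptp(session.eog_v) - np.ptp(prep.eog_v)
print(f"peak-to-peak reduced by {drift_before:.0f} uV after filtering + excision")
print("\nEvery artifact was injected with a coincident acceleration burst, "
      "so the 3-sigma magnitude rule recovers the event times.")
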