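"""Generate a small synthetic cohort and look at one subject.

Builds a 10-subject cohort (two-channel frontopolar EEG + symptom
questionnaires, with injected artifacts) and prints the ground truth
for the first subject.
"""

import dataclasses

from frontoboost.synthetic import CohortSpec, generate_cohort, write_cohort

spec = dataclasses.replace(
    CohortSpec(),
    n_mtbi=5, n_control=5, duration_s=30.0, seed=7,
    artifact_rates={"blink": 2.0, "emg": 1.0, "saturation": 0.5,
                    "excursion": 0.5, "spike": 1.0},
)
cohort = generate_cohort(spec)
write_cohort(cohort, "example_cohort")

s = cohort[0]
print(f"{len(cohort)} subjects written to example_cohort/")
print(f"subject {s.subject_id} ({s.label}):")
print(f"  recording: {s.recording.n_samples} samples at {s.recording.fs} Hz")
print(f"  true band RMS amplitudes (µV, L/R): "
      f"{ {b: tuple(round(a, 1) for a in v) for b, v in s.band_amps_uV.items()} }")
print(f"  endorsed symptoms: "
      f"{[k for k, v in s.symptoms.answers.items() if v]}")
print(f"  injected artifacts: "
      f"{[(a.kind, a.start_sample, a.end_sample) for a in s.artifacts]}")
# The amplitudes are the generator's ground truth: downstream band-power
# features should recover their ordering, and the artifact list is what
# the detectors are scored against.
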