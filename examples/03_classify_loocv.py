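"""Boosted classification of a synthetic cohort with LOOCV.

Builds a 30-subject cohort with informative EEG, assembles the three
standard variable sets (EEG-only, symptoms-only, combined), and prints
leave-one-out and resubstitution accuracy for each.
"""

import pandas as pd

from frontoboost import boost
from frontoboost.spectral import eeg_features
from frontoboost.symptoms import symptom_table
from frontoboost.synthetic import CohortSpec, generate_cohort

spec = CohortSpec(n_mtbi=14, n_control=16, duration_s=20.0,
                  eeg_class_effect=1.0, seed=3)
cohort = generate_cohort(spec)
eeg = pd.DataFrame(
    {s.subject_id: eeg_features(s.recording) for s in cohort}
).T
sym = symptom_table(cohort)
labels = sym["label"].to_numpy()

for case in ("eeg_only", "symptoms_only", "combined"):
    fm = boost.assemble(eeg, sym.drop(columns="label"), labels, case)
    res = boost.loocv(fm)
    print(f"{case:>14} ({fm.X.shape[1]:2d} variables): "
          f"LOOCV accuracy {res.accuracy:.3f}, "
          f"resubstitution {res.resubstitution_accuracy:.3f}")
# Resubstitution saturates at 1.0 — expected for a margin-maximizing
# ensemble on a small cohort — while LOOCV accuracy is the honest
# estimate; the combined set should beat either block alone here
# because this cohort's EEG carries real class signal.
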