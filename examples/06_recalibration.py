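"""Personalized recalibration: monitor drift and refit per-patient.

Checks recent paired readings against a MARD threshold and, when the
device has drifted, refits only the clinical ranges the patient visits.
"""

import numpy as np

from pgms import pipeline as pl, synthetic as syn
from pgms.data import PairedDataset

data = syn.generate_dataset(syn.dataset2_spec(), syn.dataset2_config(seed=1))
train, test = pl.split_train_test(data, 0.7, seed=1)
model = pl.train_pgms(train, seed=1)

recent = test.subset(np.arange(10))
print("recent window decision:",
      pl.check_recalibration(recent, model, threshold_mard=15.0))

# a patient whose glucose spans 95..162 mg/dl during calibration
rs = np.random.RandomState(7)
y = rs.uniform(95, 162, 40)
patient = PairedDataset(y, 0.8 * y + 20)
refit = pl.personalize(model, patient)
changed = [refit.partitioner.name(j) for j in refit.models
           if refit.models[j] is not model.models.get(j)]
print("ranges refit for this patient:", ", ".join(changed))
# Only the ranges the patient actually visits are retrained; the
# population models elsewhere are untouched.
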