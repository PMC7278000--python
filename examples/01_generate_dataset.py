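"""Generate the GlucoTrack-like paired dataset and check its marginals.

Builds 918 paired (invasive reference, non-invasive measured) readings
whose count, value ranges and signed-error extremes are exact and whose
MARD lands within +/-1 % of the 23.9 % target, then writes the CSV.
"""

from pgms import synthetic as syn
from pgms.data import write_paired_csv

spec = syn.dataset1_spec()
data = syn.generate_dataset(spec, syn.dataset1_config(seed=1))
report = syn.validate_against_spec(data, spec)

print(f"pairs:            {len(data)}")
print(f"invasive range:   {data.invasive.min():.0f}..{data.invasive.max():.0f} mg/dl")
print(f"noninvasive range:{data.noninvasive.min():.0f}..{data.noninvasive.max():.0f} mg/dl")
print(f"realized MARD:    {data.provenance['realized_mard']:.2f} % (target {spec.target_mard})")
print(f"all marginal checks pass: {report.passed}")

write_paired_csv(data, "dataset1_pairs.csv")
print("wrote dataset1_pairs.csv")
# Each row is one paired measurement; the MARD says the raw sensor is
# off by ~24 % on average, which is what the correction model must fix.
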