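"""Generate reproducible synthetic record files for experiments.

Writes sample.csv / test.csv in the package's CSV dialect.  Identical
configuration (including the seed) always yields byte-identical files.
"""

import tempfile
from pathlib import Path

from glucoguide import GeneratorConfig, generate, write_records

out_dir = Path(tempfile.mkdtemp(prefix="glucoguide_"))
sample, test = generate(
    GeneratorConfig(n_sample=200, n_test=100, seed=42,
                    label_mode="noisy", noise_p=0.2)
)
write_records(sample, out_dir / "sample.csv")
write_records(test, out_dir / "test.csv")

print(f"wrote {len(sample)} sample and {len(test)} test records to {out_dir}/")
print("first sample record:", sample[0])
print()
print("Each record: hour of day, blood sugar (mg/dL), systolic/diastolic "
      "pressure (mmHg), exercise and meal calories (at most one nonzero), "
      "daily calorie target, and a 1-5 treatment label.")
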