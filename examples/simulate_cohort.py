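"""Generate a small synthetic acquisition cohort on disk.

Writes a desk-scale cohort (2 patients per class, 2 containers each, 2
acquisitions per container) in the acquisition dialect: one CSV of 32
voltage traces per acquisition plus a JSON sidecar with provenance and the
socket-to-sensor map.  The full clinical design (20+20 patients, 4
containers, 5 acquisitions) produces 800 such files.
"""

import tempfile
from pathlib import Path

from enose import SyntheticConfig, read_acquisition, simulate_cohort

config = SyntheticConfig(
    n_patients_per_class=2, containers_per_patient=2, acquisitions_per_container=2, seed=0
)
with tempfile.TemporaryDirectory() as tmp:
    manifest = simulate_cohort(config, tmp)
    print(f"wrote {len(manifest)} acquisition files under {tmp}")
    first = manifest[0]
    curves = read_acquisition(first.path)
    print(f"{first.path.name}: patient {first.patient_id} (label {first.label}), "
          f"{len(curves)} curves of {curves[0].samples.size} samples")
    print(f"cohort would yield {len(manifest) * 32} classifier instances "
          f"({config.containers_per_patient * config.acquisitions_per_container * 32} per patient)")
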