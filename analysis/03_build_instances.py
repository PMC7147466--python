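#!/usr/bin/env python
"""Turn each usable night into a labeled learning instance.

One instance per night: 29 pre-sleep features (6 h before sleep onset)
and a binary label marking whether any glucose reading fell below
70 mg/dL in the 6 h after onset.  Nights with under 80% CGM coverage in
either window are dropped.  Writes scratch/instances.csv plus the
class-count bookkeeping table (results/instance_counts.csv) and the
feature catalog sidecar.
"""

import json
from pathlib import Path

from nhpredict.instances import class_count_summary, feature_catalog_json, instances_to_frame
from nhpredict.pipeline import patient_instances, prepare_patient
from nhpredict.synthetic import read_raw_exports

ROOT = Path(__file__).resolve().parents[1]
RAW_DIR = ROOT / "scratch" / "raw"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    instances = []
    for patient_dir in sorted(RAW_DIR.iterdir()):
        pid = patient_dir.name
        prep = prepare_patient(pid, read_raw_exports(patient_dir))
        nights = patient_instances(prep)
        instances.extend(nights)
        pos = sum(ni.y for ni in nights)
        print(f"{pid}: {len(nights)} instances, {pos} with nocturnal hypoglycemia")
    frame = instances_to_frame(instances)
    frame.to_csv(ROOT / "scratch" / "instances.csv", index=False,
                 lineterminator="\n", float_format="%.6f")
    counts = class_count_summary(instances)
    counts.to_csv(RESULTS / "instance_counts.csv", index=False, lineterminator="\n")
    (RESULTS / "feature_catalog.json").write_text(
        json.dumps(feature_catalog_json(), indent=2) + "\n")
    total = len(frame)
    pos = int(frame["label"].sum())
    print(f"\ncohort: {total} instances, {pos} Class 1 ({100 * pos / total:.1f}% of nights)")
    print(counts.to_string(index=False))


if __name__ == "__main__":
    main()
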