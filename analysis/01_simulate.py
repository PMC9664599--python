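"""Generate the synthetic multi-site facility dataset.

Emulates the study sample: 27 district, 16 private and 11 tertiary hospitals
across 11 states, each with several specialties holding OP/IP and (in the
configured fractions) ICU/OT cost centres. Writes the three pipeline input
tables under results/data/ and prints the sample profile (median and IQR of
beds, ALOS and bed occupancy per provider type and city tier).
"""

import sys
from pathlib import Path

from hospicost import default_study_config, generate_dataset
from hospicost.io import config_hash, write_tables
from hospicost.report import profile_table

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 1) -> None:
    config = default_study_config(seed=seed)
    dataset = generate_dataset(config)
    paths = write_tables(dataset, OUT)
    profile = profile_table(dataset.utilization, dataset.facilities)
    profile.to_csv(OUT.parent / "sample_profile.csv", index=False)

    print(f"config {config_hash(config)}, seed {seed}")
    print(
        f"{len(dataset.facilities)} facilities, {len(dataset.utilization)} specialties, "
        f"{len(dataset.line_items)} resource line items -> {OUT}"
    )
    print(profile.round(2).to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
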