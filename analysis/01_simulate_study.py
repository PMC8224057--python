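"""Generate the synthetic study inputs.

Writes the longitudinal translocation table for the gold arm (3 species x
{10, 30, 60, 240} min x 3 replicates) and the silver arm, a reference and a
sample spICP-MS event stream, and an EAF4 field series — everything the
downstream fitting and reduction steps consume.
"""

import pathlib
import sys

import pandas as pd

from nanotrans.spicpms import AcquisitionConfig, IonicCalibration
from nanotrans.synth import (AG_STUDY_DESIGN, AU_STUDY_DESIGN,
                             default_population_parameters,
                             generate_event_stream, generate_field_series,
                             generate_translocation)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    params = default_population_parameters()
    au = generate_translocation(params, AU_STUDY_DESIGN, seed=SEED)
    au.to_csv(OUT / "translocation_au.csv")
    ag = generate_translocation(params, AG_STUDY_DESIGN, seed=SEED + 1)
    ag.to_csv(OUT / "translocation_ag.csv")
    print(f"gold arm: {len(au)} observations, species {au.species}")
    print(f"silver arm: {len(ag)} observations")

    cal = IonicCalibration(slope=20.0)
    config = AcquisitionConfig(neb_efficiency=0.058)
    ref = generate_event_stream(5e7, config=config, cal=cal,
                                size_median_nm=58.0, seed=SEED + 2)
    ref.to_csv(OUT / "spicpms_reference_58nm.csv")
    config.to_yaml(OUT / "spicpms_config.yaml")
    n_spikes = int((ref.intensities > 100).sum())
    print(f"reference stream: {len(ref)} dwells, ~{n_spikes} particle events")

    series = generate_field_series(-2.74e-8, timing_noise_rel=0.01, seed=SEED + 3)
    pd.DataFrame({"field_v_per_m": series.fields_v_m,
                  "retention_min": series.retention_min}
                 ).to_csv(OUT / "eaf4_field_series.csv", index=False)
    print(f"EAF4 series: {series.fields_v_m.size} fractionations, "
          f"fields 0-{series.fields_v_m.max():.0f} V/m")


if __name__ == "__main__":
    main()
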