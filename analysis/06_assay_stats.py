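"""Assay statistics: viability normalisation, qPCR fold change, Welch tests.

Simulates plate readings and qPCR cycle thresholds with realistic noise,
reduces them with the package operations, and prints the normalised
viability with significance stars and the fold-change decisions against
the two-fold upregulation threshold.
"""

import sys

import numpy as np

from nanotrans.assays import (PlateReadings, QpcrRecord,
                              relative_quantification, upregulation_flag,
                              viability_percent, welch_test)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    rng = np.random.default_rng(SEED)
    control = rng.normal(10000.0, 150.0, size=6)
    scenarios = {
        "AuNP 2 h (no effect)": rng.normal(10050.0, 160.0, size=6),
        "AgNP 24 h (toxic)": rng.normal(4770.0, 120.0, size=6),
        "positive control (TritonX)": rng.normal(220.0, 40.0, size=6),
    }
    print("alamarBlue viability vs untreated control (= 100%):")
    for name, wells in scenarios.items():
        readings = PlateReadings(treated=wells, negative_control=control)
        v = viability_percent(readings)
        w = welch_test(wells, control)
        print(f"  {name:<28s} {v.percent:6.2f} +/- {v.sd_percent:.2f} %  "
              f"p = {w.p_value:.2e} {w.stars}")

    print("\nqPCR 2^-ddCT fold change (reference HPRT1, 2-fold threshold):")
    base_ref = 20.0
    for gene, shift in (("CAT", 0.1), ("GPX1", -0.3)):
        record = QpcrRecord(
            sample_target_ct=rng.normal(25.0 - shift, 0.05, size=3),
            sample_reference_ct=rng.normal(base_ref, 0.05, size=3),
            control_target_ct=rng.normal(25.0, 0.05, size=3),
            control_reference_ct=rng.normal(base_ref, 0.05, size=3),
        )
        rq = relative_quantification(record)
        flag = "UPREGULATED" if upregulation_flag(rq) else "no effect"
        print(f"  {gene}: RQ = {rq:.2f}  ({flag})")


if __name__ == "__main__":
    main()
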