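"""EAF4 retention shifts -> electrophoretic mobility -> zeta potential.

Recovers the mobility from the simulated field series, then converts the
eight published mobility measurements (four particle species in ultrapure
water and in cell culture medium) to zeta potentials with the fixed medium
constants.
"""

import pathlib
import sys

import pandas as pd

from nanotrans.eaf4 import FieldSeries, mobility_from_field_series, zeta_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frame = pd.read_csv(OUT / "eaf4_field_series.csv")
    series = FieldSeries(frame["field_v_per_m"].to_numpy(),
                         frame["retention_min"].to_numpy(),
                         cross_flow_ml_min=0.15)
    res = mobility_from_field_series(series)
    print(f"recovered mobility: {res.mobility_m2_v_s:.3e} "
          f"+/- {res.uncertainty_m2_v_s:.1e} m^2/(V s), R^2 = {res.r_squared:.3f}")

    table = zeta_table()
    table.to_csv(OUT / "zeta_table.csv", index=False)
    print("\nmobility -> zeta conversions (eta_visc = 8.872e-4 Pa s, "
          "eps_r = 78.4, f(ka) = 1.5):")
    for _, row in table.iterrows():
        print(f"  {row['species']:>9s} {row['solvent']}: "
              f"{row['mobility_e8_m2_v_s']:+.2f}e-8 m^2/(V s) -> "
              f"{row['zeta_mv']:+.1f} +/- {row['zeta_sd_mv']:.1f} mV")


if __name__ == "__main__":
    main()
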