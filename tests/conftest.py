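import pandas as pd
import pytest

from nanotrans.kinetics import KineticRates
from nanotrans.nlme import PopulationParameters, TranslocationDataset


@pytest.fixture
def default_rates() -> KineticRates:
    return KineticRates(k12=0.002, k21=0.005, k23=0.007, k32=0.003)


@pytest.fixture
def default_params(default_rates) -> PopulationParameters:
    return PopulationParameters(phi=0.69, omega2=0.08**2, rates=default_rates,
                                sigma1=0.15, sigma2=0.01)


@pytest.fixture
def small_dataset() -> TranslocationDataset:
    """Hand-built two-species dataset, strictly positive observations."""
    rows = []
    for species, offset in (("A", 0.0), ("B", 0.05)):
        for t, (ap, ba) in zip((10.0, 60.0, 240.0),
                               ((0.66, 0.002), (0.60, 0.02), (0.45, 0.09))):
            for rep in (1, 2):
                rows.append({"species": species, "replicate": rep,
                             "time_min": t, "compartment": "apical",
                             "fraction": ap + offset + 0.01 * rep})
                rows.append({"species": species, "replicate": rep,
                             "time_min": t, "compartment": "basolateral",
                             "fraction": ba + 0.005 * rep})
    return TranslocationDataset(pd.DataFrame(rows))
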