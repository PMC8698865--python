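import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fspibr import synthetic

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    return synthetic.build_design()


def random_panel(rng, n_d6=(4, 5), n_d12=(3, 4),
                 biomarkers=("SOD", "CAT", "DNAd")):
    """A small random long-format panel with both days, two species and two
    treatments; values are positive lognormals."""
    rows = []
    for si, sp in enumerate(("R_decussatus", "R_philippinarum")):
        for k in range(n_d6[si]):
            for b in biomarkers:
                rows.append((f"{sp[:4]}d6a{k}", sp, "CT", 6,
                             f"{sp[:4]}_d6_{k}", b,
                             float(rng.lognormal(1.0, 0.4)), ""))
        for tr in ("CT", "HW"):
            for k in range(n_d12[si]):
                for b in biomarkers:
                    rows.append((f"{sp[:4]}{tr}a{k}", sp, tr, 12,
                                 f"{sp[:4]}_{tr}_{k}", b,
                                 float(rng.lognormal(1.2, 0.5)), ""))
    return pd.DataFrame(rows, columns=[
        "aquarium_id", "species", "treatment", "day", "individual_id",
        "biomarker", "value", "unit"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
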