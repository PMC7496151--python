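import math

import pytest

from cce.quantal import QuantalDataset
from cce.severity import SeverityCategory


def make_dataset(
    compound="A",
    *,
    background=0.05,
    beta=100.0,
    steepness=1.0,
    doses=(0.0, 50.0, 100.0, 200.0),
    group_size=1000,
    severity=3,
    noise_free=True,
    n_affected=None,
    lesion_term="adenocarcinoma",
    exposure_weeks=104,
):
    """Incidence table from the quantal exponential curve.

    With ``noise_free`` the affected counts are the expected counts rounded
    to integers, so the maximum-likelihood fit should recover the generating
    parameters up to rounding.
    """
    if n_affected is None:
        assert noise_free
        n_affected = [
            round(
                group_size
                * (
                    background
                    + (1 - background) * (-math.expm1(-((d / beta) ** steepness)))
                )
            )
            for d in doses
        ]
    return QuantalDataset(
        compound_id=compound,
        lesion_term=lesion_term,
        severity=SeverityCategory(severity),
        tissue="lung",
        sex="m",
        tumor_type=lesion_term,
        exposure_weeks=exposure_weeks,
        study_weeks=104,
        doses=doses,
        n_at_risk=[group_size] * len(doses),
        n_affected=n_affected,
    )


@pytest.fixture(scope="session")
def case_inputs():
    """(e_cig, e_htp, rpf) bound mappings of the packaged 8-compound study."""
    from cce.tables import case_study_inputs

    return case_study_inputs()
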