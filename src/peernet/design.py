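"""Covariate encoding shared by the simulator and the model fitters.

Age enters the models only as Age x AgeObserved (centered age, zeroed where
age is missing) together with the AgeObserved indicator main effect, so the
age slope is informed solely by physicians whose age is known while missing
ages do not drop observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Covariate column order used throughout the package.
COVARIATES = ("age", "age_observed", "sex_male", "years_org")


def covariate_frame(physicians: pd.DataFrame) -> pd.DataFrame:
    """Encode physician attributes as model covariates.

    ``age`` is (age - mean observed age) x AgeObserved, ``age_observed`` is
    the 0/1 observation indicator, ``sex_male`` is the 0/1 male indicator and
    ``years_org`` is years with the physician organization, untransformed.
    """
    obs = physicians["age_observed"].astype(float)
    age = pd.to_numeric(physicians["age"], errors="coerce")
    center = age[obs > 0].mean()
    age_term = ((age - center) * obs).fillna(0.0)
    return pd.DataFrame(
        {
            "age": age_term,
            "age_observed": obs,
            "sex_male": (physicians["sex"] == "M").astype(float),
            "years_org": physicians["years_org"].astype(float),
        },
        index=physicians.index,
    )
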