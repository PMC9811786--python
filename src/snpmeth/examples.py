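"""Published worked-example inputs.

Small printed tables from blood/brain methylation cohort analyses of
suicide-attempt severity and depression, used to exercise the Wald and FDR
arithmetic against their printed outputs, plus the cohort counts behind the
group-percentage summaries.  These are inputs (rounded to the precision
they were printed at), not values this package estimates.
"""

from __future__ import annotations

import pandas as pd

#: suicide-severity logistic model: printed beta and SE per coefficient
SEVERITY_LOGISTIC_COEFS = pd.DataFrame(
    [
        ("intercept", -17.163, 6.029),
        ("methylation_m", 4.437, 1.505),
        ("sex", -1.728, 0.582),
        ("age", -0.012, 0.022),
        ("batch", -1.422, 1.479),
        ("personality_disorder", 0.649, 0.599),
        ("alcohol_addiction", 0.955, 0.676),
    ],
    columns=["coef", "beta", "se"],
).set_index("coef")

#: methylation-transcript models: printed raw p-values (six CpG x probe pairs)
TRANSCRIPT_MODEL_RAW_P = [0.8066, 0.834, 0.0102, 0.5613, 0.0582, 0.4646]

#: the printed FDR-adjusted column for the same six models
TRANSCRIPT_MODEL_ADJ_P_PRINTED = [0.834, 0.834, 0.0611, 0.834, 0.1747, 0.834]

#: suicide cohort: severe vs not-severe attempt counts
SEVERITY_GROUP_COUNTS = {"severe": 31, "not_severe": 57}

#: adolescent screening cohort: depression-risk group counts
RISK_GROUP_COUNTS = {"high": 24, "low": 197}

#: trauma-project cohort: initial size and rows removed for missing covariates
TRAUMA_COHORT_TOTAL = 422
TRAUMA_COHORT_MISSING = 45
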