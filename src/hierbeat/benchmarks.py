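"""Published reference numbers for the MIT-BIH inter-patient benchmark.

These are the printed results of the hierarchical random-projection /
RR-ratio system evaluated on the standard inter-patient division of the
MIT-BIH arrhythmia database (DS1 trains, DS2 tests, paced records
excluded). They serve as worked-example inputs: the evaluation module must
reproduce every derived percentage from the raw counts, and the
model-selection criterion must reproduce the tabulated Ave values from the
tabulated rates. Nothing here is used to fit anything.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix

#: Final-system confusion matrix on the test division DS2 (reference classes
#: N,S,V,F,Q by algorithm classes N,S,V); 49,711 beats in total.
DS2_REFERENCE_CONFUSION = ConfusionMatrix(
    pd.DataFrame(
        np.array(
            [
                [41931, 2146, 181],
                [98, 1673, 66],
                [52, 144, 3025],
                [333, 1, 54],
                [4, 0, 3],
            ]
        ),
        index=["N", "S", "V", "F", "Q"],
        columns=["N", "S", "V"],
    )
)

#: DS1 leave-one-recording-out CV rates at the optimal parameters
#: (delta=1.3, C=1, lead A): Se_N, PP_N, Se_V, PP_V in percent.
DS1_CV_LEAD_A_RATES = {"se_n": 95.4, "pp_n": 97.4, "se_v": 83.1, "pp_v": 57.0}

#: DS2 test rates for the same configuration.
DS2_TEST_LEAD_A_RATES = {"se_n": 99.2, "pp_n": 95.2, "se_v": 93.9, "pp_v": 90.9}

#: Class totals of the inter-patient division (beats per AAMI class).
DATASET_CLASS_TOTALS = {
    "DS1": {"N": 45868, "S": 942, "V": 3787, "F": 415, "Q": 8, "total": 51020},
    "DS2": {"N": 44258, "S": 1837, "V": 3221, "F": 388, "Q": 7, "total": 49711},
}
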