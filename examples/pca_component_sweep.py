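"""Sweep the PCA explained-variance threshold and watch test error stabilize.

Builds data with five planted orthogonal signal directions (the label
depends on the weakest), then sweeps the cumulative explained-variance
threshold.  Test error should drop sharply once the fifth principal
component is retained and stay flat afterwards — the same stabilization
curve used to pick an operating threshold on real cohorts.
"""

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from tsdpso import FeatureTable, sweep_n_components

rng = np.random.default_rng(0)
n = 600
z = rng.normal(size=(n, 8)) * np.array([8, 6, 5, 4, 3, 0.3, 0.3, 0.3])
mixing, _ = np.linalg.qr(rng.normal(size=(8, 8)))
table = FeatureTable(
    pd.DataFrame(z @ mixing.T, columns=[f"f{i}" for i in range(8)]),
    pd.Series((z[:, 4] > 0).astype(int)),
)


def holdout_error(t: FeatureTable) -> float:
    xtr, xte, ytr, yte = train_test_split(
        t.features.to_numpy(), t.labels.to_numpy(), random_state=0, test_size=0.3
    )
    clf = LogisticRegression().fit(xtr, ytr)
    return float(np.mean(clf.predict(xte) != yte))


curve = sweep_n_components(table, [0.3, 0.5, 0.7, 0.9, 0.999], holdout_error)
print(curve.to_string(index=False))
print("Retaining fewer than 5 components misses the label-bearing direction")
print("(error near 0.5); from 5 on, the error stabilizes near its floor.")
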