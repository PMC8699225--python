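"""Thin adapter turning ML variable importance into SNP weights.

Baseline learners and permutation importance are delegated to
scikit-learn; only the importance -> nonnegative weight mapping lives
here.  The weighted-GRM construction is agnostic to where weights come
from, so these vectors plug in exactly like GWAS score weights.
"""

from __future__ import annotations

import numpy as np

from polygs.dosage_io import DosageMatrix, PhenotypeVector
from polygs.grm import WeightVector

_ESTIMATORS = ("rf", "svr")


def permutation_importance_weights(
    d: DosageMatrix,
    y: PhenotypeVector,
    estimator: str = "rf",
    n_repeats: int = 5,
    seed: int = 0,
    floor_eps: float = 1e-6,
    normalization: str = "mean_one",
    **estimator_kwargs,
) -> WeightVector:
    """Fit a baseline regressor and use permutation importance as weights.

    Negative importances (pure noise features) are floored at
    ``floor_eps`` so the resulting vector is a valid GRM weight.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance
    from sklearn.svm import SVR

    if d.sample_ids != y.sample_ids:
        raise ValueError("genotypes and phenotypes are not aligned; call align first")
    if d.has_missing:
        raise ValueError("impute missing genotypes before computing importance")

    if estimator == "rf":
        model = RandomForestRegressor(
            n_estimators=estimator_kwargs.pop("n_estimators", 200),
            random_state=seed,
            **estimator_kwargs,
        )
    elif estimator == "svr":
        model = SVR(**estimator_kwargs)
    else:
        raise ValueError(f"unknown estimator {estimator!r}; known: {_ESTIMATORS}")

    X = d.values
    model.fit(X, y.values)
    imp = permutation_importance(
        model, X, y.values, n_repeats=n_repeats, random_state=seed
    )
    w = np.maximum(imp.importances_mean, floor_eps)
    return WeightVector(
        w,
        source=f"importance:{estimator}",
        normalization=normalization,
        marker_ids=d.marker_ids,
    )
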