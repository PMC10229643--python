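"""Independent brute-force re-implementation of the nested-CV loop.

Used as the oracle against which the package's nested cross-validation is
checked; deliberately shares no loop code with the implementation (only the
scikit-learn estimator and metric primitives, and the seed-derivation
convention, which is part of the contract under test).
"""

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import mean_absolute_error, r2_score

from medopt.design import derive_seed


def brute_force_nested_cv(X, y, settings, seed, n_outer=5, n_inner=5):
    """Returns (mae, r2, rmse) arrays over the outer folds."""
    perm = np.random.default_rng(seed).permutation(len(y))
    outer = [np.sort(f) for f in np.array_split(perm, n_outer)]
    bf_mae, bf_r2, bf_rmse = [], [], []
    for fold_i, test_idx in enumerate(outer):
        tr = np.setdiff1d(np.arange(len(y)), test_idx)
        inner_seed = derive_seed(seed, "inner", fold_i)
        inner_perm = np.random.default_rng(inner_seed).permutation(len(tr))
        inner_folds = [np.sort(f) for f in np.array_split(inner_perm, n_inner)]
        best, best_score = None, np.inf
        for params in settings:
            scores = []
            for itest in inner_folds:
                itr = np.setdiff1d(np.arange(len(tr)), itest)
                est = GradientBoostingRegressor(random_state=inner_seed, **params)
                est.fit(X[tr][itr], y[tr][itr])
                scores.append(mean_absolute_error(y[tr][itest], est.predict(X[tr][itest])))
            sc = float(np.mean(scores))
            if sc < best_score - 1e-15:
                best, best_score = params, sc
        est = GradientBoostingRegressor(random_state=inner_seed, **best)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[test_idx])
        bf_mae.append(mean_absolute_error(y[test_idx], pred))
        bf_r2.append(r2_score(y[test_idx], pred))
        bf_rmse.append(float(np.sqrt(np.mean((pred - y[test_idx]) ** 2))))
    return np.array(bf_mae), np.array(bf_r2), np.array(bf_rmse)
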