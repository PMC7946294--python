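"""Wake-vs-anesthesia classification with nested leave-one-pair-out CV.

Features are the pipeline's outputs per channel set: a single mechanism's
phi (1 feature), the full IIS (2**k - 1 features), or system-level Phi
(1 feature).  Samples come in wake/anesthesia *pairs* (same epoch within a
subject, or same subject across subjects), and cross-validation always
leaves out whole pairs so the two classes stay balanced in every split.

The classifier is an L2-regularized squared-hinge linear SVM.  The cost
parameter is chosen by an inner leave-one-pair-out loop over a fixed grid of
11 powers spanning 2**-50 .. 2**50 in decade steps of the exponent;
inner-accuracy ties go to the lowest cost.  Features are z-scored with the
training fold's statistics only (population SD; zero-SD features map to 0),
so no information leaks from test pairs into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .pipeline import mechanism_sizes
from .synthetic import ANESTHESIA, WAKE

#: 2^-50, 2^-40, ..., 2^50 — exponent steps of 10
COST_GRID = tuple(float(2.0**e) for e in range(-50, 51, 10))


@dataclass
class CVResult:
    """Outcome of one nested leave-one-pair-out run."""

    accuracy: float
    fold_accuracies: np.ndarray
    chosen_costs: list = field(default_factory=list)
    unit: str = ""


def zscore_fit_apply(train: np.ndarray, test: np.ndarray):
    """Standardize both sets with the training mean/SD (population SD).

    Zero-SD (constant) features map to 0 in both sets rather than NaN.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.size == 0:
        raise ValueError("empty training set")
    if train.shape[1] != test.shape[1]:
        raise ValueError("train and test must share the feature dimension")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)  # population convention (ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    train_z = np.where(sd > 0, (train - mu) / safe, 0.0)
    test_z = np.where(sd > 0, (test - mu) / safe, 0.0)
    return train_z, test_z


def train_linear_svm(train: np.ndarray, labels: np.ndarray, cost: float):
    """L2-regularized, L2-loss (squared hinge) linear SVM at penalty ``cost``."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    clf = LinearSVC(
        C=cost,
        penalty="l2",
        loss="squared_hinge",
        dual=True,
        tol=1e-5,
        max_iter=2_000,
        random_state=0,
    )
    with warnings.catch_warnings():
        # the extreme ends of the cost grid legitimately hit the iteration
        # cap; the fitted model is still deterministic given the data
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(train, labels)
    return clf


def _fit_score(train_pairs, test_pairs, cost):
    """Train on pair-structured features, return accuracy on test pairs."""
    Xtr = train_pairs.reshape(-1, train_pairs.shape[-1])
    ytr = np.tile([1, 0], train_pairs.shape[0])
    Xte = test_pairs.reshape(-1, test_pairs.shape[-1])
    yte = np.tile([1, 0], test_pairs.shape[0])
    Xtr, Xte = zscore_fit_apply(Xtr, Xte)
    clf = train_linear_svm(Xtr, ytr, cost)
    return float(np.mean(clf.predict(Xte) == yte))


def nested_loo_pair_cv(
    features: np.ndarray,
    cost_grid=COST_GRID,
    unit: str = "",
) -> CVResult:
    """Nested leave-one-pair-out cross-validation.

    Parameters
    ----------
    features
        Array of shape ``(n_pairs, 2, n_features)``; along axis 1 the first
        sample is the wake member of the pair, the second the anesthesia
        member.
    cost_grid
        Candidate SVM costs, ascending; inner ties pick the lowest.

    The outer loop holds out one pair; the inner loop (over the remaining
    pairs) picks the cost with the best inner leave-one-pair-out accuracy;
    the final model is retrained on all inner pairs at that cost and scored
    on the held-out pair.  Accuracy is the mean over outer folds.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 3 or features.shape[1] != 2:
        raise ValueError("features must have shape (n_pairs, 2, n_features)")
    n_pairs = features.shape[0]
    if n_pairs < 3:
        raise ValueError("nested pair CV needs at least 3 pairs")
    cost_grid = sorted(cost_grid)
    fold_acc = np.empty(n_pairs)
    chosen = []
    for outer in range(n_pairs):
        inner_idx = np.array([p for p in range(n_pairs) if p != outer])
        inner = features[inner_idx]
        best_cost, best_acc = None, -1.0
        for cost in cost_grid:
            accs = []
            for v in range(inner.shape[0]):
                tr = np.delete(inner, v, axis=0)
                accs.append(_fit_score(tr, inner[v : v + 1], cost))
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:  # ties keep the lower cost
                best_acc = acc
                best_cost = cost
        chosen.append(best_cost)
        fold_acc[outer] = _fit_score(
            inner, features[outer : outer + 1], best_cost
        )
    return CVResult(float(fold_acc.mean()), fold_acc, chosen, unit)


def aggregate_by_mechanism_size(per_mechanism: np.ndarray, k: int = 4) -> dict:
    """Mean accuracy per mechanism size (k=4: over 4, 6, 4 and 1 mechanisms)."""
    per_mechanism = np.asarray(per_mechanism, dtype=float)
    sizes = mechanism_sizes(k)
    if per_mechanism.shape[0] != sizes.size:
        raise ValueError(
            f"expected {sizes.size} mechanism accuracies, got "
            f"{per_mechanism.shape[0]}"
        )
    return {
        int(s): float(per_mechanism[sizes == s].mean())
        for s in np.unique(sizes)
    }


def _phi_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("phi_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def _pair_features(table, cols, pair_field, pair_values):
    """Stack (n_pairs, 2, d) arrays: wake then anesthesia per pair."""
    out = np.empty((len(pair_values), 2, len(cols)))
    for p, val in enumerate(pair_values):
        for c, cond in enumerate((WAKE, ANESTHESIA)):
            sel = table[
                (table[pair_field] == val) & (table["condition"] == cond)
            ]
            if len(sel) != 1:
                raise ValueError(
                    f"expected exactly one {cond} row for {pair_field}={val}"
                )
            out[p, c] = sel[cols].to_numpy()[0]
    return out


def decode_study(
    table: pd.DataFrame,
    feature: str = "iis",
    mode: str = "within",
    cost_grid=COST_GRID,
) -> pd.DataFrame:
    """Decode condition from a study table, per channel set.

    ``feature``: ``"iis"`` (all mechanism phis), ``"big_phi"``, or ``"mech"``
    (each mechanism separately, one row per mechanism).  ``mode``:
    ``"within"`` pairs the epochs of one subject (one CV per subject);
    ``"across"`` pairs the subjects at one epoch (one CV per epoch).

    Returns a tidy frame with columns unit, channel_set, feature, mechanism
    (empty unless ``feature="mech"``), accuracy.
    """
    if mode not in ("within", "across"):
        raise ValueError("mode must be 'within' or 'across'")
    phi_cols = _phi_columns(table)
    if feature == "iis":
        col_sets = [("", phi_cols)]
    elif feature == "big_phi":
        col_sets = [("", ["big_phi"])]
    elif feature == "mech":
        col_sets = [(c.split("_")[1], [c]) for c in phi_cols]
    else:
        raise ValueError("feature must be 'iis', 'big_phi' or 'mech'")

    pair_field = "epoch" if mode == "within" else "subject"
    unit_field = "subject" if mode == "within" else "epoch"
    rows = []
    for cset in sorted(table["channel_set"].unique()):
        sub_set = table[table["channel_set"] == cset]
        for unit in sorted(sub_set[unit_field].unique()):
            sub = sub_set[sub_set[unit_field] == unit]
            pair_values = sorted(sub[pair_field].unique())
            for mech_id, cols in col_sets:
                feats = _pair_features(sub, cols, pair_field, pair_values)
                res = nested_loo_pair_cv(
                    feats, cost_grid=cost_grid, unit=str(unit)
                )
                rows.append(
                    {
                        "unit": unit,
                        "channel_set": cset,
                        "feature": feature,
                        "mechanism": mech_id,
                        "accuracy": res.accuracy,
                        "n_pairs": feats.shape[0],
                    }
                )
    return pd.DataFrame(rows)
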