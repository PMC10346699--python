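"""Group-level statistical screens.

Two complementary screens compare the control and inoculated groups:

* per-feature two-tailed t-tests (Welch's unequal-variance test by default;
  the pooled-variance variant is available behind a flag), and
* PLS-DA — partial least squares regression against a {0, 1}-coded class
  response with Monte Carlo cross-validation: repeated random 70:30
  train/test partitions, features standardized on each training set, test
  samples classified by predicted response >= 0.5.

A comparison report merges p-values from all screens on a -log10 scale with
the conventional 0.05 significance reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.preprocessing import StandardScaler

from .root_detection import split_train_validation

logger = logging.getLogger(__name__)

Array = np.ndarray

#: -log10 of the conventional significance level, the reference line of the
#: cross-approach comparison
SIGNIFICANCE_REFERENCE = -math.log10(0.05)


@dataclass
class TTestResult:
    feature_name: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    group_means: tuple[float, float]


@dataclass
class MCCVResult:
    n_iterations: int
    train_fraction: float
    train_accuracies: Array
    test_accuracies: Array

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean(self.train_accuracies))

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean(self.test_accuracies))


def two_tailed_t_test(sample_a: Array, sample_b: Array,
                      feature_name: str = "", equal_var: bool = False) -> TTestResult:
    """Two-tailed two-sample t-test (Welch by default).

    NaNs are dropped per sample.  When both samples are constant and equal
    the statistic is undefined; the result is reported as t = 0, p = 1 (no
    evidence of a difference).  Requires at least two finite values per
    sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two finite values")
    if np.var(a) == 0.0 and np.var(b) == 0.0 and a.mean() == b.mean():
        return TTestResult(feature_name, 0.0, float(len(a) + len(b) - 2), 1.0,
                           (float(a.mean()), float(b.mean())))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        feature_name=feature_name,
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
    )


def benjamini_hochberg(p_values: Array) -> Array:
    """Benjamini-Hochberg adjusted p-values (FDR).  Off by default in the
    screens, which report raw p-values; provided for sensitivity checks."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def ttest_table(features: pd.DataFrame, group_col: str = "group",
                groups: tuple[str, str] = ("control", "inoculated"),
                feature_cols: list[str] | None = None,
                equal_var: bool = False,
                fdr_adjust: bool = False) -> pd.DataFrame:
    """Welch t-tests for every feature column of a per-plant table.

    With ``fdr_adjust`` a Benjamini-Hochberg ``q`` column is appended; the
    default output carries raw p-values only.
    """
    cols = feature_cols or [c for c in features.columns
                            if c not in (group_col, "plant_id")]
    ga = features[features[group_col] == groups[0]]
    gb = features[features[group_col] == groups[1]]
    rows = []
    for col in cols:
        r = two_tailed_t_test(ga[col].to_numpy(), gb[col].to_numpy(),
                              feature_name=col, equal_var=equal_var)
        rows.append({
            "feature": col,
            f"mean_{groups[0]}": r.group_means[0],
            f"mean_{groups[1]}": r.group_means[1],
            "t": r.t_statistic,
            "df": r.degrees_of_freedom,
            "p": r.p_value,
        })
    table = pd.DataFrame(rows)
    if fdr_adjust:
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
    return table


def plsda_fit_predict(X_train: Array, y_train: Array, X_test: Array,
                      n_components: int) -> tuple[Array, Array]:
    """One PLS-DA fit: standardize on the training set, regress the {0, 1}
    response on the standardized features, return predicted responses for
    train and test samples."""
    scaler = StandardScaler().fit(X_train)
    Xtr = scaler.transform(X_train)
    Xte = scaler.transform(X_test)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xtr, np.asarray(y_train, dtype=float))
    return pls.predict(Xtr).ravel(), pls.predict(Xte).ravel()


def plsda_mccv(features: Array, labels: Array, train_fraction: float = 0.7,
               n_iterations: int = 1000, n_components: int = 2,
               seed: int = 0) -> MCCVResult:
    """PLS-DA with Monte Carlo cross-validation.

    Per iteration: a seeded random ``train_fraction`` split, training-set
    standardization, a PLS regression of the standardized features on the
    {0, 1}-coded response, and classification of train and test samples at
    the 0.5 response threshold (ties to class 1).  Iterations that draw a
    single-class training set are resampled (logged).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("plsda_mccv requires exactly two classes")
    y01 = (y == classes[1]).astype(float)
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
        raise ValueError("need at least two samples per class")
    n = len(y01)
    n_comp = min(n_components, X.shape[1])
    rng = np.random.default_rng(seed)
    train_acc = np.empty(n_iterations)
    test_acc = np.empty(n_iterations)
    for it in range(n_iterations):
        for _ in range(100):
            split_seed = int(rng.integers(0, 2**31 - 1))
            tr, te = split_train_validation(n, train_fraction, split_seed)
            if len(np.unique(y01[tr])) == 2:
                break
            logger.info("resampled single-class training draw at iteration %d", it)
        else:
            raise RuntimeError("could not draw a two-class training set")
        resp_tr, resp_te = plsda_fit_predict(X[tr], y01[tr], X[te],
                                             min(n_comp, len(tr) - 1))
        pred_tr = (resp_tr >= 0.5).astype(float)
        pred_te = (resp_te >= 0.5).astype(float)
        train_acc[it] = float(np.mean(pred_tr == y01[tr]))
        test_acc[it] = float(np.mean(pred_te == y01[te]))
    return MCCVResult(n_iterations, train_fraction, train_acc, test_acc)


def build_comparison_report(p_values_by_approach: dict[str, dict[str, float]],
                            ) -> pd.DataFrame:
    """Merge per-approach p-values into one -log10-scale comparison table.

    ``p_values_by_approach`` maps an approach name (e.g. shoot vegetation
    indices, root color, root structure) to a {feature: p} mapping.  Zero
    p-values are clipped to the smallest positive float (logged).  The
    returned frame carries the -log10(0.05) reference in
    ``df.attrs["reference"]``.
    """
    rows = []
    for approach, pvals in p_values_by_approach.items():
        for feat, p in pvals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value out of range for {approach}/{feat}: {p}")
            if p == 0.0:
                logger.warning("p=0 clipped for %s/%s", approach, feat)
                p = np.nextafter(0.0, 1.0)
            rows.append({
                "approach": approach,
                "feature": feat,
                "p_value": p,
                "minus_log10_p": -math.log10(p),
            })
    df = pd.DataFrame(rows, columns=["approach", "feature", "p_value", "minus_log10_p"])
    df.attrs["reference"] = SIGNIFICANCE_REFERENCE
    return df
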