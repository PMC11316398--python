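"""Association ranking of pathway-level and raw input features.

Each unit (pathway score column or raw feature) is tested for univariate
association with the binary phenotype. The default test is the logistic
score test of the slope in ``logit P(y=1) = a + b x`` — it is well defined
under complete separation (unlike the Wald test), reduces to a chi-square
on one degree of freedom, and is applied identically at both levels for
internal consistency. A Wilcoxon rank-sum alternative is available. P
values are reported nominally; a Benjamini–Hochberg column is added for
information only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stage1 import PathwayFeatureMatrix, columnwise_pcc

__all__ = [
    "logistic_score_test",
    "association_pvalues",
    "pathway_feature_stats",
    "input_feature_stats",
]

P_FLOOR = 1e-300  # smaller P values are clamped and flagged


def logistic_score_test(x, y) -> float:
    """Two-sided P for the slope score test of a univariate logistic model.

    Statistic: U²/V with U = Σ x_i (y_i − ȳ) and V = ȳ(1−ȳ) Σ (x_i − x̄)²,
    chi-square with 1 df under the null. Returns 1.0 for a constant
    predictor (no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    v = y.mean() * (1 - y.mean()) * (xc @ xc)
    if v <= 0:
        return 1.0
    u = xc @ (y - y.mean())
    return float(stats.chi2.sf(u * u / v, df=1))


def _wilcoxon_p(x, y) -> float:
    cases = x[np.asarray(y) == 1]
    controls = x[np.asarray(y) == 0]
    return float(stats.mannwhitneyu(cases, controls, alternative="two-sided").pvalue)


def association_pvalues(X: np.ndarray, y, method: str = "score") -> np.ndarray:
    """Per-column association P values (``score`` or ``wilcoxon``)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if method == "score":
        xc = X - X.mean(axis=0)
        ss = (xc * xc).sum(axis=0)
        v = y.mean() * (1 - y.mean()) * ss
        u = xc.T @ (y - y.mean())
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(v > 0, u * u / np.where(v > 0, v, 1.0), 0.0)
        p = stats.chi2.sf(chi2, df=1)
        return np.where(v > 0, p, 1.0)
    if method == "wilcoxon":
        return np.array([_wilcoxon_p(X[:, j], y) for j in range(X.shape[1])])
    raise ValueError(f"unknown test method {method!r}")


def _ranking_table(unit_ids, X, y, method: str, sizes=None) -> pd.DataFrame:
    y = np.asarray(y, dtype=float)
    p = association_pvalues(X, y, method=method)
    clamped = p < P_FLOOR
    p = np.clip(p, P_FLOOR, 1.0)
    pcc = columnwise_pcc(np.atleast_2d(np.asarray(X, dtype=float)), y)
    constant = np.isnan(pcc)
    table = pd.DataFrame({
        "unit_id": list(unit_ids),
        "pcc": pcc,
        "p_value": p,
        "neg_log10_p": -np.log10(p),
        "p_clamped": clamped,
        "constant": constant,
        "significant": p < 0.05,
        "p_bh": multipletests(p, method="fdr_bh")[1],
    })
    if sizes is not None:
        table["size"] = [sizes.get(u, np.nan) for u in table["unit_id"]]
    # descending significance; ties resolved by unit id for stable output
    return table.sort_values(["neg_log10_p", "unit_id"],
                             ascending=[False, True], kind="mergesort",
                             ignore_index=True)


def pathway_feature_stats(
    S: PathwayFeatureMatrix,
    y,
    *,
    sizes: dict[str, int] | None = None,
    method: str = "score",
    top: int | None = None,
) -> pd.DataFrame:
    """Rank pathway-level score columns by phenotype association.

    Returns a table sorted by descending −log10 P with PCC, nominal and
    BH-adjusted P values, and (when provided) the pathway gene-set size.
    ``top`` truncates to the head of the ranking (10 is the conventional
    display size).
    """
    table = _ranking_table(S.pathway_ids, S.S, y, method, sizes=sizes)
    return table.head(top) if top is not None else table


def input_feature_stats(X_k: np.ndarray, feature_ids, y, *, method: str = "score") -> pd.DataFrame:
    """Rank one pathway's raw features by univariate phenotype association.

    ``significant`` flags features at the nominal P < .05 level.
    """
    return _ranking_table(feature_ids, X_k, y, method)
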