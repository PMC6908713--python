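"""Model evaluation: accuracy metrics on known vs predicted lifespans,
per-promoter lifespan correlations, PCA of the density matrix, and the
class-effect ANCOVA.

MAE here is the *median* absolute error in years. R-squared on the ln scale
is the squared Pearson correlation between known and predicted ln lifespan;
the simple-regression R-squared is reported alongside (for a univariate
linear fit the two coincide).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.decomposition import PCA

from .density import DensityMatrix
from .predict import Prediction

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    r_squared_log: float
    pearson_r_log: float
    regression_r_squared_log: float
    mae_years: float
    relative_errors: dict[str, float]
    max_relative_error: float
    per_class_r2: dict[str, tuple[float, float]] = field(default_factory=dict)
    ancova_p: float | None = None
    group_comparison_p: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r_squared_log": self.r_squared_log,
            "pearson_r_log": self.pearson_r_log,
            "regression_r_squared_log": self.regression_r_squared_log,
            "mae_years": self.mae_years,
            "max_relative_error": self.max_relative_error,
            "relative_errors": self.relative_errors,
            "per_class_r2": {c: {"r2": r, "p": p} for c, (r, p) in self.per_class_r2.items()},
            "ancova_p": self.ancova_p,
            "group_comparison_p": self.group_comparison_p,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"ln-scale R^2 (Pearson^2): {self.r_squared_log:.4f}",
            f"median absolute error:    {self.mae_years:.2f} years",
            f"max relative error:       {100 * self.max_relative_error:.1f}%",
        ]
        for c, (r2, p) in sorted(self.per_class_r2.items()):
            lines.append(f"  {c}: R^2 = {r2:.3f} (p = {p:.3g})")
        if self.ancova_p is not None:
            lines.append(f"class-effect ANCOVA p:    {self.ancova_p:.4g}")
        for name, p in self.group_comparison_p.items():
            lines.append(f"  {name} error t-test p = {p:.3g}")
        return "\n".join(lines)


def score_predictions(
    known: Mapping[str, float],
    predicted: Sequence[Prediction],
    split: Mapping[str, str] | None = None,
    sources: Mapping[str, str] | None = None,
) -> EvaluationReport:
    """Score predictions against known maximum lifespans (years).

    Computes ln-scale R-squared, median absolute error in years, per-species
    relative errors, per-class R-squared for classes with n >= 3, the
    class-effect ANCOVA when >= 2 such classes exist, and Welch t-tests on
    absolute errors between train/test and captivity/wild groups when the
    labels are supplied.
    """
    pred_by_id = {p.species_id: p for p in predicted}
    diff = set(known) ^ set(pred_by_id)
    if diff:
        raise ValueError(f"species sets differ: {sorted(diff)}")
    if len(known) < 3:
        raise ValueError("need at least 3 species to score")

    ids = sorted(known)
    known_years = np.array([known[s] for s in ids], dtype=float)
    pred_years = np.array([pred_by_id[s].lifespan_years for s in ids])
    ln_known = np.log(known_years)
    ln_pred = np.array([pred_by_id[s].ln_lifespan for s in ids])
    classes = [pred_by_id[s].vertebrate_class for s in ids]

    r, _ = stats.pearsonr(ln_known, ln_pred)
    ols = sm.OLS(ln_known, sm.add_constant(ln_pred)).fit()
    abs_err = np.abs(pred_years - known_years)
    rel_err = abs_err / known_years

    per_class_r2: dict[str, tuple[float, float]] = {}
    for c in sorted(set(classes)):
        mask = np.array([ci == c for ci in classes])
        if mask.sum() < 3:
            continue
        if np.ptp(ln_pred[mask]) == 0 or np.ptp(ln_known[mask]) == 0:
            continue
        rc, pc = stats.pearsonr(ln_known[mask], ln_pred[mask])
        per_class_r2[c] = (float(rc ** 2), float(pc))

    ancova_p = None
    if len(per_class_r2) >= 2:
        use = [i for i, c in enumerate(classes) if c in per_class_r2]
        ancova_p = ancova_class_effect(
            ln_known[use], ln_pred[use], [classes[i] for i in use]
        )

    group_p: dict[str, float] = {}
    if split is not None:
        tr = np.array([split.get(s) == "train" for s in ids])
        te = np.array([split.get(s) == "test" for s in ids])
        if tr.sum() >= 2 and te.sum() >= 2:
            group_p["train_vs_test"] = float(
                stats.ttest_ind(abs_err[tr], abs_err[te], equal_var=False).pvalue
            )
    if sources is not None:
        cap = np.array([sources.get(s) == "captivity" for s in ids])
        wild = np.array([sources.get(s) == "wild" for s in ids])
        if cap.sum() >= 2 and wild.sum() >= 2:
            group_p["captivity_vs_wild"] = float(
                stats.ttest_ind(abs_err[cap], abs_err[wild], equal_var=False).pvalue
            )

    return EvaluationReport(
        r_squared_log=float(r ** 2),
        pearson_r_log=float(r),
        regression_r_squared_log=float(ols.rsquared),
        mae_years=float(np.median(abs_err)),
        relative_errors={s: float(e) for s, e in zip(ids, rel_err)},
        max_relative_error=float(rel_err.max()),
        per_class_r2=per_class_r2,
        ancova_p=ancova_p,
        group_comparison_p=group_p,
    )


def per_promoter_correlations(
    densities: DensityMatrix | pd.DataFrame,
    ln_lifespans: Sequence[float],
) -> pd.DataFrame:
    """Pearson correlation of each promoter's density with ln lifespan.

    Returns a DataFrame with promoter_id, pearson_r, p_value, direction
    (sign of r), and a ``flagged`` column marking zero-variance promoters,
    for which no correlation is reported.
    """
    frame = densities.frame if isinstance(densities, DensityMatrix) else densities
    y = np.asarray(ln_lifespans, dtype=float)
    if frame.shape[0] < 3:
        raise ValueError("need at least 3 species")
    rows = []
    for pid in frame.columns:
        col = frame[pid].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            rows.append({"promoter_id": pid, "pearson_r": np.nan,
                         "p_value": np.nan, "direction": 0, "flagged": True})
            continue
        r, p = stats.pearsonr(col, y)
        rows.append({"promoter_id": pid, "pearson_r": float(r),
                     "p_value": float(p), "direction": int(np.sign(r)), "flagged": False})
    return pd.DataFrame(rows)


def pca_densities(
    densities: DensityMatrix | pd.DataFrame,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the column-standardized density matrix.

    Columns are centred and scaled to unit (population) variance before
    decomposition; zero-variance columns are dropped with a warning.
    Returns (scores DataFrame indexed by species, explained-variance
    fractions).
    """
    frame = densities.frame if isinstance(densities, DensityMatrix) else densities
    if frame.shape[0] < 3 or frame.shape[1] < 2:
        raise ValueError("need >= 3 species and >= 2 promoters")
    X = frame.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance promoters before PCA")
    X = X[:, keep]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    k = n_components or min(Xs.shape)
    k = min(k, min(Xs.shape))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xs)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=frame.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def ancova_class_effect(
    known: Sequence[float],
    predicted: Sequence[float],
    classes: Sequence[str],
) -> float:
    """p-value for the vertebrate-class effect in known ~ predicted + class.

    Sequential (type-I) sums of squares with the covariate entered first;
    the returned p is the F-test for the class factor.
    """
    classes = list(classes)
    counts = pd.Series(classes).value_counts()
    if (counts >= 3).sum() < 2:
        raise ValueError("need >= 2 classes with >= 3 members each")
    df = pd.DataFrame({
        "known": np.asarray(known, dtype=float),
        "predicted": np.asarray(predicted, dtype=float),
        "cls": classes,
    })
    # sequential SS with the covariate first: F from the nested-model SSR drop
    # (anova_lm typ=1 would enter the categorical term first instead)
    reduced = smf.ols("known ~ predicted", data=df).fit()
    full = smf.ols("known ~ predicted + C(cls)", data=df).fit()
    df_cls = full.df_model - reduced.df_model
    f_stat = (reduced.ssr - full.ssr) / df_cls / (full.ssr / full.df_resid)
    return float(stats.f.sf(f_stat, df_cls, full.df_resid))
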