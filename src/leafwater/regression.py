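"""Cross-validated index -> water-status regression.

The estimation step fits a one-predictor regression of a water-status
target (EWT in g cm^-2, or FMC as a fraction) on a spectral index, in one
of three functional forms:

* linear      y = b1*x + b0
* quadratic   y = b2*x^2 + b1*x + b0
* exponential y = a * exp(b*x)

and judges it by k-fold cross-validation (default k = 10): the samples are
randomly partitioned into k near-equal folds, each fold is predicted by a
model trained on the other k-1, and the pooled out-of-fold predictions are
scored by

* R2cv     — squared Pearson correlation between out-of-fold predictions
             and observations (a 1 - SSE/SST variant is also available),
* rRMSEcv  — out-of-fold RMSE divided by the mean observed target.

The public surface follows the statsmodels convention: build an
:class:`IndexRegression` model from an index table, call ``fit()`` and get
a :class:`CVFitResult` carrying coefficients, per-fold predictions, scores
and a ``summary()`` table.  Convenience functions (:func:`cross_validate`,
:func:`rank_indices`, :func:`similarity_analysis`,
:func:`group_by_species`) wrap the model for pipeline use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

logger = logging.getLogger(__name__)

FORMS = ("linear", "quadratic", "exponential")
DEFAULT_K = 10
DEFAULT_SEED = 20190515


# ---------------------------------------------------------------------------
# fold construction

@dataclass(frozen=True)
class FoldPlan:
    """Assignment of n samples to k cross-validation folds."""

    k: int
    assignment: np.ndarray  # fold id per sample position
    seed: int

    @property
    def n(self) -> int:
        return len(self.assignment)

    def fold_sizes(self) -> list[int]:
        return np.bincount(self.assignment, minlength=self.k).tolist()

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def make_folds(n: int, k: int = DEFAULT_K, seed: int = DEFAULT_SEED) -> FoldPlan:
    """Random k-fold partition with fold sizes differing by at most one.

    A seeded random permutation of the samples is dealt round-robin into the
    k folds, so e.g. n=292, k=10 gives two folds of 30 and eight of 29.
    """
    if not (n >= k >= 2):
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# functional forms

def fit_form(x: np.ndarray, y: np.ndarray, form: str) -> np.ndarray:
    """Least-squares coefficients of one functional form.

    Returns highest-degree-first polynomial coefficients for linear /
    quadratic, or (a, b) for the exponential y = a*exp(b*x), fitted by
    nonlinear least squares started from the log-linear solution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("fit_form requires finite x and y")
    min_n = {"linear": 3, "quadratic": 4, "exponential": 4}
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
    if len(x) < min_n[form]:
        raise ValueError(f"{form} fit needs >= {min_n[form]} points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError(f"{form} fit: singular design (constant index)")

    if form == "linear":
        return np.polyfit(x, y, 1)
    if form == "quadratic":
        return np.polyfit(x, y, 2)

    # exponential: log-linear init, then true nonlinear least squares
    positive = y > 0
    if positive.sum() >= 3:
        b0, loga = np.polyfit(x[positive], np.log(y[positive]), 1)
        p0 = (float(np.exp(loga)), float(b0))
    else:
        p0 = (float(np.mean(y)), 0.0)
    try:
        popt, _ = optimize.curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                                     p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"exponential fit did not converge: {exc}") from exc
    return np.asarray(popt)


def predict_form(coefficients: np.ndarray, form: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if form in ("linear", "quadratic"):
        return np.polyval(coefficients, x)
    if form == "exponential":
        a, b = coefficients
        return a * np.exp(b * x)
    raise ValueError(f"unknown form {form!r}")


def format_equation(coefficients: np.ndarray, form: str, decimals: int = 3) -> str:
    """Human-readable equation string, coefficients rounded for reports."""
    c = np.round(np.asarray(coefficients, dtype=float), decimals)

    def term(v: float, suffix: str, first: bool) -> str:
        sign = "-" if v < 0 else ("" if first else "+")
        return f"{sign}{abs(v):.{decimals}f}{suffix}"

    if form == "linear":
        return f"y = {term(c[0], '*x', True)}{term(c[1], '', False)}"
    if form == "quadratic":
        return f"y = {term(c[0], '*x^2', True)}{term(c[1], '*x', False)}{term(c[2], '', False)}"
    if form == "exponential":
        return f"y = {term(c[0], '', True)}*exp({term(c[1], '', True)}*x)"
    raise ValueError(f"unknown form {form!r}")


def association_pvalue(x: np.ndarray, y: np.ndarray, form: str) -> float:
    """Overall F-test p-value of the full-data fit of the given form.

    For linear/quadratic this is the OLS regression F-test; for the
    exponential form the F statistic is built from the nonlinear fit's R^2
    with 1 model degree of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if form == "linear":
        design = sm.add_constant(x)
    elif form == "quadratic":
        design = sm.add_constant(np.column_stack([x, x ** 2]))
    else:
        coef = fit_form(x, y, form)
        resid = y - predict_form(coef, form, x)
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = max(0.0, 1.0 - sse / sst) if sst > 0 else 0.0
        df_resid = len(y) - 2
        if df_resid <= 0 or r2 >= 1.0:
            return 0.0
        f_stat = r2 / ((1.0 - r2) / df_resid)
        return float(stats.f.sf(f_stat, 1, df_resid))
    return float(sm.OLS(y, design).fit().f_pvalue)


# ---------------------------------------------------------------------------
# model / results objects

def _score(observed: np.ndarray, predicted: np.ndarray, variant: str = "corr"):
    """(R2cv, rRMSEcv) from pooled out-of-fold predictions."""
    resid = observed - predicted
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    rrmse = rmse / float(np.mean(observed))
    if variant == "corr":
        if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
            r2 = 1.0 if rmse == 0 else 0.0
        else:
            r2 = float(np.corrcoef(observed, predicted)[0, 1] ** 2)
    elif variant == "sse":
        sst = float(((observed - observed.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else (1.0 if rmse == 0 else 0.0)
    else:
        raise ValueError(f"unknown r2 variant {variant!r}")
    return r2, rrmse


@dataclass
class CVFitResult:
    """Results of one cross-validated (index, target, form) regression."""

    index_name: str
    target: str
    form: str
    coefficients: np.ndarray          # full-data fit, reported in equations
    p_value: float                    # full-data association F-test
    r2cv: float
    rrmse_cv: float                   # fraction; multiply by 100 for percent
    n_used: int
    per_fold_predictions: pd.DataFrame = field(repr=False)  # sample_id, fold, observed, predicted
    folds: FoldPlan = field(repr=False, default=None)  # type: ignore[assignment]
    r2_variant: str = "corr"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def equation(self) -> str:
        return format_equation(self.coefficients, self.form)

    def summary(self) -> str:
        lines = [
            f"Cross-validated {self.form} regression: {self.target} ~ {self.index_name}",
            "=" * 64,
            f"n used:              {self.n_used}",
            f"folds:               {self.folds.k if self.folds else '-'}",
            f"equation:            {self.equation}",
            f"P (association):     {'<0.0001' if self.p_value < 1e-4 else f'{self.p_value:.4g}'}",
            f"R2cv ({self.r2_variant}):         {self.r2cv:.3f}",
            f"rRMSEcv:             {100 * self.rrmse_cv:.2f}%",
        ]
        if not self.significant:
            lines.append("note: association not significant at the 0.05 level (n.s.)")
        return "\n".join(lines)


class IndexRegression:
    """Model object: one spectral index predicting one water-status target.

    Parameters
    ----------
    table : DataFrame
        Per-sample index table with at least ``sample_id``, the index
        column, and the target column (``ewt`` or ``fmc``).
    index_name, target : str
        Column names of predictor and response.
    form : {"linear", "quadratic", "exponential"}

    Rows with a missing index or target are dropped (count logged).
    ``fit`` performs the k-fold cross-validation and returns a
    :class:`CVFitResult`.
    """

    def __init__(self, table: pd.DataFrame, index_name: str, target: str,
                 form: str = "linear"):
        for col in (index_name, target):
            if col not in table.columns:
                raise KeyError(f"column {col!r} not in table "
                               f"(available: {sorted(table.columns)})")
        if form not in FORMS:
            raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
        keep = table[[index_name, target]].notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s ~ %s: dropped %d samples with missing values",
                        target, index_name, n_dropped)
        self.data = table.loc[keep].reset_index(drop=True)
        self.index_name = index_name
        self.target = target
        self.form = form
        self.x = self.data[index_name].to_numpy(dtype=float)
        self.y = self.data[target].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, index_name: str, target: str,
                       form: str = "linear") -> "IndexRegression":
        return cls(table, index_name, target, form)

    def fit(self, folds: FoldPlan | None = None, k: int = DEFAULT_K,
            seed: int = DEFAULT_SEED, r2_variant: str = "corr") -> CVFitResult:
        n = len(self.x)
        if folds is None:
            folds = make_folds(n, k=k, seed=seed)
        if folds.n != n:
            raise ValueError(f"fold plan for n={folds.n} does not match data n={n}")

        predicted = np.full(n, np.nan)
        for fold in range(folds.k):
            test = folds.test_indices(fold)
            train = np.flatnonzero(folds.assignment != fold)
            if len(train) < 3:
                raise ValueError(f"fold {fold}: only {len(train)} training points")
            coef = fit_form(self.x[train], self.y[train], self.form)
            predicted[test] = predict_form(coef, self.form, self.x[test])
        assert not np.isnan(predicted).any()  # folds partition the samples

        r2cv, rrmse = _score(self.y, predicted, variant=r2_variant)
        full_coef = fit_form(self.x, self.y, self.form)
        pval = association_pvalue(self.x, self.y, self.form)
        per_fold = pd.DataFrame({
            "sample_id": self.data["sample_id"] if "sample_id" in self.data else np.arange(n),
            "fold": folds.assignment,
            "observed": self.y,
            "predicted": predicted,
        })
        return CVFitResult(
            index_name=self.index_name, target=self.target, form=self.form,
            coefficients=full_coef, p_value=pval, r2cv=r2cv, rrmse_cv=rrmse,
            n_used=n, per_fold_predictions=per_fold, folds=folds,
            r2_variant=r2_variant,
        )


def cross_validate(table: pd.DataFrame, index_name: str, target: str,
                   form: str = "linear", folds: FoldPlan | None = None,
                   k: int = DEFAULT_K, seed: int = DEFAULT_SEED,
                   r2_variant: str = "corr") -> CVFitResult:
    """Functional wrapper: build an IndexRegression and fit it."""
    model = IndexRegression(table, index_name, target, form)
    return model.fit(folds=folds, k=k, seed=seed, r2_variant=r2_variant)


# ---------------------------------------------------------------------------
# report-level analyses

def rank_indices(table: pd.DataFrame, target: str,
                 index_names: list[str] | None = None,
                 forms: tuple[str, ...] = FORMS,
                 k: int = DEFAULT_K, seed: int = DEFAULT_SEED,
                 r2_variant: str = "corr") -> pd.DataFrame:
    """Per-index best-form report, sorted by descending R2cv.

    For each index the functional form with the highest R2cv is retained.
    Indices whose full-data association is not significant at the 0.05
    level are marked "n.s." with no equation or scores, and sort last.
    Columns mirror the conventional report layout:
    index, P, regression_equation, r2cv, rrmse_cv_pct, form, n_used.
    """
    from .indices import ALL_INDEX_NAMES
    if index_names is None:
        index_names = [c for c in ALL_INDEX_NAMES if c in table.columns]
    if len(index_names) < 2:
        raise ValueError("ranking needs at least 2 indices")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} available samples")

    rows = []
    for name in index_names:
        best: CVFitResult | None = None
        for form in forms:
            try:
                res = cross_validate(table, name, target, form, k=k, seed=seed,
                                     r2_variant=r2_variant)
            except (ValueError, KeyError) as exc:
                logger.warning("%s/%s (%s) failed: %s", name, target, form, exc)
                continue
            if best is None or res.r2cv > best.r2cv:
                best = res
        if best is None:
            continue
        if best.significant:
            rows.append({
                "index": name,
                "P": "<0.0001" if best.p_value < 1e-4 else f"{best.p_value:.4g}",
                "regression_equation": best.equation,
                "r2cv": best.r2cv,
                "rrmse_cv_pct": 100 * best.rrmse_cv,
                "form": best.form,
                "n_used": best.n_used,
            })
        else:
            rows.append({
                "index": name, "P": "n.s.", "regression_equation": "-",
                "r2cv": np.nan, "rrmse_cv_pct": np.nan,
                "form": best.form, "n_used": best.n_used,
            })
    report = pd.DataFrame(rows)
    return report.sort_values("r2cv", ascending=False, na_position="last").reset_index(drop=True)


def similarity_analysis(table: pd.DataFrame, pair: tuple[str, str], target: str,
                        form: str = "linear", k: int = DEFAULT_K,
                        seed: int = DEFAULT_SEED) -> float:
    """Squared correlation between two indices' out-of-fold predictions.

    Both indices are cross-validated with the same fold plan over the
    samples where both (and the target) are present, so the prediction
    vectors are aligned sample-by-sample.
    """
    a, b = pair
    cols = [a, b, target]
    sub = table.loc[table[cols].notna().all(axis=1)].reset_index(drop=True)
    folds = make_folds(len(sub), k=k, seed=seed)
    res_a = cross_validate(sub, a, target, form, folds=folds)
    res_b = cross_validate(sub, b, target, form, folds=folds)
    pa = res_a.per_fold_predictions["predicted"].to_numpy()
    pb = res_b.per_fold_predictions["predicted"].to_numpy()
    if len(pa) != len(pb):
        raise ValueError("prediction vector length mismatch")
    return float(np.corrcoef(pa, pb)[0, 1] ** 2)


def group_by_species(table: pd.DataFrame, target: str, index_name: str,
                     form: str = "linear", min_samples: int = 5) -> pd.DataFrame:
    """Per-species full-data fits of one index-target relation.

    Species with fewer than ``min_samples`` usable rows are skipped with a
    warning.  Returns one row per fitted species with its coefficients and,
    for the linear form, the slope/intercept; use the slope spread across
    species to judge whether one pooled relation transfers across species.
    """
    if "species" not in table.columns:
        raise KeyError("table has no species column")
    rows = []
    for species, grp in table.groupby("species", sort=True):
        sub = grp[[index_name, target]].dropna()
        if len(sub) < min_samples:
            logger.warning("species %s: only %d samples, skipped", species, len(sub))
            continue
        coef = fit_form(sub[index_name].to_numpy(), sub[target].to_numpy(), form)
        row = {"species": species, "n": len(sub), "form": form,
               "equation": format_equation(coef, form)}
        if form == "linear":
            row["slope"], row["intercept"] = float(coef[0]), float(coef[1])
        rows.append(row | {"coefficients": coef})
    out = pd.DataFrame(rows)
    if form == "linear" and len(out):
        out.attrs["slope_range"] = (float(out.slope.min()), float(out.slope.max()))
        out.attrs["intercept_range"] = (float(out.intercept.min()), float(out.intercept.max()))
    return out
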