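"""Differential abundance, variance decomposition, classification, and
pseudobulk utilities.

Statistical conventions: features are mean-centered and scaled before model
fitting; treatment contrasts are fixed-effects linear models with Wald tests;
multiple testing is controlled with Benjamini-Hochberg FDR across all
(marker, stratum, contrast) tests of one invocation; a feature is called
significant when ``padj <= 0.1`` AND ``|coefficient| >= 0.5`` (both
configurable). Variance partitioning uses sequential (type-I) sums of squares
over a fixed term order: main effects, then two-way, three-way, and four-way
interactions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .matrix import ExpressionMatrix
from .panels import DEFAULT_PANEL, PanelDefinition

DEFAULT_PADJ_MAX = 0.1
DEFAULT_COEF_MIN = 0.5


def scale_features(m: ExpressionMatrix) -> ExpressionMatrix:
    """Mean-center and unit-scale every channel (z-score, population SD).

    Zero-variance channels are set to all zeros with a warning.
    """
    m.require_state("normalized", "scale_features")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        names = [m.channel_names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant channels scaled to zero: {names}", stacklevel=2)
    safe_sd = np.where(constant, 1.0, sd)
    values = (m.values - mean) / safe_sd
    values[:, constant] = 0.0
    return m.with_values(values, scaled=True)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def differential_test(
    m: ExpressionMatrix,
    contrast: str,
    reference: str,
    stratify_by: Optional[str] = None,
    padj_max: float = DEFAULT_PADJ_MAX,
    coef_min: float = DEFAULT_COEF_MIN,
) -> pd.DataFrame:
    """Per-marker fixed-effects linear models with Wald tests.

    For each stratum (optionally a phase label column) and marker, scaled
    abundance is regressed on the contrast indicator(s) with ``reference`` as
    the baseline level. The coefficient is the difference of scaled group
    means in the two-group case. BH adjustment spans all (marker, stratum,
    contrast) tests; significance requires ``padj <= padj_max`` and
    ``|coef| >= coef_min``.
    """
    if not m.transform_info.get("scaled"):
        raise ParameterError("differential_test expects scale_features output")
    meta = m.cell_meta
    if contrast not in meta.columns:
        raise ParameterError(f"contrast column {contrast!r} not in cell_meta")
    strata = (
        meta[stratify_by].to_numpy() if stratify_by is not None
        else np.full(m.n_cells, "all", dtype=object)
    )
    labels = meta[contrast].to_numpy()
    if reference not in labels:
        raise ParameterError(f"reference level {reference!r} not present")

    rows = []
    for stratum in pd.unique(strata):
        mask = strata == stratum
        y = m.values[mask]
        lab = labels[mask]
        levels = [l for l in pd.unique(lab) if l != reference]
        if reference not in lab or not levels:
            warnings.warn(
                f"stratum {stratum!r} has a single contrast level; skipped",
                stacklevel=2,
            )
            continue
        # Design: intercept + one indicator per non-reference level.
        x = np.column_stack(
            [np.ones(mask.sum())] + [(lab == l).astype(float) for l in levels]
        )
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y  # (1 + n_levels) x n_markers
        resid = y - x @ beta
        dof = y.shape[0] - x.shape[1]
        if dof <= 0:
            warnings.warn(f"stratum {stratum!r} has no residual df; skipped",
                          stacklevel=2)
            continue
        sigma2 = (resid**2).sum(axis=0) / dof
        for j, level in enumerate(levels, start=1):
            se = np.sqrt(sigma2 * xtx_inv[j, j])
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, beta[j] / se, 0.0)
            pvals = 2.0 * sps.norm.sf(np.abs(z))
            for marker, coef, p in zip(m.channel_names, beta[j], pvals):
                rows.append(
                    {
                        "marker": marker,
                        "stratum": stratum,
                        "contrast": f"{level}_vs_{reference}",
                        "coef": float(coef),
                        "wald_p": float(p),
                    }
                )
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(
            columns=["marker", "stratum", "contrast", "coef", "wald_p",
                     "padj", "significant"]
        )
    result["padj"] = bh_adjust(result["wald_p"].to_numpy())
    result["significant"] = (result["padj"] <= padj_max) & (
        result["coef"].abs() >= coef_min
    )
    return result


def variance_explained(m: ExpressionMatrix | pd.DataFrame,
                       factor: np.ndarray) -> pd.Series:
    """One-way ANOVA percent variance explained, per marker.

    Between-group sum of squares over total sum of squares, as a percentage
    (equivalently 100 x R-squared of the one-way model).
    """
    if isinstance(m, ExpressionMatrix):
        df = m.to_dataframe()
    else:
        df = m
    factor = np.asarray(factor)
    if len(factor) != len(df):
        raise ParameterError("factor labels do not align with the matrix")
    if len(pd.unique(factor)) < 2:
        raise ParameterError("factor must have >= 2 levels")
    grand = df.mean(axis=0)
    total_ss = ((df - grand) ** 2).sum(axis=0)
    between_ss = pd.Series(0.0, index=df.columns)
    for g in pd.unique(factor):
        mask = factor == g
        between_ss += mask.sum() * (df[mask].mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * between_ss / total_ss
    return pct.fillna(0.0)


def variance_partition(pseudobulk: pd.DataFrame, factors: pd.DataFrame
                       ) -> pd.DataFrame:
    """Fixed-effects variance partition with all interactions.

    Per marker, an OLS model with every main effect and all interactions up
    to the order of ``factors``' columns; proportions are sequential (type-I)
    sums of squares over total SS, plus residual. Term order is fixed: main
    effects in column order, then two-way, three-way, ... interactions.
    Aliased (zero-df) terms are dropped and reported with proportion NaN.
    """
    if len(pseudobulk) != len(factors):
        raise ParameterError("pseudobulk and factors must align")
    fac_names = list(factors.columns)
    if not fac_names:
        raise ParameterError("no factors supplied")
    data = factors.copy().reset_index(drop=True)
    terms = []
    for order in range(1, len(fac_names) + 1):
        for combo in itertools.combinations(fac_names, order):
            terms.append(":".join(f"C({f})" for f in combo))
    formula_rhs = " + ".join(terms)

    rows = []
    for marker in pseudobulk.columns:
        data["_y"] = pseudobulk[marker].to_numpy()
        model = smf.ols(f"_y ~ {formula_rhs}", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=1)
        total_ss = float(anova["sum_sq"].sum())
        for term, row in anova.iterrows():
            name = (
                "residual" if term == "Residual"
                else term.replace("C(", "").replace(")", "")
            )
            prop = row["sum_sq"] / total_ss if total_ss > 0 else np.nan
            if term != "Residual" and row["df"] == 0:
                prop = np.nan  # aliased term dropped by the design
            rows.append({"marker": marker, "term": name,
                         "proportion": float(prop) if prop == prop else np.nan})
    return pd.DataFrame(rows)


def pseudobulk_aggregate(m: ExpressionMatrix, sample_labels: np.ndarray,
                         statistic: str = "median",
                         normalize: bool = False) -> pd.DataFrame:
    """Per-sample aggregate (default median) of every marker.

    With ``normalize=True`` each marker is divided by its grand median across
    samples (per-line medians relative to the all-line median).
    """
    sample_labels = np.asarray(sample_labels)
    if len(sample_labels) != m.n_cells:
        raise ParameterError("sample labels do not align with the matrix")
    df = m.to_dataframe()
    df["_sample"] = sample_labels
    grouped = df.groupby("_sample", observed=True)
    if statistic == "median":
        out = grouped.median()
    elif statistic == "mean":
        out = grouped.mean()
    else:
        raise ParameterError(f"unknown statistic {statistic!r}")
    out.index.name = "sample"
    if normalize:
        grand = out.median(axis=0)
        if (grand == 0).any():
            warnings.warn("zero grand median; affected markers left unnormalized",
                          stacklevel=2)
            grand = grand.replace(0, 1.0)
        out = out / grand
    return out


@dataclass
class ClassificationReport:
    panel: str
    accuracy: float
    per_class: pd.DataFrame      # class, sensitivity, specificity, accuracy
    pairwise: pd.DataFrame       # line_a, line_b, sensitivity, specificity, accuracy
    n_train: int
    n_test: int
    split: dict = field(default_factory=dict)


def _ovr_metrics(y_true: np.ndarray, y_pred: np.ndarray, positive) -> tuple[float, float, float]:
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    fp = int(((y_true != positive) & (y_pred == positive)).sum())
    tn = int(((y_true != positive) & (y_pred != positive)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(y_true)
    return sens, spec, acc


def classify_cell_lines(
    m: ExpressionMatrix,
    lines: np.ndarray,
    panel: str = "core",
    panel_def: PanelDefinition = DEFAULT_PANEL,
    train_per_line: int = 2000,
    test_per_line: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationReport:
    """Multinomial logistic regression on a feature panel.

    Training uses a balanced per-line sample; test cells are held out
    (disjoint from training). Reports one-vs-rest sensitivity/specificity/
    accuracy per line and per line pair. Deterministic given the seed.
    """
    lines = np.asarray(lines)
    features = panel_def.markers(panel)
    x = m.subset_channels(features)
    rng = np.random.default_rng(seed)

    levels = sorted(pd.unique(lines))
    if len(levels) < 2:
        raise ParameterError("need >= 2 cell lines")
    train_idx, test_idx = [], []
    for line in levels:
        idx = np.flatnonzero(lines == line)
        if len(idx) < train_per_line + 1:
            raise ParameterError(f"line {line!r} too small for the split")
        perm = rng.permutation(idx)
        train_idx.append(perm[:train_per_line])
        test_idx.append(perm[train_per_line : train_per_line + test_per_line])
    train = np.concatenate(train_idx)
    test = np.concatenate(test_idx)

    clf = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, max_iter=2000),
    )
    clf.fit(x[train], lines[train])
    y_true = lines[test]
    y_pred = clf.predict(x[test])
    proba = clf.predict_proba(x[test])
    classes = list(clf.classes_)

    per_class = pd.DataFrame(
        [
            dict(zip(("sensitivity", "specificity", "accuracy"),
                     _ovr_metrics(y_true, y_pred, line)), **{"class": line})
            for line in levels
        ]
    )[["class", "sensitivity", "specificity", "accuracy"]]

    pair_rows = []
    for a, b in itertools.combinations(levels, 2):
        mask = np.isin(y_true, [a, b])
        pa, pb = proba[mask][:, classes.index(a)], proba[mask][:, classes.index(b)]
        pred_pair = np.where(pa >= pb, a, b)
        sens, spec, acc = _ovr_metrics(y_true[mask], pred_pair, a)
        pair_rows.append({"line_a": a, "line_b": b, "sensitivity": sens,
                          "specificity": spec, "accuracy": acc})

    return ClassificationReport(
        panel=panel,
        accuracy=float((y_true == y_pred).mean()),
        per_class=per_class,
        pairwise=pd.DataFrame(pair_rows),
        n_train=len(train),
        n_test=len(test),
        split={"train_per_line": train_per_line, "test_per_line": test_per_line,
               "seed": seed},
    )


def correlation_similarity(m: ExpressionMatrix, groups: np.ndarray,
                           feature_set: Optional[Sequence[str]] = None
                           ) -> pd.DataFrame:
    """Similarity of marker correlation patterns between groups.

    Per group, the Pearson correlation matrix over features; similarity
    between two groups is the Pearson correlation between the vectorized
    upper triangles of their correlation matrices. Constant features within a
    group get zero correlations with a warning.
    """
    groups = np.asarray(groups)
    x = _features_block(m, feature_set)
    if x.shape[1] < 2:
        raise ParameterError("need >= 2 features")
    levels = list(pd.unique(groups))
    triangles = {}
    iu = np.triu_indices(x.shape[1], k=1)
    for g in levels:
        xg = x[groups == g]
        if xg.shape[0] < 3:
            raise ParameterError(f"group {g!r} has fewer than 3 cells")
        sd = xg.std(axis=0)
        if (sd == 0).any():
            warnings.warn(
                f"group {g!r}: constant feature(s); correlations set to 0",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(xg, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        triangles[g] = corr[iu]

    sim = pd.DataFrame(np.eye(len(levels)), index=levels, columns=levels)
    for a, b in itertools.combinations(levels, 2):
        r = float(np.corrcoef(triangles[a], triangles[b])[0, 1])
        sim.loc[a, b] = sim.loc[b, a] = r
    return sim


def _features_block(m: ExpressionMatrix, feature_set) -> np.ndarray:
    if feature_set is None:
        return m.values
    return m.subset_channels(list(feature_set))
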