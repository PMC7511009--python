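"""Type-III GLM inference for size-class and season effects.

Responses are modelled on two crossed factors, 5-cm size class and season,
plus their interaction: Gaussian with identity link for isotope values and
trophic level, binomial with logit link for prey presence/absence, Poisson
with log link for prey counts. Each term is tested by a type-III
likelihood-ratio test — the model without the term, refitted in the
presence of all the others (including the interaction), against the full
model — with chi-square p-values on the deviance difference. Sum-to-zero
contrasts are used throughout; type-III main-effect tests are only
meaningful under such contrasts.

An unbalanced design with an empty factor cell (no small whiting in winter)
makes the interaction block rank-deficient; aliased interaction columns are
detected and dropped with a warning, and the term's df shrinks accordingly.

Model fitting is delegated to statsmodels' GLM (iteratively reweighted
least squares); the design construction, aliasing handling and deviance
table are built here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: aliased-column sets already reported once (subsequent repeats log at DEBUG)
_seen_aliased: set[tuple[str, ...]] = set()

FAMILIES = {
    "gaussian_identity": lambda: sm.families.Gaussian(sm.families.links.Identity()),
    "binomial_logit": lambda: sm.families.Binomial(sm.families.links.Logit()),
    "poisson_log": lambda: sm.families.Poisson(sm.families.links.Log()),
}

#: deviance-change convergence tolerance and iteration cap for IRLS
IRLS_TOL = 1e-8
IRLS_MAXITER = 100

#: |coefficient| above which a logit fit is treated as separated
SEPARATION_CAP = 20.0


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list[str]
    term_cols: dict[str, list[int]]  # term name -> column indices in X
    levels: dict[str, list[str]]
    dropped: list[str] = field(default_factory=list)


@dataclass
class GLMFit:
    family: str
    coefficients: np.ndarray
    deviance: float
    df_resid: int
    converged: bool
    iterations: int
    dispersion: float = 1.0
    separated: bool = False
    design: DesignMatrix | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    fitted_values: np.ndarray | None = field(default=None, repr=False)


def sum_contrast(levels: Sequence[str], values: Sequence[str]) -> np.ndarray:
    """Sum-to-zero (deviation) encoding: k levels → k−1 columns.

    Level j < k−1 maps to the j-th unit vector; the last level maps to −1
    in every column, so each column sums to zero over a balanced factor.
    """
    levels = list(levels)
    k = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    out = np.zeros((len(values), k - 1))
    for r, v in enumerate(values):
        if v not in idx:
            raise ValueError(f"factor level {v!r} not among fitted levels {levels}")
        i = idx[v]
        if i < k - 1:
            out[r, i] = 1.0
        else:
            out[r, :] = -1.0
    return out


def build_design(
    data: pd.DataFrame,
    terms: Sequence[str] = ("size_class", "season"),
    interaction: bool = True,
    levels: dict[str, list[str]] | None = None,
) -> DesignMatrix:
    """Full-rank design matrix with intercept, sum-contrast mains, interaction.

    Interaction columns are products of main-effect columns; columns that
    are aliased (linearly dependent given the preceding columns, e.g. from
    an empty factor cell) are dropped with a warning.
    """
    n = len(data)
    if levels is None:
        levels = {t: sorted(data[t].astype(str).unique()) for t in terms}
    cols: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    term_cols: dict[str, list[int]] = {"intercept": [0]}
    mains: dict[str, np.ndarray] = {}
    for t in terms:
        enc = sum_contrast(levels[t], data[t].astype(str).tolist())
        mains[t] = enc
        start = sum(c.shape[1] for c in cols)
        cols.append(enc)
        names.extend(f"{t}[{lv}]" for lv in levels[t][:-1])
        term_cols[t] = list(range(start, start + enc.shape[1]))

    dropped: list[str] = []
    if interaction and len(terms) == 2:
        a, b = terms
        inter_name = f"{a}:{b}"
        term_cols[inter_name] = []
        X_sofar = np.hstack(cols)
        kept: list[np.ndarray] = []
        for i, lva in enumerate(levels[a][:-1]):
            for j, lvb in enumerate(levels[b][:-1]):
                col = (mains[a][:, i] * mains[b][:, j])[:, None]
                trial = np.hstack([X_sofar] + kept + [col])
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    kept.append(col)
                    names.append(f"{a}[{lva}]:{b}[{lvb}]")
                else:
                    dropped.append(f"{a}[{lva}]:{b}[{lvb}]")
        if dropped:
            key = tuple(dropped)
            level = logging.DEBUG if key in _seen_aliased else logging.WARNING
            _seen_aliased.add(key)
            logger.log(level, "dropping %d aliased interaction column(s): %s",
                       len(dropped), ", ".join(dropped))
        start = X_sofar.shape[1]
        term_cols[inter_name] = list(range(start, start + len(kept)))
        cols.extend(kept)

    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient after aliasing removal")
    return DesignMatrix(X=X, columns=names, term_cols=term_cols, levels=levels,
                        dropped=dropped)


def irls_fit(design: DesignMatrix | np.ndarray, y: np.ndarray, family: str) -> GLMFit:
    """Maximum-likelihood GLM fit by iteratively reweighted least squares."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {sorted(FAMILIES)}")
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if family == "binomial_logit" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial response must be binary 0/1")
    if family == "poisson_log" and (np.any(y < 0) or np.any(y != np.round(y))):
        raise ValueError("poisson response must be non-negative integers")

    model = sm.GLM(y, X, family=FAMILIES[family]())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation / domain warnings handled below
        res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)

    coefs = np.asarray(res.params, dtype=float)
    separated = False
    if family == "binomial_logit" and np.any(np.abs(coefs) > SEPARATION_CAP):
        separated = True
        coefs = np.clip(coefs, -SEPARATION_CAP, SEPARATION_CAP)
        logger.warning("possible separation in binomial fit; coefficients capped at ±%g",
                       SEPARATION_CAP)

    df_resid = len(y) - X.shape[1]
    if family == "gaussian_identity":
        dispersion = float(res.pearson_chi2 / df_resid) if df_resid > 0 else float("nan")
    else:
        dispersion = 1.0
    return GLMFit(
        family=family,
        coefficients=coefs,
        deviance=float(res.deviance),
        df_resid=df_resid,
        converged=bool(getattr(res, "converged", True)) and not separated,
        iterations=int(getattr(res.fit_history, "iteration", 0))
        if hasattr(res, "fit_history") else IRLS_MAXITER,
        dispersion=dispersion,
        separated=separated,
        design=design if isinstance(design, DesignMatrix) else None,
        y=y,
        fitted_values=np.asarray(res.fittedvalues, dtype=float),
    )


def _fit_columns(X: np.ndarray, keep: list[int], y: np.ndarray, family: str) -> GLMFit:
    return irls_fit(X[:, keep], y, family)


def type3_table(
    data: pd.DataFrame,
    response: str,
    family: str,
    terms: Sequence[str] = ("size_class", "season"),
) -> pd.DataFrame:
    """Type-III likelihood-ratio deviance table for the two-factor model.

    The full model is ``size_class + season + size_class:season``. For each
    term the model omitting (only) that term's columns is refitted and the
    deviance difference is referred to a chi-square with the term's df. For
    the Gaussian family the statistic uses the scaled deviance
    (deviance / Pearson dispersion of the full model); binomial and Poisson
    deviances are already on the chi-square scale.
    """
    design = build_design(data, terms=terms, interaction=True)
    y = data[response].to_numpy(float)
    full = irls_fit(design, y, family)
    phi = full.dispersion if family == "gaussian_identity" else 1.0

    inter = f"{terms[0]}:{terms[1]}"
    all_cols = list(range(design.X.shape[1]))
    rows = []
    for term in [*terms, inter]:
        omit = set(design.term_cols[term])
        keep = [c for c in all_cols if c not in omit]
        reduced = _fit_columns(design.X, keep, y, family)
        lr = (reduced.deviance - full.deviance) / phi
        if lr < -1e-8:
            raise RuntimeError(f"negative LR deviance for term {term!r}: {lr}")
        lr = max(lr, 0.0)
        df = len(omit)
        rows.append({
            "term": term,
            "df": df,
            "deviance": lr,
            "resid_deviance": reduced.deviance,
            "resid_df": reduced.df_resid,
            "p_value": float(stats.chi2.sf(lr, df)) if df > 0 else float("nan"),
        })
    out = pd.DataFrame(rows)
    out.attrs["full_deviance"] = full.deviance
    out.attrs["full_df_resid"] = full.df_resid
    out.attrs["dispersion"] = phi
    out.attrs["dropped_columns"] = list(design.dropped)
    return out


def type3_tables_all_responses(
    diet_obs: pd.DataFrame,
    isotope_obs: pd.DataFrame,
    groups: Sequence[str],
) -> pd.DataFrame:
    """Deviance-table blocks for every response of the standard analysis.

    ``diet_obs`` holds one row per non-empty stomach with binary
    ``occ_<group>`` and count ``count_<group>`` columns; ``isotope_obs``
    one row per fish with d13C, d15N, TL. Returns the stacked blocks with a
    ``response`` column, mirroring a type-III GLM results table.
    """
    blocks = []
    for g in groups:
        for prefix, fam in (("occ", "binomial_logit"), ("count", "poisson_log")):
            col = f"{prefix}_{g}"
            if col not in diet_obs.columns:
                continue
            if diet_obs[col].nunique() < 2:
                logger.info("response %s is constant; skipped", col)
                continue
            t = type3_table(diet_obs, col, fam)
            t.insert(0, "response", f"{'occurrence' if prefix == 'occ' else 'abundance'}_{g}")
            t.insert(1, "family", fam)
            blocks.append(t)
    for col in ("d13C", "d15N", "TL"):
        if col in isotope_obs.columns:
            t = type3_table(isotope_obs, col, "gaussian_identity")
            t.insert(0, "response", col)
            t.insert(1, "family", "gaussian_identity")
            blocks.append(t)
    out = pd.concat(blocks, ignore_index=True)
    out["significant"] = out["p_value"] < 0.05
    return out


def qq_residuals(fit: GLMFit) -> tuple[pd.DataFrame, float | None]:
    """Normal QQ pairing of standardized residuals, with its correlation.

    Only defined for the Gaussian family. Residuals are standardized,
    sorted and paired with standard-normal quantiles at (i − ½)/n. The
    correlation of the pairs is a scalar normality diagnostic (≈1 for
    normal residuals); it is None for degenerate (constant) residuals.
    """
    if fit.family != "gaussian_identity":
        raise ValueError("QQ residual diagnostic is defined for the Gaussian family")
    if fit.y is None or fit.fitted_values is None:
        raise ValueError("fit does not carry data; refit with irls_fit")
    resid = fit.y - fit.fitted_values
    n = len(resid)
    if n < 3:
        raise ValueError("need at least 3 residuals for a QQ diagnostic")
    s = np.std(resid, ddof=1)
    if s < 1e-10 * max(1.0, float(np.max(np.abs(fit.y)))):  # degenerate: exact fit

        z = np.zeros(n)
        corr = None
    else:
        z = np.sort((resid - resid.mean()) / s)
        theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        corr = float(np.corrcoef(theo, z)[0, 1])
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"theoretical_quantile": theo, "sample_quantile": np.sort(z)}), corr


def quasi_dispersion(fit: GLMFit) -> float:
    """Pearson χ²/df — a quasi-likelihood overdispersion diagnostic (log only)."""
    if fit.y is None or fit.fitted_values is None:
        raise ValueError("fit does not carry data")
    mu = fit.fitted_values
    if fit.family == "poisson_log":
        var = mu
    elif fit.family == "binomial_logit":
        var = mu * (1 - mu)
    else:
        return fit.dispersion
    pearson = float(np.sum((fit.y - mu) ** 2 / np.maximum(var, 1e-12)))
    return pearson / max(fit.df_resid, 1)
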