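"""Multiplicative independence of mutation effects on enzyme levels.

Fits, separately for each enzyme, the no-interaction linear model

    log(level) ~ intercept + sum_i beta_i * [mutation i present]

by ordinary least squares, so exp(beta_i) is mutation i's total
multiplicative effect on that enzyme and exp(intercept) the ancestral
level.  A good fit (adjusted R^2 near 1, structureless residuals on
the combination rows) is the signature of mutations acting
independently on expression even when they interact strongly on
fitness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ExpressionEffectFit", "fit_multiplicative_expression",
           "predict_expression"]

logger = logging.getLogger(__name__)

ENZYMES = {"flha": "flha_obs", "fgha": "fgha_obs"}


@dataclass
class ExpressionEffectFit:
    """Per-enzyme log-scale OLS fit of mutation-presence indicators."""

    mutations: list[str]
    intercept_log: dict[str, float]
    coef_log: dict[str, dict[str, float]]        # enzyme -> mutation -> beta
    r2: dict[str, float]
    adj_r2: dict[str, float]
    residuals: pd.DataFrame
    mode: str = "all"                            # "all" or "singles_only"

    @property
    def multipliers(self) -> dict[str, dict[str, float]]:
        """Exponentiated coefficients: per-mutation fold effects."""
        return {enz: {m: float(np.exp(b)) for m, b in coefs.items()}
                for enz, coefs in self.coef_log.items()}


def _parse_genotype(s) -> list[str]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return []
    return [m for m in str(s).split(";") if m]


def _design_matrix(genotypes: list[list[str]],
                   mutations: list[str]) -> np.ndarray:
    X = np.zeros((len(genotypes), len(mutations)))
    idx = {m: j for j, m in enumerate(mutations)}
    for i, g in enumerate(genotypes):
        for m in g:
            X[i, idx[m]] = 1.0
    return X


def _check_rank(X: np.ndarray, mutations: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name the confounded columns via near-zero pivots of a QR decomposition
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = [mutations[j - 1] for j in range(1, X.shape[1])
           if diag[j] < 1e-8 * max(diag.max(), 1.0)]
    raise ValueError(
        "design matrix is rank deficient; confounded mutation columns: "
        f"{bad or mutations}")


def fit_multiplicative_expression(strains: pd.DataFrame,
                                  mode: str = "all",
                                  enzymes: dict[str, str] | None = None
                                  ) -> ExpressionEffectFit:
    """Fit the no-interaction log-expression model to a strain table.

    Uses rows whose genotype defines them (ancestor, singles,
    combinations); inducible-promoter rows are excluded since their
    expression is set by the inducer, not by mutations.  With
    ``mode="singles_only"`` the coefficients come from ancestor and
    single mutants alone and combination rows are scored purely out of
    sample.  Non-positive expression values are excluded with a logged
    warning.
    """
    if mode not in ("all", "singles_only"):
        raise ValueError("mode must be 'all' or 'singles_only'")
    enzymes = dict(ENZYMES if enzymes is None else enzymes)
    for col in ("genotype", *enzymes.values()):
        if col not in strains.columns:
            raise ValueError(f"strain table missing column {col!r}")

    df = strains.copy()
    if "category" in df.columns:
        df = df[df["category"] != "inducible"]
    genos = [_parse_genotype(g) for g in df["genotype"]]
    df = df.assign(_geno=genos, _nmut=[len(g) for g in genos])
    mutations = sorted({m for g in genos for m in g})
    if not mutations:
        raise ValueError("no mutant strains in table")

    intercept_log, coef_log, r2, adj_r2 = {}, {}, {}, {}
    resid_rows = []
    for enz, col in enzymes.items():
        sub = df.copy()
        bad = sub[col] <= 0
        if bad.any():
            logger.warning("%s: excluding %d rows with non-positive %s",
                           enz, int(bad.sum()), col)
            sub = sub[~bad]
        fit_rows = sub if mode == "all" else sub[sub["_nmut"] <= 1]
        X = _design_matrix(list(fit_rows["_geno"]), mutations)
        _check_rank(np.column_stack([np.ones(len(X)), X]), mutations)
        y = np.log(fit_rows[col].to_numpy(float))
        model = sm.OLS(y, sm.add_constant(X)).fit()
        intercept_log[enz] = float(model.params[0])
        coef_log[enz] = {m: float(b)
                         for m, b in zip(mutations, model.params[1:])}
        r2[enz] = float(model.rsquared)
        adj_r2[enz] = float(model.rsquared_adj)

        X_all = _design_matrix(list(sub["_geno"]), mutations)
        pred = intercept_log[enz] + X_all @ np.array(
            [coef_log[enz][m] for m in mutations])
        for (_, row), p in zip(sub.iterrows(), pred):
            resid_rows.append({
                "strain": row.get("strain", ""),
                "genotype": row["genotype"] if isinstance(row["genotype"], str) else "",
                "enzyme": enz,
                "observed": float(row[col]),
                "predicted": float(np.exp(p)),
                "log_residual": float(np.log(row[col]) - p),
                "n_mutations": int(row["_nmut"]),
            })

    return ExpressionEffectFit(mutations=mutations,
                               intercept_log=intercept_log,
                               coef_log=coef_log, r2=r2, adj_r2=adj_r2,
                               residuals=pd.DataFrame(resid_rows), mode=mode)


def predict_expression(genotype, fit: ExpressionEffectFit
                       ) -> tuple[float, float]:
    """Predicted (FlhA, FghA) levels for a genotype under the fitted model.

    The empty genotype returns the fitted ancestral levels; predictions
    are multiplicative in the constituent mutations by construction.
    """
    muts = sorted(genotype) if not isinstance(genotype, str) \
        else _parse_genotype(genotype)
    unknown = [m for m in muts if m not in fit.mutations]
    if unknown:
        raise KeyError(f"unknown mutation ids: {unknown}")
    out = []
    for enz in fit.coef_log:
        log_level = fit.intercept_log[enz] + sum(
            fit.coef_log[enz][m] for m in muts)
        out.append(float(np.exp(log_level)))
    return tuple(out)
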