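"""Epistasis statistics on ancestor-normalized relative fitness.

The multiplicative null expects a combination's fitness to be the
product of its constituents' fitnesses, W_ig = W_i x W_g; epistasis is
the deviation on the fitness-difference scale,

    epsilon = W_ig - W_i * W_g,

computed on fitnesses already normalized by the ancestor (ancestor
W = 1).  Sign epistasis is flagged when a mutation changes the
direction of its effect across backgrounds.  The module also fits the
multiplicative null to a whole strain table, summarizes the
relationship between a mutation's selection coefficient s and its mean
epsilon across backgrounds, and harmonizes external genotype-fitness
tables (optionally exponentiating base 2 for growth rates reported in
doublings, then dividing by the ancestor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations as _combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EpistasisRecord",
    "multiplicative_expectation",
    "epistasis",
    "is_sign_epistatic",
    "records_from_strain_table",
    "fit_multiplicative_fitness_null",
    "s_epsilon_trend",
    "TrendSummary",
    "normalize_dataset",
    "load_genotype_fitness_csv",
    "normalize_to_ancestor",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["mutation_id", "background_id", "w_i", "w_g", "w_ig",
                  "s_i", "epsilon", "sign_epistasis"]


@dataclass(frozen=True)
class EpistasisRecord:
    """One focal-mutation-in-background observation."""

    mutation_id: str
    background_id: str          # semicolon-joined ids; "" = ancestor
    w_i: float                  # focal single-mutant fitness
    w_g: float                  # background fitness
    w_ig: float                 # combined fitness
    s_i: float
    epsilon: float
    sign_epistasis: bool

    @classmethod
    def build(cls, mutation_id: str, background_id: str,
              w_i: float, w_g: float, w_ig: float) -> "EpistasisRecord":
        return cls(mutation_id=mutation_id, background_id=background_id,
                   w_i=w_i, w_g=w_g, w_ig=w_ig, s_i=w_i - 1.0,
                   epsilon=epistasis(w_ig, w_i, w_g),
                   sign_epistasis=is_sign_epistatic(w_ig, w_i, w_g))


def multiplicative_expectation(w_i: float, w_j: float) -> float:
    """Expected fitness of a combination under multiplicative independence."""
    if w_i <= 0 or w_j <= 0:
        raise ValueError("fitness values must be positive")
    return w_i * w_j


def epistasis(w_ig: float, w_i: float, w_g: float) -> float:
    """epsilon = W_ig - W_i * W_g on ancestor-normalized fitnesses.

    Zero iff the combination is exactly multiplicative; negative for
    antagonism, positive for synergy.
    """
    if min(w_ig, w_i, w_g) <= 0:
        raise ValueError("fitness values must be positive")
    return w_ig - w_i * w_g


def is_sign_epistatic(w_ig: float, w_i: float, w_g: float) -> bool:
    """True when the focal mutation reverses direction across backgrounds.

    Beneficial alone (W_i > 1) but deleterious in the background
    (W_ig < W_g), or vice versa.
    """
    return (w_ig < w_g and w_i > 1.0) or (w_ig > w_g and w_i < 1.0)


def _parse_genotype(s) -> frozenset[str]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return frozenset()
    return frozenset(m for m in str(s).split(";") if m)


def normalize_to_ancestor(strains: pd.DataFrame,
                          fitness_col: str = "fitness_obs") -> pd.DataFrame:
    """Divide all fitness values by the ancestor row's fitness."""
    genos = strains["genotype"].map(_parse_genotype)
    is_anc = (genos.map(len) == 0)
    if "category" in strains.columns:
        is_anc &= strains["category"] == "ancestor"
    if not is_anc.any():
        raise ValueError("no ancestor row (empty genotype) in strain table")
    w_anc = float(strains.loc[is_anc, fitness_col].iloc[0])
    if w_anc <= 0:
        raise ValueError("ancestor fitness must be positive")
    out = strains.copy()
    out[fitness_col] = out[fitness_col] / w_anc
    return out


def _single_fitness_map(strains: pd.DataFrame, fitness_col: str
                        ) -> dict[str, float]:
    singles = {}
    for _, row in strains.iterrows():
        g = _parse_genotype(row["genotype"])
        if len(g) == 1:
            singles[next(iter(g))] = float(row[fitness_col])
    return singles


def records_from_strain_table(strains: pd.DataFrame,
                              fitness_col: str = "fitness_obs",
                              *,
                              normalize: bool = True) -> pd.DataFrame:
    """Epistasis records for every (focal, background) split of each combination.

    Each multi-mutation genotype contributes one record per constituent
    mutation, with the remaining mutations as the background; the
    background's fitness must be present in the table (for pairs it is
    the other single).  Fitness values are ancestor-normalized first
    unless ``normalize=False``.
    """
    df = normalize_to_ancestor(strains, fitness_col) if normalize else strains
    by_geno: dict[frozenset, float] = {}
    for _, row in df.iterrows():
        g = _parse_genotype(row["genotype"])
        if row.get("category") == "inducible":
            continue
        by_geno.setdefault(g, float(row[fitness_col]))

    recs = []
    for g, w_ig in by_geno.items():
        if len(g) < 2:
            continue
        for focal in sorted(g):
            bg = g - {focal}
            w_i = by_geno.get(frozenset([focal]))
            w_g = by_geno.get(bg)
            if w_i is None:
                raise ValueError(
                    f"combination {';'.join(sorted(g))} references single "
                    f"mutant {focal!r} absent from the table")
            if w_g is None:
                logger.warning("background %s not measured; skipping record",
                               ";".join(sorted(bg)))
                continue
            recs.append(EpistasisRecord.build(
                focal, ";".join(sorted(bg)), w_i, w_g, w_ig))
    return pd.DataFrame([r.__dict__ for r in recs], columns=RECORD_COLUMNS)


def fit_multiplicative_fitness_null(strains: pd.DataFrame,
                                    fitness_col: str = "fitness_obs",
                                    *,
                                    normalize: bool = True):
    """Score the multiplicative null W_comb = prod(W_singles) on a table.

    For every combination genotype the expected fitness is the product
    of its constituent single-mutant fitnesses.  Returns
    ``(r2, adj_r2, residuals)`` where R^2 is the squared Pearson
    correlation of observed on expected, the adjustment uses the number
    of single-mutant parameters, and ``residuals`` lists observed,
    expected and their difference (= epsilon) per combination.
    """
    df = normalize_to_ancestor(strains, fitness_col) if normalize else strains
    singles = _single_fitness_map(df, fitness_col)
    rows = []
    for _, row in df.iterrows():
        g = _parse_genotype(row["genotype"])
        if len(g) < 2 or row.get("category") == "inducible":
            continue
        missing = [m for m in sorted(g) if m not in singles]
        if missing:
            raise ValueError(
                f"combination {';'.join(sorted(g))} references missing "
                f"singles: {missing}")
        expected = float(np.prod([singles[m] for m in sorted(g)]))
        observed = float(row[fitness_col])
        rows.append({"genotype": ";".join(sorted(g)),
                     "observed": observed, "expected": expected,
                     "residual": observed - expected})
    if not rows:
        raise ValueError("no combination genotypes in table")
    resid = pd.DataFrame(rows)
    n = len(resid)
    if n >= 2 and resid["expected"].std() > 0 and resid["observed"].std() > 0:
        r = float(np.corrcoef(resid["observed"], resid["expected"])[0, 1])
        r2 = r ** 2
    else:
        r2 = float("nan")
    p = len({m for g in resid["genotype"] for m in g.split(";")})
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 \
        else float("nan")
    return r2, adj_r2, resid


@dataclass
class TrendSummary:
    """Summary of the s vs mean-epsilon relationship."""

    per_mutation: pd.DataFrame       # mutation_id, s, mean_epsilon, n
    slope: float
    slope_ci: tuple[float, float]
    slope_pvalue: float              # two-sided, H0: slope = 0
    intercept: float
    compare: tuple[str, str] | None = None
    t_statistic: float | None = None
    t_pvalue: float | None = None


def s_epsilon_trend(records: pd.DataFrame,
                    compare: tuple[str, str] | None = None,
                    *,
                    equal_var: bool = False) -> TrendSummary:
    """Per-mutation mean epsilon, OLS of mean epsilon on s, group test.

    Averages epsilon over all backgrounds for each focal mutation,
    regresses the means on the mutations' selection coefficients, and
    optionally compares the epsilon sets of two named mutations with a
    t-test (Welch by default).
    """
    if records.empty:
        raise ValueError("no epistasis records")
    grp = records.groupby("mutation_id")
    per = grp.agg(s=("s_i", "mean"), mean_epsilon=("epsilon", "mean"),
                  n=("epsilon", "size")).reset_index()
    empty = per[per["n"] == 0]
    if len(empty):
        logger.warning("mutations with zero records excluded: %s",
                       list(empty["mutation_id"]))
        per = per[per["n"] > 0]
    if per["mutation_id"].nunique() < 2:
        raise ValueError("need at least two distinct mutations")

    X = sm.add_constant(per["s"].to_numpy(float))
    ols = sm.OLS(per["mean_epsilon"].to_numpy(float), X).fit()
    ci = ols.conf_int()[1]

    t_stat = t_p = None
    if compare is not None:
        a, b = compare
        ea = records.loc[records["mutation_id"] == a, "epsilon"]
        eb = records.loc[records["mutation_id"] == b, "epsilon"]
        if ea.empty or eb.empty:
            raise ValueError(f"no records for one of {compare}")
        t = stats.ttest_ind(ea, eb, equal_var=equal_var)
        t_stat, t_p = float(t.statistic), float(t.pvalue)

    return TrendSummary(per_mutation=per,
                        slope=float(ols.params[1]),
                        slope_ci=(float(ci[0]), float(ci[1])),
                        slope_pvalue=float(ols.pvalues[1]),
                        intercept=float(ols.params[0]),
                        compare=compare, t_statistic=t_stat, t_pvalue=t_p)


def normalize_dataset(table: pd.DataFrame, ancestor_id: str = "",
                      transform: str = "none") -> pd.DataFrame:
    """Harmonize an external genotype-fitness table.

    ``transform="exp2"`` first exponentiates fitness base 2 (for data
    reported as growth rate in doublings per hour); the table is then
    divided by the ancestor row's fitness so the ancestor maps to 1.
    The ancestor row is the one whose genotype equals ``ancestor_id``
    (default: the empty genotype).
    """
    if transform not in ("none", "exp2"):
        raise ValueError("transform must be 'none' or 'exp2'")
    if "genotype" not in table.columns or "fitness" not in table.columns:
        raise ValueError("table needs 'genotype' and 'fitness' columns")
    out = table.copy()
    out["genotype"] = out["genotype"].fillna("")
    if transform == "exp2":
        out["fitness"] = 2.0 ** out["fitness"].astype(float)
    anc = out["genotype"].astype(str) == str(ancestor_id)
    if not anc.any():
        raise ValueError(f"no ancestor row with genotype {ancestor_id!r}")
    w_anc = float(out.loc[anc, "fitness"].iloc[0])
    if w_anc <= 0:
        raise ValueError("ancestor fitness must be positive")
    out["fitness"] = out["fitness"].astype(float) / w_anc
    return out


def load_genotype_fitness_csv(path) -> pd.DataFrame:
    """Load a generic genotype-fitness CSV.

    Expected columns: ``genotype`` (semicolon-joined mutation ids,
    empty for the ancestor), ``fitness``, and optionally ``dataset``.
    """
    df = pd.read_csv(path, dtype={"genotype": str}, keep_default_na=False)
    missing = {"genotype", "fitness"} - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {sorted(missing)}")
    df["fitness"] = df["fitness"].astype(float)
    return df
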