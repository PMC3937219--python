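"""Regression-to-the-mean null model for the s-epsilon correlation.

Simulates fitness landscapes constructed to have *no* mean epistatic
tendency: each locus i carries a background-independent log-fitness
main effect m_i, plus an idiosyncratic deviation eta_{i,b} ~ N(0,
sigma^2) drawn independently for every (locus, background) pairing.
A genotype's fitness is

    W_g = exp( sum_{i in g} m_i + eta_{i, g \\ i} ),

so for any pair of loci E[epsilon] = 0 exactly: both the combination
and the product of singles have the same expected value given the main
effects.

The point of the exercise: if loci are *ascertained* as beneficial in
the ancestor (W_i > 1), the ancestral deviation eta_{i, ancestor} is
biased upward, the single-mutant fitness overstates the locus's
typical effect, and epsilon = W_ig - W_i*W_g becomes negative on
average -- most strongly for the largest observed s.  A negative
s-epsilon trend therefore arises from conditioning alone, with no
physiological antagonism in the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epistasis import s_epsilon_trend, TrendSummary

__all__ = ["NullSimConfig", "simulate_null_landscape", "trend_summary"]


@dataclass(frozen=True)
class NullSimConfig:
    """Settings for the no-mean-epistasis landscape simulation."""

    n_loci: int = 6
    s_mean: float = 0.0          # mean of per-locus log-fitness main effects
    s_sd: float = 0.2            # sd of main effects
    sigma_idiosyncratic: float = 0.15   # sd of per-(locus, background) deviations
    condition_on_beneficial: bool = False
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 2:
            raise ValueError("need at least two loci")
        if self.sigma_idiosyncratic < 0 or self.s_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_null_landscape(config: NullSimConfig) -> pd.DataFrame:
    """Simulate replicate landscapes and emit epistasis records.

    Per replicate: draw main effects m_i, the ancestral deviations
    eta_{i, ancestor}, and pairwise deviations eta_{i, {j}}; build all
    single and double mutants; emit one record per ordered
    (focal, single background) pair.  With
    ``condition_on_beneficial=True`` only loci whose single-mutant
    fitness exceeds 1 in the ancestor are retained, mimicking how
    beneficial mutations are ascertained in evolution experiments.
    Deterministic given ``config.seed``; mutation ids are unique per
    (replicate, locus) so downstream trend statistics treat replicates
    as independent draws of "mutations".
    """
    rng = np.random.default_rng(config.seed)
    L, R = config.n_loci, config.n_replicates
    m = rng.normal(config.s_mean, config.s_sd, size=(R, L))
    eta_anc = rng.normal(0.0, config.sigma_idiosyncratic, size=(R, L))
    # eta_pair[r, i, j]: deviation of locus i in background {j}
    eta_pair = rng.normal(0.0, config.sigma_idiosyncratic, size=(R, L, L))

    w_single = np.exp(m + eta_anc)                       # (R, L)
    # W_{ij} = exp(m_i + eta_{i,{j}} + m_j + eta_{j,{i}}), symmetric in (i, j)
    log_w_pair = (m[:, :, None] + eta_pair
                  + m[:, None, :] + np.swapaxes(eta_pair, 1, 2))
    w_pair = np.exp(log_w_pair)                          # (R, L, L)

    keep = w_single > 1.0 if config.condition_on_beneficial \
        else np.ones_like(w_single, dtype=bool)

    reps, focals, bgs = [], [], []
    w_i_col, w_g_col, w_ig_col = [], [], []
    for r in range(R):
        loci = np.flatnonzero(keep[r])
        if len(loci) < 2:
            continue
        ii, jj = np.meshgrid(loci, loci, indexing="ij")
        mask = ii != jj
        ii, jj = ii[mask], jj[mask]
        reps.append(np.full(len(ii), r))
        focals.append(ii)
        bgs.append(jj)
        w_i_col.append(w_single[r, ii])
        w_g_col.append(w_single[r, jj])
        w_ig_col.append(w_pair[r, ii, jj])
    if not reps:
        raise RuntimeError(
            "conditioning left fewer than two beneficial loci in every "
            "replicate; lower the threshold or raise s_mean/s_sd")

    rep = np.concatenate(reps)
    focal = np.concatenate(focals)
    bg = np.concatenate(bgs)
    w_i = np.concatenate(w_i_col)
    w_g = np.concatenate(w_g_col)
    w_ig = np.concatenate(w_ig_col)
    eps = w_ig - w_i * w_g
    df = pd.DataFrame({
        "replicate": rep,
        "mutation_id": [f"r{r}_L{i}" for r, i in zip(rep, focal)],
        "background_id": [f"r{r}_L{j}" for r, j in zip(rep, bg)],
        "w_i": w_i, "w_g": w_g, "w_ig": w_ig,
        "s_i": w_i - 1.0,
        "epsilon": eps,
        "sign_epistasis": ((w_ig < w_g) & (w_i > 1))
                          | ((w_ig > w_g) & (w_i < 1)),
        "conditioned": config.condition_on_beneficial,
    })
    return df


def trend_summary(records: pd.DataFrame) -> dict:
    """Slope and CI of the s-epsilon relation plus conditional mean gap.

    Delegates the regression to
    :func:`fitscape.epistasis.s_epsilon_trend` over per-mutation means.
    If the table mixes conditioned and unconditioned records (column
    ``conditioned``), also reports the conditional-minus-unconditional
    mean-epsilon gap.
    """
    if records["s_i"].nunique() < 2:
        raise ValueError("need at least two distinct s values")
    trend: TrendSummary = s_epsilon_trend(records)
    if "replicate" in records.columns:
        # records within a replicate share draws; the Monte-Carlo error
        # of the mean comes from the independent per-replicate means
        per_rep = records.groupby("replicate")["epsilon"].mean()
        sem = float(per_rep.std(ddof=1) / np.sqrt(len(per_rep)))
    else:
        sem = float(records["epsilon"].std(ddof=1) / np.sqrt(len(records)))
    out = {
        "slope": trend.slope,
        "slope_ci": trend.slope_ci,
        "slope_pvalue": trend.slope_pvalue,
        "mean_epsilon": float(records["epsilon"].mean()),
        "sem_epsilon": sem,
        "n_records": int(len(records)),
    }
    if "conditioned" in records.columns and records["conditioned"].nunique() == 2:
        cond = records.loc[records["conditioned"], "epsilon"].mean()
        uncond = records.loc[~records["conditioned"], "epsilon"].mean()
        out["mean_epsilon_conditional"] = float(cond)
        out["mean_epsilon_unconditional"] = float(uncond)
        out["conditional_gap"] = float(cond - uncond)
    return out
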