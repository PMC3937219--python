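"""Synthetic study generator with known ground truth.

Emulates the design of the experimental study: one ancestor carrying a
two-enzyme formaldehyde-oxidation cassette on a medium-copy plasmid
(~9 per cell), three Class A mutations that lower per-copy expression,
Class B variants (B2, B3, B5 and the co-occurring B2-B3 pair) that
lower plasmid copy number, all 3 x 4 = 12 A x B combination plasmids,
and an inducible-promoter dilution series that scales both enzymes by a
common factor at ancestral copy number.

Mutation effects compose multiplicatively on expression (total enzyme
level = ancestor level x product of per-copy multipliers x copy-number
ratio); true fitness comes from the benefit-cost landscape model; every
record carries both the noise-free truth and observations perturbed by
a configurable noise model, plus a partition flag: ancestor, singles
and the inducible series form the "fit" set, combinations the
"predict" set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assays import CompetitionAssay, StandardCurve, molecules_from_mass
from .landscape import LandscapeParameters, landscape_fitness

__all__ = [
    "StudyDesign",
    "MutationEffect",
    "NoiseModel",
    "default_design",
    "default_effects",
    "default_true_params",
    "default_noise",
    "generate_study",
    "simulate_competition_counts",
    "simulate_qpcr",
    "write_study",
    "QPCR_STANDARD_MASSES_NG",
    "GENOME_COPIES_PER_25NG",
    "PLASMID_LENGTH_BP",
]

#: four-point qPCR dilution ladder (ng of plasmid per reaction)
QPCR_STANDARD_MASSES_NG = (1.0, 0.1, 0.01, 0.001)
#: genome equivalents in the 25 ng of genomic DNA loaded per reaction
GENOME_COPIES_PER_25NG = 3.03e6
#: plasmid length (bp) used to convert standard masses to molecules;
#: chosen so 1 ng corresponds to ~9.09e7 molecules
PLASMID_LENGTH_BP = 10_190


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the study: who gets built and at what baseline."""

    n_class_a: int = 3
    class_b_ids: tuple[str, ...] = ("B2", "B3", "B5", "B2B3")
    inducible_levels: tuple[float, ...] = (1.0, 0.85, 0.7, 0.55, 0.45, 0.35,
                                           0.27, 0.2, 0.14, 0.09, 0.05, 0.03)
    ancestor_expression: tuple[float, float] = (100.0, 100.0)  # (FlhA, FghA) mU
    ancestor_copy_number: float = 9.0

    def __post_init__(self) -> None:
        if self.n_class_a < 1 or not self.class_b_ids:
            raise ValueError("need at least one Class A and one Class B id")
        if min(self.ancestor_expression) <= 0:
            raise ValueError("ancestor expression must be positive")
        if self.ancestor_copy_number <= 0:
            raise ValueError("ancestor copy number must be positive")
        lv = self.inducible_levels
        if any(not (0 < x <= 1) for x in lv):
            raise ValueError("inducible levels must lie in (0, 1]")
        if list(lv) != sorted(lv, reverse=True):
            raise ValueError("inducible levels must be sorted descending")

    @property
    def class_a_ids(self) -> tuple[str, ...]:
        return tuple(f"A{i}" for i in range(1, self.n_class_a + 1))


@dataclass(frozen=True)
class MutationEffect:
    """Per-mutation multiplicative effect on expression and copy number.

    ``mult_flha``/``mult_fgha`` act on per-copy expression;
    ``mult_copy`` scales plasmid copy number (and with it both enzymes,
    since total level is per-copy level times dosage).  Class A
    mutations leave copy number untouched (mult_copy = 1).  Idealized
    Class B mutations act purely through copy number, but non-unit
    per-copy multipliers are allowed to represent variants that, like
    B2 and B5, depress FghA more than FlhA through mechanisms beyond
    dosage.
    """

    id: str
    mutation_class: str  # "A" or "B"
    mult_flha: float = 1.0
    mult_fgha: float = 1.0
    mult_copy: float = 1.0

    def __post_init__(self) -> None:
        if self.mutation_class not in ("A", "B"):
            raise ValueError("mutation_class must be 'A' or 'B'")
        if min(self.mult_flha, self.mult_fgha, self.mult_copy) <= 0:
            raise ValueError(f"{self.id}: all multipliers must be positive")
        if self.mutation_class == "A" and self.mult_copy != 1.0:
            raise ValueError(
                f"{self.id}: Class A mutations do not change copy number")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the generator.

    Observed values are means of ``n_replicates`` independent
    measurements, mirroring the triplicate enzyme and qPCR assays of
    the study design.  Expression noise is lognormal (mean-preserving)
    with coefficient of variation ``cv_expression``; fitness noise is
    additive Gaussian with sd ``sd_fitness`` per replicate; copy-number
    noise enters as Gaussian dCt error of sd ``qpcr_sd_ct`` per Ct
    measurement (two Ct reads per dCt).
    """

    cv_expression: float = 0.05
    sd_fitness: float = 0.02
    flow_counts: int = 50_000
    qpcr_sd_ct: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv_expression, self.sd_fitness, self.qpcr_sd_ct) < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.flow_counts < 1:
            raise ValueError("flow_counts must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(cv_expression=0.0, sd_fitness=0.0, qpcr_sd_ct=0.0,
                   seed=seed)


def default_design() -> StudyDesign:
    return StudyDesign()


def default_effects() -> list[MutationEffect]:
    """Ground-truth mutation effects for the default study.

    Class A mutants cut FlhA roughly in half and FghA much harder
    (ribosome-binding-site mutations upstream of fghA); Class B
    variants cut copy number, with B2 and B5 additionally depressing
    per-copy FghA (the asymmetric-B case).  B2B3 is the co-occurring
    haplotype, the product of B2 and B3.
    """
    return [
        MutationEffect("A1", "A", mult_flha=0.55, mult_fgha=0.25),
        MutationEffect("A2", "A", mult_flha=0.50, mult_fgha=0.12),
        MutationEffect("A3", "A", mult_flha=0.45, mult_fgha=0.035),
        MutationEffect("B2", "B", mult_fgha=0.80, mult_copy=0.55),
        MutationEffect("B3", "B", mult_copy=0.60),
        MutationEffect("B5", "B", mult_fgha=0.70, mult_copy=0.45),
        MutationEffect("B2B3", "B", mult_fgha=0.80, mult_copy=0.33),
    ]


def default_true_params() -> LandscapeParameters:
    """Ground-truth landscape for the default study.

    Chosen so that, with the ancestor at (100, 100) mU and 9 copies:
    the ancestor has W ~ 1 and sits on the costly (over-expressing)
    flank; the FlhA optimum lies at ~44 mU inside the simulated range;
    the strongest single mutants gain s ~ 0.4-0.5; and the local
    fitness gradient at the ancestor is dominated by the FlhA cost
    (FlhA is the more expensive enzyme per unit), so the steepest
    ascent direction differs markedly from the direction to the global
    optimum.
    """
    return LandscapeParameters(vmax=2.8, eh=10.0, ft=0.30,
                               cost_flha=0.009, cost_fgha=0.0025,
                               cost_copy=0.01)


def default_noise(seed: int = 0) -> NoiseModel:
    return NoiseModel(seed=seed)


def _genotype_label(ids: Sequence[str]) -> str:
    return ";".join(sorted(ids))


def _true_phenotypes(design: StudyDesign,
                     effects: Sequence[MutationEffect]) -> tuple[float, float, float]:
    ea, eg = design.ancestor_expression
    copy_ratio = 1.0
    for e in effects:
        ea *= e.mult_flha
        eg *= e.mult_fgha
        copy_ratio *= e.mult_copy
    # total expression scales with gene dosage
    return ea * copy_ratio, eg * copy_ratio, design.ancestor_copy_number * copy_ratio


def _observe(rng: np.random.Generator, noise: NoiseModel,
             ea: float, eg: float, p: float, w: float) -> tuple[float, float, float, float]:
    n = noise.n_replicates
    if noise.cv_expression > 0:
        sigma = float(np.sqrt(np.log1p(noise.cv_expression ** 2)))
        # mean-preserving lognormal factors
        fa = np.exp(rng.normal(-sigma ** 2 / 2, sigma, n)).mean()
        fg = np.exp(rng.normal(-sigma ** 2 / 2, sigma, n)).mean()
    else:
        fa = fg = 1.0
    if noise.qpcr_sd_ct > 0:
        # dCt = Ct_kan - Ct_rpsB: two Ct reads -> sd*sqrt(2); slope -1
        dct_err = rng.normal(0.0, noise.qpcr_sd_ct * np.sqrt(2), n)
        fp = float(np.mean(2.0 ** dct_err))
    else:
        fp = 1.0
    dw = rng.normal(0.0, noise.sd_fitness, n).mean() if noise.sd_fitness > 0 else 0.0
    return ea * fa, eg * fg, p * fp, w + dw


def generate_study(design: StudyDesign,
                   effects: Sequence[MutationEffect],
                   true_params: LandscapeParameters,
                   noise: NoiseModel,
                   *,
                   clamp: bool = True) -> pd.DataFrame:
    """Generate the full strain table for one simulated study.

    Rows: ancestor, every single mutant, every Class A x Class B
    combination, and one row per inducible-promoter level.  Columns
    carry genotype (semicolon-joined mutation ids, empty for ancestor
    and inducible constructs), category, partition flag, the
    noise-free ``*_true`` phenotypes and the ``*_obs`` observations.
    Deterministic given ``noise.seed``.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("effects list is empty")
    by_id = {e.id: e for e in effects}
    if len(by_id) != len(effects):
        raise ValueError("duplicate mutation ids in effects")
    a_ids = [e.id for e in effects if e.mutation_class == "A"]
    b_ids = [e.id for e in effects if e.mutation_class == "B"]
    if not a_ids or not b_ids:
        raise ValueError("need at least one Class A and one Class B effect")

    rng = np.random.default_rng(noise.seed)
    rows: list[dict] = []

    def add(strain: str, genotype: Sequence[str], category: str,
            partition: str, muts: Sequence[MutationEffect],
            inducible_level: float = np.nan,
            scale: float = 1.0) -> None:
        ea, eg, p = _true_phenotypes(design, muts)
        ea, eg = ea * scale, eg * scale
        w = landscape_fitness(ea, eg, p, true_params, clamp=clamp)
        oa, og, op, ow = _observe(rng, noise, ea, eg, p, w)
        rows.append({
            "strain": strain,
            "genotype": _genotype_label(genotype),
            "category": category,
            "partition": partition,
            "inducible_level": inducible_level,
            "flha_true": ea, "fgha_true": eg, "copy_true": p,
            "fitness_true": w,
            "flha_obs": oa, "fgha_obs": og, "copy_obs": op,
            "fitness_obs": ow,
        })

    add("ancestor", [], "ancestor", "fit", [])
    for mid in a_ids:
        add(mid, [mid], "single_A", "fit", [by_id[mid]])
    for mid in b_ids:
        add(mid, [mid], "single_B", "fit", [by_id[mid]])
    for aid in a_ids:
        for bid in b_ids:
            add(f"{aid}+{bid}", [aid, bid], "combination", "predict",
                [by_id[aid], by_id[bid]])
    for level in design.inducible_levels:
        add(f"ind_{level:g}", [], "inducible", "fit", [],
            inducible_level=level, scale=level)

    return pd.DataFrame(rows)


def simulate_competition_counts(w_true: float,
                                expansion: float = 64.0,
                                n0: int = 50_000,
                                n1: int = 50_000,
                                seed: int = 0,
                                *,
                                exact: bool = False) -> CompetitionAssay:
    """Simulate flow-cytometry counts of a head-to-head competition.

    The test strain is mixed with the reference near a 50:50 ratio and
    the culture expands ``expansion``-fold.  Given the true Malthusian
    fitness ratio ``w_true``, the reference growth factor g solves
    f0*g**w + (1-f0)*g = expansion, the test factor is g**w, and the
    final test fraction follows; pre/post counts are binomial samples
    of the two fractions.  With ``exact=True`` the initial fraction is
    exactly 0.5 and counts are the (fractional) expected values, so
    :func:`fitscape.assays.competition_fitness` recovers ``w_true``
    exactly.
    """
    if w_true <= 0:
        raise ValueError("w_true must be positive")
    if expansion <= 1:
        raise ValueError("expansion must exceed 1")
    if min(n0, n1) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    f0 = 0.5 if exact else float(np.clip(rng.normal(0.5, 0.02), 0.3, 0.7))

    def gap(g_ref: float) -> float:
        return f0 * g_ref ** w_true + (1 - f0) * g_ref - expansion

    g_ref = brentq(gap, 1e-9, expansion / (1 - f0))
    f1 = f0 * g_ref ** w_true / expansion

    if exact:
        return CompetitionAssay(n0 * f0, n0 * (1 - f0),
                                n1 * f1, n1 * (1 - f1), expansion=expansion)
    t0 = int(rng.binomial(n0, f0))
    t1 = int(rng.binomial(n1, f1))
    return CompetitionAssay(t0, n0 - t0, t1, n1 - t1, expansion=expansion)


def simulate_qpcr(copies_per_genome: float,
                  curve_truth: StandardCurve | None = None,
                  noise: NoiseModel | None = None,
                  *,
                  genome_copies: float = GENOME_COPIES_PER_25NG,
                  plasmid_length_bp: int = PLASMID_LENGTH_BP):
    """Simulate a qPCR copy-number determination.

    Returns ``(sample_dct, standards)`` where ``standards`` is the
    four-point dilution ladder (mass, molecules, dCt) at the canonical
    masses and ``sample_dct`` is the dCt of a sample containing
    ``copies_per_genome * genome_copies`` plasmid molecules.  At zero
    Ct noise, fitting the standards and interpolating the sample dCt
    recovers ``copies_per_genome`` exactly.
    """
    if copies_per_genome <= 0:
        raise ValueError("copies_per_genome must be positive")
    if curve_truth is None:
        # perfect amplification efficiency: one cycle per doubling
        curve_truth = StandardCurve(slope=-1.0, intercept=30.0, r_squared=1.0)
    if noise is None:
        noise = NoiseModel.noiseless()
    rng = np.random.default_rng(noise.seed)
    sd = noise.qpcr_sd_ct * np.sqrt(2)  # dCt is a difference of two Ct reads

    recs = []
    for mass in QPCR_STANDARD_MASSES_NG:
        mol = molecules_from_mass(mass, plasmid_length_bp)
        dct = curve_truth.slope * np.log2(mol) + curve_truth.intercept
        if sd > 0:
            dct += rng.normal(0.0, sd)
        recs.append({"mass_ng": mass, "molecules": mol, "dct": dct})
    standards = pd.DataFrame(recs)

    sample_molecules = copies_per_genome * genome_copies
    sample_dct = curve_truth.slope * np.log2(sample_molecules) \
        + curve_truth.intercept
    if sd > 0:
        sample_dct += rng.normal(0.0, sd)
    return float(sample_dct), standards


def write_study(strains: pd.DataFrame, outdir,
                design: StudyDesign | None = None,
                effects: Sequence[MutationEffect] | None = None,
                true_params: LandscapeParameters | None = None,
                noise: NoiseModel | None = None) -> dict[str, Path]:
    """Write the strain table as CSV plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"strains": outdir / "strains.csv"}
    strains.to_csv(paths["strains"], index=False)
    truth = {}
    if design is not None:
        truth["design"] = asdict(design)
    if effects is not None:
        truth["effects"] = [asdict(e) for e in effects]
    if true_params is not None:
        truth["landscape_parameters"] = true_params.to_dict()
    if noise is not None:
        truth["noise"] = asdict(noise)
    if truth:
        paths["ground_truth"] = outdir / "ground_truth.json"
        with open(paths["ground_truth"], "w") as fh:
            json.dump(truth, fh, indent=2)
    return paths
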