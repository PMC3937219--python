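"""Reduce raw assay observations to model-ready phenotypes.

Three assay chains are covered:

* head-to-head competition counts (flow cytometry) -> relative fitness
  ``W`` as a ratio of Malthusian parameters under a known total fold
  expansion of the mixed culture;
* enzyme activities in mU -> levels relative to the ancestor (= 100);
* qPCR threshold cycles -> plasmid copies per genome via a standard
  curve of dCt = Ct_kan - Ct_rpsB against log2 plasmid molecules.

The competition-fitness equation is reconstructed as the ratio of log
realized expansions of test vs reference strains; the culture-wide
expansion factor is a parameter (default 64, i.e. a 1/64 serial
transfer, log2(64) = 6 generations per cycle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompetitionAssay",
    "StandardCurve",
    "AVOGADRO",
    "DSDNA_G_PER_MOL_BP",
    "competition_fitness",
    "selection_coefficient",
    "generations_per_cycle",
    "relative_level",
    "molecules_from_mass",
    "fit_standard_curve",
    "copies_per_genome",
    "reduce_competition_table",
]

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
#: average molar mass of one double-stranded base pair, g/mol/bp
DSDNA_G_PER_MOL_BP = 650.0

#: counting floor below which flow-cytometry fractions get noisy
MIN_FLOW_COUNTS = 50_000


@dataclass(frozen=True)
class CompetitionAssay:
    """Pre/post cell counts of test and reference populations.

    Counts are usually integers from a cytometer but fractional values
    are accepted (e.g. expected counts from a noise-free simulation);
    only the fractions matter.
    """

    test_count_0: float
    ref_count_0: float
    test_count_1: float
    ref_count_1: float
    expansion: float = 64.0

    def __post_init__(self) -> None:
        if min(self.test_count_0, self.ref_count_0,
               self.test_count_1, self.ref_count_1) < 0:
            raise ValueError("counts must be non-negative")
        if self.test_count_0 + self.ref_count_0 <= 0 \
                or self.test_count_1 + self.ref_count_1 <= 0:
            raise ValueError("each timepoint needs a positive total count")
        if self.expansion <= 1:
            raise ValueError("expansion must exceed 1")
        for t, tot in (("0", self.test_count_0 + self.ref_count_0),
                       ("1", self.test_count_1 + self.ref_count_1)):
            if tot < MIN_FLOW_COUNTS:
                logger.warning(
                    "timepoint %s total count %.0f below the %d-count floor",
                    t, tot, MIN_FLOW_COUNTS)

    @property
    def f0(self) -> float:
        return self.test_count_0 / (self.test_count_0 + self.ref_count_0)

    @property
    def f1(self) -> float:
        return self.test_count_1 / (self.test_count_1 + self.ref_count_1)


def competition_fitness(assay: CompetitionAssay) -> float:
    """Relative fitness W of the test strain from a competition assay.

    With test fractions f0 before and f1 after growth and total
    expansion X, the test strain expanded by X*f1/f0 and the reference
    by X*(1-f1)/(1-f0); W is the ratio of their log (Malthusian)
    expansions:

        W = ln(X * f1/f0) / ln(X * (1-f1)/(1-f0))

    W = 1 for a neutral competitor (f1 = f0) and W > 1 iff the test
    strain gained ground.
    """
    if min(assay.test_count_0, assay.ref_count_0,
           assay.test_count_1, assay.ref_count_1) <= 0:
        raise ValueError(
            "all four counts must be positive for a defined fitness "
            "(a fraction of exactly 0 or 1 gives an undefined log ratio)")
    f0, f1 = assay.f0, assay.f1
    ref_growth = assay.expansion * (1.0 - f1) / (1.0 - f0)
    if ref_growth <= 1.0:
        raise ValueError(
            "reference population did not grow (log denominator <= 0); "
            "fitness ratio undefined")
    return math.log(assay.expansion * f1 / f0) / math.log(ref_growth)


def selection_coefficient(w: float) -> float:
    """Selection coefficient s = W - 1 of a mutation vs the ancestor."""
    if w <= 0:
        raise ValueError("relative fitness must be positive")
    return w - 1.0


def generations_per_cycle(expansion: float = 64.0) -> float:
    """Generations of binary fission per growth cycle: log2(expansion)."""
    if expansion <= 1:
        raise ValueError("expansion must exceed 1")
    return math.log2(expansion)


def relative_level(activity: float, ancestor_activity: float) -> float:
    """Enzyme level on the relative scale where the ancestor is 100."""
    if ancestor_activity <= 0:
        raise ValueError("ancestor activity must be positive")
    if activity < 0:
        raise ValueError("activity must be non-negative")
    return 100.0 * activity / ancestor_activity


def molecules_from_mass(mass_ng: float, length_bp: int) -> float:
    """Number of dsDNA molecules in ``mass_ng`` of a ``length_bp`` species.

    molecules = mass[g] * N_A / (650 g/mol/bp * length)
    Linear in mass, so a 10-fold dilution ladder maps to exactly
    10-fold molecule ratios.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return mass_ng * 1e-9 * AVOGADRO / (DSDNA_G_PER_MOL_BP * length_bp)


@dataclass(frozen=True)
class StandardCurve:
    """Linear qPCR standard curve: dCt vs log2(plasmid molecules)."""

    slope: float
    intercept: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                "standard-curve slope must be negative: more template "
                "means an earlier threshold cycle")


def fit_standard_curve(standards) -> StandardCurve:
    """Ordinary least squares of dCt on log2(molecules).

    ``standards`` is an iterable of ``(dct, molecules)`` pairs with at
    least two distinct molecule counts.
    """
    pairs = [(float(d), float(m)) for d, m in standards]
    if len(pairs) < 2:
        raise ValueError("need at least two standards")
    dct = np.array([p[0] for p in pairs])
    mol = np.array([p[1] for p in pairs])
    if np.any(mol <= 0):
        raise ValueError("molecule counts must be positive")
    x = np.log2(mol)
    if np.ptp(x) == 0:
        raise ValueError("standards are degenerate: all at one molecule count")
    res = stats.linregress(x, dct)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2))


def copies_per_genome(sample_dct: float, curve: StandardCurve,
                      genome_copies_in_reaction: float) -> float:
    """Plasmid copies per genome from a sample dCt and a standard curve.

    Inverts the curve: molecules = 2**((dCt - intercept)/slope), then
    divides by the genome copies loaded in the reaction (25 ng of
    genomic DNA corresponds to 3.03e6 genome equivalents).
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope must be nonzero")
    if genome_copies_in_reaction <= 0:
        raise ValueError("genome copies in reaction must be positive")
    molecules = 2.0 ** ((sample_dct - curve.intercept) / curve.slope)
    return molecules / genome_copies_in_reaction


def reduce_competition_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Reduce a tidy competition-count table to per-strain fitness.

    Expects columns ``strain, test_count_0, ref_count_0, test_count_1,
    ref_count_1`` and optionally ``expansion``; replicate rows per
    strain are averaged after reduction.  Returns a tidy table
    ``(strain, phenotype, value, sd, n)``.
    """
    required = {"strain", "test_count_0", "ref_count_0",
                "test_count_1", "ref_count_1"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"competition table missing columns: {sorted(missing)}")
    rows = []
    for _, r in counts.iterrows():
        assay = CompetitionAssay(
            r["test_count_0"], r["ref_count_0"],
            r["test_count_1"], r["ref_count_1"],
            expansion=float(r.get("expansion", 64.0)))
        rows.append({"strain": r["strain"], "w": competition_fitness(assay)})
    per = pd.DataFrame(rows).groupby("strain")["w"]
    out = per.agg(["mean", "std", "count"]).reset_index()
    out.columns = ["strain", "value", "sd", "n"]
    out.insert(1, "phenotype", "fitness")
    return out
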