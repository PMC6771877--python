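"""Host-plant niche overlap and preference-difference testing."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import EstimationError, OvipositionTable, ValidationError

log = logging.getLogger("isobarrier.hostplant")


@dataclass
class OverlapResult:
    pair: tuple[str, str]
    overlap: float
    proportions: pd.DataFrame  # 2 x plants proportion vectors used


def pianka_overlap(p, q) -> float:
    """Pianka's niche overlap ``O = sum(p q) / sqrt(sum(p^2) sum(q^2))``.

    Inputs may be raw counts; they are normalized internally.  O is symmetric
    and ranges from 0 (disjoint resource use) to 1 (identical use).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("resource vectors must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValidationError("resource-use vectors must be non-negative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValidationError("all-zero resource vector: overlap undefined")
    p = p / p.sum()
    q = q / q.sum()
    return float((p * q).sum() / np.sqrt((p**2).sum() * (q**2).sum()))


def overlap_matrix(table: OvipositionTable) -> pd.DataFrame:
    """Pairwise Pianka overlap between all taxa in an oviposition table."""
    props = table.proportions()
    taxa = list(props.index)
    out = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            o = pianka_overlap(props.loc[a], props.loc[b])
            out.loc[a, b] = out.loc[b, a] = o
    return out


def pair_overlap(table: OvipositionTable, pair: tuple[str, str]) -> OverlapResult:
    props = table.proportions().loc[list(pair)]
    return OverlapResult(pair=pair, overlap=pianka_overlap(props.iloc[0], props.iloc[1]),
                         proportions=props)


def hostplant_x(overlap: float) -> float:
    """Gene-flow probability for the host-plant barrier: ``x = O``.

    Chosen because ``Ri = 1 - 2O`` reproduces the published host-plant
    isolation values from the published overlap values.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap}")
    return float(overlap)


@dataclass
class PreferenceTestResult:
    pair: tuple[str, str]
    statistic: float  # LRT deviance difference
    df: int
    pvalue: float
    delta_aic: float  # AIC(no interaction) - AIC(interaction)
    skipped: bool = False
    reason: str = ""


def preference_difference_test(
    table: OvipositionTable, pair: tuple[str, str]
) -> PreferenceTestResult:
    """Test for a taxon x plant interaction in per-female egg counts.

    Negative-binomial count model with per-female total-activity offsets (a
    fixed-effect simplification of a random female intercept): the model with
    the ``taxon x plant`` interaction is compared against main effects alone
    by a likelihood-ratio test with ``(taxa - 1)(plants - 1)`` df.  Plants with no
    eggs from either taxon are dropped (logged).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not table.has_females:
        raise ValidationError("per-female data required for the preference test")
    a, b = pair
    df = table.long[table.long["taxon"].isin([a, b])]
    # complete the (female, plant) grid with zeros
    counts = (
        df.groupby(["taxon", "female_id", "plant"])["eggs"].sum().unstack(fill_value=0)
    )
    plant_totals = counts.sum(axis=0)
    dead = plant_totals.index[plant_totals == 0]
    if len(dead):
        log.warning("dropping plant(s) with zero total eggs: %s", list(dead))
        counts = counts.drop(columns=dead)
    n_plants = counts.shape[1]
    taxa_present = counts.index.get_level_values("taxon").unique()
    df_int = (len(taxa_present) - 1) * (n_plants - 1)
    if df_int < 1:
        return PreferenceTestResult(
            pair=pair, statistic=float("nan"), df=0, pvalue=float("nan"),
            delta_aic=float("nan"), skipped=True,
            reason="degenerate design: fewer than two taxa or plants",
        )
    female_totals = counts.sum(axis=1)
    keep = female_totals > 0
    counts = counts[keep]
    female_totals = female_totals[keep]
    if counts.index.get_level_values("taxon").nunique() < 2:
        return PreferenceTestResult(
            pair=pair, statistic=float("nan"), df=0, pvalue=float("nan"),
            delta_aic=float("nan"), skipped=True,
            reason="a taxon has no egg-laying females",
        )

    long = counts.stack().rename("eggs").reset_index()
    long["offset"] = np.log(
        long.set_index(["taxon", "female_id"]).index.map(female_totals) / n_plants
    ).to_numpy()

    kwargs = dict(offset=long["offset"], data=long)
    null_f = "eggs ~ C(plant) + C(taxon)"
    alt_f = "eggs ~ C(plant) * C(taxon)"
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NB alpha near boundary is routine here
        try:
            m0 = smf.negativebinomial(null_f, **kwargs).fit(disp=0, maxiter=200)
            m1 = smf.negativebinomial(alt_f, **kwargs).fit(disp=0, maxiter=200)
            llf0, llf1 = m0.llf, m1.llf
            aic0, aic1 = m0.aic, m1.aic
        except Exception:  # NB alpha on the boundary: fall back to Poisson GLM
            log.warning("NB fit failed for pair %s; falling back to Poisson", pair)
            m0 = smf.glm(null_f, family=sm.families.Poisson(), **kwargs).fit()
            m1 = smf.glm(alt_f, family=sm.families.Poisson(), **kwargs).fit()
            llf0, llf1 = m0.llf, m1.llf
            aic0, aic1 = m0.aic, m1.aic
    stat = 2.0 * (llf1 - llf0)
    p = float(chi2.sf(stat, df_int))
    return PreferenceTestResult(
        pair=pair, statistic=float(stat), df=int(df_int), pvalue=p,
        delta_aic=float(aic0 - aic1),
    )
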