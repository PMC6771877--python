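"""Hatch-rate modelling with overdispersion and pupal survivorship tests.

Hatch rates are modelled as quasi-binomial proportions: logit link, fit by
IRLS, with the variance ``V(mu) = Phi * mu * (1 - mu)`` and the dispersion
``Phi`` estimated from the Pearson statistic over residual df.  Parasitized
eggs are excluded from the denominator before fitting.  Pupal survivorship
uses the Pearson equality-of-proportions chi-square (no continuity
correction) with Wilson score intervals per cross.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.proportion import proportion_confint

from .core import BroodTable, EstimationError, PupalFateTable, ValidationError

log = logging.getLogger("isobarrier.viability")


# --------------------------------------------------------------------------
# egg hatch
# --------------------------------------------------------------------------

def parasitism_filter(broods: BroodTable) -> pd.DataFrame:
    """Per-brood hatch data with parasitized eggs removed from the denominator."""
    df = broods.df.copy()
    df["eggs_at_risk"] = df["eggs_laid"] - df["eggs_parasitized"]
    excluded = int(df["eggs_parasitized"].sum())
    if excluded:
        log.info("excluded %d parasitized egg(s) from hatch denominators", excluded)
    bad = df.index[df["eggs_hatched"] > df["eggs_at_risk"]]
    if len(bad):
        raise ValidationError(f"hatched exceeds at-risk eggs at row {bad[0]}")
    return df


@dataclass
class HatchModelResult:
    predictions: pd.DataFrame  # per cross: mu, ci_lower, ci_upper
    dispersion: float  # Phi, Pearson X2 / residual df
    protocol_effect: tuple[float, int, float]  # scaled LRT for the phase covariate
    cross_effect: tuple[float, int, float]  # scaled LRT for the cross factor
    dropped_crosses: list[str]


def hatch_model(broods: BroodTable, level: float = 0.95) -> HatchModelResult:
    """Quasi-binomial hatch model with protocol-phase and cross-type factors.

    Deviance differences are scaled by the dispersion of the richer model and
    referred to chi-square distributions.  Per-cross predicted probabilities
    carry Wald CIs on the logit scale, inflated by sqrt(Phi).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy.special import expit

    df = parasitism_filter(broods)
    df = df[df["eggs_at_risk"] > 0].copy()
    per_cross = df.groupby("cross_type").size()
    dropped = sorted(set(broods.df["cross_type"]) - set(per_cross.index))
    if dropped:
        log.warning("dropping cross(es) with no at-risk eggs: %s", dropped)
    few = per_cross.index[per_cross < 2]
    if len(few):
        log.warning("cross(es) with a single brood retained: %s", list(few))
    if df.empty:
        raise EstimationError("no broods with at-risk eggs")
    df["failures"] = df["eggs_at_risk"] - df["eggs_hatched"]

    fam = sm.families.Binomial()
    kwargs = dict(data=df, family=fam)
    m_null = smf.glm("eggs_hatched + failures ~ 1", **kwargs).fit()
    m_phase = smf.glm("eggs_hatched + failures ~ C(protocol_phase)", **kwargs).fit()
    m_full = smf.glm(
        "eggs_hatched + failures ~ C(protocol_phase) + C(cross_type)", **kwargs
    ).fit()

    # Pearson dispersion over residual df; statsmodels' scale="X2" mishandles
    # two-column binomial endog, so Phi is taken from pearson_chi2 directly.
    resid_df = m_full.df_resid
    if resid_df <= 0:
        phi = 1.0
        log.warning("saturated hatch model; dispersion fixed at 1")
    else:
        phi = float(m_full.pearson_chi2 / resid_df)

    def scaled_lrt(smaller, larger, df_diff: int) -> tuple[float, int, float]:
        stat = (smaller.deviance - larger.deviance) / phi
        return float(stat), int(df_diff), float(chi2.sf(stat, df_diff))

    protocol_effect = scaled_lrt(m_null, m_phase, 1)
    n_cross = df["cross_type"].nunique()
    cross_effect = scaled_lrt(m_phase, m_full, n_cross - 1)

    # per-cross predictions at the reference protocol phase ("after")
    phase = "after" if "after" in set(df["protocol_phase"]) else df["protocol_phase"].iloc[0]
    crosses = sorted(df["cross_type"].unique())
    new = pd.DataFrame({"cross_type": crosses, "protocol_phase": phase})
    lin = m_full.get_prediction(new, which="linear").summary_frame()
    # Wald interval on the logit scale, se inflated by sqrt(Phi)
    z = chi2.ppf(level, 1) ** 0.5
    se = lin["se"].to_numpy() * np.sqrt(phi)
    mu = expit(lin["predicted"].to_numpy())
    lo = expit(lin["predicted"].to_numpy() - z * se)
    hi = expit(lin["predicted"].to_numpy() + z * se)
    predictions = pd.DataFrame(
        {"cross_type": crosses, "mu": mu, "ci_lower": lo, "ci_upper": hi}
    )
    return HatchModelResult(
        predictions=predictions,
        dispersion=phi,
        protocol_effect=protocol_effect,
        cross_effect=cross_effect,
        dropped_crosses=dropped,
    )


# --------------------------------------------------------------------------
# sterility
# --------------------------------------------------------------------------

@dataclass
class FertilityStatus:
    cross_type: str
    status: str  # "sterile" | "fertile" | "insufficient_evidence" | "conflict"
    n_females: int
    total_eggs: int
    dissection_sterile: bool | None


def sterility_classifier(
    broods: BroodTable,
    dissections: dict[str, bool] | None = None,
    min_females: int = 2,
) -> list[FertilityStatus]:
    """Classify each cross as sterile / fertile / insufficient evidence.

    A cross is sterile when no eggs were laid by any of its females and
    either enough females were tested or a dissection confirmed undeveloped
    ovaries.  Eggs laid despite a sterile dissection flag is a conflict that
    is surfaced, never auto-resolved.
    """
    dissections = dissections or {}
    out = []
    for cross, grp in broods.df.groupby("cross_type"):
        n_females = len(grp)
        total_eggs = int(grp["eggs_laid"].sum())
        dissected = dissections.get(cross)
        if total_eggs > 0 and dissected is True:
            status = "conflict"
        elif total_eggs > 0:
            status = "fertile"
        elif dissected is True or n_females >= min_females:
            status = "sterile"
        else:
            status = "insufficient_evidence"
        out.append(
            FertilityStatus(
                cross_type=cross, status=status, n_females=n_females,
                total_eggs=total_eggs, dissection_sterile=dissected,
            )
        )
    return out


# --------------------------------------------------------------------------
# pupal survivorship
# --------------------------------------------------------------------------

@dataclass
class PupalSurvivalResult:
    chi2: float
    df: int
    pvalue: float
    proportions: pd.DataFrame  # per cross: emerged, total, proportion, CI


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval; endpoints pinned to 0/1 for degenerate counts."""
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return float(lo), float(hi)


def clopper_pearson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(np.nan_to_num(lo, nan=0.0)), float(np.nan_to_num(hi, nan=1.0))


def pupal_survival_test(
    table: PupalFateTable,
    level: float = 0.95,
    ci_method: str = "wilson",
) -> PupalSurvivalResult:
    """Equality of emergence proportions across crosses (Pearson chi-square).

    The 2 x c table of emerged vs total-failures counts is tested without
    continuity correction; crosses with zero pupae are dropped.
    """
    counts = table.counts
    totals = table.totals
    keep = totals.index[totals > 0]
    if len(keep) < len(totals):
        log.warning(
            "dropping cross(es) with zero pupae: %s",
            sorted(set(totals.index) - set(keep)),
        )
    counts = counts.loc[keep]
    totals = totals.loc[keep]
    if len(keep) < 2:
        raise EstimationError("need at least 2 crosses with pupae")
    emerged = counts["emerged"].to_numpy(dtype=float)
    failed = (totals - counts["emerged"]).to_numpy(dtype=float)

    observed = np.vstack([emerged, failed])
    col = observed.sum(axis=0)
    row = observed.sum(axis=1, keepdims=True)
    expected = row * col / observed.sum()
    stat = float(((observed - expected) ** 2 / expected).sum())
    dof = len(keep) - 1
    p = float(chi2.sf(stat, dof))

    ci_fn = {"wilson": wilson_interval, "clopper-pearson": clopper_pearson_interval}[
        ci_method
    ]
    rows = []
    for cross in keep:
        k_e, n_t = int(counts.loc[cross, "emerged"]), int(totals.loc[cross])
        lo, hi = ci_fn(k_e, n_t, level)
        rows.append(
            {
                "cross_type": cross,
                "emerged": k_e,
                "total": n_t,
                "proportion": k_e / n_t,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return PupalSurvivalResult(
        chi2=stat, df=dof, pvalue=p, proportions=pd.DataFrame(rows)
    )
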