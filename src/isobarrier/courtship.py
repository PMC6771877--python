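"""Colour-pattern preference probabilities and courtship-count models."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, norm

from .core import CourtshipTable, EstimationError, ValidationError

log = logging.getLogger("isobarrier.courtship")


# --------------------------------------------------------------------------
# colour-pattern preference (binomial model on courtship events)
# --------------------------------------------------------------------------

@dataclass
class ColorPreference:
    comparison: str  # e.g. "E_vs_Pb": focal taxon vs alternative model
    n_own: int
    n_alt: int
    probability: float  # P(court own phenotype)
    ci: tuple[float, float]
    significant: bool  # CI excludes 0.5


@dataclass
class ColorPreferenceFit:
    estimates: list[ColorPreference]
    location_lrt: tuple[float, int, float] | None  # (stat, df, p) or None


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald CI on the logit scale; Clopper-Pearson at the boundary."""
    alpha = 1 - level
    if k == 0:
        return 0.0, float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    if k == n:
        return float(beta_dist.ppf(alpha / 2, k, n - k + 1)), 1.0
    p = k / n
    logit = np.log(p / (1 - p))
    se = np.sqrt(1 / k + 1 / (n - k))
    z = norm.ppf(1 - alpha / 2)
    lo, hi = logit - z * se, logit + z * se
    expit = lambda t: 1 / (1 + np.exp(-t))
    return float(expit(lo)), float(expit(hi))


def color_preference_fit(
    events: pd.DataFrame, level: float = 0.95
) -> ColorPreferenceFit:
    """Probability of courting the own phenotype, per pairwise comparison.

    ``events`` has one row per (comparison[, location]) with columns
    ``n_own`` and ``n_alt`` counting courtship events toward the own and
    alternative colour-pattern models.  The saturated binomial model with a
    categorical comparison factor has the pooled proportion per comparison as
    its MLE, so estimates and CIs are computed in closed form; an optional
    ``location`` column is tested by a likelihood-ratio test on the binomial
    GLM (df = 1).
    """
    for col in ("comparison", "n_own", "n_alt"):
        if col not in events.columns:
            raise ValidationError(f"events table missing column {col!r}")
    pooled = events.groupby("comparison")[["n_own", "n_alt"]].sum()
    estimates = []
    for comp, row in pooled.iterrows():
        k, n = int(row["n_own"]), int(row["n_own"] + row["n_alt"])
        if n == 0:
            log.warning("comparison %s has no courtship events; skipped", comp)
            continue
        ci = _binomial_ci(k, n, level)
        estimates.append(
            ColorPreference(
                comparison=comp, n_own=k, n_alt=n - k,
                probability=k / n, ci=ci,
                significant=not (ci[0] <= 0.5 <= ci[1]),
            )
        )
    if not estimates:
        raise EstimationError("no comparisons with any courtship events")

    location_lrt = None
    if "location" in events.columns and events["location"].nunique() > 1:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = events.copy()
        df["total"] = df["n_own"] + df["n_alt"]
        df = df[df["total"] > 0]
        m0 = smf.glm(
            "n_own + n_alt ~ C(comparison)", data=df,
            family=sm.families.Binomial(),
        ).fit()
        m1 = smf.glm(
            "n_own + n_alt ~ C(comparison) + C(location)", data=df,
            family=sm.families.Binomial(),
        ).fit()
        stat = 2.0 * (m1.llf - m0.llf)
        location_lrt = (float(stat), 1, float(chi2.sf(stat, 1)))
    return ColorPreferenceFit(estimates=estimates, location_lrt=location_lrt)


def color_x(probabilities: dict[str, float], pair: tuple[str, str]) -> float:
    """Colour-barrier gene flow: mean over the pair of 1 - P(court own).

    ``probabilities`` maps each taxon of the pair to its fitted probability
    of courting its own phenotype when offered against the other taxon.
    """
    a, b = pair
    missing = [t for t in (a, b) if t not in probabilities]
    if missing:
        raise EstimationError(f"missing preference estimate for {missing}")
    return float(np.mean([1 - probabilities[a], 1 - probabilities[b]]))


# --------------------------------------------------------------------------
# courtship-rate count model
# --------------------------------------------------------------------------

@dataclass
class CourtshipRateFit:
    female_taxon: str
    behavior: str
    expected: pd.DataFrame  # per male taxon: expected events/trial + Wald CI
    contrasts: pd.DataFrame  # pairwise male-taxon contrasts, Bonferroni-adjusted
    family: str  # "negative_binomial" or "poisson" fallback
    n_trials: int


def courtship_rate_fit(
    table: CourtshipTable,
    female_taxon: str,
    behavior: str = "hover",
    level: float = 0.95,
) -> CourtshipRateFit:
    """Expected courtship events per trial by male taxon, for one female taxon.

    Negative-binomial count model with male taxon as the predictor and a
    per-trial exposure offset (the trial's total event count across male
    taxa, divided by the number of male taxa) standing in for a female
    random intercept.  Trials with zero events carry no information about
    relative male effort under this conditioning and are dropped with a log
    note.  Contrasts are Wald z tests on coefficient differences with
    Bonferroni adjustment.
    """
    import statsmodels.api as sm

    df = table.long
    df = df[(df["female_taxon"] == female_taxon) & (df["behavior"] == behavior)]
    if df.empty or df["count"].sum() == 0:
        raise EstimationError(
            f"no {behavior!r} events recorded toward {female_taxon!r} females"
        )
    trials = df["trial_id"].unique()
    if len(trials) < 2:
        raise EstimationError("need at least 2 trials per female taxon")

    totals = df.groupby("trial_id")["count"].sum()
    live = totals.index[totals > 0]
    dropped = len(totals) - len(live)
    if dropped:
        log.info(
            "dropping %d zero-event trial(s) for %s females", dropped, female_taxon
        )
    df = df[df["trial_id"].isin(live)].copy()
    male_taxa = sorted(df["male_taxon"].unique())
    k = len(male_taxa)
    df["offset"] = np.log(df["trial_id"].map(totals) / k).to_numpy()

    x = pd.get_dummies(df["male_taxon"], dtype=float)[male_taxa].to_numpy()
    y = df["count"].to_numpy()
    family = "negative_binomial"
    import warnings

    with warnings.catch_warnings():
        # the offset absorbs between-female heterogeneity, so the NB alpha
        # often sits on the zero boundary; the Poisson fallback is recorded
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(y, x, offset=df["offset"].to_numpy())
            fit = model.fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)[:k]
            cov = np.asarray(fit.cov_params())[:k, :k]
            if not fit.mle_retvals.get("converged", True) or not np.isfinite(np.diag(cov)).all():
                raise RuntimeError("NB fit did not converge")
        except Exception:
            log.warning("NB fit failed for %s; using Poisson", female_taxon)
            family = "poisson"
            fit = sm.GLM(
                y, x, offset=df["offset"].to_numpy(), family=sm.families.Poisson()
            ).fit()
            params, cov = np.asarray(fit.params), np.asarray(fit.cov_params())

    z = norm.ppf(1 - (1 - level) / 2)
    mean_exposure = totals[live].mean() / k
    se = np.sqrt(np.diag(cov))
    expected = pd.DataFrame(
        {
            "male_taxon": male_taxa,
            "expected_per_trial": mean_exposure * np.exp(params),
            "ci_lower": mean_exposure * np.exp(params - z * se),
            "ci_upper": mean_exposure * np.exp(params + z * se),
        }
    )

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    rows = []
    for i, j in pairs:
        diff = params[i] - params[j]
        sed = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        zstat = diff / sed if sed > 0 else np.nan
        p = 2 * norm.sf(abs(zstat))
        rows.append(
            {
                "contrast": f"{male_taxa[i]} - {male_taxa[j]}",
                "log_rate_ratio": float(diff),
                "z": float(zstat),
                "pvalue": float(p),
                "pvalue_bonferroni": float(min(1.0, p * len(pairs))),
            }
        )
    return CourtshipRateFit(
        female_taxon=female_taxon,
        behavior=behavior,
        expected=expected,
        contrasts=pd.DataFrame(rows),
        family=family,
        n_trials=len(live),
    )


def courtship_x(
    table: CourtshipTable,
    pair: tuple[str, str],
    behavior: str = "hover",
) -> tuple[float, str]:
    """Heterospecific courtship share averaged over the reciprocal directions.

    For each female taxon of the pair, the heterospecific share is the
    fraction of pair-male events contributed by the other taxon's males;
    reciprocal averaging keeps unequal trial numbers per direction from
    biasing x.  Returns ``(x, provenance)`` where provenance flags a
    one-direction estimate.
    """
    a, b = pair
    df = table.long
    df = df[df["behavior"] == behavior]
    shares = {}
    for fem, own, other in ((a, a, b), (b, b, a)):
        sub = df[(df["female_taxon"] == fem) & (df["male_taxon"].isin([a, b]))]
        own_events = sub.loc[sub["male_taxon"] == own, "count"].sum()
        other_events = sub.loc[sub["male_taxon"] == other, "count"].sum()
        total = own_events + other_events
        if total > 0:
            shares[fem] = other_events / total
    if not shares:
        raise EstimationError(f"no courtship events within pair {pair}")
    if len(shares) == 1:
        (fem,) = shares
        return float(shares[fem]), f"one_direction:{fem}"
    return float(np.mean(list(shares.values()))), "both_directions"
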