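"""Putative-pheromone screen, Bray-Curtis dissimilarity, NMDS and ANOSIM.

The screen mirrors the published workflow: drop listed contaminants and
singleton compounds, then retain a compound as a putative pheromone when its
androconial amounts exceed paired male hind-wing controls (one-sided Wilcoxon
signed-rank) or female controls (one-sided Mann-Whitney U), or both.  Exact
small-sample null distributions are used below the exact/approximation
switch (n <= 25).  Retained-compound proportions per individual feed a
Bray-Curtis matrix, a nonmetric MDS ordination and the ANOSIM permutation
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from .core import CompoundTable, ValidationError

log = logging.getLogger("isobarrier.pheromones")

EXACT_MAX_N = 25  # exact rank-test nulls below this, normal approximation above
DEFAULT_ALPHA = 0.05


# --------------------------------------------------------------------------
# screen
# --------------------------------------------------------------------------

def prefilter_compounds(
    table: CompoundTable,
    contaminant_list: list[str] | None = None,
    min_occurrences: int = 2,
) -> CompoundTable:
    """Drop listed contaminants and compounds seen in < ``min_occurrences`` samples."""
    contaminants = set(contaminant_list or [])
    occurrences = (
        table.long[table.long["amount"] > 0]
        .groupby("compound_id")["individual_id"]
        .nunique()
    )
    keep = []
    for comp in table.compounds:
        if comp in contaminants:
            log.info("excluding %s: listed contaminant", comp)
        elif occurrences.get(comp, 0) < min_occurrences:
            log.info(
                "excluding %s: seen in %d sample(s) (< %d)",
                comp, occurrences.get(comp, 0), min_occurrences,
            )
        else:
            keep.append(comp)
    return table.subset_compounds(keep)


@dataclass
class ScreenResult:
    retained: list[str]
    excluded: dict[str, str]  # compound -> reason
    stats: pd.DataFrame  # per-compound test statistics and p-values
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.excluded)
        if overlap:
            raise ValueError(f"compounds both retained and excluded: {overlap}")


def _paired_wilcoxon_greater(diff: np.ndarray) -> float:
    """One-sided signed-rank p for median(diff) > 0; exact for small n."""
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    method = "exact" if diff.size <= EXACT_MAX_N and np.unique(np.abs(diff)).size == diff.size else "approx"
    return float(
        wilcoxon(diff, alternative="greater", method=method).pvalue
    )


def _mwu_greater(x: np.ndarray, y: np.ndarray) -> float:
    if x.size == 0 or y.size == 0:
        return 1.0
    # exact null whenever the smaller group is small-sample and data are
    # tie-free; the normal approximation is anticonservative at n ~ 4
    method = "exact" if min(x.size, y.size) <= EXACT_MAX_N else "asymptotic"
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if ties:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def enrichment_screen(
    table: CompoundTable, alpha: float = DEFAULT_ALPHA
) -> ScreenResult:
    """Per-compound androconial-enrichment tests across all sampled males.

    A compound is retained when either comparison is significant at ``alpha``
    *and* the androconial median exceeds the corresponding control median.
    Taxa without female controls simply contribute nothing to the U-test.
    """
    andro = table.wide("androconia")
    male_ctrl = table.wide("hindwing_control")
    female_ctrl = table.wide("female_control")
    paired_males = andro.index.intersection(male_ctrl.index)
    if len(paired_males) < 3:
        raise ValidationError(
            "need >= 3 males with paired androconia/control samples"
        )

    rows = []
    retained, excluded = [], {}
    for comp in table.compounds:
        a_all = andro[comp] if comp in andro else pd.Series(0.0, index=andro.index)
        a_pair = a_all.reindex(paired_males, fill_value=0.0).to_numpy()
        c_pair = (
            male_ctrl[comp].reindex(paired_males, fill_value=0.0).to_numpy()
            if comp in male_ctrl
            else np.zeros(len(paired_males))
        )
        f_ctrl = (
            female_ctrl[comp].to_numpy()
            if comp in female_ctrl and len(female_ctrl)
            else np.array([])
        )

        p_paired = _paired_wilcoxon_greater(a_pair - c_pair)
        p_mwu = _mwu_greater(a_all.to_numpy(), f_ctrl) if f_ctrl.size else np.nan

        vs_male = p_paired < alpha and np.median(a_pair) > np.median(c_pair)
        vs_female = (
            f_ctrl.size > 0
            and p_mwu < alpha
            and np.median(a_all) > np.median(f_ctrl)
        )
        if vs_male and vs_female:
            reason = "both"
        elif vs_male:
            reason = "vs_male_control"
        elif vs_female:
            reason = "vs_female_control"
        else:
            reason = ""
        if reason:
            retained.append(comp)
        else:
            excluded[comp] = "not_enriched"
        rows.append(
            {
                "compound_id": comp,
                "p_signed_rank": p_paired,
                "p_mann_whitney": p_mwu,
                "median_androconia": float(np.median(a_all)),
                "median_male_control": float(np.median(c_pair)),
                "median_female_control": float(np.median(f_ctrl)) if f_ctrl.size else np.nan,
                "retained": bool(reason),
                "reason": reason or "not_enriched",
            }
        )
    return ScreenResult(
        retained=retained, excluded=excluded,
        stats=pd.DataFrame(rows), alpha=alpha,
    )


# --------------------------------------------------------------------------
# dissimilarity / ordination / ANOSIM
# --------------------------------------------------------------------------

def compound_proportions(table: CompoundTable, compounds: list[str]) -> pd.DataFrame:
    """Per-individual androconial proportions over the retained compound set."""
    wide = table.subset_compounds(compounds).wide("androconia")
    wide = wide.reindex(columns=sorted(compounds), fill_value=0.0)
    totals = wide.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(
            f"individual(s) with all-zero retained profile: {list(zero)}"
        )
    return wide.div(totals, axis=0)


def bray_curtis_matrix(proportions: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities ``sum|p-q| / sum(p+q)``."""
    arr = proportions.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("proportions must be non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise ValidationError("all-zero profile: dissimilarity undefined")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=proportions.index, columns=proportions.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # individuals x 2, centered
    stress: float  # Kruskal stress-1 of the returned configuration
    n_starts: int
    seed: int


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling used as one NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(
    dissimilarity: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_starts: int = 8,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric MDS by SMACOF with monotone regression (Kruskal stress-1).

    Runs from a classical-scaling start plus ``n_starts`` random starts and
    returns the lowest-stress configuration, centered at the origin.
    """
    from sklearn.manifold import smacof

    index = None
    if isinstance(dissimilarity, pd.DataFrame):
        index = dissimilarity.index
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValidationError("dissimilarity matrix must be square and symmetric")
    if d.shape[0] < 4:
        raise ValidationError("NMDS needs at least 4 objects")

    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    inits = [_classical_scaling(d, k)] + [
        rng.normal(size=(d.shape[0], k)) for _ in range(n_starts)
    ]
    for init in inits:
        coords, stress = smacof(
            d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            normalized_stress=True,
            random_state=0,
        )
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    best_coords = best_coords - best_coords.mean(axis=0)
    frame = pd.DataFrame(
        best_coords, index=index, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=frame, stress=float(best_stress),
        n_starts=len(inits), seed=seed,
    )


@dataclass
class AnosimResult:
    r: float
    pvalue: float
    n_permutations: int


def anosim_r(condensed_ranks: np.ndarray, between: np.ndarray, m: int) -> float:
    """Clarke's R from ranked dissimilarities and a between-group mask."""
    rb = condensed_ranks[between].mean()
    rw = condensed_ranks[~between].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dissimilarity: pd.DataFrame | np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """ANOSIM permutation test of group separation in a dissimilarity matrix.

    ``R = (mean between-group rank - mean within-group rank) / (M / 2)`` with
    ``M = n(n-1)/2``; this normalization makes R exactly 1 when every
    between-group dissimilarity exceeds every within-group one.  The p-value
    is ``(#{permuted R >= observed} + 1) / (n_permutations + 1)``.
    """
    d = (
        dissimilarity.to_numpy(dtype=float)
        if isinstance(dissimilarity, pd.DataFrame)
        else np.asarray(dissimilarity, dtype=float)
    )
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must match the matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 members")

    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])
    m = n * (n - 1) // 2

    def between_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] != lab[iu[1]]

    observed = anosim_r(ranks, between_mask(labels), m)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if anosim_r(ranks, between_mask(perm), m) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AnosimResult(r=observed, pvalue=float(p), n_permutations=n_permutations)
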