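"""Seeded generators for every input table, with known ground truth.

Each generator draws from its own substream derived from the root seed and a
stable per-generator tag (CRC32 of the generator name), so adding a generator
never perturbs the streams of existing ones and identical configurations
produce byte-identical output.

Count overdispersion follows the parameterizations used downstream:
negative binomial with variance ``mu + mu**2 / theta`` and beta-binomial with
intra-brood correlation ``rho`` (``rho = 0`` collapses to the binomial).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import DEFAULT_TAXA
from .core import (
    BroodTable,
    CompoundTable,
    CourtshipTable,
    MatingTrialRecord,
    OccurrenceTable,
    OvipositionTable,
    PupalFateTable,
    ValidationError,
    check_taxa,
)


class ConfigError(ValueError):
    """A simulation configuration violates one of its invariants."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named simulation component."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tag,)))


def _check_probs(p: Sequence[float], what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ConfigError(f"{what}: probabilities must be >= 0 and sum to 1, got {p}")
    return p


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the full synthetic bundle.

    ``mating_probabilities[f]`` is a probability vector over male taxa plus a
    trailing no-mating entry.  ``compound_profiles[taxon]`` maps compound id
    to the androconial mean amount (nmol).  All dispersions are >= 0.
    """

    seed: int = 0
    taxa: tuple[str, ...] = DEFAULT_TAXA

    # mate-choice trials
    n_females: Mapping[str, int] = field(
        default_factory=lambda: {"E": 60, "Pb": 70, "Ps": 30}
    )
    mating_probabilities: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            # P(male E), P(male Pb), P(male Ps), P(no mating)
            "E": (0.10, 0.0, 0.0, 0.90),
            "Pb": (0.0, 0.10, 0.08, 0.82),
            "Ps": (0.0, 0.17, 0.10, 0.73),
        }
    )
    fraction_trials_15male: float = 0.5

    # oviposition
    plants: tuple[str, ...] = tuple(f"P{i:02d}" for i in range(1, 22))
    oviposition_preferences: Mapping[str, Sequence[float]] | None = None
    eggs_per_female_mean: float = 10.0
    eggs_per_female_theta: float = 2.0  # NB dispersion: var = mu + mu^2/theta
    n_oviposition_females: Mapping[str, int] = field(
        default_factory=lambda: {"E": 34, "Pb": 51, "Ps": 37}
    )

    # compound profiles
    n_males: Mapping[str, int] = field(
        default_factory=lambda: {"E": 10, "Pb": 13, "Ps": 5}
    )
    n_male_controls: int = 5
    n_female_controls: Mapping[str, int] = field(
        default_factory=lambda: {"E": 2, "Pb": 2, "Ps": 0}
    )
    compound_profiles: Mapping[str, Mapping[str, float]] | None = None
    n_true_pheromones: int = 25
    n_shared_compounds: int = 10
    n_contaminants: int = 5
    n_singletons: int = 3
    androconial_enrichment: float = 8.0
    compound_log_sd: float = 0.5

    # courtship
    courtship_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "E": {"E": 4.0, "Pb": 1.0, "Ps": 1.0},
            "Pb": {"E": 1.0, "Pb": 5.0, "Ps": 1.5},
            "Ps": {"E": 1.0, "Pb": 1.5, "Ps": 1.5},
        }
    )
    courtship_female_sd: float = 0.5  # sd of log female random effect
    n_courtship_trials: Mapping[str, int] = field(
        default_factory=lambda: {"E": 24, "Pb": 24, "Ps": 24}
    )

    # broods
    hatch_probability: Mapping[str, float] = field(
        default_factory=lambda: {
            "E × E": 0.80,
            "Pb × Pb": 0.85,
            "Ps × Ps": 0.75,
            "E × Pb": 0.80,
            "Pb × E": 0.78,
        }
    )
    sterile_crosses: tuple[str, ...] = (
        "(Pb × Ps) × Pb",
        "(Ps × Pb) × Pb",
        "(Ps × E) × E",
        "(E × Ps) × E",
    )
    broods_per_cross: int = 20
    brood_size_mean: float = 40.0
    brood_size_theta: float = 5.0
    hatch_rho: float = 0.05  # beta-binomial intra-brood correlation
    parasitism_rate: float = 0.1
    protocol_change_fraction: float = 0.5

    # pupal fates
    pupal_fate_probabilities: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            # emerged, failed_emerge, never_emerged, failed_pupation
            "E × E": (0.75, 0.08, 0.10, 0.07),
            "Pb × Pb": (0.89, 0.03, 0.01, 0.07),
            "Ps × Ps": (0.77, 0.10, 0.13, 0.0),
            "E × Pb": (0.80, 0.03, 0.10, 0.07),
        }
    )
    pupae_per_cross: int = 100

    # occurrence grids
    range_overlap_fraction: float = 0.0
    grid_width: int = 20
    grid_height: int = 10
    climate_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "E": (25.0, 1500.0),
            "Pb": (26.0, 2000.0),
            "Ps": (24.0, 900.0),
        }
    )
    climate_sds: tuple[float, float] = (0.5, 100.0)

    def __post_init__(self) -> None:
        self.taxa = check_taxa(self.taxa)
        for f, p in self.mating_probabilities.items():
            _check_probs(p, f"mating_probabilities[{f}]")
        for c, p in self.pupal_fate_probabilities.items():
            _check_probs(p, f"pupal_fate_probabilities[{c}]")
        for c, p in self.hatch_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"hatch_probability[{c}] outside [0, 1]: {p}")
        if not 0.0 <= self.range_overlap_fraction <= 1.0:
            raise ConfigError("range_overlap_fraction must lie in [0, 1]")
        if self.hatch_rho < 0:
            raise ConfigError("hatch_rho must be >= 0")
        if self.compound_log_sd < 0:
            raise ConfigError("compound_log_sd must be >= 0")
        if self.courtship_female_sd < 0:
            raise ConfigError("courtship_female_sd must be >= 0")
        if self.oviposition_preferences is None:
            self.oviposition_preferences = self._default_preferences()
        for t, p in self.oviposition_preferences.items():
            _check_probs(p, f"oviposition_preferences[{t}]")

    def _default_preferences(self) -> dict[str, np.ndarray]:
        """Distinct long-tailed plant preferences per taxon."""
        prefs = {}
        k = len(self.plants)
        for i, t in enumerate(self.taxa):
            w = np.exp(-0.4 * np.abs(np.arange(k) - 4 * i))
            prefs[t] = w / w.sum()
        return prefs


def _negbin(rng: np.random.Generator, mean: float, theta: float, size: int) -> np.ndarray:
    """NB draws with variance ``mean + mean**2 / theta``."""
    if theta <= 0:
        raise ConfigError("NB dispersion theta must be > 0")
    lam = rng.gamma(shape=theta, scale=mean / theta, size=size)
    return rng.poisson(lam)


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: float, rho: float
) -> np.ndarray:
    """Beta-binomial draws with correlation rho; rho = 0 is plain binomial."""
    n = np.asarray(n)
    if rho == 0 or p in (0.0, 1.0):
        return rng.binomial(n, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    q = rng.beta(a, b, size=n.shape)
    return rng.binomial(n, q)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def gen_mating_trials(config: SimulationConfig) -> list[MatingTrialRecord]:
    rng = substream(config.seed, "mating_trials")
    outcomes = list(config.taxa) + [None]
    records: list[MatingTrialRecord] = []
    i = 0
    for f in config.taxa:
        p = _check_probs(config.mating_probabilities[f], f)
        if len(p) != len(config.taxa) + 1:
            raise ConfigError(
                f"mating_probabilities[{f}] must have k + 1 entries "
                "(male taxa plus no-mating)"
            )
        n = config.n_females[f]
        draws = rng.choice(len(outcomes), size=n, p=p)
        comps = np.where(
            rng.random(n) < config.fraction_trials_15male, 15, 3
        )
        for d, c in zip(draws, comps):
            records.append(
                MatingTrialRecord(
                    trial_id=f"T{i:04d}",
                    female_taxon=f,
                    composition=int(c),
                    outcome=outcomes[d],
                    observed=True,
                )
            )
            i += 1
    return records


def gen_oviposition(config: SimulationConfig) -> OvipositionTable:
    rng = substream(config.seed, "oviposition")
    rows = []
    for t in config.taxa:
        pref = np.asarray(config.oviposition_preferences[t])
        n_fem = config.n_oviposition_females[t]
        totals = _negbin(
            rng, config.eggs_per_female_mean, config.eggs_per_female_theta, n_fem
        )
        for j, total in enumerate(totals):
            alloc = rng.multinomial(total, pref)
            for plant, eggs in zip(config.plants, alloc):
                if eggs > 0:
                    rows.append((t, plant, int(eggs), f"{t}_f{j:03d}"))
    return OvipositionTable(
        pd.DataFrame(rows, columns=["taxon", "plant", "eggs", "female_id"])
    )


def _compound_ids(config: SimulationConfig) -> dict[str, list[str]]:
    n_true = config.n_true_pheromones
    return {
        "true": [f"C{i:03d}" for i in range(n_true)],
        "shared": [f"S{i:03d}" for i in range(config.n_shared_compounds)],
        "contaminant": [f"X{i:03d}" for i in range(config.n_contaminants)],
        "singleton": [f"U{i:03d}" for i in range(config.n_singletons)],
    }


def true_pheromones(config: SimulationConfig) -> list[str]:
    """Ground-truth androconia-enriched compound ids."""
    return _compound_ids(config)["true"]


def contaminant_compounds(config: SimulationConfig) -> list[str]:
    return _compound_ids(config)["contaminant"]


def gen_compound_table(config: SimulationConfig) -> CompoundTable:
    """Log-normal compound amounts with androconial enrichment.

    "True" compounds are enriched in androconia by ``androconial_enrichment``
    and have taxon-specific mean profiles; "shared" compounds appear in all
    regions at similar levels (not enriched); contaminants are constant
    across all regions and singletons appear in exactly one sample each.
    """
    rng = substream(config.seed, "compounds")
    ids = _compound_ids(config)
    taxa = config.taxa
    k_true = len(ids["true"])

    # taxon-specific mean profile over true compounds: smooth bumps at
    # different positions so taxa separate in composition space
    profiles = {}
    if config.compound_profiles is not None:
        profiles = {t: dict(config.compound_profiles[t]) for t in taxa}
    else:
        pos = np.linspace(0, k_true - 1, len(taxa) + 2)[1:-1]
        for t, c in zip(taxa, pos):
            w = np.exp(-0.5 * ((np.arange(k_true) - c) / (k_true / 6)) ** 2)
            profiles[t] = dict(zip(ids["true"], 0.3 + 5.0 * w))

    sd = config.compound_log_sd
    rows = []

    def emit(ind, taxon, sex, region, comp, mean):
        if mean <= 0:
            return
        amount = mean * rng.lognormal(mean=0.0, sigma=sd) if sd > 0 else mean
        rows.append((ind, taxon, sex, region, comp, float(amount)))

    male_ids = {
        t: [f"{t}_m{i:02d}" for i in range(config.n_males[t])] for t in taxa
    }
    for t in taxa:
        for j, ind in enumerate(male_ids[t]):
            has_control = j < config.n_male_controls
            for comp in ids["true"]:
                mu = profiles[t][comp]
                emit(ind, t, "M", "androconia", comp, mu)
                if has_control:
                    emit(ind, t, "M", "hindwing_control", comp,
                         mu / config.androconial_enrichment)
            for comp in ids["shared"]:
                emit(ind, t, "M", "androconia", comp, 1.0)
                if has_control:
                    emit(ind, t, "M", "hindwing_control", comp, 1.0)
            for comp in ids["contaminant"]:
                emit(ind, t, "M", "androconia", comp, 2.0)
                if has_control:
                    emit(ind, t, "M", "hindwing_control", comp, 2.0)
        for j in range(config.n_female_controls.get(t, 0)):
            ind = f"{t}_f{j:02d}"
            for comp in ids["true"]:
                emit(ind, t, "F", "female_control", comp,
                     profiles[t][comp] / config.androconial_enrichment)
            for comp in ids["shared"]:
                emit(ind, t, "F", "female_control", comp, 1.0)
            for comp in ids["contaminant"]:
                emit(ind, t, "F", "female_control", comp, 2.0)

    # singletons: one appearance each, in a random male androconial sample
    all_males = [m for t in taxa for m in male_ids[t]]
    meta = {m: t for t in taxa for m in male_ids[t]}
    for comp in ids["singleton"]:
        ind = all_males[rng.integers(len(all_males))]
        emit(ind, meta[ind], "M", "androconia", comp, 1.0)

    return CompoundTable(
        pd.DataFrame(
            rows,
            columns=["individual_id", "taxon", "sex", "region", "compound_id", "amount"],
        )
    )


def gen_courtship(config: SimulationConfig, behavior: str = "hover") -> CourtshipTable:
    """Overdispersed courtship counts with a per-female multiplicative effect."""
    rng = substream(config.seed, "courtship")
    rows = []
    i = 0
    for f in config.taxa:
        rates = config.courtship_rates[f]
        for _ in range(config.n_courtship_trials[f]):
            trial = f"CT{i:04d}"
            i += 1
            effect = (
                rng.lognormal(mean=-config.courtship_female_sd**2 / 2,
                              sigma=config.courtship_female_sd)
                if config.courtship_female_sd > 0
                else 1.0
            )
            for m in config.taxa:
                count = rng.poisson(rates[m] * effect)
                rows.append((trial, f, m, behavior, int(count)))
    return CourtshipTable(
        pd.DataFrame(
            rows, columns=["trial_id", "female_taxon", "male_taxon", "behavior", "count"]
        )
    )


def gen_broods(config: SimulationConfig) -> BroodTable:
    """Beta-binomial hatch counts with parasitism and sterile crosses."""
    rng = substream(config.seed, "broods")
    rows = []
    i = 0
    crosses = list(config.hatch_probability) + list(config.sterile_crosses)
    for cross in crosses:
        sterile = cross in config.sterile_crosses
        p = 0.0 if sterile else config.hatch_probability[cross]
        for j in range(config.broods_per_cross):
            brood = f"B{i:04d}"
            i += 1
            phase = "before" if j < config.protocol_change_fraction * config.broods_per_cross else "after"
            if sterile:
                rows.append((brood, cross, 0, 0, 0, phase))
                continue
            laid = int(_negbin(rng, config.brood_size_mean, config.brood_size_theta, 1)[0])
            parasitized = int(rng.binomial(laid, config.parasitism_rate))
            at_risk = laid - parasitized
            hatched = int(_beta_binomial(rng, np.array(at_risk), p, config.hatch_rho))
            rows.append((brood, cross, laid, hatched, parasitized, phase))
    return BroodTable(
        pd.DataFrame(
            rows,
            columns=[
                "brood_id", "cross_type", "eggs_laid", "eggs_hatched",
                "eggs_parasitized", "protocol_phase",
            ],
        )
    )


def gen_pupal_fates(config: SimulationConfig) -> PupalFateTable:
    rng = substream(config.seed, "pupal_fates")
    fates = ("emerged", "failed_emerge", "never_emerged", "failed_pupation")
    rows = {}
    for cross, p in config.pupal_fate_probabilities.items():
        p = _check_probs(p, f"pupal_fate_probabilities[{cross}]")
        rows[cross] = rng.multinomial(config.pupae_per_cross, p)
    return PupalFateTable(pd.DataFrame.from_dict(rows, orient="index", columns=fates))


def gen_occurrence_grid(config: SimulationConfig) -> OccurrenceTable:
    """Two rectangular ranges sharing the requested fraction of cells.

    Each of the first two taxa occupies ``grid_width`` x ``grid_height``
    unit cells; the ranges are slid horizontally so that a fraction
    ``range_overlap_fraction`` of each taxon's cells is co-occupied.  One
    record is emitted at each occupied cell center, so rasterizing at cell
    size 1 recovers the occupancy exactly.
    """
    rng = substream(config.seed, "occurrences")
    f = config.range_overlap_fraction
    w, h = config.grid_width, config.grid_height
    shared_cols = int(round(f * w))
    offset = w - shared_cols
    rows = []
    tsd, psd = config.climate_sds
    for t, x0 in zip(config.taxa[:2], (0, offset)):
        tmean, pmean = config.climate_means[t]
        for ix in range(x0, x0 + w):
            for iy in range(h):
                rows.append(
                    (
                        t,
                        ix + 0.5,
                        iy + 0.5,
                        float(rng.normal(tmean, tsd)),
                        float(rng.normal(pmean, psd)),
                    )
                )
    return OccurrenceTable(
        pd.DataFrame(
            rows, columns=["taxon", "lon", "lat", "mean_annual_temp", "annual_precip"]
        )
    )


def ground_truth(config: SimulationConfig) -> dict:
    """Configured parameters as a plain dict (for the `simulate` YAML)."""
    return {
        "seed": config.seed,
        "taxa": list(config.taxa),
        "mating_probabilities": {
            f: [float(x) for x in p] for f, p in config.mating_probabilities.items()
        },
        "hatch_probability": {c: float(p) for c, p in config.hatch_probability.items()},
        "hatch_rho": float(config.hatch_rho),
        "sterile_crosses": list(config.sterile_crosses),
        "courtship_rates": {
            f: {m: float(r) for m, r in d.items()}
            for f, d in config.courtship_rates.items()
        },
        "range_overlap_fraction": float(config.range_overlap_fraction),
        "true_pheromones": true_pheromones(config),
        "contaminants": contaminant_compounds(config),
        "parasitism_rate": float(config.parasitism_rate),
    }
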