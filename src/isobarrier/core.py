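"""Domain types and validation shared by every analysis stage.

All tabular types are thin, validated wrappers around :class:`pandas.DataFrame`
so they can round-trip through the delimited-text readers in
:mod:`isobarrier.io` without loss.  Taxon sets are configurable (``k >= 2``);
``("E", "Pb", "Ps")`` is the packaged default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import DEFAULT_TAXA

REGIONS = ("androconia", "hindwing_control", "female_control")
BEHAVIORS = ("approach", "hover", "alight")
PUPAL_FATES = ("emerged", "failed_emerge", "never_emerged", "failed_pupation")


class SchemaError(ValueError):
    """A delimited file does not match the expected column schema."""


class ValidationError(ValueError):
    """A table violates a domain invariant (negative count, bad sum, ...)."""


class EstimationError(RuntimeError):
    """A fit was requested on data that cannot support it."""


@dataclass(frozen=True)
class Taxon:
    id: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("taxon id must be non-empty")


def check_taxa(taxa: Sequence[str]) -> tuple[str, ...]:
    taxa = tuple(taxa)
    if len(taxa) < 2:
        raise ValidationError(f"need at least 2 taxa, got {len(taxa)}")
    if len(set(taxa)) != len(taxa):
        raise ValidationError(f"taxon ids must be unique: {taxa}")
    return taxa


@dataclass(frozen=True)
class MatingTrialRecord:
    """One mate-choice trial: a single virgin female with a group of males."""

    trial_id: str
    female_taxon: str
    composition: int  # 3 = one male of each taxon, 15 = five of each
    outcome: str | None  # taxon of the mating male, or None if no mating
    observed: bool = True  # directly seen vs spermatophore-inferred

    def __post_init__(self) -> None:
        if self.composition not in (3, 15):
            raise ValidationError(
                f"trial {self.trial_id}: composition must be 3 or 15, "
                f"got {self.composition}"
            )


class MatingCountTable:
    """k x k table of mating counts: rows = female taxon, cols = male taxon.

    Houses the multinomial data of the mate-choice likelihood: for female
    taxon ``f`` the row gives the counts ``y_i`` of type-``i`` matings, with
    ``n`` their sum and ``k`` the number of mating types.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        n_trials: pd.Series | None = None,
    ) -> None:
        counts = counts.copy()
        check_taxa(counts.columns)
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("mating counts must be numeric")
        if (arr < 0).any():
            bad = counts.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative mating count in row {bad!r}")
        if (arr != np.round(arr)).any():
            raise ValidationError("mating counts must be integers")
        self.counts = counts.astype(int)
        if n_trials is not None:
            n_trials = n_trials.reindex(counts.index)
            if (self.counts.sum(axis=1) > n_trials).any():
                raise ValidationError("row sum of matings exceeds trial count")
        self.n_trials = n_trials

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @classmethod
    def from_trials(
        cls,
        trials: Sequence[MatingTrialRecord],
        taxa: Sequence[str] = DEFAULT_TAXA,
        include_unobserved: bool = False,
    ) -> "MatingCountTable":
        """Tabulate realized matings.

        Matings that were inferred from a spermatophore but never observed
        carry no male identity; they are excluded unless
        ``include_unobserved`` (in which case the recorded outcome is
        trusted).
        """
        taxa = check_taxa(taxa)
        counts = pd.DataFrame(0, index=list(taxa), columns=list(taxa))
        n_trials = pd.Series(0, index=list(taxa))
        for t in trials:
            if t.female_taxon not in taxa:
                raise ValidationError(
                    f"trial {t.trial_id}: unknown female taxon {t.female_taxon!r}"
                )
            n_trials[t.female_taxon] += 1
            if t.outcome is None:
                continue
            if t.outcome not in taxa:
                raise ValidationError(
                    f"trial {t.trial_id}: outcome {t.outcome!r} not in male group"
                )
            if not t.observed and not include_unobserved:
                continue
            counts.loc[t.female_taxon, t.outcome] += 1
        return cls(counts, n_trials)

    def row(self, female_taxon: str) -> np.ndarray:
        return self.counts.loc[female_taxon].to_numpy()

    def pair_counts(self, pair: tuple[str, str]) -> pd.DataFrame:
        """2x2 sub-table restricted to a taxon pair."""
        a, b = pair
        return self.counts.loc[[a, b], [a, b]]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MatingCountTable)
            and self.counts.equals(other.counts)
        )


class OvipositionTable:
    """Egg counts per (taxon, plant), optionally resolved by individual female.

    ``long`` holds one row per (taxon, plant[, female_id]) with an ``eggs``
    count; :meth:`matrix` pivots to the taxon x plant matrix used by the
    niche-overlap index.
    """

    REQUIRED = ("taxon", "plant", "eggs")

    def __init__(self, long: pd.DataFrame) -> None:
        long = long.copy()
        for col in self.REQUIRED:
            if col not in long.columns:
                raise SchemaError(f"oviposition table missing column {col!r}")
        neg = long.index[long["eggs"] < 0]
        if len(neg):
            raise ValidationError(f"negative egg count at row {neg[0]}")
        self.long = long

    @property
    def has_females(self) -> bool:
        return "female_id" in self.long.columns

    def matrix(self) -> pd.DataFrame:
        return (
            self.long.groupby(["taxon", "plant"])["eggs"]
            .sum()
            .unstack(fill_value=0)
        )

    def proportions(self) -> pd.DataFrame:
        m = self.matrix()
        totals = m.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValidationError(f"taxon {bad!r} laid no eggs")
        return m.div(totals, axis=0)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OvipositionTable) and self.long.equals(other.long)


class CompoundTable:
    """Long table of per-individual compound amounts (nmol) by wing region."""

    REQUIRED = ("individual_id", "taxon", "sex", "region", "compound_id", "amount")

    def __init__(self, long: pd.DataFrame) -> None:
        long = long.copy()
        for col in self.REQUIRED:
            if col not in long.columns:
                raise SchemaError(f"compound table missing column {col!r}")
        neg = long.index[long["amount"] < 0]
        if len(neg):
            raise ValidationError(f"negative amount at row {neg[0]}")
        bad_region = set(long["region"]) - set(REGIONS)
        if bad_region:
            raise ValidationError(f"unknown region(s) {sorted(bad_region)}")
        self.long = long

    @property
    def compounds(self) -> list[str]:
        return sorted(self.long["compound_id"].unique())

    def wide(self, region: str | None = None) -> pd.DataFrame:
        """Individuals x compounds amount matrix (zeros for absences)."""
        df = self.long
        if region is not None:
            df = df[df["region"] == region]
        return (
            df.pivot_table(
                index="individual_id",
                columns="compound_id",
                values="amount",
                aggfunc="sum",
                fill_value=0.0,
            )
        )

    def subset_compounds(self, keep: Sequence[str]) -> "CompoundTable":
        return CompoundTable(self.long[self.long["compound_id"].isin(set(keep))])

    def individual_meta(self) -> pd.DataFrame:
        return (
            self.long.groupby("individual_id")[["taxon", "sex"]]
            .first()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundTable):
            return False
        a = self.long.sort_values(list(self.REQUIRED)).reset_index(drop=True)
        b = other.long.sort_values(list(self.REQUIRED)).reset_index(drop=True)
        return a[list(self.REQUIRED)].equals(b[list(self.REQUIRED)])


class CourtshipTable:
    """Counts of stereotyped courtship behaviours per trial and male taxon."""

    REQUIRED = ("trial_id", "female_taxon", "male_taxon", "behavior", "count")

    def __init__(self, long: pd.DataFrame) -> None:
        long = long.copy()
        for col in self.REQUIRED:
            if col not in long.columns:
                raise SchemaError(f"courtship table missing column {col!r}")
        neg = long.index[long["count"] < 0]
        if len(neg):
            raise ValidationError(f"negative courtship count at row {neg[0]}")
        bad = set(long["behavior"]) - set(BEHAVIORS)
        if bad:
            raise ValidationError(f"unknown behavior(s) {sorted(bad)}")
        self.long = long

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CourtshipTable) and self.long.equals(other.long)


class BroodTable:
    """Per-brood egg fates: laid, hatched, parasitized, protocol phase."""

    REQUIRED = (
        "brood_id",
        "cross_type",
        "eggs_laid",
        "eggs_hatched",
        "eggs_parasitized",
        "protocol_phase",
    )

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise SchemaError(f"brood table missing column {col!r}")
        for col in ("eggs_laid", "eggs_hatched", "eggs_parasitized"):
            neg = df.index[df[col] < 0]
            if len(neg):
                raise ValidationError(f"negative {col} at row {neg[0]}")
        over = df.index[df["eggs_hatched"] + df["eggs_parasitized"] > df["eggs_laid"]]
        if len(over):
            raise ValidationError(
                f"hatched + parasitized exceeds eggs laid at row {over[0]}"
            )
        bad = set(df["protocol_phase"]) - {"before", "after"}
        if bad:
            raise ValidationError(f"unknown protocol phase(s) {sorted(bad)}")
        self.df = df

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BroodTable) and self.df.equals(other.df)


class PupalFateTable:
    """Cross type x fate count matrix for pupal survivorship."""

    def __init__(self, counts: pd.DataFrame) -> None:
        counts = counts.copy()
        missing = set(PUPAL_FATES) - set(counts.columns)
        if missing:
            raise SchemaError(f"pupal fate table missing fate(s) {sorted(missing)}")
        arr = counts[list(PUPAL_FATES)].to_numpy()
        if (arr < 0).any():
            bad = counts.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative pupal count for cross {bad!r}")
        self.counts = counts[list(PUPAL_FATES)].astype(int)

    @property
    def totals(self) -> pd.Series:
        """Total pupations per cross (sum over fates)."""
        return self.counts.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PupalFateTable) and self.counts.sort_index().equals(
            other.counts.sort_index()
        )


class OccurrenceTable:
    """Georeferenced records per taxon, with optional climate values."""

    REQUIRED = ("taxon", "lon", "lat")

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise SchemaError(f"occurrence table missing column {col!r}")
        coords = df[["lon", "lat"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            bad = df.index[~np.isfinite(coords).all(axis=1)][0]
            raise ValidationError(f"non-finite coordinates at row {bad}")
        self.df = df

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OccurrenceTable) and self.df.equals(other.df)


# --------------------------------------------------------------------------
# Cross-label pedigrees
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Pedigree:
    """Binary mother x father tree; leaves are taxon ids.

    Labels follow the mother-first convention: ``"Pb × E"`` is a
    H. p. butleri mother and H. elevatus father; parenthesized terms are
    hybrid parents, e.g. ``"(E × Pb) × (E × Pb)"`` for an F1 x F1 cross.
    """

    mother: "Pedigree | str"
    father: "Pedigree | str"

    def label(self) -> str:
        def fmt(side: "Pedigree | str") -> str:
            return f"({side.label()})" if isinstance(side, Pedigree) else side

        return f"{fmt(self.mother)} × {fmt(self.father)}"

    @property
    def is_f1(self) -> bool:
        return isinstance(self.mother, str) and isinstance(self.father, str) \
            and self.mother != self.father


class CrossLabelError(ValueError):
    """A cross label could not be parsed."""


def parse_cross_label(label: str) -> Pedigree:
    """Parse a mother x father cross label into a :class:`Pedigree`.

    Accepts ``×`` or ``x`` as the separator and nested parentheses for
    hybrid parents.
    """
    tokens = _tokenize(label)
    tree, rest = _parse_cross(tokens)
    if rest:
        raise CrossLabelError(f"trailing tokens {rest!r} in label {label!r}")
    return tree


def _tokenize(label: str) -> list[str]:
    out: list[str] = []
    cur = ""
    for ch in label:
        if ch in "()" or ch == "×":
            if cur.strip():
                out.append(cur.strip())
            cur = ""
            out.append(ch)
        elif ch.isspace():
            if cur.strip():
                out.append(cur.strip())
            cur = ""
        else:
            cur += ch
    if cur.strip():
        out.append(cur.strip())
    # a bare "x"/"X" token between terms is a separator
    return ["×" if t in ("x", "X") else t for t in out]


def _parse_cross(tokens: list[str]) -> tuple[Pedigree, list[str]]:
    mother, rest = _parse_term(tokens)
    if not rest or rest[0] != "×":
        raise CrossLabelError("expected '×' between mother and father")
    father, rest = _parse_term(rest[1:])
    return Pedigree(mother, father), rest


def _parse_term(tokens: list[str]):
    if not tokens:
        raise CrossLabelError("unexpected end of label")
    tok = tokens[0]
    if tok == "(":
        inner, rest = _parse_cross(tokens[1:])
        if not rest or rest[0] != ")":
            raise CrossLabelError("unbalanced parentheses")
        return inner, rest[1:]
    if tok in ("×", ")"):
        raise CrossLabelError(f"unexpected token {tok!r}")
    return tok, tokens[1:]


def validate_cross_label(label: str) -> Pedigree:
    """Alias kept for the public API: parse and validate a cross label."""
    return parse_cross_label(label)
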