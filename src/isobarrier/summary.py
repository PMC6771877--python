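"""Per-trait isolation indices ``Ri = 1 - 2x`` and table assembly.

``x`` is the trait-specific probability of heterospecific gene flow:
``Ri = 1`` is complete isolation, ``Ri = 0`` random mating and ``Ri = -1``
complete disassortativity.  Cells whose ``x`` cannot be computed from data
(e.g. values assigned because of female hybrid sterility) are carried as
"assigned" with an explicit note, never silently computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EstimationError, OccurrenceTable

BARRIERS = (
    "geography",
    "host_plant",
    "pheromones",
    "color_pattern_preference",
    "live_courtship",
    "mating",
    "f1_fertility",
)


def ri_from_x(x: float) -> float:
    """``Ri = 1 - 2x`` for a gene-flow probability ``x`` in [0, 1]."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x}")
    return 1.0 - 2.0 * x


def x_from_ri(ri: float) -> float:
    if not -1.0 <= ri <= 1.0:
        raise ValueError(f"Ri must lie in [-1, 1], got {ri}")
    return (1.0 - ri) / 2.0


@dataclass
class BarrierEstimate:
    pair: tuple[str, str]
    barrier: str
    x: float | None  # None for assigned / unavailable cells
    ri: float
    method: str = "computed"  # "computed" | "assigned" | "unavailable"
    note: str = ""

    def __post_init__(self) -> None:
        if self.barrier not in BARRIERS:
            raise ValueError(f"unknown barrier {self.barrier!r}")
        if self.method == "computed":
            if self.x is None:
                raise ValueError("computed estimates require x")
            expected = ri_from_x(self.x)
            if not np.isclose(self.ri, expected, atol=1e-9):
                raise ValueError("Ri must equal 1 - 2x for computed cells")
        if not np.isnan(self.ri) and not -1.0 <= self.ri <= 1.0:
            raise ValueError(f"Ri outside [-1, 1]: {self.ri}")

    @classmethod
    def computed(cls, pair, barrier, x, note="") -> "BarrierEstimate":
        return cls(pair=tuple(pair), barrier=barrier, x=float(x),
                   ri=ri_from_x(x), method="computed", note=note)

    @classmethod
    def assigned(cls, pair, barrier, ri, note) -> "BarrierEstimate":
        return cls(pair=tuple(pair), barrier=barrier, x=None, ri=float(ri),
                   method="assigned", note=note)

    @classmethod
    def unavailable(cls, pair, barrier, note="no data available") -> "BarrierEstimate":
        return cls(pair=tuple(pair), barrier=barrier, x=None, ri=float("nan"),
                   method="unavailable", note=note)


def geography_x(
    occurrences: OccurrenceTable,
    pair: tuple[str, str],
    grid_cell_size: float = 1.0,
) -> float:
    """Default geographic gene-flow estimator from rasterized occurrences.

    Records are binned into square cells of side ``grid_cell_size``; ``x`` is
    the mean over the two taxa of the fraction of a taxon's occupied cells
    that the other taxon also occupies.
    """
    df = occurrences.df
    cells: dict[str, set[tuple[int, int]]] = {}
    for t in pair:
        sub = df[df["taxon"] == t]
        if sub.empty:
            raise EstimationError(f"no occurrence records for taxon {t!r}")
        ix = np.floor(sub["lon"].to_numpy() / grid_cell_size).astype(int)
        iy = np.floor(sub["lat"].to_numpy() / grid_cell_size).astype(int)
        cells[t] = set(zip(ix.tolist(), iy.tolist()))
    a, b = pair
    shared = cells[a] & cells[b]
    frac_a = len(shared) / len(cells[a])
    frac_b = len(shared) / len(cells[b])
    return float(0.5 * (frac_a + frac_b))


class RiTable:
    """Per-pair, per-barrier isolation indices with cell provenance."""

    def __init__(self, frame: pd.DataFrame) -> None:
        self.frame = frame

    def cell(self, pair: tuple[str, str], barrier: str) -> BarrierEstimate:
        m = self.frame[
            (self.frame["pair"] == "-".join(pair)) & (self.frame["barrier"] == barrier)
        ]
        if m.empty:
            raise KeyError((pair, barrier))
        row = m.iloc[0]
        return BarrierEstimate(
            pair=tuple(pair), barrier=barrier,
            x=None if pd.isna(row["x"]) else float(row["x"]),
            ri=float(row["ri"]), method=row["method"], note=row["note"],
        )

    def display(self) -> pd.DataFrame:
        """Pairs x barriers display table, 2 dp, with the ``>0.99`` rendering."""
        def fmt(ri: float, x) -> str:
            if np.isnan(ri):
                return "-"
            if x is not None and not pd.isna(x) and x > 0 and 0.98 < ri < 1:
                return ">0.99"
            return f"{ri:.2f}"

        rows = {}
        for pair, grp in self.frame.groupby("pair"):
            rows[pair] = {
                r["barrier"]: fmt(r["ri"], r["x"]) for _, r in grp.iterrows()
            }
        out = pd.DataFrame.from_dict(rows, orient="index")
        cols = [b for b in BARRIERS if b in out.columns]
        return out[cols]


def assemble_ri_table(estimates: list[BarrierEstimate]) -> RiTable:
    """Merge computed, assigned and unavailable cells; duplicates are errors."""
    seen = set()
    rows = []
    for e in estimates:
        key = (e.pair, e.barrier)
        if key in seen:
            raise ValueError(f"duplicate Ri cell for {key}")
        seen.add(key)
        rows.append(
            {
                "pair": "-".join(e.pair),
                "barrier": e.barrier,
                "x": np.nan if e.x is None else e.x,
                "ri": e.ri,
                "method": e.method,
                "note": e.note,
            }
        )
    return RiTable(pd.DataFrame(rows, columns=["pair", "barrier", "x", "ri", "method", "note"]))
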