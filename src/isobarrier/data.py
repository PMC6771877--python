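"""Published count tables from the Heliconius reproductive-isolation study.

These small tables are bundled so the headline analyses can be reproduced
end-to-end without external files: the mate-choice counts by female and male
taxon, the pupal-fate matrix for the seven cross types, and the published
host-plant overlap values (the raw 21-plant egg matrix is not public, so the
overlap enters downstream computations as a published input).
"""

from __future__ import annotations

import pandas as pd

from .core import MatingCountTable, PupalFateTable

TAXA = ("E", "Pb", "Ps")


def mating_counts() -> MatingCountTable:
    """Observed matings: rows = female taxon, columns = male taxon.

    E females mated only with E males (13); Pb females with Pb (13) and
    Ps (10) males; Ps females with Pb (5) and Ps (3) males; no
    heterospecific matings involved E in either direction.
    """
    counts = pd.DataFrame(
        [[13, 0, 0], [0, 13, 10], [0, 5, 3]],
        index=list(TAXA),
        columns=list(TAXA),
    )
    return MatingCountTable(counts)


def pupal_fates() -> PupalFateTable:
    """Pupal fate counts for the seven cross types (844 pupae)."""
    rows = {
        "E × E": (131, 14, 18, 12),
        "Pb × Pb": (255, 9, 4, 20),
        "Ps × Ps": (24, 3, 4, 0),
        "E × Pb": (24, 1, 3, 2),
        "(E × Pb) × (E × Pb)": (173, 8, 17, 7),
        "Pb × Ps": (31, 0, 1, 0),
        "Pb × (Pb × Ps)": (79, 1, 1, 2),
    }
    frame = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["emerged", "failed_emerge", "never_emerged", "failed_pupation"],
    )
    return PupalFateTable(frame)


#: Published pairwise Pianka host-plant overlap values (21-plant experiment).
HOST_PLANT_OVERLAP: dict[tuple[str, str], float] = {
    ("Pb", "Ps"): 0.81,
    ("E", "Pb"): 0.47,
    ("E", "Ps"): 0.38,
}
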