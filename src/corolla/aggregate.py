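"""Per-flower corolla descriptors in the Koyama-Smith construction.

A flower's petals, laid side by side, are summarised by three numbers:
the total petal area A_T (corolla area), the sum of the petal widths
L_KS, and the maximum petal length W_KS.  A_T is then modelled as
proportional to L_KS * W_KS, the area of the rectangle those collective
dimensions span.  (In the original shoot/leaf setting L_KS is the
"foliage length" — leaves side by side along the shoot — and W_KS the
"foliage width"; here the same construction is applied to petals.)

Because each petal satisfies A <= L*W and every petal length is at most
W_KS, the flower-level bound A_T <= L_KS * W_KS always holds, so the
fitted proportionality coefficient cannot exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .geometry import PetalRecord

__all__ = ["FlowerSummary", "aggregate_flowers",
           "read_flower_table", "write_flower_table"]

FLOWER_COLUMNS = ["species", "flower_id", "n_petals", "A_T", "L_KS", "W_KS"]


@dataclass(frozen=True)
class FlowerSummary:
    """Corolla descriptors of one flower.

    A_T : total petal area, cm^2 (sum of member petal areas)
    L_KS : sum of member petal widths, cm
    W_KS : maximum member petal length, cm
    """

    species: str
    flower_id: str
    n_petals: int
    A_T: float
    L_KS: float
    W_KS: float

    def __post_init__(self) -> None:
        if self.n_petals < 1:
            raise ValueError("flower must have at least one petal")
        if min(self.A_T, self.L_KS, self.W_KS) <= 0:
            raise ValueError("A_T, L_KS, W_KS must be positive")

    @property
    def aspect_ratio(self) -> float:
        """W_KS/L_KS, the corolla-level shape ratio."""
        return self.W_KS / self.L_KS


def aggregate_flowers(petals: list[PetalRecord]) -> list[FlowerSummary]:
    """Group petal records by (species, flower_id) into flower summaries.

    Grouping is exact string match on both labels, so flower ids need
    only be unique within a species.  Output order follows first
    appearance in the input; petal order within a flower is irrelevant
    (sums and maxima are permutation invariant).

    Raises
    ------
    ValueError
        On empty input.
    """
    if not petals:
        raise ValueError("no petal records to aggregate")
    groups: dict[tuple[str, str], list[PetalRecord]] = {}
    for p in petals:
        groups.setdefault((p.species, p.flower_id), []).append(p)
    return [
        FlowerSummary(
            species=sp,
            flower_id=fid,
            n_petals=len(members),
            A_T=sum(p.A for p in members),
            L_KS=sum(p.W for p in members),
            W_KS=max(p.L for p in members),
        )
        for (sp, fid), members in groups.items()
    ]


def write_flower_table(flowers: list[FlowerSummary], path: str | Path) -> None:
    """Write flower summaries as CSV (A_T cm^2, L_KS and W_KS cm)."""
    df = pd.DataFrame([f.__dict__ for f in flowers], columns=FLOWER_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# units: A_T cm^2, L_KS cm, W_KS cm\n")
        df.to_csv(fh, index=False)


def read_flower_table(path: str | Path) -> list[FlowerSummary]:
    df = pd.read_csv(path, comment="#")
    missing = set(FLOWER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flower table missing columns: {sorted(missing)}")
    return [
        FlowerSummary(str(r.species), str(r.flower_id), int(r.n_petals),
                      float(r.A_T), float(r.L_KS), float(r.W_KS))
        for r in df.itertuples(index=False)
    ]
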