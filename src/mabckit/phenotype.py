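"""Compatibility-index and pollen-tube phenotyping.

Self-compatibility of a plant is scored two ways:

* **CI** (compatibility index): seeds set per manually self-pollinated
  flower, ``CI = n_seeds / n_flowers``.  Classes: SI (CI < 1),
  MSC (1 <= CI <= 4), SC (CI > 4).
* **NPT**: number of pollen tubes penetrating the stigma six hours after
  self-pollination.  Classes: SI (NPT < 10), MSC (10 <= NPT <= 25),
  SC (NPT > 25).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

SI = "SI"
MSC = "MSC"
SC = "SC"


def compute_ci(n_seeds: int, n_flowers: int) -> float:
    """Seeds per pollinated flower (exact ratio)."""
    if n_flowers <= 0:
        raise ValueError("number of pollinated flowers must be > 0")
    if n_seeds < 0:
        raise ValueError("seed count must be >= 0")
    return n_seeds / n_flowers


def classify_ci(ci: float) -> str:
    """SI (CI < 1), MSC (1 <= CI <= 4), SC (CI > 4)."""
    if ci < 0:
        raise ValueError("CI must be >= 0")
    if ci < 1:
        return SI
    if ci <= 4:
        return MSC
    return SC


def classify_npt(npt: int) -> str:
    """SI (NPT < 10), MSC (10 <= NPT <= 25), SC (NPT > 25)."""
    if npt < 0:
        raise ValueError("pollen-tube count must be >= 0")
    if npt < 10:
        return SI
    if npt <= 25:
        return MSC
    return SC


@dataclass(frozen=True)
class CIRecord:
    id: str
    n_flowers: int
    n_seeds: int
    ci: float
    ci_class: str

    def __post_init__(self):
        if self.n_flowers <= 0:
            raise ValueError("n_flowers must be > 0")

    @classmethod
    def from_counts(cls, id: str, n_flowers: int, n_seeds: int) -> "CIRecord":
        ci = compute_ci(n_seeds, n_flowers)
        return cls(id=id, n_flowers=n_flowers, n_seeds=n_seeds, ci=ci,
                   ci_class=classify_ci(ci))


@dataclass(frozen=True)
class PollinationAssay:
    id: str
    npt: int

    def __post_init__(self):
        if self.npt < 0:
            raise ValueError("npt must be >= 0")

    @property
    def npt_class(self) -> str:
        return classify_npt(self.npt)


def ci_summary(records: Iterable[CIRecord]) -> dict[str, int]:
    """Counts per compatibility class (always reports all three keys)."""
    counts = {SC: 0, MSC: 0, SI: 0}
    for rec in records:
        counts[rec.ci_class] += 1
    return counts


def read_pollination_tsv(path: str | Path) -> list[CIRecord]:
    """Read (id, flowers, seeds) records and classify them."""
    df = pd.read_csv(path, sep="\t")
    return [
        CIRecord.from_counts(str(r.id), int(r.flowers), int(r.seeds))
        for r in df.itertuples(index=False)
    ]


def write_ci_tsv(records: Iterable[CIRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "flowers": r.n_flowers,
                "seeds": r.n_seeds,
                "ci": round(r.ci, 2),
                "class": r.ci_class,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
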