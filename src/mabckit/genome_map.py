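"""Physical/genetic coordinate arithmetic for the *Brassica rapa* genome.

A :class:`GenomeMap` holds one :class:`ChromosomeMap` per chromosome; each
chromosome carries its physical length (bp), genetic length (cM) and an
ordered set of monotone ``(bp, cM)`` anchor points.  Conversion between
physical and genetic coordinates is piecewise-linear interpolation between
flanking anchors; by default only the two telomeric anchors
``(1 bp, 0 cM)`` and ``(phys_len, gen_len)`` exist, i.e. a uniform
recombination rate per chromosome.  Denser anchor sets (e.g. from a real
linkage map) can be loaded from a TSV file.

Physical coordinates are 1-based inclusive throughout, matching the
convention of printed variant and segment positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class CoordinateError(ValueError):
    """Unknown chromosome or out-of-range position."""


@dataclass(frozen=True)
class ChromosomeMap:
    """Monotone bp <-> cM map of a single chromosome."""

    name: str
    phys_len: int
    gen_len: float
    anchors: tuple[tuple[int, float], ...] = field(default=())

    def __post_init__(self):
        if self.phys_len <= 0:
            raise ValueError(f"{self.name}: phys_len must be > 0")
        if self.gen_len <= 0:
            raise ValueError(f"{self.name}: gen_len must be > 0")
        anchors = self.anchors or ((1, 0.0), (self.phys_len, float(self.gen_len)))
        anchors = tuple((int(bp), float(cm)) for bp, cm in anchors)
        if anchors[0] != (1, 0.0):
            raise ValueError(f"{self.name}: first anchor must be (1 bp, 0 cM)")
        if anchors[-1][0] != self.phys_len or abs(anchors[-1][1] - self.gen_len) > 1e-9:
            raise ValueError(f"{self.name}: last anchor must be (phys_len, gen_len)")
        bps = [a[0] for a in anchors]
        cms = [a[1] for a in anchors]
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])) or any(
            c2 <= c1 for c1, c2 in zip(cms, cms[1:])
        ):
            raise ValueError(f"{self.name}: anchors must be strictly increasing in bp and cM")
        object.__setattr__(self, "anchors", anchors)

    @property
    def _bp(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors], dtype=float)

    @property
    def _cm(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors], dtype=float)

    def bp_to_cm(self, pos) -> float | np.ndarray:
        pos_arr = np.asarray(pos, dtype=float)
        if np.any(pos_arr < 1) or np.any(pos_arr > self.phys_len):
            raise CoordinateError(
                f"{self.name}: bp position out of range [1, {self.phys_len}]"
            )
        out = np.interp(pos_arr, self._bp, self._cm)
        return float(out) if np.isscalar(pos) or out.ndim == 0 else out

    def cm_to_bp(self, pos) -> float | np.ndarray:
        pos_arr = np.asarray(pos, dtype=float)
        if np.any(pos_arr < 0) or np.any(pos_arr > self.gen_len + 1e-9):
            raise CoordinateError(f"{self.name}: cM position out of range [0, {self.gen_len}]")
        out = np.interp(pos_arr, self._cm, self._bp)
        return float(out) if np.isscalar(pos) or out.ndim == 0 else out


class GenomeMap:
    """Ordered collection of :class:`ChromosomeMap` objects."""

    def __init__(self, chromosomes: Iterable[ChromosomeMap]):
        self._chroms: dict[str, ChromosomeMap] = {}
        for c in chromosomes:
            if c.name in self._chroms:
                raise ValueError(f"duplicate chromosome {c.name}")
            self._chroms[c.name] = c
        if not self._chroms:
            raise ValueError("empty genome map")

    def __getitem__(self, name: str) -> ChromosomeMap:
        try:
            return self._chroms[name]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __iter__(self):
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    @property
    def total_gen_len(self) -> float:
        return sum(c.gen_len for c in self)

    @property
    def total_phys_len(self) -> int:
        return sum(c.phys_len for c in self)

    def bp_to_cm(self, chrom: str, pos) -> float | np.ndarray:
        return self[chrom].bp_to_cm(pos)

    def cm_to_bp(self, chrom: str, pos) -> float | np.ndarray:
        return self[chrom].cm_to_bp(pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.name for c in self],
                "phys_len": [c.phys_len for c in self],
                "gen_len": [c.gen_len for c in self],
            }
        )

    @classmethod
    def from_frame(
        cls, table: pd.DataFrame, anchors: pd.DataFrame | None = None
    ) -> "GenomeMap":
        chroms = []
        for row in table.itertuples(index=False):
            anc: tuple = ()
            if anchors is not None:
                sub = anchors[anchors["chrom"] == row.chrom]
                if len(sub):
                    anc = tuple(
                        (int(b), float(c))
                        for b, c in zip(sub["pos_bp"], sub["pos_cM"])
                    )
            chroms.append(
                ChromosomeMap(
                    name=str(row.chrom),
                    phys_len=int(row.phys_len),
                    gen_len=float(row.gen_len),
                    anchors=anc,
                )
            )
        return cls(chroms)

    @classmethod
    def from_tsv(cls, path: str | Path, anchors_path: str | Path | None = None) -> "GenomeMap":
        """Read a genome map from TSV (columns chrom, phys_len, gen_len).

        An optional anchor TSV (chrom, pos_bp, pos_cM) refines the
        per-chromosome linear map into a piecewise-linear one.
        """
        table = pd.read_csv(path, sep="\t")
        anchors = pd.read_csv(anchors_path, sep="\t") if anchors_path else None
        return cls.from_frame(table, anchors)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def haldane(d_cm: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM.

    Assumes crossovers are Poisson (no interference):
    ``r = (1 - exp(-2d/100)) / 2``, bounded in ``[0, 0.5)``.
    """
    if d_cm < 0:
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def kosambi(d_cm: float) -> float:
    """Kosambi map function (moderate positive interference)."""
    if d_cm < 0:
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * np.tanh(2.0 * d_cm / 100.0)


_MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


def recombination_fraction(d_cm: float, model: str = "haldane") -> float:
    """Map a genetic distance (cM) to a recombination probability."""
    try:
        fn = _MAP_FUNCTIONS[model]
    except KeyError:
        raise ValueError(f"unknown map function {model!r}") from None
    return fn(d_cm)


#: Chromosome lengths of the B. rapa (Chiifu v3.0) reference genome with the
#: genetic lengths of the associated linkage map; the default coordinate
#: backbone for simulation and marker design.
BRASSICA_RAPA_CHROMOSOMES: tuple[tuple[str, int, float], ...] = (
    ("A01", 29595527, 106.84),
    ("A02", 31442979, 98.25),
    ("A03", 38154160, 111.76),
    ("A04", 21928416, 71.58),
    ("A05", 28493056, 108.50),
    ("A06", 29167992, 98.83),
    ("A07", 28928902, 90.36),
    ("A08", 22981702, 71.88),
    ("A09", 45156810, 115.21),
    ("A10", 20725698, 72.11),
)


def brassica_rapa_map() -> GenomeMap:
    """The bundled *B. rapa* A01..A10 genome map (two-point linear per chromosome)."""
    return GenomeMap(
        ChromosomeMap(name=n, phys_len=p, gen_len=g)
        for n, p, g in BRASSICA_RAPA_CHROMOSOMES
    )
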