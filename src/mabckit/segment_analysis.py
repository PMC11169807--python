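"""Introgression-segment delineation and cross-individual comparison.

Dense per-locus genotype states along a chromosome are collapsed into
maximal runs of identical state; runs supported by fewer loci than
``min_support`` are absorbed into the better-supported flank (smoothing
over genotyping errors).  Boundaries between adjacent segments are
placed at the bp midpoint between the last locus of one run and the
first locus of the next, and the outermost segments extend to the
chromosome ends, so every delineation tiles ``[1, phys_len]`` exactly.

Coordinates are 1-based inclusive; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .calls import HET, HOM_DON, HOM_REC, MISSING, STATE_NAMES
from .synthetic_data import TargetLocus


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    state: int  # HOM_REC | HET | HOM_DON
    n_support: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.state not in (HOM_REC, HET, HOM_DON):
            raise ValueError("invalid segment state")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def segment_length_mb(seg: Segment) -> float:
    """Inclusive segment length in Mb, reported to 1 decimal."""
    return round(seg.length_bp / 1e6, 1)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, first_idx, last_idx) for maximal runs of equal state."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((int(states[start]), start, i - 1))
            start = i
    return runs


def delineate_segments(
    positions: Sequence[int],
    states: Sequence[int],
    chrom: str,
    phys_len: int,
    min_support: int = 3,
) -> list[Segment]:
    """Collapse sorted per-locus states into introgression segments.

    ``positions``/``states`` are parallel, sorted by position; missing
    calls are skipped.  Runs with fewer than ``min_support`` informative
    loci are merged into the flanking run with more support (iterated to
    a fixed point; ``min_support=1`` disables smoothing).
    """
    pos = np.asarray(positions, dtype=np.int64)
    st = np.asarray(states, dtype=np.int64)
    if len(pos) != len(st):
        raise ValueError("positions and states must be parallel")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    keep = st != MISSING
    pos, st = pos[keep], st[keep]
    if len(pos) == 0:
        raise ValueError("no informative (non-missing) calls")
    if np.any(pos < 1) or np.any(pos > phys_len):
        raise ValueError("locus position outside the chromosome")

    st = st.copy()
    while True:
        runs = _runs(st)
        if len(runs) == 1:
            break
        weak = [
            k for k, (_, a, b) in enumerate(runs) if (b - a + 1) < min_support
        ]
        if not weak:
            break
        # absorb the weakest run first so ties resolve deterministically
        k = min(weak, key=lambda k: (runs[k][2] - runs[k][1], k))
        _, a, b = runs[k]
        if k == 0:
            winner = runs[1]
        elif k == len(runs) - 1:
            winner = runs[k - 1]
        else:
            left, right = runs[k - 1], runs[k + 1]
            winner = left if (left[2] - left[1]) >= (right[2] - right[1]) else right
        st[a : b + 1] = winner[0]

    runs = _runs(st)
    segments: list[Segment] = []
    prev_end = 0
    for k, (state, a, b) in enumerate(runs):
        if k == len(runs) - 1:
            end = phys_len
        else:
            end = int((pos[b] + pos[runs[k + 1][1]]) // 2)
        segments.append(
            Segment(chrom=chrom, start=prev_end + 1, end=end, state=state,
                    n_support=b - a + 1)
        )
        prev_end = end
    return segments


def states_from_segments(
    segments: Sequence[Segment], positions: Sequence[int]
) -> np.ndarray:
    """Per-locus states implied by a segment tiling (inverse of delineation)."""
    out = np.empty(len(positions), dtype=np.int64)
    for i, p in enumerate(positions):
        for seg in segments:
            if seg.start <= p <= seg.end:
                out[i] = seg.state
                break
        else:
            raise ValueError(f"position {p} not covered by any segment")
    return out


@dataclass(frozen=True)
class DragReport:
    """The donor segment dragged along with the target locus."""

    segment: Segment
    upstream_boundary: int | None  # recombination breakpoint 5' of the segment
    downstream_boundary: int | None

    @property
    def length_mb(self) -> float:
        return segment_length_mb(self.segment)


def drag_report(
    segments: Sequence[Segment],
    locus: TargetLocus,
    target_genotype: str | None = None,
) -> DragReport:
    """Locate the segment containing the target locus.

    If the individual is genotyped ``mm`` but the containing segment is
    homozygous-recurrent, the calls contradict the target genotype and a
    ``ValueError`` flags the inconsistency.
    """
    on_chrom = sorted(
        (s for s in segments if s.chrom == locus.chrom), key=lambda s: s.start
    )
    for k, seg in enumerate(on_chrom):
        if seg.start <= locus.pos <= seg.end:
            if target_genotype == "mm" and seg.state == HOM_REC:
                raise ValueError(
                    "target genotyped mm but the containing segment is "
                    "homozygous recurrent"
                )
            up = on_chrom[k - 1].end if k > 0 else None
            down = on_chrom[k + 1].start if k < len(on_chrom) - 1 else None
            return DragReport(segment=seg, upstream_boundary=up, downstream_boundary=down)
    raise ValueError("target locus not covered by any segment (tiling violated)")


def non_recurrent_intervals(segments: Iterable[Segment]) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome 1-based inclusive intervals where the genotype is
    not homozygous recurrent (i.e. carries donor chromatin)."""
    out: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        if s.state != HOM_REC:
            out.setdefault(s.chrom, []).append((s.start, s.end))
    return {c: sorted(v) for c, v in out.items()}


def _to_half_open(ivs: list[tuple[int, int]]) -> list[tuple[float, float]]:
    return [(float(s), float(e) + 1.0) for s, e in ivs]


def _from_half_open(ivs: list[tuple[float, float]]) -> list[tuple[int, int]]:
    out = []
    for s, e in ivs:
        a, b = int(np.ceil(s)), int(np.floor(e)) - 1
        if a <= b:
            out.append((a, b))
    return out


def shared_segments(
    carriers: Sequence[Iterable[Segment]],
    non_carriers: Sequence[Iterable[Segment]] = (),
) -> dict[str, list[tuple[int, int]]]:
    """Candidate intervals present in every carrier but in no non-carrier.

    Intersects the non-recurrent (donor-carrying) regions of all
    carriers, then subtracts the union of the non-carriers' non-recurrent
    regions.  Returns per-chromosome 1-based inclusive intervals; may be
    empty.
    """
    if not carriers:
        return {}
    carrier_sets = [non_recurrent_intervals(c) for c in carriers]
    chroms = set(carrier_sets[0])
    for cs in carrier_sets[1:]:
        chroms &= set(cs)
    excl = [non_recurrent_intervals(nc) for nc in non_carriers]
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted(chroms):
        acc = _to_half_open(carrier_sets[0][chrom])
        for cs in carrier_sets[1:]:
            acc = iv.intersect(acc, _to_half_open(cs[chrom]))
        minus = iv.union(*[_to_half_open(e.get(chrom, [])) for e in excl]) if excl else []
        acc = iv.subtract(acc, minus)
        res = _from_half_open(acc)
        if res:
            out[chrom] = res
    return out


# ---------------------------------------------------------------------------
# export


def segments_to_frame(segments: Iterable[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "state": STATE_NAMES[s.state],
                "n_support": s.n_support,
                "length_mb": segment_length_mb(s),
            }
            for s in segments
        ]
    )


def write_segments_tsv(segments: Iterable[Segment], path: str | Path) -> None:
    """1-based inclusive coordinates, matching printed conventions."""
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: Iterable[Segment], path: str | Path) -> None:
    """BED export: 0-based half-open, name = state."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{STATE_NAMES[s.state]}\n")


def read_segments_tsv(path: str | Path) -> list[Segment]:
    name_to_state = {v: k for k, v in STATE_NAMES.items()}
    df = pd.read_csv(path, sep="\t")
    return [
        Segment(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            state=name_to_state[str(r.state)],
            n_support=int(r.n_support),
        )
        for r in df.itertuples(index=False)
    ]
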