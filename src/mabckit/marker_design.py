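"""Design of HRM background markers and the allele-specific target marker.

High-resolution melting (HRM) genotyping distinguishes the two parental
alleles of a small amplicon by the shift in its melting curve; an INDEL
between the parents changes the amplicon length and composition enough
to separate the curves.  The design chain implemented here:

1. filter parental variants to homozygous INDELs of >= 3 bp;
2. place a primer pair in the 150 bp flanks so that both allele products
   fall in the 130-260 bp window with 18-23 bp primers;
3. predict the melting temperature of each allele product with the
   unified nearest-neighbor thermodynamic model (1 M Na+);
4. retain candidates whose allele products differ by more than 0.5 deg C
   (strict), the resolution limit of HRM instruments;
5. pick a panel evenly spaced in genetic-map distance, with per-chromosome
   counts, and report marker densities on both maps.

The target locus itself is a SNP, invisible to HRM; it gets a KASP-style
competitive allele-specific marker with two 3'-anchored allele primers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from math import fsum, log
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_map import GenomeMap
from .synthetic_data import TargetLocus, Variant, variant_context

R_GAS = 1.987  # cal / (mol K)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# nearest-neighbor thermodynamics


class NNParameterTable:
    """Dinucleotide-stack enthalpies/entropies plus initiation terms.

    Enthalpy in kcal/mol, entropy in cal/(mol K).  The table must contain
    all 16 stacks and satisfy duplex symmetry: the parameters of a stack
    equal those of its reverse complement (the same duplex read from the
    other strand).
    """

    def __init__(
        self,
        stacks: Mapping[str, tuple[float, float]],
        init_at: tuple[float, float],
        init_gc: tuple[float, float],
        sym: tuple[float, float],
    ):
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(stacks)
        if missing:
            raise ValueError(f"missing stacks: {sorted(missing)}")
        for st, (dh, ds) in stacks.items():
            rc = revcomp(st)
            if stacks[rc] != (dh, ds):
                raise ValueError(f"stack {st} and its reverse complement {rc} disagree")
        self.stacks = dict(stacks)
        self.init_at = init_at
        self.init_gc = init_gc
        self.sym = sym

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NNParameterTable":
        df = pd.read_csv(path, sep="\t")
        entries = {
            str(r.entry): (float(r.dh_kcal_per_mol), float(r.ds_cal_per_mol_K))
            for r in df.itertuples(index=False)
        }
        stacks = {k: v for k, v in entries.items() if len(k) == 2 and k.isupper()}
        return cls(
            stacks=stacks,
            init_at=entries["init_AT"],
            init_gc=entries["init_GC"],
            sym=entries["sym"],
        )

    @classmethod
    def unified(cls) -> "NNParameterTable":
        """The bundled unified duplex parameter set (editable data file)."""
        with resources.as_file(
            resources.files("mabckit.data") / "nn_unified.tsv"
        ) as p:
            return cls.from_tsv(p)


_DEFAULT_TABLE: NNParameterTable | None = None


def _default_table() -> NNParameterTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = NNParameterTable.unified()
    return _DEFAULT_TABLE


def predict_tm(
    seq: str,
    na_molar: float = 1.0,
    ct_molar: float = 0.25e-6,
    x: float = 4.0,
    table: NNParameterTable | None = None,
) -> float:
    """Duplex melting temperature (deg C) by the nearest-neighbor model.

    ``Tm = dH / (dS + R ln(C_T / x)) - 273.15`` with dH/dS summed over
    dinucleotide stacks plus terminal initiation terms; entropy receives
    the salt adjustment ``0.368 (N-1) ln[Na+]`` (identity at 1 M Na+).
    ``C_T`` is total strand concentration and ``x`` = 4 for
    non-self-complementary duplexes (1 if self-complementary, applied
    automatically together with the symmetry entropy correction).
    """
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bases long")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must contain only A, C, G, T")
    table = table or _default_table()
    dh_terms = []
    ds_terms = []
    for i in range(len(seq) - 1):
        h, s = table.stacks[seq[i : i + 2]]
        dh_terms.append(h)
        ds_terms.append(s)
    for terminal in (seq[0], seq[-1]):
        h, s = table.init_at if terminal in "AT" else table.init_gc
        dh_terms.append(h)
        ds_terms.append(s)
    if seq == revcomp(seq):
        dh_terms.append(table.sym[0])
        ds_terms.append(table.sym[1])
        x = 1.0
    ds_terms.append(0.368 * (len(seq) - 1) * log(na_molar))
    # fsum: order-independent, so a duplex and its reverse complement get
    # bit-identical Tm
    dh = fsum(dh_terms)
    ds = fsum(ds_terms)
    tm = dh * 1000.0 / (ds + R_GAS * log(ct_molar / x)) - 273.15
    if not np.isfinite(tm):
        raise ValueError("non-finite melting temperature")
    return tm


# ---------------------------------------------------------------------------
# variant filtering


def filter_variants(variants: Iterable[Variant], min_indel_len: int = 3) -> list[Variant]:
    """Keep homozygous INDELs of at least ``min_indel_len`` bp."""
    return [
        v
        for v in variants
        if v.kind == "INDEL" and v.donor_zygosity == "hom" and v.indel_len >= min_indel_len
    ]


# ---------------------------------------------------------------------------
# amplicon construction


class AmpliconRejection(Exception):
    """A variant for which no valid primer placement exists."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass(frozen=True)
class AmpliconPair:
    """The two allele products of one HRM primer pair."""

    variant: Variant
    primer_fwd: str
    primer_rev: str
    amp_rec: str  # recurrent (reference) allele product
    amp_don: str  # donor (alternate) allele product
    tm_rec: float
    tm_don: float

    @property
    def delta_tm(self) -> float:
        return abs(self.tm_rec - self.tm_don)


def build_amplicon_pair(
    variant: Variant,
    ref_context: str,
    var_index: int | None = None,
    flank: int = 150,
    product_range: tuple[int, int] = (130, 260),
    primer_len_range: tuple[int, int] = (18, 23),
    tm_kwargs: Mapping | None = None,
) -> AmpliconPair:
    """Place primers around an INDEL and materialise both allele products.

    ``ref_context`` is reference (recurrent-parent) sequence with the
    variant's REF allele starting at ``var_index`` (default: ``flank``).
    A deterministic grid search over product length and start offset
    returns the first placement whose primers lie fully outside the
    variant interval and whose two allele products both fall inside
    ``product_range``.  Raises :class:`AmpliconRejection` when no
    placement exists, and ``ValueError`` for SNP input or a context that
    does not cover ``pos +- flank``.
    """
    if variant.kind != "INDEL":
        raise ValueError("HRM amplicons are INDEL-based; SNP input is not supported")
    if var_index is None:
        var_index = flank
    if len(ref_context) < 2 * flank + 1:
        raise ValueError(f"context must cover pos +- {flank} bp")
    ref_context = ref_context.upper()
    ref, alt = variant.ref_allele, variant.alt_allele
    if ref_context[var_index : var_index + len(ref)] != ref.upper():
        raise ValueError("context does not carry the REF allele at var_index")
    pmin, pmax = primer_len_range
    lo, hi = product_range
    delta = len(alt) - len(ref)
    v0, v1 = var_index, var_index + len(ref) - 1
    l_lo = max(lo, lo - delta)
    l_hi = min(hi, hi - delta)
    for length in range(l_lo, l_hi + 1):
        a_max = min(v0 - pmin, len(ref_context) - length)
        a_min = max(0, v1 + pmin - (length - 1))
        for a in range(a_max, a_min - 1, -1):
            b = a + length - 1
            if b - v1 < pmin or b >= len(ref_context):
                continue
            fl = min(pmax, v0 - a)
            rl = min(pmax, b - v1)
            amp_rec = ref_context[a : b + 1]
            amp_don = ref_context[a:v0] + alt + ref_context[v0 + len(ref) : b + 1]
            if not (lo <= len(amp_don) <= hi):
                continue
            kw = dict(tm_kwargs or {})
            return AmpliconPair(
                variant=variant,
                primer_fwd=ref_context[a : a + fl],
                primer_rev=revcomp(ref_context[b - rl + 1 : b + 1]),
                amp_rec=amp_rec,
                amp_don=amp_don,
                tm_rec=predict_tm(amp_rec, **kw),
                tm_don=predict_tm(amp_don, **kw),
            )
    raise AmpliconRejection("no primer placement satisfies the length constraints")


def score_delta_tm(pair: AmpliconPair, threshold: float = 0.5) -> tuple[bool, float]:
    """Retain the candidate iff its allele products melt apart by more
    than ``threshold`` deg C (strict inequality)."""
    return pair.delta_tm > threshold, pair.delta_tm


# ---------------------------------------------------------------------------
# markers and panels


@dataclass(frozen=True)
class Marker:
    id: str
    chrom: str
    pos_bp: int
    pos_cm: float
    type: str  # "HRM" | "KASP"
    amplicon: AmpliconPair | None = None
    kasp: "KaspMarker | None" = None

    @property
    def delta_tm(self) -> float:
        return self.amplicon.delta_tm if self.amplicon else 0.0


@dataclass(frozen=True)
class MarkerPanel:
    """A sorted, uniquely-named collection of genotyping markers."""

    markers: tuple[Marker, ...]

    def __post_init__(self):
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        key = [(m.chrom, m.pos_bp) for m in self.markers]
        if key != sorted(key):
            raise ValueError("markers must be sorted by (chrom, pos)")

    @classmethod
    def from_markers(cls, markers: Iterable[Marker]) -> "MarkerPanel":
        return cls(tuple(sorted(markers, key=lambda m: (m.chrom, m.pos_bp))))

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def loci(self) -> list[tuple[str, str, int]]:
        return [(m.id, m.chrom, m.pos_bp) for m in self.markers]

    def by_chrom(self) -> dict[str, list[Marker]]:
        out: dict[str, list[Marker]] = {}
        for m in self.markers:
            out.setdefault(m.chrom, []).append(m)
        return out

    def subset(self, ids: Sequence[str]) -> "MarkerPanel":
        wanted = set(ids)
        return MarkerPanel.from_markers(m for m in self.markers if m.id in wanted)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.markers:
            rows.append(
                {
                    "id": m.id,
                    "chrom": m.chrom,
                    "pos_bp": m.pos_bp,
                    "pos_cM": round(m.pos_cm, 4),
                    "type": m.type,
                    "primer_fwd": m.amplicon.primer_fwd if m.amplicon else "",
                    "primer_rev": m.amplicon.primer_rev if m.amplicon else "",
                    "tm_rec": round(m.amplicon.tm_rec, 3) if m.amplicon else "",
                    "tm_don": round(m.amplicon.tm_don, 3) if m.amplicon else "",
                    "delta_tm": round(m.amplicon.delta_tm, 3) if m.amplicon else "",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        """Positions/ids only; amplicon detail is not round-tripped."""
        df = pd.read_csv(path, sep="\t")
        return cls.from_markers(
            Marker(
                id=str(r.id),
                chrom=str(r.chrom),
                pos_bp=int(r.pos_bp),
                pos_cm=float(r.pos_cM),
                type=str(r.type),
            )
            for r in df.itertuples(index=False)
        )


#: Per-chromosome background-marker counts of the default panel (131 total).
DEFAULT_PANEL_COUNTS: dict[str, int] = {
    "A01": 13, "A02": 12, "A03": 17, "A04": 13, "A05": 14,
    "A06": 13, "A07": 10, "A08": 10, "A09": 15, "A10": 14,
}


def design_hrm_candidates(
    variants: Iterable[Variant],
    gmap: GenomeMap,
    seed: int = 0,
    min_indel_len: int = 3,
    delta_tm_threshold: float = 0.5,
    flank: int = 150,
    product_range: tuple[int, int] = (130, 260),
    primer_len_range: tuple[int, int] = (18, 23),
) -> list[Marker]:
    """Run the full candidate chain: filter -> amplicons -> Tm -> delta-Tm."""
    out: list[Marker] = []
    for k, v in enumerate(filter_variants(variants, min_indel_len)):
        ctx, vi = variant_context(v, flank=flank, seed=seed)
        try:
            pair = build_amplicon_pair(
                v, ctx, var_index=vi, flank=flank,
                product_range=product_range, primer_len_range=primer_len_range,
            )
        except AmpliconRejection:
            continue
        keep, _ = score_delta_tm(pair, delta_tm_threshold)
        if not keep:
            continue
        out.append(
            Marker(
                id=f"HRM-{v.chrom}-{v.pos}",
                chrom=v.chrom,
                pos_bp=v.pos,
                pos_cm=float(gmap.bp_to_cm(v.chrom, v.pos)),
                type="HRM",
                amplicon=pair,
            )
        )
    return out


def select_even_panel(
    candidates: Sequence[Marker],
    gmap: GenomeMap,
    per_chrom_counts: Mapping[str, int] | None = None,
) -> MarkerPanel:
    """Pick an evenly spaced marker panel in genetic-map coordinates.

    Each chromosome's genetic length is split into ``k`` equal cM bins
    (``k`` = requested count); in each bin the candidate nearest the bin
    midpoint wins, ties broken by larger delta-Tm then smaller bp.  An
    empty bin steals the nearest unused candidate on the chromosome
    (with a warning), so the requested counts are always met when enough
    candidates exist.
    """
    per_chrom_counts = dict(per_chrom_counts or DEFAULT_PANEL_COUNTS)
    by_chrom: dict[str, list[Marker]] = {}
    for m in candidates:
        by_chrom.setdefault(m.chrom, []).append(m)
    chosen: list[Marker] = []
    for chrom, k in per_chrom_counts.items():
        cands = sorted(by_chrom.get(chrom, []), key=lambda m: m.pos_cm)
        if len(cands) < k:
            raise ValueError(
                f"{chrom}: {len(cands)} candidates for {k} requested markers"
            )
        gl = gmap[chrom].gen_len
        width = gl / k
        unused = set(range(len(cands)))

        def pick(pool: Iterable[int], mid: float) -> int:
            return min(
                pool,
                key=lambda i: (abs(cands[i].pos_cm - mid), -cands[i].delta_tm, cands[i].pos_bp),
            )

        for b in range(k):
            lo, hi = b * width, (b + 1) * width
            mid = (lo + hi) / 2.0
            in_bin = [
                i for i in unused
                if lo <= cands[i].pos_cm < hi or (b == k - 1 and cands[i].pos_cm == hi)
            ]
            if in_bin:
                idx = pick(in_bin, mid)
            else:
                warnings.warn(
                    f"{chrom}: no candidate in bin {b} "
                    f"[{lo:.2f}, {hi:.2f}) cM; using nearest unused candidate",
                    stacklevel=2,
                )
                idx = pick(unused, mid)
            unused.discard(idx)
            chosen.append(cands[idx])
    return MarkerPanel.from_markers(chosen)


def density_report(panel: MarkerPanel, gmap: GenomeMap) -> pd.DataFrame:
    """Per-chromosome and genome-wide marker-density statistics.

    ``avg_density_mb`` = physical length / marker count (Mb);
    ``avg_density_cm`` = genetic length / marker count (cM);
    ``max_gap_cm`` = largest cM distance between adjacent panel markers.
    The genome row holds the mean of the ten per-chromosome values.
    All figures rounded to 2 decimals.
    """
    by_chrom = panel.by_chrom()
    rows = []
    raw = {"mb": [], "cm": [], "gap": []}
    for chrom in gmap:
        ms = by_chrom.get(chrom.name, [])
        if not ms:
            raise ValueError(f"chromosome {chrom.name} has no markers")
        cms = sorted(m.pos_cm for m in ms)
        gaps = [b - a for a, b in zip(cms, cms[1:])]
        avg_mb = chrom.phys_len / len(ms) / 1e6
        avg_cm = chrom.gen_len / len(ms)
        max_gap = max(gaps) if gaps else float("nan")
        raw["mb"].append(avg_mb)
        raw["cm"].append(avg_cm)
        raw["gap"].append(max_gap)
        rows.append(
            {
                "chrom": chrom.name,
                "phys_len": chrom.phys_len,
                "gen_len": chrom.gen_len,
                "n_markers": len(ms),
                "avg_density_mb": round(avg_mb, 2),
                "avg_density_cm": round(avg_cm, 2),
                "max_gap_cm": round(max_gap, 2),
            }
        )
    rows.append(
        {
            "chrom": "genome",
            "phys_len": gmap.total_phys_len,
            "gen_len": round(gmap.total_gen_len, 2),
            "n_markers": len(panel),
            "avg_density_mb": round(float(np.mean(raw["mb"])), 2),
            "avg_density_cm": round(float(np.mean(raw["cm"])), 2),
            "max_gap_cm": round(float(np.nanmean(raw["gap"])), 2),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target-locus (KASP) marker


@dataclass(frozen=True)
class KaspMarker:
    """Competitive allele-specific marker for the G/C target SNP.

    Two forward primers share a common tail but end (3') on the
    alternative SNP bases; each is read out on its own fluorophore
    channel (FAM for the dominant G allele, VIC for the recessive C
    allele), with one common reverse primer.
    """

    id: str
    locus: TargetLocus
    primer_dominant: str  # FAM channel, 3' base = G
    primer_recessive: str  # VIC channel, 3' base = C
    primer_common: str
    product_len: int

    def genotype_call(self, signals: set[str] | frozenset[str]) -> str | None:
        """Decode fluorescence signals: both -> Mm, FAM -> MM, VIC -> mm,
        none (no-template control) -> no call."""
        signals = set(signals)
        if not signals <= {"FAM", "VIC"}:
            raise ValueError(f"unknown signals {signals - {'FAM', 'VIC'}}")
        if signals == {"FAM", "VIC"}:
            return "Mm"
        if signals == {"FAM"}:
            return "MM"
        if signals == {"VIC"}:
            return "mm"
        return None


def design_target_marker(
    locus: TargetLocus,
    context: str,
    var_index: int,
    allele_primer_len: int = 20,
    common_primer_len: int = 20,
    product_range: tuple[int, int] = (50, 120),
) -> KaspMarker:
    """Build the allele-specific marker around the target SNP.

    ``context`` is reference sequence carrying the dominant (G) allele
    at ``var_index``.  The two allele primers end exactly on the SNP;
    the common reverse primer is placed so the product length falls in
    ``product_range``.
    """
    context = context.upper()
    if {locus.dominant_allele, locus.recessive_allele} != {"G", "C"}:
        raise ValueError("target SNP must be biallelic G/C")
    if context[var_index] != locus.dominant_allele:
        raise ValueError("context does not carry the dominant allele at var_index")
    a = var_index - allele_primer_len + 1
    if a < 0:
        raise ValueError("context too short upstream of the SNP")
    stem = context[a:var_index]
    lo, hi = product_range
    b = var_index + (lo - allele_primer_len) + common_primer_len - 1
    b = max(b, var_index + common_primer_len)  # common primer clear of the SNP
    product_len = b - a + 1
    if b >= len(context) or product_len > hi:
        raise ValueError("context too short downstream of the SNP")
    return KaspMarker(
        id=f"SC-{locus.chrom}-{locus.pos}",
        locus=locus,
        primer_dominant=stem + locus.dominant_allele,
        primer_recessive=stem + locus.recessive_allele,
        primer_common=revcomp(context[b - common_primer_len + 1 : b + 1]),
        product_len=product_len,
    )
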