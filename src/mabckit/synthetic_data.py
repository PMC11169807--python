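"""Synthetic backcross populations with realistic genetic structure.

This module generates everything the downstream analysis consumes, in
place of real plants and resequencing data:

* two fully homozygous inbred parents (recurrent and donor) differing at
  SNPs and INDELs across the ten *B. rapa* chromosomes, including the
  biallelic self-compatibility target locus (a G->C substitution in the
  *MLPK* coding sequence whose homozygous ``mm`` state abolishes the
  stigmatic self-incompatibility response);
* backcross and selfed generations produced by simulated meiosis
  (Poisson crossovers, no interference, breakpoints uniform in cM);
* marker-level and dense (resequencing-like) genotype-call matrices with
  configurable missing and error rates;
* a compatibility-index (CI) phenotype driven by the target locus plus
  donor-derived modifier loci, reproducing the observed segregation of
  self-compatibility among ``mm`` plants.

Haplotypes are phased donor-segment interval lists in centimorgan space:
a chromosome haplotype is the (possibly empty) sorted list of intervals
inherited from the donor parent.  State queries are interval lookups, so
individuals are exact and compact regardless of variant density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .calls import HET, HOM_DON, HOM_REC, MISSING
from .genome_map import GenomeMap
from .phenotype import CIRecord, classify_ci

BASES = "ACGT"

Haplotype = tuple[tuple[float, float], ...]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Variant:
    """A homozygous difference between the two parents (SNP or INDEL)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: str  # "SNP" | "INDEL"
    indel_len: int = 0
    donor_zygosity: str = "hom"  # "hom" | "het"

    def __post_init__(self):
        if self.kind == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.indel_len != 0:
                raise ValueError("SNP has indel_len 0")
        elif self.kind == "INDEL":
            if abs(len(self.ref_allele) - len(self.alt_allele)) != self.indel_len:
                raise ValueError("indel_len must equal the allele length difference")
            if self.indel_len < 1:
                raise ValueError("INDEL alleles must differ in length by >= 1")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.donor_zygosity not in ("hom", "het"):
            raise ValueError("donor_zygosity must be 'hom' or 'het'")


@dataclass(frozen=True)
class TargetLocus:
    """The self-compatibility target: a G->C substitution in *MLPK*.

    The recessive ``m`` allele (C) in homozygous state confers
    self-compatibility; genotype classes are named ``MM`` (G/G),
    ``Mm`` (G/C) and ``mm`` (C/C).  The genomic position is a synthetic
    placement on chromosome A03 inside the region that remains linked to
    the target through backcrossing.
    """

    chrom: str = "A03"
    pos: int = 14_000_000
    cds_offset: int = 1277
    aa_change: str = "G194R"
    dominant_allele: str = "G"
    recessive_allele: str = "C"

    def genotype_from_dosage(self, donor_dosage: int) -> str:
        return {0: "MM", 1: "Mm", 2: "mm"}[donor_dosage]


@dataclass(frozen=True)
class Individual:
    """A phased diplotype: per chromosome, two donor-segment interval lists."""

    id: str
    generation: str
    diplotype: dict[str, tuple[Haplotype, Haplotype]]

    def dosage_at(self, chrom: str, cm: float) -> int:
        """Donor allele count (0, 1 or 2) at a genetic position."""
        h0, h1 = self.diplotype[chrom]
        return int(iv.contains(h0, cm)) + int(iv.contains(h1, cm))

    def target_genotype(self, locus: TargetLocus, gmap: GenomeMap) -> str:
        cm = gmap.bp_to_cm(locus.chrom, locus.pos)
        return locus.genotype_from_dosage(self.dosage_at(locus.chrom, cm))

    def donor_fraction(self, gmap: GenomeMap) -> float:
        """Length-weighted donor-genome fraction over both haplotypes."""
        tot = 2.0 * gmap.total_gen_len
        donor = sum(
            iv.total_length(h)
            for pair in self.diplotype.values()
            for h in pair
        )
        return donor / tot

    def het_fraction(self, gmap: GenomeMap) -> float:
        """Length fraction of the genome heterozygous for parental origin."""
        het = 0.0
        for chrom, (h0, h1) in self.diplotype.items():
            shared = iv.intersect(list(h0), list(h1))
            het += iv.total_length(h0) + iv.total_length(h1) - 2 * iv.total_length(shared)
        return het / gmap.total_gen_len

    def validate(self, gmap: GenomeMap) -> None:
        for chrom, pair in self.diplotype.items():
            gl = gmap[chrom].gen_len
            for hap in pair:
                last = -1.0
                for s, e in hap:
                    if not (0.0 <= s < e <= gl + 1e-9):
                        raise ValueError(f"{self.id}/{chrom}: interval {(s, e)} out of range")
                    if s < last:
                        raise ValueError(f"{self.id}/{chrom}: intervals overlap or unsorted")
                    last = e


@dataclass
class Population:
    generation: str
    members: list[Individual]
    seed: int | None = None

    def __post_init__(self):
        for m in self.members:
            if m.generation != self.generation:
                raise ValueError("all members must share the population's generation label")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]


@dataclass(frozen=True)
class ModifierModel:
    """Genetic architecture of residual self-compatibility variation.

    The compatibility index of an individual is modelled as a baseline
    set by its target-locus genotype plus additive contributions from
    donor alleles at a handful of modifier loci, with Gaussian noise:

    ``CI = base_ci[genotype] + sum(effect * dosage / 2) + N(0, noise_sd)``

    clipped at zero.  The default architecture (see
    :func:`default_modifier_model`) makes the ``mm`` genotype necessary
    but not sufficient for self-compatibility, so selfed progenies
    segregate for CI among ``mm`` plants.
    """

    modifier_loci: tuple[tuple[str, int, float], ...]
    base_ci: dict[str, float] = field(
        default_factory=lambda: {"MM": 0.1, "Mm": 0.1, "mm": 1.0}
    )
    noise_sd: float = 0.4

    def __post_init__(self):
        if not all(np.isfinite(e) for _, _, e in self.modifier_loci):
            raise ValueError("modifier effects must be finite")
        b = self.base_ci
        if not (b["MM"] <= b["Mm"] <= b["mm"]):
            raise ValueError("base_ci must be non-decreasing in donor dosage")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_modifier_model() -> ModifierModel:
    """Four modifier loci at the midpoints of the candidate segments on
    A03, A06, A07 and A09, each adding +3 CI per homozygous donor dose."""
    loci = (
        ("A03", (16451403 + 17244940) // 2, 3.0),
        ("A06", (8101576 + 19449508) // 2, 3.0),
        ("A07", (14002870 + 14798378) // 2, 3.0),
        ("A09", (12255709 + 12997755) // 2, 3.0),
    )
    return ModifierModel(modifier_loci=loci)


# ---------------------------------------------------------------------------
# generation labels


def next_backcross_label(label: str) -> str:
    if label == "F1":
        return "BC1"
    if label.startswith("BC") and label[2:].isdigit():
        return f"BC{int(label[2:]) + 1}"
    raise ValueError(f"cannot backcross from generation {label!r}")


def selfed_label(label: str) -> str:
    return f"{label}S1"


# ---------------------------------------------------------------------------
# parents and variants


def _chrom_entropy(chrom: str) -> int:
    return sum(ord(c) for c in chrom)


def variant_context(variant: Variant, flank: int = 150, seed: int = 0) -> tuple[str, int]:
    """Deterministic random reference context around a variant.

    Returns ``(sequence, var_index)`` where the reference allele starts
    at ``var_index`` (= ``flank``).  The same ``(variant, seed)`` always
    yields the same sequence, so amplicon design is reproducible without
    storing a genome.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _chrom_entropy(variant.chrom), variant.pos])
    )
    left = "".join(rng.choice(list(BASES), size=flank))
    right = "".join(rng.choice(list(BASES), size=flank))
    return left + variant.ref_allele + right, flank


def _random_variant(chrom: str, pos: int, kind: str, rng: np.random.Generator,
                    het_fraction: float) -> Variant:
    zyg = "het" if rng.random() < het_fraction else "hom"
    if kind == "SNP":
        ref = BASES[rng.integers(4)]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]
        return Variant(chrom, pos, ref, alt, "SNP", 0, zyg)
    length = int(rng.geometric(0.35))
    anchor = BASES[rng.integers(4)]
    extra = "".join(rng.choice(list(BASES), size=length))
    if rng.random() < 0.5:  # deletion in donor
        return Variant(chrom, pos, anchor + extra, anchor, "INDEL", length, zyg)
    return Variant(chrom, pos, anchor, anchor + extra, "INDEL", length, zyg)


def make_parents(
    gmap: GenomeMap,
    snp_density: float = 50.0,
    indel_density: float = 25.0,
    het_fraction: float = 0.05,
    target: TargetLocus | None = None,
    seed: int = 0,
) -> tuple[Individual, Individual, list[Variant]]:
    """Simulate the two inbred parents and their variant set.

    Densities are per Mb.  The recurrent parent carries no donor
    segments; the donor parent is donor end-to-end.  A configurable
    fraction of variants is flagged heterozygous in the donor to
    exercise the homozygosity filter downstream.  The target-locus
    variant (always homozygous) is carried only by the donor.
    """
    if snp_density <= 0 or indel_density <= 0:
        raise ValueError("variant densities must be > 0")
    target = target or TargetLocus()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11E1E]))
    variants: list[Variant] = []
    for chrom in gmap:
        mb = chrom.phys_len / 1e6
        taken = {target.pos} if chrom.name == target.chrom else set()
        for kind, dens in (("SNP", snp_density), ("INDEL", indel_density)):
            n = int(rng.poisson(dens * mb))
            if n == 0:
                warnings.warn(
                    f"variant density {dens}/Mb left chromosome {chrom.name} "
                    f"without any {kind}s",
                    stacklevel=2,
                )
                continue
            positions = rng.integers(1, chrom.phys_len + 1, size=n)
            for pos in sorted(set(int(p) for p in positions) - taken):
                variants.append(_random_variant(chrom.name, pos, kind, rng, het_fraction))
                taken.add(pos)
    variants.append(
        Variant(
            target.chrom,
            target.pos,
            target.dominant_allele,
            target.recessive_allele,
            "SNP",
            0,
            "hom",
        )
    )
    variants.sort(key=lambda v: (v.chrom, v.pos))

    empty: Haplotype = ()
    recurrent = Individual(
        id="recurrent",
        generation="P",
        diplotype={c.name: (empty, empty) for c in gmap},
    )
    donor = Individual(
        id="donor",
        generation="P",
        diplotype={c.name: (((0.0, c.gen_len),), ((0.0, c.gen_len),)) for c in gmap},
    )
    return recurrent, donor, variants


# ---------------------------------------------------------------------------
# meiosis


def simulate_gamete(
    parent: Individual, gmap: GenomeMap, rng: np.random.Generator
) -> dict[str, Haplotype]:
    """One meiotic product per chromosome.

    Crossover count per chromosome is Poisson with mean ``gen_len/100``
    (one expected crossover per Morgan, no interference); breakpoints
    are uniform in cM; strands alternate from a random starting strand.
    """
    gamete: dict[str, Haplotype] = {}
    for chrom in gmap:
        h = parent.diplotype[chrom.name]
        gl = chrom.gen_len
        k = int(rng.poisson(gl / 100.0)) if gl > 0 else 0
        if k:
            breaks = np.sort(rng.uniform(0.0, gl, size=k))
        else:
            breaks = np.empty(0)
        strand = int(rng.integers(2))
        bounds = [0.0, *breaks.tolist(), gl]
        pieces: list[tuple[float, float]] = []
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            if lo < hi:
                pieces.extend(iv.clip(h[(strand + i) % 2], lo, hi))
        gamete[chrom.name] = tuple(iv.merge(pieces))
    return gamete


def cross(
    mother: Individual,
    father: Individual,
    n: int,
    gmap: GenomeMap,
    seed: int = 0,
    generation: str | None = None,
    id_prefix: str | None = None,
) -> Population:
    """n offspring from mother x father, each from two independent gametes."""
    if n <= 0:
        raise ValueError("population size must be >= 1")
    if generation is None:
        generation = next_backcross_label(mother.generation)
    prefix = id_prefix or generation
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC055]))
    members = []
    for i in range(n):
        g_m = simulate_gamete(mother, gmap, rng)
        g_f = simulate_gamete(father, gmap, rng)
        members.append(
            Individual(
                id=f"{prefix}-{i + 1}",
                generation=generation,
                diplotype={c: (g_m[c], g_f[c]) for c in gmap.names},
            )
        )
    return Population(generation=generation, members=members, seed=seed)


def backcross(
    mother: Individual, recurrent: Individual, n: int, gmap: GenomeMap, seed: int = 0
) -> Population:
    """Backcross to the recurrent parent; generation label increments."""
    return cross(mother, recurrent, n, gmap, seed=seed)


def self_pollinate(parent: Individual, n: int, gmap: GenomeMap, seed: int = 0) -> Population:
    """Self the parent: two independent gametes from it per child."""
    label = selfed_label(parent.generation)
    return cross(
        parent, parent, n, gmap, seed=seed, generation=label, id_prefix=f"{parent.id}S1"
    )


# ---------------------------------------------------------------------------
# genotype calling


def call_genotypes(
    pop: Population | Sequence[Individual],
    loci: Iterable[tuple[str, str, int]],
    gmap: GenomeMap,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-call matrix (rows = individuals, columns = loci).

    ``loci`` is an iterable of ``(locus_id, chrom, pos_bp)``.  Truth is
    read from the diplotype at the locus position; with probability
    ``missing_rate`` a call becomes missing, and with probability
    ``error_rate`` it flips to one of the two wrong states uniformly.
    Values are the integer call codes of :mod:`mabckit.calls`.
    """
    if not (0 <= missing_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    members = list(pop)
    loci = list(loci)
    cms = [(lid, chrom, gmap.bp_to_cm(chrom, pos)) for lid, chrom, pos in loci]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    truth = np.empty((len(members), len(loci)), dtype=np.int8)
    for i, ind in enumerate(members):
        for j, (_, chrom, cm) in enumerate(cms):
            truth[i, j] = ind.dosage_at(chrom, cm)
    calls = truth.copy()
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        offsets = rng.integers(1, 3, size=calls.shape)
        calls = np.where(flip, (calls + offsets) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, MISSING, calls).astype(np.int8)
    return pd.DataFrame(calls, index=[m.id for m in members], columns=[l[0] for l in loci])


# ---------------------------------------------------------------------------
# phenotype simulation


def simulate_ci(
    ind: Individual,
    model: ModifierModel,
    gmap: GenomeMap,
    rng: np.random.Generator,
    target: TargetLocus | None = None,
    n_flowers: int = 20,
) -> CIRecord:
    """Draw a compatibility-index record for one individual."""
    target = target or TargetLocus()
    geno = ind.target_genotype(target, gmap)
    ci = model.base_ci[geno]
    for chrom, pos, effect in model.modifier_loci:
        dosage = ind.dosage_at(chrom, gmap.bp_to_cm(chrom, pos))
        ci += effect * dosage / 2.0
    if model.noise_sd > 0:
        ci += rng.normal(0.0, model.noise_sd)
    ci = max(ci, 0.0)
    n_seeds = int(round(ci * n_flowers))
    return CIRecord(
        id=ind.id,
        n_flowers=n_flowers,
        n_seeds=n_seeds,
        ci=n_seeds / n_flowers,
        ci_class=classify_ci(n_seeds / n_flowers),
    )
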