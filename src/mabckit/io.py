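"""Readers/writers for the interchange formats (VCF, TSV matrices).

The variant set is exchanged as a minimal VCF with one sample column
carrying the donor parent's genotype (the recurrent parent is the
reference by construction).  Genotype matrices are TSV with rows =
individuals, columns = marker ids and single-character calls
(A/H/B/- for homozygous-recurrent / het / homozygous-donor / missing).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .calls import chars_to_codes, codes_to_chars
from .genome_map import GenomeMap
from .phenotype import CIRecord
from .synthetic_data import Variant


def write_vcf(
    variants: Iterable[Variant],
    gmap: GenomeMap,
    path: str | Path,
    sample: str = "donor",
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mabckit\n")
        for chrom in gmap:
            fh.write(f"##contig=<ID={chrom.name},length={chrom.phys_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gt = "1/1" if v.donor_zygosity == "hom" else "0/1"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_vcf_variants(path: str | Path) -> list[Variant]:
    """Read a two-parent variant VCF back into :class:`Variant` records."""
    from cyvcf2 import VCF

    out: list[Variant] = []
    for rec in VCF(str(path)):
        ref = rec.REF
        alt = rec.ALT[0]
        kind = "SNP" if len(ref) == len(alt) == 1 else "INDEL"
        gts = rec.genotypes[0] if rec.genotypes else [1, 1, True]
        zyg = "hom" if gts[0] == gts[1] else "het"
        out.append(
            Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=ref,
                alt_allele=alt,
                kind=kind,
                indel_len=abs(len(ref) - len(alt)),
                donor_zygosity=zyg,
            )
        )
    return out


def write_genotype_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    chars = pd.DataFrame(
        codes_to_chars(calls.to_numpy()), index=calls.index, columns=calls.columns
    )
    chars.to_csv(path, sep="\t", index_label="id")


def read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    chars = pd.read_csv(path, sep="\t", index_col="id", dtype=str)
    return pd.DataFrame(
        chars_to_codes(chars.to_numpy()).astype("int8"),
        index=chars.index,
        columns=chars.columns,
    )


def write_pollination_tsv(records: Iterable[CIRecord], path: str | Path) -> None:
    """Raw pollination records (id, flowers, seeds) for re-analysis."""
    pd.DataFrame(
        [{"id": r.id, "flowers": r.n_flowers, "seeds": r.n_seeds} for r in records]
    ).to_csv(path, sep="\t", index=False)
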