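"""End-to-end marker-assisted backcrossing experiment.

Orchestrates the whole scheme: simulate the two parents and their
variants; design the background HRM panel and the allele-specific
target marker; cross to F1 and backcross three times with target-allele
(carrier) selection and marker-based background selection at each step;
self the best BC3 plants into BC3S1 families; select homozygous-target
(mm) plants; then score genome recovery (marker-based and dense),
delineate introgression segments, locate the linkage-drag segment,
intersect donor segments across self-compatible vs self-incompatible
plants, and classify compatibility-index phenotypes.

All randomness derives from one master seed; stage outputs are written
to a run directory, and a machine-readable JSON summary records the
per-generation population sizes, segregation tests and the maximum
marker-based genome recovery (PRm) trajectory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .calls import MISSING
from .genome_map import GenomeMap, brassica_rapa_map
from .marker_design import (
    DEFAULT_PANEL_COUNTS,
    MarkerPanel,
    design_hrm_candidates,
    design_target_marker,
    density_report,
    select_even_panel,
)
from .phenotype import write_ci_tsv
from .segment_analysis import (
    delineate_segments,
    drag_report,
    segment_length_mb,
    shared_segments,
    write_segments_bed,
    write_segments_tsv,
)
from .selection import (
    background_reports,
    graphical_genotypes,
    segregation_test,
    select_by_target,
    two_step_mas,
)
from .synthetic_data import (
    Individual,
    ModifierModel,
    Population,
    TargetLocus,
    backcross,
    call_genotypes,
    cross,
    default_modifier_model,
    make_parents,
    self_pollinate,
    simulate_ci,
    variant_context,
)


@dataclass
class PipelineConfig:
    """Declarative settings for one experiment run.

    Population sizes default to the study design: 12 BC1, 1120 BC2,
    768 BC3 plants, three BC3 founders selfed into BC3S1 families with
    ten homozygous-target plants selected per family.
    """

    seed: int = 0
    n_bc1: int = 12
    n_bc2: int = 1120
    n_bc3: int = 768
    n_families: int = 3
    n_self_per_family: int = 60
    n_mm_per_family: int = 10
    keep_step1: int = 96
    snp_density: float = 50.0
    indel_density: float = 25.0
    het_fraction: float = 0.05
    per_chrom_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_COUNTS)
    )
    marker_missing_rate: float = 0.0
    marker_error_rate: float = 0.0
    dense_missing_rate: float = 0.02
    dense_error_rate: float = 0.005
    min_support: int = 3
    n_flowers: int = 20
    select_background: bool = True
    select_target: bool = True
    render_png: bool = True
    modifier: ModifierModel = field(default_factory=default_modifier_model)
    target: TargetLocus = field(default_factory=TargetLocus)

    def __post_init__(self):
        for name in ("n_bc1", "n_bc2", "n_bc3", "n_families",
                     "n_self_per_family", "n_mm_per_family", "keep_step1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _rank_by_pr(calls: pd.DataFrame, ids: list[str]) -> list[str]:
    reports = background_reports(calls.loc[ids])
    return sorted(ids, key=lambda i: (-reports.loc[i, "pr"], str(i)))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full experiment; returns (and writes) the JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    gmap = brassica_rapa_map()
    summary: dict[str, Any] = {"seed": cfg.seed, "generations": {}}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    # --- parents and variants -------------------------------------------
    with stage("parents"):
        recurrent, donor, variants = make_parents(
            gmap,
            snp_density=cfg.snp_density,
            indel_density=cfg.indel_density,
            het_fraction=cfg.het_fraction,
            target=cfg.target,
            seed=_sub_seed(cfg.seed, 1),
        )
        mio.write_vcf(variants, gmap, out / "variants.vcf")
        gmap.to_tsv(out / "genome_map.tsv")

    # --- marker design ---------------------------------------------------
    with stage("marker_design"):
        candidates = design_hrm_candidates(
            variants, gmap, seed=_sub_seed(cfg.seed, 2)
        )
        panel = select_even_panel(candidates, gmap, cfg.per_chrom_counts)
        panel.to_tsv(out / "marker_panel.tsv")
        dens = density_report(panel, gmap)
        dens.to_csv(out / "marker_density.tsv", sep="\t", index=False)
        tvar = next(
            v for v in variants
            if v.chrom == cfg.target.chrom and v.pos == cfg.target.pos
        )
        ctx, vi = variant_context(tvar, seed=_sub_seed(cfg.seed, 1))
        kasp = design_target_marker(cfg.target, ctx, vi)
        summary["panel"] = {
            "n_markers": len(panel),
            "n_candidates": len(candidates),
            "target_marker": kasp.id,
            "genome_avg_density_mb": float(
                dens.loc[dens["chrom"] == "genome", "avg_density_mb"].iloc[0]
            ),
            "genome_avg_density_cm": float(
                dens.loc[dens["chrom"] == "genome", "avg_density_cm"].iloc[0]
            ),
        }

    marker_loci = panel.loci

    def genotype(pop, k):
        return call_genotypes(
            pop, marker_loci, gmap,
            missing_rate=cfg.marker_missing_rate,
            error_rate=cfg.marker_error_rate,
            seed=_sub_seed(cfg.seed, k),
        )

    max_prm: dict[str, float] = {}

    # --- F1 and backcross generations ------------------------------------
    with stage("crossing"):
        f1 = cross(
            donor, recurrent, 1, gmap,
            seed=_sub_seed(cfg.seed, 3), generation="F1",
        )
        mother = f1.members[0]
        mothers_by_gen = {"F1": mother}
        bc_pops: dict[str, Population] = {}
        for g, n in (("BC1", cfg.n_bc1), ("BC2", cfg.n_bc2), ("BC3", cfg.n_bc3)):
            pop = backcross(mother, recurrent, n, gmap, seed=_sub_seed(cfg.seed, 10 + len(bc_pops)))
            bc_pops[g] = pop
            carriers = (
                select_by_target(pop, cfg.target, gmap, "Mm")
                if cfg.select_target
                else list(pop)
            )
            n_mm_like = len(select_by_target(pop, cfg.target, gmap, "Mm"))
            chi2, p = segregation_test(n_mm_like, len(pop) - n_mm_like)
            calls = genotype(pop, 20 + len(bc_pops))
            mio.write_genotype_tsv(calls, out / f"genotypes_{g}.tsv")
            reports = background_reports(calls)
            reports.to_csv(out / f"background_{g}.tsv", sep="\t")
            if not carriers:
                raise RuntimeError(f"no target carriers in {g}")
            carrier_ids = [c.id for c in carriers]
            if cfg.select_background:
                if g == "BC2":
                    step1 = [
                        next(m.id for m in panel.markers if m.chrom == c)
                        for c in ("A01", "A02", "A09")
                    ]
                    ranked = two_step_mas(
                        calls.loc[carrier_ids], step1, keep_step1=cfg.keep_step1
                    ).index.tolist()
                else:
                    ranked = _rank_by_pr(calls, carrier_ids)
            else:
                ranked = carrier_ids
            by_id = {m.id: m for m in pop}
            mother = by_id[ranked[0]]
            mothers_by_gen[g] = mother
            max_prm[g] = float(reports.loc[carrier_ids, "pr"].max())
            summary["generations"][g] = {
                "n": len(pop),
                "n_carriers": n_mm_like,
                "segregation_chi2": round(chi2, 4),
                "segregation_p": round(p, 6),
                "max_prm_carriers": round(max_prm[g], 2),
                "mean_donor_fraction": round(
                    float(np.mean([m.donor_fraction(gmap) for m in pop])), 5
                ),
                "selected": ranked[0],
            }

    # --- BC3 families -> BC3S1 -------------------------------------------
    with stage("selfing"):
        bc3 = bc_pops["BC3"]
        bc3_calls = mio.read_genotype_tsv(out / "genotypes_BC3.tsv")
        carriers = (
            select_by_target(bc3, cfg.target, gmap, "Mm")
            if cfg.select_target
            else list(bc3)
        )
        founders_ids = (
            _rank_by_pr(bc3_calls, [c.id for c in carriers])
            if cfg.select_background
            else [c.id for c in carriers]
        )[: cfg.n_families]
        by_id = {m.id: m for m in bc3}
        founders = [by_id[i] for i in founders_ids]
        selected: list[Individual] = []
        fam_sizes = {}
        for k, founder in enumerate(founders):
            fam = self_pollinate(
                founder, cfg.n_self_per_family, gmap, seed=_sub_seed(cfg.seed, 30 + k)
            )
            mm = (
                select_by_target(fam, cfg.target, gmap, "mm")
                if cfg.select_target
                else list(fam)
            )
            fam_calls = genotype(fam, 40 + k)
            ranked = (
                _rank_by_pr(fam_calls, [m.id for m in mm])
                if cfg.select_background and mm
                else [m.id for m in mm]
            )
            keep = ranked[: cfg.n_mm_per_family]
            fam_by_id = {m.id: m for m in fam}
            selected.extend(fam_by_id[i] for i in keep)
            fam_sizes[founder.id] = {"n_selfed": len(fam), "n_mm": len(mm),
                                     "n_selected": len(keep)}
        if not selected:
            raise RuntimeError("no homozygous-target plants recovered in BC3S1")
        s1_calls = genotype(selected, 50)
        mio.write_genotype_tsv(s1_calls, out / "genotypes_BC3S1.tsv")
        s1_reports = background_reports(s1_calls)
        s1_reports.to_csv(out / "background_BC3S1.tsv", sep="\t")
        graphical_genotypes(
            s1_calls, panel,
            png_path=(out / "graphical_genotypes.png") if cfg.render_png else None,
            tsv_path=out / "graphical_genotypes.tsv",
        )
        max_prm["BC3S1"] = float(s1_reports["pr"].max())
        summary["generations"]["BC3S1"] = {
            "n": len(selected),
            "families": fam_sizes,
            "max_prm_carriers": round(max_prm["BC3S1"], 2),
            "prm_range": [
                round(float(s1_reports["pr"].min()), 2),
                round(float(s1_reports["pr"].max()), 2),
            ],
        }

    # --- phenotype --------------------------------------------------------
    with stage("phenotype"):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 60]))
        ci_records = [
            simulate_ci(ind, cfg.modifier, gmap, rng, target=cfg.target,
                        n_flowers=cfg.n_flowers)
            for ind in selected
        ]
        write_ci_tsv(ci_records, out / "ci_records.tsv")
        mio.write_pollination_tsv(ci_records, out / "pollination.tsv")
        from .phenotype import ci_summary

        summary["ci_classes"] = ci_summary(ci_records)

    # --- dense genotyping and segment analysis ----------------------------
    with stage("segments"):
        # one representative (top PRm mm plant) per family, like the
        # resequenced individuals of the study
        per_family_best: list[Individual] = []
        for founder in founders:
            fam_members = [s for s in selected if s.id.startswith(founder.id)]
            if fam_members:
                ranked = _rank_by_pr(s1_calls, [m.id for m in fam_members])
                per_family_best.append(
                    next(m for m in fam_members if m.id == ranked[0])
                )
        dense_loci = [
            (f"{v.chrom}:{v.pos}", v.chrom, v.pos)
            for v in variants
            if v.donor_zygosity == "hom"
        ]
        dense_calls = call_genotypes(
            per_family_best, dense_loci, gmap,
            missing_rate=cfg.dense_missing_rate,
            error_rate=cfg.dense_error_rate,
            seed=_sub_seed(cfg.seed, 70),
        )
        dense_reports = background_reports(dense_calls, source="dense")
        dense_reports.to_csv(out / "background_dense.tsv", sep="\t")
        by_locus = pd.DataFrame(
            [(lid, chrom, pos) for lid, chrom, pos in dense_loci],
            columns=["id", "chrom", "pos"],
        ).set_index("id")
        seg_by_ind = {}
        for ind in per_family_best:
            segs = []
            row = dense_calls.loc[ind.id]
            for chrom in gmap:
                ids = by_locus.index[by_locus["chrom"] == chrom.name]
                pos = by_locus.loc[ids, "pos"].to_numpy()
                states = row.loc[ids].to_numpy()
                segs.extend(
                    delineate_segments(pos, states, chrom.name, chrom.phys_len,
                                       min_support=cfg.min_support)
                )
            seg_by_ind[ind.id] = segs
            write_segments_tsv(segs, out / f"segments_{ind.id}.tsv")
            write_segments_bed(segs, out / f"segments_{ind.id}.bed")
        drag = {}
        for ind in per_family_best:
            rep = drag_report(seg_by_ind[ind.id], cfg.target,
                              ind.target_genotype(cfg.target, gmap))
            drag[ind.id] = {
                "chrom": rep.segment.chrom,
                "start": rep.segment.start,
                "end": rep.segment.end,
                "state": rep.segment.state,
                "length_mb": rep.length_mb,
            }
        summary["drag_segments"] = drag
        ci_by_id = {r.id: r for r in ci_records}
        sc_ids = [i.id for i in per_family_best if ci_by_id[i.id].ci_class == "SC"]
        non_sc_ids = [i.id for i in per_family_best if ci_by_id[i.id].ci_class != "SC"]
        shared = shared_segments(
            [seg_by_ind[i] for i in sc_ids],
            [seg_by_ind[i] for i in non_sc_ids],
        )
        summary["shared_segments"] = {
            chrom: [[int(s), int(e)] for s, e in ivs] for chrom, ivs in shared.items()
        }
        summary["representatives"] = {
            ind.id: {
                "prm": round(float(s1_reports.loc[ind.id, "pr"]), 2),
                "hgbm": round(float(s1_reports.loc[ind.id, "hgb"]), 2),
                "prs": round(float(dense_reports.loc[ind.id, "pr"]), 2),
                "hgbs": round(float(dense_reports.loc[ind.id, "hgb"]), 2),
                "ci": ci_by_id[ind.id].ci,
                "ci_class": ci_by_id[ind.id].ci_class,
                "target_genotype": ind.target_genotype(cfg.target, gmap),
            }
            for ind in per_family_best
        }

    summary["max_prm_by_generation"] = [
        round(max_prm[g], 2) for g in ("BC1", "BC2", "BC3", "BC3S1")
    ]
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# input validation


@dataclass
class ValidationReport:
    errors: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, path: str, line: int, message: str) -> None:
        self.errors.append((path, line, message))

    def __str__(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(f"{p}:{ln}: {msg}" for p, ln, msg in self.errors)


def validate_inputs(
    map_path: str | Path | None = None,
    vcf_path: str | Path | None = None,
    genotype_path: str | Path | None = None,
    phenotype_path: str | Path | None = None,
) -> ValidationReport:
    """Schema checks on the interchange files.

    Reports unknown chromosomes, unsorted positions, bad call characters
    and malformed tables with (file, line/record number, message).
    """
    report = ValidationReport()
    gmap: GenomeMap | None = None
    if map_path is not None:
        try:
            gmap = GenomeMap.from_tsv(map_path)
        except Exception as exc:
            report.add(str(map_path), 0, f"invalid genome map: {exc}")
    if vcf_path is not None:
        try:
            variants = mio.read_vcf_variants(vcf_path)
        except Exception as exc:
            report.add(str(vcf_path), 0, f"unreadable VCF: {exc}")
        else:
            last: dict[str, int] = {}
            for i, v in enumerate(variants, start=1):
                if gmap is not None:
                    if v.chrom not in gmap:
                        report.add(str(vcf_path), i, f"unknown contig {v.chrom!r}")
                        continue
                    if not (1 <= v.pos <= gmap[v.chrom].phys_len):
                        report.add(str(vcf_path), i, f"position {v.pos} out of range")
                if v.chrom in last and v.pos < last[v.chrom]:
                    report.add(str(vcf_path), i,
                               f"unsorted position {v.pos} on {v.chrom}")
                last[v.chrom] = v.pos
    if genotype_path is not None:
        try:
            raw = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:
            report.add(str(genotype_path), 0, f"unreadable genotype matrix: {exc}")
        else:
            valid = {"A", "H", "B", "-"}
            for r, (ind, row) in enumerate(raw.iterrows(), start=2):
                bad = set(row.dropna()) - valid
                if bad:
                    report.add(str(genotype_path), r,
                               f"invalid call characters {sorted(bad)} for {ind}")
    if phenotype_path is not None:
        try:
            df = pd.read_csv(phenotype_path, sep="\t")
            missing = {"id", "flowers", "seeds"} - set(df.columns)
            if missing:
                report.add(str(phenotype_path), 1,
                           f"missing columns {sorted(missing)}")
            else:
                for r, row in enumerate(df.itertuples(index=False), start=2):
                    if int(row.flowers) <= 0:
                        report.add(str(phenotype_path), r, "flowers must be > 0")
        except Exception as exc:
            report.add(str(phenotype_path), 0, f"unreadable phenotype table: {exc}")
    return report
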