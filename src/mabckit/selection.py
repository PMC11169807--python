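"""Background selection: genome recovery, two-step MAS, segregation tests.

Recovery of the recurrent-parent genome is scored from genotype calls:

* **PR** (proportion of recurrent-parent genome):
  ``PR = (2 n_rec + n_het) / (2 (n_rec + n_het + n_don)) * 100``
* **HGB** (homozygosity of the genetic background):
  ``HGB = (n_rec + n_don) / (n_rec + n_het + n_don) * 100``

Missing calls are excluded from numerator and denominator.  When
computed from marker calls the quantities are conventionally written
PRm/HGBm; from dense resequencing-like calls, PRs/HGBs — the ``source``
field of a report records which.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calls import HET, HOM_DON, HOM_REC, MISSING, codes_to_chars
from .genome_map import GenomeMap
from .marker_design import MarkerPanel
from .synthetic_data import Individual, Population, TargetLocus


def _counts(calls) -> tuple[int, int, int, int]:
    a = np.asarray(calls)
    return (
        int((a == HOM_REC).sum()),
        int((a == HET).sum()),
        int((a == HOM_DON).sum()),
        int((a == MISSING).sum()),
    )


def compute_pr(calls) -> float:
    """Percent recurrent-parent alleles among non-missing calls."""
    n_rec, n_het, n_don, _ = _counts(calls)
    total = n_rec + n_het + n_don
    if total == 0:
        raise ValueError("all calls missing; PR undefined")
    return 100.0 * (2 * n_rec + n_het) / (2 * total)


def compute_hgb(calls) -> float:
    """Percent homozygous (either parent) among non-missing calls."""
    n_rec, n_het, n_don, _ = _counts(calls)
    total = n_rec + n_het + n_don
    if total == 0:
        raise ValueError("all calls missing; HGB undefined")
    return 100.0 * (n_rec + n_don) / total


@dataclass(frozen=True)
class BackgroundReport:
    id: str
    n_rec: int
    n_het: int
    n_don: int
    n_missing: int
    pr: float
    hgb: float
    source: str  # "marker" -> PRm/HGBm, "dense" -> PRs/HGBs

    @classmethod
    def from_calls(cls, id: str, calls, source: str = "marker") -> "BackgroundReport":
        n_rec, n_het, n_don, n_missing = _counts(calls)
        return cls(
            id=id,
            n_rec=n_rec,
            n_het=n_het,
            n_don=n_don,
            n_missing=n_missing,
            pr=compute_pr(calls),
            hgb=compute_hgb(calls),
            source=source,
        )


def background_reports(calls: pd.DataFrame, source: str = "marker") -> pd.DataFrame:
    """Per-individual PR/HGB table from a call matrix (rows = individuals)."""
    rows = []
    for ind_id, row in calls.iterrows():
        rep = BackgroundReport.from_calls(str(ind_id), row.to_numpy(), source)
        rows.append(
            {
                "id": rep.id,
                "n_rec": rep.n_rec,
                "n_het": rep.n_het,
                "n_don": rep.n_don,
                "n_missing": rep.n_missing,
                "pr": rep.pr,
                "hgb": rep.hgb,
                "source": rep.source,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def two_step_mas(
    calls: pd.DataFrame,
    step1_markers: Sequence[str],
    step2_markers: Sequence[str] | None = None,
    keep_step1: int = 96,
    keep_final: int | None = None,
) -> pd.DataFrame:
    """Two-round background selection on a call matrix.

    Round 1 ranks all individuals by PR over ``step1_markers`` (a small
    screening set, typically three markers on separate chromosomes) and
    keeps the top ``keep_step1``; round 2 re-ranks the survivors by PR
    over all markers (step1 + step2).  Ties break by individual id for
    determinism.  Returns the final ranking with ``pr_step1`` and
    ``pr_full`` columns, truncated to ``keep_final`` if given.
    """
    step1 = list(step1_markers)
    step2 = list(step2_markers) if step2_markers is not None else [
        c for c in calls.columns if c not in step1
    ]
    if set(step1) & set(step2):
        raise ValueError("step marker sets must be disjoint")
    for mk in step1 + step2:
        if mk not in calls.columns:
            raise KeyError(f"marker {mk!r} absent from call matrix")
    if keep_step1 <= 0:
        raise ValueError("keep_step1 must be >= 1")

    pr1 = calls[step1].apply(lambda r: compute_pr(r.to_numpy()), axis=1)
    order1 = sorted(calls.index, key=lambda i: (-pr1[i], str(i)))
    survivors = order1[: min(keep_step1, len(order1))]

    full = calls.loc[survivors, step1 + step2]
    pr_full = full.apply(lambda r: compute_pr(r.to_numpy()), axis=1)
    order2 = sorted(survivors, key=lambda i: (-pr_full[i], str(i)))
    out = pd.DataFrame(
        {"pr_step1": pr1.loc[order2], "pr_full": pr_full.loc[order2]},
        index=pd.Index(order2, name="id"),
    )
    if keep_final is not None:
        out = out.iloc[:keep_final]
    return out


def select_by_target(
    pop: Population | Iterable[Individual],
    locus: TargetLocus,
    gmap: GenomeMap,
    required: str,
) -> list[Individual]:
    """Individuals whose target-locus genotype equals ``required``
    (``"MM"``, ``"Mm"`` or ``"mm"``); order preserved."""
    if required not in ("MM", "Mm", "mm"):
        raise ValueError("required genotype must be MM, Mm or mm")
    return [m for m in pop if m.target_genotype(locus, gmap) == required]


def segregation_test(
    n_class1: int, n_class2: int, ratio: tuple[int, int] = (1, 1)
) -> tuple[float, float]:
    """1-df chi-square goodness of fit to an expected segregation ratio
    (no continuity correction).  Returns ``(chi2, p)``."""
    if n_class1 < 0 or n_class2 < 0:
        raise ValueError("counts must be non-negative")
    total = n_class1 + n_class2
    if total == 0:
        raise ValueError("total count must be > 0")
    r1, r2 = ratio
    expected = [total * r1 / (r1 + r2), total * r2 / (r1 + r2)]
    chi2, p = stats.chisquare([n_class1, n_class2], expected)
    return float(chi2), float(p)


def graphical_genotypes(
    calls: pd.DataFrame,
    panel: MarkerPanel,
    png_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Chromosome-painted genotype matrix ordered by marker position.

    Columns are reordered to the panel's physical order; the rendering
    colours cells light blue (homozygous recurrent), navy (heterozygous),
    red (homozygous donor) and white (missing), one row per individual.
    The text matrix uses the A/H/B/- character code.
    """
    order = [m.id for m in panel.markers if m.id in calls.columns]
    mat = calls[order]
    if tsv_path is not None:
        chars = pd.DataFrame(codes_to_chars(mat.to_numpy()), index=mat.index, columns=order)
        chars.to_csv(tsv_path, sep="\t", index_label="id")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        cmap = ListedColormap(["white", "#9ecae1", "#08306b", "#cb181d"])
        norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5, 2.5], cmap.N)
        fig, ax = plt.subplots(
            figsize=(max(6, len(order) * 0.12), max(2, len(mat) * 0.25))
        )
        ax.imshow(mat.to_numpy(), aspect="auto", cmap=cmap, norm=norm,
                  interpolation="nearest")
        ax.set_yticks(range(len(mat)))
        ax.set_yticklabels(mat.index, fontsize=6)
        ax.set_xticks([])
        ax.set_xlabel("markers (physical order)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return mat


def read_graphical_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a text genotype matrix written by :func:`graphical_genotypes`."""
    from .calls import chars_to_codes

    chars = pd.read_csv(path, sep="\t", index_col="id", dtype=str)
    return pd.DataFrame(
        chars_to_codes(chars.to_numpy()), index=chars.index, columns=chars.columns
    )
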