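"""TSS-to-gene assignment, 5'-UTR statistics, and promoter catalogs.

A TSS is assigned to the nearest same-strand downstream start codon within
a maximum leader length (650 bp); leaders of <=5 nt define leaderless
transcripts.  TSSs assigned from within an upstream gene keep the
``intragenic_upstream_gene`` location flag.  Unassigned TSSs are
categorized as intragenic (inside a same-strand gene), antisense (inside
an opposite-strand gene) or intergenic.  The module also flags regulated
promoters (>=10-fold activity change between conditions, with the high
condition above the chromosomal mean promoter activity) and selects
constant-promoter candidates from a differential-expression table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneRecord, SiteCall

MAX_LEADER = 650
LEADERLESS_MAX = 5


@dataclass(frozen=True)
class TssGenePair:
    """A TSS assigned to a downstream gene."""

    tss_id: str
    gene_id: str
    replicon_id: str
    position: int
    strand: str
    utr_length: int
    leaderless: bool
    tss_location: str  # intergenic | intragenic_upstream_gene
    conditions_detected: frozenset = frozenset()


@dataclass(frozen=True)
class UnassignedTss:
    tss_id: str
    replicon_id: str
    position: int
    strand: str
    category: str  # intragenic | antisense | intergenic


def _tss_id(site: SiteCall) -> str:
    return f"TSS_{site.replicon_id}_{site.position}_{site.strand}"


def assign_tss_to_genes(
    tss_catalog: list,
    genes: list,
    max_leader: int = MAX_LEADER,
    leaderless_max: int = LEADERLESS_MAX,
) -> tuple:
    """Assign each TSS to the nearest same-strand downstream start codon.

    Distance is ``start_codon_pos - position`` on +, ``position -
    start_codon_pos`` on -; 0 (TSS at the start codon) is allowed.
    Assignment within ``max_leader`` wins over intragenic/antisense
    categorization.  Returns ``(pairs, unassigned)``.
    """
    pairs, unassigned = [], []
    by_replicon: dict[str, list] = {}
    for g in genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for site in tss_catalog:
        reps = by_replicon.get(site.replicon_id, [])
        same = [g for g in reps if g.strand == site.strand]
        best: GeneRecord | None = None
        best_d = None
        for g in same:
            if g.feature_class != "protein_coding":
                continue
            d = (
                g.start_codon_pos - site.position
                if site.strand == "+"
                else site.position - g.start_codon_pos
            )
            if d < 0 or d > max_leader:
                continue
            if (
                best is None
                or d < best_d
                or (d == best_d and (g.length, g.gene_id) > (best.length, best.gene_id))
            ):
                # genes sharing a start coordinate: longest wins, then gene_id
                best, best_d = g, d
        inside_same = any(g.contains(site.position) for g in same)
        if best is not None:
            pairs.append(
                TssGenePair(
                    tss_id=_tss_id(site),
                    gene_id=best.gene_id,
                    replicon_id=site.replicon_id,
                    position=site.position,
                    strand=site.strand,
                    utr_length=best_d,
                    leaderless=best_d <= leaderless_max,
                    tss_location=(
                        "intragenic_upstream_gene"
                        if any(
                            g.contains(site.position) and g.gene_id != best.gene_id
                            for g in same
                        )
                        else "intergenic"
                    ),
                    conditions_detected=site.conditions_detected,
                )
            )
            continue
        if inside_same:
            category = "intragenic"
        elif any(
            g.contains(site.position) for g in reps if g.strand != site.strand
        ):
            category = "antisense"
        else:
            category = "intergenic"
        unassigned.append(
            UnassignedTss(
                tss_id=_tss_id(site),
                replicon_id=site.replicon_id,
                position=site.position,
                strand=site.strand,
                category=category,
            )
        )
    return pairs, unassigned


def compute_utr_stats(pairs: list) -> dict:
    """Median/mean 5'-UTR length, the >100 / <=100 nt split, and the
    leaderless count."""
    if not pairs:
        raise ValueError("no TSS-gene pairs")
    utrs = np.array([p.utr_length for p in pairs])
    return {
        "n_pairs": len(pairs),
        "median_utr": float(np.median(utrs)),
        "mean_utr": float(np.mean(utrs)),
        "n_leaderless": int(sum(p.leaderless for p in pairs)),
        "n_utr_gt_100": int(np.sum(utrs > 100)),
        "n_utr_le_100": int(np.sum(utrs <= 100)),
    }


def find_regulated_promoters(
    activities: pd.DataFrame,
    chrom_mean: pd.Series | None = None,
    fold: float = 10.0,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Flag regulated promoters.

    ``activities`` is promoters x conditions (size-factor-normalized
    replicate-mean treated counts).  A promoter is regulated when some
    condition c1 has activity above the chromosomal mean promoter activity
    for c1 *and* at least ``fold`` times its activity under some other
    condition c2 (zeros replaced by ``pseudocount``).  ``chrom_mean``
    defaults to the per-condition mean over the supplied promoters.
    """
    if activities.shape[1] < 2:
        raise ValueError("need >=2 conditions")
    if chrom_mean is None:
        chrom_mean = activities.mean(axis=0)
    act = activities.to_numpy(dtype=float)
    act_pc = np.where(act > 0, act, pseudocount)
    flags = []
    means = chrom_mean.reindex(activities.columns).to_numpy(dtype=float)
    for row, row_pc in zip(act, act_pc):
        regulated = False
        for i in range(row.size):
            if row[i] <= means[i]:
                continue
            if np.any(row_pc[i] >= fold * np.delete(row_pc, i)):
                regulated = True
                break
        flags.append(regulated)
    return pd.Series(flags, index=activities.index, name="regulated")


def select_constant_promoters(
    pairs: list,
    de_table: pd.DataFrame,
    growth_conditions: list,
    lfc_bound: float = 0.45,
    padj_min: float = 0.05,
) -> list:
    """Automated constant-promoter candidate selection.

    ``de_table`` is a long table with columns gene_id, comparison, log2FC,
    padj covering three pairwise comparisons between the growth-phase
    conditions.  A gene qualifies when every comparison satisfies
    ``-lfc_bound < log2FC < lfc_bound`` and ``padj > padj_min`` (both
    bounds exclusive).  Candidates are the qualifying genes' TSS-gene
    pairs whose TSS is intergenic-located or leaderless and was detected
    under all supplied growth-phase conditions.
    """
    for col in ("gene_id", "comparison", "log2FC", "padj"):
        if col not in de_table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    n_comparisons = de_table["comparison"].nunique()
    ok = de_table.assign(
        _pass=(de_table["log2FC"].gt(-lfc_bound))
        & (de_table["log2FC"].lt(lfc_bound))
        & (de_table["padj"].gt(padj_min))
    )
    per_gene = ok.groupby("gene_id")["_pass"].agg(["sum", "count"])
    constant_genes = set(
        per_gene.index[(per_gene["sum"] == n_comparisons) & (per_gene["count"] == n_comparisons)]
    )
    required = set(growth_conditions)
    candidates = []
    for p in pairs:
        if p.gene_id not in constant_genes:
            continue
        if not (p.tss_location == "intergenic" or p.leaderless):
            continue
        if not required <= set(p.conditions_detected):
            continue
        candidates.append(p)
    return candidates


def predominance_filter(
    candidates: list,
    activities: dict,
    max_utr: int = 200,
    min_share: float = 0.5,
) -> list:
    """Automated stand-in for the manual curation step: keep candidates
    whose leader is <= ``max_utr`` nt and whose TSS contributes at least
    ``min_share`` of the summed activity of its gene's TSSs.

    ``activities`` maps tss_id -> scalar activity.  This approximates a
    by-eye "single or predominant TSS" judgement and is labelled as such.
    """
    by_gene: dict[str, float] = {}
    for p in candidates:
        by_gene[p.gene_id] = by_gene.get(p.gene_id, 0.0) + activities.get(p.tss_id, 0.0)
    kept = []
    for p in candidates:
        if p.utr_length > max_utr:
            continue
        total = by_gene[p.gene_id]
        share = activities.get(p.tss_id, 0.0) / total if total > 0 else 0.0
        if share >= min_share:
            kept.append(p)
    return kept


def pairs_to_frame(pairs: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                tss_id=p.tss_id, gene_id=p.gene_id, replicon_id=p.replicon_id,
                position=p.position, strand=p.strand, utr_length=p.utr_length,
                leaderless=p.leaderless, tss_location=p.tss_location,
                conditions_detected=",".join(sorted(p.conditions_detected)),
            )
            for p in pairs
        ]
    )
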