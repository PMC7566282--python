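"""Classify preliminary 3' termini into RNA processing sites vs TTSs.

An endonucleolytic cleavage leaves a 3'-hydroxyl (seen by term-seq) at
position p and a 5'-monophosphate (seen by RppH-untreated TSS-seq) at the
immediately downstream position.  Preliminary 3' termini paired with such
a 5'P site — or overlapping a tRNA — are processing sites; termini with a
5'P at their own position or immediately upstream violate the expected
cleavage geometry and are removed; the rest are TTSs.  Processing sites
are pooled across conditions and purged from every condition's TTS list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import SiteCall, downstream, upstream
from .tts_calling import DynamicLambdaSpec, call_termini_for_condition


@dataclass
class TerminiClassification:
    """Partition of one condition's preliminary 3' termini."""

    condition_id: str
    processing: list = field(default_factory=list)
    tts: list = field(default_factory=list)
    removed: list = field(default_factory=list)  # (SiteCall, reason)

    REASONS = ("upstream_5p_conflict", "pooled_processing", "trna_overlap")

    def all_sites(self) -> list:
        return self.processing + self.tts + [s for s, _ in self.removed]


def call_monophosphate_sites(
    untreated_tracks: list,
    tss_catalog: list,
    spec: DynamicLambdaSpec = DynamicLambdaSpec(),
    percentile: float = 95.0,
    fdr_threshold: float = 0.05,
    min_replicates: int = 2,
    condition_id: str | None = None,
    remove_secondary: bool = True,
) -> list:
    """5'-monophosphoryl sites from RppH-untreated 5'-end coverage.

    The preliminary-3'-terminus machinery (per-sample Poisson screen with
    dynamic lambda, BH, >=2-replicate consensus) is applied to the
    untreated tracks, then every called TSS position (primary and, by
    default, secondary) is removed from the result.
    """
    sites = call_termini_for_condition(
        untreated_tracks,
        spec=spec,
        percentile=percentile,
        fdr_threshold=fdr_threshold,
        min_replicates=min_replicates,
        site_kind="monophosphate_5p",
        condition_id=condition_id,
    )
    tss_keys = {
        s.key
        for s in tss_catalog
        if s.site_kind == "tss_primary"
        or (remove_secondary and s.site_kind == "tss_secondary")
    }
    return [s for s in sites if s.key not in tss_keys]


def classify_termini(
    prelim_3p: list,
    mono_5p: list,
    genes: list,
    condition_id: str = "",
    pair_offset: int = 1,
) -> TerminiClassification:
    """Partition preliminary 3' termini for one condition.

    Precedence per terminus at (p, s): a 5'P site `pair_offset` nt
    downstream (same strand) -> processing; overlap with a same-strand
    tRNA -> processing; a 5'P at p itself or `pair_offset` nt upstream ->
    removed (ambiguous cleavage geometry); otherwise -> TTS.
    """
    mono_keys = {s.key for s in mono_5p}
    trnas = [g for g in genes if g.feature_class == "tRNA"]
    result = TerminiClassification(condition_id=condition_id)
    for site in prelim_3p:
        down_key = (site.replicon_id, downstream(site.position, site.strand, pair_offset), site.strand)
        up_key = (site.replicon_id, upstream(site.position, site.strand, pair_offset), site.strand)
        if down_key in mono_keys:
            result.processing.append(site.with_kind("processing"))
        elif any(
            t.replicon_id == site.replicon_id
            and t.strand == site.strand
            and t.contains(site.position)
            for t in trnas
        ):
            result.processing.append(site.with_kind("processing"))
        elif site.key in mono_keys or up_key in mono_keys:
            result.removed.append((site, "upstream_5p_conflict"))
        else:
            result.tts.append(site.with_kind("tts"))
    return result


def pool_processing_sites(classifications: list) -> list:
    """Cross-condition pooling of processing sites.

    A 3' terminus classified as a processing site under any condition is
    most likely a processing site everywhere, so the pooled processing
    positions are removed from every condition's TTS list (reason
    ``pooled_processing``).  Returns new classifications in input order.
    """
    pooled = set()
    for c in classifications:
        pooled |= {s.key for s in c.processing}
    out = []
    for c in classifications:
        kept, purged = [], []
        for s in c.tts:
            if s.key in pooled:
                purged.append((s, "pooled_processing"))
            else:
                kept.append(s)
        out.append(
            TerminiClassification(
                condition_id=c.condition_id,
                processing=list(c.processing),
                tts=kept,
                removed=list(c.removed) + purged,
            )
        )
    return out


def final_tts_union(classifications: list) -> list:
    """Union of per-condition final TTSs, with detecting conditions merged."""
    tally: dict[tuple, list] = {}
    for c in classifications:
        for s in c.tts:
            tally.setdefault(s.key, []).append((c.condition_id, s))
    out = []
    for key in sorted(tally):
        entries = tally[key]
        replicon_id, pos, strand = key
        conds = frozenset(cid for cid, _ in entries if cid)
        best = min(entries, key=lambda e: e[1].fdr)[1]
        out.append(
            SiteCall(
                replicon_id=replicon_id, position=pos, strand=strand,
                site_kind="tts", p_value=best.p_value, fdr=best.fdr,
                mean_signal=max(s.mean_signal for _, s in entries),
                conditions_detected=conds,
            )
        )
    return out
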