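"""Mapping TTSs onto predicted intrinsic terminators and characterizing them.

An intrinsic terminator is an RNA hairpin followed by a U-rich tract that
releases RNA polymerase 7-9 nt after the hairpin.  A TTS maps to a
predicted terminator when it falls in positions 1-12 of the terminator's
3'-flanking sequence (the 8-nt U tract plus 4 nt downstream).  TTSs on
the *opposite* strand falling in the mirror window on the 5' side are
rescued as the reverse-complement use of a bidirectional terminator and
reported with an "r"-suffixed terminator id.  Matched terminators are
classified by genomic orientation (in-line / internal / convergent /
divergent) and characterized by hairpin stem, loop and an approximate
nearest-neighbor folding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GeneRecord, SiteCall, TerminatorPrediction

U_TRACT_WINDOW = 12
INTERNAL_MARGIN = 50


@dataclass(frozen=True)
class TerminatorMatch:
    """A TTS mapped onto a predicted intrinsic terminator."""

    tts_id: str
    terminator_id: str  # suffixed "r" for a reverse-complement rescue
    replicon_id: str
    tts_position: int
    tts_strand: str
    u_tract_offset: int  # 1..12, position within the 12-nt 3' flank
    is_rescue: bool = False
    orientation_class: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.u_tract_offset <= U_TRACT_WINDOW):
            raise ValueError("u_tract_offset must be in 1..12")


@dataclass(frozen=True)
class HairpinProperties:
    stem_len: int
    loop_len: int
    delta_g: float  # kcal/mol, nearest-neighbor approximation


def _tts_id(site: SiteCall) -> str:
    return f"TTS_{site.replicon_id}_{site.position}_{site.strand}"


def map_tts_to_terminators(
    tts_list: list,
    predictions: list,
    window: int = U_TRACT_WINDOW,
) -> list:
    """Map TTSs to predicted terminators by the U-tract window rule.

    Forward match: a TTS on the terminator's strand at the k-th position
    (1 <= k <= window) of the 3' flank downstream of the hairpin.  Rescue
    match: a TTS on the opposite strand at the k-th position upstream of
    the hairpin (the 3' flank of the unpredicted reverse-complement
    terminator); reported against ``terminator_id + "r"``.  A TTS may
    match several terminators; all matches are reported.
    """
    by_key: dict[tuple, list] = {}
    for s in tts_list:
        by_key.setdefault((s.replicon_id, s.position, s.strand), []).append(s)

    matches = []
    for p in predictions:
        flip = {"+": "-", "-": "+"}[p.strand]
        for k in range(1, window + 1):
            if p.strand == "+":
                fwd_pos, resc_pos = p.hairpin_end + k, p.hairpin_start - k
            else:
                fwd_pos, resc_pos = p.hairpin_start - k, p.hairpin_end + k
            for s in by_key.get((p.replicon_id, fwd_pos, p.strand), []):
                matches.append(
                    TerminatorMatch(
                        tts_id=_tts_id(s), terminator_id=p.terminator_id,
                        replicon_id=p.replicon_id, tts_position=s.position,
                        tts_strand=s.strand, u_tract_offset=k, is_rescue=False,
                    )
                )
            for s in by_key.get((p.replicon_id, resc_pos, flip), []):
                matches.append(
                    TerminatorMatch(
                        tts_id=_tts_id(s), terminator_id=p.terminator_id + "r",
                        replicon_id=p.replicon_id, tts_position=s.position,
                        tts_strand=s.strand, u_tract_offset=k, is_rescue=True,
                    )
                )
    return sorted(matches, key=lambda m: (m.replicon_id, m.tts_position, m.terminator_id))


def classify_orientation(
    site_key: tuple,
    genes: list,
    internal_margin: int = INTERNAL_MARGIN,
) -> str:
    """Orientation of a site relative to its flanking genes.

    ``internal``: inside a same-strand gene more than ``internal_margin``
    bp after its start codon.  Otherwise the nearest gene on each genomic
    side decides: ``convergent`` when both point toward the site (-> <-),
    ``divergent`` when both point away (<- ->), ``in_line`` otherwise
    (including sites beyond the outermost gene of a replicon).
    """
    replicon_id, position, strand = site_key
    reps = [g for g in genes if g.replicon_id == replicon_id]
    if not reps:
        raise ValueError(f"no genes on replicon {replicon_id}")
    for g in reps:
        if g.strand == strand and g.contains(position):
            after_start = (
                position - g.start if strand == "+" else g.end - position
            )
            if after_start > internal_margin:
                return "internal"
    left = [g for g in reps if g.end < position]
    right = [g for g in reps if g.start > position]
    left_gene = max(left, key=lambda g: g.end) if left else None
    right_gene = min(right, key=lambda g: g.start) if right else None
    if left_gene is None or right_gene is None:
        return "in_line"
    if left_gene.strand == "+" and right_gene.strand == "-":
        return "convergent"
    if left_gene.strand == "-" and right_gene.strand == "+":
        return "divergent"
    return "in_line"


def annotate_orientations(matches: list, genes: list,
                          internal_margin: int = INTERNAL_MARGIN) -> list:
    from dataclasses import replace

    return [
        replace(
            m,
            orientation_class=classify_orientation(
                (m.replicon_id, m.tts_position, m.tts_strand), genes, internal_margin
            ),
        )
        for m in matches
    ]


# ---------------------------------------------------------------------------
# Hairpin thermodynamics (nearest-neighbor approximation)
# ---------------------------------------------------------------------------

# RNA nearest-neighbor stack free energies at 37 C, kcal/mol, indexed by
# (pair closing below, pair above) in 5'->3' stem order; Turner-89-style
# values, Watson-Crick plus G.U wobble.  Versioned constants: ordinal
# comparisons only are promised by this module's API.
STACK_DELTA_G = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -0.9, ("AU", "GC"): -2.1,
    ("AU", "CG"): -1.8, ("AU", "GU"): -0.5, ("AU", "UG"): -0.7,
    ("UA", "AU"): -1.1, ("UA", "UA"): -0.9, ("UA", "GC"): -2.3,
    ("UA", "CG"): -1.7, ("UA", "GU"): -0.5, ("UA", "UG"): -0.5,
    ("GC", "AU"): -1.8, ("GC", "UA"): -2.1, ("GC", "GC"): -3.3,
    ("GC", "CG"): -3.4, ("GC", "GU"): -1.4, ("GC", "UG"): -1.5,
    ("CG", "AU"): -2.3, ("CG", "UA"): -2.1, ("CG", "GC"): -2.9,
    ("CG", "CG"): -3.3, ("CG", "GU"): -1.2, ("CG", "UG"): -1.9,
    ("GU", "AU"): -0.8, ("GU", "UA"): -0.8, ("GU", "GC"): -1.9,
    ("GU", "CG"): -1.5, ("GU", "GU"): -0.4, ("GU", "UG"): -0.4,
    ("UG", "AU"): -0.8, ("UG", "UA"): -0.8, ("UG", "GC"): -1.6,
    ("UG", "CG"): -1.4, ("UG", "GU"): -0.4, ("UG", "UG"): -0.4,
}

# hairpin-loop initiation free energies by loop length (kcal/mol); beyond
# the table: Jacobson-Stockmayer extrapolation from 9 nt
HAIRPIN_LOOP_DELTA_G = {3: 5.4, 4: 4.9, 5: 4.4, 6: 4.3, 7: 4.1, 8: 4.1, 9: 4.2}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def _pairs(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b or (a, b) in _WOBBLE


def _loop_init(loop_len: int) -> float:
    if loop_len < 3:
        raise ValueError("hairpin loop must be >=3 nt")
    if loop_len in HAIRPIN_LOOP_DELTA_G:
        return HAIRPIN_LOOP_DELTA_G[loop_len]
    return HAIRPIN_LOOP_DELTA_G[9] + 1.75 * 0.616 * np.log(loop_len / 9.0)


def parse_stem(rna: str) -> tuple:
    """Maximal complementary pairing from the hairpin ends inward (G.U
    allowed); returns (stem_len, loop_len)."""
    n = len(rna)
    stem = 0
    while stem < (n - 3) // 2 and _pairs(rna[stem], rna[n - 1 - stem]):
        stem += 1
    loop = n - 2 * stem
    return stem, loop


def hairpin_properties(
    prediction: TerminatorPrediction, genome: dict
) -> HairpinProperties:
    """Stem/loop geometry and approximate folding free energy of a
    predicted terminator hairpin.

    The hairpin RNA is taken from the genome in transcript orientation.
    Stem/loop lengths come from the predictor when present, else from
    maximal pairing inward from the ends.  Delta G sums nearest-neighbor
    stack energies along the stem plus a loop-initiation term; it
    approximates exact-folding values and only ordinal comparisons are
    guaranteed.
    """
    rep = genome[prediction.replicon_id]
    rna = rep.subseq(
        prediction.hairpin_start, prediction.hairpin_end, prediction.strand
    ).replace("T", "U")
    if prediction.stem_len >= 1 and prediction.loop_len >= 3:
        stem, loop = prediction.stem_len, prediction.loop_len
    else:
        stem, loop = parse_stem(rna)
    if loop < 3:
        raise ValueError(
            f"terminator {prediction.terminator_id}: loop {loop} < 3 after parsing"
        )
    dg = _loop_init(loop)
    for i in range(stem - 1):
        below = rna[i] + rna[len(rna) - 1 - i]
        above = rna[i + 1] + rna[len(rna) - 2 - i]
        dg += STACK_DELTA_G.get((below, above), 0.0)
    return HairpinProperties(stem_len=stem, loop_len=loop, delta_g=float(dg))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def u_tract_position_histogram(matches: list) -> dict:
    """Counts of TTSs by U-tract offset 1..12, plus the modal offset."""
    if not matches:
        raise ValueError("no matches")
    counts = {k: 0 for k in range(1, U_TRACT_WINDOW + 1)}
    for m in matches:
        counts[m.u_tract_offset] += 1
    mode = max(counts, key=lambda k: (counts[k], -k))
    return {"counts": counts, "mode": mode}


def flank_frequency_matrix(
    predictions: list,
    genome: dict,
    side: str = "5prime_a_tract",
    width: int = 10,
) -> np.ndarray:
    """(4 x width) base-frequency matrix of terminator flanks in
    transcript orientation (rows A, C, G, T).

    ``5prime_a_tract``: the `width` nt immediately upstream of the
    hairpin; ``3prime_u_tract``: the `width` nt immediately downstream.
    Orientation filtering is done by the caller (pass a filtered
    prediction list).
    """
    base_index = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((4, width))
    n = 0
    for p in predictions:
        rep = genome[p.replicon_id]
        if side == "5prime_a_tract":
            if p.strand == "+":
                lo, hi = p.hairpin_start - width, p.hairpin_start - 1
            else:
                lo, hi = p.hairpin_end + 1, p.hairpin_end + width
        elif side == "3prime_u_tract":
            if p.strand == "+":
                lo, hi = p.hairpin_end + 1, p.hairpin_end + width
            else:
                lo, hi = p.hairpin_start - width, p.hairpin_start - 1
        else:
            raise ValueError(f"unknown side {side!r}")
        if lo < 1 or hi > rep.length:
            continue
        seq = rep.subseq(lo, hi, p.strand)
        if "N" in seq:
            continue
        for j, c in enumerate(seq):
            counts[base_index[c], j] += 1
        n += 1
    if n == 0:
        raise ValueError("no usable flanks")
    return counts / n


def dedupe_matched_tts(matches: list) -> set:
    """Distinct TTS ids among matches (headline counts de-duplicate by TTS)."""
    return {m.tts_id for m in matches}


def matched_terminator_ids(matches: list) -> set:
    """Distinct terminator ids (without the rescue suffix) hit by >=1 TTS."""
    return {m.terminator_id.rstrip("r") for m in matches}
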