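"""Synthetic genomes, annotations and end-coverage tracks with planted truth.

Every caller in the pipeline is exercised against simulations in which the
ground truth is known: planted TSSs (treated 5'-end mean far above the
untreated mean), planted 3'-terminus pileups at intrinsic-terminator U
tracts, planted processing sites as paired (3'-OH at p, 5'-P at p+1)
signals, and planted promoter hexamers with stated spacer/discriminator
distributions.  Counts are negative-binomial: mean ``m``, dispersion
``a``, variance ``m + a m^2`` (``a = 0`` degenerates to Poisson); planted
events add to, not replace, the background.  All simulators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    STRANDS,
    EndCoverageTrack,
    GeneRecord,
    GenomeSequence,
    TerminatorPrediction,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedTss:
    replicon_id: str
    position: int
    strand: str
    treated_mean: float
    untreated_mean: float
    gene_id: str | None = None


@dataclass(frozen=True)
class PlantedTts:
    replicon_id: str
    position: int
    strand: str
    mean: float
    terminator_id: str | None = None


@dataclass(frozen=True)
class PlantedProcessing:
    """A cleavage event: 3'-OH at `three_prime_pos`, 5'-P one nt downstream."""

    replicon_id: str
    three_prime_pos: int
    five_p_pos: int
    strand: str
    mean_3p: float
    mean_5p: float


@dataclass
class SimulationTruth:
    seed: int
    planted_tss: list = field(default_factory=list)
    planted_tts: list = field(default_factory=list)
    planted_processing: list = field(default_factory=list)
    planted_genes: list = field(default_factory=list)
    terminator_predictions: list = field(default_factory=list)


@dataclass(frozen=True)
class NoiseModel:
    """Background/noise parameters shared by the track simulators."""

    nb_dispersion: float = 0.1
    background_rate: float = 0.2  # mean background end events per position
    monophosphate_background_rate: float = 0.2  # 5'P noise, both library kinds
    size_factors: tuple = ()  # per-replicate; empty = all 1.0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0 or self.background_rate < 0:
            raise ValueError("noise parameters must be non-negative")

    def replicate_size_factor(self, r: int) -> float:
        if not self.size_factors:
            return 1.0
        return float(self.size_factors[r % len(self.size_factors)])


def nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + dispersion*mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def simulate_genome(
    n_genes: int,
    length: int,
    gc: float = 0.46,
    seed: int = 0,
    n_trna: int = 0,
    replicon_id: str = "chr",
    gene_length=(300, 1500),
    gap_length=(50, 400),
) -> tuple:
    """An i.i.d. background genome with non-overlapping genes.

    Gene strands are drawn at random, so the junction mix includes
    in-line, convergent and divergent neighbour pairs.  tRNAs are placed
    as short (80-bp) features after the protein-coding genes.  Returns
    ``(genome_dict, genes, SimulationTruth skeleton)``.
    """
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=length, p=probs)
    genes = []
    cursor = 1 + int(rng.integers(gap_length[0], gap_length[1]))
    for i in range(n_genes):
        glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
        if cursor + glen + gap_length[1] > length:
            raise ValueError(
                f"cannot pack {n_genes} genes of ~{gene_length} bp into {length} bp"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                gene_id=f"gene_{i + 1:04d}",
                replicon_id=replicon_id,
                start=cursor,
                end=cursor + glen - 1,
                strand=strand,
                feature_class="protein_coding",
            )
        )
        cursor += glen + int(rng.integers(gap_length[0], gap_length[1] + 1))
    for i in range(n_trna):
        glen = 80
        if cursor + glen + gap_length[1] > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                gene_id=f"trna_{i + 1:03d}",
                replicon_id=replicon_id,
                start=cursor,
                end=cursor + glen - 1,
                strand=strand,
                feature_class="tRNA",
            )
        )
        cursor += glen + int(rng.integers(gap_length[0], gap_length[1] + 1))
    genome = {replicon_id: GenomeSequence(replicon_id, "".join(seq))}
    return genome, genes, SimulationTruth(seed=seed, planted_genes=genes)


def plant_terminator(
    genome: dict,
    replicon_id: str,
    hairpin_start: int,
    strand: str,
    terminator_id: str,
    rng: np.random.Generator,
    stem_len: int = 10,
    loop_len: int = 4,
) -> tuple:
    """Write an intrinsic-terminator sequence (GC-rich stem, loop, U tract)
    into the genome and return the updated genome plus the prediction."""
    stem = "".join(rng.choice(list("GC"), size=stem_len))
    loop = "".join(rng.choice(list("ACGT"), size=loop_len))
    utract = "T" * 8 + "".join(rng.choice(list("ACGT"), size=4))
    cassette = stem + loop + _revcomp(stem) + utract
    hp_len = 2 * stem_len + loop_len
    rep = genome[replicon_id]
    if strand == "+":
        lo = hairpin_start
        insert = cassette
        hp_start, hp_end = lo, lo + hp_len - 1
    else:
        # transcript runs right->left; genomic layout is revcomp(cassette)
        hp_end = hairpin_start  # genomic upper bound of the hairpin
        lo = hp_end - len(cassette) + 1
        insert = _revcomp(cassette)
        hp_start = hp_end - hp_len + 1
        hp_start, hp_end = hp_end - hp_len + 1, hp_end
    seq = rep.sequence
    if lo < 1 or lo + len(cassette) - 1 > rep.length:
        raise ValueError("terminator cassette out of range")
    new_seq = seq[: lo - 1] + insert + seq[lo - 1 + len(cassette):]
    genome = dict(genome)
    genome[replicon_id] = GenomeSequence(replicon_id, new_seq, rep.is_circular)
    pred = TerminatorPrediction(
        terminator_id=terminator_id,
        replicon_id=replicon_id,
        strand=strand,
        hairpin_start=hp_start,
        hairpin_end=hp_end,
        confidence=100,
        stem_len=stem_len,
        loop_len=loop_len,
    )
    return genome, pred


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------


def _background_tracks(
    rng, lengths, rate, dispersion, sf, library_id, condition_id, replicate_id, kind
) -> EndCoverageTrack:
    t = EndCoverageTrack(library_id, condition_id, replicate_id, kind, lengths)
    for key, arr in t.counts.items():
        arr[:] = nb_draw(rng, np.full(arr.size, rate * sf), dispersion)
    return t


def simulate_tss_libraries(
    truth: SimulationTruth,
    noise: NoiseModel,
    lengths: dict,
    n_replicates: int = 3,
    seed: int = 0,
    condition_id: str = "cond1",
) -> tuple:
    """Treated and untreated 5'-end tracks per replicate.

    A planted TSS contributes ``treated_mean`` to treated and
    ``untreated_mean`` to untreated libraries; planted 5'-monophosphoryl
    partners of processing events contribute equally to both (RppH
    treatment exposes triphosphates; monophosphates ligate either way).
    """
    rng = np.random.default_rng(seed)
    treated, untreated = [], []
    for r in range(n_replicates):
        sf = noise.replicate_size_factor(r)
        t = _background_tracks(
            rng, lengths, noise.background_rate, noise.nb_dispersion, sf,
            f"{condition_id}_treated_r{r + 1}", condition_id, f"r{r + 1}", "tss_treated",
        )
        u = _background_tracks(
            rng, lengths, noise.monophosphate_background_rate, noise.nb_dispersion, sf,
            f"{condition_id}_untreated_r{r + 1}", condition_id, f"r{r + 1}", "tss_untreated",
        )
        for ts in truth.planted_tss:
            t.add_count(ts.replicon_id, ts.strand, ts.position,
                        int(nb_draw(rng, ts.treated_mean * sf, noise.nb_dispersion)))
            u.add_count(ts.replicon_id, ts.strand, ts.position,
                        int(nb_draw(rng, ts.untreated_mean * sf, noise.nb_dispersion)))
        for pr in truth.planted_processing:
            for track in (t, u):
                track.add_count(pr.replicon_id, pr.strand, pr.five_p_pos,
                                int(nb_draw(rng, pr.mean_5p * sf, noise.nb_dispersion)))
        treated.append(t)
        untreated.append(u)
    return treated, untreated


def simulate_term_libraries(
    truth: SimulationTruth,
    noise: NoiseModel,
    lengths: dict,
    n_replicates: int = 3,
    seed: int = 0,
    condition_id: str = "cond1",
) -> list:
    """Strand-corrected term-seq (3'-end) tracks per replicate: background
    plus planted TTS pileups and processing-site 3' partners."""
    rng = np.random.default_rng(seed)
    tracks = []
    for r in range(n_replicates):
        sf = noise.replicate_size_factor(r)
        t = _background_tracks(
            rng, lengths, noise.background_rate, noise.nb_dispersion, sf,
            f"{condition_id}_termseq_r{r + 1}", condition_id, f"r{r + 1}", "termseq",
        )
        for tt in truth.planted_tts:
            t.add_count(tt.replicon_id, tt.strand, tt.position,
                        int(nb_draw(rng, tt.mean * sf, noise.nb_dispersion)))
        for pr in truth.planted_processing:
            t.add_count(pr.replicon_id, pr.strand, pr.three_prime_pos,
                        int(nb_draw(rng, pr.mean_3p * sf, noise.nb_dispersion)))
        tracks.append(t)
    return tracks


# ---------------------------------------------------------------------------
# Promoter-sequence simulation
# ---------------------------------------------------------------------------


def simulate_promoter_set(
    n: int,
    minus35_consensus: str = "TTGACA",
    minus10_consensus: str = "TATAAT",
    minus35_identity=(1.0,) * 6,
    minus10_identity=(1.0,) * 6,
    spacer_dist: dict | None = None,
    disc_dist: dict | None = None,
    width: int = 61,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple:
    """Promoter windows with planted -35/-10 hexamers.

    Each window is i.i.d. background into which the -10 is written ending
    a discriminator's length before the TSS (last character) and the -35 a
    spacer's length before the -10.  Each motif base is emitted as the
    consensus base with its per-position identity, else uniformly at
    random.  Returns ``(windows, truth)`` where truth rows are
    ``(minus35_offset, minus10_offset, spacer, discriminator)``.
    """
    if len(minus35_consensus) != 6 or len(minus10_consensus) != 6:
        raise ValueError("consensus strings must be hexamers")
    spacer_dist = spacer_dist or {17: 1.0}
    disc_dist = disc_dist or {6: 1.0}
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    s_vals, s_p = zip(*sorted(spacer_dist.items()))
    d_vals, d_p = zip(*sorted(disc_dist.items()))
    s_p = np.array(s_p, float) / sum(s_p)
    d_p = np.array(d_p, float) / sum(d_p)
    max_need = max(s_vals) + max(d_vals) + 12
    if max_need > width - 1:
        raise ValueError("spacer+discriminator+two hexamers exceed the window")

    def emit(consensus, identity):
        return "".join(
            c if rng.random() < pid else "ACGT"[rng.integers(4)]
            for c, pid in zip(consensus, identity)
        )

    windows, offsets = [], []
    for _ in range(n):
        w = list(rng.choice(list("ACGT"), size=width, p=probs))
        disc = int(rng.choice(d_vals, p=d_p))
        spacer = int(rng.choice(s_vals, p=s_p))
        o10 = width - 7 - disc
        o35 = o10 - 6 - spacer
        w[o10 : o10 + 6] = emit(minus10_consensus, minus10_identity)
        w[o35 : o35 + 6] = emit(minus35_consensus, minus35_identity)
        windows.append("".join(w))
        offsets.append((o35, o10, spacer, disc))
    return windows, offsets


def score_recovery(scenario: dict, fdr: float = 0.05) -> dict:
    """Run the callers on a simulated scenario and score them against the
    planted truth: TSS/TTS recovery, processing-pair classification, and
    TSS-to-gene assignment accuracy (fractions in [0, 1])."""
    from . import end_integration, tss_calling, tts_calling, tu_annotation

    truth: SimulationTruth = scenario["truth"]
    cond = scenario["condition_id"]
    genes = scenario["genes"]

    tss_sites = tss_calling.call_condition(
        scenario["treated"], scenario["untreated"], cond, fdr
    )
    called_tss_keys = {s.key for s in tss_sites}  # primary or secondary
    planted_tss_keys = {
        (t.replicon_id, t.position, t.strand) for t in truth.planted_tss
    }
    tss_recovery = (
        len(planted_tss_keys & called_tss_keys) / len(planted_tss_keys)
        if planted_tss_keys else 1.0
    )

    prelim = tts_calling.call_termini_for_condition(
        scenario["termseq"], condition_id=cond, fdr_threshold=fdr
    )
    mono = end_integration.call_monophosphate_sites(
        scenario["untreated"], tss_sites, condition_id=cond, fdr_threshold=fdr
    )
    cls = end_integration.classify_termini(prelim, mono, genes, cond)
    (cls,) = end_integration.pool_processing_sites([cls])

    final_tts_keys = {s.key for s in cls.tts}
    planted_tts_keys = {
        (t.replicon_id, t.position, t.strand) for t in truth.planted_tts
    }
    tts_recovery = (
        len(planted_tts_keys & final_tts_keys) / len(planted_tts_keys)
        if planted_tts_keys else 1.0
    )

    processing_keys = {s.key for s in cls.processing}
    planted_proc_keys = {
        (p.replicon_id, p.three_prime_pos, p.strand)
        for p in truth.planted_processing
    }
    processing_accuracy = (
        len(planted_proc_keys & processing_keys) / len(planted_proc_keys)
        if planted_proc_keys else 1.0
    )

    primaries = [s for s in tss_sites if s.site_kind == "tss_primary"]
    pairs, _ = tu_annotation.assign_tss_to_genes(primaries, genes)
    gene_by_pos = {(p.replicon_id, p.position, p.strand): p.gene_id for p in pairs}
    recovered_with_gene = [
        t for t in truth.planted_tss
        if t.gene_id and (t.replicon_id, t.position, t.strand) in
        {s.key for s in primaries}
    ]
    correct = sum(
        1 for t in recovered_with_gene
        if gene_by_pos.get((t.replicon_id, t.position, t.strand)) == t.gene_id
    )
    gene_assignment_accuracy = (
        correct / len(recovered_with_gene) if recovered_with_gene else 1.0
    )

    return {
        "tss_recovery": tss_recovery,
        "tts_recovery": tts_recovery,
        "processing_accuracy": processing_accuracy,
        "gene_assignment_accuracy": gene_assignment_accuracy,
        "n_called_tss_primary": len(primaries),
        "n_final_tts": len(final_tts_keys),
        "n_processing": len(processing_keys),
    }


def plant_promoter_motifs(
    genome: dict,
    replicon_id: str,
    tss_position: int,
    strand: str,
    minus10: str = "TATAAT",
    minus35: str = "TTGACA",
    discriminator: int = 6,
    spacer: int = 17,
) -> dict:
    """Write -35/-10 hexamers into the genome upstream of a TSS."""
    rep = genome[replicon_id]
    seq = rep.sequence

    def put(s: str, start_1b: int, motif: str) -> str:
        return s[: start_1b - 1] + motif + s[start_1b - 1 + len(motif):]

    if strand == "+":
        m10_start = tss_position - discriminator - 6
        m35_start = m10_start - spacer - 6
        if m35_start < 1:
            return genome
        seq = put(seq, m10_start, minus10)
        seq = put(seq, m35_start, minus35)
    else:
        m10_start = tss_position + discriminator + 1
        m35_start = m10_start + 6 + spacer
        if m35_start + 5 > rep.length:
            return genome
        seq = put(seq, m10_start, _revcomp(minus10))
        seq = put(seq, m35_start, _revcomp(minus35))
    out = dict(genome)
    out[replicon_id] = GenomeSequence(replicon_id, seq, rep.is_circular)
    return out


# ---------------------------------------------------------------------------
# The default end-to-end scenario
# ---------------------------------------------------------------------------


def default_scenario(
    seed: int = 0,
    length: int = 100_000,
    n_genes: int = 60,
    n_tss: int = 40,
    n_tts: int = 25,
    n_terminator_tts: int = 10,
    n_processing: int = 10,
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
    tss_treated_mean: float = 200.0,
    tss_untreated_mean: float = 2.0,
    tts_mean: float = 100.0,
    processing_mean: float = 100.0,
    u_tract_offset: int = 7,
    condition_id: str = "cond1",
    plant_promoters: bool = True,
    promoter_spacer: int = 17,
    promoter_discriminator: int = 6,
) -> dict:
    """The default synthetic scenario used by the recovery suites.

    A 100-kb genome with 60 genes; 40 TSSs planted 0-300 nt upstream of
    gene start codons (a few leaderless); 25 3'-terminus pileups of which
    10 sit at planted intrinsic terminators (offset 7 in the U tract);
    10 processing pairs inside gene bodies; 3 replicates per library kind.
    """
    rng = np.random.default_rng(seed)
    genome, genes, truth = simulate_genome(
        n_genes, length, seed=int(rng.integers(2**31)), n_trna=2
    )
    replicon_id = next(iter(genome))
    coding = [g for g in genes if g.feature_class == "protein_coding"]

    used: set = set()

    # TSSs upstream of gene start codons
    chosen = rng.choice(len(coding), size=min(n_tss, len(coding)), replace=False)
    for gi in sorted(chosen.tolist()):
        g = coding[gi]
        utr = int(rng.choice([0, 3] + list(range(20, 301, 10))))
        pos = g.start_codon_pos - utr if g.strand == "+" else g.start_codon_pos + utr
        if not (100 < pos < length - 100) or (pos, g.strand) in used:
            continue
        used.add((pos, g.strand))
        truth.planted_tss.append(
            PlantedTss(replicon_id, pos, g.strand, tss_treated_mean,
                       tss_untreated_mean, gene_id=g.gene_id)
        )
        if plant_promoters:
            genome = plant_promoter_motifs(
                genome, replicon_id, pos, g.strand,
                discriminator=promoter_discriminator, spacer=promoter_spacer,
            )

    # intrinsic terminators downstream of gene ends, with a TTS in the U tract
    gaps = []
    ordered = sorted(genes, key=lambda g: g.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start - a.end > 120:
            gaps.append((a.end + 30, b.start - 90))
    rng.shuffle(gaps)
    preds = []
    for i in range(min(n_terminator_tts, len(gaps))):
        lo, hi = gaps[i]
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = int(rng.integers(lo, hi)) if hi > lo else lo
        genome, pred = plant_terminator(
            genome, replicon_id, anchor, strand, f"TERMSIM_{i + 1:03d}", rng
        )
        preds.append(pred)
        tts_pos = (
            pred.hairpin_end + u_tract_offset
            if strand == "+"
            else pred.hairpin_start - u_tract_offset
        )
        if (tts_pos, strand) not in used:
            used.add((tts_pos, strand))
            truth.planted_tts.append(
                PlantedTts(replicon_id, tts_pos, strand, tts_mean, pred.terminator_id)
            )
    truth.terminator_predictions = preds

    # free-standing TTSs (non-terminator 3' ends)
    while sum(1 for t in truth.planted_tts) < n_tts:
        pos = int(rng.integers(200, length - 200))
        strand = "+" if rng.random() < 0.5 else "-"
        if (pos, strand) in used or (pos + 1, strand) in used:
            continue
        used.add((pos, strand))
        truth.planted_tts.append(PlantedTts(replicon_id, pos, strand, tts_mean, None))

    # processing pairs inside gene bodies
    bodies = [g for g in coding if g.length > 400]
    chosen = rng.choice(len(bodies), size=min(n_processing, len(bodies)), replace=False)
    for gi in sorted(chosen.tolist()):
        g = bodies[gi]
        p3 = int(rng.integers(g.start + 100, g.end - 100))
        p5 = p3 + 1 if g.strand == "+" else p3 - 1
        if (p3, g.strand) in used or (p5, g.strand) in used:
            continue
        used.add((p3, g.strand))
        used.add((p5, g.strand))
        truth.planted_processing.append(
            PlantedProcessing(replicon_id, p3, p5, g.strand,
                              processing_mean, processing_mean)
        )

    lengths = {replicon_id: length}
    sub = rng.integers(2**31, size=2)
    treated, untr = simulate_tss_libraries(
        truth, noise, lengths, n_replicates, int(sub[0]), condition_id
    )
    term = simulate_term_libraries(
        truth, noise, lengths, n_replicates, int(sub[1]), condition_id
    )
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "terminator_predictions": preds,
        "treated": treated,
        "untreated": untr,
        "termseq": term,
        "lengths": lengths,
        "condition_id": condition_id,
    }
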