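"""Information-theoretic discovery of the two-hexamer sigma-A promoter model.

Bacterial housekeeping promoters carry -35 and -10 hexamers separated by a
variable-length spacer; the -10 is separated from the TSS by a variable
discriminator.  The model is built from fixed-width windows upstream of
refined TSSs:

1. *malign*: an iterative alignment of the -10 hexamer.  Five windows are
   drawn at random and all offset combinations are enumerated to seed a
   heuristic profile with maximal information content; every window is
   then greedily aligned to and added to the profile; the seed counts are
   removed; and refinement passes re-place each window (a re-placement is
   kept only if total information does not decrease) until the per-pass
   improvement falls below a tolerance.
2. A preliminary -35 profile is built at an assumed spacing from the -10
   placements and optimized with malign over the spacer-compatible offsets.
3. *multiscan*: final -35 placement maximizing the -35 individual
   information minus a gap surprisal penalty for non-modal spacer lengths,
   iterated to convergence; windows whose total score is <= 0 bits do not
   conform to the model and are dropped.

Information quantities are in bits.  Position frequencies carry a 0.25
per-base pseudocount; the small-sample entropy correction is
``e(n) = 3 / (2 ln2 n)`` (the large-n approximation for 4 symbols).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import GenomeSequence, SiteCall

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_WINDOW = 61
DEFAULT_SPACER_RANGE = (12, 22)
DEFAULT_DISC_RANGE = (3, 12)
PSEUDOCOUNT = 0.25
MOTIF_WIDTH = 6


def encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


@dataclass(frozen=True)
class PromoterSequence:
    """A fixed-width promoter window in transcript orientation; the TSS is
    the last character."""

    tss_id: str
    window: str

    @property
    def codes(self) -> np.ndarray:
        return encode(self.window)


def extract_promoter_windows(
    tss_list: list,
    genome: dict,
    width: int = DEFAULT_WINDOW,
) -> list:
    """Windows covering genomic TSS-(W-1) .. TSS in transcript orientation
    (minus-strand windows reverse-complemented).  TSSs too close to a
    replicon end, or whose window contains N, are skipped."""
    windows = []
    for site in tss_list:
        rep: GenomeSequence = genome[site.replicon_id]
        if site.strand == "+":
            lo, hi = site.position - (width - 1), site.position
        else:
            lo, hi = site.position, site.position + (width - 1)
        if lo < 1 or hi > rep.length:
            continue
        seq = rep.subseq(lo, hi, site.strand)
        if "N" in seq:
            continue
        windows.append(
            PromoterSequence(
                tss_id=f"TSS_{site.replicon_id}_{site.position}_{site.strand}",
                window=seq,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Information measures
# ---------------------------------------------------------------------------


def small_sample_correction(n: int) -> float:
    """e(n) = 3/(2 ln2 n): expected overestimate of information (bits per
    position) when entropy is estimated from n sequences over 4 symbols."""
    return 3.0 / (2.0 * math.log(2.0) * n)


def _count_matrix(hexamers: np.ndarray) -> np.ndarray:
    """(4 x width) base counts from an (n x width) code array."""
    n, width = hexamers.shape
    counts = np.zeros((4, width), dtype=np.float64)
    for b in range(4):
        counts[b] = np.sum(hexamers == b, axis=0)
    return counts


def information_content(
    hexamers: np.ndarray, correct_small_sample: bool = True
) -> float:
    """Total information R = sum_l (2 - H_l - e(n)) of an aligned set.

    ``hexamers`` is an (n x width) code array; entropies use raw
    (un-pseudocounted) frequencies, with 0*log0 = 0.
    """
    n, width = hexamers.shape
    if n < 2:
        raise ValueError("need >=2 sequences")
    freq = _count_matrix(hexamers) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=0)
    e = small_sample_correction(n) if correct_small_sample else 0.0
    return float(np.sum(2.0 - h - e))


@dataclass(frozen=True)
class InformationMatrix:
    """Pseudocounted frequency matrix with individual-information weights."""

    freq: np.ndarray  # 4 x width
    n: int
    correct_small_sample: bool = True
    width: int = MOTIF_WIDTH

    @classmethod
    def from_hexamers(
        cls, hexamers: np.ndarray, correct_small_sample: bool = True
    ) -> "InformationMatrix":
        counts = _count_matrix(hexamers)
        return cls.from_counts(counts, hexamers.shape[0], correct_small_sample)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, n: int, correct_small_sample: bool = True
    ) -> "InformationMatrix":
        freq = (counts + PSEUDOCOUNT) / (n + 4 * PSEUDOCOUNT)
        return cls(freq=freq, n=n, width=counts.shape[1],
                   correct_small_sample=correct_small_sample)

    @property
    def e_n(self) -> float:
        return small_sample_correction(self.n) if self.correct_small_sample else 0.0

    @property
    def riw(self) -> np.ndarray:
        """Individual-information weights: riw(b,l) = 2 + log2 f(b,l) - e(n)."""
        return 2.0 + np.log2(self.freq) - self.e_n

    @property
    def per_position_information(self) -> np.ndarray:
        """2 - H_l - e(n) per position, from the pseudocounted frequencies."""
        h = -np.sum(self.freq * np.log2(self.freq), axis=0)
        return 2.0 - h - self.e_n

    @property
    def r_sequence(self) -> float:
        return float(np.sum(self.per_position_information))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.freq, axis=0))


def individual_information(matrix: InformationMatrix, hexamer) -> float:
    """Ri = sum_l riw(b_l, l) of one sequence against the matrix."""
    codes = encode(hexamer) if isinstance(hexamer, str) else np.asarray(hexamer)
    if codes.size != matrix.width:
        raise ValueError(f"hexamer width {codes.size} != matrix width {matrix.width}")
    return float(matrix.riw[codes, np.arange(matrix.width)].sum())


# ---------------------------------------------------------------------------
# malign
# ---------------------------------------------------------------------------


def _slices(codes: np.ndarray, offsets, width: int) -> np.ndarray:
    """(n_offsets x width) candidate hexamers of one window."""
    return np.stack([codes[o : o + width] for o in offsets])


def _profile_riw(counts: np.ndarray, n: int, correct: bool) -> np.ndarray:
    freq = (counts + PSEUDOCOUNT) / (n + 4 * PSEUDOCOUNT)
    e = small_sample_correction(max(n, 2)) if correct else 0.0
    return 2.0 + np.log2(freq) - e


def _best_offset(cand: np.ndarray, riw: np.ndarray, width: int) -> int:
    """Index of the best-scoring candidate hexamer; ties to the smallest
    offset index."""
    scores = riw[cand, np.arange(width)[None, :]].sum(axis=1)
    return int(np.argmax(scores))  # argmax takes the first maximum


def _seed_profile(
    seqs: list, offset_lists: list, width: int, correct: bool
) -> tuple:
    """Exhaustive search over all offset tuples of the seed sequences;
    returns (offsets, counts) of the max-information alignment."""
    n = len(seqs)
    cand_sets = [_slices(c, offs, width) for c, offs in zip(seqs, offset_lists)]
    sizes = [c.shape[0] for c in cand_sets]
    total = int(np.prod(sizes))
    best_R, best_combo = -np.inf, None
    # enumerate in chunks to bound memory
    chunk = 20000
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        combo = np.empty((idx.size, n), dtype=np.int64)
        rem = idx.copy()
        for j in range(n - 1, -1, -1):
            combo[:, j] = rem % sizes[j]
            rem //= sizes[j]
        # stack hexamers: (chunk, n, width)
        hex_stack = np.stack(
            [cand_sets[j][combo[:, j]] for j in range(n)], axis=1
        )
        counts = np.stack(
            [(hex_stack == b).sum(axis=1) for b in range(4)], axis=1
        ).astype(np.float64)  # (chunk, 4, width)
        freq = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=1)
        e = small_sample_correction(n) if correct else 0.0
        R = np.sum(2.0 - h - e, axis=1)
        k = int(np.argmax(R))
        if R[k] > best_R:
            best_R = float(R[k])
            best_combo = combo[k].copy()
    offsets = [offset_lists[j][best_combo[j]] for j in range(n)]
    counts = _count_matrix(
        np.stack([cand_sets[j][best_combo[j]] for j in range(n)])
    )
    return offsets, counts


def _canonicalize_register(
    codes: list,
    offsets: list,
    offset_lists: list,
    width: int,
    correct: bool,
) -> list:
    """Resolve the register ambiguity of partially informative motifs.

    When only a subset of motif columns is informative (e.g. a "TAnnnn"
    -10), every common shift of all placements that keeps the informative
    columns inside the hexamer has essentially the same information
    content, so the register the iteration lands in is arbitrary.  Among
    global shifts within 20% (at least 0.3 bits) of the maximum total
    information — misplaced minority sequences cost a shift a little
    information without making it a different alignment — choose the one
    that packs the information into the leftmost (5') columns — the
    conventional register of the sigma -10/-35 hexamers (TATAAT, TTGACA
    lead with their informative bases).  Ties go to the smallest absolute
    shift.  Returns the shifted offsets.
    """
    n = len(codes)

    def shifted(i: int, delta: int) -> int:
        # clip to the nearest allowed offset so boundary sequences cannot
        # veto a register shift for the whole alignment
        want = offsets[i] + delta
        return min(offset_lists[i], key=lambda o: (abs(o - want), o))

    results = []
    for delta in range(-(width - 1), width):
        hexes = np.stack(
            [codes[i][shifted(i, delta) : shifted(i, delta) + width] for i in range(n)]
        )
        freq = _count_matrix(hexes) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=0)
        e = small_sample_correction(n) if correct else 0.0
        info = 2.0 - h - e
        r_total = float(info.sum())
        leftness = float(np.sum(np.clip(info, 0, None) * (width - np.arange(width))))
        results.append((delta, r_total, leftness))
    r_max = max(r for _, r, _ in results)
    near = [t for t in results if t[1] >= r_max - max(0.3, 0.2 * r_max)]
    delta = max(near, key=lambda t: (t[2], -abs(t[0]), -t[0]))[0]
    return [shifted(i, delta) for i in range(n)]


def malign(
    sequences: list,
    offset_range,
    width: int = MOTIF_WIDTH,
    seed: int | np.random.Generator = 0,
    n_seed_sequences: int = 5,
    tol: float = 0.01,
    max_passes: int = 100,
    correct_small_sample: bool = True,
    n_restarts: int = 5,
) -> tuple:
    """Iterative information-maximizing alignment of one hexamer.

    ``sequences`` are window strings or code arrays; ``offset_range`` is
    either a single iterable of allowed 0-based offsets (shared by all
    windows) or a list of per-window offset lists.  The heuristic
    5-sequence seeding is restarted ``n_restarts`` times (seeded RNG) and
    the highest-information result kept.  Returns
    ``(offsets, InformationMatrix)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = [encode(s) if isinstance(s, str) else np.asarray(s) for s in sequences]
    nseq = len(codes)
    if isinstance(offset_range[0], (list, tuple, np.ndarray)):
        offset_lists = [list(o) for o in offset_range]
    else:
        offset_lists = [list(offset_range)] * nseq
    if any(len(o) == 0 for o in offset_lists):
        raise ValueError("a sequence has an empty offset range")
    if nseq < 2:
        raise ValueError("need >=2 sequences")

    cand_sets = [_slices(c, offs, width) for c, offs in zip(codes, offset_lists)]

    best = None
    for _ in range(max(1, n_restarts) if nseq > n_seed_sequences else 1):
        offsets, matrix = _malign_once(
            codes, cand_sets, offset_lists, width, rng, n_seed_sequences,
            tol, max_passes, correct_small_sample,
        )
        if best is None or matrix.r_sequence > best[1].r_sequence:
            best = (offsets, matrix)
    return best


def _malign_once(
    codes, cand_sets, offset_lists, width, rng, n_seed_sequences,
    tol, max_passes, correct_small_sample,
):
    nseq = len(codes)
    if nseq <= n_seed_sequences:
        # tiny inputs: exhaustive alignment is the whole job
        offsets, counts = _seed_profile(codes, offset_lists, width, correct_small_sample)
        offsets = _canonicalize_register(
            codes, offsets, offset_lists, width, correct_small_sample
        )
        hexes = np.stack([cand_sets[i][offset_lists[i].index(offsets[i])] for i in range(nseq)])
        return offsets, InformationMatrix.from_hexamers(hexes, correct_small_sample)

    seed_idx = sorted(rng.choice(nseq, size=n_seed_sequences, replace=False).tolist())
    seed_offsets, seed_counts = _seed_profile(
        [codes[i] for i in seed_idx],
        [offset_lists[i] for i in seed_idx],
        width,
        correct_small_sample,
    )

    # greedy pass: align every sequence against the growing profile
    counts = seed_counts.copy()
    n_in = n_seed_sequences
    offsets = [None] * nseq
    for i in range(nseq):
        riw = _profile_riw(counts, n_in, correct_small_sample)
        k = _best_offset(cand_sets[i], riw, width)
        offsets[i] = offset_lists[i][k]
        counts += _count_matrix(cand_sets[i][k : k + 1])
        n_in += 1

    # remove the heuristic seed contribution
    for j, i in enumerate(seed_idx):
        k = offset_lists[i].index(seed_offsets[j])
        counts -= _count_matrix(cand_sets[i][k : k + 1])
        n_in -= 1
    assert n_in == nseq

    # refinement passes (re-place each sequence; keep only non-decreasing
    # moves), then register canonicalization; a second round consolidates
    # sequences displaced by a register shift
    aligned = np.stack(
        [cand_sets[i][offset_lists[i].index(offsets[i])] for i in range(nseq)]
    )
    for _round in range(2):
        R_prev = information_content(aligned, correct_small_sample)
        for _ in range(max_passes):
            for i in range(nseq):
                old_k = offset_lists[i].index(offsets[i])
                counts -= _count_matrix(cand_sets[i][old_k : old_k + 1])
                riw = _profile_riw(counts, nseq - 1, correct_small_sample)
                new_k = _best_offset(cand_sets[i], riw, width)
                if new_k != old_k:
                    trial = aligned.copy()
                    trial[i] = cand_sets[i][new_k]
                    if information_content(
                        trial, correct_small_sample
                    ) >= information_content(aligned, correct_small_sample):
                        aligned = trial
                        offsets[i] = offset_lists[i][new_k]
                        old_k = new_k
                counts += _count_matrix(cand_sets[i][old_k : old_k + 1])
            R_now = information_content(aligned, correct_small_sample)
            if R_now - R_prev < tol:
                break
            R_prev = R_now
        new_offsets = _canonicalize_register(
            codes, offsets, offset_lists, width, correct_small_sample
        )
        changed = new_offsets != offsets
        offsets = new_offsets
        aligned = np.stack(
            [cand_sets[i][offset_lists[i].index(offsets[i])] for i in range(nseq)]
        )
        counts = _count_matrix(aligned)
        if not changed:
            break
    return offsets, InformationMatrix.from_hexamers(aligned, correct_small_sample)


# ---------------------------------------------------------------------------
# Gap surprisal and multiscan
# ---------------------------------------------------------------------------


def gap_surprisal(spacer_hist: dict, allowed_range=None) -> dict:
    """Gap penalty GS(d) = -log2(n_d/N) - min_d'(-log2(n_d'/N)) in bits.

    The modal spacing gets GS = 0.  Unobserved spacings inside
    ``allowed_range`` get a 0.5 pseudocount.
    """
    if not spacer_hist:
        raise ValueError("empty spacer histogram")
    counts = dict(spacer_hist)
    if allowed_range is not None:
        lo, hi = allowed_range
        for d in range(lo, hi + 1):
            counts.setdefault(d, 0)
    counts = {d: (c if c > 0 else 0.5) for d, c in counts.items()}
    max_count = max(counts.values())
    return {d: math.log2(max_count / c) for d, c in sorted(counts.items())}


@dataclass
class PromoterModel:
    """Learned two-hexamer promoter model."""

    minus10: InformationMatrix
    minus35: InformationMatrix
    spacer_hist: dict
    discriminator_hist: dict
    gap_penalty: dict
    contributing: list  # (tss_id, minus35_offset, minus10_offset, score)
    window_width: int = DEFAULT_WINDOW
    n_dropped: int = 0

    @property
    def modal_spacer(self) -> int:
        return max(self.spacer_hist, key=lambda d: (self.spacer_hist[d], -d))

    @property
    def modal_discriminator(self) -> int:
        return max(self.discriminator_hist, key=lambda d: (self.discriminator_hist[d], -d))

    def to_dict(self) -> dict:
        return {
            "window_width": self.window_width,
            "minus10": {
                "freq": self.minus10.freq.tolist(),
                "n": self.minus10.n,
                "per_position_information": self.minus10.per_position_information.tolist(),
                "consensus": self.minus10.consensus(),
            },
            "minus35": {
                "freq": self.minus35.freq.tolist(),
                "n": self.minus35.n,
                "per_position_information": self.minus35.per_position_information.tolist(),
                "consensus": self.minus35.consensus(),
            },
            "spacer_hist": {str(k): v for k, v in sorted(self.spacer_hist.items())},
            "discriminator_hist": {
                str(k): v for k, v in sorted(self.discriminator_hist.items())
            },
            "gap_penalty": {str(k): v for k, v in sorted(self.gap_penalty.items())},
            "n_contributing": len(self.contributing),
            "n_dropped": self.n_dropped,
        }


def minus10_offset_range(width: int, disc_range=DEFAULT_DISC_RANGE) -> list:
    """Allowed 0-based -10 hexamer offsets for a window whose last character
    is the TSS: discriminator d implies offset (width - 1) - 6 - d."""
    lo, hi = disc_range
    return [width - 7 - d for d in range(hi, lo - 1, -1)]


def discriminator_of_offset(offset: int, width: int) -> int:
    return width - 7 - offset


def multiscan(
    windows: list,
    minus10_offsets: list,
    minus10_matrix: InformationMatrix,
    prelim_minus35: InformationMatrix,
    spacer_range=DEFAULT_SPACER_RANGE,
    drop_nonconforming: bool = True,
    max_iter: int = 50,
    correct_small_sample: bool = True,
    window_width: int = DEFAULT_WINDOW,
) -> PromoterModel:
    """Place final -35 hexamers by maximizing Ri(-35) - GS(spacer).

    The -35 matrix and the gap-surprisal table are re-derived from the
    current placements and the scan repeated until placements converge.
    Windows with total score Ri(-10) + Ri(-35) - GS <= 0 are dropped when
    ``drop_nonconforming`` (after convergence), and the final model is
    rebuilt from the survivors.
    """
    codes = [w.codes if isinstance(w, PromoterSequence) else encode(w) for w in windows]
    ids = [
        w.tss_id if isinstance(w, PromoterSequence) else f"seq_{i}"
        for i, w in enumerate(windows)
    ]
    lo_s, hi_s = spacer_range
    feasible = []
    for i, (c, o10) in enumerate(zip(codes, minus10_offsets)):
        spacers = [s for s in range(lo_s, hi_s + 1) if o10 - 6 - s >= 0]
        if not spacers:
            continue
        feasible.append(i)
    if not feasible:
        raise ValueError("no window admits the spacer range")

    m35 = prelim_minus35
    gs = {s: 0.0 for s in range(lo_s, hi_s + 1)}
    placements = {i: None for i in feasible}
    for _ in range(max_iter):
        new_placements = {}
        for i in feasible:
            o10 = minus10_offsets[i]
            best = None
            for s in range(lo_s, hi_s + 1):
                o35 = o10 - 6 - s
                if o35 < 0:
                    continue
                ri = individual_information(m35, codes[i][o35 : o35 + 6])
                score = ri - gs.get(s, 0.0)
                if best is None or score > best[0] or (
                    score == best[0] and s < best[1]
                ):
                    best = (score, s, o35)
            new_placements[i] = (best[1], best[2])
        converged = new_placements == placements
        placements = new_placements
        hexes = np.stack([codes[i][placements[i][1] : placements[i][1] + 6] for i in feasible])
        m35 = InformationMatrix.from_hexamers(hexes, correct_small_sample)
        hist: dict = {}
        for i in feasible:
            hist[placements[i][0]] = hist.get(placements[i][0], 0) + 1
        gs = gap_surprisal(hist, allowed_range=spacer_range)
        if converged:
            break

    contributing, dropped = [], 0
    for i in feasible:
        s, o35 = placements[i]
        o10 = minus10_offsets[i]
        total = (
            individual_information(minus10_matrix, codes[i][o10 : o10 + 6])
            + individual_information(m35, codes[i][o35 : o35 + 6])
            - gs.get(s, 0.0)
        )
        if drop_nonconforming and total <= 0:
            dropped += 1
            continue
        contributing.append((ids[i], o35, o10, float(total)))

    if not contributing:
        raise ValueError("all windows dropped as non-conforming")
    keep_idx = [i for i in feasible if ids[i] in {c[0] for c in contributing}]
    hex10 = np.stack([codes[i][minus10_offsets[i] : minus10_offsets[i] + 6] for i in keep_idx])
    hex35 = np.stack([codes[i][placements[i][1] : placements[i][1] + 6] for i in keep_idx])
    spacer_hist: dict = {}
    disc_hist: dict = {}
    for i in keep_idx:
        spacer_hist[placements[i][0]] = spacer_hist.get(placements[i][0], 0) + 1
        d = discriminator_of_offset(minus10_offsets[i], window_width)
        disc_hist[d] = disc_hist.get(d, 0) + 1
    return PromoterModel(
        minus10=InformationMatrix.from_hexamers(hex10, correct_small_sample),
        minus35=InformationMatrix.from_hexamers(hex35, correct_small_sample),
        spacer_hist=spacer_hist,
        discriminator_hist=disc_hist,
        gap_penalty=gap_surprisal(spacer_hist, allowed_range=spacer_range),
        contributing=contributing,
        window_width=window_width,
        n_dropped=dropped,
    )


def build_promoter_model(
    windows: list,
    seed: int = 0,
    width: int = DEFAULT_WINDOW,
    disc_range=DEFAULT_DISC_RANGE,
    spacer_range=DEFAULT_SPACER_RANGE,
    assumed_spacer: int = 17,
    tol: float = 0.01,
    max_passes: int = 100,
    drop_nonconforming: bool = True,
    min_surviving: int = 10,
) -> PromoterModel:
    """Full pipeline: malign the -10, drop non-scoring windows, build and
    malign-optimize a preliminary -35, then finalize with multiscan."""
    rng = np.random.default_rng(seed)
    seqs = [w.window if isinstance(w, PromoterSequence) else w for w in windows]
    if any(len(s) != width for s in seqs):
        raise ValueError(f"all windows must have width {width}")
    off10_range = minus10_offset_range(width, disc_range)
    offsets10, m10 = malign(
        seqs, off10_range, seed=rng, tol=tol, max_passes=max_passes
    )

    survivors = []
    for i, (s, o) in enumerate(zip(seqs, offsets10)):
        if individual_information(m10, s[o : o + 6]) > 0:
            survivors.append(i)
    if len(survivors) < min_surviving:
        raise ValueError(
            f"only {len(survivors)} windows carry a scoring -10 element"
        )
    kept_windows = [windows[i] for i in survivors]
    kept_seqs = [seqs[i] for i in survivors]
    kept_off10 = [offsets10[i] for i in survivors]

    # preliminary -35: implied by an assumed spacer, then malign-optimized
    # over the spacer-compatible offsets of each window
    lo_s, hi_s = spacer_range
    off35_lists = []
    m35_windows_idx = []
    for i, o10 in enumerate(kept_off10):
        offs = [o10 - 6 - s for s in range(lo_s, hi_s + 1) if o10 - 6 - s >= 0]
        if offs:
            off35_lists.append(sorted(offs))
            m35_windows_idx.append(i)
    prelim_hexes = []
    for i in m35_windows_idx:
        o35 = kept_off10[i] - 6 - assumed_spacer
        if o35 >= 0:
            prelim_hexes.append(encode(kept_seqs[i][o35 : o35 + 6]))
    if len(prelim_hexes) >= 2:
        prelim35 = InformationMatrix.from_hexamers(np.stack(prelim_hexes))
    else:
        prelim35 = InformationMatrix.from_counts(np.zeros((4, 6)), 2)
    off35_opt, m35 = malign(
        [kept_seqs[i] for i in m35_windows_idx],
        off35_lists,
        seed=rng,
        tol=tol,
        max_passes=max_passes,
    )
    # seed multiscan with the malign-optimized -35 matrix (falls back to the
    # assumed-spacer profile when the optimization had too few windows)
    prelim35 = m35 if m35.n >= 2 else prelim35

    return multiscan(
        kept_windows if isinstance(windows[0], PromoterSequence) else kept_seqs,
        kept_off10,
        minus10_matrix=m10,
        prelim_minus35=prelim35,
        spacer_range=spacer_range,
        drop_nonconforming=drop_nonconforming,
        window_width=width,
    )


def write_pfm(matrix: InformationMatrix, path, name: str = "motif") -> None:
    """Plain-text position frequency matrix (logo-ready)."""
    with open(path, "w") as fh:
        fh.write(f"# PFM {name}; rows A C G T; n={matrix.n}\n")
        fh.write("PO\t" + "\t".join(str(i + 1) for i in range(matrix.width)) + "\n")
        for b, row in zip(BASES, matrix.freq):
            fh.write(b + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
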