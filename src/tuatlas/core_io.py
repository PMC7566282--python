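"""Data model and file I/O for end-coverage-based transcript boundary mapping.

Coordinate conventions used throughout the package:

* Internal coordinates are 1-based inclusive (GenBank style).  BED and
  bedGraph files are converted at the I/O boundary (0-based half-open).
* Strand is ``"+"`` or ``"-"``.  "Downstream" of position ``p`` means
  ``p+1`` on the plus strand and ``p-1`` on the minus strand, everywhere.
* Replicons are treated as linear; windows are truncated at replicon ends.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = ("+", "-")

_VALID_BASES = set("ACGTN")


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """One replicon: a chromosome or plasmid sequence."""

    replicon_id: str
    sequence: str
    is_circular: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"replicon {self.replicon_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive slice; reverse-complemented for the minus strand."""
        if start < 1 or end > self.length or start > end:
            raise ValidationError(
                f"subseq [{start},{end}] out of range for {self.replicon_id}"
                f" (length {self.length})"
            )
        s = self.sequence[start - 1 : end]
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


@dataclass(frozen=True)
class GeneRecord:
    """A gene with strand-aware translation start coordinate."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )

    @property
    def start_codon_pos(self) -> int:
        """First base of the start codon: `start` on +, `end` on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class SiteCall:
    """A called genomic RNA end (TSS, preliminary 3' terminus, 5'P site, TTS)."""

    replicon_id: str
    position: int
    strand: str
    site_kind: str
    p_value: float = float("nan")
    fdr: float = float("nan")
    mean_signal: float = float("nan")
    conditions_detected: frozenset = field(default_factory=frozenset)

    SITE_KINDS = (
        "tss_primary",
        "tss_secondary",
        "prelim_3prime",
        "monophosphate_5p",
        "processing",
        "tts",
    )

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"site at {self.position}: bad strand")
        if self.site_kind not in self.SITE_KINDS:
            raise ValidationError(f"unknown site_kind {self.site_kind!r}")
        object.__setattr__(
            self, "conditions_detected", frozenset(self.conditions_detected)
        )

    @property
    def key(self) -> tuple:
        return (self.replicon_id, self.position, self.strand)

    def with_kind(self, kind: str) -> "SiteCall":
        return replace(self, site_kind=kind)


@dataclass(frozen=True)
class TerminatorPrediction:
    """A predicted intrinsic terminator (hairpin plus 12-nt 3' flank)."""

    terminator_id: str
    replicon_id: str
    strand: str
    hairpin_start: int
    hairpin_end: int
    confidence: int
    stem_len: int = 0
    loop_len: int = 0
    tail_seq: str = ""

    def __post_init__(self) -> None:
        if self.hairpin_start > self.hairpin_end:
            raise ValidationError(
                f"terminator {self.terminator_id}: hairpin_start > hairpin_end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"terminator {self.terminator_id}: bad strand")

    @property
    def genomic_3prime_flank_start(self) -> int:
        """First genomic position of the 3' flank, in transcript orientation."""
        return self.hairpin_end + 1 if self.strand == "+" else self.hairpin_start - 1


class EndCoverageTrack:
    """Strand-specific per-position counts of RNA end events for one library.

    Counts are dense ``int64`` arrays per (replicon, strand); index ``i``
    holds the count at 1-based position ``i + 1``.
    """

    def __init__(
        self,
        library_id: str,
        condition_id: str,
        replicate_id: str,
        library_kind: str,
        lengths: dict,
    ):
        if library_kind not in ("tss_treated", "tss_untreated", "termseq"):
            raise ValidationError(f"unknown library_kind {library_kind!r}")
        self.library_id = library_id
        self.condition_id = condition_id
        self.replicate_id = replicate_id
        self.library_kind = library_kind
        self.lengths = dict(lengths)
        self.counts = {
            (rep, s): np.zeros(n, dtype=np.int64)
            for rep, n in self.lengths.items()
            for s in STRANDS
        }

    def get(self, replicon_id: str, strand: str) -> np.ndarray:
        return self.counts[(replicon_id, strand)]

    def set_count(self, replicon_id: str, strand: str, position: int, value: int) -> None:
        if value < 0:
            raise ValidationError(f"negative count at {replicon_id}:{position}")
        n = self.lengths[replicon_id]
        if not (1 <= position <= n):
            raise ValidationError(
                f"position {position} outside {replicon_id} (length {n})"
            )
        self.counts[(replicon_id, strand)][position - 1] = value

    def add_count(self, replicon_id: str, strand: str, position: int, value: int) -> None:
        cur = int(self.counts[(replicon_id, strand)][position - 1])
        self.set_count(replicon_id, strand, position, cur + value)

    def total(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))

    def nonzero_values(self) -> np.ndarray:
        """All nonzero counts of the library, both strands, all replicons."""
        vals = [a[a > 0] for a in self.counts.values()]
        return np.concatenate(vals) if vals else np.array([], dtype=np.int64)

    def strand_mean(self, strand: str) -> float:
        """Genome-wide mean for one strand; denominator includes zeros."""
        tot = sum(int(self.counts[(r, strand)].sum()) for r in self.lengths)
        n = sum(self.lengths.values())
        return tot / n if n else 0.0

    def replicon_strand_mean(self, replicon_id: str, strand: str) -> float:
        n = self.lengths[replicon_id]
        return float(self.counts[(replicon_id, strand)].sum()) / n if n else 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EndCoverageTrack):
            return NotImplemented
        return (
            self.lengths == other.lengths
            and all(
                np.array_equal(self.counts[k], other.counts[k]) for k in self.counts
            )
        )


# ---------------------------------------------------------------------------
# Genome and annotation readers
# ---------------------------------------------------------------------------


def read_genome_fasta(path) -> dict:
    """Read a (multi-)FASTA into ``{replicon_id: GenomeSequence}``."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValidationError(f"duplicate replicon id {rec.id!r}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not genome:
        raise ParseError(f"no FASTA records in {path}")
    return genome


def write_genome_fasta(genome: dict, path) -> None:
    with open(path, "w") as fh:
        for rep in genome.values():
            fh.write(f">{rep.replicon_id}\n")
            for i in range(0, rep.length, 70):
                fh.write(rep.sequence[i : i + 70] + "\n")


_FEATURE_CLASSES = {"tRNA": "tRNA", "rRNA": "rRNA"}


def read_gene_annotations(path, format: str = "gff3", genome: dict | None = None) -> list:
    """Read gene records from GFF3 or a BED-like TSV.

    The TSV dialect has columns gene_id, replicon_id, start, end, strand,
    feature_class (header required).  GFF3 uses ``gene`` features, taking
    the class from a gene_biotype/biotype attribute when present, and
    standalone tRNA/rRNA features otherwise.
    """
    if format == "gff3":
        genes = _read_gff3_genes(path)
    elif format == "bed_like_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "replicon_id": str})
        genes = [
            GeneRecord(
                gene_id=str(r.gene_id),
                replicon_id=str(r.replicon_id),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                feature_class=str(r.feature_class),
            )
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if genome is not None:
        for g in genes:
            if g.replicon_id in genome and g.end > genome[g.replicon_id].length:
                raise ValidationError(
                    f"gene {g.gene_id} extends past end of {g.replicon_id}"
                )
    return genes


def _read_gff3_genes(path) -> list:
    genes: dict[str, GeneRecord] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("gene", "tRNA", "rRNA"):
                continue
            if strand not in STRANDS:
                raise ValidationError(f"{path}:{ln}: unknown strand {strand!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("locus_tag") or f"feature_{ln}"
            if ftype == "gene":
                fclass = attr.get("gene_biotype", attr.get("biotype", "protein_coding"))
                if fclass not in ("protein_coding", "tRNA", "rRNA"):
                    fclass = "other" if fclass != "protein_coding" else fclass
                rec = GeneRecord(gid, seqid, int(start), int(end), strand, fclass)
                if gid not in genes:
                    order.append(gid)
                genes[gid] = rec
            else:
                parent = attr.get("Parent")
                if parent and parent in genes:
                    g = genes[parent]
                    genes[parent] = replace(g, feature_class=_FEATURE_CLASSES[ftype])
                elif gid not in genes:
                    order.append(gid)
                    genes[gid] = GeneRecord(
                        gid, seqid, int(start), int(end), strand,
                        _FEATURE_CLASSES[ftype],
                    )
    return [genes[g] for g in order]


def write_gene_annotations_gff3(genes: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};gene_biotype={g.feature_class}"
            fh.write(
                f"{g.replicon_id}\ttuatlas\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# End-coverage track I/O
# ---------------------------------------------------------------------------


def read_end_coverage(
    paths,
    dialect: str,
    library_meta: dict,
    lengths: dict,
) -> EndCoverageTrack:
    """Read a strand-specific end-coverage track.

    ``paths`` is a ``(plus_file, minus_file)`` pair for both dialects.
    ``bedgraph_pair`` files are standard 0-based half-open bedGraph;
    ``per_base_depth`` files have 3 columns (replicon, 1-based position,
    count), the per-base "depth" dialect.
    """
    if dialect not in ("bedgraph_pair", "per_base_depth"):
        raise ValueError(f"unknown dialect {dialect!r}")
    plus_path, minus_path = paths
    track = EndCoverageTrack(
        library_id=library_meta["library_id"],
        condition_id=library_meta.get("condition_id", ""),
        replicate_id=library_meta.get("replicate_id", ""),
        library_kind=library_meta.get("library_kind", "tss_treated"),
        lengths=lengths,
    )
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        _read_one_coverage_file(path, strand, dialect, track)
    return track


def _read_one_coverage_file(path, strand, dialect, track) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            try:
                if dialect == "bedgraph_pair":
                    if len(parts) != 4:
                        raise ValueError("expected 4 bedGraph columns")
                    rep, start0, end0, val = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                    if val < 0:
                        raise ValidationError(f"{path}:{ln}: negative count")
                    for pos in range(start0 + 1, end0 + 1):  # 0-based half-open -> 1-based
                        track.set_count(rep, strand, pos, val)
                else:
                    if len(parts) != 3:
                        raise ValueError("expected 3 depth columns")
                    rep, pos, val = parts[0], int(parts[1]), int(parts[2])
                    if val < 0:
                        raise ValidationError(f"{path}:{ln}: negative count")
                    track.set_count(rep, strand, pos, val)
            except ValidationError:
                raise
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc


def write_end_coverage(track: EndCoverageTrack, plus_path, minus_path, dialect: str) -> None:
    """Write a track as a (plus, minus) file pair in either dialect."""
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path, "w") as fh:
            for rep in sorted(track.lengths):
                arr = track.get(rep, strand)
                if dialect == "per_base_depth":
                    for idx in np.flatnonzero(arr):
                        fh.write(f"{rep}\t{idx + 1}\t{arr[idx]}\n")
                elif dialect == "bedgraph_pair":
                    for start0, end0, val in _runs(arr):
                        fh.write(f"{rep}\t{start0}\t{end0}\t{val}\n")
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")


def _runs(arr: np.ndarray):
    """Yield (start0, end0, value) runs of equal nonzero values."""
    nz = np.flatnonzero(arr)
    if nz.size == 0:
        return
    run_start = nz[0]
    prev = nz[0]
    for idx in nz[1:]:
        if idx == prev + 1 and arr[idx] == arr[run_start]:
            prev = idx
            continue
        yield int(run_start), int(prev + 1), int(arr[run_start])
        run_start = prev = idx
    yield int(run_start), int(prev + 1), int(arr[run_start])


# ---------------------------------------------------------------------------
# Terminator predictions
# ---------------------------------------------------------------------------


def read_transterm_output(path, genome: dict | None = None) -> list:
    """Parse TransTermHP report output (or the equivalent TSV).

    The report layout is detected from a leading ``TERM`` token; otherwise
    the file is read as a TSV with columns terminator_id, replicon_id,
    strand, hairpin_start, hairpin_end, confidence and optional stem_len,
    loop_len.  When a genome is supplied, the 12-nt 3'-flanking tail
    (8-nt U tract plus 4 nt downstream) is extracted in transcript
    orientation.
    """
    with open(path) as fh:
        text = fh.read()
    if "TERM" in text.split("\n", 50)[0] or "\n  TERM" in text or text.lstrip().startswith("TERM"):
        preds = _parse_transterm_report(text, path)
    else:
        preds = _parse_terminator_tsv(path)
    if genome is not None:
        preds = [replace(p, tail_seq=_tail_seq(p, genome)) for p in preds]
    return preds


def _tail_seq(p: TerminatorPrediction, genome: dict, width: int = 12) -> str:
    rep = genome[p.replicon_id]
    if p.strand == "+":
        lo, hi = p.hairpin_end + 1, p.hairpin_end + width
    else:
        lo, hi = p.hairpin_start - width, p.hairpin_start - 1
    lo, hi = max(1, lo), min(rep.length, hi)
    if lo > hi:
        return ""
    return rep.subseq(lo, hi, p.strand)


def _parse_transterm_report(text: str, path) -> list:
    preds = []
    current_seq = None
    lines = text.split("\n")
    i = 0
    while i < len(lines):
        line = lines[i]
        stripped = line.strip()
        if stripped.startswith("SEQUENCE"):
            current_seq = stripped.split()[1]
        elif stripped.startswith("TERM"):
            parts = stripped.split()
            # TERM <n> <start> - <end> <strand> <region> <conf> <dG...>
            try:
                term_num = parts[1]
                start = int(parts[2])
                assert parts[3] == "-"
                end = int(parts[4])
                strand = parts[5]
                conf = int(parts[7])
            except (IndexError, ValueError, AssertionError) as exc:
                raise ParseError(f"{path}: malformed TERM record: {stripped!r}") from exc
            if strand not in STRANDS:
                raise ValidationError(f"{path}: bad strand in {stripped!r}")
            lo, hi = min(start, end), max(start, end)
            stem_len = loop_len = 0
            # optional context line: 5'-flank  stem1 loop stem2  3'-flank
            if i + 1 < len(lines):
                ctx = lines[i + 1].split()
                if len(ctx) == 5 and all(set(c) <= set("ACGTN-") for c in ctx):
                    stem_len = len(ctx[1])
                    loop_len = len(ctx[2])
                    i += 1
            if current_seq is None:
                raise ParseError(f"{path}: TERM record before any SEQUENCE line")
            preds.append(
                TerminatorPrediction(
                    terminator_id=f"TERM_{term_num}",
                    replicon_id=current_seq,
                    strand=strand,
                    hairpin_start=lo,
                    hairpin_end=hi,
                    confidence=conf,
                    stem_len=stem_len,
                    loop_len=loop_len,
                )
            )
        i += 1
    return preds


def _parse_terminator_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = {"terminator_id", "replicon_id", "strand", "hairpin_start", "hairpin_end", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing terminator columns {sorted(missing)}")
    if df["confidence"].isna().any():
        raise ParseError(f"{path}: record missing confidence")
    preds = []
    for r in df.itertuples():
        preds.append(
            TerminatorPrediction(
                terminator_id=str(r.terminator_id),
                replicon_id=str(r.replicon_id),
                strand=str(r.strand),
                hairpin_start=int(r.hairpin_start),
                hairpin_end=int(r.hairpin_end),
                confidence=int(r.confidence),
                stem_len=int(getattr(r, "stem_len", 0) or 0),
                loop_len=int(getattr(r, "loop_len", 0) or 0),
            )
        )
    return preds


def write_terminator_tsv(preds: list, path) -> None:
    rows = [
        dict(
            terminator_id=p.terminator_id, replicon_id=p.replicon_id, strand=p.strand,
            hairpin_start=p.hairpin_start, hairpin_end=p.hairpin_end,
            confidence=p.confidence, stem_len=p.stem_len, loop_len=p.loop_len,
            tail_seq=p.tail_seq,
        )
        for p in preds
    ]
    pd.DataFrame(
        rows,
        columns=[
            "terminator_id", "replicon_id", "strand", "hairpin_start",
            "hairpin_end", "confidence", "stem_len", "loop_len", "tail_seq",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site catalogs
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "replicon_id", "position", "strand", "site_kind",
    "p_value", "fdr", "mean_signal", "conditions_detected",
]


def bed_score(fdr: float) -> int:
    """BED score column: round(-10*log10(fdr)), capped at 1000."""
    if not np.isfinite(fdr) or fdr <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(fdr))))


def write_site_catalog(sites: list, path, format: str = "tsv") -> None:
    """Write a site catalog as TSV (all fields) or BED6 (single-base features)."""
    sites = sorted(sites, key=lambda s: (s.replicon_id, s.position, s.strand))
    if format == "tsv":
        rows = [
            dict(
                replicon_id=s.replicon_id, position=s.position, strand=s.strand,
                site_kind=s.site_kind, p_value=s.p_value, fdr=s.fdr,
                mean_signal=s.mean_signal,
                conditions_detected=",".join(sorted(s.conditions_detected)),
            )
            for s in sites
        ]
        pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "bed6":
        with open(path, "w") as fh:
            fh.write('track name="tuatlas_sites"\n')
            for i, s in enumerate(sites):
                name = f"{s.site_kind}_{i + 1}"
                fh.write(
                    f"{s.replicon_id}\t{s.position - 1}\t{s.position}\t"
                    f"{name}\t{bed_score(s.fdr)}\t{s.strand}\n"
                )
    else:
        raise ValueError(f"unknown catalog format {format!r}")


def read_site_catalog(path) -> list:
    """Read a TSV site catalog written by :func:`write_site_catalog`."""
    df = pd.read_csv(path, sep="\t", dtype={"replicon_id": str})
    sites = []
    for r in df.itertuples():
        conds = r.conditions_detected
        conds = frozenset() if pd.isna(conds) or conds == "" else frozenset(str(conds).split(","))
        sites.append(
            SiteCall(
                replicon_id=str(r.replicon_id), position=int(r.position),
                strand=str(r.strand), site_kind=str(r.site_kind),
                p_value=float(r.p_value), fdr=float(r.fdr),
                mean_signal=float(r.mean_signal), conditions_detected=conds,
            )
        )
    return sites


def downstream(position: int, strand: str, offset: int = 1) -> int:
    """Position `offset` nt downstream of `position` in transcript orientation."""
    return position + offset if strand == "+" else position - offset


def upstream(position: int, strand: str, offset: int = 1) -> int:
    return position - offset if strand == "+" else position + offset
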