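"""Domain types shared across the pipeline, plus readers/writers for the
standard on-disk formats it touches.

Coordinate convention
---------------------
Every on-disk format and every public dataclass uses GFF3-style coordinates:
1-based, inclusive on both ends.  Internal interval arithmetic (sequence
slicing, depth arrays) uses 0-based half-open coordinates.  Conversion
between the two happens in exactly one place: :func:`to_slice` /
:func:`from_slice`.  BED input, which is natively 0-based half-open, is
converted to 1-based inclusive at read time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-")

ACCURACY_CLASSES = ("conserved", "slightly_conserved", "hypothetical", "predicted")
#: ordering used when two overlapping single-predictor models compete
ACCURACY_RANK = {c: r for r, c in enumerate(reversed(ACCURACY_CLASSES))}


class PipelineError(ValueError):
    """Raised on malformed input or infeasible configuration."""


# ---------------------------------------------------------------------------
# coordinate conversion — the single authorised place
# ---------------------------------------------------------------------------

def to_slice(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open slice bounds."""
    return start - 1, end


def from_slice(lo: int, hi: int) -> tuple[int, int]:
    """0-based half-open slice bounds -> 1-based inclusive interval."""
    return lo + 1, hi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig (supercontig/chromosome) over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PipelineError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise PipelineError(
                f"contig {self.contig_id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A strand-aware genomic interval with predictor provenance and
    (optionally) homology evidence and an annotation-accuracy class.
    """

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    predictors: frozenset[str] = frozenset()
    best_homolog: Optional[tuple[str, float]] = None
    accuracy_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PipelineError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise PipelineError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def coords(self) -> tuple[str, str, int, int]:
        return (self.contig_id, self.strand, self.start, self.end)

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Coding-strand sequence of the model."""
        lo, hi = to_slice(self.start, self.end)
        seq = genome[self.contig_id][lo:hi]
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


@dataclass(frozen=True)
class SimilarityHit:
    """One query->subject protein comparison, aggregated over its HSPs."""

    query_id: str
    subject_id: str
    evalue: float
    hsp_total_length: int
    query_length: Optional[int] = None
    subject_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise PipelineError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )

    def coverage(self) -> float:
        """HSP coverage of the *shorter* of the two sequences."""
        if self.query_length is None or self.subject_length is None:
            raise PipelineError(
                f"hit {self.query_id}->{self.subject_id}: sequence lengths "
                "required for coverage but not supplied"
            )
        return self.hsp_total_length / min(self.query_length, self.subject_length)


@dataclass(frozen=True)
class ProteinFamily:
    """A merged triangle-clustered set of (species_id, protein_id) members."""

    family_id: str
    members: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise PipelineError(
                f"family {self.family_id!r}: fewer than 3 members"
            )


@dataclass
class StrandedCounts:
    """Raw per-gene tag counts, genes x samples, split by strand class.

    ``sense`` and ``antisense`` are DataFrames with identical index
    (gene_id) and columns (sample_id).  ``sample_summary`` carries the
    alignment accounting per sample: total_reads, aligned_reads,
    uniquely_aligned_reads, rrna_filtered_reads.
    """

    sense: pd.DataFrame
    antisense: pd.DataFrame
    sample_summary: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sense.index.equals(self.antisense.index) or not list(
            self.sense.columns
        ) == list(self.antisense.columns):
            raise PipelineError("sense/antisense matrices are not aligned")
        ss = self.sample_summary
        if len(ss):
            ok = (
                (ss["uniquely_aligned_reads"] <= ss["aligned_reads"])
                & (ss["aligned_reads"] <= ss["total_reads"])
            ).all()
            if not ok:
                raise PipelineError(
                    "sample summary violates unique <= aligned <= total"
                )


@dataclass
class NormalizedCounts:
    """Upper-quartile normalized expression, same shape as StrandedCounts."""

    sense: pd.DataFrame
    antisense: pd.DataFrame
    upper_quartile: pd.Series  # per sample


@dataclass
class TranscribedContig:
    """A strand-specific run of expressed bases."""

    contig_id: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    mean_depth: float
    klass: Optional[str] = None  # genic_sense | antisense | intergenic

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PipelineConfig:
    """Every tunable cut-off of the pipeline, with its published default."""

    min_protein_aa: int = 60
    max_internal_gap_nt: int = 10  # consecutive N that disqualify a model
    homolog_evalue: float = 1e-10
    family_evalue: float = 1e-20
    family_min_coverage: float = 0.50
    nonortholog_evalue: float = 1e-5
    interrupted_max_gap_bp: int = 600
    read_len: int = 50
    half_len: int = 25
    max_mismatch_5prime: int = 2
    heg_uq_threshold: float = 10.0
    min_contig_bp: int = 181
    min_expressed_depth: int = 2
    pathway_heg_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_protein_aa",
            "max_internal_gap_nt",
            "homolog_evalue",
            "family_evalue",
            "family_min_coverage",
            "nonortholog_evalue",
            "interrupted_max_gap_bp",
            "read_len",
            "half_len",
            "max_mismatch_5prime",
            "heg_uq_threshold",
            "min_contig_bp",
            "min_expressed_depth",
            "pathway_heg_fraction",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config field {name} must be positive")

    @property
    def min_gene_nt(self) -> int:
        return self.min_protein_aa * 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def gc_fraction(seq: str) -> float:
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc / acgt if acgt else 0.0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records.

    Sequences are uppercased and U is mapped to T; duplicate ids and
    characters outside {A,C,G,T,N} are hard errors.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise PipelineError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeSequence(rec.id, seq))
    return records


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]],
                path: str | Path) -> None:
    out = []
    for rec in records:
        if isinstance(rec, GenomeSequence):
            out.append(SeqRecord(Seq(rec.sequence), id=rec.contig_id, description=""))
        else:
            name, seq = rec
            out.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(out, str(path), "fasta-2line")


def genome_dict(records: Iterable[GenomeSequence]) -> dict[str, str]:
    return {r.contig_id: r.sequence for r in records}


# ---------------------------------------------------------------------------
# GFF3 (flat gene-style features only)
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read flat gene features from GFF3.

    The source column is recorded as the predictor tag.  Multi-level
    gene/mRNA/CDS hierarchies are out of scope: every non-comment line is
    treated as one independent feature.
    """
    genes: list[GeneModel] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        feat = feature_from_line(line)
        if feat.start > feat.end:
            raise PipelineError(f"{path}: start > end in line {line!r}")
        if feat.strand not in STRANDS:
            raise PipelineError(
                f"{path}: unknown strand {feat.strand!r} in line {line!r}"
            )
        attrs = dict(feat.attributes)
        gene_id = attrs.get("ID", [f"{feat.seqid}:{feat.start}-{feat.end}"])[0]
        # gffutils splits comma-separated attribute values already
        predictors = frozenset(
            attrs["predictors"] if "predictors" in attrs else [feat.source]
        )
        best = None
        if "best_homolog" in attrs:
            subj, ev = attrs["best_homolog"][0].split("|evalue=")
            best = (subj, float(ev))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                predictors=predictors,
                best_homolog=best,
                accuracy_class=attrs.get("accuracy_class", [None])[0],
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               feature_type: str = "gene") -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = [f"ID={g.gene_id}"]
        if g.predictors:
            attrs.append(f"predictors={','.join(sorted(g.predictors))}")
        if g.accuracy_class:
            attrs.append(f"accuracy_class={g.accuracy_class}")
        if g.best_homolog:
            attrs.append(f"best_homolog={g.best_homolog[0]}|evalue={g.best_homolog[1]:g}")
        source = ",".join(sorted(g.predictors)) if g.predictors else "."
        lines.append(
            f"{g.contig_id}\t{source}\t{feature_type}\t{g.start}\t{g.end}"
            f"\t.\t{g.strand}\t.\t{';'.join(attrs)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_contigs_gff3(contigs: Iterable[TranscribedContig],
                       path: str | Path) -> None:
    """Export discovered transcribed regions as flat GFF3 features."""
    lines = ["##gff-version 3"]
    for i, c in enumerate(contigs):
        attrs = f"ID=tr{i:06d};mean_depth={c.mean_depth:.3f}"
        if c.klass:
            attrs += f";klass={c.klass}"
        lines.append(
            f"{c.contig_id}\tutiliseq\ttranscribed_region\t{c.start}\t{c.end}"
            f"\t.\t{c.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular similarity hits (12-column, BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

_HIT_COLS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path,
              lengths: Mapping[str, int] | str | Path | None = None,
              ) -> list[SimilarityHit]:
    """Read 12-column tabular similarity output.

    Multiple HSP rows per (query, subject) pair are aggregated into one
    hit: e-value is the minimum over HSPs, hsp_total_length the sum of
    alignment lengths.  Self-hits are dropped.

    ``lengths`` optionally supplies per-sequence (aa) lengths — either a
    mapping or a 2-column TSV path — used downstream for coverage.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_HIT_COLS,
                         comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if (df["evalue"] < 0).any():
        raise PipelineError(f"{path}: negative e-value")
    df = df[df["query_id"] != df["subject_id"]]
    if isinstance(lengths, (str, Path)):
        ldf = pd.read_csv(lengths, sep="\t", header=None,
                          names=["seq_id", "aa_len"])
        lengths = dict(zip(ldf["seq_id"], ldf["aa_len"]))
    agg = df.groupby(["query_id", "subject_id"], sort=True).agg(
        evalue=("evalue", "min"), hsp_total_length=("length", "sum")
    )
    hits = []
    for (q, s), row in agg.iterrows():
        ql = sl = None
        if lengths is not None:
            ql = lengths.get(q)
            sl = lengths.get(s)
        hits.append(
            SimilarityHit(q, s, float(row["evalue"]),
                          int(row["hsp_total_length"]), ql, sl)
        )
    return hits


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write aggregated hits back out as one 12-column row per pair."""
    rows = []
    for h in hits:
        rows.append(
            f"{h.query_id}\t{h.subject_id}\t100.0\t{h.hsp_total_length}"
            f"\t0\t0\t1\t{h.hsp_total_length}\t1\t{h.hsp_total_length}"
            f"\t{h.evalue:g}\t0.0"
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# BED (rRNA intervals) and pathway membership
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+-column BED file; returns 1-based inclusive intervals."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PipelineError(f"{path}:{ln}: fewer than 3 BED columns")
        try:
            lo, hi = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise PipelineError(f"{path}:{ln}: non-integer coordinates") from exc
        if lo >= hi or lo < 0:
            raise PipelineError(f"{path}:{ln}: invalid interval {lo}-{hi}")
        start, end = from_slice(lo, hi)
        out.append((parts[0], start, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    lines = []
    for contig, start, end in intervals:
        lo, hi = to_slice(start, end)
        lines.append(f"{contig}\t{lo}\t{hi}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_pathways(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV (pathway_id <TAB> gene_id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway_id", "gene_id"])
    out: dict[str, set[str]] = {}
    for pw, gid in zip(df["pathway_id"], df["gene_id"]):
        out.setdefault(str(pw), set()).add(str(gid))
    return out


def write_pathways(pathways: Mapping[str, set[str]], path: str | Path) -> None:
    lines = []
    for pw in sorted(pathways):
        for g in sorted(pathways[pw]):
            lines.append(f"{pw}\t{g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
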