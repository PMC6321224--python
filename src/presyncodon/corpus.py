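"""Training-corpus construction from CDS FASTA files.

Pipeline: read and validate nucleotide coding sequences, drop short genes,
cluster the remaining proteins by global-alignment identity (greedy
longest-first, the strategy CD-HIT uses), keep only clusters with at least a
minimum number of homologs (a guard against horizontally transferred
singletons), and return one representative per surviving cluster.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genetics import STANDARD_CODE, CodonError, GeneticCode, translate

logger = logging.getLogger(__name__)


class InvalidCdsError(ValueError):
    """A single CDS record failed validation."""


class CorpusError(ValueError):
    """Corpus-level failure (no valid records, empty corpus after filters)."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence: codons plus cached translation."""

    id: str
    codons: tuple[str, ...]
    protein: str

    @classmethod
    def from_nucleotide(
        cls, rec_id: str, seq, code: GeneticCode = STANDARD_CODE
    ) -> "CodingSequence":
        """Validate and split a nucleotide sequence into codons.

        Rejects sequences whose length is not a multiple of 3, that contain
        ambiguity characters (N etc.), or that contain an internal stop. A
        single trailing stop codon is dropped.
        """
        s = str(seq).upper().replace("U", "T")
        if len(s) == 0:
            raise InvalidCdsError("empty sequence")
        if len(s) % 3 != 0:
            raise InvalidCdsError(f"length {len(s)} not a multiple of 3")
        bad = sorted(set(s) - set("ACGT"))
        if bad:
            raise InvalidCdsError(f"ambiguous or invalid characters: {bad}")
        codons = tuple(s[i : i + 3] for i in range(0, len(s), 3))
        protein = translate(codons, code)  # raises CodonError on internal stop
        if codons[-1] in code.stop_codons:
            codons = codons[:-1]
        if not codons:
            raise InvalidCdsError("no sense codons (stop codon only)")
        return cls(id=rec_id, codons=codons, protein=protein)

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def nucleotide(self) -> str:
        return "".join(self.codons)


@dataclass
class ReadReport:
    """Summary of a FASTA read: record counts and per-record rejections."""

    n_records: int
    n_valid: int
    rejections: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def read_cds_fasta(
    path, code: GeneticCode = STANDARD_CODE
) -> tuple[list[CodingSequence], ReadReport]:
    """Read a (plain or gzipped) multi-FASTA of nucleotide CDS records.

    Records failing validation are skipped and listed in the returned
    :class:`ReadReport`. Raises :class:`CorpusError` if no record is valid.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    records: list[CodingSequence] = []
    rejections: list[tuple[str, str]] = []
    n = 0
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            n += 1
            try:
                records.append(CodingSequence.from_nucleotide(rec.id, rec.seq, code))
            except (InvalidCdsError, CodonError) as exc:
                rejections.append((rec.id, str(exc)))
    if not records:
        raise CorpusError(
            f"no valid CDS records in {path} ({len(rejections)} rejected of {n})"
        )
    if rejections:
        logger.info("read %s: %d valid, %d rejected", path, len(records), len(rejections))
    return records, ReadReport(n_records=n, n_valid=len(records), rejections=rejections)


def write_cds_fasta(records: Iterable[CodingSequence], path, append_stop: str | None = None) -> None:
    """Write coding sequences as plain FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.nucleotide + (append_stop or "")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Identity clustering
# ---------------------------------------------------------------------------


def make_protein_aligner(matrix_name: str = "BLOSUM62") -> PairwiseAligner:
    """Global Needleman–Wunsch aligner (BLOSUM62, gap open 10 / extend 1)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global identity of two proteins: matched columns / alignment length."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if aligner is None:
        aligner = make_protein_aligner()
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_by_identity(
    proteins: Sequence[str],
    ids: Sequence[str] | None = None,
    threshold: float = 0.40,
    aligner: PairwiseAligner | None = None,
) -> list[list[int]]:
    """Greedy longest-first single-pass clustering by global identity.

    Sequences are processed in order of decreasing length (ties broken by id);
    each joins the first existing cluster whose representative (founder)
    shares more than ``threshold`` identity, else founds a new cluster.
    Returns clusters as lists of input indices, representative first.
    """
    if len(proteins) == 0:
        raise CorpusError("cannot cluster an empty sequence list")
    if ids is None:
        ids = [str(i) for i in range(len(proteins))]
    if aligner is None:
        aligner = make_protein_aligner()
    order = sorted(range(len(proteins)), key=lambda i: (-len(proteins[i]), ids[i]))
    clusters: list[list[int]] = []
    for i in order:
        for cluster in clusters:
            rep = cluster[0]
            if pairwise_identity(proteins[i], proteins[rep], aligner) > threshold:
                cluster.append(i)
                break
        else:
            clusters.append([i])
    return clusters


# ---------------------------------------------------------------------------
# Corpus filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusConfig:
    """Filter parameters for the non-redundant training corpus.

    ``min_codons``: genes must be strictly longer than this many sense codons.
    ``identity_threshold``: protein identity above which two genes are
    redundant (clustered together). ``min_cluster_size``: minimum number of
    homologs a cluster needs for its representative to be kept.
    """

    min_codons: int = 100
    identity_threshold: float = 0.40
    min_cluster_size: int = 3

    def __post_init__(self):
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.min_codons < 0:
            raise ValueError("min_codons must be nonnegative")


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_out: int


@dataclass
class CorpusResult:
    """Non-redundant corpus plus the stage-by-stage attrition report."""

    corpus: list[CodingSequence]
    attrition: list[StageCount]
    clusters: list[list[str]]  # gene ids per cluster (all clusters, rep first)


def build_corpus(
    raw: Sequence[CodingSequence],
    config: CorpusConfig = CorpusConfig(),
    aligner: PairwiseAligner | None = None,
) -> CorpusResult:
    """Apply length, redundancy, and homolog-count filters to raw genes.

    Returns one representative (the cluster founder: longest member, ties by
    lexicographic id) per cluster with at least ``min_cluster_size`` members.
    Raises :class:`CorpusError` with the attrition report if nothing survives.
    """
    attrition: list[StageCount] = []
    long_genes = [g for g in raw if len(g) > config.min_codons]
    attrition.append(StageCount("length_filter", len(raw), len(long_genes)))
    if not long_genes:
        raise CorpusError(f"empty corpus after filters; attrition: {attrition}")

    clusters_ix = cluster_by_identity(
        [g.protein for g in long_genes],
        ids=[g.id for g in long_genes],
        threshold=config.identity_threshold,
        aligner=aligner,
    )
    attrition.append(StageCount("clustering", len(long_genes), len(clusters_ix)))

    kept = [c for c in clusters_ix if len(c) >= config.min_cluster_size]
    attrition.append(StageCount("cluster_size_filter", len(clusters_ix), len(kept)))

    corpus = [long_genes[c[0]] for c in kept]
    attrition.append(StageCount("representatives", len(kept), len(corpus)))
    clusters = [[long_genes[i].id for i in c] for c in clusters_ix]
    if not corpus:
        raise CorpusError(f"empty corpus after filters; attrition: {attrition}")
    return CorpusResult(corpus=corpus, attrition=attrition, clusters=clusters)


def write_attrition(attrition: Sequence[StageCount], path) -> None:
    """Write the filter attrition report as TSV (stage, in_count, out_count)."""
    with open(path, "w") as fh:
        fh.write("stage\tin_count\tout_count\n")
        for row in attrition:
            fh.write(f"{row.stage}\t{row.n_in}\t{row.n_out}\n")
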