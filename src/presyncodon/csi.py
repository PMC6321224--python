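"""Codon selection index (CSI): context-conditioned codon usage of fragments.

Every gene in the training corpus is split into sliding peptide windows of an
odd size w (5 or 7 by default). For each distinct fragment the index records
the codon distribution observed for the middle residue and, per fragment
position, the mean background relative usage of the codons observed there.
Fragments whose middle residue is Met or Trp carry no prediction problem
(a single codon) and are excluded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import CodingSequence
from .genetics import (
    STANDARD_CODE,
    CodonUsageTable,
    GeneticCode,
    usage_table_from_corpus,
)

logger = logging.getLogger(__name__)

CSI_MAGIC = "#presyncodon-csi"
CSI_VERSION = 1

#: Decimal places used for per-position mean usage, in memory and on disk.
_MEAN_DECIMALS = 6


class CsiFormatError(ValueError):
    """Raised on malformed, wrong-magic, or wrong-version CSI files."""


@dataclass(frozen=True)
class CsiEntry:
    """Aggregate statistics for one distinct peptide fragment.

    ``middle_codon_counts`` maps each observed codon of the middle amino acid
    to its count; ``position_mean_usage[i]`` is the mean (over occurrences)
    background relative usage of the codon observed at fragment position i.
    """

    fragment: str
    middle_codon_counts: Mapping[str, int]
    position_mean_usage: tuple[float, ...]
    occurrences: int

    @property
    def middle_aa(self) -> str:
        return self.fragment[len(self.fragment) // 2]

    def middle_distribution(self, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
        """Normalized middle-codon distribution over the synonymous codons of
        the middle amino acid, in codon-lexicographic order."""
        codons = code.codons_for(self.middle_aa)
        counts = np.array([self.middle_codon_counts.get(c, 0) for c in codons], float)
        return counts / counts.sum()


@dataclass(eq=False)
class CodonSelectionIndex:
    """The per-window fragment index plus corpus background usage."""

    window: int
    entries: dict[str, CsiEntry]
    background: CodonUsageTable
    n_genes: int

    @property
    def total_occurrences(self) -> int:
        return sum(e.occurrences for e in self.entries.values())


def extract_fragments(
    gene: CodingSequence, window: int, code: GeneticCode = STANDARD_CODE
) -> list[tuple[str, str, tuple[str, ...]]]:
    """All sliding-window items of a gene (stride 1).

    Returns ``(fragment, middle_codon, position_codons)`` for every window
    position, including windows whose middle residue is non-degenerate (the
    CSI builder filters those). A gene shorter than the window yields an
    empty list.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    h = window // 2
    prot = gene.protein
    if len(prot) < window:
        logger.debug("gene %s shorter than window %d", gene.id, window)
        return []
    out = []
    for i in range(h, len(prot) - h):
        out.append(
            (prot[i - h : i + h + 1], gene.codons[i], tuple(gene.codons[i - h : i + h + 1]))
        )
    return out


def build_csi(
    corpus: Sequence[CodingSequence],
    window: int,
    code: GeneticCode = STANDARD_CODE,
    background: CodonUsageTable | None = None,
) -> CodonSelectionIndex:
    """Accumulate the CSI over a corpus.

    The background usage table defaults to the corpus' own codon usage; pass
    one explicitly to keep several indexes on a common scale.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot build a CSI from an empty corpus")
    if background is None:
        background = usage_table_from_corpus(corpus, code)
    h = window // 2
    acc: dict[str, list] = {}  # fragment -> [Counter, usage sums ndarray, occurrences]
    for gene in corpus:
        for frag, mid, pos_codons in extract_fragments(gene, window, code):
            if frag[h] not in code.degenerate_aas:
                continue
            slot = acc.get(frag)
            if slot is None:
                slot = acc[frag] = [Counter(), np.zeros(window), 0]
            slot[0][mid] += 1
            slot[1] += [background.usage[c] for c in pos_codons]
            slot[2] += 1
    entries = {
        frag: CsiEntry(
            fragment=frag,
            middle_codon_counts=dict(sorted(counts.items())),
            position_mean_usage=tuple(round(v / occ, _MEAN_DECIMALS) for v in sums),
            occurrences=occ,
        )
        for frag, (counts, sums, occ) in acc.items()
    }
    return CodonSelectionIndex(
        window=window, entries=entries, background=background, n_genes=len(corpus)
    )


def merge_csi(a: CodonSelectionIndex, b: CodonSelectionIndex) -> CodonSelectionIndex:
    """Merge two indexes built with the same window and background.

    Middle-codon counts are exactly additive; position means are combined as
    occurrence-weighted averages (exact up to the stored rounding).
    """
    if a.window != b.window:
        raise ValueError(f"window mismatch: {a.window} != {b.window}")
    entries = dict(a.entries)
    for frag, eb in b.entries.items():
        ea = entries.get(frag)
        if ea is None:
            entries[frag] = eb
            continue
        counts = Counter(ea.middle_codon_counts)
        counts.update(eb.middle_codon_counts)
        occ = ea.occurrences + eb.occurrences
        means = tuple(
            round(
                (ma * ea.occurrences + mb * eb.occurrences) / occ,
                _MEAN_DECIMALS,
            )
            for ma, mb in zip(ea.position_mean_usage, eb.position_mean_usage)
        )
        entries[frag] = CsiEntry(frag, dict(sorted(counts.items())), means, occ)
    return CodonSelectionIndex(
        window=a.window,
        entries=entries,
        background=a.background,
        n_genes=a.n_genes + b.n_genes,
    )


def fragment_space_size(window: int, code: GeneticCode = STANDARD_CODE) -> int:
    """Number of possible fragments with a degenerate middle residue.

    The middle position ranges over the degenerate amino acids, every other
    position over all 20: ``18 * 20**(window - 1)`` for the standard code
    (2,880,000 at window 5; 1,152,000,000 at window 7).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    return len(code.degenerate_aas) * 20 ** (window - 1)


# ---------------------------------------------------------------------------
# Serialization: versioned header + TSV body, bit-stable across platforms
# ---------------------------------------------------------------------------


def save_csi(index: CodonSelectionIndex, path) -> None:
    """Write a CSI file: magic/version header, background counts, TSV body.

    Body columns: fragment, occurrences, middle-codon ``codon:count`` pairs
    (comma-separated, codon-lexicographic), per-position means (6 decimals).
    Rows are sorted by fragment for reproducible bytes.
    """
    with open(path, "w") as fh:
        fh.write(f"{CSI_MAGIC} v{CSI_VERSION} window={index.window} genes={index.n_genes}\n")
        bg = ",".join(f"{c}:{index.background.counts[c]}" for c in sorted(index.background.counts))
        fh.write(f"#background {bg}\n")
        for frag in sorted(index.entries):
            e = index.entries[frag]
            counts = ",".join(f"{c}:{n}" for c, n in sorted(e.middle_codon_counts.items()))
            means = ",".join(f"{v:.6f}" for v in e.position_mean_usage)
            fh.write(f"{frag}\t{e.occurrences}\t{counts}\t{means}\n")


def load_csi(path, code: GeneticCode = STANDARD_CODE) -> CodonSelectionIndex:
    """Load a CSI file written by :func:`save_csi`; checks magic and version."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        parts = header.split()
        if len(parts) < 4 or parts[0] != CSI_MAGIC:
            raise CsiFormatError(f"not a CSI file: bad magic in {path}")
        if parts[1] != f"v{CSI_VERSION}":
            raise CsiFormatError(f"unsupported CSI version {parts[1]} (expected v{CSI_VERSION})")
        try:
            window = int(parts[2].split("=", 1)[1])
            n_genes = int(parts[3].split("=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise CsiFormatError(f"malformed CSI header: {header!r}") from exc
        bg_line = fh.readline().rstrip("\n")
        if not bg_line.startswith("#background "):
            raise CsiFormatError("missing #background line")
        bg_counts = {}
        for pair in bg_line.split(" ", 1)[1].split(","):
            codon, count = pair.split(":")
            bg_counts[codon] = int(count)
        background = CodonUsageTable.from_counts(bg_counts, code)
        entries: dict[str, CsiEntry] = {}
        for line in fh:
            frag, occ, counts_s, means_s = line.rstrip("\n").split("\t")
            counts = {}
            for pair in counts_s.split(","):
                codon, count = pair.split(":")
                counts[codon] = int(count)
            means = tuple(float(v) for v in means_s.split(","))
            if len(means) != window:
                raise CsiFormatError(f"fragment {frag!r}: {len(means)} means for window {window}")
            entries[frag] = CsiEntry(frag, counts, means, int(occ))
    return CodonSelectionIndex(window=window, entries=entries, background=background, n_genes=n_genes)
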