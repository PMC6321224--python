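"""Back-translation of proteins into host-tuned genes.

The first and last two codons come from positional codon tables (the modal
codon per amino acid at those gene positions in the training corpus), because
the windowed classifiers cannot cover gene termini. Every interior degenerate
position is designed by extracting the surrounding peptide window, searching
the host CSI through a descending cut-off cascade, and predicting the codon
with the model of the first cut-off that yields at least one match; positions
with no match (or no model) fall back to the host's most frequent codon.
Met and Trp positions are emitted directly (ATG / TGG).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import CodingSequence
from .genetics import STANDARD_AAS, STANDARD_CODE, CodonUsageTable, GeneticCode, translate
from .models import ClassifierBundle

logger = logging.getLogger(__name__)

#: Position-record sources.
SRC_HEAD = "head-table"
SRC_TAIL = "tail-table"
SRC_FALLBACK = "fallback"
SRC_NONDEGENERATE = "non-degenerate"


@dataclass(frozen=True)
class DesignConfig:
    """Window, cut-off cascade, and fallback policy for gene design.

    The cascade is tried in order (strictly descending cut-offs); the single
    fallback policy is the highest-background-usage codon. ``append_stop``
    optionally appends a stop codon to the designed DNA.
    """

    window: int = 7
    cutoff_cascade: tuple[float, ...] = (0.9, 0.8, 0.7)
    fallback: str = "max-frequency-codon"
    seed: int = 0
    append_stop: str | None = None

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if not self.cutoff_cascade:
            raise ValueError("cutoff_cascade must be non-empty")
        if any(not (0 < c <= 1) for c in self.cutoff_cascade):
            raise ValueError("cascade cut-offs must be in (0, 1]")
        if any(a <= b for a, b in zip(self.cutoff_cascade, self.cutoff_cascade[1:])):
            raise ValueError("cutoff_cascade must be strictly descending")
        if self.fallback != "max-frequency-codon":
            raise ValueError(f"unknown fallback policy {self.fallback!r}")
        if self.append_stop is not None and self.append_stop not in STANDARD_CODE.stop_codons:
            raise ValueError(f"append_stop must be a stop codon, got {self.append_stop!r}")


# ---------------------------------------------------------------------------
# Positional codon tables for gene termini
# ---------------------------------------------------------------------------


@dataclass
class PositionalCodonTable:
    """Modal codon per amino acid at the first and last two gene positions.

    ``head[s]`` (slot s in {1, 2}) maps an amino acid to its most frequent
    codon at gene position s; ``tail[1]`` is the penultimate position and
    ``tail[2]`` the last. Raw counts are retained for reporting. Ties are
    broken by higher background usage, then lexicographically.
    """

    head: dict[int, dict[str, str]]
    tail: dict[int, dict[str, str]]
    head_counts: dict[int, dict[str, Counter]]
    tail_counts: dict[int, dict[str, Counter]]


def _modal(counter: Counter, background: CodonUsageTable) -> str:
    best = max(counter.values())
    tied = [c for c, n in counter.items() if n == best]
    usage_best = max(background.usage[c] for c in tied)
    return min(c for c in tied if background.usage[c] == usage_best)


def build_positional_tables(
    corpus: Sequence[CodingSequence],
    background: CodonUsageTable | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> PositionalCodonTable:
    """Measure codon usage of the first and last two residues of each gene."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot build positional tables from an empty corpus")
    if background is None:
        from .genetics import usage_table_from_corpus

        background = usage_table_from_corpus(corpus, code)
    head_counts: dict[int, dict[str, Counter]] = {1: defaultdict(Counter), 2: defaultdict(Counter)}
    tail_counts: dict[int, dict[str, Counter]] = {1: defaultdict(Counter), 2: defaultdict(Counter)}
    for gene in corpus:
        if len(gene) < 4:  # head/tail would overlap; such genes carry no signal here
            continue
        head_counts[1][gene.protein[0]][gene.codons[0]] += 1
        head_counts[2][gene.protein[1]][gene.codons[1]] += 1
        tail_counts[1][gene.protein[-2]][gene.codons[-2]] += 1
        tail_counts[2][gene.protein[-1]][gene.codons[-1]] += 1
    head = {s: {aa: _modal(c, background) for aa, c in by_aa.items()} for s, by_aa in head_counts.items()}
    tail = {s: {aa: _modal(c, background) for aa, c in by_aa.items()} for s, by_aa in tail_counts.items()}
    return PositionalCodonTable(
        head=head,
        tail=tail,
        head_counts={s: dict(v) for s, v in head_counts.items()},
        tail_counts={s: dict(v) for s, v in tail_counts.items()},
    )


def write_positional_tables(tables: PositionalCodonTable, path) -> None:
    """TSV serialization: region, slot, amino_acid, codon, count."""
    with open(path, "w") as fh:
        fh.write("region\tslot\tamino_acid\tcodon\tcount\n")
        for region, counts in (("head", tables.head_counts), ("tail", tables.tail_counts)):
            for slot in sorted(counts):
                for aa in sorted(counts[slot]):
                    for codon, n in sorted(counts[slot][aa].items()):
                        fh.write(f"{region}\t{slot}\t{aa}\t{codon}\t{n}\n")


def read_positional_tables(
    path, background: CodonUsageTable, code: GeneticCode = STANDARD_CODE
) -> PositionalCodonTable:
    head_counts: dict[int, dict[str, Counter]] = {1: defaultdict(Counter), 2: defaultdict(Counter)}
    tail_counts: dict[int, dict[str, Counter]] = {1: defaultdict(Counter), 2: defaultdict(Counter)}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("region\t"):
            raise ValueError(f"{path} is not a positional-table TSV")
        for line in fh:
            region, slot, aa, codon, n = line.rstrip("\n").split("\t")
            target = head_counts if region == "head" else tail_counts
            target[int(slot)][aa][codon] += int(n)
    head = {s: {aa: _modal(c, background) for aa, c in by_aa.items()} for s, by_aa in head_counts.items()}
    tail = {s: {aa: _modal(c, background) for aa, c in by_aa.items()} for s, by_aa in tail_counts.items()}
    return PositionalCodonTable(
        head=head,
        tail=tail,
        head_counts={s: dict(v) for s, v in head_counts.items()},
        tail_counts={s: dict(v) for s, v in tail_counts.items()},
    )


# ---------------------------------------------------------------------------
# Gene design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionRecord:
    """Provenance of one designed codon (1-based position)."""

    position: int
    amino_acid: str
    codon: str
    source: str
    background_usage: float


@dataclass
class DesignResult:
    """Designed DNA plus per-position provenance."""

    dna: str
    per_position: list[PositionRecord]
    host: str

    @property
    def codons(self) -> list[str]:
        return [r.codon for r in self.per_position]


def fallback_codon(aa: str, background: CodonUsageTable, code: GeneticCode = STANDARD_CODE) -> str:
    """The host's most frequently used codon for ``aa``."""
    return background.modal_codon(aa, code)


def design_gene(
    protein: str,
    bundle: ClassifierBundle,
    config: DesignConfig | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> DesignResult:
    """Back-translate ``protein`` into a gene tuned to the bundle's host.

    The designed DNA always translates back to the input protein exactly
    (checked before returning). Deterministic for a fixed bundle and config.
    """
    config = config or DesignConfig()
    for i, aa in enumerate(protein):
        if aa not in STANDARD_AAS:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
    if not protein:
        raise ValueError("empty protein sequence")

    w = config.window
    h = w // 2
    n = len(protein)
    searcher = bundle.searcher(w) if w in bundle.csis else None
    tables = bundle.positional_tables
    codons: list[str | None] = [None] * n
    sources: list[str | None] = [None] * n
    pending: list[tuple[int, str, str]] = []

    for i, aa in enumerate(protein):
        if aa == "M" or aa == "W":
            codons[i] = "ATG" if aa == "M" else "TGG"
            sources[i] = SRC_NONDEGENERATE
        elif i < 2:
            codon = tables.head.get(i + 1, {}).get(aa)
            if codon is None:
                codons[i], sources[i] = fallback_codon(aa, bundle.background, code), SRC_FALLBACK
            else:
                codons[i], sources[i] = codon, SRC_HEAD
        elif i >= n - 2:
            codon = tables.tail.get(i - (n - 2) + 1, {}).get(aa)
            if codon is None:
                codons[i], sources[i] = fallback_codon(aa, bundle.background, code), SRC_FALLBACK
            else:
                codons[i], sources[i] = codon, SRC_TAIL
        elif i < h or i + h >= n or searcher is None:
            # the window does not fit (or no CSI for this window size)
            codons[i], sources[i] = fallback_codon(aa, bundle.background, code), SRC_FALLBACK
        else:
            pending.append((i, aa, protein[i - h : i + h + 1]))

    # Cascade: first cut-off with both a model and >= 1 CSI match wins.
    batches: dict[tuple[str, float], list[tuple[int, np.ndarray]]] = defaultdict(list)
    for i, aa, fragment in pending:
        for cutoff in config.cutoff_cascade:
            model = bundle.get_model(aa, w, cutoff)
            if model is None:
                logger.debug("no model for (%s, %d, %g); next cascade step", aa, w, cutoff)
                continue
            fv = searcher.feature_vector(fragment, cutoff)
            if fv is None:
                continue
            batches[(aa, round(cutoff, 4))].append((i, fv))
            break
        else:
            codons[i], sources[i] = fallback_codon(aa, bundle.background, code), SRC_FALLBACK

    for (aa, cutoff), items in batches.items():
        model = bundle.get_model(aa, w, cutoff)
        X = np.vstack([fv for _, fv in items])
        preds = model.predict(X)
        for (i, _), codon in zip(items, preds):
            codons[i] = str(codon)
            sources[i] = f"model@{cutoff:g}"

    per_position = [
        PositionRecord(
            position=i + 1,
            amino_acid=protein[i],
            codon=codons[i],
            source=sources[i],
            background_usage=bundle.background.usage[codons[i]],
        )
        for i in range(n)
    ]
    dna = "".join(codons) + (config.append_stop or "")
    designed = translate([r.codon for r in per_position], code)
    if designed != protein:
        raise RuntimeError(
            "internal error: designed gene does not translate back to the input"
        )
    return DesignResult(dna=dna, per_position=per_position, host=bundle.host_name)


def design_report(
    result: DesignResult, code: GeneticCode = STANDARD_CODE
) -> tuple[pd.DataFrame, dict]:
    """Per-position table plus a summary.

    A designed codon is flagged rare when its background relative usage is
    below 0.5 / k (half the uniform share among the k synonymous codons).
    """
    rows = []
    for rec in result.per_position:
        k = code.degeneracy(rec.amino_acid)
        rows.append(
            {
                "position": rec.position,
                "amino_acid": rec.amino_acid,
                "codon": rec.codon,
                "source": rec.source,
                "background_usage": rec.background_usage,
                "rare": rec.background_usage < 0.5 / k,
            }
        )
    df = pd.DataFrame(rows)
    n = len(df)
    fractions = (df["source"].value_counts() / n).to_dict() if n else {}
    summary = {
        "host": result.host,
        "n_positions": n,
        "source_fractions": fractions,
        "n_rare": int(df["rare"].sum()) if n else 0,
        "rare_positions": df.loc[df["rare"], "position"].tolist() if n else [],
    }
    return df, summary
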