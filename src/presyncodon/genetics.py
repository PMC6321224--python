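"""Standard genetic code, CDS translation, and synonymous codon-usage tables.

These are the foundation types for the package: the genetic code with its
degeneracy structure (which amino acids have more than one codon), translation
of codon lists into protein sequences, and per-amino-acid relative codon-usage
tables computed from a coding-sequence corpus.

Only the standard genetic code (NCBI translation table 1) is supported: 61
sense codons for the 20 standard amino acids, of which 18 are encoded by two
or more synonymous codons (all but Met and Trp).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"


class CodonError(ValueError):
    """Raised for codons that are not sense codons of the active code."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons plus degeneracy structure.

    Attributes
    ----------
    codon_to_aa
        Map of 3-letter DNA codon to 1-letter amino acid, sense codons only.
    stop_codons
        The stop codons (not present in ``codon_to_aa``).
    aa_to_codons
        Map of amino acid to its synonymous codons in lexicographic order.
    degenerate_aas
        Amino acids with two or more synonymous codons.
    """

    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    aa_to_codons: Mapping[str, tuple[str, ...]]
    degenerate_aas: frozenset[str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard genetic code (NCBI translation table 1)."""
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = dict(sorted(table.forward_table.items()))
        by_aa: dict[str, list[str]] = {}
        for codon, aa in codon_to_aa.items():
            by_aa.setdefault(aa, []).append(codon)
        return cls(
            codon_to_aa=codon_to_aa,
            stop_codons=frozenset(table.stop_codons),
            aa_to_codons={aa: tuple(sorted(cs)) for aa, cs in sorted(by_aa.items())},
            degenerate_aas=frozenset(aa for aa, cs in by_aa.items() if len(cs) > 1),
        )

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """Synonymous codons of ``aa`` in lexicographic order."""
        try:
            return self.aa_to_codons[aa]
        except KeyError:
            raise CodonError(f"unknown amino acid {aa!r}") from None

    def degeneracy(self, aa: str) -> int:
        """Number of synonymous codons of ``aa``."""
        return len(self.codons_for(aa))

    def is_degenerate(self, aa: str) -> bool:
        return aa in self.degenerate_aas


#: Module-wide default code; every API takes an optional ``code`` override.
STANDARD_CODE = GeneticCode.standard()


def translate(codons: Sequence[str], code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a codon list into a protein sequence.

    A single trailing stop codon is permitted and dropped. An internal stop
    codon or any non-sense codon raises :class:`CodonError` naming the
    offending codon position (0-based).
    """
    last = len(codons) - 1
    aas = []
    for i, codon in enumerate(codons):
        aa = code.codon_to_aa.get(codon)
        if aa is None:
            if codon in code.stop_codons:
                if i == last:
                    break
                raise CodonError(f"internal stop codon {codon!r} at codon position {i}")
            raise CodonError(f"unknown codon {codon!r} at codon position {i}")
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-amino-acid relative synonymous codon usage.

    ``usage[codon]`` is the relative frequency of the codon among the
    synonymous codons of its amino acid, so the values for each amino acid sum
    to 1 and are comparable across amino acids (always in [0, 1]). For an
    amino acid never observed in the source counts the distribution is
    uniform, so a usage value exists for every sense codon.
    """

    counts: Mapping[str, int]
    usage: Mapping[str, float]

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], code: GeneticCode = STANDARD_CODE
    ) -> "CodonUsageTable":
        full = {c: int(counts.get(c, 0)) for c in code.codon_to_aa}
        if any(v < 0 for v in full.values()):
            raise ValueError("codon counts must be nonnegative")
        unknown = set(counts) - set(full)
        if unknown:
            raise CodonError(f"non-sense codons in counts: {sorted(unknown)}")
        usage: dict[str, float] = {}
        for aa, codons in code.aa_to_codons.items():
            total = sum(full[c] for c in codons)
            if total == 0:
                for c in codons:
                    usage[c] = 1.0 / len(codons)
            else:
                for c in codons:
                    usage[c] = full[c] / total
        return cls(counts=full, usage=usage)

    @classmethod
    def from_frequencies(
        cls, freqs: Mapping[str, float], code: GeneticCode = STANDARD_CODE
    ) -> "CodonUsageTable":
        """Build a table from target relative frequencies.

        Frequencies are renormalized per amino acid; pseudo-counts are stored
        on an arbitrary integer scale (1e6 per amino acid).
        """
        counts = {c: int(round(1_000_000 * freqs.get(c, 0.0))) for c in code.codon_to_aa}
        return cls.from_counts(counts, code)

    def modal_codon(self, aa: str, code: GeneticCode = STANDARD_CODE) -> str:
        """Most frequently used codon of ``aa`` (ties broken lexicographically)."""
        codons = code.codons_for(aa)
        best = max(self.usage[c] for c in codons)
        return min(c for c in codons if self.usage[c] == best)


def usage_table_from_corpus(
    corpus: Iterable, code: GeneticCode = STANDARD_CODE
) -> CodonUsageTable:
    """Codon usage table counted over a corpus of coding sequences.

    ``corpus`` items are either objects with a ``codons`` attribute (e.g.
    :class:`presyncodon.corpus.CodingSequence`) or plain codon sequences.
    """
    counter: Counter[str] = Counter()
    n = 0
    for item in corpus:
        codons = getattr(item, "codons", item)
        counter.update(codons)
        n += 1
    if n == 0:
        raise ValueError("cannot build a codon usage table from an empty corpus")
    return CodonUsageTable.from_counts(counter, code)
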