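"""Fragment matching against a CSI and classifier feature assembly.

A query fragment is scored against every index fragment sharing its middle
residue with a positionwise substitution-matrix sum (BLOSUM62 by default):
matched score s, expected maximal score m = the query's self-score, matched
percent p = s/m. Entries passing a cut-off contribute to the (k + w)-
dimensional feature vector: the arithmetic mean of their normalized
middle-codon distributions (k = degeneracy of the middle amino acid) followed
by the mean of their per-position usage vectors (w = window size).
"""

from __future__ import annotations

import os
import weakref
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .csi import CodonSelectionIndex, CsiEntry
from .genetics import STANDARD_AAS, STANDARD_CODE, GeneticCode

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AAS)}

_MATRIX_CACHE: dict[str, np.ndarray] = {}


class NoMatchError(LookupError):
    """No CSI entry passed the cut-off; the caller should fall back."""


def load_substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Load a substitution matrix as a dense 20x20 array over STANDARD_AAS.

    ``name`` is either a matrix shipped with biopython (e.g. "BLOSUM62",
    "PAM250") or a path to a file in NCBI matrix text format.
    """
    cached = _MATRIX_CACHE.get(name)
    if cached is not None:
        return cached
    if os.path.exists(name):
        arr = substitution_matrices.read(name)
    else:
        arr = substitution_matrices.load(name)
    m = np.empty((20, 20))
    for i, a in enumerate(STANDARD_AAS):
        for j, b in enumerate(STANDARD_AAS):
            m[i, j] = arr[a, b]
    _MATRIX_CACHE[name] = m
    return m


def _encode(fragment: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in fragment], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {fragment!r}") from None


def self_score(fragment: str, matrix: np.ndarray | str = "BLOSUM62") -> float:
    """m: sum of diagonal matrix scores over the fragment's residues."""
    if isinstance(matrix, str):
        matrix = load_substitution_matrix(matrix)
    codes = _encode(fragment)
    return float(matrix[codes, codes].sum())


def score_pair(query: str, candidate: str, matrix: np.ndarray | str = "BLOSUM62") -> float:
    """s: positionwise substitution-matrix sum of two equal-length fragments."""
    if len(query) != len(candidate):
        raise ValueError(f"length mismatch: {len(query)} vs {len(candidate)}")
    if isinstance(matrix, str):
        matrix = load_substitution_matrix(matrix)
    return float(matrix[_encode(query), _encode(candidate)].sum())


@dataclass(frozen=True)
class MatchConfig:
    """Cut-off level and scoring options for CSI searches."""

    cutoff: float = 1.0
    substitution_matrix: str = "BLOSUM62"
    require_middle_identity: bool = True

    def __post_init__(self):
        if not (0 < self.cutoff <= 1):
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")


@dataclass(frozen=True)
class MatchResult:
    entry: CsiEntry
    s: float
    m: float
    p: float


def _passes(s: np.ndarray, p: np.ndarray, cutoff: float) -> np.ndarray:
    # c = 1 admits exact matches (p >= 1); a strict reading would select nothing.
    if cutoff >= 1.0:
        return (s > 0) & (p >= 1.0)
    return (s > 0) & (p > cutoff)


class _Group:
    """Entries of one middle amino acid, encoded for vectorized scoring."""

    __slots__ = ("fragments", "codes", "dists", "usage", "entries")

    def __init__(self, entries: list[CsiEntry], window: int, code: GeneticCode):
        entries = sorted(entries, key=lambda e: e.fragment)
        self.entries = entries
        self.fragments = [e.fragment for e in entries]
        self.codes = np.stack([_encode(e.fragment) for e in entries])
        self.dists = np.stack([e.middle_distribution(code) for e in entries])
        self.usage = np.array([e.position_mean_usage for e in entries], float)


class CsiSearcher:
    """Reusable searcher over one CSI: scores are memoized per query fragment.

    The exhaustive per-fragment precomputation the original service stored in
    a database is replaced by this on-demand cache.
    """

    def __init__(
        self,
        index: CodonSelectionIndex,
        config: MatchConfig | None = None,
        code: GeneticCode = STANDARD_CODE,
    ):
        self.index = index
        self.config = config or MatchConfig()
        self.code = code
        if not self.config.require_middle_identity:
            # Averaging middle-codon distributions across different middle
            # residues is undefined; the candidate pool is always same-middle.
            raise NotImplementedError(
                "matching without middle-residue identity is not supported"
            )
        self.matrix = load_substitution_matrix(self.config.substitution_matrix)
        by_aa: dict[str, list[CsiEntry]] = {}
        for e in index.entries.values():
            by_aa.setdefault(e.middle_aa, []).append(e)
        self._groups = {
            aa: _Group(entries, index.window, code) for aa, entries in by_aa.items()
        }
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _validate_query(self, query: str) -> str:
        if len(query) != self.index.window:
            raise ValueError(
                f"query length {len(query)} != index window {self.index.window}"
            )
        middle = query[len(query) // 2]
        if middle not in self.code.degenerate_aas:
            raise ValueError(f"middle residue {middle!r} is not degenerate")
        return middle

    def _percents(self, query: str) -> tuple[str, np.ndarray, np.ndarray, float]:
        """(middle_aa, s array, p array, m) over the query's candidate group."""
        middle = self._validate_query(query)
        m = self_score(query, self.matrix)
        cached = self._cache.get(query)
        if cached is not None:
            s, p = cached
            return middle, s, p, m
        group = self._groups.get(middle)
        if group is None:
            s = p = np.empty(0)
        else:
            codes = _encode(query)
            s = np.zeros(len(group.fragments))
            for i in range(self.index.window):
                s = s + self.matrix[codes[i], group.codes[:, i]]
            p = s / m
        self._cache[query] = (s, p)
        return middle, s, p, m

    def search(self, query: str, cutoff: float | None = None) -> list[MatchResult]:
        """All entries passing the cut-off, sorted by p descending then fragment."""
        if cutoff is None:
            cutoff = self.config.cutoff
        middle, s, p, m = self._percents(query)
        if s.size == 0:
            return []
        group = self._groups[middle]
        mask = _passes(s, p, cutoff)
        results = [
            MatchResult(entry=group.entries[i], s=float(s[i]), m=m, p=float(p[i]))
            for i in np.flatnonzero(mask)
        ]
        results.sort(key=lambda r: (-r.p, r.entry.fragment))
        return results

    def feature_vector(self, query: str, cutoff: float | None = None) -> np.ndarray | None:
        """The (k + w) feature vector, or None if no entry passes the cut-off.

        Equivalent to ``build_feature_vector(self.search(query, cutoff), ...)``
        but avoids materializing match objects.
        """
        if cutoff is None:
            cutoff = self.config.cutoff
        middle, s, p, _ = self._percents(query)
        if s.size == 0:
            return None
        mask = _passes(s, p, cutoff)
        if not mask.any():
            return None
        group = self._groups[middle]
        return np.concatenate(
            [group.dists[mask].mean(axis=0), group.usage[mask].mean(axis=0)]
        )


# One searcher per (index, matrix, middle-identity flag); indexes are held weakly.
_SEARCHERS: "weakref.WeakKeyDictionary[CodonSelectionIndex, dict]" = weakref.WeakKeyDictionary()


def get_searcher(
    index: CodonSelectionIndex,
    config: MatchConfig | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> CsiSearcher:
    config = config or MatchConfig()
    key = (config.substitution_matrix, config.require_middle_identity)
    per_index = _SEARCHERS.setdefault(index, {})
    if key not in per_index:
        per_index[key] = CsiSearcher(index, config, code)
    return per_index[key]


def search_csi(
    query: str,
    index: CodonSelectionIndex,
    config: MatchConfig,
    code: GeneticCode = STANDARD_CODE,
) -> list[MatchResult]:
    """Score ``query`` against every same-middle entry of ``index``.

    Returns matches with p = s/m above ``config.cutoff`` (p >= 1 when the
    cut-off is 1), sorted by p descending with ties broken by fragment.
    """
    return get_searcher(index, config, code).search(query, config.cutoff)


def build_feature_vector(
    matches: Sequence[MatchResult],
    middle_aa: str,
    window: int,
    code: GeneticCode = STANDARD_CODE,
) -> np.ndarray:
    """Unweighted arithmetic mean of the matched entries' coding vectors.

    First k components (k = degeneracy of ``middle_aa``): mean normalized
    middle-codon distribution in codon-lexicographic order; last w: mean
    per-position usage. Raises :class:`NoMatchError` on an empty match list.
    """
    if not matches:
        raise NoMatchError(f"no CSI match for middle residue {middle_aa!r}")
    for r in matches:
        if r.entry.middle_aa != middle_aa:
            raise ValueError(
                f"match fragment {r.entry.fragment!r} has middle "
                f"{r.entry.middle_aa!r}, expected {middle_aa!r}"
            )
        if len(r.entry.fragment) != window:
            raise ValueError("match window does not equal requested window")
    dists = np.stack([r.entry.middle_distribution(code) for r in matches])
    usage = np.array([r.entry.position_mean_usage for r in matches], float)
    return np.concatenate([dists.mean(axis=0), usage.mean(axis=0)])
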