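"""Per-amino-acid codon classifiers over the (window x cut-off) grid.

For each degenerate amino acid, window size, and cut-off level, a multi-class
random forest is trained to predict the codon used at the middle of a peptide
fragment from the (k + w) CSI feature vector. The full grid of two windows
(5, 7) and seven cut-offs (0.7 ... 1) gives 18 x 2 x 7 = 252 model slots per
host. Models are evaluated by seeded stratified ten-fold cross validation and
persisted as a bundle directory (JSON manifest + one model file per cell).
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .corpus import CodingSequence
from .csi import CodonSelectionIndex, build_csi, extract_fragments, load_csi, save_csi
from .genetics import (
    STANDARD_CODE,
    CodonUsageTable,
    GeneticCode,
    usage_table_from_corpus,
)
from .matching import CsiSearcher, MatchConfig, get_searcher

logger = logging.getLogger(__name__)

FULL_GRID_CUTOFFS = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0)
FULL_GRID_WINDOWS = (5, 7)
FULL_N_TREES = 10_000
DEFAULT_N_TREES = 200

BUNDLE_FORMAT = "presyncodon-bundle"
BUNDLE_VERSION = 1


class TrainingDataError(ValueError):
    """No usable training vectors for a grid cell."""


class BundleFormatError(ValueError):
    """Malformed or wrong-version bundle directory."""


def _cutoff_key(cutoff: float) -> float:
    return round(float(cutoff), 4)


@dataclass(frozen=True)
class ClassifierSpec:
    """One grid cell: amino acid, window, cut-off, forest size, seed."""

    amino_acid: str
    window: int
    cutoff: float
    n_trees: int = DEFAULT_N_TREES
    seed: int = 0

    def __post_init__(self):
        if self.amino_acid not in STANDARD_CODE.degenerate_aas:
            raise ValueError(f"{self.amino_acid!r} is not a degenerate amino acid")
        if not (0 < self.cutoff <= 1):
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")


@dataclass
class TrainingSet:
    """Feature matrix and codon labels for one (amino acid, window, cutoff)."""

    amino_acid: str
    window: int
    cutoff: float
    features: np.ndarray  # (n, k + w)
    labels: np.ndarray  # (n,) codon strings
    gene_ids: tuple[str, ...]
    n_skipped: int = 0  # positions with no CSI match above the cut-off

    def __len__(self) -> int:
        return len(self.labels)


class TrainedModel:
    """A trained grid-cell predictor.

    Wraps either a fitted random forest or, when the training labels were a
    single codon, a constant predictor flagged ``degenerate``. Predictions are
    always codons synonymous with the cell's amino acid.
    """

    def __init__(self, spec: ClassifierSpec, n_features: int, classes: tuple[str, ...],
                 estimator=None, constant_label: str | None = None):
        if (estimator is None) == (constant_label is None):
            raise ValueError("exactly one of estimator/constant_label is required")
        self.spec = spec
        self.n_features = n_features
        self.classes = classes
        self.estimator = estimator
        self.constant_label = constant_label

    @property
    def degenerate(self) -> bool:
        return self.estimator is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != expected {self.n_features} "
                f"for {self.spec.amino_acid} w={self.spec.window}"
            )
        if self.degenerate:
            return np.full(len(X), self.constant_label, dtype=object)
        return self.estimator.predict(X)


def assemble_training_data(
    corpus: Sequence[CodingSequence],
    index: CodonSelectionIndex,
    config: MatchConfig,
    amino_acid: str,
    code: GeneticCode = STANDARD_CODE,
    searcher: CsiSearcher | None = None,
) -> TrainingSet:
    """Training vectors for one amino acid at ``config.cutoff``.

    Every corpus window position with the given middle residue whose CSI
    search returns at least one match contributes (feature vector, observed
    codon); unmatched positions are skipped and counted.
    """
    if amino_acid not in code.degenerate_aas:
        raise ValueError(f"{amino_acid!r} is not a degenerate amino acid")
    if searcher is None:
        searcher = get_searcher(index, config, code)
    h = index.window // 2
    feats, labels, gids = [], [], []
    n_skipped = 0
    for gene in corpus:
        for frag, mid, _ in extract_fragments(gene, index.window, code):
            if frag[h] != amino_acid:
                continue
            fv = searcher.feature_vector(frag, config.cutoff)
            if fv is None:
                n_skipped += 1
                continue
            feats.append(fv)
            labels.append(mid)
            gids.append(gene.id)
    if not feats:
        raise TrainingDataError(
            f"no training vectors for amino acid {amino_acid} "
            f"(window={index.window}, cutoff={config.cutoff})"
        )
    return TrainingSet(
        amino_acid=amino_acid,
        window=index.window,
        cutoff=_cutoff_key(config.cutoff),
        features=np.vstack(feats),
        labels=np.array(labels, dtype=object),
        gene_ids=tuple(gids),
        n_skipped=n_skipped,
    )


def train_classifier(
    ts: TrainingSet, spec: ClassifierSpec, code: GeneticCode = STANDARD_CODE
) -> TrainedModel:
    """Fit the random forest for one cell (seeded, single-threaded).

    With a single distinct label a constant predictor is stored instead and
    flagged degenerate.
    """
    expected = code.degeneracy(spec.amino_acid) + spec.window
    if ts.features.ndim != 2 or ts.features.shape[1] != expected:
        raise ValueError(
            f"feature dimension {ts.features.shape[1:]} != expected {expected} "
            f"(k={code.degeneracy(spec.amino_acid)} + w={spec.window})"
        )
    valid = set(code.codons_for(spec.amino_acid))
    bad = set(ts.labels) - valid
    if bad:
        raise ValueError(f"labels not synonymous with {spec.amino_acid}: {sorted(bad)}")
    classes = tuple(sorted(set(ts.labels)))
    if len(classes) == 1:
        logger.info(
            "constant predictor for %s w=%d c=%g (single label %s)",
            spec.amino_acid, spec.window, spec.cutoff, classes[0],
        )
        return TrainedModel(spec, expected, classes, constant_label=classes[0])
    rf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        random_state=spec.seed % (2**31),
        n_jobs=1,
    )
    rf.fit(ts.features, ts.labels)
    return TrainedModel(spec, expected, classes, estimator=rf)


@dataclass(frozen=True)
class CvResult:
    accuracy: float
    fold_accuracies: tuple[float, ...]
    n: int


def cross_validate(
    ts: TrainingSet,
    spec: ClassifierSpec,
    folds: int = 10,
    code: GeneticCode = STANDARD_CODE,
) -> CvResult:
    """Seeded k-fold cross validation of one grid cell.

    Folds are stratified by codon label when every class has at least
    ``folds`` members, otherwise plain shuffled folds. Accuracy is the
    fraction of held-out positions whose predicted codon equals the observed
    codon, averaged over folds.
    """
    n = len(ts)
    if n < folds:
        raise ValueError(f"{n} samples < {folds} folds; use fewer folds")
    _, class_counts = np.unique(ts.labels.astype(str), return_counts=True)
    if len(class_counts) > 1 and class_counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed % (2**31))
        splits = splitter.split(ts.features, ts.labels.astype(str))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=spec.seed % (2**31))
        splits = splitter.split(ts.features)
    accs = []
    for train_ix, test_ix in splits:
        fold_ts = TrainingSet(
            ts.amino_acid, ts.window, ts.cutoff,
            ts.features[train_ix], ts.labels[train_ix],
            tuple(ts.gene_ids[i] for i in train_ix),
        )
        model = train_classifier(fold_ts, spec, code)
        pred = model.predict(ts.features[test_ix])
        accs.append(float(np.mean(pred == ts.labels[test_ix])))
    return CvResult(accuracy=float(np.mean(accs)), fold_accuracies=tuple(accs), n=n)


# ---------------------------------------------------------------------------
# Grid training and bundles
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ClassifierBundle:
    """The trained model grid plus everything design needs at run time."""

    host_name: str
    windows: tuple[int, ...]
    cutoffs: tuple[float, ...]
    models: dict[tuple[str, int, float], TrainedModel]
    positional_tables: "object"  # design.PositionalCodonTable
    background: CodonUsageTable
    csis: dict[int, CodonSelectionIndex]
    n_trees: int
    seed: int
    substitution_matrix: str = "BLOSUM62"
    skipped: dict[tuple[str, int, float], str] = field(default_factory=dict)
    _searchers: dict = field(default_factory=dict, repr=False)

    @property
    def n_slots(self) -> int:
        """Grid cardinality: degenerate amino acids x windows x cut-offs."""
        return len(STANDARD_CODE.degenerate_aas) * len(self.windows) * len(self.cutoffs)

    def searcher(self, window: int) -> CsiSearcher:
        if window not in self._searchers:
            self._searchers[window] = CsiSearcher(
                self.csis[window], MatchConfig(substitution_matrix=self.substitution_matrix)
            )
        return self._searchers[window]

    def get_model(self, amino_acid: str, window: int, cutoff: float) -> TrainedModel | None:
        return self.models.get((amino_acid, window, _cutoff_key(cutoff)))


def _cell_seed(base_seed: int, cell_index: int) -> int:
    return (base_seed * 100_003 + 7919 * cell_index + 1) % (2**31 - 1)


def _positions_by_aa(corpus, window, code):
    pos = defaultdict(list)  # aa -> [(fragment, observed middle codon, gene id)]
    h = window // 2
    for gene in corpus:
        for frag, mid, _ in extract_fragments(gene, window, code):
            aa = frag[h]
            if aa in code.degenerate_aas:
                pos[aa].append((frag, mid, gene.id))
    return pos


def train_grid(
    corpus: Sequence[CodingSequence],
    windows: Sequence[int] = FULL_GRID_WINDOWS,
    cutoffs: Sequence[float] = FULL_GRID_CUTOFFS,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    host_name: str = "host",
    substitution_matrix: str = "BLOSUM62",
    code: GeneticCode = STANDARD_CODE,
) -> ClassifierBundle:
    """Train one classifier per (degenerate amino acid, window, cut-off).

    Cells with no training vectors are recorded in ``bundle.skipped`` rather
    than failing the whole grid. CSI scores are computed once per distinct
    fragment and shared across cut-offs.
    """
    from .design import build_positional_tables  # local: avoids module cycle

    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot train on an empty corpus")
    windows = tuple(int(w) for w in windows)
    cutoffs = tuple(_cutoff_key(c) for c in cutoffs)
    background = usage_table_from_corpus(corpus, code)
    positional = build_positional_tables(corpus, background, code)

    models: dict[tuple[str, int, float], TrainedModel] = {}
    skipped: dict[tuple[str, int, float], str] = {}
    csis: dict[int, CodonSelectionIndex] = {}
    aas = sorted(code.degenerate_aas)
    cell_index = 0
    for window in windows:
        index = build_csi(corpus, window, code, background)
        csis[window] = index
        searcher = CsiSearcher(index, MatchConfig(substitution_matrix=substitution_matrix), code)
        positions = _positions_by_aa(corpus, window, code)
        for aa in aas:
            items = positions.get(aa, [])
            feat_cache: dict[tuple[str, float], np.ndarray | None] = {}
            for cutoff in cutoffs:
                key = (aa, window, cutoff)
                cell_index += 1
                if not items:
                    skipped[key] = "amino acid absent from corpus windows"
                    continue
                feats, labels, gids = [], [], []
                for frag, mid, gid in items:
                    ck = (frag, cutoff)
                    if ck not in feat_cache:
                        feat_cache[ck] = searcher.feature_vector(frag, cutoff)
                    fv = feat_cache[ck]
                    if fv is None:
                        continue
                    feats.append(fv)
                    labels.append(mid)
                    gids.append(gid)
                if not feats:
                    skipped[key] = "no CSI match above cut-off"
                    continue
                ts = TrainingSet(
                    aa, window, cutoff,
                    np.vstack(feats), np.array(labels, dtype=object), tuple(gids),
                    n_skipped=len(items) - len(feats),
                )
                spec = ClassifierSpec(aa, window, cutoff, n_trees, _cell_seed(seed, cell_index))
                models[key] = train_classifier(ts, spec, code)
    if not models:
        raise TrainingDataError("no grid cell had any training data")
    return ClassifierBundle(
        host_name=host_name,
        windows=windows,
        cutoffs=cutoffs,
        models=models,
        positional_tables=positional,
        background=background,
        csis=csis,
        n_trees=n_trees,
        seed=seed,
        substitution_matrix=substitution_matrix,
        skipped=skipped,
    )


def cross_validate_grid(
    corpus: Sequence[CodingSequence],
    windows: Sequence[int] = FULL_GRID_WINDOWS,
    cutoffs: Sequence[float] = FULL_GRID_CUTOFFS,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    folds: int = 10,
    substitution_matrix: str = "BLOSUM62",
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Ten-fold CV accuracy for every grid cell, as a tidy DataFrame.

    Columns: amino_acid, window, cutoff, n, n_skipped, accuracy, fold
    accuracies (semicolon-joined). Cells without data are omitted.
    """
    corpus = list(corpus)
    background = usage_table_from_corpus(corpus, code)
    rows = []
    cell_index = 0
    for window in windows:
        index = build_csi(corpus, window, code, background)
        searcher = CsiSearcher(index, MatchConfig(substitution_matrix=substitution_matrix), code)
        positions = _positions_by_aa(corpus, window, code)
        for aa in sorted(code.degenerate_aas):
            items = positions.get(aa, [])
            feat_cache: dict[tuple[str, float], np.ndarray | None] = {}
            for cutoff in (_cutoff_key(c) for c in cutoffs):
                cell_index += 1
                feats, labels = [], []
                for frag, mid, _ in items:
                    ck = (frag, cutoff)
                    if ck not in feat_cache:
                        feat_cache[ck] = searcher.feature_vector(frag, cutoff)
                    if feat_cache[ck] is not None:
                        feats.append(feat_cache[ck])
                        labels.append(mid)
                if len(feats) < folds:
                    continue
                ts = TrainingSet(
                    aa, window, cutoff, np.vstack(feats),
                    np.array(labels, dtype=object), ("",) * len(labels),
                    n_skipped=len(items) - len(feats),
                )
                spec = ClassifierSpec(aa, window, cutoff, n_trees, _cell_seed(seed, cell_index))
                cv = cross_validate(ts, spec, folds, code)
                rows.append(
                    {
                        "amino_acid": aa,
                        "window": window,
                        "cutoff": cutoff,
                        "n": cv.n,
                        "n_skipped": ts.n_skipped,
                        "accuracy": cv.accuracy,
                        "fold_accuracies": ";".join(f"{a:.6f}" for a in cv.fold_accuracies),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------


def _cell_filename(aa: str, window: int, cutoff: float) -> str:
    return f"{aa}_w{window}_c{int(round(cutoff * 100)):03d}.joblib"


def save_bundle(bundle: ClassifierBundle, path) -> None:
    """Persist a bundle as a directory; refuses to save an empty bundle."""
    from .design import write_positional_tables  # local: avoids module cycle

    if not bundle.models:
        raise ValueError("refusing to save a bundle with no trained models")
    root = Path(path)
    (root / "models").mkdir(parents=True, exist_ok=True)
    for window, index in bundle.csis.items():
        save_csi(index, root / f"csi_w{window}.csi")
    write_positional_tables(bundle.positional_tables, root / "positional_tables.tsv")
    cells = []
    for (aa, window, cutoff), model in sorted(bundle.models.items()):
        fname = _cell_filename(aa, window, cutoff)
        joblib.dump(model, root / "models" / fname)
        cells.append(
            {
                "amino_acid": aa,
                "window": window,
                "cutoff": cutoff,
                "status": "degenerate" if model.degenerate else "trained",
                "file": f"models/{fname}",
            }
        )
    manifest = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        "host_name": bundle.host_name,
        "windows": list(bundle.windows),
        "cutoffs": list(bundle.cutoffs),
        "n_trees": bundle.n_trees,
        "seed": bundle.seed,
        "substitution_matrix": bundle.substitution_matrix,
        "cells": cells,
        "skipped": [
            {"amino_acid": aa, "window": w, "cutoff": c, "reason": reason}
            for (aa, w, c), reason in sorted(bundle.skipped.items())
        ],
        "background_counts": dict(sorted(bundle.background.counts.items())),
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_bundle(path, code: GeneticCode = STANDARD_CODE) -> ClassifierBundle:
    """Load a bundle directory; predictions are identical to pre-save."""
    from .design import read_positional_tables  # local: avoids module cycle

    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise BundleFormatError(f"{path} is not a bundle (missing manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != BUNDLE_FORMAT:
        raise BundleFormatError(f"unexpected bundle format {manifest.get('format')!r}")
    if manifest.get("version") != BUNDLE_VERSION:
        raise BundleFormatError(
            f"unsupported bundle version {manifest.get('version')} (expected {BUNDLE_VERSION})"
        )
    background = CodonUsageTable.from_counts(manifest["background_counts"], code)
    csis = {
        int(w): load_csi(root / f"csi_w{w}.csi", code) for w in manifest["windows"]
    }
    positional = read_positional_tables(root / "positional_tables.tsv", background, code)
    models = {}
    for cell in manifest["cells"]:
        key = (cell["amino_acid"], int(cell["window"]), _cutoff_key(cell["cutoff"]))
        models[key] = joblib.load(root / cell["file"])
    skipped = {
        (s["amino_acid"], int(s["window"]), _cutoff_key(s["cutoff"])): s["reason"]
        for s in manifest.get("skipped", [])
    }
    return ClassifierBundle(
        host_name=manifest["host_name"],
        windows=tuple(int(w) for w in manifest["windows"]),
        cutoffs=tuple(_cutoff_key(c) for c in manifest["cutoffs"]),
        models=models,
        positional_tables=positional,
        background=background,
        csis=csis,
        n_trees=int(manifest["n_trees"]),
        seed=int(manifest["seed"]),
        substitution_matrix=manifest.get("substitution_matrix", "BLOSUM62"),
        skipped=skipped,
    )
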