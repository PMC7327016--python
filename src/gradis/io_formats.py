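"""Readers and writers for the external artifacts of a GRN-inference run.

All on-disk formats follow the DREAM-challenge dialect: tab-separated
values, genes as rows in expression matrices, plain one-id-per-line TF
lists, and (tf, target[, label]) edge lists for gold standards.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataValidationError",
    "TrainingError",
    "ExpressionMatrix",
    "GoldStandard",
    "read_expression",
    "write_expression",
    "read_tf_list",
    "write_tf_list",
    "read_gold_standard",
    "write_gold_standard",
    "ranked_edge_list",
    "write_ranked_edges",
    "read_ranked_edges",
    "write_score_table",
    "read_score_table",
]


class DataValidationError(ValueError):
    """Raised when an input artifact violates a format or consistency rule."""


class TrainingError(RuntimeError):
    """Raised when a classifier cannot be fit (numerical/training failure)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix with identifier axes.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        dup = [g for g, c in Counter(self.gene_ids).items() if c > 1]
        if dup:
            raise DataValidationError(f"duplicate gene ids: {sorted(dup)}")
        dup = [s for s, c in Counter(self.sample_ids).items() if c > 1]
        if dup:
            raise DataValidationError(f"duplicate sample ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise DataValidationError(f"unknown gene id: {gene_id!r}") from None

    def profile(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        return self.values[self.gene_index(gene_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))


@dataclass
class GoldStandard:
    """Known TF->gene regulatory interactions (the positive class).

    ``positives`` and ``known_negatives`` are sets of ordered (tf, gene)
    pairs; direction always runs from a TF in ``tf_ids`` to a target gene.
    """

    tf_ids: set[str]
    positives: set[tuple[str, str]]
    known_negatives: set[tuple[str, str]] = field(default_factory=set)
    allow_self_pairs: bool = False

    def __post_init__(self) -> None:
        self.tf_ids = set(map(str, self.tf_ids))
        self.positives = {(str(a), str(b)) for a, b in self.positives}
        self.known_negatives = {(str(a), str(b)) for a, b in self.known_negatives}
        clash = self.positives & self.known_negatives
        if clash:
            raise DataValidationError(
                f"pairs labelled both positive and negative: {sorted(clash)[:5]}"
            )
        for pair_set, name in ((self.positives, "positive"), (self.known_negatives, "negative")):
            for tf, g in pair_set:
                if tf not in self.tf_ids:
                    raise DataValidationError(f"{name} pair ({tf}, {g}): {tf!r} is not a listed TF")
                if tf == g and not self.allow_self_pairs:
                    raise DataValidationError(f"self-pair ({tf}, {g}) not allowed")

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    def uncharacterized_pairs(
        self,
        gene_universe: Iterable[str],
        target_universe: Iterable[str] | None = None,
    ) -> list[tuple[str, str]]:
        """All (tf, gene) pairs with no label: the candidate pool for
        negative-class mining and for network-wide prediction.

        The gene universe defaults to every gene in the expression matrix;
        ``target_universe`` restricts the allowed targets (some benchmarks
        score only genes known to be regulated).
        """
        targets = sorted(set(target_universe if target_universe is not None else gene_universe))
        labelled = self.positives | self.known_negatives
        return [
            (tf, g)
            for tf in sorted(self.tf_ids)
            for g in targets
            if g != tf and (tf, g) not in labelled
        ]


def read_expression(
    path: str | Path,
    *,
    genes_as_rows: bool = True,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read an expression TSV: one header row of sample ids, first column gene ids.

    Set ``genes_as_rows=False`` for transposed files, or ``sep=','`` for CSV.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not genes_as_rows:
        df = df.T
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise DataValidationError(f"duplicate gene ids in {path}: {dup}")
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise DataValidationError(
                f"non-numeric value {df[col].iloc[i]!r} at row {df.index[i]!r}, "
                f"column {col!r} in {path}"
            )
        df[col] = numeric
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise DataValidationError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    expr = ExpressionMatrix.from_dataframe(df)
    logger.info("read expression matrix %s: %d genes x %d samples", path, *expr.shape)
    return expr


def write_expression(expr: ExpressionMatrix, path: str | Path, *, sep: str = "\t") -> Path:
    path = Path(path)
    expr.to_dataframe().to_csv(path, sep=sep, float_format="%.10g")
    return path


def read_tf_list(path: str | Path) -> list[str]:
    """Plain-text TF list, one identifier per line; blank lines ignored."""
    with open(path) as fh:
        tfs = [line.strip() for line in fh if line.strip()]
    dup = [t for t, c in Counter(tfs).items() if c > 1]
    if dup:
        raise DataValidationError(f"duplicate TF ids in {path}: {sorted(dup)}")
    return tfs


def write_tf_list(tf_ids: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{t}\n" for t in sorted(tf_ids)))
    return path


def read_gold_standard(
    path: str | Path,
    tf_list_path: str | Path | None = None,
    *,
    tf_ids: Iterable[str] | None = None,
    strict: bool = True,
    sep: str = "\t",
) -> GoldStandard:
    """Read a DREAM-style edge list: (tf, target[, label]) rows, label in {1, 0}.

    Without a label column every row is a positive. With ``strict`` (default)
    an edge whose source is missing from the TF list is an error; otherwise it
    is dropped with a warning.
    """
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] == 2:
        df[2] = "1"
    elif df.shape[1] != 3:
        raise DataValidationError(
            f"{path}: expected 2 or 3 columns (tf, target[, label]), got {df.shape[1]}"
        )
    bad_labels = sorted(set(df[2]) - {"0", "1"})
    if bad_labels:
        raise DataValidationError(f"{path}: labels must be 0/1, found {bad_labels}")

    if tf_ids is None:
        tf_ids = read_tf_list(tf_list_path) if tf_list_path is not None else sorted(set(df[0]))
    tf_set = set(map(str, tf_ids))

    unknown = sorted(set(df[0]) - tf_set)
    if unknown:
        if strict:
            raise DataValidationError(f"{path}: edge sources not in TF list: {unknown[:10]}")
        logger.warning("dropping %d edges with unlisted TF sources: %s", len(unknown), unknown[:10])
        df = df[df[0].isin(tf_set)]

    labelled: dict[tuple[str, str], str] = {}
    for tf, g, lab in df.itertuples(index=False):
        prev = labelled.get((tf, g))
        if prev is not None and prev != lab:
            raise DataValidationError(f"{path}: contradictory labels for pair ({tf}, {g})")
        labelled[(tf, g)] = lab
    positives = {p for p, lab in labelled.items() if lab == "1"}
    negatives = {p for p, lab in labelled.items() if lab == "0"}
    return GoldStandard(tf_set, positives, negatives)


def write_gold_standard(gold: GoldStandard, path: str | Path) -> Path:
    path = Path(path)
    rows = [(tf, g, 1) for tf, g in sorted(gold.positives)]
    rows += [(tf, g, 0) for tf, g in sorted(gold.known_negatives)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path


def ranked_edge_list(rows: Iterable[tuple[str, str, float]]) -> pd.DataFrame:
    """Build a ranked edge list: columns (tf, target, score), score descending.

    Ties are broken by (tf, target) so the ranking is reproducible.
    """
    df = pd.DataFrame(list(rows), columns=["tf", "target", "score"])
    df["score"] = pd.to_numeric(df["score"])
    if not np.all(np.isfinite(df["score"])):
        raise DataValidationError("ranked edge list contains non-finite scores")
    df = df.sort_values(
        ["score", "tf", "target"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def write_ranked_edges(ranked: pd.DataFrame, path: str | Path, *, precision: int = 6) -> Path:
    """Write a DREAM-dialect prediction file: tf <tab> target <tab> score, no header."""
    if len(ranked) == 0:
        raise DataValidationError("refusing to write an empty ranked edge list")
    scores = pd.to_numeric(ranked["score"])
    if not np.all(np.isfinite(scores)):
        raise DataValidationError("ranked edge list contains NaN/inf scores")
    if not (scores.diff().dropna() <= 0).all():
        raise DataValidationError("ranked edge list is not sorted by descending score")
    path = Path(path)
    ranked.to_csv(path, sep="\t", header=False, index=False, float_format=f"%.{precision}f")
    return path


def read_ranked_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target", "score"], dtype={0: str, 1: str})
    return ranked_edge_list(df.itertuples(index=False))


def write_score_table(scores: dict[tuple[str, str], int], path: str | Path) -> Path:
    """Write the pair-plausibility score table as (tf, gene, score) TSV."""
    path = Path(path)
    rows = sorted((tf, g, int(s)) for (tf, g), s in scores.items())
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path


def read_score_table(path: str | Path) -> dict[tuple[str, str], int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "gene", "score"], dtype={0: str, 1: str})
    return {(r.tf, r.gene): int(r.score) for r in df.itertuples(index=False)}
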