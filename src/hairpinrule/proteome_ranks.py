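"""Virion proteome abundance processing and paired-rank comparison.

Pipeline, in this fixed order: keep proteins identified by at least ``k``
peptides, divide each replicate iBAQ column by its own sum (relative
abundance), score each protein by the row sum of the normalized columns,
rank with 1 = most abundant (average ranks on ties), and compare two
virions through their ortholog pairs. The correlation refers to viral
pairs only; host pairs are carried for reporting.

Tables are pandas DataFrames with columns ``protein_id``, ``source``
('viral'/'host'), ``peptide_count`` and one or more ``ibaq*`` intensity
columns (two analytical replicates in the canonical design).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enrichment_stats import CorrelationResult, pearson_test

REQUIRED_COLUMNS = ("protein_id", "source", "peptide_count")


@dataclass
class RankComparison:
    """Paired ranks of orthologous proteins in two virions."""

    pairs: pd.DataFrame  # columns: id_a, id_b, source, rank_a, rank_b
    correlation: CorrelationResult  # viral pairs only
    n_shared_viral: int
    n_only_a: int
    n_only_b: int


def ibaq_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("ibaq")]
    if not cols:
        raise ValueError("no ibaq* intensity columns")
    return cols


def read_proteome_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ibaq_columns(table)
    return table


def write_proteome_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def filter_min_peptides(table: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Keep proteins identified by at least k peptides; order preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return table[table["peptide_count"] >= k].reset_index(drop=True)


def normalize_columns(table: pd.DataFrame) -> np.ndarray:
    """Column-wise normalized intensity matrix (each column sums to 1)."""
    if len(table) == 0:
        raise ValueError("empty table")
    mat = table[ibaq_columns(table)].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative intensity")
    sums = mat.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("all-zero intensity column")
    return mat / sums


def rank_by_summed_ibaq(normalized: np.ndarray) -> np.ndarray:
    """Ranks from the summed normalized intensities; 1 = most abundant,
    ties get the average of the ranks they span."""
    scores = normalized.sum(axis=1)
    return rankdata(-scores, method="average")


def add_ranks(table: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """filter -> normalize -> rank; returns the filtered table + 'rank'."""
    kept = filter_min_peptides(table, k)
    if len(kept) == 0:
        raise ValueError("no proteins left after the peptide filter")
    kept = kept.copy()
    kept["rank"] = rank_by_summed_ibaq(normalize_columns(kept))
    return kept


def pair_orthologs(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    ortholog_pairs: Sequence[tuple[str, str]],
    min_peptides: int = 2,
) -> RankComparison:
    """Rank two virion tables independently and join them on orthologs.

    Each id may appear in at most one ortholog pair. The Pearson
    correlation is computed on the paired ranks of viral proteins only;
    ``n_only_a``/``n_only_b`` count filtered proteins left without a
    detected partner.
    """
    ids_a = [p[0] for p in ortholog_pairs]
    ids_b = [p[1] for p in ortholog_pairs]
    for ids, label in ((ids_a, "A"), (ids_b, "B")):
        dup = pd.Series(ids).duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate ortholog mapping in table {label}: "
                f"{sorted(set(np.array(ids)[dup]))}"
            )
    ranked_a = add_ranks(table_a, min_peptides).set_index("protein_id")
    ranked_b = add_ranks(table_b, min_peptides).set_index("protein_id")
    rows = []
    for id_a, id_b in ortholog_pairs:
        if id_a in ranked_a.index and id_b in ranked_b.index:
            rows.append(
                {
                    "id_a": id_a,
                    "id_b": id_b,
                    "source": ranked_a.loc[id_a, "source"],
                    "rank_a": float(ranked_a.loc[id_a, "rank"]),
                    "rank_b": float(ranked_b.loc[id_b, "rank"]),
                }
            )
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "source", "rank_a", "rank_b"])
    paired_a = set(pairs["id_a"])
    paired_b = set(pairs["id_b"])
    viral = pairs[pairs["source"] == "viral"]
    if len(viral) >= 3:
        corr = pearson_test(viral["rank_a"], viral["rank_b"])
    else:
        corr = CorrelationResult(
            r=float("nan"), r_squared=float("nan"), p_value=float("nan"), n=len(viral)
        )
    return RankComparison(
        pairs=pairs,
        correlation=corr,
        n_shared_viral=len(viral),
        n_only_a=int((~ranked_a.index.isin(paired_a)).sum()),
        n_only_b=int((~ranked_b.index.isin(paired_b)).sum()),
    )


def read_ortholog_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (id_a, id_b), optional header line."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("id_a", "idA"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            pairs.append((parts[0], parts[1]))
    return pairs
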