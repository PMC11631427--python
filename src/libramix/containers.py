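"""In-memory containers for antigen barcode count data and BCR chain tables.

A LIBRA-seq experiment yields, per droplet (cell), one UMI count for every
DNA-barcoded antigen in the panel, plus the assembled B cell receptor
chains.  These containers hold both, with validation of the invariants the
rest of the pipeline relies on (nonnegative integer counts, unique
identifiers, a restricted amino-acid alphabet for CDR3 strings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The 20 standard amino acids plus X (unknown residue).
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

HEAVY = "heavy"
LIGHT = "light"


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True)
class UmiCountMatrix:
    """Cells x antigens matrix of nonnegative integer UMI counts."""

    cell_ids: list[str]
    antigen_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.cell_ids), len(self.antigen_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.antigen_ids)} antigens"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at cell {self.cell_ids[i]!r}, "
                f"antigen {self.antigen_ids[j]!r}"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.antigen_ids, "antigen")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_antigens(self) -> int:
        return len(self.antigen_ids)

    def column(self, antigen_id: str) -> np.ndarray:
        """Counts for one antigen across all cells, in cell order."""
        j = self.antigen_ids.index(antigen_id)
        return self.counts[:, j]

    def subset_cells(self, cell_ids) -> "UmiCountMatrix":
        """Row subset in the given order; unknown ids raise."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            rows = [index[c] for c in cell_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown cell id {exc.args[0]!r}") from None
        return UmiCountMatrix(list(cell_ids), list(self.antigen_ids),
                              self.counts[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.cell_ids, name="cell_id"),
                            columns=list(self.antigen_ids))


@dataclass(frozen=True)
class ScoreMatrix:
    """Cells x antigens matrix of real-valued scores (same shape as counts)."""

    cell_ids: list[str]
    antigen_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.cell_ids), len(self.antigen_ids)):
            raise ValidationError("scores shape does not match ids")
        if scores.size and not np.all(np.isfinite(scores)):
            raise ValidationError("scores must be finite")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.antigen_ids, "antigen")
        object.__setattr__(self, "scores", scores)

    def column(self, antigen_id: str) -> np.ndarray:
        j = self.antigen_ids.index(antigen_id)
        return self.scores[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=pd.Index(self.cell_ids, name="cell_id"),
                            columns=list(self.antigen_ids))


@dataclass(frozen=True)
class BcrTable:
    """Per-cell receptor chain records: (cell_id, chain, cdr3_aa).

    Exact duplicate rows are collapsed on construction; the same cell may
    legitimately carry several distinct heavy chains (it is then removed by
    the multi-heavy-chain filter downstream).
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = {"cell_id", "chain", "cdr3_aa"} - set(df.columns)
        if missing:
            raise ValidationError(f"BCR table missing columns: {sorted(missing)}")
        df = df[["cell_id", "chain", "cdr3_aa"]].astype(str)
        bad_chain = ~df["chain"].isin([HEAVY, LIGHT])
        if bad_chain.any():
            raise ValidationError(
                f"chain must be 'heavy' or 'light', got {df.loc[bad_chain, 'chain'].iloc[0]!r}"
            )
        for cdr3 in df["cdr3_aa"]:
            if not cdr3:
                raise ValidationError("empty cdr3_aa")
            extra = set(cdr3) - AA_ALPHABET
            if extra:
                raise ValidationError(
                    f"cdr3_aa {cdr3!r} contains non-amino-acid characters {sorted(extra)}"
                )
        df = df.drop_duplicates(ignore_index=True)
        object.__setattr__(self, "records", df)

    @property
    def cell_ids(self) -> list[str]:
        """Unique cell ids in first-appearance order."""
        return list(dict.fromkeys(self.records["cell_id"]))

    def heavy_chains(self) -> pd.DataFrame:
        return self.records[self.records["chain"] == HEAVY]

    def __len__(self) -> int:
        return len(self.records)
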