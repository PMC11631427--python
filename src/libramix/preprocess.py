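"""Preprocessing filters applied before model fitting.

Three steps precede any fitting: cells with more than one heavy chain are
removed (possible multiplets or sequencing errors); negative-control cells
are separated from donor B cells by comparing heavy-chain CDR3 amino-acid
sequences to the control antibody's CDR3 with a normalized Levenshtein
distance (default threshold 0.05, i.e. 95% identity); and, per antigen and
per population, UMI counts above the 99th percentile are dropped as
outliers.  Low counts (<4) are deliberately retained here — they carry the
shape of the noise distribution — and are zeroed only on the LIBRA-seq
score path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np

from .containers import HEAVY, BcrTable

logger = logging.getLogger(__name__)

__all__ = [
    "SplitResult",
    "filter_multi_heavy_chain",
    "normalized_levenshtein",
    "split_control_cells",
    "remove_outliers",
]


@dataclass(frozen=True)
class SplitResult:
    """Control/donor partition of cells with per-cell audit distances."""

    control_cell_ids: set[str]
    donor_cell_ids: set[str]
    distances: dict[str, float]
    excluded_cell_ids: set[str]  # cells without a heavy chain
    threshold: float

    def __post_init__(self) -> None:
        assert self.control_cell_ids.isdisjoint(self.donor_cell_ids)


def filter_multi_heavy_chain(bcr: BcrTable) -> tuple[BcrTable, set[str]]:
    """Remove every cell that carries two or more distinct heavy chains.

    All rows (heavy and light) of a removed cell are dropped.  Idempotent;
    empty input passes through.
    """
    df = bcr.records
    if df.empty:
        return bcr, set()
    heavy_counts = df[df["chain"] == HEAVY].groupby("cell_id")["cdr3_aa"].nunique()
    removed = set(heavy_counts[heavy_counts > 1].index)
    kept = BcrTable(df[~df["cell_id"].isin(removed)].reset_index(drop=True))
    if removed:
        logger.info("multi-heavy-chain filter removed %d cells", len(removed))
    return kept, removed


def normalized_levenshtein(a: str, b: str) -> float:
    """Edit distance (unit-cost insert/delete/substitute) / max(len(a), len(b))."""
    if not a or not b:
        raise ValueError("normalized_levenshtein requires nonempty strings")
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return dist / max(len(a), len(b))


def split_control_cells(bcr: BcrTable, reference_cdr3: str,
                        threshold: float = 0.05) -> SplitResult:
    """Partition cells into controls (CDR3 near the reference) and donors.

    Assumes the multi-heavy-chain filter already ran, so each cell has at
    most one heavy chain; cells with none are excluded with a warning.
    A cell is a control iff its normalized Levenshtein distance to
    ``reference_cdr3`` is <= ``threshold``.
    """
    if not reference_cdr3:
        raise ValueError("reference_cdr3 must be nonempty")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    heavy = bcr.heavy_chains()
    cells_with_heavy = dict(zip(heavy["cell_id"], heavy["cdr3_aa"]))
    excluded = set(bcr.cell_ids) - set(cells_with_heavy)
    if excluded:
        logger.warning("%d cells lack a heavy chain and were excluded from the "
                       "control/donor split", len(excluded))
    controls: set[str] = set()
    donors: set[str] = set()
    distances: dict[str, float] = {}
    for cell_id, cdr3 in cells_with_heavy.items():
        d = normalized_levenshtein(cdr3, reference_cdr3)
        distances[cell_id] = d
        (controls if d <= threshold else donors).add(cell_id)
    return SplitResult(control_cell_ids=controls, donor_cell_ids=donors,
                       distances=distances, excluded_cell_ids=excluded,
                       threshold=threshold)


def remove_outliers(values, percentile: float = 99.0) -> tuple[np.ndarray, np.ndarray]:
    """Drop values strictly above the given percentile (linear interpolation).

    Ties at the percentile are kept.  Returns (kept, removed) preserving
    input order within each part.  Intended to be applied per antigen and
    separately to the control and donor populations.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must lie in (0, 100]")
    cut = np.percentile(values, percentile, method="linear")
    mask = values > cut
    return values[~mask], values[mask]
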