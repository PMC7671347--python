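"""Subgenome assignment of allopolyploid read pairs by mismatch comparison.

Each hybrid fragment (paired-end read pair) is aligned upstream to both the
reference progenitor genome and the virtual second-progenitor genome; the
fragment is assigned to whichever genome it matches with strictly fewer
mismatches, and left unassigned on a tie.  Mismatch counting itself is out of
scope here — the module consumes per-fragment edit distances (e.g. alignment
NM tags summed over mates) from a table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SortSummary", "sort_fragment", "sort_all", "read_fragment_tsv"]

CALLS = ("Bd", "Bs", "unassigned")


@dataclass(frozen=True)
class SortSummary:
    n_bd: int
    n_bs: int
    n_unassigned: int

    @property
    def total(self) -> int:
        return self.n_bd + self.n_bs + self.n_unassigned

    @property
    def assignment_rate(self) -> float:
        """(Bd + Bs) / total — the fraction of fragments sorted to a subgenome."""
        return (self.n_bd + self.n_bs) / self.total if self.total else 0.0


def sort_fragment(
    mm_bd: float, mm_bs: float, assign_single_hits: bool = True
) -> str:
    """Call one fragment from its two mismatch counts.

    Strict minority rule: ``Bd`` iff ``mm_bd < mm_bs``, ``Bs`` iff
    ``mm_bs < mm_bd``, ``unassigned`` on a tie (never broken randomly).  A
    fragment unmapped to one genome is encoded as ``NaN`` / ``inf`` on that
    side and, when ``assign_single_hits`` is true, goes to the mapped genome.
    """
    bd_missing = mm_bd is None or (isinstance(mm_bd, float) and not np.isfinite(mm_bd))
    bs_missing = mm_bs is None or (isinstance(mm_bs, float) and not np.isfinite(mm_bs))
    if bd_missing and bs_missing:
        return "unassigned"
    if bd_missing or bs_missing:
        if not assign_single_hits:
            return "unassigned"
        return "Bs" if bd_missing else "Bd"
    if mm_bd < 0 or mm_bs < 0:
        raise ValueError("mismatch counts must be non-negative")
    if mm_bd < mm_bs:
        return "Bd"
    if mm_bs < mm_bd:
        return "Bs"
    return "unassigned"


def sort_all(
    fragments: pd.DataFrame, assign_single_hits: bool = True
) -> tuple[pd.DataFrame, SortSummary]:
    """Vectorised assignment of a fragment mismatch table.

    ``fragments`` needs ``fragment_id, mm_bd, mm_bs`` (``gene_id`` optional,
    carried through for per-gene counting).  Missing-side values may be NaN.
    Raises on duplicate fragment ids or an empty table.
    """
    if len(fragments) == 0:
        raise ValueError("fragment table is empty")
    if fragments["fragment_id"].duplicated().any():
        dup = fragments.loc[fragments["fragment_id"].duplicated(), "fragment_id"].iloc[0]
        raise ValueError(f"duplicate fragment id: {dup!r}")
    mm_bd = fragments["mm_bd"].to_numpy(dtype=float)
    mm_bs = fragments["mm_bs"].to_numpy(dtype=float)
    if np.nanmin(mm_bd) < 0 or np.nanmin(mm_bs) < 0:
        raise ValueError("mismatch counts must be non-negative")
    bd_missing = ~np.isfinite(mm_bd)
    bs_missing = ~np.isfinite(mm_bs)
    if not assign_single_hits:
        work_bd = np.where(bd_missing, np.inf, mm_bd)
        work_bs = np.where(bs_missing, np.inf, mm_bs)
        work_bd[bd_missing & ~bs_missing] = work_bs[bd_missing & ~bs_missing]
        work_bs[bs_missing & ~bd_missing] = work_bd[bs_missing & ~bd_missing]
    else:
        work_bd = np.where(bd_missing, np.inf, mm_bd)
        work_bs = np.where(bs_missing, np.inf, mm_bs)
    call = np.where(
        work_bd < work_bs, "Bd", np.where(work_bs < work_bd, "Bs", "unassigned")
    )
    out = fragments.copy()
    out["call"] = call
    summary = SortSummary(
        n_bd=int((call == "Bd").sum()),
        n_bs=int((call == "Bs").sum()),
        n_unassigned=int((call == "unassigned").sum()),
    )
    return out, summary


def read_fragment_tsv(path: str | Path) -> pd.DataFrame:
    frag = pd.read_csv(path, sep="\t")
    missing = {"fragment_id", "mm_bd", "mm_bs"} - set(frag.columns)
    if missing:
        raise ValueError(f"fragment table missing columns: {sorted(missing)}")
    return frag
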