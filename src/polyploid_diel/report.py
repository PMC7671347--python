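"""Run-report bookkeeping: partition identities and percentage arithmetic.

Every summary table the pipeline emits is a partition of some gene or
fragment universe (HEB pattern classes over eligible groups, DEG directions
over DEGs, subgenome calls over fragments).  The helpers here re-check those
identities from the component counts, so a report can be validated without
re-running any stage — and so published-style summary tallies can be checked
for internal consistency by the same arithmetic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "check_partition",
    "recompute_percentages",
    "percentages_consistent",
    "validate_report",
]


def check_partition(total: int, parts) -> bool:
    """True iff the component counts sum exactly to the stated total."""
    return int(np.sum(list(parts))) == int(total)


def recompute_percentages(total: int, parts) -> list[float]:
    """Component percentages of ``total``, rounded to 0.1."""
    if total <= 0:
        raise ValueError("total must be positive")
    return [round(100.0 * p / total, 1) for p in parts]


def percentages_consistent(total: int, parts, printed, tol: float = 0.1) -> bool:
    """True iff printed percentages match recomputation within ``tol``."""
    recomputed = recompute_percentages(total, parts)
    return all(abs(r - p) <= tol + 1e-9 for r, p in zip(recomputed, printed))


def validate_report(report: dict) -> tuple[bool, list[str]]:
    """Re-check every partition identity recorded in a pipeline report.

    Returns ``(passed, failures)`` where failures name each violated
    identity.  Checked identities:

    * fragment conservation: Bd + Bs + unassigned = fragment total;
    * HEB patterns: balance_retention_all + constitutive + temporal counts
      sum to the eligible-group universe;
    * DEG directions: up_A + up_B + unclassified = DEG total, per contrast;
    * percentages stored next to counts recompute within 0.1.
    """
    failures: list[str] = []

    sorting = report.get("sorting")
    if sorting:
        if not check_partition(
            sorting["n_fragments"],
            [sorting["n_bd"], sorting["n_bs"], sorting["n_unassigned"]],
        ):
            failures.append("fragment conservation: Bd + Bs + unassigned != total")

    heb = report.get("heb")
    if heb:
        counts = [row["count"] for row in heb["pattern_table"]]
        if not check_partition(heb["n_eligible"], counts):
            failures.append("HEB pattern counts do not partition the universe")
        pcts = [row["percent"] for row in heb["pattern_table"]]
        if not percentages_consistent(heb["n_eligible"], counts, pcts):
            failures.append("HEB pattern percentages do not recompute")

    for name, deg in report.get("deg", {}).items():
        parts = [deg["up_A"], deg["up_B"], deg["unclassified"]]
        if not check_partition(deg["n_deg"], parts):
            failures.append(f"DEG composition for {name}: directions != total")

    return (not failures), failures
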