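"""Exclusion accounting: remove cores unsuitable for evaluation.

Exclusion is annotation-driven — pathologists mark cores as ductal
carcinoma in situ, insufficiently fixed, cytoplasmically stained, without
cancer, or peeled, and this module only tabulates and filters. The
exclusion annotation of the BR20810 breast-cancer TMA (104 cases,
duplicate cores) is shipped as a constant: 38 of its 208 cores (18%) are
excluded, leaving 170 analyzable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import CoreRecord

#: Pathologist exclusion annotation of the BR20810 TMA, by reason.
BR20810_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "dcis": (
        "A5", "A6", "A11", "A12", "C1", "C2", "C10", "C14", "C15", "C16",
        "D7", "D9", "D10", "F8", "G15", "G16", "H3", "H4", "I7", "I8",
        "J3", "M15", "M16",
    ),
    "fixation": ("F3", "F4", "E13", "E14", "K11", "K12", "L1", "L2"),
    "cytoplasmic": ("L7", "L8"),
    "no_cancer": ("H15", "K15", "K16"),
    "peeling": ("B4", "E5"),
}

BR20810_N_CASES = 104
BR20810_N_CORES = 208


@dataclass
class ExclusionSummary:
    """Accounting of one cohort's exclusion pass."""

    counts: dict[str, int]
    excluded_total: int
    excluded_percent: int  # rounded to nearest integer for reporting
    analyzable: int
    n_negative_controls: int = 0

    @property
    def input_size(self) -> int:
        return self.excluded_total + self.analyzable + self.n_negative_controls


def apply_exclusions(records: list[CoreRecord]) -> tuple[list[CoreRecord], ExclusionSummary]:
    """Partition records into analyzable cores and an exclusion summary.

    Analyzable = exclusion reason ``none`` and not a negative control;
    input order is preserved. Negative controls with no exclusion reason
    are counted separately (they are scored for the detection floor but
    never classified).
    """
    counts: dict[str, int] = {}
    analyzable: list[CoreRecord] = []
    n_nc = 0
    for rec in records:
        if rec.exclusion_reason != "none":
            counts[rec.exclusion_reason] = counts.get(rec.exclusion_reason, 0) + 1
        elif rec.is_negative_control:
            n_nc += 1
        else:
            analyzable.append(rec)
    excluded_total = sum(counts.values())
    n = len(records)
    pct = int(round(100.0 * excluded_total / n)) if n else 0
    return analyzable, ExclusionSummary(
        counts=counts,
        excluded_total=excluded_total,
        excluded_percent=pct,
        analyzable=len(analyzable),
        n_negative_controls=n_nc,
    )
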