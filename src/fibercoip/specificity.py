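"""Replicate-presence filtering and pre-immune specificity classes.

Candidate interactors must be detected in every independent pull-down
experiment before they enter the analysis.  Each retained protein is
then compared against the pre-immune-serum control IP: proteins never
seen in the control are *specific (absent from control)*; proteins whose
summed target-antibody spectral counts exceed the control by at least
the fold threshold (default 2) are *specific (enriched)*; the rest bind
the beads/serum non-specifically.

Fold changes are computed on total peptide counts summed over all
experiments and both extraction conditions — the simplest per-protein
aggregation consistent with a per-protein fold statement.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Iterable, Mapping, Sequence

from .io_model import (
    NOT_MEASURED,
    Antibody,
    MissingCellError,
    ProteinProfile,
    Treatment,
)

__all__ = [
    "SpecificityClass",
    "SpecificityResult",
    "presence_filter",
    "specificity_classify",
    "classify_specificity",
    "write_specificity_table",
]


class SpecificityClass(str, enum.Enum):
    SPECIFIC_ABSENT_CONTROL = "specific_absent_control"
    SPECIFIC_ENRICHED = "specific_enriched"
    NONSPECIFIC = "nonspecific"


@dataclasses.dataclass(frozen=True)
class SpecificityResult:
    protein_id: str
    target_sum: int
    control_sum: int
    fold: float  # math.inf when the control never saw the protein
    klass: SpecificityClass


def presence_filter(
    profiles: Mapping[str, ProteinProfile],
    required_experiments: int = 3,
    antibody: Antibody | str = Antibody.TARGET,
) -> set[str]:
    """Proteins detected in every one of ``required_experiments`` pull-downs.

    Detection means a total peptide count >= 1 in at least one treatment
    cell of the experiment under ``antibody``; unmeasured cells do not
    count as detection.
    """
    if required_experiments < 1:
        raise ValueError("required_experiments must be >= 1")
    ab = Antibody(antibody)
    retained: set[str] = set()
    for pid, prof in profiles.items():
        detected_everywhere = True
        for exp in range(1, required_experiments + 1):
            hit = False
            for tr in (Treatment.BLANK, Treatment.TREATED):
                total = prof.total(exp, ab, tr)
                if total is not NOT_MEASURED and total >= 1:
                    hit = True
                    break
            if not hit:
                detected_everywhere = False
                break
        if detected_everywhere:
            retained.add(pid)
    return retained


def specificity_classify(
    target_counts: Sequence[int],
    control_counts: Sequence[int],
    fold_threshold: float = 2.0,
    protein_id: str = "",
) -> SpecificityResult:
    """Classify one protein from its per-experiment total-count series.

    Both series are summed; the fold is target/control (infinite when
    the control sum is zero).  A protein absent from both sums should
    never have reached classification and raises ``ValueError``.
    """
    if len(target_counts) != len(control_counts):
        raise ValueError("target and control series must cover the same experiments")
    if any(c < 0 for c in target_counts) or any(c < 0 for c in control_counts):
        raise ValueError("counts must be non-negative")
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    target_sum = int(sum(target_counts))
    control_sum = int(sum(control_counts))
    if target_sum == 0 and control_sum == 0:
        raise ValueError(
            f"protein {protein_id!r} has zero counts under both sera; "
            "it should have been removed by the presence filter"
        )
    if control_sum == 0:
        fold = math.inf
        klass = SpecificityClass.SPECIFIC_ABSENT_CONTROL
    else:
        fold = target_sum / control_sum
        klass = (
            SpecificityClass.SPECIFIC_ENRICHED
            if fold >= fold_threshold
            else SpecificityClass.NONSPECIFIC
        )
    return SpecificityResult(protein_id, target_sum, control_sum, fold, klass)


def _sum_totals(prof: ProteinProfile, antibody: Antibody) -> tuple[list[int], bool]:
    totals: list[int] = []
    measured = False
    for (exp, ab, _tr), (total, _distinct) in sorted(prof.counts.items()):
        if ab == antibody:
            totals.append(total)
            measured = True
    return totals, measured


def classify_specificity(
    profiles: Mapping[str, ProteinProfile], fold_threshold: float = 2.0
) -> dict[str, SpecificityResult]:
    """Classify every profile that carries pre-immune control cells.

    Sums all measured total counts per antibody (experiments x
    treatments).  A profile with no pre-immune cell at all cannot be
    compared against the control and raises :class:`MissingCellError`.
    """
    results: dict[str, SpecificityResult] = {}
    for pid in sorted(profiles):
        prof = profiles[pid]
        target_totals, _ = _sum_totals(prof, Antibody.TARGET)
        control_totals, has_control = _sum_totals(prof, Antibody.PREIMMUNE)
        if not has_control:
            raise MissingCellError(
                f"{pid}: no pre-immune control cells measured; cannot classify specificity"
            )
        results[pid] = specificity_classify(
            [sum(target_totals)], [sum(control_totals)], fold_threshold, protein_id=pid
        )
    return results


def write_specificity_table(results: Mapping[str, SpecificityResult], path) -> None:
    lines = ["protein_id\ttarget_sum\tcontrol_sum\tfold\tclass"]
    for pid in sorted(results):
        r = results[pid]
        fold = "inf" if math.isinf(r.fold) else f"{r.fold:.6g}"
        lines.append(f"{pid}\t{r.target_sum}\t{r.control_sum}\t{fold}\t{r.klass.value}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
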