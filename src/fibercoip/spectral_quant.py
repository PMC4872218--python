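"""Cellulase-enhancement statistics on spectral counts.

For each protein the pull-down is run with and without cellulase in the
extraction buffer; the relative increase of its spectral count is
``(T - B) / B`` where ``B``/``T`` are the blank/treated total peptide
counts of one experiment.  Percents are computed per experiment, rounded
half-up to integers, then averaged over the (typically three)
experiments and rounded again -- the order of operations that reproduces
the published per-protein averages exactly.

A protein whose treated total strictly exceeds its blank total in
*every* experiment is Group I ("enhanced by cellulase treatment");
everything else is Group II.  The distinct-peptide series is computed
and reported alongside but does not gate the grouping: strict totals are
the only rule consistent with every published assignment (one Group-I
protein has a decreasing distinct count in one experiment).
"""

from __future__ import annotations

import dataclasses
import enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from ._rounding import round_half_up_int
from .io_model import (
    NOT_MEASURED,
    Antibody,
    MissingCellError,
    ProteinProfile,
    Treatment,
)

__all__ = [
    "EnhancementGroup",
    "EnhancementResult",
    "enhancement_percent",
    "average_enhancement",
    "classify_enhancement",
    "classify_all",
    "write_enhancement_table",
]


class EnhancementGroup(str, enum.Enum):
    GROUP_I = "I"  # more peptides upon cellulase treatment, all experiments
    GROUP_II = "II"


@dataclasses.dataclass(frozen=True)
class EnhancementResult:
    """Per-protein enhancement percents and Group I/II call.

    ``None`` entries mean the percent is undefined (blank count was
    zero, so there is no baseline to divide by).
    """

    protein_id: str
    per_experiment_total_pct: tuple[Optional[int], ...]
    per_experiment_distinct_pct: tuple[Optional[int], ...]
    avg_total_pct: Optional[int]
    avg_distinct_pct: Optional[int]
    group: EnhancementGroup


def enhancement_percent(blank_count: int, treated_count: int) -> Optional[int]:
    """Integer percent increase of ``treated_count`` over ``blank_count``.

    Computed as ``100 * (T - B) / B`` with exact rational arithmetic and
    rounded half-up.  Returns ``None`` (undefined) when the blank count
    is zero; may be negative when the treated count is lower.
    """
    if blank_count < 0 or treated_count < 0:
        raise ValueError("counts must be non-negative")
    if blank_count == 0:
        return None
    return round_half_up_int(Fraction(100 * (treated_count - blank_count), blank_count))


def average_enhancement(per_experiment_pcts: Sequence[Optional[int]]) -> Optional[int]:
    """Half-up rounded mean of already-rounded per-experiment percents.

    Undefined (``None``) as soon as any contributing percent is
    undefined; an empty list is an error.
    """
    pcts = list(per_experiment_pcts)
    if not pcts:
        raise ValueError("cannot average an empty list of percents")
    if any(p is None for p in pcts):
        return None
    return round_half_up_int(Fraction(sum(pcts), len(pcts)))


def classify_enhancement(
    profile: ProteinProfile, antibody: Antibody | str = Antibody.TARGET
) -> EnhancementResult:
    """Compute both percent series and the Group I/II call for one protein.

    Requires blank and treated cells for every experiment the profile
    covers under ``antibody``; a missing cell raises
    :class:`MissingCellError` naming it.
    """
    ab = Antibody(antibody)
    experiments = profile.experiments(ab)
    if not experiments:
        raise MissingCellError(
            f"{profile.protein_id}: no measured cells under antibody {ab.value!r}"
        )
    total_pcts: list[Optional[int]] = []
    distinct_pcts: list[Optional[int]] = []
    strictly_increasing = True
    for exp in experiments:
        cells = {}
        for tr in (Treatment.BLANK, Treatment.TREATED):
            cell = profile.get(exp, ab, tr)
            if cell is NOT_MEASURED:
                raise MissingCellError(
                    f"{profile.protein_id}: experiment {exp} "
                    f"{ab.value}/{tr.value} not measured"
                )
            cells[tr] = cell
        b_total, b_distinct = cells[Treatment.BLANK]
        t_total, t_distinct = cells[Treatment.TREATED]
        total_pcts.append(enhancement_percent(b_total, t_total))
        distinct_pcts.append(enhancement_percent(b_distinct, t_distinct))
        strictly_increasing &= t_total > b_total
    return EnhancementResult(
        protein_id=profile.protein_id,
        per_experiment_total_pct=tuple(total_pcts),
        per_experiment_distinct_pct=tuple(distinct_pcts),
        avg_total_pct=average_enhancement(total_pcts),
        avg_distinct_pct=average_enhancement(distinct_pcts),
        group=EnhancementGroup.GROUP_I if strictly_increasing else EnhancementGroup.GROUP_II,
    )


def classify_all(
    profiles: Mapping[str, ProteinProfile], antibody: Antibody | str = Antibody.TARGET
) -> tuple[dict[str, EnhancementResult], dict[EnhancementGroup, int]]:
    """Classify every profile; returns results plus Group I/II tallies."""
    results = {
        pid: classify_enhancement(profiles[pid], antibody) for pid in sorted(profiles)
    }
    counts = {EnhancementGroup.GROUP_I: 0, EnhancementGroup.GROUP_II: 0}
    for res in results.values():
        counts[res.group] += 1
    return results, counts


def _fmt(value: Optional[int]) -> str:
    return "undefined" if value is None else str(value)


def write_enhancement_table(
    results: Mapping[str, EnhancementResult],
    profiles: Mapping[str, ProteinProfile],
    path,
    antibody: Antibody | str = Antibody.TARGET,
) -> None:
    """Write a TSV mirroring the published layout: per-experiment B, T,
    percent(total), percent(distinct), the two averages, and the group."""
    ab = Antibody(antibody)
    n_exp = max((len(r.per_experiment_total_pct) for r in results.values()), default=0)
    header = ["protein_id"]
    for i in range(1, n_exp + 1):
        header += [
            f"blank_total_exp{i}",
            f"treated_total_exp{i}",
            f"pct_total_exp{i}",
            f"pct_distinct_exp{i}",
        ]
    header += ["avg_pct_total", "avg_pct_distinct", "group"]
    lines = ["\t".join(header)]
    for pid in sorted(results):
        res = results[pid]
        prof = profiles[pid]
        exps = prof.experiments(ab)
        row = [pid]
        for i in range(n_exp):
            if i < len(exps):
                exp = exps[i]
                row += [
                    str(prof.total(exp, ab, Treatment.BLANK)),
                    str(prof.total(exp, ab, Treatment.TREATED)),
                    _fmt(res.per_experiment_total_pct[i]),
                    _fmt(res.per_experiment_distinct_pct[i]),
                ]
            else:
                row += ["", "", "", ""]
        row += [_fmt(res.avg_total_pct), _fmt(res.avg_distinct_pct), res.group.value]
        lines.append("\t".join(row))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
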