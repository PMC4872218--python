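"""Core data model for the co-IP spectral-count pipeline.

Typed records shared by every analysis stage -- peptide spectral counts
from immunoprecipitation LC-MS/MS runs, radiolabel incorporation assay
readings, tissue expression matrices, and planted simulation truth --
together with strict TSV readers/writers and the packaged reference
tables used by the worked examples and the test-suite.

All files are tab-separated UTF-8 with a mandatory header row and '.'
as the decimal separator.  Readers reject malformed rows and report the
offending line number.  Absence of a measurement is always represented
explicitly (:data:`NOT_MEASURED`), never as a silent zero: a true
``0(0)`` cell participates in enhancement classification, a cell that
was never measured does not.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Antibody",
    "Treatment",
    "Method",
    "Glucan",
    "NOT_MEASURED",
    "ParseError",
    "MissingCellError",
    "PeptideCountRecord",
    "ProteinProfile",
    "AssayReading",
    "ConversionParams",
    "ExpressionMatrix",
    "SyntheticTruth",
    "read_count_table",
    "write_count_table",
    "build_profiles",
    "read_assay_table",
    "write_assay_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_truth",
    "write_truth",
    "fixture_path",
    "load_fixture",
    "load_interactome_profiles",
]


class Antibody(str, enum.Enum):
    """IP serum used for the pull-down."""

    TARGET = "target"  # anti-CESA antibody
    PREIMMUNE = "preimmune"  # pre-immunization serum, the specificity control


class Treatment(str, enum.Enum):
    """Extraction condition: with (treated) or without (blank) cellulase."""

    BLANK = "blank"
    TREATED = "treated"


class Method(str, enum.Enum):
    """Ultracentrifugation method used for membrane extraction."""

    SUCROSE_DENSITY = "sucrose_density"
    SEDIMENTATION_VELOCITY = "sedimentation_velocity"


class Glucan(str, enum.Enum):
    """Radiolabeled product fraction resolved by sequential glucanase digestion."""

    B13 = "b13"  # callose, released by beta-1,3-glucanases
    B14_NONCRYSTALLINE = "b14_noncrystalline"  # released by beta-1,4-glucanases
    B14_CRYSTALLINE = "b14_crystalline"  # digestion-resistant pellet


class _NotMeasured:
    """Singleton marker for a count cell that was never measured."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_MEASURED"

    def __bool__(self) -> bool:
        return False


NOT_MEASURED = _NotMeasured()


class ParseError(ValueError):
    """A malformed row in a delimited input file.

    Carries the 1-based line number of the offending row in ``line``.
    """

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


class MissingCellError(LookupError):
    """A required (experiment, antibody, treatment) cell is absent."""


@dataclasses.dataclass(frozen=True)
class PeptideCountRecord:
    """One protein's peptide evidence in one LC-MS/MS run cell.

    ``total_peptides`` is the spectral count (number of peptide-spectrum
    matches assigned to the protein); ``distinct_peptides`` counts the
    unique peptide sequences behind them, so it can never exceed the
    total.
    """

    protein_id: str
    experiment: int
    antibody: Antibody
    treatment: Treatment
    total_peptides: int
    distinct_peptides: int

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("empty protein_id")
        if self.experiment < 1:
            raise ValueError(f"experiment index must be >= 1, got {self.experiment}")
        if self.total_peptides < 0 or self.distinct_peptides < 0:
            raise ValueError("peptide counts must be non-negative")
        if self.distinct_peptides > self.total_peptides:
            raise ValueError(
                f"distinct_peptides ({self.distinct_peptides}) exceeds "
                f"total_peptides ({self.total_peptides})"
            )

    @property
    def key(self) -> tuple[str, int, Antibody, Treatment]:
        return (self.protein_id, self.experiment, self.antibody, self.treatment)


CellKey = tuple[int, Antibody, Treatment]
CountCell = Union[tuple[int, int], _NotMeasured]


@dataclasses.dataclass
class ProteinProfile:
    """A protein's full count matrix across experiments, antibodies, treatments.

    Only measured cells are stored; lookups for absent cells return
    :data:`NOT_MEASURED`.  No imputation is ever performed.
    """

    protein_id: str
    counts: dict[CellKey, tuple[int, int]] = dataclasses.field(default_factory=dict)
    annotation: str | None = None

    def get(self, experiment: int, antibody: Antibody | str, treatment: Treatment | str) -> CountCell:
        """Return ``(total, distinct)`` or :data:`NOT_MEASURED`."""
        key = (experiment, Antibody(antibody), Treatment(treatment))
        return self.counts.get(key, NOT_MEASURED)

    def total(self, experiment: int, antibody: Antibody | str, treatment: Treatment | str):
        cell = self.get(experiment, antibody, treatment)
        return NOT_MEASURED if cell is NOT_MEASURED else cell[0]

    def distinct(self, experiment: int, antibody: Antibody | str, treatment: Treatment | str):
        cell = self.get(experiment, antibody, treatment)
        return NOT_MEASURED if cell is NOT_MEASURED else cell[1]

    def experiments(self, antibody: Antibody | str = Antibody.TARGET) -> list[int]:
        ab = Antibody(antibody)
        return sorted({e for (e, a, _t) in self.counts if a == ab})


@dataclasses.dataclass(frozen=True)
class AssayReading:
    """One scintillation reading of a glucan fraction, in cpm per mg protein."""

    sample_id: str
    method: Method
    glucan: Glucan
    cpm_per_mg: float
    replicate: int

    def __post_init__(self):
        if self.cpm_per_mg < 0:
            raise ValueError("cpm_per_mg must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclasses.dataclass(frozen=True)
class ConversionParams:
    """Constants linking scintillation counts to glucose incorporated.

    Defaults are the study's reaction conditions: 0.05 uCi of
    14C-UDP-glucose at a specific activity of 11.174 GBq/mmol, diluted
    1:7551 into unlabeled UDP-glucose.  ``counting_efficiency`` is the
    cpm/dpm ratio of the counter (1.0 when unstated).  When
    ``factor_override`` is set, it is used directly as the nmol-per-cpm
    factor and no derivation happens.
    """

    specific_activity: float = 11.174  # GBq per mmol of labeled UDP-glucose
    label_activity: float = 0.05  # uCi of label in the reaction
    molar_ratio: float = 7551.0  # total : labeled UDP-glucose
    counting_efficiency: float = 1.0  # cpm per dpm, in (0, 1]
    factor_override: float | None = None  # nmol per cpm, bypasses derivation

    def __post_init__(self):
        for name in ("specific_activity", "label_activity", "molar_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.counting_efficiency <= 1:
            raise ValueError("counting_efficiency must be in (0, 1]")
        if self.factor_override is not None and self.factor_override <= 0:
            raise ValueError("factor_override must be positive")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x tissues expression values with stable orderings."""

    gene_ids: list[str]
    tissue_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tissue_ids)} tissues"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.tissue_ids)
        df.index.name = "gene_id"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            tissue_ids=[str(t) for t in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground-truth labels attached to a simulated dataset."""

    enhanced_ids: frozenset[str] = frozenset()
    specific_ids: frozenset[str] = frozenset()
    module_of: dict[str, str] = dataclasses.field(default_factory=dict)
    generator_params: dict[str, object] = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = [
    "protein_id",
    "experiment",
    "antibody",
    "treatment",
    "total_peptides",
    "distinct_peptides",
]

_ASSAY_COLUMNS = ["sample_id", "method", "glucan", "replicate", "cpm_per_mg"]


def _open_rows(path):
    fh = open(path, encoding="utf-8", newline="")
    return fh, csv.reader(fh, delimiter="\t")


def _check_header(header, expected, path):
    if header is None:
        raise ParseError(1, f"{path}: empty file, expected header {expected}")
    got = [h.strip() for h in header]
    if got != expected:
        raise ParseError(1, f"{path}: bad header {got}, expected {expected}")


def _parse_int(text: str, column: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(lineno, f"malformed integer in {column}: {text!r}") from None


def _parse_enum(enum_cls, text: str, column: str, lineno: int):
    try:
        return enum_cls(text)
    except ValueError:
        valid = [m.value for m in enum_cls]
        raise ParseError(
            lineno, f"unknown {column} value {text!r}, expected one of {valid}"
        ) from None


def read_count_table(path) -> list[PeptideCountRecord]:
    """Parse a peptide-count TSV into validated records.

    Duplicate (protein, experiment, antibody, treatment) keys, malformed
    integers, unknown enum values and invariant violations (distinct >
    total) are all rejected with the line number.
    """
    fh, reader = _open_rows(path)
    records: list[PeptideCountRecord] = []
    seen: set = set()
    with fh:
        _check_header(next(reader, None), _COUNT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_COUNT_COLUMNS):
                raise ParseError(lineno, f"expected {len(_COUNT_COLUMNS)} columns, got {len(row)}")
            try:
                rec = PeptideCountRecord(
                    protein_id=row[0],
                    experiment=_parse_int(row[1], "experiment", lineno),
                    antibody=_parse_enum(Antibody, row[2], "antibody", lineno),
                    treatment=_parse_enum(Treatment, row[3], "treatment", lineno),
                    total_peptides=_parse_int(row[4], "total_peptides", lineno),
                    distinct_peptides=_parse_int(row[5], "distinct_peptides", lineno),
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(lineno, str(exc)) from None
            if rec.key in seen:
                raise ParseError(lineno, f"duplicate key {rec.key}")
            seen.add(rec.key)
            records.append(rec)
    return records


def write_count_table(records: Iterable[PeptideCountRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COUNT_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.protein_id,
                    rec.experiment,
                    rec.antibody.value,
                    rec.treatment.value,
                    rec.total_peptides,
                    rec.distinct_peptides,
                ]
            )


def build_profiles(records: Iterable[PeptideCountRecord]) -> dict[str, ProteinProfile]:
    """Group records into per-protein profiles, one cell per record."""
    profiles: dict[str, ProteinProfile] = {}
    for rec in records:
        prof = profiles.setdefault(rec.protein_id, ProteinProfile(rec.protein_id))
        prof.counts[(rec.experiment, rec.antibody, rec.treatment)] = (
            rec.total_peptides,
            rec.distinct_peptides,
        )
    return profiles


def read_assay_table(path) -> list[AssayReading]:
    fh, reader = _open_rows(path)
    readings: list[AssayReading] = []
    with fh:
        _check_header(next(reader, None), _ASSAY_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_ASSAY_COLUMNS):
                raise ParseError(lineno, f"expected {len(_ASSAY_COLUMNS)} columns, got {len(row)}")
            try:
                cpm = float(row[4])
            except ValueError:
                raise ParseError(lineno, f"malformed number in cpm_per_mg: {row[4]!r}") from None
            try:
                readings.append(
                    AssayReading(
                        sample_id=row[0],
                        method=_parse_enum(Method, row[1], "method", lineno),
                        glucan=_parse_enum(Glucan, row[2], "glucan", lineno),
                        replicate=_parse_int(row[3], "replicate", lineno),
                        cpm_per_mg=cpm,
                    )
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(lineno, str(exc)) from None
    return readings


def write_assay_table(readings: Iterable[AssayReading], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ASSAY_COLUMNS)
        for r in readings:
            writer.writerow(
                [r.sample_id, r.method.value, r.glucan.value, r.replicate, repr(r.cpm_per_mg)]
            )


def read_expression_matrix(path) -> ExpressionMatrix:
    """Load a genes x tissues TSV (first column = gene id header row = tissues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix.from_dataframe(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", lineterminator="\n")


_TRUTH_COLUMNS = ["kind", "key", "value"]


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize planted truth as a long-format TSV (kind, key, value)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_COLUMNS)
        for pid in sorted(truth.enhanced_ids):
            writer.writerow(["enhanced", pid, ""])
        for pid in sorted(truth.specific_ids):
            writer.writerow(["specific", pid, ""])
        for gene in sorted(truth.module_of):
            writer.writerow(["module", gene, truth.module_of[gene]])
        for name in sorted(truth.generator_params):
            writer.writerow(["param", name, json.dumps(truth.generator_params[name])])


def read_truth(path) -> SyntheticTruth:
    fh, reader = _open_rows(path)
    enhanced, specific = set(), set()
    module_of: dict[str, str] = {}
    params: dict[str, object] = {}
    with fh:
        _check_header(next(reader, None), _TRUTH_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(lineno, f"expected 3 columns, got {len(row)}")
            kind, key, value = row
            if kind == "enhanced":
                enhanced.add(key)
            elif kind == "specific":
                specific.add(key)
            elif kind == "module":
                module_of[key] = value
            elif kind == "param":
                params[key] = json.loads(value)
            else:
                raise ParseError(lineno, f"unknown truth kind {kind!r}")
    return SyntheticTruth(
        enhanced_ids=frozenset(enhanced),
        specific_ids=frozenset(specific),
        module_of=module_of,
        generator_params=params,
    )


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

_FIXTURES = {
    "table1": "table1_glucan_products.tsv",
    "table2": "table2_cesa_cals_counts.tsv",
    "table3": "table3_known_noncesa_counts.tsv",
    "table4": "table4_novel_protein_counts.tsv",
    "annotations": "protein_annotations.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged reference table."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return Path(str(resources.files("fibercoip").joinpath("data", _FIXTURES[name])))


def load_fixture(name: str):
    """Load a packaged reference table.

    ``table2``..``table4`` return peptide-count records (the published
    blank/treated spectral counts of the 19 bait-complex proteins under
    the anti-CESA antibody); ``table1`` returns the glucan-product
    summary (cpm and nmol per mg protein, mean and SD over triplicates,
    for the two membrane-extraction methods); ``annotations`` returns
    accession/TM-domain/function metadata.
    """
    path = fixture_path(name)
    if name in {"table2", "table3", "table4"}:
        return read_count_table(path)
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_interactome_profiles() -> dict[str, ProteinProfile]:
    """All 19 reproducibly detected bait-complex proteins as profiles."""
    records: list[PeptideCountRecord] = []
    for name in ("table2", "table3", "table4"):
        records.extend(load_fixture(name))
    profiles = build_profiles(records)
    ann = load_fixture("annotations")
    notes = dict(zip(ann["protein_id"], ann["function"]))
    for pid, prof in profiles.items():
        prof.annotation = notes.get(pid)
    return profiles
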