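"""Schema-validated ingestion and export of longitudinal categorical phenotype tables.

A cohort is one row per individual: identity columns (``subject_id``,
``uterine_position``, ``genotype``), the embryonic looping class observed at
E9.5, and a set of categorical anatomical parameters annotated at E18.5.
Controlled vocabularies live in a JSON schema file, not in code, so cohorts
with different variable sets (e.g. mouse fetuses vs human patients) share one
reader.  Unknown/ambiguous values are a distinct state — they are never
coerced to a category level; analyses decide per call whether an unknown
excludes the record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariableSchema",
    "AnalysisSet",
    "CohortSchema",
    "PhenotypeRecord",
    "Cohort",
    "CohortValidationError",
    "load_schema",
    "default_schema",
    "read_cohort",
    "write_cohort",
    "filter_analysis_set",
]

#: columns present in every cohort table, in file order, before the feature columns
IDENTITY_COLUMNS = ("subject_id", "uterine_position", "genotype")

GENOTYPE_LEVELS = ("mutant", "control")
LOOPING_LEVELS = ("1", "2", "3", "4")


class CohortValidationError(ValueError):
    """A table row or schema violated the controlled vocabulary."""


@dataclass(frozen=True)
class VariableSchema:
    """Controlled vocabulary for one categorical variable.

    Parameters
    ----------
    name : variable name, used as the column header.
    role : one of ``{"E9.5", "E18.5", "meta", "outcome"}``.
    levels : ordered allowed category labels.
    missing_codes : labels treated as unknown/ambiguous (disjoint from levels).
    analysis_sets : names of the analysis sets this variable belongs to.
    """

    name: str
    role: str
    levels: tuple[str, ...]
    missing_codes: tuple[str, ...] = ("unknown",)
    analysis_sets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.levels:
            raise CohortValidationError(f"variable {self.name!r}: empty level list")
        if len(set(self.levels)) != len(self.levels):
            raise CohortValidationError(f"variable {self.name!r}: duplicate levels")
        if set(self.levels) & set(self.missing_codes):
            raise CohortValidationError(
                f"variable {self.name!r}: missing codes overlap levels"
            )
        if self.role not in {"E9.5", "E18.5", "meta", "outcome"}:
            raise CohortValidationError(f"variable {self.name!r}: bad role {self.role!r}")

    def is_known(self, value: str) -> bool:
        return value in self.levels

    def validate_value(self, value: str) -> None:
        if value not in self.levels and value not in self.missing_codes:
            raise CohortValidationError(
                f"variable {self.name!r}: label {value!r} is neither a level nor a missing code"
            )


@dataclass(frozen=True)
class AnalysisSet:
    """A named variable subset plus the variables that must be known to enter it.

    ``variables`` lists the features an analysis consumes; ``required_known``
    lists the variables whose value must be a proper level (not a missing
    code) for a record to be retained — the two differ because e.g. a forest
    can carry "unknown" as a predictor level while the response must be known.
    """

    name: str
    variables: tuple[str, ...]
    required_known: tuple[str, ...]


@dataclass(frozen=True)
class CohortSchema:
    variables: tuple[VariableSchema, ...]
    analysis_sets: Mapping[str, AnalysisSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate variable names in schema")
        by_name = {v.name: v for v in self.variables}
        for aset in self.analysis_sets.values():
            for var in (*aset.variables, *aset.required_known):
                if var != "looping_class" and var not in by_name:
                    raise CohortValidationError(
                        f"analysis set {aset.name!r} references unknown variable {var!r}"
                    )
        # the MCA variable set must be nested in the classification set
        if "mca" in self.analysis_sets and "classify" in self.analysis_sets:
            mca = set(self.analysis_sets["mca"].variables)
            clf = set(self.analysis_sets["classify"].variables)
            if not mca <= clf:
                raise CohortValidationError(
                    "the MCA variable set must be a subset of the classification set"
                )

    def __getitem__(self, name: str) -> VariableSchema:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def feature_names(self) -> tuple[str, ...]:
        """Schema-ordered names of the categorical variables other than looping class."""
        return tuple(v.name for v in self.variables if v.name != "looping_class")

    def analysis_set(self, name: str) -> AnalysisSet:
        try:
            return self.analysis_sets[name]
        except KeyError:
            raise KeyError(
                f"unknown analysis set {name!r}; defined: {sorted(self.analysis_sets)}"
            ) from None


@dataclass(frozen=True)
class PhenotypeRecord:
    """One individual's categorical annotations across stages."""

    subject_id: str
    looping_class: str = "unknown"  # "1".."4" or "unknown"
    features: Mapping[str, str] = field(default_factory=dict)
    uterine_position: str = ""  # e.g. "L2" = second embryo in the left horn
    genotype: str = "mutant"

    def direction_known(self) -> bool:
        return self.looping_class in LOOPING_LEVELS


@dataclass(frozen=True)
class Cohort:
    records: tuple[PhenotypeRecord, ...]
    schema: CohortSchema
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, rec in enumerate(self.records):
            if rec.subject_id in seen:
                raise CohortValidationError(f"duplicate subject_id {rec.subject_id!r}")
            seen.add(rec.subject_id)
            if rec.looping_class not in LOOPING_LEVELS and rec.looping_class != "unknown":
                if "looping_class" in self.schema:
                    self.schema["looping_class"].validate_value(rec.looping_class)
                else:
                    raise CohortValidationError(
                        f"record {rec.subject_id!r}: bad looping class {rec.looping_class!r}"
                    )
            for var, value in rec.features.items():
                if var not in self.schema:
                    raise CohortValidationError(
                        f"record {rec.subject_id!r}: variable {var!r} not in schema"
                    )
                try:
                    self.schema[var].validate_value(value)
                except CohortValidationError as exc:
                    raise CohortValidationError(f"record {rec.subject_id!r}: {exc}") from None

    def __len__(self) -> int:
        return len(self.records)

    def feature_column(self, name: str) -> list[str]:
        if name == "looping_class":
            return [r.looping_class for r in self.records]
        return [r.features.get(name, self.schema[name].missing_codes[0]) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Schema-ordered DataFrame, one row per individual."""
        data: dict[str, list[str]] = {
            "subject_id": [r.subject_id for r in self.records],
            "uterine_position": [r.uterine_position for r in self.records],
            "genotype": [r.genotype for r in self.records],
        }
        for v in self.schema.variables:
            data[v.name] = self.feature_column(v.name)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# schema files


def _parse_schema(payload: Mapping) -> CohortSchema:
    variables = tuple(
        VariableSchema(
            name=v["name"],
            role=v["role"],
            levels=tuple(v["levels"]),
            missing_codes=tuple(v.get("missing_codes", ["unknown"])),
            analysis_sets=tuple(v.get("analysis_sets", [])),
        )
        for v in payload["variables"]
    )
    sets = {
        name: AnalysisSet(
            name=name,
            variables=tuple(spec["variables"]),
            required_known=tuple(spec.get("required_known", spec["variables"])),
        )
        for name, spec in payload.get("analysis_sets", {}).items()
    }
    return CohortSchema(variables=variables, analysis_sets=sets)


def load_schema(path: str | Path) -> CohortSchema:
    """Load a controlled-vocabulary schema from a JSON file."""
    with open(path, encoding="utf-8") as fh:
        return _parse_schema(json.load(fh))


def default_schema() -> CohortSchema:
    """The bundled illustrative schema (11-variable MCA set, 14-variable classification set)."""
    text = resources.files("looptrax.data").joinpath("default_schema.json").read_text("utf-8")
    return _parse_schema(json.loads(text))


# ---------------------------------------------------------------------------
# reading / writing


def _detect_sep(path: Path) -> str:
    header = path.open(encoding="utf-8").readline()
    return "\t" if "\t" in header and "," not in header else ","


def read_cohort(path: str | Path, schema: CohortSchema) -> Cohort:
    """Read a delimited phenotype table and validate it against ``schema``.

    Raises :class:`CohortValidationError` naming the offending row and column
    for any out-of-vocabulary value; missing required columns and duplicate
    subject ids are also rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    required = ["subject_id"] + [v.name for v in schema.variables]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"{path.name}: missing required columns {missing_cols}")

    records = []
    for idx, row in df.iterrows():
        features = {}
        for v in schema.variables:
            if v.name == "looping_class":
                continue
            value = row[v.name]
            try:
                v.validate_value(value)
            except CohortValidationError as exc:
                raise CohortValidationError(
                    f"{path.name}: row {idx + 2}, column {v.name!r}: {exc}"
                ) from None
            features[v.name] = value
        looping = row["looping_class"] if "looping_class" in df.columns else "unknown"
        if "looping_class" in schema:
            try:
                schema["looping_class"].validate_value(looping)
            except CohortValidationError as exc:
                raise CohortValidationError(
                    f"{path.name}: row {idx + 2}, column 'looping_class': {exc}"
                ) from None
        records.append(
            PhenotypeRecord(
                subject_id=row["subject_id"],
                uterine_position=row.get("uterine_position", ""),
                genotype=row.get("genotype", "mutant"),
                looping_class=looping,
                features=features,
            )
        )
    return Cohort(records=tuple(records), schema=schema, provenance=f"read:{path}")


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort as UTF-8 CSV with schema-ordered columns.

    ``read_cohort(write_cohort(c), c.schema)`` reproduces ``c`` record for
    record; missing codes are serialized verbatim.
    """
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path


def filter_analysis_set(
    cohort: Cohort, set_name: str
) -> tuple[Cohort, list[dict[str, str]]]:
    """Drop records whose required variables for an analysis set are unknown.

    Returns the filtered cohort plus an exclusion log with one entry per
    dropped subject naming the first offending variable.  Retained records
    are passed through unmodified, so retained + excluded counts always sum
    to the input size.
    """
    aset = cohort.schema.analysis_set(set_name)
    kept, log = [], []
    for rec in cohort.records:
        offending = None
        for var in aset.required_known:
            if var == "looping_class":
                value, known = rec.looping_class, rec.direction_known()
            else:
                vs = cohort.schema[var]
                value = rec.features.get(var, vs.missing_codes[0])
                known = vs.is_known(value)
            if not known:
                offending = (var, value)
                break
        if offending is None:
            kept.append(rec)
        else:
            log.append(
                {"subject_id": rec.subject_id, "variable": offending[0], "value": offending[1]}
            )
    filtered = replace(
        cohort,
        records=tuple(kept),
        provenance=f"{cohort.provenance}|filter:{set_name}",
    )
    return filtered, log
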