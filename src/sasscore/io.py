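"""Delimited-text readers and writers for registry, findings and results.

All tables are UTF-8 CSV with a header row; a ``.tsv`` extension
switches the delimiter to tab. Empty cells mean "not observed". These
functions are the single place where file columns are mapped onto the
domain types, so the rest of the package works with validated objects.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import DataValidationError
from .rubric import PhenotypeRecord, RubricSchema
from .variants import MolecularFinding, StructuralVariant

__all__ = [
    "read_table",
    "read_registry",
    "write_registry",
    "read_findings",
    "write_findings",
]

REGISTRY_BASE_COLUMNS = ("individual_id", "sex", "age_years")
FINDINGS_COLUMNS = (
    "individual_id",
    "hgvs_c",
    "hgvs_p",
    "structural_kind",
    "size_mb",
    "intragenic",
    "pathogenicity_label",
)


def _sep_for(path: Union[str, Path]) -> str:
    return "\t" if str(path).lower().endswith(".tsv") else ","


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV/TSV (delimiter by extension) with empty cells as NA."""
    try:
        return pd.read_csv(path, sep=_sep_for(path))
    except FileNotFoundError:
        raise DataValidationError(f"input file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"cannot parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required column(s): {', '.join(missing)}")


def _cell(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_registry(path: Union[str, Path], schema: RubricSchema) -> list[PhenotypeRecord]:
    """Read a phenotype registry into records validated against a rubric schema.

    Expected columns: ``individual_id, sex, age_years`` plus one column
    per rubric category; an empty category cell marks the item missing.
    Extra columns are ignored.
    """
    df = read_table(path)
    _require_columns(df, REGISTRY_BASE_COLUMNS, path)
    cat_cols = [c for c in schema.category_names if c in df.columns]
    records = []
    for i, row in df.iterrows():
        levels: dict[str, Optional[int]] = {}
        for c in cat_cols:
            v = _cell(row[c])
            if v is not None:
                try:
                    levels[c] = int(float(v))
                except ValueError:
                    raise DataValidationError(
                        f"{path} row {i}: non-integer level {v!r} in column {c!r}"
                    ) from None
            else:
                levels[c] = None
        try:
            records.append(
                PhenotypeRecord(
                    individual_id=str(row["individual_id"]),
                    sex=str(row["sex"]).strip().lower(),
                    age_years=float(row["age_years"]),
                    levels=levels,
                )
            )
        except Exception as exc:
            raise DataValidationError(f"{path} row {i}: {exc}") from exc
    return records


def write_registry(
    records: Iterable[PhenotypeRecord], schema: RubricSchema, path: Union[str, Path]
) -> None:
    rows = []
    for r in records:
        row = {"individual_id": r.individual_id, "sex": r.sex, "age_years": r.age_years}
        for name in schema.category_names:
            v = r.levels.get(name)
            row[name] = "" if v is None else v
        rows.append(row)
    cols = [*REGISTRY_BASE_COLUMNS, *schema.category_names]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep_for(path), index=False)


def read_findings(path: Union[str, Path]) -> list[MolecularFinding]:
    """Read molecular findings (blank cell = absent field)."""
    df = read_table(path)
    _require_columns(df, ("individual_id",), path)
    for col in FINDINGS_COLUMNS:
        if col not in df.columns:
            df[col] = None
    findings = []
    for i, row in df.iterrows():
        kind = _cell(row["structural_kind"])
        structural = None
        if kind is not None:
            size = _cell(row["size_mb"])
            intragenic = str(_cell(row["intragenic"]) or "false").lower() in ("1", "true", "yes")
            structural = StructuralVariant(
                kind=kind,  # type: ignore[arg-type]
                size_mb=float(size) if size is not None else None,
                intragenic=intragenic,
            )
        try:
            findings.append(
                MolecularFinding(
                    individual_id=str(row["individual_id"]),
                    hgvs_c=_cell(row["hgvs_c"]),
                    hgvs_p=_cell(row["hgvs_p"]),
                    structural=structural,
                    pathogenicity_label=_cell(row["pathogenicity_label"]),
                )
            )
        except Exception as exc:
            raise DataValidationError(f"{path} row {i}: {exc}") from exc
    return findings


def write_findings(findings: Iterable[MolecularFinding], path: Union[str, Path]) -> None:
    rows = []
    for f in findings:
        sv = f.structural
        rows.append(
            {
                "individual_id": f.individual_id,
                "hgvs_c": f.hgvs_c or "",
                "hgvs_p": f.hgvs_p or "",
                "structural_kind": sv.kind if sv else "",
                "size_mb": "" if sv is None or sv.size_mb is None else sv.size_mb,
                "intragenic": "" if sv is None else str(sv.intragenic).lower(),
                "pathogenicity_label": f.pathogenicity_label or "",
            }
        )
    pd.DataFrame(rows, columns=list(FINDINGS_COLUMNS)).to_csv(
        path, sep=_sep_for(path), index=False
    )
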