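"""SATB2 molecular-finding parsing and classification.

Findings are classified twice:

* three **broad categories** — ``null`` (nonsense, frameshift, canonical
  ±2 splice-site, or intragenic exonic deletion), ``missense``
  (amino-acid substitution), and ``chromosomal`` (large contiguous
  deletion or duplication) — plus ``other_intronic`` for the rare
  non-canonical intronic change that is kept in overall scoring but
  excluded from molecular comparisons;
* eleven **molecular subcategories** used for fine-grained
  genotype-phenotype comparison: the recurrent Arg389Cys substitution;
  other missense variants by protein domain (CUT1, CUT2, HOX, outside
  the main domains); truncating variants split at codon 350 (the start
  of the CUT1 domain); chromosomal deletions split at 6 Mb; intragenic
  deletions; and splice variants. Findings matching no subcategory rule
  (e.g. duplications) are ``UNASSIGNED`` — a value, not an error.

The HGVS support is deliberately a narrow subset (three-letter amino
acids, ``Ter``/``*`` stops, ``fs`` frameshifts, ±1/±2 intronic offsets);
full HGVS grammar, transcript mapping and pathogenicity calling are out
of scope and pathogenicity labels are carried through untouched.
"""

from __future__ import annotations

import enum
import json
import re
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ClassificationConflictError, ConfigError, DataValidationError, ParseError

__all__ = [
    "BroadCategory",
    "Subcategory",
    "StructuralVariant",
    "MolecularFinding",
    "DomainMap",
    "ProteinChange",
    "default_domains_path",
    "load_domains",
    "parse_protein_change",
    "classify_broad",
    "classify_subcategory",
    "classify_cohort",
]

#: Codon split point for truncating variants: the start of the CUT1 domain.
CUT1_START_AA = 350
#: Size split point (Mb, inclusive upper class) for chromosomal deletions.
DELETION_SIZE_SPLIT_MB = 6.0


class BroadCategory(str, enum.Enum):
    NULL = "null"
    MISSENSE = "missense"
    CHROMOSOMAL = "chromosomal"
    OTHER_INTRONIC = "other_intronic"


class Subcategory(str, enum.Enum):
    ARG389CYS = "arg389cys"
    MISSENSE_CUT1 = "missense_cut1"
    MISSENSE_CUT2 = "missense_cut2"
    MISSENSE_HOX = "missense_hox"
    MISSENSE_OTHER = "missense_other"
    NULL_BEFORE_350 = "null_before_350"
    NULL_AT_AFTER_350 = "null_at_after_350"
    CHROM_DEL_LT6MB = "chrom_del_lt6mb"
    CHROM_DEL_GE6MB = "chrom_del_ge6mb"
    INTRAGENIC_DEL = "intragenic_del"
    SPLICE = "splice"
    UNASSIGNED = "UNASSIGNED"


#: The eleven analysis subcategories (UNASSIGNED excluded).
SUBCATEGORY_LABELS: tuple[str, ...] = tuple(
    s.value for s in Subcategory if s is not Subcategory.UNASSIGNED
)


class StructuralVariant(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal["deletion", "duplication"]
    size_mb: Optional[float] = None
    intragenic: bool = False

    @model_validator(mode="after")
    def _check(self) -> "StructuralVariant":
        if self.size_mb is not None and self.size_mb <= 0:
            raise ValueError("size_mb must be positive")
        if self.size_mb is None and not self.intragenic:
            raise ValueError("size_mb is required for non-intragenic structural variants")
        return self


class MolecularFinding(BaseModel):
    """One individual's SATB2 alteration as reported."""

    model_config = ConfigDict(frozen=True)

    individual_id: str
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    structural: Optional[StructuralVariant] = None
    pathogenicity_label: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "MolecularFinding":
        if self.hgvs_c is None and self.hgvs_p is None and self.structural is None:
            raise ValueError(
                f"{self.individual_id}: at least one of hgvs_c, hgvs_p, structural required"
            )
        return self


class DomainMap(BaseModel):
    """1-based inclusive amino-acid intervals of the SATB2 DNA-binding domains."""

    model_config = ConfigDict(frozen=True)

    cut1: tuple[int, int]
    cut2: tuple[int, int]
    hox: tuple[int, int]

    @model_validator(mode="after")
    def _check(self) -> "DomainMap":
        for name, (start, end) in self.intervals().items():
            if start > end:
                raise ValueError(f"{name}: start {start} > end {end}")
        if not (self.cut1[1] < self.cut2[0] and self.cut2[1] < self.hox[0]):
            raise ValueError("domain intervals must be ordered cut1 < cut2 < hox without overlap")
        return self

    def intervals(self) -> dict[str, tuple[int, int]]:
        return {"cut1": self.cut1, "cut2": self.cut2, "hox": self.hox}

    def domain_of(self, position: int) -> Optional[str]:
        for name, (start, end) in self.intervals().items():
            if start <= position <= end:
                return name
        return None


def default_domains_path() -> Path:
    return Path(__file__).parent / "data" / "domains_default.json"


def load_domains(config_source: Union[str, Path, Mapping, None] = None) -> DomainMap:
    """Load a domain map from JSON; with no argument, the packaged default."""
    if config_source is None:
        config_source = default_domains_path()
    if isinstance(config_source, (str, Path)):
        try:
            raw = json.loads(Path(config_source).read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read domain config {config_source}: {exc}") from exc
    else:
        raw = dict(config_source)
    raw.pop("_comment", None)
    try:
        return DomainMap.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"domain map validation failed: {exc}") from exc


class ProteinChange(NamedTuple):
    ref_aa: str
    position: int
    consequence: Literal["substitution", "nonsense", "frameshift"]
    alt_aa: Optional[str] = None


_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Sec"
)
_HGVS_P_RE = re.compile(
    rf"^(?:p\.)?\(?(?P<ref>{_AA3})(?P<pos>\d+)"
    rf"(?P<alt>{_AA3}|Ter|\*)?(?P<fs>fs.*?)?\)?$"
)
# canonical splice site: intronic offset of 1 or 2 from an exon boundary
_SPLICE_RE = re.compile(r"c\.\d+(?:_\d+)?(?P<sign>[+-])(?P<offset>\d+)")


def parse_protein_change(hgvs_p: str) -> ProteinChange:
    """Parse a protein-level HGVS description (narrow subset).

    Returns the reference amino acid, the first affected codon, and the
    consequence class. For frameshifts the position is the first altered
    codon — the only position the notation guarantees.
    """
    m = _HGVS_P_RE.match(hgvs_p.strip())
    if not m:
        raise ParseError(f"unsupported protein HGVS: {hgvs_p!r}")
    ref, pos, alt, fs = m.group("ref", "pos", "alt", "fs")
    if fs:
        consequence = "frameshift"
    elif alt in ("Ter", "*"):
        consequence = "nonsense"
    elif alt and alt != ref:
        consequence = "substitution"
    elif alt == ref:
        raise ParseError(f"synonymous change not supported: {hgvs_p!r}")
    else:
        raise ParseError(f"no consequence recognized in {hgvs_p!r}")
    return ProteinChange(
        ref_aa=ref, position=int(pos), consequence=consequence, alt_aa=alt
    )


def _intronic_offset(hgvs_c: str) -> Optional[int]:
    """Smallest intronic offset mentioned in a cDNA description, or None."""
    offsets = [int(m.group("offset")) for m in _SPLICE_RE.finditer(hgvs_c)]
    return min(offsets) if offsets else None


def classify_broad(finding: MolecularFinding) -> BroadCategory:
    """Assign the broad mutation category of one finding.

    Nonsense, frameshift, canonical (±1/±2) splice-site and intragenic
    exonic deletions are null; substitutions are missense; non-intragenic
    large deletions and duplications are chromosomal; a non-canonical
    intronic change is ``other_intronic``.
    """
    pc: Optional[ProteinChange] = None
    if finding.hgvs_p is not None:
        pc = parse_protein_change(finding.hgvs_p)

    if finding.structural is not None:
        if pc is not None:
            raise ClassificationConflictError(
                f"{finding.individual_id}: both a protein change ({finding.hgvs_p}) "
                "and a structural variant reported"
            )
        if finding.structural.kind == "deletion" and finding.structural.intragenic:
            return BroadCategory.NULL
        return BroadCategory.CHROMOSOMAL

    if pc is not None:
        if pc.consequence in ("nonsense", "frameshift"):
            return BroadCategory.NULL
        return BroadCategory.MISSENSE

    # cDNA-only description: intronic changes are the supported case
    assert finding.hgvs_c is not None
    offset = _intronic_offset(finding.hgvs_c)
    if offset is None:
        raise ParseError(
            f"{finding.individual_id}: coding cDNA change {finding.hgvs_c!r} "
            "requires a protein-level description"
        )
    if offset <= 2:
        return BroadCategory.NULL
    return BroadCategory.OTHER_INTRONIC


def classify_subcategory(
    finding: MolecularFinding, domains: DomainMap, broad: Optional[BroadCategory] = None
) -> Subcategory:
    """Assign the molecular subcategory of one finding.

    Rule order: the recurrent Arg389Cys substitution first (it is never
    relabelled ``missense_cut1`` despite lying in CUT1); then missense by
    domain; splice; intragenic deletion; truncating variants split at
    codon 350; chromosomal deletions split at 6 Mb (inclusive upper
    class). Everything else is UNASSIGNED.
    """
    if broad is None:
        broad = classify_broad(finding)

    if broad is BroadCategory.MISSENSE:
        pc = parse_protein_change(finding.hgvs_p)  # type: ignore[arg-type]
        if (pc.ref_aa, pc.position, pc.alt_aa) == ("Arg", 389, "Cys"):
            return Subcategory.ARG389CYS
        domain = domains.domain_of(pc.position)
        if domain == "cut1":
            return Subcategory.MISSENSE_CUT1
        if domain == "cut2":
            return Subcategory.MISSENSE_CUT2
        if domain == "hox":
            return Subcategory.MISSENSE_HOX
        return Subcategory.MISSENSE_OTHER

    if broad is BroadCategory.NULL:
        if finding.structural is not None:
            return Subcategory.INTRAGENIC_DEL
        if finding.hgvs_p is None:
            # canonical splice-site variant (cDNA-only null)
            return Subcategory.SPLICE
        pc = parse_protein_change(finding.hgvs_p)
        if pc.position < CUT1_START_AA:
            return Subcategory.NULL_BEFORE_350
        return Subcategory.NULL_AT_AFTER_350

    if broad is BroadCategory.CHROMOSOMAL:
        sv = finding.structural
        if sv is not None and sv.kind == "deletion" and sv.size_mb is not None:
            if sv.size_mb < DELETION_SIZE_SPLIT_MB:
                return Subcategory.CHROM_DEL_LT6MB
            return Subcategory.CHROM_DEL_GE6MB
        return Subcategory.UNASSIGNED

    return Subcategory.UNASSIGNED


def classify_cohort(
    findings: Iterable[MolecularFinding], domains: Optional[DomainMap] = None
) -> pd.DataFrame:
    """Classify every finding, one annotation row per individual.

    Parse or conflict errors are collected per individual (``error``
    column) and do not abort the rest of the cohort. Columns:
    ``individual_id, broad_category, subcategory, codon_position,
    deletion_size_mb, pathogenicity_label, error``.
    """
    if domains is None:
        domains = load_domains()
    rows = []
    for f in findings:
        row: dict = {
            "individual_id": f.individual_id,
            "broad_category": None,
            "subcategory": None,
            "codon_position": None,
            "deletion_size_mb": None,
            "pathogenicity_label": f.pathogenicity_label,
            "error": None,
        }
        try:
            broad = classify_broad(f)
            sub = classify_subcategory(f, domains, broad)
            row["broad_category"] = broad.value
            row["subcategory"] = sub.value
            if f.hgvs_p is not None:
                row["codon_position"] = parse_protein_change(f.hgvs_p).position
            if f.structural is not None and f.structural.size_mb is not None:
                row["deletion_size_mb"] = f.structural.size_mb
        except DataValidationError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "broad_category",
            "subcategory",
            "codon_position",
            "deletion_size_mb",
            "pathogenicity_label",
            "error",
        ],
    )
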