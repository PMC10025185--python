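"""Substance registry keyed by CAS-RN.

The registry is a desk-scale, file-backed stand-in for a relational
compound database: substances are keyed strictly by CAS-RN, synonyms
are merged case-insensitively, and structures are attached but never
required — substances without a structure are retained and routed to
non-QSAR methods downstream, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from toxtriage.cas import validate_cas, VALID

ANNOTATION_SOURCES = (
    "ECHA_CLP",
    "ECHA_REACH",
    "ECHA_SVHC",
    "ECHA_REGDOSSIER",
    "ECHA_OTHER",
    "REFERENCE_DB",
    "PHAROS",
)

STRUCTURE_STATUSES = ("ok", "parse_fail", "sanitize_fail", "missing")


class CasValidationError(ValueError):
    """Raised when a record's CAS-RN fails validation in strict mode."""


class StructureConflictError(ValueError):
    """Two non-identical SMILES registered under one CAS-RN.

    Carries both structures so the caller can resolve the conflict;
    the registry never overwrites silently.
    """

    def __init__(self, cas: str, existing: str, incoming: str):
        self.cas = cas
        self.existing = existing
        self.incoming = incoming
        super().__init__(
            f"conflicting structures for {cas}: {existing!r} vs {incoming!r}"
        )


def _norm_name(name: str) -> str:
    return " ".join(name.split()).lower()


@dataclass
class Substance:
    cas: str
    names: dict = field(default_factory=dict)  # normalized -> display form
    smiles: Optional[str] = None
    ec_number: Optional[str] = None
    category: Optional[str] = None
    structure_status: str = "missing"

    @property
    def synonyms(self) -> set:
        return set(self.names.values())

    def add_name(self, name: str) -> None:
        if name:
            self.names.setdefault(_norm_name(name), name.strip())


@dataclass(frozen=True)
class HazardAnnotation:
    """One source-level hazard assertion, prior to integration."""

    cas: str
    source: str
    hazard_code: str
    polarity: str  # "positive" | "negative"

    def __post_init__(self):
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(f"unknown annotation source: {self.source}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative: {self.polarity}")


@dataclass
class RegistrySummary:
    n_compounds: int
    n_with_structure: int
    n_annotations_by_source: dict
    label_tally: dict  # value -> count over 4 endpoints


class Registry:
    """In-memory substance registry keyed by CAS-RN."""

    def __init__(self):
        self._substances: dict[str, Substance] = {}

    def __len__(self) -> int:
        return len(self._substances)

    def __contains__(self, cas: str) -> bool:
        return cas in self._substances

    def __iter__(self):
        return iter(self._substances.values())

    def get(self, cas: str) -> Optional[Substance]:
        return self._substances.get(cas)

    def register(
        self,
        cas: str,
        name: str,
        smiles: Optional[str] = None,
        ec_number: Optional[str] = None,
        lenient: bool = False,
    ) -> Substance:
        """Register or merge one record.

        A new CAS creates an entry; an existing CAS merges the name into
        the synonym set and fills the structure only if previously
        absent.  Conflicting non-identical SMILES raise
        :class:`StructureConflictError`.
        """
        verdict = validate_cas(cas)
        if verdict != VALID and not lenient:
            raise CasValidationError(f"CAS {cas!r} failed validation: {verdict}")
        smiles = smiles if smiles and str(smiles).strip() else None
        sub = self._substances.get(cas)
        if sub is None:
            sub = Substance(cas=cas)
            sub.add_name(name)
            if smiles is not None:
                sub.smiles = smiles
                sub.structure_status = "ok"
            self._substances[cas] = sub
            return sub
        sub.add_name(name)
        if smiles is not None:
            if sub.smiles is None:
                sub.smiles = smiles
                sub.structure_status = "ok"
            elif sub.smiles != smiles:
                raise StructureConflictError(cas, sub.smiles, smiles)
        if ec_number and not sub.ec_number:
            sub.ec_number = ec_number
        return sub

    def summarize(
        self,
        labels: Optional[pd.DataFrame] = None,
        annotations: Iterable[HazardAnnotation] = (),
    ) -> RegistrySummary:
        """Registry-in-numbers summary.

        ``labels`` is the integrated label table (columns cas, endpoint,
        value); any (substance, endpoint) pair it does not cover counts
        as NoInformation, so the tally always sums to 4 x n_compounds.
        """
        from toxtriage.integration import ENDPOINTS, NO_INFORMATION

        n = len(self)
        tally = {v: 0 for v in ("YES", "NO", "Pending", "NoInformation")}
        covered = 0
        if labels is not None and len(labels):
            known = labels[labels["cas"].isin(self._substances)]
            for value, count in known["value"].value_counts().items():
                tally[value] = tally.get(value, 0) + int(count)
                covered += int(count)
        tally[NO_INFORMATION] += len(ENDPOINTS) * n - covered
        by_source: dict[str, int] = {}
        for ann in annotations:
            by_source[ann.source] = by_source.get(ann.source, 0) + 1
        return RegistrySummary(
            n_compounds=n,
            n_with_structure=sum(1 for s in self if s.smiles is not None),
            n_annotations_by_source=by_source,
            label_tally=tally,
        )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, lenient: bool = False) -> "Registry":
        reg = cls()
        for row in frame.itertuples(index=False):
            smiles = getattr(row, "smiles", None)
            if pd.isna(smiles):
                smiles = None
            ec = getattr(row, "ec_number", None)
            if ec is not None and pd.isna(ec):
                ec = None
            reg.register(str(row.cas), str(row.name), smiles, ec, lenient=lenient)
        return reg

    @classmethod
    def from_csv(cls, path, lenient: bool = False) -> "Registry":
        """Load a substances CSV with columns cas,name,smiles[,ec_number]."""
        return cls.from_frame(pd.read_csv(path, dtype=str), lenient=lenient)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cas": s.cas,
                "name": sorted(s.synonyms)[0] if s.names else "",
                "smiles": s.smiles,
                "ec_number": s.ec_number,
            }
            for s in self
        ]
        return pd.DataFrame(rows, columns=["cas", "name", "smiles", "ec_number"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_annotations(path_or_frame) -> list[HazardAnnotation]:
    """Read an annotations CSV (cas,source,hazard_code,polarity)."""
    if isinstance(path_or_frame, pd.DataFrame):
        frame = path_or_frame
    else:
        frame = pd.read_csv(path_or_frame, dtype=str)
    return [
        HazardAnnotation(
            cas=str(r.cas),
            source=str(r.source),
            hazard_code=str(r.hazard_code),
            polarity=str(r.polarity),
        )
        for r in frame.itertuples(index=False)
    ]
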