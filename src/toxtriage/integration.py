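"""Integration of source-level hazard annotations into endpoint labels.

Each substance receives one label per endpoint (CMR, ED, PBT, vPvB)
drawn from {YES, NO, Pending, NoInformation}.  The decision workflow
checks sources in a fixed precedence order and is deliberately
conservative: a positive assertion from a core regulatory source
(CLP, REACH, SVHC) outweighs everything else.

Precedence tiers:

1. any positive annotation from ECHA_CLP / ECHA_REACH / ECHA_SVHC -> YES;
2. else any positive from ECHA_REGDOSSIER / ECHA_OTHER -> Pending
   (the substance is still in a classification process);
3. else any reference-database annotation -> its polarity (YES/NO),
   positive beating negative;
4. else any Pharos annotation -> its polarity, positive beating negative;
5. else -> NoInformation.

The hazard-code -> endpoint mapping is a configurable table: CLP
carcinogenicity/mutagenicity/reprotoxicity H-codes map to CMR, REACH
Annex XIII flags to PBT/vPvB, endocrine-assessment entries to ED, and
bare endpoint tags (used by Pharos and reference databases) pass
through.  Unknown codes map to no endpoint at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from toxtriage.registry import HazardAnnotation

ENDPOINTS = ("CMR", "ED", "PBT", "vPvB")

YES = "YES"
NO = "NO"
PENDING = "Pending"
NO_INFORMATION = "NoInformation"
LABEL_VALUES = (YES, NO, PENDING, NO_INFORMATION)

PROVENANCE_INTEGRATED = "integrated"
PROVENANCE_PREDICTED = "predicted"
PROVENANCE_RAX = "rax"

ECHA_CORE = frozenset({"ECHA_CLP", "ECHA_REACH", "ECHA_SVHC"})
ECHA_SECONDARY = frozenset({"ECHA_REGDOSSIER", "ECHA_OTHER"})

#: Default hazard-code -> endpoint table.  CLP H340/H341 (mutagenicity),
#: H350/H351 (carcinogenicity) and H360/H361/H362 (reproductive
#: toxicity) all fold into the combined CMR label.
DEFAULT_CODE_TABLE: dict[str, frozenset] = {
    "H340": frozenset({"CMR"}),
    "H341": frozenset({"CMR"}),
    "H350": frozenset({"CMR"}),
    "H350i": frozenset({"CMR"}),
    "H351": frozenset({"CMR"}),
    "H360": frozenset({"CMR"}),
    "H361": frozenset({"CMR"}),
    "H362": frozenset({"CMR"}),
    "PBT_Annex_XIII": frozenset({"PBT"}),
    "vPvB_Annex_XIII": frozenset({"vPvB"}),
    "ED_assessment": frozenset({"ED"}),
    # bare endpoint tags (Pharos / reference-database style) pass through
    "CMR": frozenset({"CMR"}),
    "ED": frozenset({"ED"}),
    "PBT": frozenset({"PBT"}),
    "vPvB": frozenset({"vPvB"}),
}


@dataclass
class HazardEndpointMapping:
    """Editable (hazard_code -> endpoints) lookup table.

    Total over the shipped default code list; unknown codes map to the
    empty set, so unmapped annotations are inert rather than errors.
    """

    table: dict = field(default_factory=lambda: dict(DEFAULT_CODE_TABLE))

    @classmethod
    def default(cls) -> "HazardEndpointMapping":
        return cls()

    @classmethod
    def from_csv(cls, path) -> "HazardEndpointMapping":
        """Load a mapping config CSV with columns hazard_code,endpoint."""
        frame = pd.read_csv(path, dtype=str)
        table: dict[str, set] = {}
        for row in frame.itertuples(index=False):
            if row.endpoint not in ENDPOINTS:
                raise ValueError(f"unknown endpoint in mapping: {row.endpoint}")
            table.setdefault(str(row.hazard_code), set()).add(str(row.endpoint))
        return cls({k: frozenset(v) for k, v in table.items()})

    def endpoints_for(self, hazard_code: str) -> frozenset:
        return self.table.get(hazard_code, frozenset())


def map_hazard_to_endpoint(
    annotation: HazardAnnotation, mapping: HazardEndpointMapping
) -> set:
    """Endpoint hits for one annotation: set of (endpoint, polarity)."""
    return {(ep, annotation.polarity) for ep in mapping.endpoints_for(annotation.hazard_code)}


def integrate_endpoint_label(annotations: Iterable[HazardAnnotation]) -> str:
    """Resolve the annotation multiset for one (cas, endpoint) pair.

    The annotations must already be endpoint-mapped (i.e. all relevant
    to the same endpoint).  The outcome depends only on the multiset,
    never on input order.
    """
    anns = list(annotations)
    if any(a.source in ECHA_CORE and a.polarity == "positive" for a in anns):
        return YES
    if any(a.source in ECHA_SECONDARY and a.polarity == "positive" for a in anns):
        return PENDING
    ref = [a for a in anns if a.source == "REFERENCE_DB"]
    if ref:
        return YES if any(a.polarity == "positive" for a in ref) else NO
    pharos = [a for a in anns if a.source == "PHAROS"]
    if pharos:
        return YES if any(a.polarity == "positive" for a in pharos) else NO
    return NO_INFORMATION


@dataclass
class IntegrationResult:
    labels: pd.DataFrame  # cas, endpoint, value, provenance
    rejects: pd.DataFrame  # annotations whose CAS is not in the registry


def integrate_all(
    registry,
    annotations: Iterable[HazardAnnotation],
    mapping: Optional[HazardEndpointMapping] = None,
) -> IntegrationResult:
    """Label every (substance, endpoint) pair in the registry.

    Annotations referencing a CAS absent from the registry are
    collected in a rejects table, not silently dropped.  The result is
    independent of annotation order and idempotent.
    """
    mapping = mapping or HazardEndpointMapping.default()
    per_pair: dict[tuple, list] = {}
    rejects = []
    for ann in annotations:
        if ann.cas not in registry:
            rejects.append(
                {"cas": ann.cas, "source": ann.source,
                 "hazard_code": ann.hazard_code, "polarity": ann.polarity}
            )
            continue
        for endpoint, _pol in map_hazard_to_endpoint(ann, mapping):
            per_pair.setdefault((ann.cas, endpoint), []).append(ann)
    rows = []
    for sub in registry:
        for endpoint in ENDPOINTS:
            value = integrate_endpoint_label(per_pair.get((sub.cas, endpoint), []))
            rows.append(
                {"cas": sub.cas, "endpoint": endpoint, "value": value,
                 "provenance": PROVENANCE_INTEGRATED}
            )
    labels = pd.DataFrame(rows, columns=["cas", "endpoint", "value", "provenance"])
    rejects_df = pd.DataFrame(
        rejects, columns=["cas", "source", "hazard_code", "polarity"]
    )
    return IntegrationResult(labels=labels, rejects=rejects_df)
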