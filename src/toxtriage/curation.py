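"""Structure parsing, sanitization and ten-way curation categorization.

Industrial inventories contain many substances a QSAR pipeline cannot
digest: bare metals, inorganic salts, organometallics, structures that
violate valence rules.  This module classifies every parseable SMILES
into one of ten categories and selects the modelable subset (organic,
organic salt, peptide), desalting organic salts to their largest
organic fragment.

Rule ladder (each rule is an individually testable predicate):

1. sanitize failure -> the matching no-sanitizable subcategory, chosen
   by rules 2-4 applied to the raw (unsanitized) parse;
2. any carbon-metal bond -> organometallic;
3. multi-fragment input -> salt; organic_salt if any fragment has a
   carbon bonded to H or another C, else inorganic_salt;
4. single fragment: carbon-bearing -> organic; a single metal atom or
   ion -> inorganic_metal; else inorganic;
5. organic with >= 2 amide backbone repeats -> peptide.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import SanitizeMol

RDLogger.DisableLog("rdApp.*")


class CurationCategory(str, enum.Enum):
    ORGANIC = "organic"
    ORGANIC_SALT = "organic_salt"
    ORGANOMETALLIC = "organometallic"
    PEPTIDE = "peptide"
    INORGANIC = "inorganic"
    INORGANIC_SALT = "inorganic_salt"
    INORGANIC_METAL = "inorganic_metal"
    NOSANITIZABLE_ORGANIC = "nosanitizable_organic"
    NOSANITIZABLE_INORGANIC = "nosanitizable_inorganic"
    NOSANITIZABLE_ORGANOMETALLIC = "nosanitizable_organometallic"


#: Categories eligible for fingerprint-based modelling.
MODELABLE = frozenset(
    {CurationCategory.ORGANIC, CurationCategory.ORGANIC_SALT, CurationCategory.PEPTIDE}
)

# Elements NOT counted as metals: H, C, N, O, P, S, Se, halogens,
# noble gases, B, Si.  Everything else is a metal for rule 2.
_NONMETALS = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53, 85,
                        2, 10, 18, 36, 54, 86})

# Two of these backbone repeats (amine/amide N - alpha carbon - carbonyl)
# mark a peptide.
_PEPTIDE_REPEAT = Chem.MolFromSmarts("[NX3][CX4][CX3](=O)")


@dataclass
class ParsedStructure:
    status: str  # "ok" | "parse_fail" | "sanitize_fail"
    mol: Optional[Chem.Mol] = None
    canonical_smiles: Optional[str] = None


@dataclass
class CurationReport:
    kept: list = field(default_factory=list)  # cas list
    excluded: list = field(default_factory=list)  # (cas, reason)

    EXCLUSION_REASONS = ("discarded_category", "missing_structure", "parse_fail")


def parse_and_sanitize(smiles: str) -> ParsedStructure:
    """Parse a SMILES and attempt sanitization.

    Failures are statuses, never exceptions: an unparseable string is
    ``parse_fail``; a parseable structure that violates valence or
    aromaticity rules is ``sanitize_fail`` and the raw parse is kept so
    it can still be categorized.
    """
    if smiles is None or not str(smiles).strip():
        return ParsedStructure(status="parse_fail")
    mol = Chem.MolFromSmiles(str(smiles), sanitize=False)
    if mol is None:
        return ParsedStructure(status="parse_fail")
    try:
        SanitizeMol(mol)
    except Exception:
        raw = Chem.MolFromSmiles(str(smiles), sanitize=False)
        try:
            raw.UpdatePropertyCache(strict=False)
        except Exception:
            pass
        return ParsedStructure(status="sanitize_fail", mol=raw)
    return ParsedStructure(status="ok", mol=mol, canonical_smiles=Chem.MolToSmiles(mol))


def is_metal(atom: Chem.Atom) -> bool:
    z = atom.GetAtomicNum()
    return z > 0 and z not in _NONMETALS


def has_carbon_metal_bond(mol: Chem.Mol) -> bool:
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if (a.GetAtomicNum() == 6 and is_metal(b)) or (
            b.GetAtomicNum() == 6 and is_metal(a)
        ):
            return True
    return False


def fragment_has_organic_carbon(frag: Chem.Mol) -> bool:
    """True if any carbon is bonded to hydrogen or another carbon."""
    try:
        frag.UpdatePropertyCache(strict=False)
    except Exception:
        pass
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        if atom.GetTotalNumHs() > 0:
            return True
        if any(nb.GetAtomicNum() in (1, 6) for nb in atom.GetNeighbors()):
            return True
    return False


def has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def is_peptide(mol: Chem.Mol) -> bool:
    return len(mol.GetSubstructMatches(_PEPTIDE_REPEAT)) >= 2


def _base_category(mol: Chem.Mol) -> CurationCategory:
    """Rules 2-5 on an already-parsed molecule (sanitized or raw)."""
    if has_carbon_metal_bond(mol):
        return CurationCategory.ORGANOMETALLIC
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        if any(fragment_has_organic_carbon(f) for f in frags):
            return CurationCategory.ORGANIC_SALT
        return CurationCategory.INORGANIC_SALT
    if has_carbon(mol):
        if is_peptide(mol):
            return CurationCategory.PEPTIDE
        return CurationCategory.ORGANIC
    if mol.GetNumAtoms() == 1 and is_metal(mol.GetAtomWithIdx(0)):
        return CurationCategory.INORGANIC_METAL
    return CurationCategory.INORGANIC


_NOSAN_MAP = {
    CurationCategory.ORGANOMETALLIC: CurationCategory.NOSANITIZABLE_ORGANOMETALLIC,
    CurationCategory.ORGANIC: CurationCategory.NOSANITIZABLE_ORGANIC,
    CurationCategory.ORGANIC_SALT: CurationCategory.NOSANITIZABLE_ORGANIC,
    CurationCategory.PEPTIDE: CurationCategory.NOSANITIZABLE_ORGANIC,
    CurationCategory.INORGANIC: CurationCategory.NOSANITIZABLE_INORGANIC,
    CurationCategory.INORGANIC_SALT: CurationCategory.NOSANITIZABLE_INORGANIC,
    CurationCategory.INORGANIC_METAL: CurationCategory.NOSANITIZABLE_INORGANIC,
}


def classify_structure(parsed: ParsedStructure) -> CurationCategory:
    """Deterministic ten-way categorization of a parsed structure."""
    if parsed.status == "parse_fail" or parsed.mol is None:
        raise ValueError("cannot classify a structure that failed to parse")
    base = _base_category(parsed.mol)
    if parsed.status == "sanitize_fail":
        return _NOSAN_MAP[base]
    return base


def classify_smiles(smiles: str) -> CurationCategory:
    """Convenience: parse, sanitize and classify in one call."""
    return classify_structure(parse_and_sanitize(smiles))


def largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Desalt: keep the carbon-bearing fragment with most heavy atoms."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if has_carbon(f)] or list(frags)
    return max(organic, key=lambda f: f.GetNumHeavyAtoms())


def curate_registry(registry) -> "pd.DataFrame":
    """Classify every substance; returns cas,category,status,canonical_smiles.

    Substances without a structure get an empty category and status
    ``missing``; they are retained for non-QSAR methods.
    """
    import pandas as pd

    rows = []
    for sub in registry:
        if sub.smiles is None:
            sub.structure_status = "missing"
            rows.append(
                {"cas": sub.cas, "category": None, "status": "missing",
                 "canonical_smiles": None}
            )
            continue
        parsed = parse_and_sanitize(sub.smiles)
        sub.structure_status = parsed.status
        if parsed.status == "parse_fail":
            rows.append(
                {"cas": sub.cas, "category": None, "status": "parse_fail",
                 "canonical_smiles": None}
            )
            continue
        category = classify_structure(parsed)
        sub.category = category.value
        canonical = parsed.canonical_smiles
        if canonical is not None and category in (
            CurationCategory.ORGANIC_SALT,
        ):
            frag = largest_organic_fragment(parsed.mol)
            canonical = Chem.MolToSmiles(frag)
        rows.append(
            {"cas": sub.cas, "category": category.value, "status": parsed.status,
             "canonical_smiles": canonical}
        )
    return pd.DataFrame(rows, columns=["cas", "category", "status", "canonical_smiles"])


def select_modelable(curation: "pd.DataFrame") -> CurationReport:
    """Split a curation table into modelable and excluded substances.

    Kept: organic, organic_salt (desalted) and peptide.  Exclusions
    carry one of the closed reasons; |kept| + |excluded| equals the
    input size.
    """
    report = CurationReport()
    modelable_values = {c.value for c in MODELABLE}
    for row in curation.itertuples(index=False):
        if row.status == "missing":
            report.excluded.append((row.cas, "missing_structure"))
        elif row.status == "parse_fail":
            report.excluded.append((row.cas, "parse_fail"))
        elif row.category in modelable_values:
            report.kept.append(row.cas)
        else:
            report.excluded.append((row.cas, "discarded_category"))
    return report
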