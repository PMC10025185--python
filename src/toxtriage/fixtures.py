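"""Deterministic synthetic data emulating an industrial-chemical inventory.

Real hazard inventories are sparse (roughly 84% of possible endpoint
annotations missing), strongly imbalanced per endpoint, and fed by
multiple, occasionally conflicting sources.  These generators
reproduce that statistical structure from a seed so every pipeline
stage is testable without any download, and emit ground-truth tables
alongside so downstream tests need no re-derivation.

Default endpoint prevalences mirror the regimes the pipeline must
handle: a CMR-like endpoint where positives dominate (triggering
balanced-subset ensembles), PBT/vPvB-like endpoints with rare
positives (triggering oversampling), and an ED-like endpoint with
almost no negatives (triggering the read-across fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from toxtriage.cas import format_cas
from toxtriage.curation import CurationCategory
from toxtriage.integration import ENDPOINTS, YES, NO

# -- curated SMILES template library spanning all ten curation categories --

TEMPLATES: dict[str, list] = {
    "organic": [
        "CCO", "c1ccccc1", "CC(=O)O", "CCN", "Oc1ccccc1", "CCCCCC",
        "CC(C)O", "c1ccncc1", "CCOC(C)=O", "CC(=O)Nc1ccccc1",
        "Clc1ccccc1", "CCCCO", "CC(C)Cc1ccccc1", "OCCO", "N#Cc1ccccc1",
    ],
    "organic_salt": [
        "CC(=O)[O-].[Na+]", "c1ccccc1C(=O)[O-].[K+]", "CC[NH3+].[Cl-]",
        "CS(=O)(=O)[O-].[Na+]",
    ],
    "organometallic": ["CC[Sn](CC)CC", "C[Hg]C", "CC[Pb](CC)(CC)CC"],
    "peptide": ["NCC(=O)NCC(=O)O", "CC(N)C(=O)NC(C)C(=O)NCC(=O)O"],
    "inorganic": ["O=S(=O)(O)O", "N#N", "O", "NN", "O=[N+]([O-])O"],
    "inorganic_salt": ["[Na+].[Cl-]", "[K+].[Br-]", "[Mg+2].[O-]S([O-])(=O)=O"],
    "inorganic_metal": ["[Fe]", "[Cu+2]", "[Zn]"],
    "nosanitizable_organic": ["N(C)(C)(C)(C)C", "CC(C)(C)(C)C"],
    "nosanitizable_inorganic": ["F(F)F"],
    "nosanitizable_organometallic": ["CC(C)(C)(C)[Sn]C"],
}

DEFAULT_STRUCTURE_MIX = {
    "organic": 0.72,
    "organic_salt": 0.08,
    "peptide": 0.02,
    "inorganic": 0.05,
    "inorganic_salt": 0.05,
    "inorganic_metal": 0.03,
    "organometallic": 0.02,
    "nosanitizable_organic": 0.015,
    "nosanitizable_inorganic": 0.005,
    "nosanitizable_organometallic": 0.01,
}

#: Per-endpoint P(YES) among annotated substances, mirroring the
#: positive-heavy CMR regime, rare-positive PBT/vPvB regimes and the
#: almost-all-positive ED regime.
DEFAULT_PREVALENCE = {"CMR": 0.75, "ED": 0.98, "PBT": 0.10, "vPvB": 0.11}

DEFAULT_SOURCE_WEIGHTS = {
    "ECHA_CLP": 0.35,
    "ECHA_REACH": 0.15,
    "ECHA_SVHC": 0.10,
    "REFERENCE_DB": 0.15,
    "PHAROS": 0.25,
}

#: Hazard codes the default mapping resolves for each endpoint.
_CODES = {
    "CMR": ("H340", "H350", "H360"),
    "ED": ("ED_assessment",),
    "PBT": ("PBT_Annex_XIII",),
    "vPvB": ("vPvB_Annex_XIII",),
}


@dataclass
class FixtureConfig:
    n_substances: int = 200
    structure_mix: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURE_MIX))
    endpoint_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    annotation_sparsity: float = 0.84
    source_weights: dict = field(default_factory=lambda: dict(DEFAULT_SOURCE_WEIGHTS))
    conflict_rate: float = 0.05
    missing_structure_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.structure_mix.values()) - 1.0) > 1e-9:
            raise ValueError("structure_mix proportions must sum to 1")
        for p in (self.annotation_sparsity, self.conflict_rate,
                  self.missing_structure_rate, *self.endpoint_prevalence.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def generate_registry(config: FixtureConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic substances CSV frame plus its ground-truth categories.

    Returns ``(substances, truth)``: substances has columns
    cas,name,smiles,ec_number; truth has cas,category (category is None
    for the configured fraction of structureless substances).  All CAS
    identifiers carry correct check digits; output is a pure function
    of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    categories = list(config.structure_mix)
    probs = np.array([config.structure_mix[c] for c in categories])
    sub_rows, truth_rows = [], []
    for i in range(config.n_substances):
        cas = format_cas(1000 + i * 7)
        name = f"substance-{i:05d}"
        if rng.random() < config.missing_structure_rate:
            smiles, category = None, None
        else:
            category = categories[rng.choice(len(categories), p=probs)]
            pool = TEMPLATES[category]
            smiles = pool[rng.integers(len(pool))]
        sub_rows.append({"cas": cas, "name": name, "smiles": smiles,
                         "ec_number": None})
        truth_rows.append({"cas": cas, "category": category})
    substances = pd.DataFrame(sub_rows, columns=["cas", "name", "smiles", "ec_number"])
    truth = pd.DataFrame(truth_rows, columns=["cas", "category"])
    return substances, truth


def generate_source_annotations(
    registry: pd.DataFrame, config: FixtureConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic multi-source hazard annotations plus ground-truth labels.

    For each (substance, endpoint) a latent YES/NO truth is drawn at
    the configured prevalence.  With probability 1 - sparsity the pair
    is annotated by 1-3 source-level assertions; with probability
    ``conflict_rate`` the assertions are made to disagree in polarity.
    Positive truths may be asserted by any source; negative truths only
    by the reference-database and Pharos tiers (core regulatory sources
    assert hazards, not their absence), so with a zero conflict rate the
    integrated label equals the truth wherever annotated.
    """
    rng = np.random.default_rng(config.seed + 1)
    sources = list(config.source_weights)
    weights = np.array([config.source_weights[s] for s in sources])
    weights = weights / weights.sum()
    negative_sources = [s for s in sources if s in ("REFERENCE_DB", "PHAROS")]
    ann_rows, truth_rows = [], []
    for row in registry.itertuples(index=False):
        for endpoint in ENDPOINTS:
            truth = YES if rng.random() < config.endpoint_prevalence[endpoint] else NO
            annotated = rng.random() >= config.annotation_sparsity
            truth_rows.append(
                {"cas": row.cas, "endpoint": endpoint, "truth": truth,
                 "annotated": annotated}
            )
            if not annotated:
                continue
            k = int(rng.integers(1, 4))
            conflict = config.conflict_rate > 0 and rng.random() < config.conflict_rate
            if conflict and k == 1:
                k = 2
            polarity = "positive" if truth == YES else "negative"
            for j in range(k):
                pol = polarity
                if conflict and j == k - 1:
                    pol = "negative" if polarity == "positive" else "positive"
                if pol == "positive":
                    source = sources[rng.choice(len(sources), p=weights)]
                else:
                    source = negative_sources[rng.integers(len(negative_sources))]
                code = _CODES[endpoint][rng.integers(len(_CODES[endpoint]))]
                ann_rows.append(
                    {"cas": row.cas, "source": source, "hazard_code": code,
                     "polarity": pol}
                )
    annotations = pd.DataFrame(
        ann_rows, columns=["cas", "source", "hazard_code", "polarity"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["cas", "endpoint", "truth", "annotated"]
    )
    return annotations, truth


# -- binary-labelled structure datasets for QSAR property testing --------

_SIDE_CHAINS = ["C", "CC", "CCC", "C(C)C", "O", "OC", "N", "CCO", "C=O",
                "OCC", "CN", ""]


def _substituted_benzene(rng: np.random.Generator, n_chlorine: int) -> str:
    """Random benzene with 4 substituent slots, n of them chlorine."""
    subs = [_SIDE_CHAINS[rng.integers(len(_SIDE_CHAINS))] for _ in range(4)]
    positions = rng.choice(4, size=min(n_chlorine, 4), replace=False)
    for p in positions:
        subs[p] = "Cl"
    atoms = ["c1"] + [f"c({s})" if s else "c" for s in subs] + ["c1"]
    return "".join(atoms)


def generate_binary_structure_dataset(
    n_pos: int,
    n_neg: int,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exchangeable SMILES dataset with a structural class signal.

    The positive class carries a ring-chlorination motif (2-4 chlorine
    substituents on a benzene scaffold); negatives carry none.  Observed
    labels flip with probability ``noise``, independently, giving an
    exchangeable dataset whose Bayes error is controlled — the setting
    under which conformal validity can be checked by simulation.

    Returns columns cas, smiles, y (observed) and y_true.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one record")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos + n_neg):
        true = 1 if i < n_pos else 0
        n_cl = int(rng.integers(2, 5)) if true else 0
        smiles = _substituted_benzene(rng, n_cl)
        observed = true
        if noise > 0 and rng.random() < noise:
            observed = 1 - true
        rows.append(
            {"cas": format_cas(500000 + i * 3), "smiles": smiles,
             "y": observed, "y_true": true}
        )
    frame = pd.DataFrame(rows, columns=["cas", "smiles", "y", "y_true"])
    return frame.sample(frac=1.0, random_state=seed).reset_index(drop=True)


# -- presets -------------------------------------------------------------

PRESETS = {
    "cmr": FixtureConfig(
        n_substances=300,
        endpoint_prevalence={"CMR": 0.75, "ED": 0.6, "PBT": 0.3, "vPvB": 0.3},
        annotation_sparsity=0.5,
    ),
    "pbt": FixtureConfig(
        n_substances=300,
        endpoint_prevalence={"CMR": 0.5, "ED": 0.5, "PBT": 0.10, "vPvB": 0.11},
        annotation_sparsity=0.5,
    ),
    "ed": FixtureConfig(
        n_substances=300,
        endpoint_prevalence={"CMR": 0.5, "ED": 0.99, "PBT": 0.3, "vPvB": 0.3},
        annotation_sparsity=0.5,
    ),
}
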