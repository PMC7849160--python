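"""Functional-class vocabulary for KEGG-level-3-like category names.

Metabolic categories split into *specialized* functions (restricted to narrow
taxonomic guilds: sulfur, nitrogen and methane cycling, terpenoid/polyketide
biosynthesis, xenobiotics degradation) and *broad* functions (core carbohydrate,
amino-acid and lipid metabolism present in essentially all living cells).
Non-metabolic level-1 parents (genetic information processing, cellular
processes, environmental information processing, organismal systems) map to
their own classes. Names are matched case-insensitively with punctuation
normalized; unknown names get the explicit ``unmapped`` label, never a guess.
The vocabulary is user-extensible via ``register_categories``.
"""

from __future__ import annotations

import re

__all__ = [
    "SPECIALIZED_METABOLIC",
    "BROAD_METABOLIC",
    "GENETIC_INFORMATION_PROCESSING",
    "ORGANISMAL_SYSTEMS",
    "CELLULAR_PROCESSES",
    "ENVIRONMENTAL_INFORMATION_PROCESSING",
    "UNMAPPED",
    "SPECIALIZED_CATEGORIES",
    "BROAD_CATEGORIES",
    "functional_class_of",
    "register_categories",
    "class_map",
]

SPECIALIZED_METABOLIC = "specialized_metabolic"
BROAD_METABOLIC = "broad_metabolic"
GENETIC_INFORMATION_PROCESSING = "genetic_information_processing"
ORGANISMAL_SYSTEMS = "organismal_systems"
CELLULAR_PROCESSES = "cellular_processes"
ENVIRONMENTAL_INFORMATION_PROCESSING = "environmental_information_processing"
UNMAPPED = "unmapped"

METABOLIC_CLASSES = frozenset({SPECIALIZED_METABOLIC, BROAD_METABOLIC})
ENVIRONMENTAL_RESPONSE_CLASSES = frozenset(
    {CELLULAR_PROCESSES, ENVIRONMENTAL_INFORMATION_PROCESSING}
)

SPECIALIZED_CATEGORIES = (
    "Sulfur metabolism",
    "Nitrogen metabolism",
    "Methane metabolism",
    "Terpenoids and polyketides metabolism",
    "Xenobiotics biodegradation/metabolism",
)

BROAD_CATEGORIES = (
    "Glycolysis/Gluconeogenesis",
    "TCA cycle",
    "Pentose phosphate pathway",
    "Fructose and mannose metabolism",
    "Galactose metabolism",
    "Starch and sucrose metabolism",
    "Pyruvate metabolism",
    "Glyoxylate and dicarboxylate metabolism",
    "Butanoate metabolism",
    "Propanoate metabolism",
    "Amino acid metabolism",
    "Lipid metabolism",
)

_GENETIC_CATEGORIES = (
    "Ribosome",
    "DNA replication",
    "Transcription machinery",
    "Aminoacyl-tRNA biosynthesis",
    "Homologous recombination",
    "Mismatch repair",
    "RNA degradation",
)

_CELLULAR_CATEGORIES = (
    "Flagellar assembly",
    "Bacterial chemotaxis",
    "Biofilm formation",
    "Quorum sensing",
    "Cell cycle - Caulobacter",
    "Peptidoglycan biosynthesis",
)

_ENVIRONMENTAL_CATEGORIES = (
    "Ion channels",
    "ABC transporters",
    "Two-component system",
    "Phosphotransferase system",
    "Bacterial secretion system",
)

_ORGANISMAL_CATEGORIES = (
    "Antigen processing and presentation",
    "Plant-pathogen interaction",
)


def _norm(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", name.lower()).strip()


_CLASS_MAP: dict[str, str] = {}
for _names, _cls in (
    (SPECIALIZED_CATEGORIES, SPECIALIZED_METABOLIC),
    (BROAD_CATEGORIES, BROAD_METABOLIC),
    (_GENETIC_CATEGORIES, GENETIC_INFORMATION_PROCESSING),
    (_CELLULAR_CATEGORIES, CELLULAR_PROCESSES),
    (_ENVIRONMENTAL_CATEGORIES, ENVIRONMENTAL_INFORMATION_PROCESSING),
    (_ORGANISMAL_CATEGORIES, ORGANISMAL_SYSTEMS),
):
    for _n in _names:
        _CLASS_MAP[_norm(_n)] = _cls

# common phosphorus-cycle category; specialized guild like N and S cycling
_CLASS_MAP[_norm("Phosphonate and phosphinate metabolism")] = SPECIALIZED_METABOLIC

_VALID_CLASSES = frozenset({
    SPECIALIZED_METABOLIC, BROAD_METABOLIC, GENETIC_INFORMATION_PROCESSING,
    ORGANISMAL_SYSTEMS, CELLULAR_PROCESSES, ENVIRONMENTAL_INFORMATION_PROCESSING,
})


def functional_class_of(category_name: str) -> str:
    """Class label for a category name; ``unmapped`` when unknown."""
    return _CLASS_MAP.get(_norm(category_name), UNMAPPED)


def register_categories(mapping: dict[str, str]) -> None:
    """Extend the vocabulary with user categories (name -> class label)."""
    for name, cls in mapping.items():
        if cls not in _VALID_CLASSES:
            raise ValueError(f"unknown functional class {cls!r}")
        _CLASS_MAP[_norm(name)] = cls


def class_map(category_names) -> dict[str, str]:
    """Classes for a list of category names (total mapping, unmapped allowed)."""
    return {name: functional_class_of(name) for name in category_names}
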