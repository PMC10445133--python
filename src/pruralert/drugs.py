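"""Dermatologic drug catalog and treatment-course classification.

Five therapeutic categories are tracked: systemic antipruritics,
antibiotics (topical and/or systemic), topical otic preparations,
topical skin preparations, and nutritionals.  Each drug type prescribed
at a visit counts as one treatment course regardless of duration.

Some combination products legitimately appear in more than one category
(e.g. gentamicin/betamethasone is both an antibiotic and an otic
preparation).  Classification resolves these by an explicit
``context`` argument when the prescribing context is known, otherwise
by the fixed priority otic > topical skin > antibiotic.
"""

from __future__ import annotations

__all__ = ["CATEGORIES", "DRUG_CATALOG", "classify_drug", "UNCLASSIFIED"]

UNCLASSIFIED = "unclassified"

ANTIPRURITIC = (
    "lokivetmab",
    "chlorpheniramine",
    "cyclosporine",
    "dexamethasone",
    "diphenhydramine",
    "hydroxyzine",
    "oclacitinib",
    "prednisone",
    "trimeprazine/prednisone",
)

ANTIBIOTIC = (
    "amoxicillin",
    "amoxicillin/clavulanate",
    "bacitracin/neomycin/polymyxin",
    "cefadroxil",
    "cefazolin",
    "cefovecin",
    "cefpodoxime",
    "clindamycin",
    "doxycycline",
    "enrofloxacin",
    "enrofloxacin/silver sulfadiazine",
    "gentamicin/betamethasone",
    "gentamicin/clotrimazole/mometasone",
    "marbofloxacin",
    "nystatin/neomycin/thiostrepton/triamcinolone acetonide",
    "sulfadimethoxine/ormetoprim",
    "sulfamethoxazole/trimethoprim",
)

OTIC = (
    "acetic acid/boric acid",
    "acetic acid/hydocortisone",
    "ear cleaner non-medicated",
    "enrofloxacin/silver sulfadiazine",
    "florfenicol/terbinafine/betamethasone acetate",
    "florfenicol/terbinafine/mometasone furoate",
    "fluocinolone/dimethyl sulfoxide",
    "gentamicin/betamethasone",
    "gentamicin/clotrimazole/mometasone",
    "ketoconazole/chlorhexidine/tris-edta",
    "tromethamine/disodium edta dihydrate",
)

TOPICAL_SKIN = (
    "acetic acid/chlorhexidine/ketoconazole",
    "benzoyl peroxide",
    "benzoyl peroxide/sulfur/salicylic acid",
    "chlorhexidine/climbazole",
    "chlorhexidine/tromethamine/disodium edta dihydrate",
    "conditioner non-medicated",
    "hydrocortisone/aluminum acetate",
    "nystatin/neomycin/thiostrepton/triamcinolone acetonide",
    "sulfur/salicylic acid",
)

NUTRITIONAL = (
    "dermatology diet",
    "fish oil/omega fatty acids/vitamin e",
)

# Lookup priority resolves drugs listed under several categories.
CATEGORIES = ("otic", "topical_skin", "antibiotic", "antipruritic", "nutritional")

DRUG_CATALOG: dict[str, tuple[str, ...]] = {
    "antipruritic": ANTIPRURITIC,
    "antibiotic": ANTIBIOTIC,
    "otic": OTIC,
    "topical_skin": TOPICAL_SKIN,
    "nutritional": NUTRITIONAL,
}

_MEMBERSHIP = {
    category: frozenset(name.lower() for name in names)
    for category, names in DRUG_CATALOG.items()
}


def classify_drug(drug_name: str, context: str | None = None) -> str:
    """Therapeutic category of a drug name (case-insensitive).

    ``context``, when given and consistent with the catalog, wins for
    drugs listed under several categories; otherwise the priority
    otic > topical_skin > antibiotic > antipruritic > nutritional
    applies.  Unknown names map to the ``unclassified`` sentinel.
    """
    name = " ".join(str(drug_name).lower().split())
    if context is not None:
        ctx = str(context).lower()
        if ctx in _MEMBERSHIP and name in _MEMBERSHIP[ctx]:
            return ctx
    for category in CATEGORIES:
        if name in _MEMBERSHIP[category]:
            return category
    return UNCLASSIFIED
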