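"""Small stand-in vocabularies and a hand-built miniature cohort.

Production runs require user-supplied vocabularies (the named inclusion /
exclusion code sets and the public ICD9→phecode table, which is not
redistributed here).  For tests, documentation, and the synthetic study this
module ships a compact but structurally faithful stand-in: ~35 ICD9 codes in
~20 PheWAS groups across 8 physiological systems, plus prefix code sets for
SMA, neuromuscular disease/degeneration, and pregnancy billing codes.

:func:`twelve_member_cohort` builds a fully hand-checked 12-member claims
universe (2 genuine SMA cases, 3 look-alike contaminants, 7 controls) whose
correct cohort assignment is known by construction; it is the reference
fixture for the selection rules.
"""

from __future__ import annotations

import pandas as pd

from .claims_model import Claim, Member, claims_frame, members_frame
from .vocab import CodeSet, PhewasMap, SystemMap, Vocabulary

__all__ = ["fixture_vocabulary", "twelve_member_cohort"]

# ICD9 (canonical) -> (phewas_code, phenotype_label, system_label)
_PHEWAS_ROWS: list[tuple[str, str, str, str]] = [
    # Cardiovascular
    ("4242",  "395.3",  "Nonrheumatic tricuspid valve disorders", "Cardiovascular"),
    ("4276",  "427.6",  "Premature beats",                        "Cardiovascular"),
    ("42760", "427.6",  "Premature beats",                        "Cardiovascular"),
    ("42769", "427.6",  "Premature beats",                        "Cardiovascular"),
    ("7450",  "747.11", "Cardiac shunt/heart septal defect",      "Cardiovascular"),
    ("7454",  "747.11", "Cardiac shunt/heart septal defect",      "Cardiovascular"),
    ("4439",  "443.9",  "Peripheral vascular disease, unspecified", "Cardiovascular"),
    # Gastrointestinal
    ("7872",  "532",    "Dysphagia",                              "Gastrointestinal"),
    ("78720", "532",    "Dysphagia",                              "Gastrointestinal"),
    ("78729", "532",    "Dysphagia",                              "Gastrointestinal"),
    ("5640",  "563",    "Constipation",                           "Gastrointestinal"),
    ("56400", "563",    "Constipation",                           "Gastrointestinal"),
    ("56409", "563",    "Constipation",                           "Gastrointestinal"),
    ("53081", "530.11", "GERD",                                   "Gastrointestinal"),
    ("5362",  "789.1",  "Persistent vomiting",                    "Gastrointestinal"),
    ("5589",  "558",    "Noninfectious gastroenteritis",          "Gastrointestinal"),
    # Skeletal
    ("7373",  "737.3",  "Kyphoscoliosis and scoliosis",           "Skeletal"),
    ("73730", "737.3",  "Kyphoscoliosis and scoliosis",           "Skeletal"),
    ("7545",  "754.7",  "Congenital deformities of feet",         "Skeletal"),
    ("7546",  "754.7",  "Congenital deformities of feet",         "Skeletal"),
    ("734",   "735",    "Flat feet",                              "Skeletal"),
    # Neurological (symptom-level, outside the degeneration code set)
    ("7813",  "350.3",  "Lack of coordination",                   "Neurological"),
    ("7834",  "315.3",  "Developmental delays and disorders",     "Neurological"),
    ("3159",  "315.3",  "Developmental delays and disorders",     "Neurological"),
    # Metabolic
    ("2512",  "251.1",  "Hypoglycemia",                           "Metabolic"),
    ("2768",  "276.8",  "Hypopotassemia",                         "Metabolic"),
    # Male reproductive
    ("2572",  "257.1",  "Testicular hypofunction",                "Male_Reproductive"),
    ("6060",  "609.1",  "Infertility, male",                      "Male_Reproductive"),
    ("6069",  "609.1",  "Infertility, male",                      "Male_Reproductive"),
    # Other / symptoms
    ("3382",  "338.2",  "Chronic pain",                           "Other/Symptoms"),
    ("33829", "338.2",  "Chronic pain",                           "Other/Symptoms"),
    ("7833",  "783",    "Feeding difficulties",                   "Other/Symptoms"),
    # Muscular (these ARE neuromuscular codes; they appear in entire-window
    # analyses and exercise near-separation, but never in pre windows)
    ("3350",  "335",    "Anterior horn cell disease",             "Muscular"),
    ("33510", "335",    "Anterior horn cell disease",             "Muscular"),
    ("33511", "335",    "Anterior horn cell disease",             "Muscular"),
    ("7282",  "728.2",  "Muscular wasting and atrophy",           "Muscular"),
]


def fixture_vocabulary() -> Vocabulary:
    """The bundled stand-in vocabulary used by tests, docs, and simulations."""
    phewas = PhewasMap(pd.DataFrame(
        [(i, p, l) for i, p, l, _ in _PHEWAS_ROWS],
        columns=["icd9", "phewas_code", "phenotype_label"]))
    systems = SystemMap(pd.DataFrame(
        sorted({(p, s) for _, p, _, s in _PHEWAS_ROWS}),
        columns=["phewas_code", "system_label"]))
    return Vocabulary(
        sma=CodeSet("sma", frozenset({"3350", "3351"}), "prefix"),
        neuromuscular=CodeSet(
            "neuromuscular", frozenset({"335", "358", "359", "7282"}), "prefix"),
        pregnancy=CodeSet(
            "pregnancy", frozenset({"V22", "V23", "650", "651"}), "prefix"),
        phewas_map=phewas,
        system_map=systems,
    )


def twelve_member_cohort() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A hand-built 12-member universe with known-correct assignments.

    Contents (all infants, so the cases stratify into Group A):

    * ``M01``, ``M02`` — genuine cases: ≥2 SMA codes on distinct dates,
      final neuromuscular diagnosis SMA, no pregnancy codes.  ``M02``'s
      first SMA code shares its date with a degeneration code (same-date
      tie on the final-diagnosis rule is resolved in favour of SMA).
    * ``M03`` — one SMA code only (billing one-off): excluded, single_visit.
    * ``M04`` — two SMA codes but a *later* muscular-dystrophy code:
      excluded, final_dx_not_sma (likely misdiagnosis).
    * ``M05`` — SMA codes alongside pregnancy billing codes (prenatal
      testing artifact): excluded, pregnancy_codes.
    * ``M06``–``M12`` — controls, enrollment ages inside the cases' range;
      ``M08`` carries a muscular-dystrophy code mid-enrollment (truncated in
      the pre-degeneration window), ``M10`` has zero claims.

    Returns ``(members, claims, expected)`` where ``expected`` has columns
    ``member_id, role, group, exclusion_reason``.
    """
    members = members_frame([
        Member("M01", "male",   2009, "2009-06-15", "2012-06-15", birth_date="2009-06-01"),
        Member("M02", "female", 2009, "2009-07-01", "2013-01-10", birth_date="2009-01-01"),
        Member("M03", "male",   2009, "2010-01-01", "2012-01-01", birth_date="2009-10-01"),
        Member("M04", "male",   2009, "2009-12-01", "2012-12-01", birth_date="2009-05-01"),
        Member("M05", "female", 1988, "2009-01-01", "2012-01-01", birth_date="1988-03-01"),
        Member("M06", "female", 2009, "2009-06-01", "2012-06-01", birth_date="2009-04-01"),
        Member("M07", "male",   2009, "2009-05-01", "2012-05-01", birth_date="2009-01-15"),
        Member("M08", "male",   2009, "2009-03-15", "2012-03-15", birth_date="2009-02-01"),
        Member("M09", "female", 2009, "2009-07-15", "2012-07-15", birth_date="2009-05-01"),
        Member("M10", "male",   2009, "2009-08-01", "2013-08-01", birth_date="2009-06-20"),
        Member("M11", "female", 2008, "2009-04-01", "2012-04-01", birth_date="2008-12-01"),
        Member("M12", "male",   2009, "2009-05-20", "2012-05-20", birth_date="2009-03-10"),
    ])
    claims = claims_frame([
        # M01: phenotypes before inflection 2010-03-01, SMA codes after
        Claim("M01", "2009-10-15", "424.2"),
        Claim("M01", "2010-02-01", "787.2"),
        Claim("M01", "2010-03-01", "335.10"),
        Claim("M01", "2010-04-01", "335.10"),
        # M02: inflection 2010-06-01 (SMA + wasting, same date)
        Claim("M02", "2009-12-01", "564.0"),
        Claim("M02", "2010-06-01", "335.0"),
        Claim("M02", "2010-06-01", "728.2"),
        Claim("M02", "2010-08-01", "335.11"),
        # M03: single SMA code
        Claim("M03", "2010-06-01", "335.10"),
        # M04: SMA then later muscular dystrophy
        Claim("M04", "2010-02-01", "335.10"),
        Claim("M04", "2010-03-01", "335.10"),
        Claim("M04", "2011-01-01", "359.0"),
        # M05: SMA codes with pregnancy billing
        Claim("M05", "2010-01-05", "335.10"),
        Claim("M05", "2010-01-05", "V22.0"),
        Claim("M05", "2010-02-05", "335.10"),
        # Controls
        Claim("M06", "2010-01-15", "424.2"),
        Claim("M07", "2010-03-01", "564.0"),
        Claim("M08", "2010-09-01", "359.0"),   # MD code: pre-window truncation
        Claim("M09", "2010-02-01", "783.3"),
        Claim("M11", "2011-01-01", "530.81"),
        Claim("M12", "2010-04-01", "251.2"),
    ])
    expected = pd.DataFrame(
        [
            ("M01", "case", "A", None),
            ("M02", "case", "A", None),
            ("M03", "excluded", None, "single_visit"),
            ("M04", "excluded", None, "final_dx_not_sma"),
            ("M05", "excluded", None, "pregnancy_codes"),
            ("M06", "control", "A", None),
            ("M07", "control", "A", None),
            ("M08", "control", "A", None),
            ("M09", "control", "A", None),
            ("M10", "control", "A", None),
            ("M11", "control", "A", None),
            ("M12", "control", "A", None),
        ],
        columns=["member_id", "role", "group", "exclusion_reason"],
    )
    return members, claims, expected
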