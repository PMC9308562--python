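"""WHO ICD-10 chapter table (version 10, 2016 block boundaries).

Chapters are identified by their Roman numerals I–XXII; each chapter owns a
contiguous range of 3-character code stems.  The table is embedded as a
versioned constant so chapter assignment needs no external lookup.
"""

from __future__ import annotations

import re

__all__ = ["CHAPTERS", "icd10_chapter", "normalize_code", "is_cancer", "NON_MELANOMA_SKIN"]

# (numeral, first stem, last stem, title)
CHAPTERS: tuple[tuple[str, str, str, str], ...] = (
    ("I", "A00", "B99", "Certain infectious and parasitic diseases"),
    ("II", "C00", "D48", "Neoplasms"),
    ("III", "D50", "D89", "Diseases of the blood and blood-forming organs"),
    ("IV", "E00", "E90", "Endocrine, nutritional and metabolic diseases"),
    ("V", "F00", "F99", "Mental and behavioural disorders"),
    ("VI", "G00", "G99", "Diseases of the nervous system"),
    ("VII", "H00", "H59", "Diseases of the eye and adnexa"),
    ("VIII", "H60", "H95", "Diseases of the ear and mastoid process"),
    ("IX", "I00", "I99", "Diseases of the circulatory system"),
    ("X", "J00", "J99", "Diseases of the respiratory system"),
    ("XI", "K00", "K93", "Diseases of the digestive system"),
    ("XII", "L00", "L99", "Diseases of the skin and subcutaneous tissue"),
    ("XIII", "M00", "M99", "Diseases of the musculoskeletal system and connective tissue"),
    ("XIV", "N00", "N99", "Diseases of the genitourinary system"),
    ("XV", "O00", "O99", "Pregnancy, childbirth and the puerperium"),
    ("XVI", "P00", "P96", "Certain conditions originating in the perinatal period"),
    ("XVII", "Q00", "Q99", "Congenital malformations, deformations and chromosomal abnormalities"),
    ("XVIII", "R00", "R99", "Symptoms, signs and abnormal clinical and laboratory findings"),
    ("XIX", "S00", "T98", "Injury, poisoning and certain other consequences of external causes"),
    ("XX", "V01", "Y98", "External causes of morbidity and mortality"),
    ("XXI", "Z00", "Z99", "Factors influencing health status and contact with health services"),
    ("XXII", "U00", "U99", "Codes for special purposes"),
)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[0-9]{1,2})?$")

NON_MELANOMA_SKIN = "C44"


def normalize_code(code: str) -> str:
    """Uppercase, strip the decimal point: 'i25.1' -> 'I251'."""
    code = str(code).strip().upper()
    if not _CODE_RE.match(code):
        raise ValueError(f"not a valid ICD-10 code: {code!r}")
    return code.replace(".", "")


def icd10_chapter(code: str) -> str:
    """Roman numeral of the WHO chapter containing ``code``'s 3-character stem."""
    stem = normalize_code(code)[:3]
    for numeral, lo, hi, _ in CHAPTERS:
        if lo <= stem <= hi:
            return numeral
    raise ValueError(f"ICD-10 code {code!r} maps to no chapter")


def is_cancer(code: str, include_nmsc: bool = False) -> bool:
    """True for malignant neoplasms C00–C97; C44 (non-melanoma skin) optional."""
    stem = normalize_code(code)[:3]
    if not ("C00" <= stem <= "C97"):
        return False
    if stem == NON_MELANOMA_SKIN and not include_nmsc:
        return False
    return True
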