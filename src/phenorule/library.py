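"""The shipped five-disease rule library.

Twelve (or six) numbered component algorithms per disease over admission,
discharge, and outpatient records, combining ICD-10 code patterns with
diagnostic-term synonym lists, plus the validated final OR-composite for
each disease.  Synonyms ship in both Chinese and English, selectable per
call; multiplicity thresholds (2 or 3 distinct record dates) are attached to
the components that require them, and the compound type-1-diabetes rules
require the code and the ketosis term on the same encounter.

Emergency and inpatient records are supported by the engine but referenced
by no shipped component.
"""

from __future__ import annotations

from .errors import ConfigError
from .model import Source
from .rules import ComponentAlgorithm, CompositeAlgorithm, Matcher

__all__ = ["DISEASES", "builtin_library", "disease_synonyms"]

DISEASES = ("hashimoto", "ibd", "itp", "ra", "t1d")

#: Synonym lists per disease concept, keyed by language.
_SYNONYMS = {
    "hashimoto": {
        "en": ["Hashimoto", "Chiomoto", "lymphocytic goiter"],
        "zh": ["桥本", "乔本", "淋巴细胞性甲状腺肿"],
    },
    "crohn": {"en": ["Crohn"], "zh": ["克罗恩", "克隆病"]},
    "ulcerative_colitis": {"en": ["ulcerative colitis"], "zh": ["溃疡性结肠炎"]},
    "immune_tp": {"en": ["immune thrombocytopenia"], "zh": ["免疫性血小板减少"]},
    "idiopathic_tp": {"en": ["idiopathic thrombocytopenia"], "zh": ["特发性血小板减少"]},
    "ra": {"en": ["rheumatoid arthritis"], "zh": ["类风湿关节炎", "类风湿性关节炎"]},
    "t1d": {
        "en": ["type I diabetes", "type 1 diabetes", "insulin-dependent diabetes"],
        "zh": ["1型糖尿病", "Ⅰ型糖尿病", "胰岛素依赖型糖尿病"],
    },
    "autoimmune_diabetes": {
        "en": ["autoimmune diabetes"],
        "zh": ["自身免疫性糖尿病", "自身免疫糖尿病"],
    },
    "diabetic_ketosis": {"en": ["diabetic ketosis"], "zh": ["糖尿病酮症"]},
}


def disease_synonyms(concept: str, language: str = "both") -> list[str]:
    """Synonyms for one disease concept in the requested language(s)."""
    try:
        entry = _SYNONYMS[concept]
    except KeyError:
        raise ConfigError(f"unknown synonym concept {concept!r}") from None
    if language == "both":
        return entry["en"] + entry["zh"]
    try:
        return list(entry[language])
    except KeyError:
        raise ConfigError(f"unknown language {language!r}; use 'en', 'zh' or 'both'") from None


def _term(concept: str, language: str) -> Matcher:
    return Matcher.term(*disease_synonyms(concept, language))


def builtin_library(language: str = "both") -> dict:
    """The validated component and final algorithms for the five diseases.

    Returns ``{disease: (components, final)}`` where ``components`` is the
    full numbered list and ``final`` the validated OR-composite.  ``language``
    selects the synonym lists ('en', 'zh', or 'both'; default matches either
    language, as the source records mix scripts).
    """
    adm, dis, outp = Source.ADMISSION, Source.DISCHARGE, Source.OUTPATIENT
    lib: dict[str, tuple] = {}

    def comp(disease, n, source, matcher, conjunct=None, min_count=1):
        return ComponentAlgorithm(
            id=f"{disease.upper()}-{n}", source=source, matcher=matcher,
            conjunct=conjunct, min_count=min_count,
        )

    # Hashimoto's thyroiditis: term and E06.3 over the three sources; all six
    # components enter the final composite.
    ht_term = _term("hashimoto", language)
    ht_icd = Matcher.icd("E06.3")
    ht = [
        comp("hashimoto", 1, adm, ht_term),
        comp("hashimoto", 2, adm, ht_icd),
        comp("hashimoto", 3, dis, ht_term),
        comp("hashimoto", 4, dis, ht_icd),
        comp("hashimoto", 5, outp, ht_term),
        comp("hashimoto", 6, outp, ht_icd),
    ]
    lib["hashimoto"] = (ht, CompositeAlgorithm("hashimoto", tuple(ht)))

    # IBD: Crohn's disease (K50) and ulcerative colitis (K51); outpatient
    # rows 11-12 require 3 or more record dates.
    crohn, uc = _term("crohn", language), _term("ulcerative_colitis", language)
    k50, k51 = Matcher.icd("K50"), Matcher.icd("K51")
    ibd = [
        comp("ibd", 1, adm, crohn),
        comp("ibd", 2, adm, k50),
        comp("ibd", 3, adm, uc),
        comp("ibd", 4, adm, k51),
        comp("ibd", 5, dis, crohn),
        comp("ibd", 6, dis, k50),
        comp("ibd", 7, dis, uc),
        comp("ibd", 8, dis, k51),
        comp("ibd", 9, outp, crohn),
        comp("ibd", 10, outp, k50),
        comp("ibd", 11, outp, uc, min_count=3),
        comp("ibd", 12, outp, k51, min_count=3),
    ]
    ibd_final = [1, 3, 5, 6, 9, 10, 11, 12]
    lib["ibd"] = (
        ibd,
        CompositeAlgorithm("ibd", tuple(c for c in ibd if int(c.id.split("-")[1]) in ibd_final)),
    )

    # ITP: immune/idiopathic thrombocytopenia terms with D69.3/D69.4;
    # outpatient rows 10-11 require 2 or more record dates.
    imm, idio = _term("immune_tp", language), _term("idiopathic_tp", language)
    d693, d694 = Matcher.icd("D69.3"), Matcher.icd("D69.4")
    itp = [
        comp("itp", 1, adm, imm),
        comp("itp", 2, adm, d693),
        comp("itp", 3, adm, idio),
        comp("itp", 4, adm, d694),
        comp("itp", 5, dis, imm),
        comp("itp", 6, dis, d693),
        comp("itp", 7, dis, idio),
        comp("itp", 8, dis, d694),
        comp("itp", 9, outp, imm),
        comp("itp", 10, outp, d693, min_count=2),
        comp("itp", 11, outp, idio, min_count=2),
        comp("itp", 12, outp, d694),
    ]
    itp_final = [1, 2, 3, 5, 9, 10, 11, 12]
    lib["itp"] = (
        itp,
        CompositeAlgorithm("itp", tuple(c for c in itp if int(c.id.split("-")[1]) in itp_final)),
    )

    # RA: term plus the seropositive/other code families M05.3/.8/.9, M06.3/.8/.9
    # expressed as a start-anchored regex; all six components are final.
    ra_term = _term("ra", language)
    ra_icd = Matcher.icd(r"M0[56]\.[389]")
    ra = [
        comp("ra", 1, adm, ra_term),
        comp("ra", 2, adm, ra_icd),
        comp("ra", 3, dis, ra_term),
        comp("ra", 4, dis, ra_icd),
        comp("ra", 5, outp, ra_term),
        comp("ra", 6, outp, ra_icd),
    ]
    lib["ra"] = (ra, CompositeAlgorithm("ra", tuple(ra)))

    # T1D: type-1/autoimmune-diabetes terms and E10, with compound rules
    # requiring E10 (or the type-1 term) together with "diabetic ketosis" on
    # the same record; outpatient rows 9-11 require 2 or more record dates.
    t1 = _term("t1d", language)
    aid = _term("autoimmune_diabetes", language)
    e10 = Matcher.icd("E10")
    ketosis = _term("diabetic_ketosis", language)
    t1d = [
        comp("t1d", 1, adm, t1),
        comp("t1d", 2, adm, aid),
        comp("t1d", 3, adm, e10),
        comp("t1d", 4, adm, e10, conjunct=ketosis),
        comp("t1d", 5, dis, t1),
        comp("t1d", 6, dis, aid),
        comp("t1d", 7, dis, e10),
        comp("t1d", 8, dis, e10, conjunct=ketosis),
        comp("t1d", 9, outp, t1, min_count=2),
        comp("t1d", 10, outp, e10, min_count=2),
        comp("t1d", 11, outp, aid, min_count=2),
        comp("t1d", 12, outp, Matcher.any_of(t1, e10), conjunct=ketosis),
    ]
    t1d_final = [1, 2, 5, 10, 11, 12]
    lib["t1d"] = (
        t1d,
        CompositeAlgorithm("t1d", tuple(c for c in t1d if int(c.id.split("-")[1]) in t1d_final)),
    )
    return lib
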