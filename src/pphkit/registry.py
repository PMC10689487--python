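"""Registry of the 24 postpartum-hemorrhage concepts.

Each concept carries (1) an ordered list of zero-shot prompt templates in the
"Answer the following yes/no question. ... note: <note>" grammar, and (2) a
set of case-insensitive regular expressions used by the pattern baseline
backend. Twenty-three concepts are binary (present / absent); one —
estimated blood loss — is a measurement concept whose prompts ask the model
to extract a value and answer ``unanswerable`` when none is present.

Four complex concepts (placenta accreta spectrum, PPH due to surgical causes,
coagulation disorders, misoprostol used as a uterotonic) chain several
prompts; a concept is called present if any prompt fires on any chunk.

The registry is serializable to YAML so users can add concepts or edit
patterns without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PLACEHOLDER",
    "PromptTemplate",
    "ConceptSpec",
    "Registry",
    "builtin_registry",
    "render_prompt",
    "validate_registry",
    "CONCEPT_PHRASES",
    "VARIANT_PHRASES",
    "DISTRACTOR_PHRASES",
]

PLACEHOLDER = "<note>"

YES_NO_GRAMMAR = (
    "Answer the following yes/no question. Does the following discharge summary "
    "mention {what} during the current delivery? note: " + PLACEHOLDER
)


@dataclass(frozen=True)
class PromptTemplate:
    """One prompt with a single ``<note>`` placeholder for the chunk text."""

    template_text: str
    answer_mode: str = "yes_no"  # yes_no | extract

    def __post_init__(self) -> None:
        if self.answer_mode not in ("yes_no", "extract"):
            raise ValueError(f"answer_mode must be yes_no or extract, got {self.answer_mode!r}")


@dataclass(frozen=True)
class ConceptSpec:
    """Definition of one PPH-related concept."""

    concept_id: str
    display_name: str
    kind: str  # binary | measurement
    prompts: tuple[PromptTemplate, ...]
    patterns: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "measurement"):
            raise ValueError(f"kind must be binary or measurement, got {self.kind!r}")
        if isinstance(self.prompts, list):
            object.__setattr__(self, "prompts", tuple(self.prompts))
        if isinstance(self.patterns, list):
            object.__setattr__(self, "patterns", tuple(self.patterns))

    def compiled_patterns(self) -> list[re.Pattern]:
        return [re.compile(p, re.IGNORECASE) for p in self.patterns]


class Registry(dict):
    """Mapping concept_id -> ConceptSpec with convenience constructors."""

    @classmethod
    def from_specs(cls, specs) -> "Registry":
        reg = cls()
        for s in specs:
            if s.concept_id in reg:
                raise ValueError(f"duplicate concept_id {s.concept_id!r}")
            reg[s.concept_id] = s
        return reg

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "concept_id": s.concept_id,
                "display_name": s.display_name,
                "kind": s.kind,
                "prompts": [
                    {"template_text": p.template_text, "answer_mode": p.answer_mode}
                    for p in s.prompts
                ],
                "patterns": list(s.patterns),
                "description": s.description,
            }
            for s in self.values()
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Registry":
        data = yaml.safe_load(Path(path).read_text())
        specs = [
            ConceptSpec(
                concept_id=d["concept_id"],
                display_name=d["display_name"],
                kind=d["kind"],
                prompts=tuple(
                    PromptTemplate(p["template_text"], p.get("answer_mode", "yes_no"))
                    for p in d["prompts"]
                ),
                patterns=tuple(d.get("patterns", ())),
                description=d.get("description", ""),
            )
            for d in data
        ]
        return cls.from_specs(specs)


def render_prompt(template: PromptTemplate, chunk_text: str) -> str:
    """Substitute the chunk text into the template's single placeholder.

    Single-pass: a placeholder literal inside the chunk is inserted verbatim
    and never re-expanded.
    """
    if not chunk_text:
        raise ValueError("chunk_text must be non-empty")
    if template.template_text.count(PLACEHOLDER) != 1:
        raise ValueError(
            f"template must contain the placeholder {PLACEHOLDER!r} exactly once"
        )
    return template.template_text.replace(PLACEHOLDER, chunk_text, 1)


def validate_registry(registry: Registry) -> list[str]:
    """Check registry invariants; return a list of human-readable violations."""
    violations: list[str] = []
    n_measurement = 0
    for cid, spec in registry.items():
        if cid != spec.concept_id:
            violations.append(f"{cid}: key does not match concept_id {spec.concept_id!r}")
        if spec.kind == "measurement":
            n_measurement += 1
        if not spec.prompts:
            violations.append(f"{cid}: prompts must be non-empty")
        for i, p in enumerate(spec.prompts):
            if p.template_text.count(PLACEHOLDER) != 1:
                violations.append(f"{cid}: prompt {i} must contain {PLACEHOLDER!r} exactly once")
            expected = "extract" if spec.kind == "measurement" else "yes_no"
            if p.answer_mode != expected:
                violations.append(
                    f"{cid}: prompt {i} answer_mode {p.answer_mode!r} inconsistent with kind {spec.kind!r}"
                )
        for pat in spec.patterns:
            try:
                re.compile(pat, re.IGNORECASE)
            except re.error as exc:
                violations.append(f"{cid}: pattern {pat!r} does not compile ({exc})")
    if n_measurement != 1:
        violations.append(f"registry must have exactly one measurement concept, found {n_measurement}")
    return violations


# ---------------------------------------------------------------------------
# Built-in concepts
# ---------------------------------------------------------------------------

def _yn(what: str) -> PromptTemplate:
    return PromptTemplate(YES_NO_GRAMMAR.format(what=what), "yes_no")


def _binary(cid, name, prompts, patterns, desc=""):
    return ConceptSpec(cid, name, "binary", tuple(prompts), tuple(patterns), desc)


# The first four concepts below use the published example prompt texts
# verbatim; the rest are authored in the same grammar.
_PPH_MENTION_PROMPT = PromptTemplate(
    "Answer the following yes/no question. Does the following discharge summary "
    "mention postpartum hemorrhage (PPH) during the current delivery? note: " + PLACEHOLDER,
    "yes_no",
)
_METHYLERGONOVINE_PROMPT = PromptTemplate(
    "Answer the following yes/no question. Does the following discharge summary "
    "mention the drug methergine (methylergonovine)? note: " + PLACEHOLDER,
    "yes_no",
)
_EBL_PROMPT = PromptTemplate(
    "Extract the estimated blood loss (EBL) in the following discharge summary. "
    'If you can\'t find the answer, please respond "unanswerable". note: ' + PLACEHOLDER,
    "extract",
)

# Capture regexes for the measurement concept: group 1 is the value span
# (number plus any adjoining unit token). `cc\w*` tolerates concatenated
# shorthand like "500ccf/b".
_EBL_PATTERNS = (
    r"(?:estimated\s+blood\s+loss|blood\s+loss|\bebl\b)\s*(?:of|:|was|is|=|~|approximately)?\s*"
    r"((?:\d[\d,]*(?:\.\d+)?|\.\d+)\s*(?:milliliters?|liters?|m?ls?\b|cc\w*)?)",
)


def builtin_registry() -> Registry:
    """The packaged default: 24 PPH-related concepts."""
    specs = [
        _binary(
            "laceration", "Laceration",
            [_yn("a perineal, cervical, vaginal or sulcal laceration")],
            [r"lacerat\w*"],
            "Birth-canal laceration of any degree.",
        ),
        _binary(
            "bakri_balloon", "Bakri balloon",
            [_yn("placement of a Bakri balloon")],
            [r"bakri"],
            "Intrauterine balloon tamponade device.",
        ),
        _binary(
            "cesarean_delivery", "Cesarean delivery",
            [_yn("a cesarean delivery (c-section)")],
            [r"c[\s-]?section", r"cesarean", r"cesarian"],
            "Delivery by cesarean section; also drives the delivery-mode call.",
        ),
        ConceptSpec(
            "methylergonovine", "Methylergonovine",
            "binary", (_METHYLERGONOVINE_PROMPT,),
            (r"methergine", r"methylergonovine"),
            "Second-line uterotonic (ergot alkaloid).",
        ),
        _binary(
            "placenta_previa", "Placenta previa",
            [_yn("placenta previa")],
            [r"previa"],
            "Placenta overlying the cervical os.",
        ),
        _binary(
            "fresh_frozen_plasma", "Fresh frozen plasma",
            [_yn("transfusion of fresh frozen plasma (FFP)")],
            [r"fresh\s+frozen\s+plasma", r"\bffp\b"],
            "FFP transfusion.",
        ),
        _binary(
            "carboprost", "Carboprost",
            [_yn("administration of carboprost (Hemabate)")],
            [r"carboprost", r"hemabate"],
            "Second-line uterotonic (prostaglandin F2-alpha).",
        ),
        _binary(
            "misoprostol_uterotonic", "Misoprostol as a uterotonic",
            [
                _yn("administration of misoprostol as a uterotonic"),
                _yn("administration of misoprostol (Cytotec) to treat uterine bleeding or atony"),
            ],
            [
                r"misoprostol[\w\s,]{0,30}\bas\s+a\s+uterotonic",
                r"(?:rectal\s+)?misoprostol\s+(?:given\s+|administered\s+)?for\s+(?:hemorrhage|bleeding|atony|uterine\s+tone)",
                r"cytotec\s+(?:given\s+|administered\s+)?for\s+(?:postpartum\s+)?(?:bleeding|hemorrhage|atony)",
            ],
            "Misoprostol given to treat bleeding, distinguished from cervical-ripening use (chained prompts).",
        ),
        _binary(
            "hysterectomy", "Hysterectomy",
            [_yn("a peripartum hysterectomy")],
            [r"hysterectomy"],
            "Surgical removal of the uterus for refractory hemorrhage.",
        ),
        _binary(
            "oleary_sutures", "O'Leary sutures",
            [_yn("placement of O'Leary sutures (uterine artery ligation stitches)")],
            [r"o.?leary"],
            "Uterine artery ligation sutures.",
        ),
        _binary(
            "uterine_atony", "Uterine atony",
            [_yn("uterine atony")],
            [r"uterine\s+atony", r"aton(?:y|ic)\b", r"boggy\s+uterus"],
            "Failure of the uterus to contract after delivery.",
        ),
        _binary(
            "retained_products", "Retained products of conception",
            [_yn("retained products of conception")],
            [r"retained\s+(?:products|poc\b)", r"retained\s+placenta\w*"],
            "Placental tissue retained in the uterus.",
        ),
        ConceptSpec(
            "pph_mention", "Direct mention of PPH",
            "binary", (_PPH_MENTION_PROMPT,),
            (r"post\s?-?\s?partum\s+ha?emorrhage", r"\bpph\b"),
            "The note states postpartum hemorrhage explicitly.",
        ),
        _binary(
            "prbc", "Packed red blood cells",
            [_yn("transfusion of packed red blood cells")],
            [r"packed\s+red\s+blood\s+cells", r"\bprbcs?\b"],
            "Red-cell transfusion.",
        ),
        _binary(
            "abruption", "Abruption of the placenta",
            [_yn("abruption of the placenta")],
            [r"abruption"],
            "Premature placental separation.",
        ),
        _binary(
            "coagulation_disorders", "Coagulation disorders",
            [
                _yn("a coagulation disorder with increased risk of bleeding"),
                _yn("disseminated intravascular coagulation (DIC)"),
            ],
            [r"disseminated\s+intravascular", r"\bdic\b", r"coagulopath\w*"],
            "Coagulopathy / DIC (chained prompts).",
        ),
        _binary(
            "cryoprecipitate", "Cryoprecipitate",
            [_yn("transfusion of cryoprecipitate")],
            [r"cryoprecipitate", r"\bcryo\b"],
            "Cryoprecipitate transfusion (fibrinogen replacement).",
        ),
        _binary(
            "dilation_curettage", "Dilation and curettage",
            [_yn("a dilation and curettage (D&C) procedure")],
            [r"dilat(?:at)?ion\s+and\s+curettage", r"\bd\s?&\s?c\b", r"curettage"],
            "Uterine curettage for retained tissue.",
        ),
        _binary(
            "platelets", "Platelets",
            [_yn("transfusion of platelets")],
            [r"platelets?"],
            "Platelet transfusion.",
        ),
        _binary(
            "accreta_spectrum", "Placenta accreta spectrum",
            [
                _yn("placenta percreta"),
                _yn("placenta increta"),
                _yn("placenta accreta"),
            ],
            [r"accreta", r"increta", r"percreta"],
            "Abnormally invasive placenta; three chained prompts, one per depth of invasion.",
        ),
        _binary(
            "manual_extraction_placenta", "Manual extraction of placenta",
            [_yn("manual extraction or manual removal of the placenta")],
            [r"manual\s+(?:extraction|removal)\s+of\s+(?:the\s+)?placenta", r"manually\s+(?:extracted|removed)\s+placenta"],
            "Manual delivery of the placenta.",
        ),
        _binary(
            "pph_surgical", "PPH due to surgical causes",
            [
                _yn("hemorrhage due to a surgical cause such as uterine artery injury"),
                _yn("bleeding from an extension of the hysterotomy incision"),
            ],
            [
                r"uterine\s+artery\s+injur\w*",
                r"surgical\s+source\s+of\s+(?:the\s+)?bleeding",
                r"extension\s+of\s+(?:the\s+)?hysterotomy",
                r"h(?:a?emorrhage|emorrhage)\s+due\s+to\s+surgical",
            ],
            "Hemorrhage attributed to surgical injury (chained prompts).",
        ),
        _binary(
            "uterine_rupture", "Uterine rupture",
            [_yn("uterine rupture")],
            [r"uterine\s+rupture", r"ruptured\s+uterus"],
            "Full-thickness uterine wall rupture; distinct from rupture of membranes.",
        ),
        ConceptSpec(
            "estimated_blood_loss", "Estimated blood loss",
            "measurement", (_EBL_PROMPT,), _EBL_PATTERNS,
            "Clinician-documented blood loss; the single measurement concept.",
        ),
    ]
    return Registry.from_specs(specs)


# ---------------------------------------------------------------------------
# Phrase banks (shared with the synthetic-note generator)
# ---------------------------------------------------------------------------

#: Clean surface phrases per concept. Every phrase matches at least one of the
#: concept's own patterns and none of any other concept's patterns — the basis
#: of the clean-corpus guarantee that the pattern backend recovers every
#: planted concept.
CONCEPT_PHRASES: dict[str, tuple[str, ...]] = {
    "laceration": (
        "second degree perineal laceration repaired",
        "cervical laceration identified and repaired",
        "sulcal laceration with minimal bleeding",
    ),
    "bakri_balloon": (
        "Bakri balloon placed for tamponade",
        "intrauterine Bakri balloon inserted",
    ),
    "cesarean_delivery": (
        "primary low transverse cesarean section",
        "repeat cesarean delivery",
        "urgent c-section for non-reassuring fetal status",
    ),
    "methylergonovine": (
        "methergine administered intramuscularly",
        "methylergonovine given with good effect",
    ),
    "placenta_previa": (
        "complete placenta previa",
        "marginal previa noted on ultrasound",
    ),
    "fresh_frozen_plasma": (
        "transfused two units of fresh frozen plasma",
        "FFP transfusion initiated",
    ),
    "carboprost": (
        "carboprost administered intramuscularly",
        "hemabate given with improvement in tone",
    ),
    "misoprostol_uterotonic": (
        "misoprostol administered as a uterotonic",
        "rectal misoprostol given for hemorrhage",
        "cytotec administered for postpartum bleeding",
    ),
    "hysterectomy": (
        "supracervical hysterectomy performed",
        "peripartum hysterectomy for refractory bleeding",
    ),
    "oleary_sutures": (
        "bilateral O'Leary sutures placed",
        "O'Leary stitches at the uterine arteries",
    ),
    "uterine_atony": (
        "uterine atony noted after delivery of the placenta",
        "uterus boggy consistent with atony",
    ),
    "retained_products": (
        "retained products of conception on imaging",
        "retained POC suspected",
    ),
    "pph_mention": (
        "postpartum hemorrhage requiring intervention",
        "course complicated by PPH",
    ),
    "prbc": (
        "transfused two units of packed red blood cells",
        "pRBC transfusion given for symptomatic anemia",
    ),
    "abruption": (
        "placental abruption diagnosed on presentation",
        "abruption of the placenta with vaginal bleeding",
    ),
    "coagulation_disorders": (
        "disseminated intravascular coagulation",
        "coagulopathy requiring factor replacement",
    ),
    "cryoprecipitate": (
        "cryoprecipitate transfused for low fibrinogen",
        "ten units of cryoprecipitate given",
    ),
    "dilation_curettage": (
        "dilation and curettage performed",
        "ultrasound-guided dilatation and curettage",
    ),
    "platelets": (
        "one unit of platelets transfused",
        "platelet transfusion for thrombocytopenia",
    ),
    "accreta_spectrum": (
        "placenta accreta confirmed at surgery",
        "placenta increta on pathology",
        "concern for placenta percreta",
    ),
    "manual_extraction_placenta": (
        "manual extraction of the placenta required",
        "manual removal of placenta performed under anesthesia",
    ),
    "pph_surgical": (
        "bleeding from a uterine artery injury",
        "surgical source of bleeding identified at exploration",
        "extension of the hysterotomy with brisk bleeding",
    ),
    "uterine_rupture": (
        "uterine rupture identified at laparotomy",
        "ruptured uterus requiring repair",
    ),
}

#: Held-out variant phrases: plausible surface forms deliberately NOT covered
#: by the shipped pattern sets, for measuring generalization of any backend
#: beyond the pattern baseline.
VARIANT_PHRASES: dict[str, tuple[str, ...]] = {
    "uterine_atony": ("poor uterine tone despite massage",),
    "retained_products": ("placental fragments left in situ",),
    "pph_mention": ("excessive bleeding after delivery",),
    "manual_extraction_placenta": ("placenta delivered manually",),
}

#: Polysemy traps: sentences that superficially resemble a concept but must
#: not be labeled positive (e.g. rupture of membranes is part of normal labor;
#: misoprostol for cervical ripening is not a uterotonic use).
DISTRACTOR_PHRASES: tuple[str, ...] = (
    "artificial rupture of membranes performed for augmentation of labor",
    "spontaneous rupture of membranes at five centimeters dilation",
    "misoprostol administered for cervical ripening",
)


#: Delivery-mode phrases for vaginal deliveries (cesarean deliveries reuse the
#: cesarean_delivery phrase bank).
VAGINAL_PHRASES: tuple[str, ...] = (
    "normal spontaneous vaginal delivery of a liveborn infant",
    "spontaneous vaginal delivery at term",
    "operative vaginal delivery with vacuum assistance",
)
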