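"""Synthetic PET-CT lung-cancer report generator.

Real PET-CT reports are confidential, so the pipeline is exercised on
synthetic reports that reproduce the *statistical* structure of the two
study populations rather than clinically realistic language:

* an **internal** profile — findings ordered by clinical priority
  (significant findings first), shorter reports, a minority of
  AIF-positive documents;
* an **external** profile — findings ordered anatomically (head to
  legs), longer reports, a majority of positives with more AIF
  sentences per report.

Each generated report carries a gold annotation that is grounded by
construction: every AIF sentence occurs verbatim in the report text.
Actionability follows the qualifier convention used in lung-cancer
PET-CT annotation: an intensifying qualifier ("severe") makes a finding
actionable, diminishing or neutral qualifiers ("mild", "moderate") do
not.  A configurable fraction of findings is restated in the
Interpretation section (multi-reference behaviour) and a configurable
fraction of findings sections uses numbered lists, so the evaluation
normalization and the multiple-reference error path are both exercised
in any moderately sized corpus.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .core import (
    AifexError,
    Dataset,
    GoldAnnotation,
    Report,
    TokenizerHook,
    whitespace_tokens,
)


class ConfigurationError(AifexError):
    """Infeasible or invalid generator configuration."""


# Anatomical ordering ranks, head to legs.
REGIONS = {"head": 0, "neck": 1, "chest": 2, "abdomen": 3, "pelvis": 4, "skeleton": 5}

STYLES = ("priority", "anatomical")


@dataclass(frozen=True)
class DatasetProfile:
    """Target statistics a synthetic corpus must match.

    ``pos_neg_ratio`` is AIF-positive count / AIF-negative count;
    ``mean_tokens`` is the per-report whitespace-token target (a subword
    tokenizer can be substituted when profiling); ``mean_aif_sentences``
    counts gold sentences per report averaged over the whole corpus.
    """

    name: str
    n_reports: int
    pos_neg_ratio: float
    mean_tokens: float
    mean_aif_sentences: float
    style: str
    seed: int = 0
    multi_ref_prob: float = 0.3
    numbered_list_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        if self.style not in STYLES:
            raise ConfigurationError(f"style must be one of {STYLES}, got {self.style!r}")
        if not (self.pos_neg_ratio >= 0 and math.isfinite(self.pos_neg_ratio)):
            raise ConfigurationError("pos_neg_ratio must be finite and >= 0")
        if not (self.mean_tokens >= 60 and math.isfinite(self.mean_tokens)):
            raise ConfigurationError("mean_tokens must be finite and >= 60")
        if self.mean_aif_sentences < 0:
            raise ConfigurationError("mean_aif_sentences must be >= 0")

    @property
    def positive_fraction(self) -> float:
        return self.pos_neg_ratio / (1.0 + self.pos_neg_ratio)


def internal_profile(n_reports: int = 500, seed: int = 0) -> DatasetProfile:
    """Internal (priority-ordered) study profile."""
    return DatasetProfile("internal", n_reports, 0.64, 392.0, 0.781, "priority", seed)


def external_profile(n_reports: int = 500, seed: int = 0) -> DatasetProfile:
    """External (anatomically ordered) study profile: longer, more positives."""
    return DatasetProfile("external", n_reports, 1.64, 570.3, 1.697, "anatomical", seed)


BUILTIN_PROFILES = {"internal": internal_profile, "external": external_profile}


@dataclass(frozen=True)
class SentenceTemplate:
    text: str  # str.format template
    region: str = "chest"


_SIDES = ("left", "right")
_LOBES = ("upper", "lower")
_SPINE = ("lumbar", "thoracic", "cervical")
_COLON = ("sigmoid", "ascending", "transverse")


@dataclass
class SentenceBank:
    """Parameterised sentence fixtures for report assembly.

    ``aif_templates`` and ``non_aif_templates`` are disjoint as strings;
    the former only carry findings the annotation guideline would deem
    actionable in a lung-cancer context, the latter only non-actionable
    distractors (including the enlarged-prostate example).  These are test
    fixtures, not clinical guidance.
    """

    aif_templates: list[SentenceTemplate] = field(default_factory=lambda: [
        SentenceTemplate("Severe emphysema is noted in the {lobe} lobes.", "chest"),
        SentenceTemplate(
            "There is a {size} cm infrarenal abdominal aortic aneurysm.", "abdomen"
        ),
        SentenceTemplate(
            "An incidental {size} cm {side} adrenal nodule is seen, requiring endocrine"
            " follow-up.",
            "abdomen",
        ),
        SentenceTemplate(
            "A {size} cm enhancing nodule on the {side} kidney is suspicious for renal"
            " cell carcinoma.",
            "abdomen",
        ),
        SentenceTemplate(
            "A {size} cm FDG-avid {side} thyroid nodule is noted, warranting ultrasound"
            " assessment.",
            "neck",
        ),
        SentenceTemplate(
            "Focal intense FDG uptake in the {colon} colon is suspicious for a"
            " synchronous primary malignancy.",
            "abdomen",
        ),
    ])
    non_aif_templates: list[SentenceTemplate] = field(default_factory=lambda: [
        SentenceTemplate("Mild emphysema is noted in both lungs.", "chest"),
        SentenceTemplate("Moderate emphysema is present in the {lobe} lobes.", "chest"),
        SentenceTemplate("A simple cyst is present on the {side} kidney.", "abdomen"),
        SentenceTemplate("Degenerative change is noted in the {spine} spine.", "skeleton"),
        SentenceTemplate("The prostate is enlarged.", "pelvis"),
        SentenceTemplate("A small hiatus hernia is noted.", "abdomen"),
        SentenceTemplate(
            "Mild atherosclerotic calcification of the thoracic aorta is seen.", "chest"
        ),
    ])
    primary_templates: list[SentenceTemplate] = field(default_factory=lambda: [
        SentenceTemplate(
            "There is an intensely FDG-avid {size} cm mass in the {side} {lobe} lobe,"
            " consistent with the known primary lung carcinoma.",
            "chest",
        ),
        SentenceTemplate(
            "The known {side} {lobe} lobe primary demonstrates intense FDG uptake with"
            " an SUVmax of {suv}.",
            "chest",
        ),
    ])
    filler_templates: list[SentenceTemplate] = field(default_factory=lambda: [
        SentenceTemplate("No abnormal FDG uptake is seen in the brain.", "head"),
        SentenceTemplate("The visualised paranasal sinuses are clear.", "head"),
        SentenceTemplate("No FDG-avid cervical lymphadenopathy is identified.", "neck"),
        SentenceTemplate(
            "Physiological tracer uptake is seen in the salivary glands.", "neck"
        ),
        SentenceTemplate(
            "No FDG-avid mediastinal or hilar lymphadenopathy is identified.", "chest"
        ),
        SentenceTemplate("The pleural spaces are clear with no effusion.", "chest"),
        SentenceTemplate("The heart shows physiological tracer distribution.", "chest"),
        SentenceTemplate(
            "The liver demonstrates uniform physiological tracer distribution.", "abdomen"
        ),
        SentenceTemplate("The spleen and pancreas appear unremarkable.", "abdomen"),
        SentenceTemplate("No abnormal uptake is seen within the bowel.", "abdomen"),
        SentenceTemplate(
            "Physiological excreted activity is noted in the bladder.", "pelvis"
        ),
        SentenceTemplate(
            "No FDG-avid pelvic or inguinal lymphadenopathy is seen.", "pelvis"
        ),
        SentenceTemplate(
            "No suspicious FDG-avid bone lesions are identified.", "skeleton"
        ),
        SentenceTemplate(
            "Visualised bone marrow demonstrates physiological uptake.", "skeleton"
        ),
    ])
    boilerplate: dict[str, list[str]] = field(default_factory=lambda: {
        "clinical": [
            "Clinical details: Staging of known {side} lung carcinoma.",
            "Clinical details: Response assessment of {side} lung carcinoma following"
            " chemotherapy.",
        ],
        "technique": [
            "Technique: Whole-body FDG PET-CT from skull base to mid-thigh following"
            " administration of {dose} MBq of FDG, with low-dose CT for attenuation"
            " correction.",
        ],
        "comparison": [
            "Comparison: Prior FDG PET-CT dated {month} 20{year}.",
        ],
        "interpretation": [
            "Appearances are in keeping with the known lung primary.",
            "No further significant incidental abnormality is identified.",
        ],
    })

    def validate(self) -> None:
        if not (
            self.aif_templates
            and self.non_aif_templates
            and self.primary_templates
            and self.filler_templates
        ):
            raise ConfigurationError("sentence bank has an empty category")
        aif = {t.text for t in self.aif_templates}
        non = {t.text for t in self.non_aif_templates}
        if aif & non:
            raise ConfigurationError("aif and non-aif template sets must be disjoint")


def _fill(template: SentenceTemplate, rng: random.Random) -> tuple[str, str]:
    """Instantiate a template's parameter slots; returns (sentence, region)."""
    text = template.text.format(
        side=rng.choice(_SIDES),
        lobe=rng.choice(_LOBES),
        spine=rng.choice(_SPINE),
        colon=rng.choice(_COLON),
        size=f"{rng.uniform(1.2, 5.5):.1f}",
        suv=f"{rng.uniform(4.0, 14.0):.1f}",
        dose=rng.randrange(250, 400, 10),
        month=rng.choice(("January", "March", "June", "September", "November")),
        year=rng.randrange(18, 25),
    )
    return text, template.region


def _poisson(lam: float, rng: random.Random) -> int:
    """Knuth inversion; lam is small here (< 2)."""
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _restate(sentence: str) -> str:
    """Interpretation-section restatement carrying the finding verbatim."""
    return sentence.rstrip(".") + ", as above."


def _findings_per_positive(profile: DatasetProfile) -> float:
    """Mean distinct AIF findings per positive report implied by the profile."""
    p_pos = profile.positive_fraction
    if p_pos <= 0:
        return 0.0
    mean_gold_per_pos = profile.mean_aif_sentences / p_pos
    return max(1.0, mean_gold_per_pos / (1.0 + profile.multi_ref_prob))


def generate_report(
    profile: DatasetProfile,
    bank: SentenceBank,
    is_positive: bool,
    rng: random.Random,
    report_id: str = "r0",
) -> tuple[Report, GoldAnnotation]:
    """Generate one labelled report.

    Positive reports plant 1+ AIF sentences drawn from the actionable bank
    and list *every* sentence referencing each planted finding in the gold
    annotation, including any Interpretation-section restatement.  Priority
    style places significant findings (primary, then AIFs) first;
    anatomical style sorts the findings section head-to-legs.  Report
    length is padded with negative filler sentences toward the profile's
    token target.
    """
    bank.validate()
    # findings: (sentence, region, insertion priority) — lower priority first
    findings: list[tuple[str, str, int]] = []
    used: set[str] = set()

    def add(template: SentenceTemplate, priority: int) -> str:
        for _ in range(8):  # re-draw parameters on string collision
            text, region = _fill(template, rng)
            if text not in used:
                used.add(text)
                findings.append((text, region, priority))
                return text
        findings.append((text, region, priority))
        return text

    add(rng.choice(bank.primary_templates), 0)

    gold: list[str] = []
    restatements: list[str] = []
    if is_positive:
        lam = _findings_per_positive(profile) - 1.0
        n_findings = 1 + min(_poisson(lam, rng), 4)
        for _ in range(n_findings):
            sent = add(rng.choice(bank.aif_templates), 1)
            gold.append(sent)
            if rng.random() < profile.multi_ref_prob:
                restatements.append(_restate(sent))

    n_distractors = rng.randrange(1, 3)
    for _ in range(n_distractors):
        add(rng.choice(bank.non_aif_templates), 2)

    clinical = bank.boilerplate["clinical"]
    technique = bank.boilerplate["technique"]
    comparison = bank.boilerplate["comparison"]
    interp_extra = bank.boilerplate["interpretation"]

    header_lines = [
        _fill(SentenceTemplate(rng.choice(clinical)), rng)[0],
        _fill(SentenceTemplate(rng.choice(technique)), rng)[0],
        _fill(SentenceTemplate(rng.choice(comparison)), rng)[0],
    ]
    interp_lines = [interp_extra[0]]
    interp_lines.extend(restatements)
    if not is_positive:
        interp_lines.append(interp_extra[1])

    numbered = rng.random() < profile.numbered_list_prob

    # Pad with filler toward the per-report token target (exact count of
    # everything assembled so far; a numbered list adds one token per line).
    target = max(80.0, rng.gauss(profile.mean_tokens, 0.08 * profile.mean_tokens))
    overhead = sum(len(s.split()) for s in header_lines + interp_lines) + 2

    def current_tokens() -> int:
        per_line = 1 if numbered else 0
        return overhead + sum(len(s.split()) + per_line for s, _, _ in findings)

    while current_tokens() < target:
        add(rng.choice(bank.filler_templates), 3)

    if profile.style == "anatomical":
        order = sorted(range(len(findings)), key=lambda i: (REGIONS[findings[i][1]], i))
    else:  # priority: significant findings first, insertion order within tier
        order = sorted(range(len(findings)), key=lambda i: (findings[i][2], i))
    ordered = [findings[i][0] for i in order]

    if numbered:
        findings_lines = [f"{k}. {s}" for k, s in enumerate(ordered, start=1)]
    else:
        findings_lines = list(ordered)

    lines = (
        header_lines
        + ["Findings:"]
        + findings_lines
        + ["Interpretation:"]
        + interp_lines
    )
    text = "\n".join(lines)

    nh = len(header_lines)
    nf = len(findings_lines)
    sections = {
        "Clinical details": (0, 1),
        "Technique": (1, 2),
        "Comparison": (2, nh),
        "Findings": (nh, nh + 1 + nf),
        "Interpretation": (nh + 1 + nf, len(lines)),
    }
    report = Report(report_id=report_id, text=text, sections=sections)
    annotation = GoldAnnotation(report_id=report_id, aif_sentences=tuple(gold + restatements))
    return report, annotation


def generate_dataset(profile: DatasetProfile, bank: SentenceBank | None = None) -> Dataset:
    """Generate a full labelled dataset matching a profile.

    The positive count is fixed at ``round(n * ratio / (1 + ratio))`` so the
    realised class ratio tracks the target tightly; length and AIF-density
    targets are met in expectation by per-report sampling.  Infeasible
    targets (a positive AIF-sentence mean with no positive reports) raise
    :class:`ConfigurationError`.
    """
    bank = bank or SentenceBank()
    bank.validate()
    n = profile.n_reports
    n_pos = round(n * profile.positive_fraction)
    if profile.mean_aif_sentences > 0 and n_pos == 0:
        raise ConfigurationError(
            "mean_aif_sentences > 0 requires a positive pos_neg_ratio and n large"
            " enough to allocate at least one positive report"
        )
    rng = random.Random(profile.seed)
    flags = [True] * n_pos + [False] * (n - n_pos)
    rng.shuffle(flags)
    reports: list[Report] = []
    annotations: dict[str, GoldAnnotation] = {}
    width = max(4, len(str(n - 1)))
    for i, is_pos in enumerate(flags):
        rid = f"{profile.name}-{i:0{width}d}"
        rep, ann = generate_report(profile, bank, is_pos, rng, report_id=rid)
        reports.append(rep)
        annotations[rid] = ann
    ds = Dataset(name=profile.name, reports=reports, annotations=annotations)
    ds.validate_grounding()
    return ds


@dataclass
class DatasetStats:
    """Realised statistics of a labelled dataset."""

    n: int
    positives: int
    negatives: int
    pos_neg_ratio: float  # inf when negatives == 0
    ratio_undefined: bool
    mean_tokens: float
    mean_aif_sentences: float


def profile_dataset(dataset: Dataset, tokenizer: TokenizerHook = whitespace_tokens) -> DatasetStats:
    """Measure a dataset against the profile quantities.

    Token counts go through the tokenizer hook (whitespace by default).
    Every report must be annotated; the class ratio is flagged undefined
    (reported as ``inf``) when there are no negatives.
    """
    if not dataset.reports:
        raise AifexError("cannot profile an empty dataset")
    positives = 0
    total_tokens = 0
    total_aif = 0
    for rep in dataset.reports:
        ann = dataset.annotations.get(rep.report_id)
        if ann is None:
            raise AifexError(f"report {rep.report_id!r} has no annotation")
        positives += int(ann.doc_label)
        total_tokens += len(tokenizer(rep.text))
        total_aif += len(ann.aif_sentences)
    n = len(dataset.reports)
    negatives = n - positives
    undefined = negatives == 0
    ratio = math.inf if undefined else positives / negatives
    return DatasetStats(
        n=n,
        positives=positives,
        negatives=negatives,
        pos_neg_ratio=ratio,
        ratio_undefined=undefined,
        mean_tokens=total_tokens / n,
        mean_aif_sentences=total_aif / n,
    )
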