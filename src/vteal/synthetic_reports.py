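"""Synthetic VTE imaging-report generator.

Builds a corpus whose class counts, modality mix and ICD-10 concordance
match a configurable composition (defaults: the 5,839-report study profile
with 1,088 VTE-positive reports).  Class counts are apportioned
deterministically by largest remainder, so composition summaries are exact;
ICD-10 flags are sampled per-report Bernoulli so concordance audits are
exercised under sampling noise.

Reports are rendered from a per-class template bank with lexical slots
(anatomy, laterality, hedging, negation) plus modality headers and optional
clinically irrelevant distractor sentences.  With ``distractor_rate`` and
``synonym_rate`` at 0 the corpus is separable by construction: every class
carries a distinct set of diagnostic anatomy terms.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .data_model import (
    LABELS_7,
    MODALITIES,
    NEGATIVE_LABEL,
    Corpus,
    Report,
)

__all__ = [
    "DEFAULT_CLASS_COUNTS",
    "DEFAULT_MODALITY_WEIGHTS",
    "GeneratorConfig",
    "TemplateBank",
    "allocate_counts",
    "render_report",
    "generate_corpus",
    "separable_config",
]

#: Study-profile class counts (sum 5,839; 1,088 VTE-positive).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "No DVT or PE": 4751,
    "PE only": 75,
    "Proximal DVT": 570,
    "Distal DVT": 286,
    "Thrombophlebitis": 58,
    "Other DVT": 11,
    "DVT and PE": 88,
}

#: Study-profile modality counts, used as sampling weights.
DEFAULT_MODALITY_WEIGHTS: dict[str, float] = {
    "chest CT": 2425,
    "pulmonary artery CT angiography": 69,
    "lower extremity vein CT": 568,
    "DVT CT": 886,
    "lower extremity vein duplex ultrasonography": 1891,
}

_COMPOUND_LABEL = "DVT and PE"
_SLOT_RE = re.compile(r"\{(\w+)\}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for :func:`generate_corpus`; all rates in [0, 1]."""

    n_reports: int = 5839
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    modality_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_WEIGHTS)
    )
    icd10_concordance: float = 0.650
    distractor_rate: float = 0.30
    synonym_rate: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        for name in ("icd10_concordance", "distractor_rate", "synonym_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        unknown = set(self.class_counts) - set(LABELS_7)
        if unknown:
            raise ValueError(f"unknown class names in class_counts: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class_counts must be non-negative")
        unknown_m = set(self.modality_weights) - set(MODALITIES)
        if unknown_m:
            raise ValueError(f"unknown modalities: {sorted(unknown_m)}")


class TemplateBank:
    """Per-class sentence templates with lexical slots, plus modality headers
    and distractor sentences.  Loaded from a YAML resource; editable."""

    def __init__(self, data: Mapping) -> None:
        self.lexicons: dict[str, list[str]] = {
            k: list(v) for k, v in data["lexicons"].items()
        }
        self.modality_headers: dict[str, list[str]] = {
            k: list(v) for k, v in data["modality_headers"].items()
        }
        self.classes: dict[str, list[str]] = {
            k: list(v) for k, v in data["classes"].items()
        }
        self.distractors: list[str] = list(data["distractors"])
        for label, templates in self.classes.items():
            if len(templates) < 3:
                raise ValueError(f"class {label!r} needs >= 3 templates")

    @classmethod
    def default(cls) -> "TemplateBank":
        ref = importlib.resources.files("vteal").joinpath("data/templates.yaml")
        return cls(yaml.safe_load(ref.read_text(encoding="utf-8")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TemplateBank":
        return cls(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def covers(self, label: str) -> bool:
        return label in self.classes or label == _COMPOUND_LABEL


def allocate_counts(config: GeneratorConfig) -> dict[str, int]:
    """Apportion ``n_reports`` across classes by largest remainder.

    Deterministic; sums exactly to ``n_reports``.  Ties in remainder are
    broken by canonical class order.
    """
    weights = np.array(
        [float(config.class_counts.get(lbl, 0)) for lbl in LABELS_7]
    )
    total = weights.sum()
    if total <= 0:
        raise ValueError("class_counts must not be all zero")
    n_positive_weight = int((weights > 0).sum())
    if config.n_reports < n_positive_weight:
        raise ValueError(
            f"n_reports={config.n_reports} is smaller than the "
            f"{n_positive_weight} classes with positive weight"
        )
    quota = config.n_reports * weights / total
    floors = np.floor(quota).astype(int)
    remainder = quota - floors
    short = config.n_reports - int(floors.sum())
    # stable sort: ties broken by class order
    order = np.argsort(-remainder, kind="stable")
    for idx in order[:short]:
        floors[idx] += 1
    return {lbl: int(floors[i]) for i, lbl in enumerate(LABELS_7)}


def _fill_slots(template: str, bank: TemplateBank, rng: np.random.Generator,
                synonym_rate: float) -> str:
    def sub(match: re.Match) -> str:
        lex = bank.lexicons[match.group(1)]
        if len(lex) > 1 and rng.random() < synonym_rate:
            return str(rng.choice(lex[1:]))
        return lex[0]

    return _SLOT_RE.sub(sub, template)


def render_report(
    label: str,
    modality: str,
    bank: TemplateBank,
    rng: np.random.Generator,
    *,
    distractor_rate: float = 0.0,
    synonym_rate: float = 0.0,
) -> str:
    """Render one free-text report body for a class/modality pair.

    Positive classes always contain a class-diagnostic phrase (anatomy terms
    from the class lexicon); the negative class always contains an explicit
    negation.  The compound "DVT and PE" class concatenates one PE finding
    and one DVT finding.
    """
    if not bank.covers(label):
        raise ValueError(f"template bank does not cover label {label!r}")
    headers = bank.modality_headers[modality]
    header = str(rng.choice(headers))
    if label == _COMPOUND_LABEL:
        # first two templates of each constituent bank carry no incidental
        # negation, so the compound text never contradicts itself
        pe_t = str(rng.choice(bank.classes["PE only"][:2]))
        dvt_label = str(rng.choice(["Proximal DVT", "Distal DVT"]))
        dvt_t = str(rng.choice(bank.classes[dvt_label][:2]))
        body = (
            _fill_slots(pe_t, bank, rng, synonym_rate)
            + " In addition, "
            + _fill_slots(dvt_t, bank, rng, synonym_rate).lower()
        )
    else:
        template = str(rng.choice(bank.classes[label]))
        body = _fill_slots(template, bank, rng, synonym_rate)
    sentences = [header, body]
    if distractor_rate > 0 and rng.random() < distractor_rate:
        sentences.append(str(rng.choice(bank.distractors)))
    return " ".join(sentences)


def generate_corpus(
    config: GeneratorConfig, bank: Optional[TemplateBank] = None
) -> Corpus:
    """Generate a synthetic corpus; fully reproducible from ``config.seed``."""
    bank = bank or TemplateBank.default()
    counts = allocate_counts(config)
    rng = np.random.default_rng(config.seed)

    labels: list[str] = []
    for lbl in LABELS_7:
        labels.extend([lbl] * counts[lbl])
    labels_arr = np.array(labels, dtype=object)
    rng.shuffle(labels_arr)

    mod_names = [m for m in MODALITIES if config.modality_weights.get(m, 0) > 0]
    mod_w = np.array([float(config.modality_weights[m]) for m in mod_names])
    mod_p = mod_w / mod_w.sum()

    n = config.n_reports
    width = max(6, len(str(n)))
    reports: list[Report] = []
    for i, label in enumerate(labels_arr):
        modality = str(rng.choice(mod_names, p=mod_p))
        text = render_report(
            label,
            modality,
            bank,
            rng,
            distractor_rate=config.distractor_rate,
            synonym_rate=config.synonym_rate,
        )
        positive = label != NEGATIVE_LABEL
        coded = positive and (rng.random() < config.icd10_concordance)
        age = int(np.clip(round(rng.normal(61.9, 15.1)), 18, 100))
        sex = "male" if rng.random() < 0.506 else "female"
        reports.append(
            Report(
                id=f"R{i + 1:0{width}d}",
                text=text,
                modality=modality,
                label=str(label),
                icd10_coded=coded,
                age=age,
                sex=sex,
            )
        )
    return Corpus(reports)


def separable_config(
    n_reports: int, seed: int = 0, balanced: bool = True
) -> GeneratorConfig:
    """Config for a noise-free corpus (no distractors, no synonym swaps).

    ``balanced=True`` gives (near-)equal class counts so minority classes
    carry enough examples for scaled-down learning experiments.
    """
    counts = (
        {lbl: 1 for lbl in LABELS_7} if balanced else dict(DEFAULT_CLASS_COUNTS)
    )
    return GeneratorConfig(
        n_reports=n_reports,
        class_counts=counts,
        distractor_rate=0.0,
        synonym_rate=0.0,
        seed=seed,
    )
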