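"""Core record types, corpus containers, file I/O and train/test splitting.

A :class:`Report` is one imaging-test record (free text plus metadata); a
:class:`Corpus` is an ordered collection of reports under a named label
scheme.  Corpora round-trip losslessly through UTF-8 CSV and JSON-lines.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from sklearn.model_selection import train_test_split

__all__ = [
    "LABELS_7",
    "LABELS_6",
    "NEGATIVE_LABEL",
    "MODALITIES",
    "Report",
    "Corpus",
    "SplitSpec",
    "CorpusValidationError",
    "CorpusSchemaError",
    "load_corpus",
    "write_corpus",
    "split_corpus",
    "restrict_labels",
]

NEGATIVE_LABEL = "No DVT or PE"

LABELS_7: tuple[str, ...] = (
    NEGATIVE_LABEL,
    "PE only",
    "Proximal DVT",
    "Distal DVT",
    "Thrombophlebitis",
    "Other DVT",
    "DVT and PE",
)

LABELS_6: tuple[str, ...] = LABELS_7[1:]

MODALITIES: tuple[str, ...] = (
    "chest CT",
    "pulmonary artery CT angiography",
    "lower extremity vein CT",
    "DVT CT",
    "lower extremity vein duplex ultrasonography",
)

_CSV_COLUMNS = ("id", "text", "modality", "label", "icd10_coded", "age", "sex")


class CorpusSchemaError(ValueError):
    """A required column/key is missing from an input file."""


class CorpusValidationError(ValueError):
    """A record carries an unparseable field (bad label, modality, ...)."""


def _norm(token: str) -> str:
    return " ".join(token.split()).lower()


_LABEL_LOOKUP = {_norm(lbl): lbl for lbl in LABELS_7}
_MODALITY_LOOKUP = {_norm(m): m for m in MODALITIES}


def canonical_label(token: str) -> str:
    """Map a label token to its canonical form (case/whitespace insensitive)."""
    try:
        return _LABEL_LOOKUP[_norm(token)]
    except KeyError:
        raise CorpusValidationError(f"unknown label token: {token!r}") from None


def canonical_modality(token: str) -> str:
    try:
        return _MODALITY_LOOKUP[_norm(token)]
    except KeyError:
        raise CorpusValidationError(f"unknown modality token: {token!r}") from None


@dataclass(frozen=True)
class Report:
    """One imaging-test record."""

    id: str
    text: str
    modality: str
    label: str
    icd10_coded: bool = False
    age: Optional[int] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusValidationError(f"report {self.id!r}: empty text")
        object.__setattr__(self, "label", canonical_label(self.label))
        object.__setattr__(self, "modality", canonical_modality(self.modality))
        if self.sex is not None and self.sex not in ("male", "female"):
            raise CorpusValidationError(
                f"report {self.id!r}: sex must be male/female, got {self.sex!r}"
            )


@dataclass
class Corpus:
    """Ordered collection of reports under a 7-class or 6-class label scheme."""

    reports: list[Report]
    label_scheme: str = "7-class"

    def __post_init__(self) -> None:
        if self.label_scheme not in ("7-class", "6-class"):
            raise ValueError(f"unknown label scheme: {self.label_scheme!r}")
        ids = [r.id for r in self.reports]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(f"duplicate report ids: {dupes[:5]}")
        if self.label_scheme == "6-class":
            bad = [r.id for r in self.reports if r.label == NEGATIVE_LABEL]
            if bad:
                raise CorpusValidationError(
                    f"6-class corpus contains negative-label reports: {bad[:5]}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return LABELS_6 if self.label_scheme == "6-class" else LABELS_7

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def __getitem__(self, i: int) -> Report:
        return self.reports[i]

    def texts(self) -> list[str]:
        return [r.text for r in self.reports]

    def label_list(self) -> list[str]:
        return [r.label for r in self.reports]

    def class_counts(self) -> dict[str, int]:
        counts = {lbl: 0 for lbl in self.labels}
        for r in self.reports:
            counts[r.label] += 1
        return counts


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters; partitions are disjoint and exhaustive."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _report_to_record(report: Report) -> dict[str, object]:
    return {
        "id": report.id,
        "text": report.text,
        "modality": report.modality,
        "label": report.label,
        "icd10_coded": report.icd10_coded,
        "age": report.age,
        "sex": report.sex,
    }


def _record_to_report(rec: dict[str, object], rownum: int) -> Report:
    missing = [c for c in ("id", "text", "modality", "label") if c not in rec or rec[c] in (None, "")]
    if missing:
        raise CorpusSchemaError(f"row {rownum}: missing required field(s) {missing}")
    raw_coded = rec.get("icd10_coded", False)
    if isinstance(raw_coded, str):
        coded = raw_coded.strip().lower() in ("true", "1", "yes")
    else:
        coded = bool(raw_coded)
    raw_age = rec.get("age")
    age = None if raw_age in (None, "") else int(float(raw_age))  # type: ignore[arg-type]
    raw_sex = rec.get("sex")
    sex = None if raw_sex in (None, "") else str(raw_sex).strip().lower()
    try:
        return Report(
            id=str(rec["id"]),
            text=str(rec["text"]),
            modality=str(rec["modality"]),
            label=str(rec["label"]),
            icd10_coded=coded,
            age=age,
            sex=sex,
        )
    except CorpusValidationError as exc:
        raise CorpusValidationError(f"row {rownum}: {exc}") from None


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    return "csv"


def load_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Load a corpus from CSV (with header) or JSON-lines.

    ``format`` is ``"csv"`` or ``"jsonl"``; when omitted it is inferred from
    the file extension.  Unknown label tokens raise
    :class:`CorpusValidationError` naming the offending row.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    reports: list[Report] = []
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CorpusSchemaError(f"{path}: empty file")
            missing = [c for c in ("id", "text", "modality", "label") if c not in reader.fieldnames]
            if missing:
                raise CorpusSchemaError(f"{path}: missing required column(s) {missing}")
            for rownum, row in enumerate(reader, start=2):
                reports.append(_record_to_report(row, rownum))
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for rownum, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                reports.append(_record_to_report(json.loads(line), rownum))
    else:
        raise ValueError(f"unknown corpus format: {fmt!r}")
    return Corpus(reports)


def write_corpus(corpus: Corpus, path: str | Path, format: Optional[str] = None) -> None:
    """Write a corpus in canonical form (stable field order, ``\\n`` endings)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for r in corpus:
            rec = _report_to_record(r)
            rec["icd10_coded"] = "true" if r.icd10_coded else "false"
            rec["age"] = "" if r.age is None else r.age
            rec["sex"] = "" if r.sex is None else r.sex
            writer.writerow(rec)
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif fmt == "jsonl":
        lines = [json.dumps(_report_to_record(r), ensure_ascii=False) for r in corpus]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    else:
        raise ValueError(f"unknown corpus format: {fmt!r}")


# ---------------------------------------------------------------------------
# Splitting / label-scheme restriction
# ---------------------------------------------------------------------------

def split_corpus(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus]:
    """Partition a corpus into train and test sets.

    Deterministic given ``spec.seed``.  Under stratified splitting, classes
    with a single member are assigned to train with a warning (they cannot
    be stratified).
    """
    if len(corpus) == 0:
        raise ValueError("cannot split an empty corpus")
    reports = list(corpus.reports)
    forced_train: list[Report] = []
    if spec.stratified:
        counts = corpus.class_counts()
        singletons = {lbl for lbl, n in counts.items() if n == 1}
        if singletons:
            warnings.warn(
                f"classes with a single member assigned to train: {sorted(singletons)}",
                stacklevel=2,
            )
            forced_train = [r for r in reports if r.label in singletons]
            reports = [r for r in reports if r.label not in singletons]
    strat = [r.label for r in reports] if spec.stratified else None
    if len(reports) < 2:
        train_reports, test_reports = reports, []
    else:
        train_reports, test_reports = train_test_split(
            reports,
            train_size=spec.train_fraction,
            random_state=spec.seed,
            shuffle=True,
            stratify=strat,
        )
    train = Corpus(forced_train + list(train_reports), corpus.label_scheme)
    test = Corpus(list(test_reports), corpus.label_scheme)
    return train, test


def restrict_labels(corpus: Corpus, scheme: str) -> Corpus:
    """Project a 7-class corpus onto a label scheme.

    Under ``"6-class"`` every negative ("No DVT or PE") report is dropped;
    all surviving reports are untouched.
    """
    if scheme == "7-class":
        return corpus
    if scheme != "6-class":
        raise ValueError(f"unknown label scheme: {scheme!r}")
    if corpus.label_scheme != "7-class":
        raise ValueError("restrict_labels expects a 7-class corpus")
    kept = [r for r in corpus if r.label != NEGATIVE_LABEL]
    if not kept:
        warnings.warn("6-class restriction produced an empty corpus", stacklevel=2)
    return Corpus(kept, "6-class")
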