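"""On-disk formats.

All tables are UTF-8 with a header row; dates are ISO-8601 (YYYY-MM-DD)
throughout, with no locale-dependent parsing. Reports travel as JSONL
(one object per line) or CSV; orders, labs, adjudications and judgments as
CSV; lexicons as TSV with ``# key=value`` metadata comment lines.
Malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from pydantic import ValidationError

from .lexicon import KeywordEntry, KeywordLexicon
from .models import (
    AdjudicationLabel,
    DipJudgment,
    DrugOrder,
    Grade,
    LabResult,
    Modality,
    PeriodPattern,
    PeriodStatus,
    RadiologyReport,
    Source,
    Status,
)

logger = logging.getLogger(__name__)

REPORT_FIELDS = (
    "report_id",
    "patient_id",
    "exam_date",
    "modality",
    "findings_text",
    "diagnosis_text",
    "gold_ip",
)


class SchemaError(ValueError):
    """Input file violates the expected schema; message carries line numbers."""


def _format_pydantic_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<record>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def _parse_bool(raw) -> Optional[bool]:
    if raw is None or raw == "":
        return None
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _build_reports(rows: list[tuple[int, dict]], path) -> list[RadiologyReport]:
    reports: list[RadiologyReport] = []
    errors: list[str] = []
    seen_ids: set[str] = set()
    for lineno, rec in rows:
        missing = [k for k in REPORT_FIELDS[:4] if k not in rec or rec[k] in (None, "")]
        if missing:
            errors.append(f"line {lineno}: missing field(s) {', '.join(missing)}")
            continue
        try:
            rec = dict(rec)
            rec["gold_ip"] = _parse_bool(rec.get("gold_ip"))
            rep = RadiologyReport(
                report_id=str(rec["report_id"]),
                patient_id=str(rec["patient_id"]),
                exam_date=rec["exam_date"],
                modality=rec["modality"],
                findings_text=rec.get("findings_text") or "",
                diagnosis_text=rec.get("diagnosis_text") or "",
                gold_ip=rec["gold_ip"],
            )
        except (ValidationError, ValueError) as exc:
            msg = _format_pydantic_error(exc) if isinstance(exc, ValidationError) else str(exc)
            errors.append(f"line {lineno}: {msg}")
            continue
        if rep.report_id in seen_ids:
            errors.append(f"line {lineno}: duplicate report_id {rep.report_id!r}")
            continue
        seen_ids.add(rep.report_id)
        reports.append(rep)
    if errors:
        raise SchemaError(f"{path}: " + " | ".join(errors))
    if not reports:
        logger.warning("%s: no report records read", path)
    return reports


def read_reports(path: str | Path, format: Optional[str] = None) -> list[RadiologyReport]:
    """Read radiology reports from JSONL or CSV (format inferred from the
    suffix unless given)."""
    path = Path(path)
    fmt = (format or ("CSV" if path.suffix.lower() == ".csv" else "JSONL")).upper()
    rows: list[tuple[int, dict]] = []
    if fmt == "JSONL":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append((lineno, json.loads(line)))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}: line {lineno}: invalid JSON: {exc}")
    elif fmt == "CSV":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                rows.append((lineno, rec))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return _build_reports(rows, path)


def write_reports(
    reports: Sequence[RadiologyReport], path: str | Path, format: Optional[str] = None
) -> None:
    path = Path(path)
    fmt = (format or ("CSV" if path.suffix.lower() == ".csv" else "JSONL")).upper()
    if fmt == "JSONL":
        with open(path, "w", encoding="utf-8") as fh:
            for r in reports:
                fh.write(json.dumps(r.model_dump(mode="json"), ensure_ascii=False) + "\n")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=REPORT_FIELDS)
            w.writeheader()
            for r in reports:
                rec = r.model_dump(mode="json")
                rec["gold_ip"] = "" if r.gold_ip is None else str(r.gold_ip).lower()
                w.writerow(rec)


def _read_csv_rows(path: Path) -> list[tuple[int, dict]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return [(lineno, rec) for lineno, rec in enumerate(reader, start=2)]


def read_orders(path: str | Path) -> list[DrugOrder]:
    """Read drug orders; rows with end_date before start_date are rejected.
    Duplicate rows are preserved (deduplication is the exposure module's
    concern)."""
    path = Path(path)
    orders: list[DrugOrder] = []
    errors: list[str] = []
    for lineno, rec in _read_csv_rows(path):
        try:
            orders.append(DrugOrder(**{k: rec[k] for k in
                                       ("patient_id", "drug_code", "start_date", "end_date")}))
        except KeyError as exc:
            errors.append(f"line {lineno}: missing field {exc}")
        except ValidationError as exc:
            errors.append(f"line {lineno}: {_format_pydantic_error(exc)}")
    if errors:
        raise SchemaError(f"{path}: " + " | ".join(errors))
    if not orders:
        logger.warning("%s: no order records read", path)
    return orders


def write_orders(orders: Sequence[DrugOrder], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "drug_code", "start_date", "end_date"])
        for o in orders:
            w.writerow([o.patient_id, o.drug_code, o.start_date.isoformat(),
                        o.end_date.isoformat()])


def read_labs(path: str | Path) -> list[LabResult]:
    path = Path(path)
    labs: list[LabResult] = []
    errors: list[str] = []
    for lineno, rec in _read_csv_rows(path):
        try:
            labs.append(LabResult(**{k: rec[k] for k in
                                     ("patient_id", "date", "analyte", "value")}))
        except KeyError as exc:
            errors.append(f"line {lineno}: missing field {exc}")
        except ValidationError as exc:
            errors.append(f"line {lineno}: {_format_pydantic_error(exc)}")
    if errors:
        raise SchemaError(f"{path}: " + " | ".join(errors))
    return labs


def write_labs(labs: Sequence[LabResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "analyte", "value"])
        for lab in labs:
            w.writerow([lab.patient_id, lab.date.isoformat(), lab.analyte.value,
                        repr(lab.value)])


JUDGMENT_FIELDS = (
    "patient_id",
    "drug_code",
    "pre_status",
    "pre_source",
    "pre_evidence",
    "during_status",
    "during_source",
    "during_evidence",
    "post_status",
    "post_source",
    "post_evidence",
    "grade",
)


def write_judgments(judgments: Sequence[DipJudgment], path: str | Path) -> None:
    """One row per patient x drug. NA statuses are written as the literal
    "NA", never as an empty cell, so missingness round-trips."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=JUDGMENT_FIELDS)
        w.writeheader()
        for j in judgments:
            row = {"patient_id": j.patient_id, "drug_code": j.drug_code,
                   "grade": j.grade.value}
            for name in ("pre", "during", "post"):
                ps: PeriodStatus = getattr(j.pattern, name)
                row[f"{name}_status"] = ps.status.value
                row[f"{name}_source"] = ps.source.value
                row[f"{name}_evidence"] = "|".join(ps.evidence_ids)
            w.writerow(row)


def read_judgments(path: str | Path) -> list[DipJudgment]:
    path = Path(path)
    out: list[DipJudgment] = []
    errors: list[str] = []
    for lineno, rec in _read_csv_rows(path):
        try:
            periods = {}
            for name in ("pre", "during", "post"):
                ev = rec[f"{name}_evidence"]
                periods[name] = PeriodStatus(
                    status=Status(rec[f"{name}_status"]),
                    source=Source(rec[f"{name}_source"]),
                    evidence_ids=tuple(ev.split("|")) if ev else (),
                )
            out.append(
                DipJudgment(
                    patient_id=rec["patient_id"],
                    drug_code=rec["drug_code"],
                    pattern=PeriodPattern(**periods),
                    grade=Grade(rec["grade"]),
                )
            )
        except (KeyError, ValueError, ValidationError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise SchemaError(f"{path}: " + " | ".join(errors))
    return out


def read_adjudications(path: str | Path) -> dict[tuple[str, str], AdjudicationLabel]:
    """Chart-review labels keyed by (patient_id, drug_code)."""
    out: dict[tuple[str, str], AdjudicationLabel] = {}
    for _, rec in _read_csv_rows(Path(path)):
        out[(rec["patient_id"], rec["drug_code"])] = AdjudicationLabel(rec["label"])
    return out


# ---------------------------------------------------------------------------
# Lexicon TSV

_LEX_COLUMNS = ("canonical", "variants", "n_ip", "n_nonip", "lr_pos", "lr_neg")
_LEX_TERM_KEYS = (
    "negation_terms",
    "organ_terms",
    "ip_diagnosis_terms",
    "exclusion_diagnosis_terms",
)


def write_lexicon(lexicon: KeywordLexicon, path: str | Path) -> None:
    """TSV with entry rows plus ``# key=value`` metadata lines (modality,
    corpus totals, and the auxiliary term lists, |-separated)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# modality={lexicon.modality.value}\n")
        fh.write(f"# n_ip_total={lexicon.n_ip_total}\n")
        fh.write(f"# n_nonip_total={lexicon.n_nonip_total}\n")
        for key in _LEX_TERM_KEYS:
            fh.write(f"# {key}={'|'.join(getattr(lexicon, key))}\n")
        fh.write("\t".join(_LEX_COLUMNS) + "\n")
        for e in lexicon.entries:
            fh.write(
                "\t".join(
                    [
                        e.canonical,
                        "|".join(e.variants),
                        str(e.n_ip),
                        str(e.n_nonip),
                        repr(e.lr_pos),
                        repr(e.lr_neg),
                    ]
                )
                + "\n"
            )


def read_lexicon(path: str | Path) -> KeywordLexicon:
    path = Path(path)
    meta: dict[str, str] = {}
    entries: list[KeywordEntry] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
                continue
            if not header_seen:
                if tuple(line.split("\t")) != _LEX_COLUMNS:
                    raise SchemaError(f"{path}: line {lineno}: bad lexicon header")
                header_seen = True
                continue
            cols = line.split("\t")
            if len(cols) != len(_LEX_COLUMNS):
                raise SchemaError(f"{path}: line {lineno}: expected "
                                  f"{len(_LEX_COLUMNS)} columns, got {len(cols)}")
            entries.append(
                KeywordEntry(
                    canonical=cols[0],
                    variants=tuple(cols[1].split("|")) if cols[1] else (cols[0],),
                    n_ip=int(cols[2]),
                    n_nonip=int(cols[3]),
                    lr_pos=float(cols[4]),
                    lr_neg=float(cols[5]),
                )
            )
    if "modality" not in meta:
        raise SchemaError(f"{path}: missing '# modality=' metadata line")
    terms = {
        key: tuple(t for t in meta.get(key, "").split("|") if t)
        for key in _LEX_TERM_KEYS
    }
    return KeywordLexicon(
        modality=Modality(meta["modality"]),
        entries=tuple(entries),
        n_ip_total=int(meta.get("n_ip_total", 0)),
        n_nonip_total=int(meta.get("n_nonip_total", 0)),
        **terms,
    )
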