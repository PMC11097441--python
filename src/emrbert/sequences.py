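"""EMR parsing and the disease / visit / time-interval sequence transforms.

A patient's electronic medical record is an ordered list of dated visits,
each carrying one or more ICD-9 diagnosis codes. Three aligned sequences are
derived from it:

* ``D``   — the flattened, visit-ordered list of diagnosis codes;
* ``VS``  — the 1-based visit index repeated for every code of that visit;
* ``TIS`` — the day gap to the previous visit, placed on the first code of
  each visit and 0 elsewhere (0 for the first visit by convention).

These three channels later feed the token, segment and positional embeddings
of the encoder.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for an absent diagnosis slot in wide-format tables; never a token
EPS = "EPS"
#: pad token appended when sequences are brought to a fixed length
PAD_CODE = "[PAD]"

_CODE_RE = re.compile(r"^([VE]?\d{1,4})(?:\.(\d{1,2}))?$")


class EMRParseError(ValueError):
    """Raised for malformed codes, dates or table rows."""


def normalize_code(raw: str, keep: Iterable[str] = (), row: int | None = None) -> str:
    """Normalize an ICD-9 token to the category + one-decimal (XXX.X) level.

    Codes listed verbatim in ``keep`` (e.g. a configured noise set containing
    five-digit codes such as 464.00) are returned unchanged; any other code
    with more than one digit after the decimal point is truncated to one.

    Raises
    ------
    EMRParseError
        If ``raw`` is not an ICD-9-like token; the message names the value
        and, when given, the offending row.
    """
    token = str(raw).strip()
    if token in keep:
        return token
    m = _CODE_RE.match(token)
    if not m or not token:
        where = f" (row {row})" if row is not None else ""
        raise EMRParseError(f"malformed ICD-9 code {raw!r}{where}")
    head, decimals = m.groups()
    if decimals is None:
        return head
    return f"{head}.{decimals[:1]}"


@dataclass(frozen=True)
class Visit:
    """One dated encounter: a date and its non-empty list of codes."""

    date: dt.date
    codes: tuple[str, ...]

    def __post_init__(self):
        if not self.codes:
            raise ValueError("a visit must carry at least one diagnosis code")


@dataclass
class PatientRecord:
    patient_id: str
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self):
        dates = [v.date for v in self.visits]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"visits of patient {self.patient_id} not date-ordered")

    @property
    def n_codes(self) -> int:
        return sum(len(v.codes) for v in self.visits)

    def disease_positions(self) -> list[str]:
        """Flattened code list (identical to ``derive_sequences(...).D``)."""
        return [c for v in self.visits for c in v.codes]


@dataclass
class AlignedSequences:
    """The (D, VS, TIS) triple; all three lists share one length."""

    D: list[str]
    VS: list[int]
    TIS: list[int]

    def __post_init__(self):
        if not (len(self.D) == len(self.VS) == len(self.TIS)):
            raise ValueError("D, VS and TIS must have equal length")

    def __len__(self) -> int:
        return len(self.D)


@dataclass
class FormatDialect:
    """Declares how an EMR table is laid out.

    ``layout`` is ``"wide"`` (one row per visit, columns dx1..dxK) or
    ``"long"`` (one row per diagnosis). ``date_format`` of ``None`` means
    ISO-8601.
    """

    layout: str = "wide"
    patient_col: str = "patient_id"
    date_col: str = "date"
    dx_prefix: str = "dx"
    dx_col: str = "dx"
    date_format: str | None = None
    delimiter: str = ","


def _parse_date(value, fmt: str | None, row: int) -> dt.date:
    try:
        if fmt is None:
            return dt.date.fromisoformat(str(value).strip())
        return dt.datetime.strptime(str(value).strip(), fmt).date()
    except ValueError as exc:
        raise EMRParseError(f"unparseable date {value!r} at row {row}: {exc}") from exc


def parse_emr(source, dialect: FormatDialect | None = None,
              keep_codes: Iterable[str] = ()) -> list[PatientRecord]:
    """Parse a delimited EMR table into one :class:`PatientRecord` per patient.

    ``source`` may be a path or an open text stream. Empty / ``EPS`` cells are
    dropped, codes are normalized (codes in ``keep_codes`` kept verbatim),
    visits are sorted by date, and duplicate (patient, date) rows are merged
    into a single visit.
    """
    dialect = dialect or FormatDialect()
    df = pd.read_csv(source, sep=dialect.delimiter, dtype=str,
                     keep_default_na=False)
    if df.empty:
        return []
    keep = frozenset(str(c) for c in keep_codes)

    if dialect.layout == "wide":
        dx_cols = [c for c in df.columns if c.startswith(dialect.dx_prefix)
                   and c not in (dialect.patient_col, dialect.date_col)]
    elif dialect.layout == "long":
        dx_cols = [dialect.dx_col]
    else:
        raise EMRParseError(f"unknown layout {dialect.layout!r}")

    # (patient, date) -> ordered codes
    by_visit: dict[str, dict[dt.date, list[str]]] = {}
    order: list[str] = []
    for i, rec in enumerate(df.to_dict("records")):
        pid = str(rec[dialect.patient_col])
        date = _parse_date(rec[dialect.date_col], dialect.date_format, i)
        codes = []
        for col in dx_cols:
            cell = str(rec.get(col, "")).strip()
            if cell and cell != EPS:
                codes.append(normalize_code(cell, keep=keep, row=i))
        if pid not in by_visit:
            by_visit[pid] = {}
            order.append(pid)
        if date in by_visit[pid] and dialect.layout == "wide":
            logger.info("merging duplicate visit row for (%s, %s)", pid, date)
        by_visit[pid].setdefault(date, []).extend(codes)

    records = []
    for pid in order:
        visits = [Visit(date=d, codes=tuple(codes))
                  for d, codes in sorted(by_visit[pid].items()) if codes]
        if visits:
            records.append(PatientRecord(patient_id=pid, visits=visits))
    return records


def write_emr(records: Sequence[PatientRecord], target,
              dialect: FormatDialect | None = None) -> None:
    """Write records as a delimited table readable by :func:`parse_emr`."""
    dialect = dialect or FormatDialect()
    close = False
    if isinstance(target, (str, io.IOBase)) and isinstance(target, str):
        target = open(target, "w", newline="")
        close = True
    try:
        w = csv.writer(target, delimiter=dialect.delimiter)
        if dialect.layout == "wide":
            width = max((len(v.codes) for r in records for v in r.visits),
                        default=1)
            w.writerow([dialect.patient_col, dialect.date_col]
                       + [f"{dialect.dx_prefix}{i + 1}" for i in range(width)])
            for r in records:
                for v in r.visits:
                    row = list(v.codes) + [EPS] * (width - len(v.codes))
                    w.writerow([r.patient_id, v.date.isoformat()] + row)
        else:
            w.writerow([dialect.patient_col, dialect.date_col, dialect.dx_col])
            for r in records:
                for v in r.visits:
                    for c in v.codes:
                        w.writerow([r.patient_id, v.date.isoformat(), c])
    finally:
        if close:
            target.close()


def derive_sequences(record: PatientRecord) -> AlignedSequences:
    """Derive the aligned (D, VS, TIS) triple from one patient record.

    TIS carries the day gap to the previous visit on the first code of each
    visit and 0 on the rest; the first visit's gap is 0 (its reference date
    is itself).
    """
    if not record.visits:
        raise ValueError("record has no visits")
    D: list[str] = []
    VS: list[int] = []
    TIS: list[int] = []
    prev_date = record.visits[0].date
    for i, visit in enumerate(record.visits, start=1):
        gap = (visit.date - prev_date).days
        for j, code in enumerate(visit.codes):
            D.append(code)
            VS.append(i)
            TIS.append(gap if j == 0 else 0)
        prev_date = visit.date
    return AlignedSequences(D=D, VS=VS, TIS=TIS)


def pad_or_truncate(seqs: AlignedSequences, L: int,
                    pad_value: str = PAD_CODE) -> AlignedSequences:
    """Bring all three sequences to length exactly ``L``.

    Truncation keeps the most recent suffix — the model predicts the future,
    so recent history dominates. Padding appends ``pad_value`` with 0 in the
    VS and TIS channels.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    n = len(seqs)
    if n >= L:
        return AlignedSequences(D=seqs.D[n - L:], VS=seqs.VS[n - L:],
                                TIS=seqs.TIS[n - L:])
    pad = L - n
    return AlignedSequences(D=seqs.D + [pad_value] * pad,
                            VS=seqs.VS + [0] * pad,
                            TIS=seqs.TIS + [0] * pad)


def sequences_to_jsonl(items: Iterable[tuple[str, AlignedSequences]], target) -> None:
    """Write ``{patient_id, D, VS, TIS}`` JSON-lines."""
    close = isinstance(target, str)
    fh = open(target, "w") if close else target
    try:
        for pid, s in items:
            fh.write(json.dumps({"patient_id": pid, "D": s.D,
                                 "VS": s.VS, "TIS": s.TIS}) + "\n")
    finally:
        if close:
            fh.close()


def sequences_from_jsonl(source) -> list[tuple[str, AlignedSequences]]:
    close = isinstance(source, str)
    fh = open(source) if close else source
    try:
        out = []
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                out.append((obj["patient_id"],
                            AlignedSequences(D=obj["D"], VS=obj["VS"],
                                             TIS=obj["TIS"])))
        return out
    finally:
        if close:
            fh.close()
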