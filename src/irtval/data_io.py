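"""Containers and text I/O for response matrices, item banks and reports.

Coding conventions enforced here and assumed everywhere else:

* response categories are 1-based integers (1..m per item) externally;
  the sentinel ``MISSING = -1`` marks a missing response;
* item banks carry a positive slope and strictly increasing thresholds
  (theta units) per item;
* all on-disk formats are plain text: RFC-4180-style CSV with a header row
  for responses and banks, JSON for reports and configs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


class ValidationError(ValueError):
    """Input data violates a documented contract."""


class ParseError(ValueError):
    """A file could not be parsed."""


class StateError(RuntimeError):
    """An operation was applied in an invalid order (e.g. double reverse-coding)."""


# ---------------------------------------------------------------------------
# ItemBank
# ---------------------------------------------------------------------------

@dataclass
class ItemBank:
    """Per-item graded-model parameters plus metadata.

    slopes: (p,) positive reals (logistic metric, no 1.7 constant);
    thresholds: list of strictly increasing arrays, one per item, length m-1.
    """
    item_ids: list
    slopes: np.ndarray
    thresholds: list
    reverse_coded: np.ndarray = None

    def __post_init__(self):
        self.item_ids = list(self.item_ids)
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.thresholds = [np.asarray(b, dtype=float) for b in self.thresholds]
        if self.reverse_coded is None:
            self.reverse_coded = np.zeros(len(self.item_ids), dtype=bool)
        else:
            self.reverse_coded = np.asarray(self.reverse_coded, dtype=bool)
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError("item_ids must be unique")
        if len(self.slopes) != len(self.item_ids) or len(self.thresholds) != len(self.item_ids):
            raise ValidationError("slopes/thresholds length mismatch with item_ids")
        if np.any(self.slopes <= 0):
            bad = self.item_ids[int(np.argmin(self.slopes))]
            raise ValidationError(f"slope must be positive (item {bad})")
        for iid, b in zip(self.item_ids, self.thresholds):
            if len(b) < 1 or np.any(np.diff(b) <= 0):
                raise ValidationError(f"thresholds must be strictly increasing (item {iid})")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([len(b) + 1 for b in self.thresholds])

    def subset(self, items) -> "ItemBank":
        items = list(items)
        return ItemBank([self.item_ids[i] for i in items],
                        self.slopes[items],
                        [self.thresholds[i] for i in items],
                        self.reverse_coded[items])

    def index_of(self, item_id) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise ValidationError(f"unknown item {item_id!r}") from None

    def copy(self) -> "ItemBank":
        return ItemBank(list(self.item_ids), self.slopes.copy(),
                        [b.copy() for b in self.thresholds],
                        self.reverse_coded.copy())

    def __eq__(self, other):
        return (isinstance(other, ItemBank)
                and self.item_ids == other.item_ids
                and np.allclose(self.slopes, other.slopes)
                and all(np.allclose(a, b) for a, b in zip(self.thresholds, other.thresholds))
                and np.array_equal(self.reverse_coded, other.reverse_coded))


def write_item_bank(bank: ItemBank, path) -> None:
    """Write a bank as CSV (item_id, slope, b1..b{m-1}, n_categories,
    reverse_coded) or as a JSON mirror, chosen by file suffix."""
    path = Path(path)
    if path.suffix == ".json":
        doc = [{"item_id": iid, "slope": float(a),
                "thresholds": [float(x) for x in b],
                "n_categories": int(len(b) + 1), "reverse_coded": bool(r)}
               for iid, a, b, r in zip(bank.item_ids, bank.slopes,
                                       bank.thresholds, bank.reverse_coded)]
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        return
    mmax = int(bank.n_categories.max())
    rows = []
    for iid, a, b, r in zip(bank.item_ids, bank.slopes, bank.thresholds,
                            bank.reverse_coded):
        row = {"item_id": iid, "slope": a}
        for k in range(mmax - 1):
            row[f"b{k + 1}"] = b[k] if k < len(b) else np.nan
        row["n_categories"] = len(b) + 1
        row["reverse_coded"] = int(r)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_item_bank(path) -> ItemBank:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        return ItemBank([d["item_id"] for d in doc],
                        [d["slope"] for d in doc],
                        [d["thresholds"] for d in doc],
                        [d.get("reverse_coded", False) for d in doc])
    df = pd.read_csv(path)
    thresholds = []
    for _, row in df.iterrows():
        m = int(row["n_categories"])
        thresholds.append([row[f"b{k + 1}"] for k in range(m - 1)])
    return ItemBank(df["item_id"].tolist(), df["slope"].to_numpy(),
                    thresholds,
                    df["reverse_coded"].to_numpy().astype(bool)
                    if "reverse_coded" in df else None)


# ---------------------------------------------------------------------------
# ResponseMatrix
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Respondents x items integer category data plus demographic covariates."""
    responses: np.ndarray                 # (n, p) int, 1-based, MISSING = -1
    person_ids: list
    item_ids: list
    covariates: pd.DataFrame | None = None
    reverse_coding_applied: bool = False

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=int)
        self.person_ids = list(self.person_ids)
        self.item_ids = list(self.item_ids)
        n, p = self.responses.shape
        if n < 1 or p < 1:
            raise ValidationError("need at least one person and one item")
        if len(self.person_ids) != n or len(self.item_ids) != p:
            raise ValidationError("id lengths do not match the response matrix")
        if len(set(self.person_ids)) != n:
            raise ValidationError("person_ids must be unique")
        if len(set(self.item_ids)) != p:
            raise ValidationError("item_ids must be unique")
        bad = (self.responses < 1) & (self.responses != MISSING)
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid code {self.responses[r, c]} at person "
                f"{self.person_ids[r]}, item {self.item_ids[c]}")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValidationError("covariates length mismatch")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def is_complete(self) -> bool:
        return not np.any(self.responses == MISSING)

    def complete_cases(self) -> "ResponseMatrix":
        """Listwise deletion: drop persons with any missing response."""
        keep = ~np.any(self.responses == MISSING, axis=1)
        if keep.all():
            return self
        cov = self.covariates.loc[keep].reset_index(drop=True) \
            if self.covariates is not None else None
        return ResponseMatrix(self.responses[keep],
                              [pid for pid, k in zip(self.person_ids, keep) if k],
                              list(self.item_ids), cov,
                              self.reverse_coding_applied)

    def require_complete(self, stage: str = "analysis") -> "ResponseMatrix":
        if not self.is_complete():
            n_bad = int(np.any(self.responses == MISSING, axis=1).sum())
            raise ValidationError(
                f"{stage} requires complete cases; {n_bad} persons have "
                "missing responses (use complete_cases() explicitly)")
        return self

    def subset_items(self, items) -> "ResponseMatrix":
        items = list(items)
        return ResponseMatrix(self.responses[:, items], list(self.person_ids),
                              [self.item_ids[i] for i in items],
                              self.covariates, self.reverse_coding_applied)


@dataclass
class ResponseSchema:
    """Column mapping for reading a response CSV."""
    person_id: str = "person_id"
    items: list = None                    # None -> every non-id, non-covariate column
    covariates: list = field(default_factory=list)
    n_categories: int = 5
    missing_tokens: tuple = ("", "NA", "nan")


def read_responses(path, schema: ResponseSchema | None = None) -> ResponseMatrix:
    """Read and validate a wide-format response CSV.

    Out-of-range or non-integer codes raise a ValidationError naming the
    offending cells (up to 10 listed).
    """
    schema = schema or ResponseSchema()
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas names the line
        raise ParseError(f"malformed CSV {path}: {exc}") from exc
    if schema.person_id not in df.columns:
        raise ParseError(f"missing id column {schema.person_id!r}")
    item_cols = schema.items or [c for c in df.columns
                                 if c != schema.person_id
                                 and c not in schema.covariates]
    missing_cols = [c for c in item_cols if c not in df.columns]
    if missing_cols:
        raise ParseError(f"missing item columns: {missing_cols}")

    n = len(df)
    resp = np.full((n, len(item_cols)), MISSING, dtype=int)
    bad_cells = []
    for j, col in enumerate(item_cols):
        for i, tok in enumerate(df[col].astype(str).str.strip()):
            if tok in schema.missing_tokens:
                continue
            try:
                v = int(tok)
            except ValueError:
                bad_cells.append((df[schema.person_id].iloc[i], col,
                                  f"non-integer {tok!r}"))
                continue
            if not 1 <= v <= schema.n_categories:
                bad_cells.append((df[schema.person_id].iloc[i], col,
                                  f"code {v} outside [1, {schema.n_categories}]"))
                continue
            resp[i, j] = v
    if bad_cells:
        shown = "; ".join(f"(person {p}, item {c}): {msg}"
                          for p, c, msg in bad_cells[:10])
        raise ValidationError(
            f"{len(bad_cells)} invalid response cells — {shown}")
    cov = df[schema.covariates].copy() if schema.covariates else None
    if cov is not None:
        for c in cov.columns:  # numeric covariates (e.g. age) back to numbers
            num = pd.to_numeric(cov[c], errors="coerce")
            if not num.isna().any():
                cov[c] = num
    return ResponseMatrix(resp, df[schema.person_id].tolist(), item_cols, cov)


def write_responses(rm: ResponseMatrix, path) -> None:
    df = pd.DataFrame(rm.responses, columns=rm.item_ids)
    df.insert(0, "person_id", rm.person_ids)
    if rm.covariates is not None:
        for c in rm.covariates.columns:
            df[c] = rm.covariates[c].to_numpy()
    df = df.replace(MISSING, "")
    df.to_csv(path, index=False)


def apply_reverse_coding(rm: ResponseMatrix, bank: ItemBank) -> ResponseMatrix:
    """Map category c -> m+1-c on items flagged reverse_coded in the bank.

    The returned matrix records that coding was applied; applying it twice
    raises a StateError, since silent double-flipping would corrupt scores.
    """
    if rm.reverse_coding_applied:
        raise StateError("reverse coding has already been applied")
    resp = rm.responses.copy()
    for j, iid in enumerate(rm.item_ids):
        i = bank.index_of(iid)
        if bank.reverse_coded[i]:
            m = len(bank.thresholds[i]) + 1
            mask = resp[:, j] != MISSING
            resp[mask, j] = m + 1 - resp[mask, j]
    return ResponseMatrix(resp, list(rm.person_ids), list(rm.item_ids),
                          rm.covariates, reverse_coding_applied=True)


# ---------------------------------------------------------------------------
# ValidationReport
# ---------------------------------------------------------------------------

def jsonify(obj):
    """Recursively convert numpy scalars/arrays so json.dumps round-trips."""
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class ValidationReport:
    """Aggregated results of a full validation run.

    Every section is a JSON-native dict so that write/read round-trips to an
    equal report, and every threshold-based flag is stored next to the raw
    statistic and the threshold that produced it.
    """
    meta: dict = field(default_factory=dict)
    dimensionality: dict | None = None
    local_dependence: dict | None = None
    mokken: dict | None = None
    grm: dict | None = None
    item_fit: dict | None = None
    dif: dict | None = None
    cat: dict | None = None
    t_scores: dict | None = None
    decisions: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return jsonify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(**d)


def write_report(report: ValidationReport, path, format: str = "json") -> None:
    """Persist a report: one JSON document, or one CSV table per section."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), sort_keys=True,
                                   indent=1, allow_nan=True))
        return
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for name, section in report.to_dict().items():
            if section is None:
                continue
            if isinstance(section, dict):
                rows = _flatten(section)
            else:
                rows = [{"value": v} for v in section]
            pd.DataFrame(rows).to_csv(path / f"{name}.csv", index=False)
        return
    raise ValidationError(f"unknown report format {format!r}")


def _flatten(d, prefix=""):
    rows = []
    flat = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            rows.extend(_flatten(v, prefix=key + "."))
        else:
            flat[key] = json.dumps(v) if isinstance(v, list) else v
    if flat:
        rows.insert(0, flat)
    return rows


def read_report(path) -> ValidationReport:
    return ValidationReport.from_dict(json.loads(Path(path).read_text()))
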