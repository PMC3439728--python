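"""Drug-label corpus I/O and side-effect term extraction.

A drug label is reduced to its three safety sections — Boxed Warning (BW),
Warnings and Precautions (WP) and Adverse Reactions (AR) — and filtered
against a flat side-effect lexicon (a stand-in for a MedDRA lowest-level-term
list).  The result is a drug x term count matrix, the "SE profile", which is
the input to topic modeling.

Formats are deliberately plain:

* labels: JSON lines, one drug per line;
* lexicon: two-column TSV ``term_id<TAB>term_text``, no header;
* matrix: TSV with a ``drug_id`` header column and term ids as columns.
"""

from __future__ import annotations

import datetime
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SECTION_KEYS = ("BW", "WP", "AR")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on anything that is not a letter or digit.

    Punctuation therefore acts as a token separator and runs of whitespace
    collapse; the token stream is the canonical form used for phrase matching.
    """
    return _TOKEN_RE.findall(text.lower())


def normalize_phrase(text: str) -> str:
    """Canonical single-spaced lowercase form of a term or indication."""
    return " ".join(tokenize(text))


@dataclass(frozen=True)
class SideEffectLexicon:
    """Ordered flat vocabulary of side-effect terms.

    ``entries`` maps a unique term id to its canonical term text.  Texts must
    be unique after normalization, otherwise matches would be ambiguous.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon is empty")
        seen: dict[str, str] = {}
        for term_id, text in self.entries.items():
            if not term_id:
                raise ValueError("empty term id in lexicon")
            norm = normalize_phrase(text)
            if not norm:
                raise ValueError(f"term {term_id!r} normalizes to nothing")
            if norm in seen:
                raise ValueError(
                    f"terms {seen[norm]!r} and {term_id!r} collide on {norm!r}"
                )
            seen[norm] = term_id

    def __len__(self) -> int:
        return len(self.entries)

    def term_ids(self) -> list[str]:
        return list(self.entries)

    def phrase_index(self) -> dict[tuple[str, ...], str]:
        """Map token-tuple of each term to its id (used by the matcher)."""
        return {tuple(tokenize(t)): tid for tid, t in self.entries.items()}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SideEffectLexicon":
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                term_id, text = parts
                if term_id in entries:
                    raise ValueError(f"{path}:{lineno}: duplicate id {term_id!r}")
                entries[term_id] = text
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term_id, text in self.entries.items():
                fh.write(f"{term_id}\t{text}\n")


@dataclass(frozen=True)
class DrugRecord:
    """One deduplicated drug label restricted to the fields the analysis uses."""

    drug_id: str
    sections: Mapping[str, str] = field(default_factory=dict)
    has_boxed_warning: bool = False
    indications: frozenset[str] = frozenset()
    effective_date: datetime.date | None = None
    atc_level1: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")
        bad = set(self.sections) - set(SECTION_KEYS)
        if bad:
            raise ValueError(f"unknown section keys {sorted(bad)}")
        if self.atc_level1 is not None and not (
            len(self.atc_level1) == 1 and self.atc_level1.isalpha()
        ):
            raise ValueError(f"atc_level1 must be one letter, got {self.atc_level1!r}")

    def section_text(self) -> str:
        """BW, WP and AR texts concatenated in that fixed order."""
        return "\n".join(self.sections.get(k, "") for k in SECTION_KEYS)

    def to_json_obj(self) -> dict:
        obj: dict = {
            "drug_id": self.drug_id,
            "sections": {k: v for k, v in self.sections.items() if v},
            "has_boxed_warning": self.has_boxed_warning,
            "indications": sorted(self.indications),
        }
        if self.effective_date is not None:
            obj["effective_date"] = self.effective_date.isoformat()
        if self.atc_level1 is not None:
            obj["atc_level1"] = self.atc_level1
        return obj


def _normalize_indications(values: Iterable[str]) -> frozenset[str]:
    out = set()
    for v in values:
        norm = " ".join(str(v).lower().split())
        if norm:
            out.add(norm)
    return frozenset(out)


def _record_from_obj(obj: dict, where: str) -> DrugRecord:
    drug_id = obj.get("drug_id")
    if not drug_id or not isinstance(drug_id, str):
        raise ValueError(f"{where}: missing or empty drug_id")
    raw_sections = obj.get("sections") or {}
    if not isinstance(raw_sections, dict):
        raise ValueError(f"{where}: sections must be an object")
    sections = {k: str(v) for k, v in raw_sections.items()}
    date = None
    if obj.get("effective_date"):
        try:
            date = datetime.date.fromisoformat(str(obj["effective_date"]))
        except ValueError as exc:
            raise ValueError(f"{where}: bad effective_date: {exc}") from None
    if "has_boxed_warning" in obj:
        has_bw = bool(obj["has_boxed_warning"])
    else:
        has_bw = bool(sections.get("BW", "").strip())
    atc = obj.get("atc_level1")
    if atc is not None:
        atc = str(atc).strip().upper() or None
    return DrugRecord(
        drug_id=drug_id,
        sections=sections,
        has_boxed_warning=has_bw,
        indications=_normalize_indications(obj.get("indications", ())),
        effective_date=date,
        atc_level1=atc,
    )


def load_labels(path: str | Path) -> list[DrugRecord]:
    """Read drug labels from a JSON-lines file.

    Missing sections become empty text; ``has_boxed_warning`` defaults to
    non-emptiness of the BW section.  A malformed line or a repeated
    ``(drug_id, effective_date)`` pair is an error.
    """
    records: list[DrugRecord] = []
    seen: set[tuple[str, datetime.date | None]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            where = f"{path}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{where}: malformed JSON: {exc}") from None
            rec = _record_from_obj(obj, where)
            key = (rec.drug_id, rec.effective_date)
            if key in seen:
                raise ValueError(f"{where}: duplicate (drug_id, effective_date) {key}")
            seen.add(key)
            records.append(rec)
    return records


def write_labels(records: Iterable[DrugRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_obj(), sort_keys=True) + "\n")


def _dedup_key(rec: DrugRecord) -> tuple:
    serialized = json.dumps(rec.to_json_obj(), sort_keys=True)
    has_date = rec.effective_date is not None
    date = rec.effective_date or datetime.date.min
    return (has_date, date, serialized)


def deduplicate_labels(records: Sequence[DrugRecord]) -> list[DrugRecord]:
    """Keep one label per drug: the latest effective date wins.

    An undated record loses to any dated one; among ties (or all undated) the
    lexicographically larger serialized record is kept, so the result is
    deterministic regardless of input order.  Output preserves first-seen
    drug order.
    """
    best: dict[str, DrugRecord] = {}
    for rec in records:
        cur = best.get(rec.drug_id)
        if cur is None or _dedup_key(rec) > _dedup_key(cur):
            best[rec.drug_id] = rec
    return list(best.values())


def _extract_with_index(
    tokens: Sequence[str], index: Mapping[tuple[str, ...], str], max_len: int
) -> dict[str, int]:
    counts: dict[str, int] = {}
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            term_id = index.get(tuple(tokens[i : i + length]))
            if term_id is not None:
                counts[term_id] = counts.get(term_id, 0) + 1
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return counts


def extract_terms(text: str, lexicon: SideEffectLexicon) -> dict[str, int]:
    """Count whole-token phrase matches of lexicon terms in ``text``.

    Matching is greedy left-to-right, longest phrase first, and matched
    tokens are consumed, so "abdominal pain" suppresses a nested "pain"
    match.  Terms without matches are omitted from the result.
    """
    index = lexicon.phrase_index()
    max_len = max(len(k) for k in index)
    return _extract_with_index(tokenize(text), index, max_len)


@dataclass(frozen=True)
class DrugTermMatrix:
    """Drug x side-effect-term count matrix (the SE profile)."""

    drug_ids: list[str]
    term_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.drug_ids), len(self.term_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if len(set(self.term_ids)) != len(self.term_ids):
            raise ValueError("duplicate term ids")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.shape[0] and (counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero drug rows are not allowed")
        object.__setattr__(self, "counts", counts)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def binarized(self) -> "DrugTermMatrix":
        """Presence/absence view of the same profile."""
        return DrugTermMatrix(
            list(self.drug_ids), list(self.term_ids), (self.counts > 0).astype(np.int64)
        )


def build_matrix(
    records: Sequence[DrugRecord],
    lexicon: SideEffectLexicon,
    binary: bool = False,
) -> DrugTermMatrix:
    """Assemble the SE profile from deduplicated labels.

    Each drug's BW/WP/AR texts are concatenated and passed through
    :func:`extract_terms`.  Columns keep lexicon order, restricted to terms
    matched in at least one drug; drugs matching nothing are dropped with a
    warning.  With ``binary=True`` multiplicities are collapsed to 0/1.
    """
    index = lexicon.phrase_index()
    max_len = max(len(k) for k in index)
    term_order = {tid: j for j, tid in enumerate(lexicon.term_ids())}

    kept_ids: list[str] = []
    rows: list[dict[str, int]] = []
    for rec in records:
        counts = _extract_with_index(tokenize(rec.section_text()), index, max_len)
        if not counts:
            logger.warning("drug %s matched no lexicon terms; dropped", rec.drug_id)
            continue
        kept_ids.append(rec.drug_id)
        rows.append(counts)
    if not rows:
        raise ValueError("empty corpus: no drug matched any lexicon term")

    used = sorted({tid for row in rows for tid in row}, key=term_order.__getitem__)
    col = {tid: j for j, tid in enumerate(used)}
    mat = np.zeros((len(rows), len(used)), dtype=np.int64)
    for i, row in enumerate(rows):
        for tid, c in row.items():
            mat[i, col[tid]] = c
    if binary:
        mat = (mat > 0).astype(np.int64)
    return DrugTermMatrix(kept_ids, used, mat)


def read_matrix(path: str | Path) -> DrugTermMatrix:
    """Read a drug x term TSV written by :func:`write_matrix`."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[0] != "drug_id":
        raise ValueError(f"{path}: first header column must be 'drug_id'")
    term_ids = header[1:]
    drug_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: ragged row")
        drug_ids.append(parts[0])
        try:
            row = [int(c) for c in parts[1:]]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer count") from None
        if any(c < 0 for c in row):
            raise ValueError(f"{path}:{lineno}: negative count")
        rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(rows), len(term_ids))
    return DrugTermMatrix(drug_ids, term_ids, counts)


def write_matrix(matrix: DrugTermMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(matrix.term_ids) + "\n")
        for i, did in enumerate(matrix.drug_ids):
            fh.write(did + "\t" + "\t".join(map(str, matrix.counts[i])) + "\n")
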