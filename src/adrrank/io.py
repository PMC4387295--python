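"""Readers, writers and validation for the tabular formats the pipeline touches.

All files are tab-separated UTF-8 with a mandatory header row.  Lines starting
with ``#`` before the header carry ``key=value`` metadata (e.g. the seed a
synthetic study was generated with) and are returned to the caller rather than
discarded.  Readers never drop rows silently: every input row is either parsed
or reported with its 1-based line number and a reason.

Canonical column layouts
------------------------
comparisons.tsv   worker_id  batch_id  adr_a  adr_b  chosen  is_qc  qc_expected
ranking.tsv       term  score  rank  percentile
associations.tsv  subject  adr  [value]
outcomes.tsv      adr  death  disability  life_threatening  required_intervention
                  hospitalization  congenital_anomaly  other_serious  none_specified

A *dialect* mapping (canonical name -> name used in the file) lets callers read
files whose headers differ from the canonical layout without rewriting them.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

COMPARISON_COLUMNS = (
    "worker_id",
    "batch_id",
    "adr_a",
    "adr_b",
    "chosen",
    "is_qc",
    "qc_expected",
)

RANKING_COLUMNS = ("term", "score", "rank", "percentile")

#: Outcome categories of an adverse-event report, in canonical order.  The six
#: specific outcomes come first, followed by the unspecific "other serious"
#: tag and reports that specify no outcome at all.
OUTCOME_CATEGORIES = (
    "death",
    "disability",
    "life_threatening",
    "required_intervention",
    "hospitalization",
    "congenital_anomaly",
    "other_serious",
    "none_specified",
)

_TRUE_TOKENS = {"true", "1", "yes", "t", "y"}
_FALSE_TOKENS = {"false", "0", "no", "f", "n", ""}

_WS = re.compile(r"\s+")


def normalize_term(name: str) -> str:
    """Canonical form of an ADR term for matching: case-folded, whitespace collapsed."""
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass
class RowIssue:
    """A rejected input row, with its 1-based line number."""

    line: int
    reason: str


@dataclass
class ParseResult:
    """Outcome of reading a table: the parsed frame plus a rejection report."""

    frame: pd.DataFrame
    rejected: list[RowIssue] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)
    duplicates_dropped: int = 0

    @property
    def n_parsed(self) -> int:
        return len(self.frame)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _read_rows(path):
    """Yield (line_number, cells) for every non-metadata line; return header separately."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, cells in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not cells or (len(cells) == 1 and not cells[0].strip()):
                continue
            if header is None and cells[0].lstrip().startswith("#"):
                text = "\t".join(cells).lstrip("#").strip()
                if "=" in text:
                    key, _, value = text.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            if header is None:
                header = [c.strip() for c in cells]
                continue
            rows.append((lineno, cells))
    if header is None:
        raise FormatError(f"{path}: empty file (no header row)")
    return header, rows, metadata


def _resolve_columns(header, required, optional, dialect, path):
    """Map canonical column names to positions in the file header."""
    dialect = dict(dialect or {})
    positions: dict[str, int] = {}
    for canonical in (*required, *optional):
        actual = dialect.get(canonical, canonical)
        if actual in header:
            positions[canonical] = header.index(actual)
        elif canonical in required:
            raise FormatError(f"{path}: missing required column {actual!r}")
    return positions


def _parse_bool(token: str) -> bool:
    token = token.strip().casefold()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"not a boolean token: {token!r}")


def read_comparisons(path, dialect: Mapping[str, str] | None = None) -> ParseResult:
    """Read a pairwise-comparison table.

    Each row records one worker's judgment of which member of an ADR pair is
    more severe (``chosen`` is ``a`` or ``b``).  Quality-control rows carry
    ``is_qc`` true and the expected answer in ``qc_expected``.

    Rows violating the record invariants (self-pair, bad ``chosen`` token,
    ``qc_expected`` present without ``is_qc`` or vice versa) are rejected and
    reported by line number, never silently dropped.
    """
    required = ("worker_id", "batch_id", "adr_a", "adr_b", "chosen", "is_qc")
    header, rows, metadata = _read_rows(path)
    pos = _resolve_columns(header, required, ("qc_expected",), dialect, path)
    records: list[dict] = []
    rejected: list[RowIssue] = []
    for lineno, cells in rows:
        def cell(name, default=""):
            idx = pos.get(name)
            return cells[idx].strip() if idx is not None and idx < len(cells) else default

        adr_a, adr_b = cell("adr_a"), cell("adr_b")
        chosen = cell("chosen").casefold()
        if not adr_a or not adr_b:
            rejected.append(RowIssue(lineno, "blank ADR term"))
            continue
        if adr_a == adr_b:
            rejected.append(RowIssue(lineno, f"self-pair {adr_a!r}"))
            continue
        if chosen not in ("a", "b"):
            rejected.append(RowIssue(lineno, f"chosen token {cell('chosen')!r} not in {{a, b}}"))
            continue
        try:
            is_qc = _parse_bool(cell("is_qc"))
        except ValueError as exc:
            rejected.append(RowIssue(lineno, str(exc)))
            continue
        qc_expected = cell("qc_expected").casefold() or None
        if is_qc and qc_expected not in ("a", "b"):
            rejected.append(RowIssue(lineno, "QC row without a valid qc_expected"))
            continue
        if not is_qc and qc_expected is not None:
            rejected.append(RowIssue(lineno, "qc_expected given on a non-QC row"))
            continue
        records.append(
            {
                "worker_id": cell("worker_id"),
                "batch_id": cell("batch_id"),
                "adr_a": adr_a,
                "adr_b": adr_b,
                "chosen": chosen,
                "is_qc": is_qc,
                "qc_expected": qc_expected,
            }
        )
    frame = pd.DataFrame(records, columns=list(COMPARISON_COLUMNS))
    if rejected:
        logger.warning("%s: rejected %d of %d rows", path, len(rejected), len(rows))
    return ParseResult(frame, rejected, metadata)


def write_comparisons(frame: pd.DataFrame, path, metadata: Mapping[str, str] | None = None) -> None:
    """Write a comparison table in the canonical layout (see module docstring)."""
    out = frame.loc[:, list(COMPARISON_COLUMNS)].copy()
    out["qc_expected"] = out["qc_expected"].fillna("")
    _write_tsv(out, path, metadata)


def read_association_table(
    path,
    subject_kind: str = "drug",
    dialect: Mapping[str, str] | None = None,
) -> ParseResult:
    """Read a (subject, adr[, value]) association table and deduplicate it.

    ``subject_kind`` ("drug" or "gene") is recorded on the result frame's
    ``attrs`` for provenance.  Duplicate (subject, adr) rows are dropped, the
    first occurrence wins, and the count is logged and returned.
    """
    header, rows, metadata = _read_rows(path)
    pos = _resolve_columns(header, ("subject", "adr"), ("value",), dialect, path)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    records, rejected = [], []
    for lineno, cells in rows:
        subject = cells[pos["subject"]].strip() if pos["subject"] < len(cells) else ""
        adr = cells[pos["adr"]].strip() if pos["adr"] < len(cells) else ""
        if not subject or not adr:
            rejected.append(RowIssue(lineno, "blank subject or adr field"))
            continue
        rec = {"subject": subject, "adr": adr}
        if "value" in pos and pos["value"] < len(cells) and cells[pos["value"]].strip():
            try:
                rec["value"] = float(cells[pos["value"]])
            except ValueError:
                rejected.append(RowIssue(lineno, f"non-numeric value {cells[pos['value']]!r}"))
                continue
        records.append(rec)
    frame = pd.DataFrame(records)
    dups = 0
    if not frame.empty:
        before = len(frame)
        frame = frame.drop_duplicates(subset=["subject", "adr"], keep="first").reset_index(drop=True)
        dups = before - len(frame)
        if dups:
            logger.info("%s: dropped %d duplicate (subject, adr) rows", path, dups)
    frame.attrs["subject_kind"] = subject_kind
    return ParseResult(frame, rejected, metadata, duplicates_dropped=dups)


def write_association_table(frame: pd.DataFrame, path, metadata=None) -> None:
    cols = ["subject", "adr"] + (["value"] if "value" in frame.columns else [])
    _write_tsv(frame.loc[:, cols], path, metadata)


def validate_ranking(ranking: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a severity ranking frame.

    Ranks must be a permutation of 1..N, the score order must agree with the
    rank order (rank 1 = highest score = most severe), and percentiles must lie
    in (0, 100].
    """
    missing = [c for c in RANKING_COLUMNS if c not in ranking.columns]
    if missing:
        raise IntegrityError(f"ranking is missing columns: {missing}")
    if ranking[list(RANKING_COLUMNS)].isna().any().any():
        raise IntegrityError("ranking has missing values")
    n = len(ranking)
    ranks = ranking["rank"].to_numpy()
    if sorted(ranks) != list(range(1, n + 1)):
        raise IntegrityError("ranks are not a permutation of 1..N")
    ordered = ranking.sort_values("rank")
    if not ordered["score"].is_monotonic_decreasing:
        raise IntegrityError("score order disagrees with rank order")
    pct = ranking["percentile"]
    if (pct <= 0).any() or (pct > 100).any():
        raise IntegrityError("percentiles outside (0, 100]")
    return ranking


def read_ranking(path, dialect: Mapping[str, str] | None = None) -> ParseResult:
    """Read a severity ranking (term, score, rank, percentile) and validate it."""
    header, rows, metadata = _read_rows(path)
    pos = _resolve_columns(header, RANKING_COLUMNS, (), dialect, path)
    records, rejected = [], []
    for lineno, cells in rows:
        try:
            records.append(
                {
                    "term": cells[pos["term"]].strip(),
                    "score": float(cells[pos["score"]]),
                    "rank": int(cells[pos["rank"]]),
                    "percentile": float(cells[pos["percentile"]]),
                }
            )
        except (ValueError, IndexError) as exc:
            rejected.append(RowIssue(lineno, f"unparseable ranking row: {exc}"))
    frame = pd.DataFrame(records, columns=list(RANKING_COLUMNS))
    validate_ranking(frame)
    return ParseResult(frame, rejected, metadata)


def write_ranking(ranking: pd.DataFrame, path, metadata: Mapping[str, str] | None = None) -> None:
    """Write a complete severity ranking sorted by rank (rank 1, most severe, first)."""
    validate_ranking(ranking)
    out = ranking.loc[:, list(RANKING_COLUMNS)].sort_values("rank")
    _write_tsv(out, path, metadata)


def read_outcome_table(path, dialect: Mapping[str, str] | None = None) -> ParseResult:
    """Read per-ADR adverse-event outcome counts (one column per category)."""
    header, rows, metadata = _read_rows(path)
    pos = _resolve_columns(header, ("adr", *OUTCOME_CATEGORIES), (), dialect, path)
    records, rejected = [], []
    for lineno, cells in rows:
        adr = cells[pos["adr"]].strip() if pos["adr"] < len(cells) else ""
        if not adr:
            rejected.append(RowIssue(lineno, "blank adr field"))
            continue
        rec = {"adr": adr}
        ok = True
        for cat in OUTCOME_CATEGORIES:
            try:
                count = int(cells[pos[cat]])
            except (ValueError, IndexError):
                rejected.append(RowIssue(lineno, f"bad count for {cat}"))
                ok = False
                break
            if count < 0:
                rejected.append(RowIssue(lineno, f"negative count for {cat}"))
                ok = False
                break
            rec[cat] = count
        if ok:
            records.append(rec)
    frame = pd.DataFrame(records, columns=["adr", *OUTCOME_CATEGORIES])
    return ParseResult(frame, rejected, metadata)


def write_outcome_table(frame: pd.DataFrame, path, metadata=None) -> None:
    _write_tsv(frame.loc[:, ["adr", *OUTCOME_CATEGORIES]], path, metadata)


def _write_tsv(frame: pd.DataFrame, path, metadata: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)
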