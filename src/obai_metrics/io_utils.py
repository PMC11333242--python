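"""File plumbing: text and wordlist readers, table readers/writers.

All text I/O is UTF-8; CRLF input is normalized to LF before tokenization.
Wordlist files hold one lowercase word per line ('#' comment lines and blank
lines are ignored).  Pair tables are CSV (RFC 4180, via pandas) or XLSX.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FileFormatError, MissingResource


def read_text(path: str | Path) -> str:
    """Read a UTF-8 plain-text document (tolerates a BOM)."""
    p = Path(path)
    try:
        return p.read_text(encoding="utf-8-sig")
    except FileNotFoundError as exc:
        raise FileFormatError(f"file not found: {p}") from exc
    except UnicodeDecodeError as exc:
        raise FileFormatError(f"{p} is not valid UTF-8 text: {exc}") from exc


def read_wordlist(path: str | Path) -> frozenset[str]:
    """Load a one-word-per-line wordlist, case-folded into a frozen set."""
    p = Path(path)
    if not p.exists():
        raise MissingResource(f"wordlist not found: {p}")
    words = set()
    for line in p.read_text(encoding="utf-8-sig").splitlines():
        w = line.strip().lower()
        if w and not w.startswith("#"):
            words.add(w)
    if not words:
        raise MissingResource(f"wordlist is empty: {p}")
    return frozenset(words)


def _bundled(name: str) -> frozenset[str]:
    ref = resources.files("obai_metrics.data").joinpath(name)
    words = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        w = line.strip().lower()
        if w and not w.startswith("#"):
            words.add(w)
    return frozenset(words)


@lru_cache(maxsize=1)
def load_easy_words() -> frozenset[str]:
    """The bundled easy-word list used by default for Dale-Chall scoring."""
    return _bundled("easy_words_synthetic.txt")


@lru_cache(maxsize=1)
def load_dictionary() -> frozenset[str]:
    """The bundled reference dictionary for neologism detection and lemma
    validation (easy words plus inflected and additional forms)."""
    return _bundled("dictionary_synthetic.txt") | load_easy_words()


def read_pairs_table(
    path: str | Path,
    target_col: str = "target",
    response_col: str = "response",
) -> pd.DataFrame:
    """Read a target/response pairs spreadsheet (CSV or XLSX).

    Raises :class:`FileFormatError` for unreadable files and
    :class:`SchemaError` (from the caller's validation) is left to
    :func:`obai_metrics.clinical_scoring.batch_score`.
    """
    p = Path(path)
    if not p.exists():
        raise FileFormatError(f"file not found: {p}")
    try:
        if p.suffix.lower() in (".xlsx", ".xlsm"):
            return pd.read_excel(p, dtype=str)
        return pd.read_csv(p, dtype=str, skip_blank_lines=False)
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"malformed table {p}: {exc}") from exc
    except ValueError as exc:
        raise FileFormatError(f"cannot read {p}: {exc}") from exc


def write_report(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> Path:
    """Write a report table as CSV, XLSX, or JSON (inferred from the suffix)."""
    p = Path(path)
    fmt = fmt or p.suffix.lstrip(".").lower() or "csv"
    if fmt == "csv":
        df.to_csv(p, index=False)
    elif fmt == "xlsx":
        df.to_excel(p, index=False)
    elif fmt == "json":
        p.write_text(json.dumps(df.to_dict(orient="records"), ensure_ascii=False, indent=1))
    else:
        raise FileFormatError(f"unsupported output format: {fmt!r}")
    return p


def write_json(obj, path: str | Path) -> Path:
    p = Path(path)
    p.write_text(json.dumps(obj, ensure_ascii=False, indent=1, default=float))
    return p
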