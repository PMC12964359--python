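"""Provenance tracking: versions and retrieval times of all input files.

Every file used in a run is recorded in a hidden JSON-lines ledger inside
the cache directory.  Fetched files carry a version string and a UTC
retrieval timestamp; user-provided files are recorded with version
"unknown" (their provenance cannot be known).  Each label keeps its full
history (latest first) so updates remain auditable, and content checksums —
not modification times — decide whether a reused file changed.

A fetcher plug-in point is defined (:class:`Fetcher`) for callers that
obtain files from remote databases; this package ships no network client.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Protocol, Union

logger = logging.getLogger(__name__)

LEDGER_NAME = ".provenance.jsonl"

USER_PROVIDED = "user-provided"
VERSION_UNKNOWN = "unknown"


class Fetcher(Protocol):
    """Plug-in interface for remote retrieval.

    Implementations download ``file_label`` into ``dest`` and return the
    version string of what they fetched; the caller records the result via
    :func:`record_file` with ``source`` set to the fetcher's label or URL.
    """

    def fetch(self, file_label: str, dest: Path) -> str: ...


def checksum_file(path: Union[str, Path]) -> str:
    """SHA-256 of a file's content, hex-encoded."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def default_ledger_path(cache_dir: Union[str, Path]) -> Path:
    return Path(cache_dir) / LEDGER_NAME


def _utc_now_iso() -> str:
    return datetime.datetime.now(datetime.timezone.utc).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )


def record_file(
    ledger_path: Union[str, Path],
    file_label: str,
    source: str,
    checksum: str,
    version: Optional[str] = None,
    retrieved_at: Optional[str] = None,
) -> dict:
    """Append a provenance record for ``file_label`` to the ledger.

    ``source`` is either ``"user-provided"`` or a fetcher label/URL.
    User-provided files get version "unknown" and no retrieval timestamp;
    fetched files get the given version and a UTC ISO-8601 timestamp
    (defaulting to now).  Prior records are untouched; a corrupt ledger is
    renamed aside and a fresh one started, with a warning.

    Returns the record written.
    """
    ledger_path = Path(ledger_path)
    ledger_path.parent.mkdir(parents=True, exist_ok=True)
    _repair_if_corrupt(ledger_path)

    if source == USER_PROVIDED:
        record = {
            "file_label": file_label,
            "source": source,
            "version": VERSION_UNKNOWN,
            "retrieved_at": None,
            "checksum": checksum,
        }
    else:
        if version is None:
            raise ValueError("fetched files must carry a version string")
        record = {
            "file_label": file_label,
            "source": source,
            "version": version,
            "retrieved_at": retrieved_at or _utc_now_iso(),
            "checksum": checksum,
        }
    with open(ledger_path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")
    return record


def record_input_file(
    ledger_path: Union[str, Path],
    file_label: str,
    path: Union[str, Path],
    source: str = USER_PROVIDED,
    version: Optional[str] = None,
) -> dict:
    """Record a file by path, computing its content checksum.

    If the label's latest record already carries the same checksum, the file
    is an unchanged reuse and no new record is appended.
    """
    digest = checksum_file(path)
    history = read_ledger(ledger_path).get(file_label)
    if history and history[0]["checksum"] == digest:
        logger.info("%s unchanged since last run (checksum match)", file_label)
        return history[0]
    return record_file(ledger_path, file_label, source, digest, version=version)


def _repair_if_corrupt(ledger_path: Path) -> None:
    if not ledger_path.exists():
        return
    try:
        with open(ledger_path) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    if "file_label" not in rec:
                        raise ValueError("record without file_label")
    except (json.JSONDecodeError, ValueError, UnicodeDecodeError):
        aside = ledger_path.with_suffix(ledger_path.suffix + ".corrupt")
        n = 0
        while aside.exists():
            n += 1
            aside = ledger_path.with_suffix(f"{ledger_path.suffix}.corrupt.{n}")
        ledger_path.rename(aside)
        logger.warning("corrupt provenance ledger moved to %s; starting fresh", aside)


def read_ledger(ledger_path: Union[str, Path]) -> dict[str, list[dict]]:
    """Read the ledger into label -> history (latest record first)."""
    ledger_path = Path(ledger_path)
    if not ledger_path.exists():
        return {}
    histories: dict[str, list[dict]] = {}
    with open(ledger_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError:
                logger.warning("skipping unreadable ledger line")
                continue
            histories.setdefault(rec["file_label"], []).insert(0, rec)
    return histories


def show_provenance(ledger_path: Union[str, Path]) -> str:
    """Human-readable report: one line per file label (latest record)."""
    histories = read_ledger(ledger_path)
    if not histories:
        return "no provenance records found\n"
    lines = []
    for label in sorted(histories):
        rec = histories[label][0]
        when = rec["retrieved_at"] or "user-provided"
        lines.append(
            f"{label}\tsource={rec['source']}\tversion={rec['version']}\t"
            f"retrieved={when}\tsha256={rec['checksum'][:12]}"
        )
    return "\n".join(lines) + "\n"
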