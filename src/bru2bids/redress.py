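"""Retroactive compliance editing for preexisting ParaVision studies.

Non-compliant operator input (underscores in subject ids, uninterpretable
scan names) is fixed by surgical line-level edits to the ``subject`` and
``ScanProgram.scanProgram`` files: the line *below* ``##$SUBJECT_id=``
(resp. ``##$SUBJECT_study_name=``) is replaced with the new ``<value>``,
and on each targeted scan-program line only the span between the
``<displayName>`` tag and the `` (E<n>)`` token is rewritten.  Untouched
lines stay byte-identical, so the files remain valid for ParaVision.
"""

from __future__ import annotations

import difflib
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from .metadata import ALNUM, ComplianceError, parse_instruction_name
from .study import _SCAN_PROGRAM_LINE

__all__ = [
    "RedressPlan",
    "RedressError",
    "redress_subject_file",
    "redress_scan_program",
    "preview",
    "apply_plan",
]


class RedressError(ValueError):
    pass


@dataclass
class RedressPlan:
    """A set of in-place edits rendering one study convertible."""

    study_path: Path
    new_subject: str | None = None
    new_session: str | None = None
    scan_renames: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.study_path = Path(self.study_path)
        for value, what in ((self.new_subject, "subject"), (self.new_session, "session")):
            if value is not None and not ALNUM.match(value):
                raise RedressError(
                    f"refusing non-alphanumeric {what} value {value!r}"
                )
        for number, name in self.scan_renames.items():
            try:
                parse_instruction_name(name)
            except ComplianceError as exc:
                raise RedressError(
                    f"rename for scan {number} is not BIDS-parseable: {exc}"
                ) from exc


def _unified_diff(old: list[str], new: list[str], label: str) -> str:
    return "".join(
        difflib.unified_diff(old, new, fromfile=f"a/{label}", tofile=f"b/{label}")
    )


def _edit_subject_lines(
    lines: list[str], new_subject: str | None, new_session: str | None
) -> list[str]:
    targets = []
    if new_subject is not None:
        targets.append(("##$SUBJECT_id=", new_subject))
    if new_session is not None:
        targets.append(("##$SUBJECT_study_name=", new_session))
    new_lines = list(lines)
    for needle, value in targets:
        hits = [i for i, line in enumerate(lines) if needle in line]
        if not hits:
            raise RedressError(f"key {needle.strip('#$=')} not found in subject file")
        index = hits[0] + 1
        if index >= len(lines):
            raise RedressError(f"no line below {needle!r} to edit")
        ending = "\n" if new_lines[index].endswith("\n") else ""
        new_lines[index] = f"<{value}>{ending}"
    return new_lines


def _edit_scan_program_lines(
    lines: list[str], scan_renames: dict[int, str]
) -> list[str]:
    pending = dict(scan_renames)
    new_lines = list(lines)
    for i, line in enumerate(lines):
        m = _SCAN_PROGRAM_LINE.search(line)
        if not m:
            continue
        number = int(m.group("number"))
        if number in pending:
            name = pending.pop(number)
            new_lines[i] = line[: m.start("name")] + name + line[m.end("name"):]
    if pending:
        raise RedressError(
            "no scan-program line found for scan number(s): "
            + ", ".join(str(n) for n in sorted(pending))
        )
    return new_lines


def _apply(
    path: Path,
    new_lines: list[str],
    old_lines: list[str],
    label: str,
    dry_run: bool,
    backup: bool,
) -> str:
    diff = _unified_diff(old_lines, new_lines, label)
    if diff and not dry_run:
        if backup:
            shutil.copy2(path, path.with_name(path.name + ".orig"))
        path.write_text("".join(new_lines), encoding="utf-8")
    return diff


def redress_subject_file(
    path: str | Path,
    new_subject: str | None,
    new_session: str | None,
    dry_run: bool = False,
    backup: bool = True,
) -> str:
    """Rewrite the subject/session value lines; returns the unified diff.

    Exactly one line per changed field is replaced (at most 2 in total);
    an unchanged value yields an empty diff and the file is not touched.
    Non-alphanumeric replacement values are refused before any write.
    """
    path = Path(path)
    for value, what in ((new_subject, "subject"), (new_session, "session")):
        if value is not None and not ALNUM.match(value):
            raise RedressError(f"refusing non-alphanumeric {what} value {value!r}")
    if not path.is_file():
        raise RedressError(f"{path}: no such file")
    old_lines = path.read_text(encoding="utf-8").splitlines(keepends=True)
    new_lines = _edit_subject_lines(old_lines, new_subject, new_session)
    return _apply(path, new_lines, old_lines, path.name, dry_run, backup)


def redress_scan_program(
    path: str | Path,
    scan_renames: dict[int, str],
    dry_run: bool = False,
    backup: bool = True,
) -> str:
    """Rewrite instruction names on the targeted scan-program lines.

    Changes exactly ``len(scan_renames)`` lines (fewer if a name already
    matches); errors listing the scan numbers for which no `` (E<n>)``
    line exists.
    """
    path = Path(path)
    for number, name in scan_renames.items():
        try:
            parse_instruction_name(name)
        except ComplianceError as exc:
            raise RedressError(
                f"rename for scan {number} is not BIDS-parseable: {exc}"
            ) from exc
    if not path.is_file():
        raise RedressError(f"{path}: no such file")
    old_lines = path.read_text(encoding="utf-8").splitlines(keepends=True)
    new_lines = _edit_scan_program_lines(old_lines, scan_renames)
    return _apply(path, new_lines, old_lines, path.name, dry_run, backup)


def preview(plan: RedressPlan) -> str:
    """Render the plan as a unified-diff patch without modifying anything."""
    return apply_plan(plan, dry_run=True)


def apply_plan(plan: RedressPlan, dry_run: bool = False, backup: bool = True) -> str:
    """Execute (or preview) a full redress plan; returns the combined patch."""
    patches = []
    if plan.new_subject is not None or plan.new_session is not None:
        patches.append(
            redress_subject_file(
                plan.study_path / "subject",
                plan.new_subject,
                plan.new_session,
                dry_run=dry_run,
                backup=backup,
            )
        )
    if plan.scan_renames:
        patches.append(
            redress_scan_program(
                plan.study_path / "ScanProgram.scanProgram",
                plan.scan_renames,
                dry_run=dry_run,
                backup=backup,
            )
        )
    return "".join(p for p in patches if p)
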