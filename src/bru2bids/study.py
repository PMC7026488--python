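"""Model of a ParaVision study directory and its scans.

A study lives in a directory named ``YYYYMMDD_HHMMSS_<...>`` and contains
a ``subject`` parameter file, usually a ``ScanProgram.scanProgram`` file,
and numbered scan subdirectories each holding ``acqp``, ``method`` and a
reconstruction under ``pdata/1/``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

from .jcampdx import ParameterDict, ParseError, parse_parameter_path

__all__ = [
    "ScanRecord",
    "StudyDirectory",
    "NotAStudyError",
    "load_study",
    "parse_scan_program",
    "parse_directory_timestamp",
    "find_studies",
]

logger = logging.getLogger(__name__)


class NotAStudyError(ValueError):
    """The directory does not look like a ParaVision study."""


# Instruction-name lines in ScanProgram.scanProgram look like
#   <displayName>acq-seEPI_task-rest_bold (E5)</displayName>
# the span before " (E" is the operator's free-field instruction name and
# the digits in the parenthesized token give the scan directory number.
_SCAN_PROGRAM_LINE = re.compile(r"<displayName>(?P<name>.*?) \(E(?P<number>\d+)\)")

# acqp fallback: ACQ_scan_name carries the same "name (E<n>)" string.
_SCAN_NAME = re.compile(r"^(?P<name>.*?) \(E(?P<number>\d+)\)$")

_TIMESTAMP = re.compile(r"^(\d{8})_(\d{6})(?:_|$)")


@dataclass
class ScanRecord:
    """One numbered scan with its parsed parameter files."""

    scan_number: int
    instruction_name: str
    sequence_name: str
    repetition_time: float | None  # seconds
    acqp: ParameterDict
    visu: ParameterDict | None
    data_path: Path | None  # pdata/1/2dseq when a reconstruction exists


@dataclass
class StudyDirectory:
    path: Path
    directory_name: str
    subject_file: ParameterDict
    scan_program_entries: list[tuple[int, str]] = field(default_factory=list)
    scans: list[ScanRecord] = field(default_factory=list)

    @property
    def timestamp(self) -> datetime | None:
        return parse_directory_timestamp(self.directory_name)


def parse_scan_program(text: str) -> list[tuple[int, str]]:
    """Extract ``(scan_number, instruction_name)`` pairs from a scan program.

    Returns an empty list when no line matches; callers fall back to the
    per-scan ``acqp`` files in that case.
    """
    entries = []
    for line in text.splitlines():
        m = _SCAN_PROGRAM_LINE.search(line)
        if m:
            entries.append((int(m.group("number")), m.group("name")))
    return entries


def parse_directory_timestamp(directory_name: str) -> datetime | None:
    """Decode the acquisition date/time a study directory name starts with.

    ``20171106_184345_21_1_1`` → 2017-11-06T18:43:45.  Returns ``None``
    (missing-timestamp marker) for non-conforming names; the study remains
    convertible, only the sessions-table onset is left blank.
    """
    m = _TIMESTAMP.match(directory_name)
    if not m:
        return None
    try:
        return datetime.strptime(m.group(1) + m.group(2), "%Y%m%d%H%M%S")
    except ValueError:
        return None


def _sequence_name(acqp: ParameterDict, method: ParameterDict | None) -> str:
    raw = acqp.get("ACQ_method")
    if raw is None and method is not None:
        raw = method.get("Method")
    if not isinstance(raw, str):
        return ""
    # ParaVision prefixes vendor sequences with "Bruker:"
    return raw.split(":", 1)[-1]


def _repetition_time(acqp: ParameterDict) -> float | None:
    tr = acqp.get("ACQ_repetition_time")
    if isinstance(tr, list):
        tr = tr[0] if tr else None
    if isinstance(tr, (int, float)) and tr > 0:
        return float(tr) / 1000.0  # ParaVision stores milliseconds
    return None


def load_study(path: str | Path) -> StudyDirectory:
    """Load a ParaVision study directory, enumerating scans ascending.

    Instruction names come from ``ScanProgram.scanProgram`` when readable
    and from each scan's ``acqp`` otherwise.  A scan whose name cannot be
    recovered from either source is skipped with a warning.
    """
    path = Path(path)
    subject_path = path / "subject"
    if not subject_path.is_file():
        raise NotAStudyError(f"{path}: no 'subject' parameter file")
    subject_file = parse_parameter_path(subject_path)

    program_entries: list[tuple[int, str]] = []
    program_path = path / "ScanProgram.scanProgram"
    if program_path.is_file():
        try:
            program_entries = parse_scan_program(
                program_path.read_text(encoding="utf-8", errors="replace")
            )
        except OSError as exc:  # pragma: no cover - unusual I/O failure
            logger.warning("%s: unreadable scan program (%s)", path, exc)
    by_number = dict(program_entries)

    scans: list[ScanRecord] = []
    scan_dirs = sorted(
        (int(p.name), p) for p in path.iterdir() if p.is_dir() and p.name.isdigit()
    )
    for number, scan_dir in scan_dirs:
        acqp_path = scan_dir / "acqp"
        try:
            acqp = parse_parameter_path(acqp_path)
        except (OSError, ParseError) as exc:
            if number in by_number:
                acqp = ParameterDict()
            else:
                logger.warning("skipping scan %s: unreadable acqp (%s)", scan_dir, exc)
                continue
        name = by_number.get(number)
        if name is None:
            raw = acqp.get("ACQ_scan_name")
            m = _SCAN_NAME.match(raw) if isinstance(raw, str) else None
            if m:
                name = m.group("name")
            elif isinstance(raw, str) and raw:
                name = raw
            else:
                logger.warning("skipping scan %s: no instruction name", scan_dir)
                continue
        method_path = scan_dir / "method"
        method = None
        if method_path.is_file():
            try:
                method = parse_parameter_path(method_path)
            except ParseError:
                method = None
        visu_path = scan_dir / "pdata" / "1" / "visu_pars"
        visu = parse_parameter_path(visu_path) if visu_path.is_file() else None
        data_path = scan_dir / "pdata" / "1" / "2dseq"
        scans.append(
            ScanRecord(
                scan_number=number,
                instruction_name=name,
                sequence_name=_sequence_name(acqp, method),
                repetition_time=_repetition_time(acqp),
                acqp=acqp,
                visu=visu,
                data_path=data_path if data_path.is_file() else None,
            )
        )
    return StudyDirectory(
        path=path,
        directory_name=path.name,
        subject_file=subject_file,
        scan_program_entries=program_entries,
        scans=scans,
    )


def find_studies(collection: str | Path) -> list[Path]:
    """List subdirectories of ``collection`` that contain a subject file."""
    collection = Path(collection)
    return sorted(
        p for p in collection.iterdir() if p.is_dir() and (p / "subject").is_file()
    )
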