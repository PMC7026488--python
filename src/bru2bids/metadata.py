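"""Turn operator free-field input into validated BIDS entities.

The operator encodes metadata in the scan "Instruction Name" as
underscore-separated ``key-value`` tokens with a trailing bare modality
suffix (e.g. ``acq-seEPI_task-rest_bold``), and subject/session come from
the study's ``subject`` parameter file.  Everything here is regex-driven
string work; scan categorization uses selector dictionaries mapping BIDS
field names to lists of accepted substrings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .jcampdx import ParameterDict
from .study import StudyDirectory

__all__ = [
    "BidsEntities",
    "ComplianceError",
    "ConfigurationError",
    "ALNUM",
    "ENTITY_KEYS",
    "SELECTOR_FIELDS",
    "CATEGORY_SUFFIXES",
    "parse_instruction_name",
    "extract_subject_session",
    "infer_modality_suffix",
    "build_metadata_table",
    "select_scans",
    "assign_run_numbers",
    "write_metadata_table",
]

logger = logging.getLogger(__name__)

ALNUM = re.compile(r"^[A-Za-z0-9]+$")

# BIDS 1.x raw-MRI short identifiers accepted in instruction names, in the
# order they must appear in file names.  'sub' and 'ses' are recognized but
# sourced from the subject file, never from the instruction name.
ENTITY_KEYS = ("sub", "ses", "task", "acq", "ce", "rec", "dir", "run", "echo")

KEY_TO_FIELD = {"sub": "subject", "ses": "session", "task": "task", "acq": "acq"}

# selector dictionaries use long BIDS field names
SELECTOR_FIELDS = {
    "subject": "subject",
    "session": "session",
    "task": "task",
    "acquisition": "acq",
    "acq": "acq",
    "suffix": "suffix",
    "sequence": "sequence",
}

CATEGORY_SUFFIXES = {
    "func": ("bold", "cbv"),
    "anat": ("T1w", "T2w"),
    "dwi": ("dwi",),
}


class ComplianceError(ValueError):
    """Operator input violates the naming constraints (alphanumeric only)."""


class ConfigurationError(ValueError):
    """A selector references an unknown BIDS field name."""


@dataclass
class BidsEntities:
    """Validated BIDS entities for one scan."""

    subject: str | None = None
    session: str | None = None
    task: str | None = None
    acq: str | None = None
    run: int | None = None
    suffix: str | None = None
    category: str | None = None  # anat | func | dwi
    extras: dict[str, str] = field(default_factory=dict)  # ce/rec/dir/echo

    def merged(self, **kwargs) -> "BidsEntities":
        return replace(self, **kwargs)


def _check_value(key: str, value: str, context: str) -> None:
    if not ALNUM.match(value):
        raise ComplianceError(
            f"{context}: value {value!r} for {key!r} must be purely alphanumeric "
            "(underscores and hyphens are BIDS field separators)"
        )


def parse_instruction_name(name: str) -> BidsEntities:
    """Parse an operator instruction name into partial BIDS entities.

    Tokens are underscore-separated.  Each ``key-value`` token maps a BIDS
    short identifier to a value; a single trailing bare token is the
    modality suffix.  A bare token anywhere else, or a value containing
    non-alphanumeric characters, is a :class:`ComplianceError`.  Unknown
    short identifiers are ignored with a warning.
    """
    if not name:
        raise ComplianceError("empty instruction name")
    entities = BidsEntities()
    tokens = name.split("_")
    for position, token in enumerate(tokens):
        is_last = position == len(tokens) - 1
        if "-" in token:
            key, _, value = token.partition("-")
            if key not in ENTITY_KEYS:
                logger.warning(
                    "instruction %r: unknown identifier %r ignored", name, key
                )
                continue
            _check_value(key, value, f"instruction {name!r}, token {token!r}")
            if key == "run":
                entities.run = int(value) if value.isdigit() else None
            elif key in KEY_TO_FIELD:
                setattr(entities, KEY_TO_FIELD[key], value)
            else:
                entities.extras[key] = value
        elif is_last:
            _check_value("suffix", token, f"instruction {name!r}")
            entities.suffix = token
        else:
            raise ComplianceError(
                f"instruction {name!r}: bare token {token!r} before the suffix "
                "position is not a legal entity"
            )
    return entities


def extract_subject_session(subject_file: ParameterDict) -> tuple[str, str]:
    """Read (subject, session) from a parsed ``subject`` parameter file.

    Sourced from ``SUBJECT_id`` and ``SUBJECT_study_name`` — never from
    the study directory name.  Both values must be purely alphanumeric.
    """
    source = subject_file.source_path or "subject file"
    values = []
    for key in ("SUBJECT_id", "SUBJECT_study_name"):
        value = subject_file.get(key)
        if value is None:
            raise ComplianceError(f"{source}: missing required key {key}")
        value = str(value)
        if not ALNUM.match(value):
            raise ComplianceError(
                f"{source}: {key} value {value!r} is not alphanumeric; "
                "redress the study to a compliant identifier first"
            )
        values.append(value)
    return values[0], values[1]


def infer_modality_suffix(sequence_name: str, entities: BidsEntities) -> BidsEntities:
    """Fill in the modality suffix from the pulse sequence when unambiguous.

    An explicit operator suffix always wins.  FLASH-family sequences map
    to ``T1w`` and RARE-family (TurboRARE) to ``T2w``; anything else stays
    undetermined and the scan is later excluded with a logged reason.
    """
    if entities.suffix:
        return entities
    sequence = (sequence_name or "").upper()
    if "FLASH" in sequence:
        return entities.merged(suffix="T1w")
    if "RARE" in sequence:
        return entities.merged(suffix="T2w")
    return entities


_COLUMNS = [
    "study_path",
    "study_name",
    "scan_number",
    "subject",
    "session",
    "task",
    "acq",
    "run",
    "suffix",
    "category",
    "sequence",
    "acq_time",
    "repetition_time",
    "instruction_name",
]


def build_metadata_table(studies: list[StudyDirectory]) -> pd.DataFrame:
    """Build the tabular record of every candidate scan.

    One row per scan whose operator input parses cleanly; non-compliant
    studies or scans are skipped with a warning (redress exists for them).
    This table is what gets persisted in the work directory for debugging.
    """
    rows = []
    for study in studies:
        try:
            subject, session = extract_subject_session(study.subject_file)
        except ComplianceError as exc:
            logger.warning("skipping study %s: %s", study.path, exc)
            continue
        timestamp = study.timestamp
        for scan in study.scans:
            try:
                entities = parse_instruction_name(scan.instruction_name)
            except ComplianceError as exc:
                logger.warning(
                    "skipping scan %s/%s: %s", study.path, scan.scan_number, exc
                )
                continue
            entities = infer_modality_suffix(scan.sequence_name, entities)
            rows.append(
                {
                    "study_path": str(study.path),
                    "study_name": study.directory_name,
                    "scan_number": scan.scan_number,
                    "subject": subject,
                    "session": session,
                    "task": entities.task,
                    "acq": entities.acq,
                    "run": None,
                    "suffix": entities.suffix,
                    "category": None,
                    "sequence": scan.sequence_name,
                    "acq_time": timestamp.isoformat() if timestamp else None,
                    "repetition_time": scan.repetition_time,
                    "instruction_name": scan.instruction_name,
                }
            )
    table = pd.DataFrame(rows, columns=_COLUMNS)
    return table.sort_values(["study_name", "scan_number"]).reset_index(drop=True)


def select_scans(
    table: pd.DataFrame, selector: dict[str, list[str]], category: str
) -> pd.DataFrame:
    """Filter the metadata table with a selector dictionary.

    A row matches when, for every selector field, its value contains at
    least one accepted string as a substring (Fig-3-style: ``"EPI"``
    selects ``acq-seEPI`` scans).  Matching rows are labeled with
    ``category``; rows whose suffix is undetermined or incompatible with
    the category are dropped with a logged reason.
    """
    if category not in CATEGORY_SUFFIXES:
        raise ConfigurationError(f"unknown scan category {category!r}")
    if table.empty:
        return table.copy()
    mask = pd.Series(True, index=table.index)
    for fieldname, accepted in selector.items():
        if fieldname not in SELECTOR_FIELDS:
            raise ConfigurationError(
                f"unknown selector field {fieldname!r}; known fields: "
                + ", ".join(sorted(SELECTOR_FIELDS))
            )
        column = SELECTOR_FIELDS[fieldname]
        accepted = [str(a) for a in accepted]
        mask &= table[column].map(
            lambda v: isinstance(v, str) and any(a in v for a in accepted)
        )
    selected = table[mask].copy()
    allowed = CATEGORY_SUFFIXES[category]
    keep = []
    for _, row in selected.iterrows():
        if row["suffix"] is None:
            logger.info(
                "excluding %s scan %s: modality suffix undetermined",
                row["study_name"],
                row["scan_number"],
            )
            keep.append(False)
        elif row["suffix"] not in allowed:
            logger.info(
                "excluding %s scan %s: suffix %r not valid for %s",
                row["study_name"],
                row["scan_number"],
                row["suffix"],
                category,
            )
            keep.append(False)
        else:
            keep.append(True)
    selected = selected[pd.Series(keep, index=selected.index, dtype=bool)].copy()
    selected["category"] = category
    return selected


def assign_run_numbers(table: pd.DataFrame, base: int = 0) -> pd.DataFrame:
    """Assign run ordinals within each (subject, session, task, acq, suffix).

    Rows sorted by scan number receive ``base, base+1, ...``; the run
    entity is always emitted, even for singleton groups, so file names
    glob uniformly.
    """
    if table.empty:
        return table.copy()
    table = table.sort_values(["subject", "session", "scan_number"]).copy()
    key_frame = table[["subject", "session", "task", "acq", "suffix"]].fillna("")
    keys = [key_frame[column] for column in key_frame.columns]
    table["run"] = table.groupby(keys, sort=False).cumcount() + base
    return table.reset_index(drop=True)


def write_metadata_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Persist the work-directory record as tab-separated text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path
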