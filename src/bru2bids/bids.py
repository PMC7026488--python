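"""Emit the BIDS directory hierarchy: names, sidecars, stubs, boilerplate.

Also ships a lightweight internal tree check (naming grammar, entity
order, sidecar presence, dataset_description) — a desk-scale stand-in for
the external Node-based BIDS validator, which remains the authoritative
check and is pointed to on pipeline completion.
"""

from __future__ import annotations

import json
import re
from datetime import datetime
from pathlib import Path

from .metadata import BidsEntities, CATEGORY_SUFFIXES
from .study import ScanRecord

__all__ = [
    "BIDS_VERSION",
    "compose_bids_path",
    "build_sidecar",
    "write_sidecar",
    "write_events_stub",
    "write_sessions_tsv",
    "write_dataset_description",
    "write_participants",
    "validate_tree",
]

BIDS_VERSION = "1.4.0"

# entity order after sub/ses, suffix always last
_ORDER = ("task", "acq", "ce", "rec", "dir", "run", "echo")
_LABEL = re.compile(r"^[A-Za-z0-9]+$")


class BidsNamingError(ValueError):
    pass


def compose_bids_path(entities: BidsEntities, extension: str) -> str:
    """Build the relative BIDS path for a scan.

    ``sub-<S>/ses-<E>/<category>/sub-<S>_ses-<E>[_task-..][_acq-..]
    [_run-..]_<suffix><extension>`` with the fixed BIDS entity order.
    """
    for mandatory in ("subject", "session", "suffix", "category"):
        if not getattr(entities, mandatory):
            raise BidsNamingError(f"missing mandatory entity {mandatory!r}")
    pairs = [("sub", entities.subject), ("ses", entities.session)]
    values = {
        "task": entities.task,
        "acq": entities.acq,
        "run": str(entities.run) if entities.run is not None else None,
        **entities.extras,
    }
    for key in _ORDER:
        value = values.get(key)
        if value is not None:
            pairs.append((key, value))
    for key, value in pairs:
        if not _LABEL.match(str(value)):
            raise BidsNamingError(f"illegal {key} label {value!r}")
    stem = "_".join(f"{k}-{v}" for k, v in pairs) + f"_{entities.suffix}"
    return (
        f"sub-{entities.subject}/ses-{entities.session}/"
        f"{entities.category}/{stem}{extension}"
    )


def _json_dump(payload: dict, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(payload, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return path


# ACQ_scan_name is deliberately not passed through: redressed studies keep
# their original acqp free text, and sidecars must match natively compliant
# conversions byte for byte.
_PASSTHROUGH_ACQP = ("ACQ_method", "ACQ_protocol_name")
_PASSTHROUGH_VISU = ("VisuCoreWordType", "VisuCoreFrameCount", "VisuCoreSize")


def build_sidecar(scan: ScanRecord, entities: BidsEntities) -> dict:
    """Assemble sidecar metadata in BIDS canonical units (seconds)."""
    sidecar: dict = {"Manufacturer": "Bruker"}
    tr = None
    if scan.visu is not None:
        tr_ms = scan.visu.get("VisuAcqRepetitionTime")
        if isinstance(tr_ms, list):
            tr_ms = tr_ms[0] if tr_ms else None
        if isinstance(tr_ms, (int, float)) and tr_ms > 0:
            tr = float(tr_ms) / 1000.0
        te_ms = scan.visu.get("VisuAcqEchoTime")
        if isinstance(te_ms, list):
            te_ms = te_ms[0] if te_ms else None
        if isinstance(te_ms, (int, float)) and te_ms > 0:
            sidecar["EchoTime"] = float(te_ms) / 1000.0
    if tr is None:
        tr = scan.repetition_time
    if tr is not None:
        sidecar["RepetitionTime"] = tr
    if scan.sequence_name:
        sidecar["PulseSequenceType"] = scan.sequence_name
    if entities.category == "func" and entities.task:
        sidecar["TaskName"] = entities.task
    vendor = {}
    for key in _PASSTHROUGH_ACQP:
        if key in scan.acqp:
            vendor[key] = scan.acqp[key]
    if scan.visu is not None:
        for key in _PASSTHROUGH_VISU:
            if key in scan.visu:
                vendor[key] = scan.visu[key]
    if vendor:
        sidecar["BrukerParaVision"] = vendor
    return sidecar


def write_sidecar(scan: ScanRecord, entities: BidsEntities, path: str | Path) -> Path:
    return _json_dump(build_sidecar(scan, entities), Path(path))


def write_events_stub(path: str | Path) -> Path:
    """Write an empty events table (header only) next to a functional scan."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("onset\tduration\n", encoding="utf-8")
    return path


def write_sessions_tsv(
    bids_root: str | Path,
    subject: str,
    sessions: list[tuple[str, datetime | None]],
) -> Path | None:
    """Write ``sub-<S>/sub-<S>_sessions.tsv`` with ISO-8601 onsets.

    Rows are sorted by acquisition time (missing times last, blank cell).
    Nothing is written for a subject without convertible sessions.
    """
    if not sessions:
        return None
    bids_root = Path(bids_root)
    sessions = sorted(
        set(sessions), key=lambda item: (item[1] is None, item[1] or datetime.min, item[0])
    )
    lines = ["session_id\tacq_time"]
    for session, acq_time in sessions:
        stamp = acq_time.isoformat() if acq_time else ""
        lines.append(f"ses-{session}\t{stamp}")
    path = bids_root / f"sub-{subject}" / f"sub-{subject}_sessions.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_dataset_description(bids_root: str | Path, name: str) -> Path:
    return _json_dump(
        {"Name": name, "BIDSVersion": BIDS_VERSION},
        Path(bids_root) / "dataset_description.json",
    )


def write_participants(bids_root: str | Path, subjects: list[str]) -> Path:
    lines = ["participant_id"] + [f"sub-{s}" for s in sorted(set(subjects))]
    path = Path(bids_root) / "participants.tsv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


_TOP_LEVEL_FILES = {
    "dataset_description.json",
    "participants.tsv",
    "participants.json",
    "README",
    "CHANGES",
    "LICENSE",
}
_SUFFIX_CATEGORY = {
    suffix: category
    for category, suffixes in CATEGORY_SUFFIXES.items()
    for suffix in suffixes
}


def _check_stem(stem: str, violations: list[str], context: str) -> dict | None:
    tokens = stem.split("_")
    if len(tokens) < 2:
        violations.append(f"{context}: no entities before suffix")
        return None
    entities: dict[str, str] = {}
    order = ("sub", "ses", *_ORDER)
    last_index = -1
    ok = True
    for token in tokens[:-1]:
        key, sep, value = token.partition("-")
        if not sep or key not in order:
            violations.append(f"{context}: bare or unknown token {token!r}")
            ok = False
            continue
        if not _LABEL.match(value):
            violations.append(f"{context}: illegal label in token {token!r}")
            ok = False
        index = order.index(key)
        if index <= last_index:
            violations.append(f"{context}: entity {key!r} out of order")
            ok = False
        last_index = index
        entities[key] = value
    suffix = tokens[-1]
    if not _LABEL.match(suffix):
        violations.append(f"{context}: illegal suffix {suffix!r}")
        ok = False
    entities["suffix"] = suffix
    if "sub" not in entities:
        violations.append(f"{context}: missing sub entity")
        ok = False
    return entities if ok else None


def validate_tree(bids_root: str | Path) -> list[str]:
    """Check a BIDS tree's naming grammar and file pairing.

    Returns a list of human-readable violations; an empty list means the
    tree passes this internal check.  Hidden entries (dot-prefixed, e.g.
    the default work directory) are skipped, as the external validator
    does.
    """
    bids_root = Path(bids_root)
    violations: list[str] = []
    if not (bids_root / "dataset_description.json").is_file():
        violations.append("missing dataset_description.json")
    else:
        try:
            desc = json.loads(
                (bids_root / "dataset_description.json").read_text(encoding="utf-8")
            )
            for key in ("Name", "BIDSVersion"):
                if key not in desc:
                    violations.append(f"dataset_description.json: missing {key}")
        except json.JSONDecodeError:
            violations.append("dataset_description.json: invalid JSON")

    for entry in sorted(bids_root.iterdir()) if bids_root.is_dir() else []:
        if entry.name.startswith("."):
            continue
        if entry.is_file() and entry.name not in _TOP_LEVEL_FILES:
            violations.append(f"unexpected top-level file {entry.name}")
        if entry.is_dir() and not entry.name.startswith("sub-"):
            violations.append(f"unexpected top-level directory {entry.name}")

    for nifti in sorted(bids_root.rglob("*.nii.gz")):
        rel = nifti.relative_to(bids_root)
        context = str(rel)
        stem = nifti.name[: -len(".nii.gz")]
        entities = _check_stem(stem, violations, context)
        parts = rel.parts
        if len(parts) != 4 or not (
            parts[0].startswith("sub-") and parts[1].startswith("ses-")
        ):
            violations.append(f"{context}: not under sub-*/ses-*/<category>/")
            continue
        category = parts[2]
        if category not in CATEGORY_SUFFIXES:
            violations.append(f"{context}: unknown category directory {category!r}")
        if entities:
            if f"sub-{entities['sub']}" != parts[0]:
                violations.append(f"{context}: sub entity disagrees with directory")
            if entities.get("ses") and f"ses-{entities['ses']}" != parts[1]:
                violations.append(f"{context}: ses entity disagrees with directory")
            expected = _SUFFIX_CATEGORY.get(entities["suffix"])
            if expected and expected != category:
                violations.append(
                    f"{context}: suffix {entities['suffix']!r} belongs in "
                    f"{expected}/, found in {category}/"
                )
        sidecar = nifti.with_name(stem + ".json")
        if not sidecar.is_file():
            violations.append(f"{context}: missing sidecar JSON")
        if entities and entities["suffix"] in CATEGORY_SUFFIXES["func"]:
            events = nifti.with_name(stem[: stem.rfind("_")] + "_events.tsv")
            if not events.is_file():
                violations.append(f"{context}: missing events stub")
    return violations
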