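"""Reader/writer for Bruker ParaVision parameter files.

ParaVision stores acquisition metadata (``subject``, ``acqp``, ``method``,
``visu_pars``) in a JCAMP-DX-like plain-text dialect::

    ##TITLE=Parameter List          (bare header, kept but not interpreted)
    ##$SUBJECT_id=( 60 )            (array-size header; value on next line)
    <Mc365A>
    ##$ACQ_size=( 2 )
    128 64
    ##$ACQ_repetition_time=1000     (scalar on the same line)
    $$ anything                     (comment, ignored)
    ##END=

Only the subset of the dialect that ParaVision 6.x emits for these four
file types is supported; compound data tables and audit trails are not.
The :func:`dumps` serializer is the authority for the dialect this package
guarantees: anything it writes, :func:`parse_parameter_file` reads back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

__all__ = [
    "ParameterDict",
    "ParseError",
    "DuplicateKeyError",
    "parse_parameter_file",
    "parse_parameter_path",
    "dumps",
]

Scalar = Union[int, float, str]
Value = Union[Scalar, list]


class ParseError(ValueError):
    """Raised when a parameter file cannot be interpreted."""


class DuplicateKeyError(ParseError):
    """Raised when the same ``##$`` key appears twice in one file."""


@dataclass
class ParameterDict:
    """Parsed content of one ParaVision parameter file.

    ``entries`` maps the text between ``##$`` and ``=`` to its value:
    a scalar (int, float or ``<>``-stripped string) or a flat list of
    such scalars.  Bare ``##NAME=`` headers land in ``headers`` and are
    never interpreted.
    """

    entries: dict[str, Value] = field(default_factory=dict)
    headers: dict[str, str] = field(default_factory=dict)
    source_path: Path | None = None

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> Value:
        return self.entries[key]

    def get(self, key: str, default: Value | None = None) -> Value | None:
        return self.entries.get(key, default)


_SIZE_HEADER = re.compile(r"^\(\s*(\d+)(?:\s*,\s*(\d+))*\s*\)\s*$")
_TOKEN = re.compile(r"<[^>]*>|\S+")
_INT = re.compile(r"^[+-]?\d+$")
_FLOAT = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _coerce(token: str) -> Scalar:
    if token.startswith("<") and token.endswith(">"):
        return token[1:-1]
    if _INT.match(token):
        return int(token)
    if _FLOAT.match(token):
        return float(token)
    return token


def _tokenize(text: str) -> Value:
    tokens = [_coerce(t) for t in _TOKEN.findall(text)]
    if not tokens:
        return ""
    if len(tokens) == 1:
        return tokens[0]
    return tokens


def parse_parameter_file(text: str, source_path: Path | None = None) -> ParameterDict:
    """Parse raw parameter-file content into a :class:`ParameterDict`.

    A ``##$KEY=`` line with a value on the same line yields a scalar (or a
    list if several whitespace-separated tokens follow).  A ``( n )`` /
    ``( n, m )`` size header is consumed — not stored — and the value is
    gathered from the following lines, joined with single spaces, until
    the next ``##`` or ``$$`` line.  ``<...>`` spans become strings with
    the delimiters stripped.

    Raises
    ------
    DuplicateKeyError
        If a ``##$`` key occurs more than once.
    ParseError
        On a malformed size header (names the 1-based line number).
    """
    result = ParameterDict(source_path=source_path)
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        stripped = line.strip()
        if not stripped or stripped.startswith("$$"):
            i += 1
            continue
        if stripped.startswith("##$"):
            body = stripped[3:]
            if "=" not in body:
                raise ParseError(f"line {i + 1}: missing '=' in parameter line")
            key, _, rest = body.partition("=")
            key = key.strip()
            if key in result.entries:
                raise DuplicateKeyError(f"line {i + 1}: duplicate key {key!r}")
            rest = rest.strip()
            if rest.startswith("("):
                if not _SIZE_HEADER.match(rest):
                    raise ParseError(
                        f"line {i + 1}: malformed array size header {rest!r}"
                    )
                chunks: list[str] = []
                i += 1
                while i < n:
                    nxt = lines[i].strip()
                    if nxt.startswith("##") or nxt.startswith("$$"):
                        break
                    if nxt:
                        chunks.append(nxt)
                    i += 1
                result.entries[key] = _tokenize(" ".join(chunks))
                continue
            result.entries[key] = _tokenize(rest)
            i += 1
            continue
        if stripped.startswith("##"):
            name, _, value = stripped[2:].partition("=")
            result.headers[name.strip()] = value.strip()
            i += 1
            continue
        # stray continuation outside an array context: tolerated, ignored
        i += 1
    return result


def parse_parameter_path(path: str | Path) -> ParameterDict:
    path = Path(path)
    return parse_parameter_file(path.read_text(encoding="utf-8"), source_path=path)


def _format_scalar(value: Scalar) -> str:
    if isinstance(value, str):
        return f"<{value}>"
    return repr(value)


def dumps(params: ParameterDict | dict, title: str = "Parameter List") -> str:
    """Serialize parameters in the ParaVision dialect this package reads.

    Strings are always written as ``<...>`` on the line *below* a ``( n )``
    size header (matching how ParaVision stores ``SUBJECT_id`` and friends,
    which the redress procedure relies on).  Numeric scalars stay on the
    ``##$KEY=`` line; lists get a size header and wrapped value lines.

    Note: one-element lists serialize identically to scalars and therefore
    parse back as scalars; callers should pass scalars for length-1 data.
    """
    if isinstance(params, ParameterDict):
        headers = dict(params.headers)
        entries = params.entries
    else:
        headers = {}
        entries = params
    out: list[str] = []
    out.append(f"##TITLE={title}")
    out.append("##JCAMPDX=4.24")
    for name, value in headers.items():
        if name in ("TITLE", "JCAMPDX", "END"):
            continue
        out.append(f"##{name}={value}")
    for key, value in entries.items():
        if isinstance(value, str):
            size = max(64, len(value) + 1)
            out.append(f"##${key}=( {size} )")
            out.append(f"<{value}>")
        elif isinstance(value, (list, tuple)):
            out.append(f"##${key}=( {len(value)} )")
            line = ""
            for item in value:
                tok = _format_scalar(item)
                if line and len(line) + len(tok) + 1 > 70:
                    out.append(line)
                    line = tok
                else:
                    line = f"{line} {tok}".strip()
            if line:
                out.append(line)
        else:
            out.append(f"##${key}={_format_scalar(value)}")
    out.append("##END=")
    return "\n".join(out) + "\n"
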