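"""ICD code sets and prefix matching.

An ICD prefix family (e.g. ``J44*``) denotes a code and all of its children.
Matching is performed on dot-stripped codes: entry ``491.2`` matches
``491.2``, ``491.20`` and ``491.21``; entry ``496`` matches ``496`` and
``496.0``.  After the prefix, only further digits are accepted, so malformed
strings such as ``491.29x`` are rejected rather than swept into a family.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

VALID_SYSTEMS = ("ICD9", "ICD10")


def _strip(code: str) -> str:
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeSet:
    """A named family of (system, dotted ICD prefix) entries."""

    name: str
    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for system, prefix in self.entries:
            if system not in VALID_SYSTEMS:
                raise ValueError(f"codeset {self.name!r}: unknown system {system!r}")
            if not prefix or not prefix.strip():
                raise ValueError(f"codeset {self.name!r}: empty prefix")
            if (system, prefix) in seen:
                raise ValueError(f"codeset {self.name!r}: duplicate entry {(system, prefix)}")
            seen.add((system, prefix))

    def stripped_entries(self) -> list[tuple[str, str]]:
        return [(system, _strip(prefix)) for system, prefix in self.entries]


def match_code(code: str, system: str, codeset: CodeSet) -> bool:
    """True iff ``code`` (in ``system``) belongs to one of the codeset's families.

    Pure predicate: a prefix entry matches when, after stripping dots, it is a
    prefix of the code and every remaining character is a digit.
    """
    if not code or not code.strip():
        return False
    stripped = _strip(code)
    for entry_system, entry in codeset.stripped_entries():
        if entry_system != system:
            continue
        if stripped == entry:
            return True
        if stripped.startswith(entry) and stripped[len(entry):].isdigit():
            return True
    return False


def load_codesets(path: str | Path | None = None) -> dict[str, CodeSet]:
    """Load named code sets from YAML (the shipped defaults when path is None)."""
    if path is None:
        text = resources.files("phenocopd.configs").joinpath("codesets.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["codesets"]
    return {
        name: CodeSet(name=name, entries=tuple((sys_, str(pref)) for sys_, pref in entries))
        for name, entries in raw.items()
    }
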