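"""Taxon naming standard, FASTA renaming and reversible alias numbering.

Every sequence in the pipeline carries a name of the form

    ``XX_yy_zzzz_<uid>``

where ``XX`` is a two-letter major-clade code (e.g. ``Op`` for
Opisthokonta, ``Ba`` for bacteria), ``yy`` a two-letter subclade code,
``zzzz`` a four-letter taxon code, and ``<uid>`` any token unique within
the dataset (a GI number, a transcriptome contig id, ...).  ``Homo
sapiens`` sequences are thus labelled ``Op_me_hsap_<uid>``.  The strict
standard makes alignments and trees scannable by eye and lets downstream
stages (contamination screening, ortholog selection) reason about clade
membership directly from leaf labels.

Because many third-party tools truncate long names, :func:`alias_numbering`
replaces names with short integer tokens and keeps a key so
:func:`restore_names` can reverse the substitution exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "NamingError",
    "TaxonCode",
    "SequenceName",
    "DomainTable",
    "NameKey",
    "parse_name",
    "rename_fasta",
    "alias_numbering",
    "restore_names",
    "DEFAULT_DOMAIN_TABLE",
]


class NamingError(ValueError):
    """A sequence name does not follow the 2+2+4 code standard."""


_CODE_RE = re.compile(r"^[A-Za-z]{2}$")
_TAXON_RE = re.compile(r"^[A-Za-z0-9]{4}$")


@dataclass(frozen=True, order=True)
class TaxonCode:
    """2-letter major clade + 2-letter subclade + 4-letter taxon code."""

    major_clade: str
    subclade: str
    taxon: str

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.major_clade):
            raise NamingError(f"bad major-clade code {self.major_clade!r} (need 2 letters)")
        if not _CODE_RE.match(self.subclade):
            raise NamingError(f"bad subclade code {self.subclade!r} (need 2 letters)")
        if not _TAXON_RE.match(self.taxon):
            raise NamingError(f"bad taxon code {self.taxon!r} (need 4 alphanumerics)")

    @property
    def prefix(self) -> str:
        """The 10-character ``XX_yy_zzzz`` taxon-level prefix."""
        return f"{self.major_clade}_{self.subclade}_{self.taxon}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.prefix


@dataclass(frozen=True, order=True)
class SequenceName:
    """A taxon code plus a dataset-unique sequence identifier."""

    code: TaxonCode
    uid: str

    def __post_init__(self) -> None:
        if not self.uid:
            raise NamingError("empty uid")

    def render(self) -> str:
        return f"{self.code.prefix}_{self.uid}"

    def __str__(self) -> str:
        return self.render()


def parse_name(raw: str) -> SequenceName:
    """Parse ``Op_me_hsap_12345`` into a :class:`SequenceName`.

    The first three underscore-separated fields are the taxon code; the
    remainder (which may itself contain underscores) is the uid.
    """
    if not raw:
        raise NamingError("empty sequence name")
    parts = raw.split("_")
    if len(parts) < 4:
        raise NamingError(f"name {raw!r}: expected XX_yy_zzzz_<uid> (got {len(parts)} fields)")
    major, sub, taxon = parts[0], parts[1], parts[2]
    uid = "_".join(parts[3:])
    try:
        code = TaxonCode(major, sub, taxon)
    except NamingError as exc:
        raise NamingError(f"name {raw!r}: {exc}") from exc
    if not uid:
        raise NamingError(f"name {raw!r}: empty uid")
    return SequenceName(code, uid)


def taxon_prefix(raw: str) -> str:
    """Taxon-level ``XX_yy_zzzz`` prefix of a full sequence name."""
    return parse_name(raw).code.prefix


# ---------------------------------------------------------------------------
# Domain table


class DomainTable:
    """Maps major-clade codes to domains and clade labels.

    Lookups of unknown codes fail fast: a dataset with an unregistered
    code is a curation error, not something to paper over with a default.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self._entries = {k: (d, c) for k, (d, c) in entries.items()}
        for code, (domain, _label) in self._entries.items():
            if domain not in ("eukaryote", "bacteria", "archaea"):
                raise ValueError(f"unknown domain {domain!r} for code {code!r}")

    def domain(self, major_clade: str) -> str:
        try:
            return self._entries[major_clade][0]
        except KeyError:
            raise NamingError(f"major-clade code {major_clade!r} not in domain table") from None

    def clade_label(self, major_clade: str) -> str:
        try:
            return self._entries[major_clade][1]
        except KeyError:
            raise NamingError(f"major-clade code {major_clade!r} not in domain table") from None

    def domain_of_name(self, raw: str) -> str:
        return self.domain(parse_name(raw).code.major_clade)

    def __contains__(self, major_clade: str) -> bool:
        return major_clade in self._entries

    def codes(self) -> list[str]:
        return sorted(self._entries)

    def validate(self, names: Iterable[str]) -> None:
        """Ensure every name parses and every major clade is registered."""
        for raw in names:
            self.domain_of_name(raw)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainTable":
        entries: dict[str, tuple[str, str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, domain, label = line.split("\t")
            entries[code] = (domain, label)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{c}\t{d}\t{l}" for c, (d, l) in sorted(self._entries.items())]
        Path(path).write_text("\n".join(lines) + "\n")


#: Five putative major eukaryotic clades plus bacteria and archaea.
DEFAULT_DOMAIN_TABLE = DomainTable(
    {
        "Am": ("eukaryote", "Amoebozoa"),
        "Ex": ("eukaryote", "Excavata"),
        "Op": ("eukaryote", "Opisthokonta"),
        "Pl": ("eukaryote", "Plantae"),
        "Sr": ("eukaryote", "SAR"),
        "EE": ("eukaryote", "orphan"),
        "Ba": ("bacteria", "Bacteria"),
        "Za": ("archaea", "Archaea"),
    }
)


# ---------------------------------------------------------------------------
# FASTA renaming


@dataclass
class RenameReport:
    renamed: int = 0
    skipped: int = 0
    skipped_names: list[str] = field(default_factory=list)


def rename_fasta(
    records: Iterable[tuple[str, str]],
    mapping: Mapping[str, SequenceName | str],
    policy: str = "fail",
) -> tuple[list[tuple[str, str]], RenameReport]:
    """Rename ``(name, sequence)`` records via ``mapping``.

    ``policy`` is ``"fail"`` (unmapped name raises) or ``"skip"``
    (record passed through unchanged and counted).
    """
    if policy not in ("fail", "skip"):
        raise ValueError(f"policy must be 'fail' or 'skip', got {policy!r}")
    out: list[tuple[str, str]] = []
    report = RenameReport()
    for name, seq in records:
        if name in mapping:
            new = mapping[name]
            out.append((str(new), seq))
            report.renamed += 1
        elif policy == "skip":
            out.append((name, seq))
            report.skipped += 1
            report.skipped_names.append(name)
        else:
            raise NamingError(f"no mapping for record {name!r}")
    return out, report


# ---------------------------------------------------------------------------
# Alias numbering


class NameKey:
    """Bijection between integer alias tokens and full sequence names."""

    def __init__(self, alias_to_name: Mapping[int, str]):
        self._fwd = dict(alias_to_name)
        self._rev = {v: k for k, v in self._fwd.items()}
        if len(self._rev) != len(self._fwd):
            raise NamingError("name key is not a bijection (duplicate names)")

    def name(self, alias: int) -> str:
        return self._fwd[alias]

    def alias(self, name: str) -> int:
        return self._rev[name]

    def __len__(self) -> int:
        return len(self._fwd)

    def items(self):
        return sorted(self._fwd.items())

    def write(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{a}\t{n}\n" for a, n in self.items()))

    @classmethod
    def read(cls, path: str | Path) -> "NameKey":
        entries: dict[int, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            alias, name = line.split("\t", 1)
            entries[int(alias)] = name
        return cls(entries)


def alias_numbering(records: Iterable[tuple[str, str]]) -> tuple[list[tuple[str, str]], NameKey]:
    """Replace names with 1-based integer tokens in input order."""
    out: list[tuple[str, str]] = []
    key: dict[int, str] = {}
    seen: set[str] = set()
    for i, (name, seq) in enumerate(records, start=1):
        if name in seen:
            raise NamingError(f"duplicate record name {name!r}")
        seen.add(name)
        key[i] = name
        out.append((str(i), seq))
    return out, NameKey(key)


def restore_names(records: Iterable[tuple[str, str]], key: NameKey) -> list[tuple[str, str]]:
    """Exact inverse of :func:`alias_numbering`."""
    return [(key.name(int(name)), seq) for name, seq in records]
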