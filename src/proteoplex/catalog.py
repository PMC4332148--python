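"""Nomenclature and membership of proteasome sub-complexes.

The 26S proteasome is built from a 20S core particle (CP) capped by
regulatory particles (RPs).  The CP exists in several subtypes that share
eleven non-catalytic subunits (α1–α7, β3, β4, β6, β7, collectively
"ncP20S") and differ in their catalytic β subunits: the standard
proteasome (sP20S, β1/β2/β5) and the immunoproteasome (iP20S,
β1i/β2i/β5i), plus intermediate subtypes carrying a mix of both.  β5 and
β2i are subtype-exclusive, which makes them convenient single-subunit
proxies for sP20S and iP20S abundance.

This module houses a curated subunit catalog (canonical label, gene-level
accession, aliases) and the reference sub-complex definitions used by the
rest of the pipeline: the ncP20S and 19S references are the median of
their subunits, PA28αβ the median of PA28α/PA28β, and sP20S/iP20S/
PA28γ/PA200/PI31 are single-subunit references.  Both tables ship as TSV
so users can extend them to other complexes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

Aggregation = Literal["median", "mean", "single"]


class UnknownSubunitError(KeyError):
    """Raised when a name cannot be resolved against the catalog."""

    def __init__(self, names: Iterable[str]):
        self.names = list(names)
        super().__init__(f"unresolvable subunit name(s): {', '.join(self.names)}")


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class Subunit:
    """One catalog entry: canonical label, accession, and aliases."""

    name: str
    accession: str
    aliases: tuple[str, ...] = ()


@dataclass
class SubunitCatalog:
    """Immutable lookup of subunit labels, accessions and aliases.

    Canonical names and accessions must each be unique, and every alias
    must resolve to exactly one canonical name.
    """

    entries: list[Subunit]
    _by_name: dict[str, Subunit] = field(init=False, repr=False)
    _by_alias: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        accessions = [e.accession for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"duplicate subunit names: {dupes}")
        if len(set(accessions)) != len(accessions):
            dupes = sorted({a for a in accessions if accessions.count(a) > 1})
            raise CatalogError(f"duplicate accessions: {dupes}")
        self._by_name = {e.name: e for e in self.entries}
        by_alias: dict[str, str] = {}
        for e in self.entries:
            for alias in e.aliases:
                if alias in by_alias or alias in self._by_name:
                    raise CatalogError(f"ambiguous alias: {alias!r}")
                by_alias[alias] = e.name
        # accessions double as aliases for convenience
        for e in self.entries:
            if e.accession not in by_alias and e.accession not in self._by_name:
                by_alias[e.accession] = e.name
        self._by_alias = by_alias

    def __contains__(self, name: str) -> bool:
        return name in self._by_name or name in self._by_alias

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def resolve_one(self, name: str) -> str:
        """Map a name or alias to its canonical subunit name."""
        if name in self._by_name:
            return name
        if name in self._by_alias:
            return self._by_alias[name]
        raise UnknownSubunitError([name])

    def accession_of(self, name: str) -> str:
        return self._by_name[self.resolve_one(name)].accession


@dataclass(frozen=True)
class ComplexDefinition:
    """A named reference sub-complex and its abundance aggregation rule.

    ``aggregation`` is how a per-sample (or per-fraction) reference value
    is computed from member values: ``median``/``mean`` across members, or
    ``single`` for one-subunit proxies (requires exactly one member).
    """

    name: str
    members: tuple[str, ...]
    aggregation: Aggregation

    def __post_init__(self) -> None:
        if not self.members:
            raise CatalogError(f"complex {self.name!r} has no members")
        if self.aggregation == "single" and len(self.members) != 1:
            raise CatalogError(
                f"complex {self.name!r} uses 'single' aggregation but has "
                f"{len(self.members)} members"
            )
        if self.aggregation not in ("median", "mean", "single"):
            raise CatalogError(f"unknown aggregation {self.aggregation!r}")


def resolve(names: Iterable[str], catalog: SubunitCatalog) -> list[str]:
    """Resolve names/aliases to canonical subunit names.

    Unresolvable names are collected and reported together in a single
    :class:`UnknownSubunitError` rather than silently dropped.
    """
    resolved, missing = [], []
    for n in names:
        try:
            resolved.append(catalog.resolve_one(n))
        except UnknownSubunitError:
            missing.append(n)
    if missing:
        raise UnknownSubunitError(missing)
    return resolved


def _data_path(filename: str) -> Path:
    return Path(str(importlib.resources.files("proteoplex.data") / filename))


def load_subunits(path: str | Path) -> SubunitCatalog:
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["subunit_name", "accession"]:
            raise CatalogError(f"unexpected subunit table header: {header}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name, accession = parts[0], parts[1]
            aliases = tuple(a for a in parts[2].split(";") if a) if len(parts) > 2 else ()
            entries.append(Subunit(name, accession, aliases))
    return SubunitCatalog(entries)


def load_complexes(path: str | Path, catalog: SubunitCatalog) -> list[ComplexDefinition]:
    defs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["complex_name", "aggregation", "members"]:
            raise CatalogError(f"unexpected complex table header: {header}")
        for line in fh:
            if not line.strip():
                continue
            name, aggregation, members_s = line.rstrip("\n").split("\t")
            members = tuple(resolve(members_s.split(";"), catalog))
            defs.append(ComplexDefinition(name, members, aggregation))  # type: ignore[arg-type]
    return defs


def write_subunits(catalog: SubunitCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subunit_name\taccession\taliases\n")
        for e in catalog.entries:
            fh.write(f"{e.name}\t{e.accession}\t{';'.join(e.aliases)}\n")


def write_complexes(defs: Iterable[ComplexDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("complex_name\taggregation\tmembers\n")
        for d in defs:
            fh.write(f"{d.name}\t{d.aggregation}\t{';'.join(d.members)}\n")


def default_catalog() -> tuple[SubunitCatalog, list[ComplexDefinition]]:
    """The packaged proteasome catalog and the eight reference definitions.

    References: ncP20S (median of the 11 non-catalytic CP subunits), 19S
    (median of the 19 RP subunits Rpt1–6, Rpn1–3, Rpn5–14), PA28αβ
    (median of PA28α/PA28β), and single-subunit proxies sP20S (β5),
    iP20S (β2i), PA28γ, PA200, PI31.  Reference construction downstream
    intersects these member lists with the detected proteins, so the full
    definitions stored here serve both the gradient and AP-MS analyses.
    """
    catalog = load_subunits(_data_path("subunits.tsv"))
    defs = load_complexes(_data_path("complexes.tsv"), catalog)
    return catalog, defs
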