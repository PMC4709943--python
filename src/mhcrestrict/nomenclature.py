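"""Parse, normalize and alias MHC designations across species dialects.

MHC names differ by species.  Human names follow IMGT/HLA style:
``HLA-DPA1*02:01/DPB1*01:01`` names a two-chain molecule (alpha chain
listed first, chains separated by ``/``), ``HLA-DPB1*04:02`` a single
chain designation, ``HLA-DP`` a locus and ``A2`` a serotype.  Mouse names
follow H2 style: ``H2-IAd`` is a class II molecule whose trailing
lower-case letter is the haplotype, ``H2d`` a haplotype.  Other species
(cattle BoLA, horse ELA, dog DLA, chicken BF, ...) follow the generic
IPD-MHC pattern ``PREFIX-LOCUS*FF:FF``.

The grammar implemented here: ``*`` separates the locus from allele
fields, ``:`` separates allele fields, ``/`` separates the two chains of a
molecule name.  The dialect registry maps species prefixes to dialects and
is extensible from a plain-text file, so new species need no code change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import InvalidNameError, UnknownDialectError


class Dialect(Enum):
    HUMAN_HLA = "human-HLA"
    MOUSE_H2 = "mouse-H2"
    GENERIC_IPD = "generic-IPD"


class NameKind(Enum):
    MOLECULE = "molecule"
    CHAIN = "chain"
    LOCUS = "locus"
    SEROTYPE = "serotype"
    HAPLOTYPE = "haplotype"


@dataclass(frozen=True)
class DialectRecord:
    """One registered species prefix."""

    prefix: str
    dialect: Dialect
    taxon: str
    canonical_prefix: Optional[str] = None  # e.g. "H-2" renders as "H2"

    @property
    def canonical(self) -> str:
        return self.canonical_prefix or self.prefix


DEFAULT_REGISTRY: tuple[DialectRecord, ...] = (
    DialectRecord("HLA", Dialect.HUMAN_HLA, "Homo sapiens"),
    DialectRecord("H2", Dialect.MOUSE_H2, "Mus musculus"),
    DialectRecord("H-2", Dialect.MOUSE_H2, "Mus musculus", canonical_prefix="H2"),
    DialectRecord("BF", Dialect.GENERIC_IPD, "Gallus gallus"),
    DialectRecord("BoLA", Dialect.GENERIC_IPD, "Bos taurus"),
    DialectRecord("ELA", Dialect.GENERIC_IPD, "Equus caballus"),
    DialectRecord("DLA", Dialect.GENERIC_IPD, "Canis lupus familiaris"),
)


def load_dialect_registry(path: Union[str, Path]) -> tuple[DialectRecord, ...]:
    """Read extra dialect records from a plain-text file.

    One record per line: ``prefix<TAB>dialect<TAB>taxon[<TAB>canonical]``.
    Blank lines and ``#`` comments are skipped.  Returns the default
    registry extended with the file's records.
    """
    records = list(DEFAULT_REGISTRY)
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InvalidNameError(f"bad dialect registry line: {raw!r}")
        prefix, dialect, taxon = parts[0], Dialect(parts[1]), parts[2]
        canonical = parts[3] if len(parts) > 3 else None
        records.append(DialectRecord(prefix, dialect, taxon, canonical))
    return tuple(records)


@dataclass(frozen=True)
class ParsedName:
    """Structured decomposition of one MHC designation."""

    raw: str
    dialect: Dialect
    kind: NameKind
    locus_tokens: tuple[str, ...] = ()
    allele_fields: tuple[str, ...] = ()
    chain_components: tuple["ParsedName", ...] = ()
    haplotype_suffix: Optional[str] = None
    prefix: str = ""

    def __post_init__(self):
        if self.allele_fields and not self.locus_tokens:
            raise InvalidNameError(
                f"allele fields without a locus in {self.raw!r}"
            )
        if self.kind is NameKind.MOLECULE and self.chain_components:
            for c in self.chain_components:
                if c.kind is not NameKind.CHAIN:
                    raise InvalidNameError(
                        f"molecule component {c.raw!r} is not a chain"
                    )


# human class II sub-locus -> parent locus (DPA1 -> DP etc.)
_SUBLOCUS_RE = re.compile(r"^(D[PQROM])[AB]\d*$")
_FIELDS_RE = re.compile(r"^\d{2,4}(:\d{2,4})*$")
# cattle class I loci are plain numbers ("BoLA-1"), so digits may lead
_LOCUS_RE = re.compile(r"^[A-Z0-9][A-Z0-9]*$")
_SEROTYPE_RE = re.compile(r"^[A-Z]{1,3}w?\d+$")
_MOUSE_TOKEN_RE = re.compile(r"^([A-Z]+)([a-z])?$")


def _registry_map(registry: Sequence[DialectRecord]) -> list[DialectRecord]:
    # longest prefixes first so "H-2" wins over "H2" never matters etc.
    return sorted(registry, key=lambda r: -len(r.prefix))


def parse_name(
    raw: str,
    dialect_hint: Optional[Dialect] = None,
    registry: Sequence[DialectRecord] = DEFAULT_REGISTRY,
) -> ParsedName:
    """Parse one MHC designation.

    Raises :class:`InvalidNameError` on empty/ill-formed input and
    :class:`UnknownDialectError` when no registered prefix matches and no
    ``dialect_hint`` is given.  Never raises anything else, on any string.
    """
    s = raw.strip()
    if not s:
        raise InvalidNameError("empty MHC designation")

    for rec in _registry_map(registry):
        p = rec.prefix
        if s == p:
            raise InvalidNameError(f"bare species prefix: {raw!r}")
        if s.upper().startswith(p.upper()) and len(s) > len(p):
            rest = s[len(p):]
            if rest[0] in "- ":
                return _parse_body(raw, rec, rest[1:])
            # mouse haplotype written without separator: "H2d"
            if rec.dialect is Dialect.MOUSE_H2 and rest.islower() and rest.isalpha():
                return ParsedName(
                    raw=raw,
                    dialect=rec.dialect,
                    kind=NameKind.HAPLOTYPE,
                    haplotype_suffix=rest,
                    prefix=rec.canonical,
                )
    if dialect_hint is not None:
        rec = _record_for_dialect(dialect_hint, registry)
        return _parse_body(raw, rec, s, prefixless=True)
    raise UnknownDialectError(f"no registered species prefix matches {raw!r}")


def _record_for_dialect(
    dialect: Dialect, registry: Sequence[DialectRecord]
) -> DialectRecord:
    for rec in registry:
        if rec.dialect is dialect and rec.canonical == rec.prefix:
            return rec
    for rec in registry:
        if rec.dialect is dialect:
            return rec
    raise UnknownDialectError(f"no registry record for dialect {dialect.value}")


def _parse_body(
    raw: str, rec: DialectRecord, body: str, prefixless: bool = False
) -> ParsedName:
    body = body.strip()
    if not body:
        raise InvalidNameError(f"nothing after species prefix in {raw!r}")
    if rec.dialect is Dialect.MOUSE_H2:
        return _parse_mouse(raw, rec, body)
    return _parse_star_dialect(raw, rec, body, prefixless)


def _parse_mouse(raw: str, rec: DialectRecord, body: str) -> ParsedName:
    if body.islower() and body.isalpha():
        return ParsedName(
            raw=raw,
            dialect=rec.dialect,
            kind=NameKind.HAPLOTYPE,
            haplotype_suffix=body,
            prefix=rec.canonical,
        )
    m = _MOUSE_TOKEN_RE.match(body)
    if not m:
        raise InvalidNameError(f"unparseable mouse designation: {raw!r}")
    locus, suffix = m.group(1), m.group(2)
    kind = NameKind.MOLECULE if suffix else NameKind.LOCUS
    return ParsedName(
        raw=raw,
        dialect=rec.dialect,
        kind=kind,
        locus_tokens=(locus,),
        haplotype_suffix=suffix,
        prefix=rec.canonical,
    )


def _parse_star_dialect(
    raw: str, rec: DialectRecord, body: str, prefixless: bool
) -> ParsedName:
    if "/" in body:
        alpha_s, _, beta_s = body.partition("/")
        if not alpha_s or not beta_s or "/" in beta_s:
            raise InvalidNameError(f"malformed two-chain name: {raw!r}")
        alpha = _parse_chain(raw, rec, alpha_s)
        beta = _parse_chain(raw, rec, beta_s)
        return ParsedName(
            raw=raw,
            dialect=rec.dialect,
            kind=NameKind.MOLECULE,
            chain_components=(alpha, beta),
            prefix=rec.canonical,
        )
    if "*" in body:
        return _parse_chain(raw, rec, body)
    token = body.upper()
    if not _LOCUS_RE.match(token):
        raise InvalidNameError(f"unparseable designation: {raw!r}")
    if prefixless and _SEROTYPE_RE.match(body if body[0].isupper() else token):
        # bare antibody-panel name like "A2", "DR4", "Aw19"
        return ParsedName(
            raw=raw,
            dialect=rec.dialect,
            kind=NameKind.SEROTYPE,
            locus_tokens=(re.match(r"^[A-Za-z]+", body).group(0).upper(),),
            prefix="",
        )
    return ParsedName(
        raw=raw,
        dialect=rec.dialect,
        kind=NameKind.LOCUS,
        locus_tokens=_with_parent(token),
        prefix=rec.canonical,
    )


def _parse_chain(raw: str, rec: DialectRecord, body: str) -> ParsedName:
    locus_s, star, fields_s = body.partition("*")
    locus = locus_s.strip().upper()
    if not star or not _LOCUS_RE.match(locus):
        raise InvalidNameError(f"missing or malformed locus in {raw!r}")
    fields_s = fields_s.strip()
    if not _FIELDS_RE.match(fields_s):
        raise InvalidNameError(f"malformed allele fields in {raw!r}")
    fields: list[str] = []
    for f in fields_s.split(":"):
        # legacy colon-free form: a single 4-digit run is two 2-digit fields
        if len(f) == 4 and not fields and ":" not in fields_s:
            fields.extend((f[:2], f[2:]))
        else:
            fields.append(f)
    return ParsedName(
        raw=raw,
        dialect=rec.dialect,
        kind=NameKind.CHAIN,
        locus_tokens=_with_parent(locus),
        allele_fields=tuple(fields),
        prefix=rec.canonical,
    )


def _with_parent(locus: str) -> tuple[str, ...]:
    m = _SUBLOCUS_RE.match(locus)
    if m and m.group(1) != locus:
        return (m.group(1), locus)
    return (locus,)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def normalize_name(p: ParsedName) -> str:
    """Canonical rendering; deterministic and stable across runs."""
    if p.dialect is Dialect.MOUSE_H2:
        if p.kind is NameKind.HAPLOTYPE:
            return f"{p.prefix}{p.haplotype_suffix}"
        suffix = p.haplotype_suffix or ""
        return f"{p.prefix}-{p.locus_tokens[-1]}{suffix}"
    if p.kind is NameKind.SEROTYPE:
        return p.raw.strip()
    if p.kind is NameKind.MOLECULE and p.chain_components:
        alpha, beta = p.chain_components
        return f"{p.prefix}-{_render_chain(alpha)}/{_render_chain(beta)}"
    if p.kind is NameKind.CHAIN:
        return f"{p.prefix}-{_render_chain(p)}"
    return f"{p.prefix}-{p.locus_tokens[-1]}"


def _render_chain(p: ParsedName) -> str:
    return f"{p.locus_tokens[-1]}*{':'.join(p.allele_fields)}"


def synonyms_for(p: ParsedName) -> list[str]:
    """Alias renderings of ``p``; never includes the canonical form.

    Covers the legacy colon-free allele form (pre-2010 HLA nomenclature,
    e.g. ``HLA-DPB1*0402``) and mouse spelling variants (``H-2`` prefix,
    ``I-Ad`` style class II names).
    """
    canonical = normalize_name(p)
    out: list[str] = []
    if p.dialect is Dialect.MOUSE_H2:
        if p.kind is NameKind.HAPLOTYPE:
            out.append(f"H-2{p.haplotype_suffix}")
        elif p.kind in (NameKind.MOLECULE, NameKind.LOCUS):
            token = p.locus_tokens[-1] + (p.haplotype_suffix or "")
            out.append(f"H-2 {token}")
            if p.locus_tokens[-1] in ("IA", "IE"):
                out.append(f"I-{p.locus_tokens[-1][1]}{p.haplotype_suffix or ''}")
    elif p.kind is NameKind.CHAIN:
        legacy = _legacy_chain(p)
        if legacy:
            out.append(f"{p.prefix}-{legacy}")
    elif p.kind is NameKind.MOLECULE and p.chain_components:
        legs = [_legacy_chain(c) for c in p.chain_components]
        if all(legs):
            out.append(f"{p.prefix}-{legs[0]}/{legs[1]}")
    return [s for s in out if s != canonical]


def _legacy_chain(p: ParsedName) -> Optional[str]:
    if all(len(f) == 2 for f in p.allele_fields) and p.allele_fields:
        return f"{p.locus_tokens[-1]}*{''.join(p.allele_fields)}"
    return None


def taxon_for(p: ParsedName, registry: Sequence[DialectRecord] = DEFAULT_REGISTRY) -> str:
    """Species label associated with the name's prefix."""
    for rec in registry:
        if rec.canonical == p.prefix or rec.prefix == p.prefix:
            return rec.taxon
    raise UnknownDialectError(f"no registry record for prefix {p.prefix!r}")
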