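"""Canonical nomenclature for photosynthesis-related genes.

The photosynthesis gene cluster (PGC) of aerobic anoxygenic phototrophs
carries five families of genes: *bch* (bacteriochlorophyll *a*
biosynthesis), *puf* (reaction-centre / LH1 subunits), *puh* (RC-H subunit
and assembly factors), *crt* (carotenoid biosynthesis) and a handful of
regulators (*ppsR*, *ppaA*, *crtJ*, BLUF-domain sensors).  This module owns
the canonical spelling of every such symbol, a synonym table for the
spellings found in real annotations (``acsF``/``ascF``, ``IhaA``/``lhaA``,
…), per-gene pathway membership, and the compact run notation used in the
comparative-genomics literature (``bchFNBHLM`` = bchF, bchN, bchB, bchH,
bchL, bchM).

The catalog ships as a plain-text table (``data/catalog.tsv``) and can be
extended at run time from a user file in the same format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .errors import CatalogError, GeneStringParseError, InputError

#: catalog categories; every category except "other" counts as a
#: photosynthesis gene for delineation purposes.
CATEGORIES = ("bch", "puf", "puh", "crt", "regulatory", "assembly", "precursor", "other")

#: categories treated as photosynthesis genes when chaining a cluster.
PHOTO_CATEGORIES = frozenset(CATEGORIES) - {"other"}

#: prefixes understood by compact run notation (prefix + one letter per gene).
RUN_PREFIXES = ("bch", "puf", "puh", "crt")

PATHWAYS = ("spheroidenone", "zeaxanthin", "spirilloxanthin", "bchl_biosynthesis")


@dataclass(frozen=True)
class GeneDescriptor:
    """A catalog entry: canonical symbol, category and pathway roles."""

    symbol: str
    category: str
    synonyms: tuple[str, ...] = ()
    pathway_roles: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_photosynthetic(self) -> bool:
        return self.category in PHOTO_CATEGORIES


@dataclass(frozen=True)
class UnknownGene:
    """Marker for a label that resolves to no catalog entry.

    Unknown genes are first-class citizens: they are carried through
    delineation with category ``other`` (clusters routinely contain
    hypothetical proteins) rather than dropped.
    """

    label: str
    category: str = "other"

    @property
    def is_photosynthetic(self) -> bool:
        return False


Resolved = Union[GeneDescriptor, UnknownGene]

_TOKEN_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")


class GeneCatalog:
    """Case-insensitive registry of :class:`GeneDescriptor` entries."""

    def __init__(self, descriptors: Iterable[GeneDescriptor]):
        self._by_symbol: dict[str, GeneDescriptor] = {}
        self._index: dict[str, GeneDescriptor] = {}
        for d in descriptors:
            self._register(d)

    def _register(self, d: GeneDescriptor) -> None:
        if d.symbol in self._by_symbol:
            raise CatalogError(f"duplicate catalog symbol {d.symbol!r}")
        if d.category not in CATEGORIES:
            raise CatalogError(f"{d.symbol!r}: unknown category {d.category!r}")
        self._by_symbol[d.symbol] = d
        for key in (d.symbol, *d.synonyms):
            self._index[key.lower()] = d

    # -- construction ----------------------------------------------------

    @classmethod
    def from_table(cls, path_or_text) -> "GeneCatalog":
        """Load a catalog from the plain-text table format.

        Tab-separated columns: symbol, category, comma-joined synonyms,
        comma-joined pathway roles; trailing columns may be omitted.
        Lines starting with ``#`` are comments.
        """
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
            text = Path(path_or_text).read_text()
        else:
            text = str(path_or_text)
        descriptors = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = (line.split("\t") + ["", "", ""])[:4]
            symbol, category, syn, roles = (p.strip() for p in parts)
            descriptors.append(
                GeneDescriptor(
                    symbol=symbol,
                    category=category,
                    synonyms=tuple(s for s in syn.split(",") if s),
                    pathway_roles=frozenset(r for r in roles.split(",") if r),
                )
            )
        return cls(descriptors)

    @classmethod
    def default(cls) -> "GeneCatalog":
        """The catalog shipped with the package."""
        text = resources.files("pgckit.data").joinpath("catalog.tsv").read_text()
        return cls.from_table(text)

    def extended_with(self, path_or_text) -> "GeneCatalog":
        """Return a new catalog with user entries appended."""
        extra = GeneCatalog.from_table(path_or_text)
        return GeneCatalog(list(self) + list(extra))

    # -- queries ---------------------------------------------------------

    def __iter__(self):
        return iter(self._by_symbol.values())

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def symbols(self, category: str | None = None) -> list[str]:
        return [d.symbol for d in self if category is None or d.category == category]

    def lookup(self, symbol: str) -> GeneDescriptor:
        """Exact lookup of a canonical symbol; raises on unregistered input."""
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise CatalogError(f"unregistered gene symbol {symbol!r}") from None

    def canonicalize(self, raw_label: str) -> Resolved:
        """Resolve a free-text annotation label to a catalog descriptor.

        Matching is case-insensitive and synonym-aware.  Labels that do not
        resolve (housekeeping genes, hypothetical proteins) come back as an
        :class:`UnknownGene` marker carrying the raw label; this never
        raises on unrecognised input.
        """
        if not raw_label or not raw_label.strip():
            raise InputError("empty gene label")
        label = raw_label.strip()
        hit = self._index.get(label.lower())
        if hit is not None:
            return hit
        # product-description keyword match for BLUF-domain sensors, which
        # rarely carry a gene symbol in annotations
        if "bluf" in label.lower():
            return self._index["bluf"]
        return UnknownGene(label)

    # -- compact run notation --------------------------------------------

    def expand_gene_string(self, compact: str) -> list[str]:
        """Expand compact multi-gene notation into canonical symbols.

        ``"bchFNBHLM"`` → ``[bchF, bchN, bchB, bchH, bchL, bchM]``; tokens
        may be chained with hyphens (``"crtF-bchCXYZ"``); tokens that are
        not prefix runs pass through synonym-aware canonicalization
        (``"lhaA"``, ``"ascF"``).
        """
        if not compact or not compact.strip():
            raise InputError("empty gene string")
        symbols: list[str] = []
        for token in compact.strip().split("-"):
            token = token.strip()
            if not token:
                continue
            symbols.extend(self._expand_token(token))
        return symbols

    def _expand_token(self, token: str) -> list[str]:
        if not _TOKEN_RE.match(token):
            raise GeneStringParseError(f"malformed gene-string token {token!r}")
        prefix = token[:3].lower()
        if prefix in RUN_PREFIXES and len(token) > 3:
            suffixes = token[3:]
            if all(s.isalpha() and s.isupper() for s in suffixes) and len(suffixes) > 1:
                run = [prefix + s for s in suffixes]
                missing = [s for s in run if s not in self._by_symbol]
                if missing:
                    raise GeneStringParseError(
                        f"token {token!r} expands to unregistered symbol(s) {missing}"
                    )
                return run
        resolved = self.canonicalize(token)
        if isinstance(resolved, UnknownGene):
            raise GeneStringParseError(f"gene-string token {token!r} is not a registered gene")
        return [resolved.symbol]


_DEFAULT: GeneCatalog | None = None


def default_catalog() -> GeneCatalog:
    """Shared instance of the shipped catalog (loaded once)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = GeneCatalog.default()
    return _DEFAULT
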