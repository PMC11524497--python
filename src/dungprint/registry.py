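"""Canonical registry of fecal steroid compounds.

The package tracks two families of biomarkers routinely measured by GC-MS in
dung and sediment extracts:

* neutral steroids — Δ5-sterols, 5α/5β-stanols and stanones, of which the
  four 5β-stanols ("zoostanols": coprostanol, epicoprostanol, 24-ethylcoprostanol
  and 24-ethylepicoprostanol) are produced by gut-microbial hydrogenation of
  dietary and endogenous sterols and therefore indicate animal fecal input;
* bile acids — secondary bile acids (deoxycholic, lithocholic, hyodeoxycholic,
  ...) produced by gut bacteria from liver-synthesised primary bile acids,
  whose relative abundances vary among vertebrate species.

Common names are matched case-insensitively with a synonym table, because the
literature uses several spellings (e.g. "epi-coprostanol" vs "epicoprostanol").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Compound",
    "CompoundRegistry",
    "ZOOSTANOLS",
    "DEFAULT_REGISTRY",
    "UnknownCompoundError",
]

#: The four 5β-stanols used for source attribution, in canonical order.
ZOOSTANOLS: tuple[str, ...] = (
    "coprostanol",
    "epicoprostanol",
    "24-ethylcoprostanol",
    "24-ethylepicoprostanol",
)

VALID_CLASSES = frozenset({"sterol", "stanol", "stanone", "bile_acid"})


class UnknownCompoundError(KeyError):
    """Raised when a name cannot be resolved against the registry."""


@dataclass(frozen=True)
class Compound:
    common_name: str
    systematic_name: str
    compound_class: str  # sterol | stanol | stanone | bile_acid

    def __post_init__(self) -> None:
        if self.compound_class not in VALID_CLASSES:
            raise ValueError(
                f"compound_class must be one of {sorted(VALID_CLASSES)}, "
                f"got {self.compound_class!r}"
            )

    @property
    def is_zoostanol(self) -> bool:
        return self.common_name in ZOOSTANOLS


def _normalize(name: str) -> str:
    """Lower-case and strip spacing/hyphen variation for matching."""
    s = name.strip().lower()
    s = s.replace("β", "b").replace("α", "a")
    s = re.sub(r"[\s_\-]+", "", s)
    return s


_DEFAULT_COMPOUNDS: tuple[Compound, ...] = (
    Compound("coprostanol", "5β-cholestan-3β-ol", "stanol"),
    Compound("epicoprostanol", "5β-cholestan-3α-ol", "stanol"),
    Compound("cholesterol", "cholest-5-en-3β-ol", "sterol"),
    Compound("cholestanol", "5α-cholestan-3β-ol", "stanol"),
    Compound("cholestanone", "5α-cholestane-3-one", "stanone"),
    Compound("24-ethylcoprostanol", "24-ethyl-5β-cholestan-3β-ol", "stanol"),
    Compound("24-ethylepicoprostanol", "24-ethyl-5β-cholestan-3α-ol", "stanol"),
    Compound("campesterol", "campest-5-en-3β-ol", "sterol"),
    Compound("stigmasterol", "stigmasta-5,22-dien-3β-ol", "sterol"),
    Compound("β-sitosterol", "stigmast-5-en-3β-ol", "sterol"),
    Compound("ergosterol", "ergosta-5,7,22-trien-3β-ol", "sterol"),
    Compound("stigmastanol", "5α-stigmastan-3β-ol", "stanol"),
    Compound("chenodeoxycholic acid", "3α,7α-dihydroxy-5β-cholan-24-oic acid", "bile_acid"),
    Compound("deoxycholic acid", "3α,12α-dihydroxy-5β-cholan-24-oic acid", "bile_acid"),
    Compound("hyodeoxycholic acid", "3α,6α-dihydroxy-5β-cholan-24-oic acid", "bile_acid"),
    Compound("lithocholic acid", "3α-hydroxy-5β-cholan-24-oic acid", "bile_acid"),
    Compound("ursodeoxycholic acid", "3α,7β-dihydroxy-5β-cholan-24-oic acid", "bile_acid"),
)

_DEFAULT_SYNONYMS: dict[str, str] = {
    "epi-coprostanol": "epicoprostanol",
    "epi coprostanol": "epicoprostanol",
    "24-ethylepi-coprostanol": "24-ethylepicoprostanol",
    "24-ethyl-epicoprostanol": "24-ethylepicoprostanol",
    "24-ethyl coprostanol": "24-ethylcoprostanol",
    "beta-sitosterol": "β-sitosterol",
    "b-sitosterol": "β-sitosterol",
    "sitosterol": "β-sitosterol",
    "deoxycholic": "deoxycholic acid",
    "lithocholic": "lithocholic acid",
    "hyodeoxycholic": "hyodeoxycholic acid",
    "chenodeoxycholic": "chenodeoxycholic acid",
    "ursodeoxycholic": "ursodeoxycholic acid",
    "dca": "deoxycholic acid",
    "lca": "lithocholic acid",
    "hdca": "hyodeoxycholic acid",
    "cdca": "chenodeoxycholic acid",
    "udca": "ursodeoxycholic acid",
}


@dataclass
class CompoundRegistry:
    """Lookup table of accepted compounds, classes and synonyms."""

    compounds: tuple[Compound, ...] = _DEFAULT_COMPOUNDS
    synonyms: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SYNONYMS))

    def __post_init__(self) -> None:
        names = [c.common_name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate common names in registry")
        self._index: dict[str, Compound] = {}
        for c in self.compounds:
            self._index[_normalize(c.common_name)] = c
        for alias, target in self.synonyms.items():
            key = _normalize(target)
            if key not in self._index:
                raise ValueError(f"synonym target {target!r} not in registry")
            self._index[_normalize(alias)] = self._index[key]

    def resolve(self, name: str) -> Compound:
        """Return the canonical compound for any accepted spelling of ``name``."""
        try:
            return self._index[_normalize(name)]
        except KeyError:
            raise UnknownCompoundError(
                f"unknown compound {name!r}; known names: "
                f"{', '.join(sorted(c.common_name for c in self.compounds))}"
            ) from None

    def canonical(self, name: str) -> str:
        return self.resolve(name).common_name

    def members(self, compound_class: str) -> list[str]:
        """Common names in a class, registry order."""
        if compound_class not in VALID_CLASSES:
            raise ValueError(
                f"unknown compound class {compound_class!r}; "
                f"valid: {sorted(VALID_CLASSES)}"
            )
        return [c.common_name for c in self.compounds if c.compound_class == compound_class]

    def neutral_members(self) -> list[str]:
        """Sterols, stanols and stanones (the GC-MS neutral fraction)."""
        return [
            c.common_name
            for c in self.compounds
            if c.compound_class in ("sterol", "stanol", "stanone")
        ]

    @property
    def zoostanols(self) -> tuple[str, ...]:
        return ZOOSTANOLS

    def __contains__(self, name: str) -> bool:
        return _normalize(name) in self._index

    def __iter__(self) -> Iterable[Compound]:
        return iter(self.compounds)


DEFAULT_REGISTRY = CompoundRegistry()
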