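"""The provenance lexicon: which qualifier chains name a licensed term.

A nomenclature term is an entity kind (neutroid, neutromer trace, chargite
trace, molecular distribution trace, ...) qualified by at most one RT
qualifier (integrated / max / average / instantaneous), the m/z qualifiers
(deisotoped, reduced) where the scope admits them, and at most one form word
(hull / distribution). The human-readable string lists qualifiers in reverse
application order — the most recent reduction first — so a tag chain
round-trips exactly through its term string.
"""

from __future__ import annotations

__all__ = [
    "RT_QUALIFIERS",
    "MZ_QUALIFIERS",
    "FORM_QUALIFIERS",
    "ENTITY_KINDS",
    "LexiconError",
    "validate_chain",
    "term_string",
    "parse_term",
]

RT_QUALIFIERS = ("integrated", "max", "average", "instantaneous")
MZ_QUALIFIERS = ("deisotoped", "reduced")
FORM_QUALIFIERS = ("hull", "distribution")
ALL_QUALIFIERS = RT_QUALIFIERS + MZ_QUALIFIERS + FORM_QUALIFIERS

ENTITY_KINDS = (
    "raw_point",
    "scan",
    "neutroid",
    "instantaneous_neutromer_hull",
    "neutromer_hull",
    "neutromer_trace",
    "chargite_trace",
    "chargite_distribution_trace",
    "molecular_distribution_trace",
)

#: Scopes on which each m/z qualifier is licensed. Deisotoping sums the
#: isotope dimension, so it needs at least chargite scope; charge reduction
#: combines charge states, so it needs molecular scope.
_MZ_SCOPE = {
    "deisotoped": ("chargite_trace", "chargite_distribution_trace", "molecular_distribution_trace"),
    "reduced": ("molecular_distribution_trace",),
}


class LexiconError(ValueError):
    """A qualifier chain that no licensed nomenclature term corresponds to."""


def validate_chain(kind: str, tags: tuple[str, ...] | list[str]) -> None:
    """Raise :class:`LexiconError` unless kind + tags form a licensed term."""
    if kind not in ENTITY_KINDS:
        raise LexiconError(f"unknown entity kind {kind!r}")
    tags = tuple(tags)
    if not tags:
        raise LexiconError("provenance chain must be non-empty")
    for t in tags:
        if t not in ALL_QUALIFIERS:
            raise LexiconError(f"unknown qualifier {t!r}")
    if len(set(tags)) != len(tags):
        raise LexiconError(f"duplicate qualifiers in chain {tags}")
    rt = [t for t in tags if t in RT_QUALIFIERS]
    if len(rt) > 1:
        raise LexiconError(f"at most one RT qualifier is licensed, got {rt}")
    form = [t for t in tags if t in FORM_QUALIFIERS]
    if len(form) > 1:
        raise LexiconError(f"at most one form qualifier is licensed, got {form}")
    for t in tags:
        if t in _MZ_SCOPE and kind not in _MZ_SCOPE[t]:
            raise LexiconError(f"qualifier {t!r} is not licensed on scope {kind!r}")
    if "reduced" in tags and "deisotoped" not in tags:
        raise LexiconError("'reduced' presupposes a deisotoped signal")


def term_string(kind: str, tags: tuple[str, ...] | list[str] = ()) -> str:
    """Human-readable nomenclature term for an entity and its reduction chain.

    Qualifiers appear most-recent-first, e.g. tags ``("deisotoped",
    "integrated")`` on a chargite trace read "integrated deisotoped chargite
    trace".
    """
    if tags:
        validate_chain(kind, tuple(tags))
    words = list(tags)[::-1] + kind.split("_")
    return " ".join(words)


def parse_term(term: str) -> tuple[str, tuple[str, ...]]:
    """Invert :func:`term_string`: term -> (entity kind, tags in application order)."""
    words = term.split()
    # Prefer the longest kind match: "instantaneous neutromer hull" is the
    # entity kind itself, not an RT-qualified neutromer hull.
    for i in range(len(words)):
        kind = "_".join(words[i:])
        if kind in ENTITY_KINDS and all(w in ALL_QUALIFIERS for w in words[:i]):
            tags = tuple(words[:i][::-1])
            if tags:
                validate_chain(kind, tags)
            return kind, tags
    raise LexiconError(f"unrecognized entity kind in term {term!r}")
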