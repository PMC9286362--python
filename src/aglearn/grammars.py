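"""Formal grammars for the visual artificial-grammar-learning task.

Three target grammars sit at ascending levels of the extended Chomsky
hierarchy, all operating over two tile categories ``A`` and ``B``:

* ``ABNA`` (regular): strings ``A B^N A`` — one long-distance dependency
  between the two edge ``A`` elements.
* ``MIRROR`` (context-free): a half-string followed by its reversal —
  nested dependencies.
* ``COPY`` (mildly context-sensitive): a half-string followed by its
  repetition — crossed dependencies.
* ``WARMUP_ABN`` (regular): ``(AB)^N``, used only for the warm-up block.

Structural *markers* (rendered as black tiles in the experiment, ``|`` in the
text dialect) separate the dependent parts: two for ``ABNA`` (between the A
and B elements), one for ``MIRROR``/``COPY`` (in the middle), none for the
warm-up grammar.  Markers never count toward the dependency length ``N``.

Alongside the target grammars, a registry of heuristic "shortcut" rules
(e.g. *ends with A*) supports consistency coding against alternate
strategies a participant might use instead of the target grammar.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "CategoryToken",
    "Marker",
    "MARKER",
    "PatternString",
    "GrammarSpec",
    "TARGET_GRAMMARS",
    "ALTERNATE_RULE_IDS",
    "grammar",
    "alternate",
    "default_registry",
    "generate_string",
    "is_member",
    "enumerate_language",
    "alt_is_member",
    "classify_all",
    "parse_pattern",
]


# ---------------------------------------------------------------------------
# tokens and pattern strings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryToken:
    """One tile: category ``A`` or ``B``, optional concrete exemplar id."""

    category: str
    exemplar: int | None = None

    def __post_init__(self) -> None:
        if self.category not in ("A", "B"):
            raise ValueError(f"category must be 'A' or 'B', got {self.category!r}")
        if self.exemplar is not None and self.exemplar < 1:
            raise ValueError("exemplar ids are positive integers")

    def __str__(self) -> str:
        return self.category if self.exemplar is None else f"{self.category}{self.exemplar}"


class Marker:
    """Structural separator (black tile); carries no category content."""

    _instance: "Marker | None" = None

    def __new__(cls) -> "Marker":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MARKER"

    def __str__(self) -> str:
        return "|"


MARKER = Marker()


@dataclass(frozen=True)
class PatternString:
    """An ordered sequence of category tokens and markers.

    ``n_value`` is the dependency-length parameter N of the generating
    grammar (category-token count is N+2 for ABNA, 2N for the half-based
    grammars).  For strings of unknown provenance (e.g. parsed foils) it may
    be absent.
    """

    tokens: tuple
    n_value: int | None = None

    @property
    def categories(self) -> str:
        """Category string with markers stripped, e.g. ``'AABBAA'``."""
        return "".join(t.category for t in self.tokens if isinstance(t, CategoryToken))

    @property
    def marker_positions(self) -> tuple[int, ...]:
        """Indices of markers counted in *category-token* offsets.

        Position ``k`` means the marker sits after the k-th category token
        (k=0: before the first).  This makes marker placement comparable
        across strings of equal category content.
        """
        out = []
        seen = 0
        for t in self.tokens:
            if isinstance(t, Marker):
                out.append(seen)
            else:
                seen += 1
        return tuple(out)

    def __str__(self) -> str:
        return "".join(str(t) for t in self.tokens)

    def __len__(self) -> int:
        return len(self.categories)


def parse_pattern(text: str, n_value: int | None = None) -> PatternString:
    """Parse the ``A/B/|`` text dialect (exemplars as ``A3``) back to tokens."""
    tokens: list = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "|":
            tokens.append(MARKER)
            i += 1
        elif ch in "AB":
            j = i + 1
            while j < len(text) and text[j].isdigit():
                j += 1
            exemplar = int(text[i + 1 : j]) if j > i + 1 else None
            tokens.append(CategoryToken(ch, exemplar))
            i = j
        else:
            raise ValueError(f"illegal character {ch!r} in pattern {text!r}")
    return PatternString(tuple(tokens), n_value)


def _from_categories(cats: str, marker_after: Iterable[int], n_value: int | None) -> PatternString:
    marker_after = set(marker_after)
    tokens: list = []
    if 0 in marker_after:
        tokens.append(MARKER)
    for k, c in enumerate(cats, start=1):
        tokens.append(CategoryToken(c))
        if k in marker_after:
            tokens.append(MARKER)
    return PatternString(tuple(tokens), n_value)


# ---------------------------------------------------------------------------
# grammar specifications
# ---------------------------------------------------------------------------

_LEVELS = {
    "WARMUP_ABN": "regular",
    "ABNA": "regular",
    "MIRROR": "context-free",
    "COPY": "mildly-context-sensitive",
}

TARGET_GRAMMARS = ("ABNA", "MIRROR", "COPY")

#: Default heuristic shortcut rules used for alternate-grammar coding.
ALTERNATE_RULE_IDS = (
    "ENDS_A",
    "BEGINS_A",
    "EDGE_MATCH",
    "HALF_COUNT_MATCH",
    "MARKER_OK",
    "LEGAL_LENGTH",
    "BIGRAM_FAMILIAR",
)


@dataclass(frozen=True)
class GrammarSpec:
    """A target grammar, the warm-up grammar, or a heuristic shortcut rule.

    ``params`` carries rule-specific context: heuristics that are defined
    relative to a condition (``MARKER_OK``, ``LEGAL_LENGTH``) hold the target
    grammar id under ``"target"``; ``BIGRAM_FAMILIAR`` holds the exposure
    bigram inventory under ``"bigrams"``.
    """

    id: str
    level: str = "heuristic"
    params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id in _LEVELS and self.level != _LEVELS[self.id]:
            object.__setattr__(self, "level", _LEVELS[self.id])

    @property
    def is_target(self) -> bool:
        return self.id in _LEVELS


def grammar(gid: str) -> GrammarSpec:
    """Spec for one of the four generative grammars."""
    if gid not in _LEVELS:
        raise KeyError(f"unknown grammar id {gid!r}")
    return GrammarSpec(gid, _LEVELS[gid])


def alternate(rule_id: str, target: str | None = None,
              bigrams: frozenset[str] | None = None) -> GrammarSpec:
    """Spec for a heuristic shortcut rule from the default registry."""
    if rule_id not in ALTERNATE_RULE_IDS:
        raise KeyError(f"unknown alternate rule id {rule_id!r}")
    params: dict = {}
    if target is not None:
        params["target"] = target
    if bigrams is not None:
        params["bigrams"] = frozenset(bigrams)
    return GrammarSpec(rule_id, "heuristic", params)


def default_registry(target: str, bigrams: Iterable[str] | None = None) -> list[GrammarSpec]:
    """Target grammar plus all default alternates, for one condition.

    ``bigrams`` is the adjacent-category-pair inventory of the condition's
    exposure set; if omitted it is derived from the target language itself at
    the exposure lengths (N = 2, 3, 5).
    """
    if bigrams is None:
        bigset: set[str] = set()
        for n in (2, 3, 5):
            for s in enumerate_language(grammar(target), n):
                c = s.categories
                bigset.update(c[i : i + 2] for i in range(len(c) - 1))
        bigrams = bigset
    regs = [grammar(target)]
    for rid in ALTERNATE_RULE_IDS:
        regs.append(alternate(rid, target=target, bigrams=frozenset(bigrams)))
    return regs


# ---------------------------------------------------------------------------
# marker conventions
# ---------------------------------------------------------------------------

def _expected_markers(gid: str, n_cats: int) -> tuple[int, ...]:
    """Marker offsets (see ``PatternString.marker_positions``) for a
    grammatical string with ``n_cats`` category tokens."""
    if gid == "ABNA":
        return (1, n_cats - 1)
    if gid in ("MIRROR", "COPY"):
        return (n_cats // 2,)
    if gid == "WARMUP_ABN":
        return ()
    raise KeyError(gid)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_string(g: GrammarSpec, n: int, rng,
                    exclude_palindrome: bool = False) -> PatternString:
    """Draw one grammatical string at dependency length ``n``.

    For MIRROR/COPY the first half is sampled uniformly over {A,B}^n; with
    ``exclude_palindrome`` the draw is restricted to non-palindromic halves,
    which keeps Mirror and Copy evidence distinguishable in test items.
    ABNA and the warm-up grammar have a single category string per ``n``.
    """
    if not g.is_target:
        raise KeyError(f"{g.id!r} is not a generative grammar")
    if n < 1:
        raise ValueError(f"invalid design: n must be >= 1, got {n}")
    gid = g.id
    if gid == "ABNA":
        cats = "A" + "B" * n + "A"
    elif gid == "WARMUP_ABN":
        cats = "AB" * n
    else:
        if exclude_palindrome and n == 1:
            raise ValueError("invalid design: every half of length 1 is palindromic")
        while True:
            half = "".join(rng.choice(("A", "B")) for _ in range(n))
            if not (exclude_palindrome and half == half[::-1]):
                break
        cats = half + (half[::-1] if gid == "MIRROR" else half)
    return _from_categories(cats, _expected_markers(gid, len(cats)), n)


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------

def is_member(s: PatternString, g: GrammarSpec, check_markers: bool = True) -> bool:
    """Decide language membership at the category level.

    Exemplar identities are ignored.  With ``check_markers`` (the default)
    markers must sit exactly in the grammar-determined positions; malformed
    marker placement makes a string ungrammatical rather than erroneous — a
    foil may have displaced structure.
    """
    if not g.is_target:
        raise KeyError(f"{g.id!r} is not a generative grammar")
    cats = s.categories
    L = len(cats)
    gid = g.id
    if gid == "ABNA":
        ok = L >= 3 and cats[0] == "A" and cats[-1] == "A" and set(cats[1:-1]) == {"B"}
    elif gid == "MIRROR":
        ok = L >= 2 and L % 2 == 0 and cats[: L // 2] == cats[L // 2 :][::-1]
    elif gid == "COPY":
        ok = L >= 2 and L % 2 == 0 and cats[: L // 2] == cats[L // 2 :]
    elif gid == "WARMUP_ABN":
        ok = L >= 2 and L % 2 == 0 and cats == "AB" * (L // 2)
    else:  # pragma: no cover
        raise KeyError(gid)
    if ok and check_markers:
        ok = s.marker_positions == _expected_markers(gid, L)
    return ok


def enumerate_language(g: GrammarSpec, n: int, cap: int = 16) -> set[PatternString]:
    """All grammatical strings at dependency length ``n`` (brute-force oracle).

    Built constructively from the defining relation, independently of
    :func:`generate_string` and :func:`is_member`.  ``cap`` bounds the
    category-token count (default 16) to keep enumeration exact and fast.
    """
    if not g.is_target:
        raise KeyError(f"{g.id!r} is not a generative grammar")
    if n < 1:
        raise ValueError("n must be >= 1")
    gid = g.id
    n_cats = n + 2 if gid == "ABNA" else 2 * n
    if n_cats > cap:
        raise ValueError(f"enumeration cap exceeded: {n_cats} > {cap}")
    marks = _expected_markers(gid, n_cats)
    out: set[PatternString] = set()
    if gid == "ABNA":
        out.add(_from_categories("A" + "B" * n + "A", marks, n))
    elif gid == "WARMUP_ABN":
        out.add(_from_categories("AB" * n, marks, n))
    else:
        for half in itertools.product("AB", repeat=n):
            h = "".join(half)
            second = h[::-1] if gid == "MIRROR" else h
            out.add(_from_categories(h + second, marks, n))
    return out


# ---------------------------------------------------------------------------
# alternate (shortcut) rules
# ---------------------------------------------------------------------------

def _legal_length(gid: str, n_cats: int) -> bool:
    if gid == "ABNA":
        return n_cats >= 3
    return n_cats >= 2 and n_cats % 2 == 0


def alt_is_member(s: PatternString, alt: GrammarSpec) -> bool:
    """Decide whether a string satisfies a heuristic shortcut rule."""
    cats = s.categories
    rid = alt.id
    if rid == "ENDS_A":
        return bool(cats) and cats[-1] == "A"
    if rid == "BEGINS_A":
        return bool(cats) and cats[0] == "A"
    if rid == "EDGE_MATCH":
        return bool(cats) and cats[0] == cats[-1]
    if rid == "HALF_COUNT_MATCH":
        if len(cats) % 2 != 0 or not cats:
            return False
        h = len(cats) // 2
        return cats[:h].count("A") == cats[h:].count("A")
    if rid == "MARKER_OK":
        target = alt.params["target"]
        return (_legal_length(target, len(cats))
                and s.marker_positions == _expected_markers(target, len(cats)))
    if rid == "LEGAL_LENGTH":
        return _legal_length(alt.params["target"], len(cats))
    if rid == "BIGRAM_FAMILIAR":
        bigrams = alt.params["bigrams"]
        return all(cats[i : i + 2] in bigrams for i in range(len(cats) - 1))
    raise KeyError(f"unknown alternate rule id {rid!r}")


def rule_is_member(s: PatternString, rule: GrammarSpec) -> bool:
    """Membership under either a generative grammar or a shortcut rule."""
    return is_member(s, rule) if rule.is_target else alt_is_member(s, rule)


def classify_all(s: PatternString, registry: Iterable[GrammarSpec]) -> dict[str, bool]:
    """Evaluate one string against every rule in a registry."""
    registry = list(registry)
    if not registry:
        raise ValueError("registry must be non-empty")
    return {r.id: rule_is_member(s, r) for r in registry}
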