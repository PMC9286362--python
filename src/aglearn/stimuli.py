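"""Exposure, warm-up, and test stimulus sets with the published composition.

The test block for each target grammar comprises 87 yes/no items: 36
grammatical strings (N = 2, 3 plus length generalizations N = 4, 6) and 51
ungrammatical foils from two families —

* *incomplete dependency*: one dependency-bearing token deleted (a terminal
  A for ABNA; a token of the second half for Mirror/Copy), and
* *incorrect tile*: one token's category flipped A<->B, length preserved.

Only the block totals are published (grammatical + incomplete foils: 30 at
N in {2,3}, 20 at N = 4, 12 at N = 6; incorrect-tile foils: 15 at N in
{2,3}, 10 at N = 4); the per-N split inside each block is configurable, with
defaults chosen to respect those totals.  Exposure blocks hold 30
grammatical strings at N in {2, 3, 5}; the warm-up block holds 15 items
under the (AB)^N grammar with a 12/15 pass criterion applied elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grammars import (
    MARKER,
    CategoryToken,
    GrammarSpec,
    PatternString,
    enumerate_language,
    generate_string,
    grammar,
    is_member,
    parse_pattern,
)

__all__ = [
    "StimulusItem",
    "StimulusSet",
    "TestDesign",
    "DEFAULT_TEST_DESIGN",
    "DEFAULT_EXPOSURE_DESIGN",
    "WarmupDesign",
    "DEFAULT_WARMUP_DESIGN",
    "build_exposure_set",
    "build_test_set",
    "build_warmup_set",
    "make_incomplete_foil",
    "make_incorrect_tile_foil",
]

FOIL_TYPES = ("none", "incomplete_dependency", "incorrect_tile")


@dataclass(frozen=True)
class StimulusItem:
    pattern: PatternString
    n_value: int
    grammatical: bool
    foil_type: str = "none"
    phase: str = "test"

    def __post_init__(self) -> None:
        if self.foil_type not in FOIL_TYPES:
            raise ValueError(f"unknown foil type {self.foil_type!r}")
        if self.grammatical != (self.foil_type == "none"):
            raise ValueError("grammatical items must have foil_type 'none' and vice versa")


@dataclass
class StimulusSet:
    """An ordered stimulus block for one grammar condition."""

    grammar: GrammarSpec
    items: list[StimulusItem]
    design: dict
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the delimited-table schema used throughout the pipeline."""
        rows = [
            {
                "item_id": f"{self.grammar.id}_{it.phase}_{i:03d}",
                "phase": it.phase,
                "grammar": self.grammar.id,
                "n_value": it.n_value,
                "pattern": str(it.pattern),
                "grammatical": int(it.grammatical),
                "foil_type": it.foil_type,
            }
            for i, it in enumerate(self.items)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSet":
        gids = df["grammar"].unique()
        if len(gids) != 1:
            raise ValueError("frame must hold a single grammar condition")
        items = [
            StimulusItem(
                pattern=parse_pattern(r.pattern, int(r.n_value)),
                n_value=int(r.n_value),
                grammatical=bool(r.grammatical),
                foil_type=r.foil_type,
                phase=r.phase,
            )
            for r in df.itertuples()
        ]
        return cls(grammar(gids[0]), items, design={})


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestDesign:
    """Per-N item counts for one test block.

    Block-total constraints (published): grammatical+incomplete must sum to
    30 over N in {2,3}, 20 at N=4 and 12 at N=6; incorrect-tile foils must
    sum to 15 over N in {2,3} and 10 at N=4.
    """

    grammatical: dict = field(default_factory=lambda: {2: 8, 3: 8, 4: 12, 6: 8})
    incomplete: dict = field(default_factory=lambda: {2: 7, 3: 7, 4: 8, 6: 4})
    incorrect: dict = field(default_factory=lambda: {2: 8, 3: 7, 4: 10})
    exclude_palindromic_halves: bool = True

    def validate(self) -> None:
        gi23 = sum(self.grammatical.get(n, 0) + self.incomplete.get(n, 0) for n in (2, 3))
        checks = [
            ("grammatical+incomplete at N in {2,3}", gi23, 30),
            ("grammatical+incomplete at N=4",
             self.grammatical.get(4, 0) + self.incomplete.get(4, 0), 20),
            ("grammatical+incomplete at N=6",
             self.grammatical.get(6, 0) + self.incomplete.get(6, 0), 12),
            ("incorrect-tile at N in {2,3}",
             self.incorrect.get(2, 0) + self.incorrect.get(3, 0), 15),
            ("incorrect-tile at N=4", self.incorrect.get(4, 0), 10),
        ]
        for label, got, want in checks:
            if got != want:
                raise ValueError(f"invalid design: {label} = {got}, required {want}")


DEFAULT_TEST_DESIGN = TestDesign()
DEFAULT_EXPOSURE_DESIGN: dict[int, int] = {2: 10, 3: 10, 5: 10}


@dataclass(frozen=True)
class WarmupDesign:
    grammatical: dict = field(default_factory=lambda: {2: 3, 3: 3, 5: 2})
    incomplete: dict = field(default_factory=lambda: {2: 2, 3: 1, 5: 1})
    incorrect: dict = field(default_factory=lambda: {2: 1, 3: 1, 5: 1})


DEFAULT_WARMUP_DESIGN = WarmupDesign()


# ---------------------------------------------------------------------------
# foil construction
# ---------------------------------------------------------------------------

def make_incomplete_foil(item: StimulusItem, g: GrammarSpec, rng) -> StimulusItem:
    """Delete one dependency-bearing token from a grammatical string.

    For ABNA one of the two terminal A elements is removed (markers stay in
    place); for Mirror/Copy one token of the second half is removed.  The
    result always fails target-grammar membership.
    """
    if not item.grammatical:
        raise ValueError("incomplete foils are derived from grammatical strings")
    toks = list(item.pattern.tokens)
    cat_idx = [i for i, t in enumerate(toks) if isinstance(t, CategoryToken)]
    if g.id == "ABNA":
        drop = cat_idx[0] if rng.random() < 0.5 else cat_idx[-1]
    elif g.id in ("MIRROR", "COPY"):
        half = len(cat_idx) // 2
        drop = cat_idx[half + int(rng.integers(half))]
    elif g.id == "WARMUP_ABN":
        drop = cat_idx[int(rng.integers(len(cat_idx)))]
    else:
        raise KeyError(g.id)
    del toks[drop]
    foil = PatternString(tuple(toks), item.n_value)
    if is_member(foil, g):  # pragma: no cover - structurally impossible
        raise RuntimeError("degenerate input: deletion left the string grammatical")
    return StimulusItem(foil, item.n_value, False, "incomplete_dependency", item.phase)


def make_incorrect_tile_foil(item: StimulusItem, g: GrammarSpec, rng) -> StimulusItem:
    """Flip the category of exactly one token (A<->B), preserving length."""
    if not item.grammatical:
        raise ValueError("incorrect-tile foils are derived from grammatical strings")
    toks = list(item.pattern.tokens)
    cat_idx = [i for i, t in enumerate(toks) if isinstance(t, CategoryToken)]
    flip = cat_idx[int(rng.integers(len(cat_idx)))]
    old = toks[flip]
    toks[flip] = CategoryToken("B" if old.category == "A" else "A", old.exemplar)
    foil = PatternString(tuple(toks), item.n_value)
    if is_member(foil, g):  # pragma: no cover - single flips always break these grammars
        raise RuntimeError("degenerate input: flip left the string grammatical")
    return StimulusItem(foil, item.n_value, False, "incorrect_tile", item.phase)


# ---------------------------------------------------------------------------
# set builders
# ---------------------------------------------------------------------------

def _sample_grammatical(g: GrammarSpec, n: int, count: int, rng,
                        exclude_palindrome: bool, unique: bool) -> list[PatternString]:
    """Sample grammatical strings, without replacement while the language allows."""
    pool = sorted(enumerate_language(g, n), key=str)
    if exclude_palindrome and g.id in ("MIRROR", "COPY"):
        half = lambda s: s.categories[: len(s.categories) // 2]
        nonpal = [s for s in pool if half(s) != half(s)[::-1]]
        pool = nonpal or pool
    out: list[PatternString] = []
    while len(out) < count:
        take = min(count - len(out), len(pool)) if unique else len(pool)
        idx = rng.permutation(len(pool))[: max(take, 1)]
        out.extend(pool[i] for i in idx)
    return out[:count]


def build_exposure_set(g: GrammarSpec, design: dict[int, int] | None = None,
                       rng=None, seed: int | None = None) -> StimulusSet:
    """30 grammatical strings at N in {2, 3, 5} (default 10 each)."""
    design = dict(DEFAULT_EXPOSURE_DESIGN if design is None else design)
    if not set(design) <= {2, 3, 5}:
        raise ValueError(f"invalid design: exposure lengths must be in {{2,3,5}}, got {sorted(design)}")
    rng = _resolve_rng(rng, seed)
    items: list[StimulusItem] = []
    for n, count in sorted(design.items()):
        for pat in _sample_grammatical(g, n, count, rng, exclude_palindrome=False, unique=False):
            items.append(StimulusItem(pat, n, True, "none", "exposure"))
    order = rng.permutation(len(items))
    return StimulusSet(g, [items[i] for i in order], {"exposure": design}, seed)


def build_test_set(g: GrammarSpec, design: TestDesign | None = None,
                   rng=None, seed: int | None = None) -> StimulusSet:
    """The 87-item test block: 36 grammatical + 26 incomplete + 25 incorrect-tile."""
    design = design or DEFAULT_TEST_DESIGN
    design.validate()
    rng = _resolve_rng(rng, seed)
    excl = design.exclude_palindromic_halves
    items: list[StimulusItem] = []
    for n, count in sorted(design.grammatical.items()):
        for pat in _sample_grammatical(g, n, count, rng, excl, unique=True):
            items.append(StimulusItem(pat, n, True, "none", "test"))
    for spec_counts, maker in ((design.incomplete, make_incomplete_foil),
                               (design.incorrect, make_incorrect_tile_foil)):
        for n, count in sorted(spec_counts.items()):
            for pat in _sample_grammatical(g, n, count, rng, excl, unique=True):
                seeditem = StimulusItem(pat, n, True, "none", "test")
                items.append(maker(seeditem, g, rng))
    order = rng.permutation(len(items))
    out = StimulusSet(g, [items[i] for i in order], {"test": design}, seed)
    _check_set(out)
    return out


def build_warmup_set(design: WarmupDesign | None = None,
                     rng=None, seed: int | None = None) -> StimulusSet:
    """The 15-item warm-up judgment block under the (AB)^N grammar."""
    design = design or DEFAULT_WARMUP_DESIGN
    rng = _resolve_rng(rng, seed)
    g = grammar("WARMUP_ABN")
    items: list[StimulusItem] = []
    for n, count in sorted(design.grammatical.items()):
        for pat in _sample_grammatical(g, n, count, rng, False, unique=False):
            items.append(StimulusItem(pat, n, True, "none", "warmup"))
    for spec_counts, maker in ((design.incomplete, make_incomplete_foil),
                               (design.incorrect, make_incorrect_tile_foil)):
        for n, count in sorted(spec_counts.items()):
            for pat in _sample_grammatical(g, n, count, rng, False, unique=False):
                seeditem = StimulusItem(pat, n, True, "none", "warmup")
                items.append(maker(seeditem, g, rng))
    order = rng.permutation(len(items))
    return StimulusSet(g, [items[i] for i in order], {"warmup": design}, seed)


def _check_set(s: StimulusSet) -> None:
    """Exhaustive post-build check: labels agree with target-grammar membership."""
    for it in s.items:
        if is_member(it.pattern, s.grammar) != it.grammatical:
            raise RuntimeError(f"label/membership mismatch for {it.pattern}")


def _resolve_rng(rng, seed):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)
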