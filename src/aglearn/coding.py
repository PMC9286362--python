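"""Grammar-consistency coding of raw yes/no trials.

A response is *consistent* with a candidate rule when the participant said
"yes" to a string the rule accepts or "no" to a string it rejects.  Coding
every trial against the condition's target grammar and a registry of
alternate shortcut rules produces the 0/1 consistency table the multilevel
models consume; consistency with the target grammar is, by construction,
ordinary accuracy.

Stimulus annotations mark two trial-level properties used by the
interaction models: *generalization* (dependency length N >= 4, never seen
during exposure) and *similarity* (the stimulus satisfies, rather than
violates, the condition's target grammar).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .grammars import GrammarSpec, default_registry, parse_pattern, rule_is_member
from .stimuli import StimulusSet

__all__ = [
    "code_trial",
    "build_consistency_table",
    "annotate_stimuli",
    "annotate_trials",
]


def code_trial(response_yes: int, pattern, rule: GrammarSpec) -> int:
    """1 if the response agrees with the rule's verdict on the stimulus."""
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    member = rule_is_member(pattern, rule)
    return int(bool(response_yes) == member)


def build_consistency_table(trials: pd.DataFrame,
                            registry: Iterable[GrammarSpec] | None = None) -> pd.DataFrame:
    """Code a trial table against every rule in the registry.

    ``trials`` must hold one grammar condition (column ``grammar`` constant)
    with ``pattern`` and ``response_yes`` columns.  If no registry is given,
    the condition's default registry (target + shortcut rules) is used.
    The result carries one 0/1 column per rule id plus ``accuracy``
    (identically the target-grammar column).
    """
    gids = trials["grammar"].unique()
    if len(gids) != 1:
        raise ValueError("consistency tables are per grammar condition; "
                         f"got {list(gids)}")
    target = gids[0]
    registry = list(registry) if registry is not None else default_registry(target)
    if target not in [r.id for r in registry]:
        raise ValueError(f"registry must include the target grammar {target!r}")

    # membership is a property of the stimulus: compute once per pattern
    verdicts = {}
    for pat in trials["pattern"].unique():
        parsed = parse_pattern(pat)
        verdicts[pat] = {r.id: rule_is_member(parsed, r) for r in registry}

    out = trials.copy()
    yes = out["response_yes"].astype(bool)
    for r in registry:
        member = out["pattern"].map(lambda p, rid=r.id: verdicts[p][rid])
        out[r.id] = (yes == member).astype(int)
    out["accuracy"] = out[target]
    return out


def annotate_stimuli(stimset: StimulusSet) -> pd.DataFrame:
    """Per-item stimulus-property flags for the interaction models."""
    frame = stimset.to_frame()
    frame["generalization"] = (frame["n_value"] >= 4).astype(int)
    frame["similar"] = frame["grammatical"].astype(int)
    return frame


def annotate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add generalization/similarity flags to a trial (or consistency) table."""
    out = trials.copy()
    out["generalization"] = (out["n_value"] >= 4).astype(int)
    out["similar"] = out["grammatical"].astype(int)
    return out
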