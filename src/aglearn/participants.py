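"""Synthetic participants for pipeline testing and parameter recovery.

Each simulated participant applies one candidate rule (a target grammar or a
shortcut heuristic) with imperfect consistency.  On a trial whose stimulus
satisfies the rule the participant answers "yes" with probability

    P(consistent) = lapse/2 + (1 - lapse) * sigmoid(base_logit + offset_i)

and with the complementary construction otherwise, so that consistency with
the applied rule — not raw yes-rate — is the stable behavioural quantity.
Participant offsets are Normal(0, sd) on the log-odds scale, matching the
random-intercept assumption of the downstream multilevel models.  The lapse
parameter (uniform guessing) defaults to 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .grammars import GrammarSpec, default_registry, grammar, rule_is_member
from .stimuli import StimulusSet, build_test_set

__all__ = [
    "StrategyProfile",
    "SimulatedStudy",
    "sample_participants",
    "simulate_trials",
    "simulate_study",
]

TRIAL_COLUMNS = [
    "participant_id", "group", "grammar", "item_id", "pattern",
    "grammatical", "foil_type", "n_value", "response_yes",
]


@dataclass(frozen=True)
class StrategyProfile:
    """The generating behavioural model for one group of participants."""

    rule: str = "target"              # "target" or an explicit rule id
    base_logit: float = 1.9           # mean log-odds of rule-consistent responding
    individual_sd: float = 0.5        # SD of participant offsets, log-odds scale
    lapse: float = 0.0                # probability of a uniform random response

    def __post_init__(self) -> None:
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be >= 0")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must be in [0, 1]")


@dataclass
class SimulatedStudy:
    """A full synthetic study: trial table plus generating ground truth."""

    trials: pd.DataFrame
    offsets: dict[str, np.ndarray]
    truth: dict[str, StrategyProfile]
    seed: int | None = None

    def truth_json(self) -> str:
        payload = {
            "seed": self.seed,
            "profiles": {g: asdict(p) for g, p in self.truth.items()},
            "offsets": {g: list(map(float, o)) for g, o in self.offsets.items()},
        }
        return json.dumps(payload, indent=1)


def sample_participants(n: int, profile: StrategyProfile, rng) -> np.ndarray:
    """Draw ``n`` participant-level log-odds offsets ~ Normal(0, individual_sd)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.normal(0.0, profile.individual_sd, size=n)


def _resolve_rule(profile: StrategyProfile, stimset: StimulusSet) -> GrammarSpec:
    if profile.rule == "target":
        return stimset.grammar
    for r in default_registry(stimset.grammar.id):
        if r.id == profile.rule:
            return r
    raise KeyError(f"rule id {profile.rule!r} not in registry for {stimset.grammar.id}")


def simulate_trials(stimset: StimulusSet, offsets: np.ndarray,
                    profile: StrategyProfile, rng, group: str = "synthetic",
                    participant_ids: list[str] | None = None) -> pd.DataFrame:
    """Simulate one group's yes/no responses to a stimulus block."""
    rule = _resolve_rule(profile, stimset)
    frame = stimset.to_frame()
    satisfies = np.array([
        rule_is_member(it.pattern, rule) for it in stimset.items
    ])
    if participant_ids is None:
        participant_ids = [f"{group}_{i + 1:02d}" for i in range(len(offsets))]
    rows = []
    for pid, off in zip(participant_ids, offsets):
        p_cons = profile.lapse / 2 + (1 - profile.lapse) / (1 + np.exp(-(profile.base_logit + off)))
        p_yes = np.where(satisfies, p_cons, 1 - p_cons)
        resp = (rng.random(len(p_yes)) < p_yes).astype(int)
        block = frame.copy()
        block.insert(0, "participant_id", pid)
        block.insert(1, "group", group)
        block["response_yes"] = resp
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    return out[TRIAL_COLUMNS]


def simulate_study(group_profiles: dict[str, StrategyProfile],
                   n_per_group: int = 15,
                   grammars: tuple[str, ...] = ("ABNA", "MIRROR", "COPY"),
                   stimsets: dict[str, StimulusSet] | None = None,
                   seed: int | None = None) -> SimulatedStudy:
    """Simulate the full two-group design: per group and grammar condition,
    every participant answers the 87-trial test block.

    Participant offsets are drawn once per group and carried across grammar
    conditions (a stable individual trait), mirroring the repeated-measures
    structure of the study.
    """
    rng = np.random.default_rng(seed)
    if stimsets is None:
        stimsets = {g: build_test_set(grammar(g), rng=rng) for g in grammars}
    offsets = {grp: sample_participants(n_per_group, prof, rng)
               for grp, prof in group_profiles.items()}
    parts = []
    for grp, prof in group_profiles.items():
        pids = [f"{grp}_{i + 1:02d}" for i in range(n_per_group)]
        for g in grammars:
            parts.append(simulate_trials(stimsets[g], offsets[grp], prof, rng,
                                         group=grp, participant_ids=pids))
    trials = pd.concat(parts, ignore_index=True)
    return SimulatedStudy(trials, offsets, dict(group_profiles), seed)
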