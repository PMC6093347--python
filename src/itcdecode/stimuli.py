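"""Hierarchically labelled visual stimulus sets.

Stimuli are labels only (no images are rendered).  The hierarchy has four
levels: a coarse level (face, body, inanimate object, plus the auxiliary
modified-face and body-part groups), a species level defined only for faces
(human / monkey), and view and identity levels defined only for human faces,
which form a complete 3-view x 5-identity grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

NA = "n/a"

COARSE_LABELS = ("face", "body", "object", "modified_face", "body_part")
#: coarse categories entering pairwise decoding (aux groups are excluded)
DECODED_COARSE = ("face", "body", "object")
SPECIES_LABELS = ("human", "monkey")
VIEW_LABELS = ("left", "center", "right")
IDENTITY_LABELS = ("1", "2", "3", "4", "5")

LEVELS = ("coarse", "species", "view", "identity")


@dataclass(frozen=True)
class Stimulus:
    """One stimulus image, identified by id and its hierarchy labels."""

    stimulus_id: str
    coarse: str
    species: str = NA
    view: str = NA
    identity: str = NA

    def __post_init__(self) -> None:
        if self.coarse not in COARSE_LABELS:
            raise ValueError(f"unknown coarse label {self.coarse!r}")
        if (self.species != NA) != (self.coarse == "face"):
            raise ValueError("species is defined iff coarse == 'face'")
        is_human = self.species == "human"
        if (self.view != NA) != is_human or (self.identity != NA) != is_human:
            raise ValueError("view/identity are defined iff species == 'human'")

    def label(self, level: str) -> str:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        return getattr(self, level)


class StimulusSet:
    """An ordered collection of stimuli with hierarchy lookups."""

    def __init__(self, stimuli: list[Stimulus]):
        ids = [s.stimulus_id for s in stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate stimulus ids")
        self.stimuli = list(stimuli)
        self._by_id = {s.stimulus_id: s for s in stimuli}
        human = [s for s in stimuli if s.species == "human"]
        grid = {(s.view, s.identity) for s in human}
        want = {(v, i) for v in VIEW_LABELS for i in IDENTITY_LABELS}
        if human and grid != want:
            raise ValueError("human-face block must be the full 3 x 5 view/identity grid")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self) -> Iterator[Stimulus]:
        return iter(self.stimuli)

    def __getitem__(self, stimulus_id: str) -> Stimulus:
        return self._by_id[stimulus_id]

    @property
    def ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli]

    def labels(self, level: str) -> list[str]:
        """Distinct non-n/a labels present at a hierarchy level."""
        out: list[str] = []
        for s in self.stimuli:
            lab = s.label(level)
            if lab != NA and lab not in out:
                out.append(lab)
        return out

    def with_label(self, level: str, label: str) -> list[Stimulus]:
        return [s for s in self.stimuli if s.label(level) == label]


def make_stimulus_set(config=None) -> StimulusSet:
    """Build the default hierarchical stimulus set.

    Human faces form the full 3-view x 5-identity block (15 images); monkey
    faces, bodies, inanimate objects and the auxiliary modified-face and
    body-part groups have configurable exemplar counts (>= 2 each for the
    decodable coarse categories).
    """
    counts = dict(monkey_face=6, body=6, object=6, modified_face=3, body_part=3)
    if config is not None:
        counts.update(
            monkey_face=config.n_monkey_faces,
            body=config.n_bodies,
            object=config.n_objects,
            modified_face=config.n_modified_faces,
            body_part=config.n_body_parts,
        )
    stimuli: list[Stimulus] = []
    for view in VIEW_LABELS:
        for ident in IDENTITY_LABELS:
            stimuli.append(
                Stimulus(f"hface_{view}_{ident}", "face", "human", view, ident)
            )
    for k in range(counts["monkey_face"]):
        stimuli.append(Stimulus(f"mface_{k:02d}", "face", "monkey"))
    for k in range(counts["body"]):
        stimuli.append(Stimulus(f"body_{k:02d}", "body"))
    for k in range(counts["object"]):
        stimuli.append(Stimulus(f"object_{k:02d}", "object"))
    for k in range(counts["modified_face"]):
        stimuli.append(Stimulus(f"modface_{k:02d}", "modified_face"))
    for k in range(counts["body_part"]):
        stimuli.append(Stimulus(f"bodypart_{k:02d}", "body_part"))
    return StimulusSet(stimuli)
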