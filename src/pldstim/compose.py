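"""Scene assembly: agent placement, congruency logic, and scene labels.

A scene holds one or two placed agents.  Dyads are arranged facing each
other about the capture midline, roughly 3 m apart, each inside its own
7 x 3.5 m capture subspace (physical-contact actions may be flagged
exempt).  Congruency follows the catalog's pairing rules: a communicative
gesture is congruent with any of its listed responses, and paired-
situation categories (HAPPY / ANGRY / SYNC) are congruent when both takes
come from the same situation; every other mix is incongruent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clips import ClipError, JointClip
from .io import read_joint_clip

INTERACTION_CATEGORIES = frozenset({"COM_A", "COM_B", "COM", "HAPPY", "ANGRY", "SYNC"})
INDIVIDUAL_CATEGORIES = frozenset({"ORA", "NORA"})

SUBSPACE_X = 3.5  # depth of each agent's half of the capture space, m
SUBSPACE_Z = 3.5  # half-width along the shared midline, m (7 m total)


class CompositionError(ValueError):
    """Invalid scene composition request."""


@dataclass
class PlacedAgent:
    """A joint clip positioned in the scene: floor offset plus facing yaw.

    Yaw 0 faces +z; agents in a dyad face each other along the x axis.
    """

    clip: JointClip
    offset: tuple[float, float] = (0.0, 0.0)  # (x, z) meters
    yaw: float = 0.0  # degrees about the vertical axis

    def world_positions(self) -> np.ndarray:
        """Clip positions rotated by yaw and translated to the offset."""
        th = np.deg2rad(self.yaw)
        rot = np.array(
            [[np.cos(th), 0.0, np.sin(th)], [0.0, 1.0, 0.0], [-np.sin(th), 0.0, np.cos(th)]]
        )
        p = self.clip.positions @ rot.T
        p = p + np.array([self.offset[0], 0.0, self.offset[1]])
        return p


@dataclass
class SceneSpec:
    """One or two placed agents plus congruency/label metadata."""

    agents: list[PlacedAgent]
    congruency: str = "n/a"  # congruent | incongruent | n/a
    category: str | None = None
    contact: bool = False  # physical-contact actions may cross the midline
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= len(self.agents) <= 2):
            raise CompositionError(f"scene must hold 1 or 2 agents, got {len(self.agents)}")
        if self.congruency not in ("congruent", "incongruent", "n/a"):
            raise CompositionError(f"unknown congruency {self.congruency!r}")
        if not self.contact:
            for k, agent in enumerate(self.agents):
                x, z = agent.offset
                if abs(x) > SUBSPACE_X or abs(z) > SUBSPACE_Z:
                    raise CompositionError(
                        f"agent {k} offset {agent.offset} outside its "
                        f"{SUBSPACE_X} x {2 * SUBSPACE_Z} m subspace"
                    )

    @property
    def rate(self) -> float:
        return self.agents[0].clip.rate

    @property
    def duration(self) -> float:
        return self.agents[0].clip.duration

    def world_positions(self) -> np.ndarray:
        """All agents' joints in world space: (frames, n_agents*13, 3)."""
        return np.concatenate([a.world_positions() for a in self.agents], axis=1)


def place_agents(
    clipA: JointClip, clipB: JointClip | None = None, separation: float = 3.0
) -> SceneSpec:
    """Place one or two agents in the scene.

    Dyads stand symmetrically about the midline, ``separation`` meters
    apart (the capture protocol used ~3 m), turned to face each other.
    A single agent stays at the origin facing the default (front) camera.
    """
    if clipB is None:
        return SceneSpec(
            agents=[PlacedAgent(clipA, offset=(0.0, 0.0), yaw=0.0)],
            congruency="n/a",
            category=clipA.meta.get("category"),
        )
    if abs(clipA.rate - clipB.rate) > 1e-9 or clipA.n_frames != clipB.n_frames:
        raise CompositionError(
            f"clips disagree: rates {clipA.rate}/{clipB.rate} Hz, "
            f"{clipA.n_frames}/{clipB.n_frames} frames"
        )
    if separation <= 0:
        raise CompositionError("separation must be positive (agents would overlap)")
    half = separation / 2.0
    # A on the -x side facing +x (yaw 90), B on the +x side facing -x
    a = PlacedAgent(clipA, offset=(-half, 0.0), yaw=90.0)
    b = PlacedAgent(clipB, offset=(half, 0.0), yaw=-90.0)
    cat = clipA.meta.get("category")
    return SceneSpec(agents=[a, b], congruency="n/a", category=cat)


# --------------------------------------------------------------------------
# catalog
# --------------------------------------------------------------------------


@dataclass
class ActionCatalog:
    """Manifest of available actions with congruent-pairing links."""

    entries: dict[str, dict]
    root: Path | None = None

    def __post_init__(self) -> None:
        for aid, e in self.entries.items():
            for p in e.get("congruent_partners", []):
                if p not in self.entries:
                    raise CompositionError(
                        f"action {aid!r} lists unknown congruent partner {p!r}"
                    )
        for aid, e in self.entries.items():
            if e["category"] == "COM_A" and not e.get("congruent_partners"):
                raise CompositionError(f"communicative gesture {aid!r} has no listed response")

    @classmethod
    def from_manifest(cls, path: str | Path) -> "ActionCatalog":
        path = Path(path)
        doc = json.loads(path.read_text())
        entries = {e["action_id"]: e for e in doc["entries"]}
        if len(entries) != len(doc["entries"]):
            raise CompositionError("duplicate action_id in catalog manifest")
        return cls(entries=entries, root=path.parent)

    def load_clip(self, action_id: str) -> JointClip:
        e = self[action_id]
        if self.root is None:
            raise CompositionError("catalog has no root directory to load clips from")
        return read_joint_clip(self.root / e["clip"])

    def __getitem__(self, action_id: str) -> dict:
        if action_id not in self.entries:
            raise KeyError(f"unknown action id {action_id!r}")
        return self.entries[action_id]


def congruency_of(a: dict, b: dict) -> str:
    """Pairing rule for two catalog entries."""
    pa = set(a.get("congruent_partners", []))
    pb = set(b.get("congruent_partners", []))
    if b["action_id"] in pa or a["action_id"] in pb:
        return "congruent"
    paired = {"HAPPY", "ANGRY", "SYNC"}
    if (
        a["category"] == b["category"]
        and a["category"] in paired
        and a.get("situation") is not None
        and a.get("situation") == b.get("situation")
    ):
        return "congruent"
    return "incongruent"


def compose(
    actionA: str,
    actionB: str | None,
    catalog: ActionCatalog,
    separation: float = 3.0,
) -> SceneSpec:
    """Build a scene from catalog action ids, deriving congruency."""
    entA = catalog[actionA]
    clipA = catalog.load_clip(actionA)
    if actionB is None:
        spec = place_agents(clipA, None)
        spec.category = entA["category"]
        spec.meta["actions"] = [actionA]
        return spec
    entB = catalog[actionB]
    clipB = catalog.load_clip(actionB)
    spec = place_agents(clipA, clipB, separation=separation)
    spec.congruency = congruency_of(entA, entB)
    spec.category = entA["category"]
    spec.meta["actions"] = [actionA, actionB]
    return spec


def label_scene(spec: SceneSpec) -> str:
    """Interaction/individual scene label, a pure function of category.

    Communicative, emotional and synchronous categories count as
    "interaction"; object- and non-object-related individual actions as
    "individual".
    """
    if spec.category is None:
        raise CompositionError("scene has no category tag")
    if spec.category in INTERACTION_CATEGORIES:
        return "interaction"
    if spec.category in INDIVIDUAL_CATEGORIES:
        return "individual"
    raise CompositionError(f"unknown category {spec.category!r}")


def second_person_variant(spec: SceneSpec) -> tuple[SceneSpec, dict]:
    """Turn a third-person dyad into a second-person single-agent scene.

    Drops the responder and returns a camera hint placing the viewpoint at
    the responder's head position at T = 0, yawed to look at the initiator
    — the action is now aimed at the observer.
    """
    roles = [a.clip.meta.get("role") or a.clip.meta.get("category") for a in spec.agents]

    def is_initiator(r):
        return r in ("initiator", "COM_A")

    def is_responder(r):
        return r in ("responder", "COM_B")

    init_idx = next((i for i, r in enumerate(roles) if is_initiator(r)), None)
    if init_idx is None:
        raise CompositionError("scene has no initiator agent (second-person view undefined)")

    initiator = spec.agents[init_idx]
    resp_idx = next((i for i, r in enumerate(roles) if is_responder(r)), None)
    if resp_idx is not None:
        head = spec.agents[resp_idx].world_positions()[0, 0, :]  # head, first frame
    else:
        # single-agent initiator scene: stand where the partner would be
        head = initiator.world_positions()[0, 0, :].copy()
        head[0] = -head[0] if abs(head[0]) > 1e-9 else head[0] + 3.0

    target = initiator.world_positions()[0, 0, :]
    d = target - head
    yaw = float(np.rad2deg(np.arctan2(d[0], d[2])))
    hint = {
        "position": tuple(float(v) for v in head),
        "rotation": (0.0, yaw, 0.0),
    }
    new = SceneSpec(
        agents=[initiator],
        congruency="n/a",
        category=spec.category,
        contact=spec.contact,
        meta={**spec.meta, "perspective": "second_person"},
    )
    return new, hint
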