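"""Episode/sequence fixtures and environmental input schedules.

An *episode* is a set of feature indices (1-based, one feature per Unit); a
*sequence* is an ordered list of episodes.  The canonical training material
is three sequences of five episodes each, in two variants: a fully
*orthogonal* set (pairwise disjoint episodes covering all 75 features) and a
*non-orthogonal* set in which a few features are shared between episodes of
different sequences (20-35% of each affected episode).

Feature indices are global and layer-invariant: feature *i* is coded by the
*i*-th Unit of every layer.  The concrete index assignment is a fixed
deterministic packing (sequence 1 -> lowest indices, etc.); a handful of
indices are pinned so that, e.g., episode 7 starts at feature 30 and the
doubly-shared feature 71 belongs to episodes 2 and 14.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .network import InputEvent
from .units import ConfigurationError

__all__ = [
    "Episode",
    "SequenceSet",
    "make_orthogonal_set",
    "make_nonorthogonal_set",
    "make_random_set",
    "make_inputs",
    "cue_event",
    "TRAIN_PRESENTATION_S",
    "CUE_DURATION_S",
    "TRAIN_AMP_P",
    "TRAIN_AMP_F",
    "CUE_AMP",
]

TRAIN_PRESENTATION_S = 0.250   # duration of one training presentation
CUE_DURATION_S = 0.050         # duration of a retrieval cue
TRAIN_AMP_P = 1800.0           # training drive to pyramidal populations
TRAIN_AMP_F = 50.0             # training drive to fast-inhibitory populations
CUE_AMP = 700.0                # retrieval cue drive to WM pyramidal units


@dataclass(frozen=True)
class Episode:
    """A set of co-occurring features. ``id`` is the global 1-based episode
    number (1-15 for the canonical sets)."""

    id: int
    features: frozenset[int]

    def __post_init__(self):
        if not self.features:
            raise ConfigurationError(f"episode {self.id} has no features")
        if min(self.features) < 1:
            raise ConfigurationError("feature indices are 1-based")

    @property
    def sorted_features(self) -> tuple[int, ...]:
        return tuple(sorted(self.features))


@dataclass
class SequenceSet:
    """Ordered sequences of episodes plus the episode-sharing structure."""

    sequences: list[list[Episode]]
    name: str = ""

    def __post_init__(self):
        seen = {}
        for seq in self.sequences:
            for ep in seq:
                if ep.id in seen:
                    raise ConfigurationError(f"duplicate episode id {ep.id}")
                seen[ep.id] = ep

    @property
    def episodes(self) -> dict[int, Episode]:
        return {ep.id: ep for seq in self.sequences for ep in seq}

    @property
    def all_features(self) -> frozenset[int]:
        out: set[int] = set()
        for ep in self.episodes.values():
            out |= ep.features
        return frozenset(out)

    @property
    def sharing_map(self) -> dict[tuple[int, int], frozenset[int]]:
        """(episode_id, episode_id) -> shared features, for overlapping pairs."""
        eps = sorted(self.episodes.values(), key=lambda e: e.id)
        out = {}
        for i, a in enumerate(eps):
            for b in eps[i + 1:]:
                common = a.features & b.features
                if common:
                    out[(a.id, b.id)] = frozenset(common)
        return out

    @property
    def is_orthogonal(self) -> bool:
        return not self.sharing_map

    def max_feature(self) -> int:
        return max(self.all_features)

    # -- serialization -----------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "sequences": [
                [{"id": ep.id, "features": list(ep.sorted_features)} for ep in seq]
                for seq in self.sequences
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SequenceSet":
        doc = yaml.safe_load(text)
        seqs = [
            [Episode(id=int(e["id"]), features=frozenset(int(f) for f in e["features"]))
             for e in seq]
            for seq in doc["sequences"]
        ]
        return cls(sequences=seqs, name=doc.get("name", ""))


def _eps(spec: list[tuple[int, list[int]]]) -> list[Episode]:
    return [Episode(id=i, features=frozenset(f)) for i, f in spec]


def make_orthogonal_set() -> SequenceSet:
    """The canonical orthogonal material: 3 sequences x 5 disjoint episodes.

    Episode sizes lie in {4, 5, 6} and the 15 episodes tile all 75 features;
    episode 6 occupies features 26-29 and episode 7 features 30-35, so the
    second sequence spans features 26-50.
    """
    seq1 = _eps([
        (1, list(range(1, 5))),
        (2, list(range(5, 11))),
        (3, list(range(11, 17))),
        (4, list(range(17, 22))),
        (5, list(range(22, 26))),
    ])
    seq2 = _eps([
        (6, list(range(26, 30))),
        (7, list(range(30, 36))),
        (8, list(range(36, 41))),
        (9, list(range(41, 46))),
        (10, list(range(46, 51))),
    ])
    seq3 = _eps([
        (11, list(range(51, 56))),
        (12, list(range(56, 61))),
        (13, list(range(61, 66))),
        (14, list(range(66, 71))),
        (15, list(range(71, 76))),
    ])
    return SequenceSet([seq1, seq2, seq3], name="orthogonal")


def make_nonorthogonal_set(variant: str = "ep9_ep13") -> SequenceSet:
    """The canonical shared-feature material.

    Sharing structure (``ep9_ep13`` variant): episodes 2 and 14 share two
    features (70, 71); episode 3 shares one feature with episode 7 (33) and
    one with episode 12 (58); episodes 9 and 13 share one feature (44).  The
    ``ep9_ep14`` variant instead places the last overlap between episodes 9
    and 14 (feature 66); the two descriptions of this material disagree on
    that pair, so both readings are provided.
    """
    if variant not in ("ep9_ep13", "ep9_ep14"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    seq1 = _eps([
        (1, [1, 2, 3, 4]),
        (2, [7, 8, 9, 10, 70, 71]),
        (3, [11, 12, 13, 14, 33, 58]),
        (4, [17, 18, 19, 20, 21]),
        (5, [22, 23, 24, 25]),
    ])
    if variant == "ep9_ep13":
        ep9 = (9, [41, 42, 43, 44, 45])
        ep13 = (13, [44, 61, 62, 64, 65])
        ep14 = (14, [66, 67, 68, 69, 70, 71])
    else:
        ep9 = (9, [41, 42, 43, 45, 66])
        ep13 = (13, [61, 62, 63, 64, 65])
        ep14 = (14, [66, 67, 68, 69, 70, 71])
    seq2 = _eps([
        (6, [26, 27, 28, 29]),
        (7, [30, 31, 32, 33, 34]),
        (8, [36, 37, 38, 39, 40]),
        ep9,
        (10, [46, 47, 48, 49, 50]),
    ])
    seq3 = _eps([
        (11, [51, 52, 53, 54, 55]),
        (12, [56, 57, 58, 59, 60]),
        ep13,
        ep14,
        (15, [72, 73, 74, 75]),
    ])
    return SequenceSet([seq1, seq2, seq3], name=f"nonorthogonal[{variant}]")


def make_random_set(
    n_sequences: int,
    episodes_per_seq: int,
    size_range: tuple[int, int] = (4, 6),
    sharing_spec: list[tuple[int, int, int]] | None = None,
    seed: int | None = None,
    n_features: int = 75,
) -> SequenceSet:
    """Generate a reproducible random sequence set.

    ``sharing_spec`` is a list of (episode_id_a, episode_id_b, n_shared)
    requests; shared features are drawn from episode ``a`` and substituted
    into episode ``b``.  Raises if the requested material does not fit into
    ``n_features`` Units.
    """
    rng = np.random.default_rng(seed)
    sharing_spec = sharing_spec or []
    sizes = {}
    eid = 0
    for _ in range(n_sequences):
        for _ in range(episodes_per_seq):
            eid += 1
            sizes[eid] = int(rng.integers(size_range[0], size_range[1] + 1))
    n_shared_total = sum(k for _, _, k in sharing_spec)
    total_needed = sum(sizes.values()) - n_shared_total
    if total_needed > n_features:
        raise ConfigurationError(
            f"need {total_needed} distinct features but only {n_features} available"
        )
    # deterministic packing, then substitution for sharing
    features: dict[int, list[int]] = {}
    nxt = 1
    for eid_, size in sizes.items():
        features[eid_] = list(range(nxt, nxt + size))
        nxt += size
    for a, b, k in sharing_spec:
        if a not in features or b not in features:
            raise ConfigurationError(f"sharing_spec references unknown episode ({a},{b})")
        if k > min(len(features[a]), len(features[b])):
            raise ConfigurationError("sharing_spec requests more features than episodes hold")
        donors = list(rng.choice(features[a], size=k, replace=False))
        keep = [f for f in features[b] if f not in donors]
        features[b] = keep[: len(features[b]) - k] + donors
    # re-pack to drop gaps beyond n_features
    used = sorted({f for fl in features.values() for f in fl})
    if used and used[-1] > n_features:
        remap = {old: new for new, old in enumerate(used, start=1)}
        features = {e: [remap[f] for f in fl] for e, fl in features.items()}
    seqs = []
    eid = 0
    for _ in range(n_sequences):
        seq = []
        for _ in range(episodes_per_seq):
            eid += 1
            seq.append(Episode(id=eid, features=frozenset(features[eid])))
        seqs.append(seq)
    return SequenceSet(seqs, name=f"random[{seed}]")


# ---------------------------------------------------------------------------
# input schedules
# ---------------------------------------------------------------------------

def _to_units(features, layer_offset: int) -> np.ndarray:
    return np.asarray(sorted(features), dtype=int) - 1 + layer_offset


def make_inputs(
    features,
    window: tuple[float, float],
    amplitude: float,
    targets: str,
    n_features: int = 75,
    batch: int | None = None,
    reset_wm: bool = False,
) -> list[InputEvent]:
    """Build the rectangular drive events for a feature set.

    ``targets`` is one of ``"wm_p"`` (retrieval cues), ``"l1_pf"`` or
    ``"l2_pf"`` (training presentations, driving pyramidal and
    fast-inhibitory populations together, the fast drive scaled by
    TRAIN_AMP_F/TRAIN_AMP_P).
    """
    feats = set(int(f) for f in (features if np.iterable(features) else [features]))
    if not feats:
        raise ConfigurationError("empty target feature set")
    if any(f < 1 or f > n_features for f in feats):
        raise ConfigurationError(f"feature index outside [1, {n_features}]")
    t0, t1 = window
    events: list[InputEvent] = []
    if targets == "wm_p":
        units = _to_units(feats, 0)
        events.append(InputEvent(t0, t1, units, "p", amplitude, batch, reset_wm=reset_wm))
    elif targets in ("l1_pf", "l2_pf"):
        off = n_features if targets == "l1_pf" else 2 * n_features
        units = _to_units(feats, off)
        events.append(InputEvent(t0, t1, units, "p", amplitude, batch))
        events.append(
            InputEvent(t0, t1, units, "f", amplitude * TRAIN_AMP_F / TRAIN_AMP_P, batch)
        )
    else:
        raise ConfigurationError(f"unknown input target {targets!r}")
    return events


def cue_event(
    feature: int,
    onset: float,
    duration: float = CUE_DURATION_S,
    amplitude: float = CUE_AMP,
    n_features: int = 75,
    batch: int | None = None,
) -> list[InputEvent]:
    """A retrieval cue: brief strong drive to one WM pyramidal Unit, with the
    working-memory reset fired at onset."""
    return make_inputs(
        [feature], (onset, onset + duration), amplitude, "wm_p",
        n_features=n_features, batch=batch, reset_wm=True,
    )
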