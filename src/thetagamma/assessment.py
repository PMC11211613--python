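"""Cycle-by-cycle scoring of sequence retrieval.

An episode counts as *recovered* within a theta cycle if every one of its
features' L2 pyramidal spike densities exceeds a threshold (70% of the
5 spikes/s ceiling, i.e. 3.5 spikes/s) simultaneously for at least one
integration step.  A sequence prefix counts as recovered if its episodes are
recovered in the correct temporal order (strictly increasing first
simultaneous-crossing times; ties fail).  Success tables report, per
sequence and episode position, the percentage of evaluated theta cycles
with correct recovery, averaged over repeated runs with different noise
seeds — the standard assessment protocol is 10 runs of 1.0 s per sequence.

Cycles are delimited on the theta generator's own trace (the pacemaker is
noise-free, so it is the natural clock): a cycle starts at each upward
crossing of 50% of the trace's range, and its *on-phase* is the
supra-threshold segment.  Episode detection is evaluated from one cycle
start to the next, so the theta tail after the on-phase still belongs to
its cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network, SimulationResult, simulate
from .sequences import SequenceSet, cue_event
from .units import ConfigurationError

__all__ = [
    "find_hybrids",
    "DETECTION_THRESHOLD",
    "ThetaCycle",
    "SuccessTable",
    "theta_cycles",
    "detect_episode",
    "episode_crossing_time",
    "detect_sequence",
    "success_table",
    "superposition_score",
]

DETECTION_THRESHOLD = 3.5  # 70% of the 5 spikes/s ceiling


@dataclass(frozen=True)
class ThetaCycle:
    """One theta cycle: [start, end) plus its supra-threshold on-phase."""

    index: int
    start: int          # step index of cycle start (upward crossing)
    end: int            # step index of next cycle start (or trace end)
    on_end: int         # step index where the on-phase ends
    dt: float

    @property
    def t_start(self) -> float:
        return self.start * self.dt

    @property
    def t_end(self) -> float:
        return self.end * self.dt


def theta_cycles(theta_trace: np.ndarray, dt: float) -> tuple[list[ThetaCycle], bool]:
    """Segment the theta generator trace into cycles.

    Returns ``(cycles, periodic)``.  For a (numerically) constant trace —
    the no-theta mode — returns an empty list with ``periodic=False``.
    Cycles extending past the end of the trace are dropped, so every
    returned cycle is fully contained in the simulated window.
    """
    x = np.asarray(theta_trace, dtype=float)
    if x.size < 2 or (x.max() - x.min()) < 0.5:
        return [], False
    thr = 0.5 * (x.max() + x.min())
    on = x > thr
    ups = np.flatnonzero(~on[:-1] & on[1:]) + 1
    cycles: list[ThetaCycle] = []
    for k, s in enumerate(ups):
        e = ups[k + 1] if k + 1 < len(ups) else None
        if e is None:
            break  # cycle not fully contained
        offs = np.flatnonzero(~on[s:e])
        on_end = s + (offs[0] if len(offs) else e - s)
        cycles.append(ThetaCycle(index=k, start=int(s), end=int(e), on_end=int(on_end), dt=dt))
    return cycles, True


def _episode_cols(episode, n_features: int) -> np.ndarray:
    cols = np.asarray(sorted(episode.features), dtype=int) - 1
    if cols.min() < 0 or cols.max() >= n_features:
        raise ConfigurationError(
            f"episode {episode.id} references features outside the layer"
        )
    return cols


def detect_episode(
    l2_trace: np.ndarray,
    episode,
    cycle: ThetaCycle | tuple[int, int],
    threshold: float = DETECTION_THRESHOLD,
) -> bool:
    """True iff all features of ``episode`` are simultaneously above
    ``threshold`` for at least one integration step inside the cycle."""
    return episode_crossing_time(l2_trace, episode, cycle, threshold) is not None


def episode_crossing_time(
    l2_trace: np.ndarray,
    episode,
    cycle: ThetaCycle | tuple[int, int],
    threshold: float = DETECTION_THRESHOLD,
) -> int | None:
    """Step index (absolute) of the first simultaneous supra-threshold step
    of the episode inside the cycle, or None."""
    s, e = (cycle.start, cycle.end) if isinstance(cycle, ThetaCycle) else cycle
    cols = _episode_cols(episode, l2_trace.shape[1])
    seg = l2_trace[s:e, cols]
    hits = np.flatnonzero((seg > threshold).all(axis=1))
    return int(s + hits[0]) if len(hits) else None


def detect_sequence(
    l2_trace: np.ndarray,
    sequence,
    cycle: ThetaCycle | tuple[int, int],
    threshold: float = DETECTION_THRESHOLD,
) -> tuple[list[bool], bool]:
    """Per-episode-position correctness plus whole-sequence correctness.

    Episode k is correct iff it is detected in the cycle and its first
    simultaneous-crossing time is strictly later than that of every
    *detected* earlier episode (a tie counts as an ordering failure).
    Episodes are scored individually — a missed episode does not forfeit
    the later ones — which is why the first, hardest position can score
    below the middle positions.  The whole sequence is correct iff every
    episode is detected in strictly increasing order.
    """
    times = [episode_crossing_time(l2_trace, ep, cycle, threshold) for ep in sequence]
    ok: list[bool] = []
    prev = -1
    for t in times:
        ok.append(t is not None and t > prev)
        prev = t if t is not None else prev
    return ok, all(ok)


@dataclass
class SuccessTable:
    """Percentage of theta cycles with correct recovery, per sequence and
    episode position, plus the unweighted cross-sequence mean row."""

    values: np.ndarray            # (n_sequences, n_positions), percent
    n_runs: int
    cycles_per_run: list[int]
    meta: dict = field(default_factory=dict)

    @property
    def mean_row(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        n_seq, n_pos = self.values.shape
        rows = [f"Sequence {i + 1}" for i in range(n_seq)] + ["Mean"]
        data = np.vstack([self.values, self.mean_row])
        return pd.DataFrame(
            data, index=rows, columns=[f"Episode {j + 1}" for j in range(n_pos)]
        )

    def __str__(self) -> str:
        hdr = "; ".join(f"{k}={v}" for k, v in self.meta.items())
        return (f"# {hdr}\n" if hdr else "") + self.to_frame().round(2).to_string()


def success_table(
    trained_network: Network,
    sequence_set: SequenceSet,
    n_runs: int = 10,
    duration: float = 1.0,
    seed: int = 0,
    cue_feature_index: int = 0,
    threshold: float = DETECTION_THRESHOLD,
    dt: float | None = None,
) -> SuccessTable:
    """Run the standard retrieval assessment.

    For each sequence, ``n_runs`` independent simulations of ``duration``
    are run (batched) with distinct noise streams; the cue is one feature
    of the sequence's first episode, delivered to WM at t = 0.05 s for
    50 ms.  Every complete theta cycle after the cue is scored with
    :func:`detect_sequence` and percentages are aggregated.
    """
    from .units import DEFAULT_DT

    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    dt = dt or DEFAULT_DT
    n_seq = len(sequence_set.sequences)
    n_pos = max(len(s) for s in sequence_set.sequences)
    values = np.zeros((n_seq, n_pos))
    cycles_per_run: list[int] = []
    cue_t = 0.05
    for s_idx, seq in enumerate(sequence_set.sequences):
        cue_feature = sorted(seq[0].features)[cue_feature_index]
        events = cue_event(cue_feature, onset=cue_t, n_features=trained_network.n_features)
        res = simulate(
            trained_network,
            duration=duration,
            events=events,
            seed=seed + 1000 * s_idx,
            batch=n_runs,
            dt=dt,
            record=("L2",),
        )
        counts = np.zeros(n_pos)
        n_cycles = 0
        for b in range(n_runs):
            cycles, periodic = theta_cycles(res.theta[b], dt)
            cycles = [c for c in cycles if c.start * dt >= cue_t]
            for cyc in cycles:
                ok, _ = detect_sequence(res.z["L2"][b].astype(float), seq, cyc, threshold)
                counts[: len(ok)] += ok
            n_cycles += len(cycles)
        values[s_idx] = 100.0 * counts / max(n_cycles, 1)
        cycles_per_run.append(n_cycles // n_runs)
    return SuccessTable(
        values=values,
        n_runs=n_runs,
        cycles_per_run=cycles_per_run,
        meta={"duration_s": duration, "n_runs": n_runs, "seed": seed},
    )


def superposition_score(
    l2_trace: np.ndarray,
    sequence_set: SequenceSet,
    cycle: ThetaCycle | tuple[int, int],
    threshold: float = DETECTION_THRESHOLD,
) -> int:
    """Number of integration steps in the cycle at which two or more
    distinct episodes are simultaneously fully above threshold, excluding
    pairs whose joint activation is explained by a shared feature alone
    (i.e. pairs that share at least one feature)."""
    s, e = (cycle.start, cycle.end) if isinstance(cycle, ThetaCycle) else cycle
    eps = sorted(sequence_set.episodes.values(), key=lambda x: x.id)
    masks = []
    for ep in eps:
        cols = _episode_cols(ep, l2_trace.shape[1])
        masks.append((l2_trace[s:e, cols] > threshold).all(axis=1))
    count = 0
    for t in range(e - s):
        active = [ep for ep, m in zip(eps, masks) if m[t]]
        hit = False
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                if not (active[i].features & active[j].features):
                    hit = True
        count += hit
    return count


def find_hybrids(
    l2_trace: np.ndarray,
    sequence_set: SequenceSet,
    cycle: ThetaCycle | tuple[int, int],
    threshold: float = DETECTION_THRESHOLD,
) -> list[tuple[list[int], list[int]]]:
    """Detect dream-like hybrid sequences within one theta cycle.

    A hybrid is a prefix of one trained sequence (at least two episodes,
    detected in order) immediately followed by a suffix run of a different
    sequence (at least one episode), where the junction episodes share at
    least one feature.  Returns a list of (prefix_episode_ids,
    suffix_episode_ids) pairs; recombination requires shared features, so
    orthogonal material can never produce hybrids.
    """
    # ordered detections
    det: list[tuple[int, int]] = []  # (time, episode id)
    for ep in sorted(sequence_set.episodes.values(), key=lambda x: x.id):
        t = episode_crossing_time(l2_trace, ep, cycle, threshold)
        if t is not None:
            det.append((t, ep.id))
    det.sort()
    order = [eid for _, eid in det]
    seq_of = {}
    pos_of = {}
    for si, seq in enumerate(sequence_set.sequences):
        for pi, ep in enumerate(seq):
            seq_of[ep.id] = si
            pos_of[ep.id] = pi
    sharing = sequence_set.sharing_map
    episodes = sequence_set.episodes

    def shares(a: int, b: int) -> bool:
        return bool(episodes[a].features & episodes[b].features)

    hybrids = []
    n = len(order)
    for i in range(n - 2):
        # grow a prefix run starting at a sequence's first episode
        a = order[i]
        if pos_of[a] != 0:
            continue
        j = i
        while (j + 1 < n and seq_of[order[j + 1]] == seq_of[a]
               and pos_of[order[j + 1]] == pos_of[order[j]] + 1):
            j += 1
        if j - i + 1 < 2 or j + 1 >= n:
            continue
        nxt = order[j + 1]
        if seq_of[nxt] == seq_of[a] or pos_of[nxt] == 0:
            continue
        # junction: the last prefix episode shares features with the suffix
        # head or with the suffix head's predecessor in its own sequence
        prev_in_b = sequence_set.sequences[seq_of[nxt]][pos_of[nxt] - 1].id
        if shares(order[j], nxt) or shares(order[j], prev_in_b):
            k = j + 1
            while (k + 1 < n and seq_of[order[k + 1]] == seq_of[nxt]
                   and pos_of[order[k + 1]] == pos_of[order[k]] + 1):
                k += 1
            hybrids.append((order[i:j + 1], order[j + 1:k + 1]))
    return hybrids
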