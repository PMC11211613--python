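"""Hebbian / anti-Hebbian training of the plastic synapse matrices.

Three glutamatergic kinds (within-L1 excitatory ``W_p``, within-L1
bi-synaptic inhibitory ``W_f``, L2->L1 excitatory ``W_p^{L1L2}``) follow a
thresholded-correlation Hebb rule: the increment is proportional to the
product of the supra-threshold parts of post- and pre-synaptic pyramidal
spike densities.  The desynchronizing kind ``A_f`` follows an anti-Hebbian
rule: it grows where the post-synaptic Unit is active while the pre-synaptic
Unit is silent, so that at retrieval a newly active episode instantly
inhibits the Units of every other stored episode.

Two standing mechanisms shape the final weights: a per-synapse saturation
``w_max`` and a per-Unit normalization capping the sum of incoming weights
of each kind, which makes episodes of different richness behave alike and
halves the incoming weights of features shared by two episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import ConnectionSet, Network, NetworkState, simulate
from .sequences import (
    SequenceSet,
    TRAIN_AMP_P,
    TRAIN_PRESENTATION_S,
    make_inputs,
)
from .units import DEFAULT_DT, ConfigurationError

__all__ = [
    "KindParams",
    "LearningParams",
    "hebbian_update",
    "anti_hebbian_update",
    "normalize_incoming",
    "train_sequences",
]


@dataclass(frozen=True)
class KindParams:
    """Learning constants for one synapse kind.

    ``rate`` is the learning factor in weight units per (spikes/s)^2 per
    second; ``theta_pre``/``theta_post`` the activity thresholds (spikes/s);
    ``w_max`` the per-synapse saturation; ``cap`` the per-Unit maximum sum
    of incoming weights of this kind.
    """

    rate: float
    theta_pre: float
    theta_post: float
    w_max: float
    cap: float

    def __post_init__(self):
        if self.cap <= 0 or self.w_max < 0:
            raise ConfigurationError("cap must be > 0 and w_max >= 0")
        if not (0 <= self.theta_pre <= 5 and 0 <= self.theta_post <= 5):
            raise ConfigurationError("thresholds must lie in [0, 5] spikes/s")


@dataclass(frozen=True)
class LearningParams:
    wp: KindParams = field(default_factory=lambda: KindParams(
        rate=400.0, theta_pre=3.0, theta_post=3.0, w_max=44.8, cap=160.0))
    wf: KindParams = field(default_factory=lambda: KindParams(
        rate=400.0, theta_pre=3.0, theta_post=3.0, w_max=3.6, cap=15.0))
    af: KindParams = field(default_factory=lambda: KindParams(
        rate=4.0, theta_pre=3.0, theta_post=1.0, w_max=0.7, cap=100.0))
    wp12: KindParams = field(default_factory=lambda: KindParams(
        rate=400.0, theta_pre=3.0, theta_post=3.0, w_max=21.6, cap=105.0))


def hebbian_update(
    w: np.ndarray,
    pre_activity: np.ndarray,
    post_activity: np.ndarray,
    params: KindParams,
    dt: float,
    zero_diagonal: bool = True,
) -> np.ndarray:
    """One step of the thresholded-correlation Hebb rule (in place).

    dW[i, j] = rate * dt * [post_i - theta_post]_+ * [pre_j - theta_pre]_+,
    clipped to [0, w_max]; the diagonal of within-layer matrices stays 0.
    """
    post = np.clip(post_activity - params.theta_post, 0.0, None)
    pre = np.clip(pre_activity - params.theta_pre, 0.0, None)
    w += params.rate * dt * np.outer(post, pre)
    np.clip(w, 0.0, params.w_max, out=w)
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)
    if np.any(w < 0):
        raise AssertionError("negative weight after Hebbian update")
    return w


def anti_hebbian_update(
    a: np.ndarray,
    pre_activity: np.ndarray,
    post_activity: np.ndarray,
    params: KindParams,
    dt: float,
) -> np.ndarray:
    """One step of the anti-Hebbian rule for the desynchronizing kind.

    dA[i, j] = rate * dt * [theta_post - post_i]_+ * [pre_j - theta_pre]_+ :
    growth requires a silent post-synaptic Unit while the pre-synaptic Unit
    fires, i.e. anti-correlated activity.  With this orientation an episode
    recovers inhibition *onto* every Unit that stayed silent while it was
    encoded, so at retrieval the active episode instantly suppresses all
    other stored episodes; a feature shared by two episodes never receives
    desynchronizing synapses from either of its partner sets, because it
    was active whenever they were.
    """
    post_silent = np.clip(params.theta_post - post_activity, 0.0, None)
    pre = np.clip(pre_activity - params.theta_pre, 0.0, None)
    a += params.rate * dt * np.outer(post_silent, pre)
    np.clip(a, 0.0, params.w_max, out=a)
    np.fill_diagonal(a, 0.0)
    return a


def normalize_incoming(w: np.ndarray, cap: float) -> np.ndarray:
    """Rescale any post-synaptic row whose incoming sum exceeds ``cap``."""
    if cap <= 0:
        raise ConfigurationError("cap must be > 0")
    sums = w.sum(axis=1)
    over = sums > cap
    if np.any(over):
        w[over] *= (cap / sums[over])[:, None]
    return w


def train_sequences(
    network: Network,
    sequence_set: SequenceSet,
    learning_params: LearningParams | None = None,
    dt: float = DEFAULT_DT,
    seed: int | None = 0,
) -> Network:
    """Encode a sequence set into the plastic matrices.

    For each sequence of N episodes, N+1 presentations of 250 ms are run;
    presentation k drives episode k in L1 and episode k-1 in L2 (null
    episodes at the ends), directly stimulating pyramidal and
    fast-inhibitory populations of the episode's features — feedforward and
    theta influences are disabled in the training mode.  Each episode pair
    is presented exactly once, and each presentation starts from the
    resting network state so that the decay tail of one pair cannot leak
    into the correlations of the next.  The plastic rules plus
    normalization are applied at every integration step.  Returns the
    trained network (a copy; the input network is untouched).
    """
    lp = learning_params or LearningParams()
    net = network.copy()
    net.mode = "training"
    f = net.n_features
    if sequence_set.max_feature() > f:
        raise ConfigurationError("sequence set references features beyond the layer size")
    conn = net.connections
    wp, wf, af, wp12 = conn.wp_l1l1, conn.wf_l1l1, conn.af_l1l1, conn.wp_l1l2

    def learn(z_l1: np.ndarray, z_l2: np.ndarray, step: int) -> None:
        l1 = z_l1[0]
        l2 = z_l2[0]
        hebbian_update(wp, l1, l1, lp.wp, dt)
        hebbian_update(wf, l1, l1, lp.wf, dt)
        anti_hebbian_update(af, l1, l1, lp.af, dt)
        hebbian_update(wp12, l2, l1, lp.wp12, dt, zero_diagonal=False)

    def normalize_all() -> None:
        normalize_incoming(wp, lp.wp.cap)
        normalize_incoming(wf, lp.wf.cap)
        normalize_incoming(af, lp.af.cap)
        normalize_incoming(wp12, lp.wp12.cap)

    for s_idx, seq in enumerate(sequence_set.sequences):
        n_ep = len(seq)
        if any(not ep.features for ep in seq):
            raise ConfigurationError("episode with no features")
        for k in range(1, n_ep + 2):  # presentations k = 1 .. N+1
            events = []
            if k <= n_ep:  # L1 gets episode k
                events += make_inputs(seq[k - 1].features, (0.0, TRAIN_PRESENTATION_S),
                                      TRAIN_AMP_P, "l1_pf", n_features=f)
            if k >= 2:     # L2 gets episode k-1
                events += make_inputs(seq[k - 2].features, (0.0, TRAIN_PRESENTATION_S),
                                      TRAIN_AMP_P, "l2_pf", n_features=f)
            simulate(
                net,
                duration=TRAIN_PRESENTATION_S,
                events=events,
                seed=None if seed is None else seed + 100 * s_idx + k,
                batch=1,
                dt=dt,
                record=(),
                learn=learn,
            )
            normalize_all()
    net.mode = network.mode if network.mode != "training" else "retrieval"
    return net
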