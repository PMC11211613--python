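"""Functioning modes: retrieval and the isolation-from-the-world variants.

After training, the network can be run in its normal *retrieval* mode (cues
arrive through working memory, theta disinhibits L1) or cut off from the
environment.  In isolation the WM->L1 pathway is disconnected and every L1
Unit receives strong positive uniform noise; depending on the neuromodulatory
state being emulated, synaptic strengths are also changed:

``imagination``
    noise only — synapses keep their trained values; the network
    spontaneously replays stored sequences in random order.
``dreaming``
    higher noise and all plastic synapses reduced to 1/3 — replay becomes
    labile and recombines sequences at shared features into novel hybrids.
``dreaming_fast_gamma``
    dreaming with the L1/L2 gamma rhythm accelerated to ~45 Hz.
``dreaming_no_theta``
    dreaming with the theta oscillation replaced by its temporal mean
    (constant disinhibition), the non-theta slow-wave-sleep-like state.
``schizophrenia``
    dreaming-level noise with only the desynchronizing A_f synapses halved —
    episodes from different memories activate simultaneously
    (delusion-like superposition).

Every transform operates on a pristine copy of the trained weights; modes
are never composed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    GAMMA_FAST_FACTOR,
    Network,
    NoiseSpec,
    SimulationResult,
    scale_time_constants,
    simulate,
)
from .sequences import cue_event
from .units import ConfigurationError

__all__ = [
    "ModeTransform",
    "CueEvent",
    "MODE_TRANSFORMS",
    "apply_mode",
    "run_retrieval",
    "run_isolation",
    "IMAGINATION_NOISE",
    "DREAMING_NOISE",
]

# uniform positive noise ranges (min, max) fed to L1 pyramidal inputs in the
# isolation modes; calibrated so that the imagination mode spontaneously
# recalls stored sequences while dreaming is noticeably more labile
IMAGINATION_NOISE = (0.0, 260.0)
DREAMING_NOISE = (0.0, 390.0)


@dataclass(frozen=True)
class ModeTransform:
    """Parameter changes that turn a trained retrieval network into one of
    the functioning modes."""

    mode: str
    noise_positive_uniform: tuple[float, float] | None = None
    synapse_scale: float = 1.0       # multiplier on all plastic weights
    af_scale: float = 1.0            # extra multiplier on A_f only
    gamma_factor: float = 1.0        # fast-GABA time-constant multiplier
    theta_mode: str = "oscillating"  # or "constant"
    wm_connected: bool = True

    def __post_init__(self):
        if self.synapse_scale <= 0 or self.af_scale <= 0 or self.gamma_factor <= 0:
            raise ConfigurationError("scale factors must be > 0")


MODE_TRANSFORMS: dict[str, ModeTransform] = {
    "retrieval": ModeTransform(mode="retrieval"),
    "imagination": ModeTransform(
        mode="imagination", noise_positive_uniform=IMAGINATION_NOISE,
        wm_connected=False),
    "dreaming": ModeTransform(
        mode="dreaming", noise_positive_uniform=DREAMING_NOISE,
        synapse_scale=1.0 / 3.0, wm_connected=False),
    "dreaming_fast_gamma": ModeTransform(
        mode="dreaming_fast_gamma", noise_positive_uniform=DREAMING_NOISE,
        synapse_scale=1.0 / 3.0, gamma_factor=GAMMA_FAST_FACTOR,
        wm_connected=False),
    "dreaming_no_theta": ModeTransform(
        mode="dreaming_no_theta", noise_positive_uniform=DREAMING_NOISE,
        synapse_scale=1.0 / 3.0, theta_mode="constant", wm_connected=False),
    "schizophrenia": ModeTransform(
        mode="schizophrenia", noise_positive_uniform=DREAMING_NOISE,
        af_scale=0.5, wm_connected=False),
}


@dataclass(frozen=True)
class CueEvent:
    """A retrieval cue: one feature driven into working memory."""

    feature: int
    onset: float
    duration: float = 0.05
    amplitude: float = 700.0


def apply_mode(network: Network, transform: ModeTransform) -> Network:
    """Return a new network with the mode transform applied.

    The input (trained) network is left untouched; weight scaling always
    starts from its pristine matrices.
    """
    net = network.copy()
    net.mode = transform.mode
    c = net.connections
    if transform.synapse_scale != 1.0:
        c.wp_l1l1 *= transform.synapse_scale
        c.wf_l1l1 *= transform.synapse_scale
        c.af_l1l1 *= transform.synapse_scale
        c.wp_l1l2 *= transform.synapse_scale
    if transform.af_scale != 1.0:
        c.af_l1l1 *= transform.af_scale
    if transform.gamma_factor != 1.0:
        scale_time_constants(net, ["L1L2_fastGABA"], transform.gamma_factor)
    net.noise = NoiseSpec(
        sigma_p=net.noise.sigma_p,
        sigma_f=net.noise.sigma_f,
        uniform_l1=transform.noise_positive_uniform,
    )
    return net


def run_retrieval(
    trained_network: Network,
    cues: list[CueEvent],
    duration: float,
    seed: int | None = None,
    batch: int = 1,
    record=("L2",),
) -> SimulationResult:
    """Run the retrieval mode: WM holds each cue until the next one arrives,
    theta disinhibits L1, and L2 replays the cued sequence once per theta
    cycle."""
    net = apply_mode(trained_network, MODE_TRANSFORMS["retrieval"])
    events = []
    for cue in cues:
        if not (1 <= cue.feature <= net.n_features):
            raise ConfigurationError(f"cue feature {cue.feature} outside [1, {net.n_features}]")
        events += cue_event(cue.feature, cue.onset, cue.duration, cue.amplitude,
                            n_features=net.n_features)
    return simulate(net, duration, events, seed=seed, batch=batch, record=record)


def run_isolation(
    trained_network: Network,
    mode: str,
    duration: float = 10.0,
    seed: int | None = None,
    batch: int = 1,
    record=("L2",),
) -> SimulationResult:
    """Run one of the isolation modes (no environmental input, no WM)."""
    if mode not in MODE_TRANSFORMS or mode == "retrieval":
        raise ConfigurationError(f"unknown isolation mode {mode!r}")
    net = apply_mode(trained_network, MODE_TRANSFORMS[mode])
    return simulate(net, duration, events=(), seed=seed, batch=batch, record=record)
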