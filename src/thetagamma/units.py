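"""Single computational Unit: a four-population neural mass model.

Each Unit lumps four interacting neural populations — pyramidal cells (p),
excitatory interneurons (e), slow GABAergic interneurons (s) and fast
GABAergic interneurons (f) — into a handful of state variables.  Every
synaptic pathway is a second-order critically damped kernel

    h(t) = G * w * t * exp(-w * t)

whose gain ``G`` (mV) and reciprocal time constant ``w`` (1/s) depend on the
neurotransmitter class (glutamatergic, slow GABA, fast GABA).  Population
firing is a sigmoid of the membrane potential, saturating at 5 spikes/s.

Internal couplings ``C_ij`` (first subscript post-synaptic) select the Unit's
intrinsic rhythm.  Three presets are provided:

``gamma``
    excitable unit whose pyramidal/fast-interneuron loop resonates near
    40 Hz; silent at rest, oscillating under moderate excitatory drive.
``theta``
    autonomous relaxation oscillator near 4 Hz built on the slow
    (glutamatergic + slow-GABA) loop; used as the external theta pacemaker.
``wm``
    gamma unit augmented with a pyramidal self-excitation loop ``C_pp``
    making it bistable: a brief strong input ignites persistent activity.

All stepping functions broadcast over leading axes, so a single code path
serves one unit, a layer of units, or a batch of independent simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "UnitParams",
    "UnitState",
    "UnitInput",
    "make_unit",
    "step_unit",
    "simulate_unit",
    "sigmoid",
    "dominant_frequency",
    "PRESETS",
    "Z_MAX",
    "DEFAULT_DT",
]

Z_MAX = 5.0          # maximum population discharge rate, spikes/s
SIG_SLOPE = 0.56     # sigmoid steepness, 1/mV
SIG_V0 = 6.0         # sigmoid half-activation potential, mV
DEFAULT_DT = 1e-4    # integration step, s

# kernel state variable names: one (y, dy) pair per internal pathway
PATHWAYS = ("p", "e", "s", "f", "up", "uf")


class ConfigurationError(ValueError):
    """Raised for unknown presets, parameter names, or invalid values."""


class NumericalError(FloatingPointError):
    """Raised when a state or input variable becomes non-finite."""


@dataclass(frozen=True)
class UnitParams:
    """Parameter set of one neural-mass Unit.

    Couplings are dimensionless synaptic contact numbers; ``g_*`` are kernel
    gains in mV and ``w_*`` reciprocal time constants in 1/s.
    """

    preset: str
    # internal couplings C_ij (post, pre)
    c_pe: float
    c_ep: float
    c_ps: float
    c_sp: float
    c_pf: float
    c_fp: float
    c_fs: float
    c_ff: float
    c_pp: float
    # synaptic kernel constants per neurotransmitter class
    g_glu: float
    w_glu: float
    g_slow: float
    w_slow: float
    g_fast: float
    w_fast: float
    # input-pathway kernel (long-range/environmental glutamatergic synapses)
    g_in: float
    w_in: float
    # tonic bias on the pyramidal membrane potential (mV); negative values
    # model the standing inhibition that the theta drive transiently lifts
    bias_p: float
    # sigmoid
    z_max: float = Z_MAX
    sig_slope: float = SIG_SLOPE
    sig_v0: float = SIG_V0

    def __post_init__(self) -> None:
        for name in ("w_glu", "w_slow", "w_fast", "w_in"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("g_glu", "g_slow", "g_fast", "g_in"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")

    def with_overrides(self, **overrides: float) -> "UnitParams":
        unknown = set(overrides) - set(self.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown parameter override(s): {sorted(unknown)}")
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# Presets.
#
# The gamma unit's pyramidal <-> fast-interneuron loop (glutamatergic kernel
# w_glu = 120/s feeding the fast GABA kernel w_fast = 500/s) has its 180-degree
# loop-phase near 40 Hz; the couplings put the resting point below the Hopf
# bifurcation (silent) and moderate drive above it (limit cycle).  The theta
# unit uses only the slow loop (pyramidal -> slow GABA -> pyramidal) with
# slowed kernels plus a constant intrinsic drive, yielding an autonomous
# relaxation oscillation near 4 Hz whose supra-threshold plateau is the theta
# "on" phase.  The wm preset adds the pyramidal self-excitation C_pp.
# ---------------------------------------------------------------------------

_GAMMA = dict(
    c_pe=120.0, c_ep=140.0,
    c_ps=10.0, c_sp=10.0,
    c_pf=350.0, c_fp=140.0,
    c_fs=10.0, c_ff=10.0,
    c_pp=0.0,
    g_glu=3.25, w_glu=110.0,
    g_slow=4.45, w_slow=30.0,
    g_fast=10.0, w_fast=450.0,
    g_in=3.25, w_in=110.0,
    bias_p=-5.0,
)

# Theta kernels are the gamma glutamatergic/slow-GABA kernels slowed to the
# theta time scale with the kernel area G/w held fixed, so the waveform is an
# exact time-rescaled relaxation oscillation.
_THETA = dict(
    c_pe=140.0, c_ep=170.0,
    c_ps=150.0, c_sp=15.0,
    c_pf=0.0, c_fp=0.0,
    c_fs=0.0, c_ff=0.0,
    c_pp=0.0,
    g_glu=7.28, w_glu=89.6,
    g_slow=9.968, w_slow=22.4,
    g_fast=10.0, w_fast=450.0,
    g_in=7.28, w_in=89.6,
    bias_p=0.0,
)

# The working-memory unit trades the regenerative e-loop for a pyramidal
# self-excitation loop, giving a noise-robust bistable switch: silent at
# rest, persistently active after a brief strong cue.
_WM = dict(
    _GAMMA,
    c_pe=0.0, c_ep=0.0,
    c_pf=100.0,
    c_pp=200.0,
    bias_p=0.0,
)
_WM["w_in"] = 110.0
_WM["g_in"] = 3.25

PRESETS = {"gamma": _GAMMA, "theta": _THETA, "wm": _WM}

# constant intrinsic drive (spikes/s) that keeps the theta preset on its
# autonomous 4.0 Hz limit cycle with a ~0.44 on-phase fraction; applied by
# callers that run the unit as a pacemaker
THETA_INTRINSIC_DRIVE = 550.0


def make_unit(preset: str, overrides: dict[str, float] | None = None) -> UnitParams:
    """Build the parameter set for one Unit.

    Parameters
    ----------
    preset : {"gamma", "theta", "wm"}
        Intrinsic-rhythm preset.  Only the ``wm`` preset has a nonzero
        pyramidal self-excitation ``c_pp``.
    overrides : dict, optional
        Field-name -> value replacements applied on top of the preset.
    """
    try:
        base = PRESETS[preset]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}"
        ) from None
    params = UnitParams(preset=preset, **base)
    if overrides:
        params = params.with_overrides(**overrides)
    return params


@dataclass
class UnitState:
    """State of one Unit: a (psp, d/dt psp) pair per synaptic pathway.

    Arrays may carry arbitrary leading batch axes.  ``y`` maps pathway name
    to the post-synaptic potential (mV), ``dy`` to its time derivative.
    """

    y: dict[str, np.ndarray]
    dy: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, shape: tuple[int, ...] = (), dtype=np.float64) -> "UnitState":
        return cls(
            y={k: np.zeros(shape, dtype) for k in PATHWAYS},
            dy={k: np.zeros(shape, dtype) for k in PATHWAYS},
        )

    def copy(self) -> "UnitState":
        return UnitState(
            y={k: v.copy() for k, v in self.y.items()},
            dy={k: v.copy() for k, v in self.dy.items()},
        )


@dataclass
class UnitInput:
    """External drives to one Unit at the current step.

    ``u_p``/``u_f`` accumulate long-range synaptic input plus environmental
    input (spikes/s equivalents); ``n_p``/``n_f`` are the noise samples added
    to them.  ``af_drive`` is the algebraic (zero-lag) drive onto the fast
    interneurons carried by the very fast A_f synapse class; ``wm_gate``
    multiplies the pyramidal self-loop (used by the working-memory reset).
    """

    u_p: np.ndarray | float = 0.0
    u_f: np.ndarray | float = 0.0
    n_p: np.ndarray | float = 0.0
    n_f: np.ndarray | float = 0.0
    af_drive: np.ndarray | float = 0.0
    wm_gate: np.ndarray | float = 1.0


def sigmoid(v, z_max=Z_MAX, slope=SIG_SLOPE, v0=SIG_V0):
    """Population rate (spikes/s) for membrane potential ``v`` (mV).

    Output is clamped to [0, z_max] to guard against rounding.
    """
    out = z_max / (1.0 + np.exp(slope * (v0 - np.asarray(v, dtype=float))))
    return np.clip(out, 0.0, z_max)


def potentials(state: UnitState, params: UnitParams, inp: UnitInput):
    """Membrane potentials (v_p, v_e, v_s, v_f) from the current state."""
    y = state.y
    v_p = (
        params.c_pe * y["e"]
        - params.c_ps * y["s"]
        - params.c_pf * y["f"]
        + params.c_pp * inp.wm_gate * y["p"]
        + y["up"]
        + params.bias_p
    )
    v_e = params.c_ep * y["p"]
    v_s = params.c_sp * y["p"]
    v_f = (
        params.c_fp * y["p"]
        - params.c_fs * y["s"]
        - params.c_ff * y["f"]
        + y["uf"]
        + inp.af_drive
    )
    return v_p, v_e, v_s, v_f


def rates(state: UnitState, params: UnitParams, inp: UnitInput | None = None):
    """Spike densities ``z_pop`` of the four populations (spikes/s)."""
    inp = inp or UnitInput()
    v_p, v_e, v_s, v_f = potentials(state, params, inp)
    sig = lambda v: sigmoid(v, params.z_max, params.sig_slope, params.sig_v0)
    return sig(v_p), sig(v_e), sig(v_s), sig(v_f)


def _kernel_step(y, dy, x, g, w, dt):
    """One fixed Euler step of y'' = g*w*x - 2*w*y' - w^2*y.

    The position update runs first and the velocity update reads the new
    position (semi-implicit Euler), which is slightly more stable for the
    fast kernels at the default step."""
    y_new = y + dt * dy
    dy_new = dy + dt * (g * w * x - 2.0 * w * dy - w * w * y_new)
    return y_new, dy_new


def step_unit(
    state: UnitState, params: UnitParams, inp: UnitInput, dt: float = DEFAULT_DT
) -> UnitState:
    """Advance one Unit by a single explicit Euler step.

    Deterministic given (state, input); noise is part of ``inp``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    z_p, z_e, z_s, z_f = rates(state, params, inp)
    for name, val in (("u_p", inp.u_p), ("u_f", inp.u_f)):
        if not np.all(np.isfinite(val)):
            raise NumericalError(f"non-finite input {name}")
    drives = {
        "p": z_p,
        "e": z_e,
        "s": z_s,
        "f": z_f,
        "up": np.asarray(inp.u_p, dtype=float) + inp.n_p,
        "uf": np.asarray(inp.u_f, dtype=float) + inp.n_f,
    }
    kernel = {
        "p": (params.g_glu, params.w_glu),
        "e": (params.g_glu, params.w_glu),
        "s": (params.g_slow, params.w_slow),
        "f": (params.g_fast, params.w_fast),
        "up": (params.g_in, params.w_in),
        "uf": (params.g_in, params.w_in),
    }
    new = UnitState(y={}, dy={})
    for k in PATHWAYS:
        g, w = kernel[k]
        y, dy = _kernel_step(state.y[k], state.dy[k], drives[k], g, w, dt)
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(dy))):
            raise NumericalError(f"non-finite state in pathway {k!r}")
        new.y[k], new.dy[k] = y, dy
    return new


def simulate_unit(
    params: UnitParams,
    duration: float,
    dt: float = DEFAULT_DT,
    u_p: float | np.ndarray = 0.0,
    u_f: float = 0.0,
    noise_sigma_p: float = 0.0,
    noise_sigma_f: float = 0.0,
    seed: int | None = None,
    state: UnitState | None = None,
):
    """Run one isolated Unit and return (t, z_p trace, final state).

    ``u_p`` may be a scalar or a per-step array.  Noise magnitudes are the
    per-step standard deviations at the default dt and are rescaled by
    1/sqrt(dt/DEFAULT_DT) so spectra are dt-invariant.
    """
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(dt / DEFAULT_DT)
    st = state.copy() if state is not None else UnitState.zeros(())
    u_p = np.broadcast_to(np.asarray(u_p, dtype=float), (n,)) if np.ndim(u_p) else np.full(n, float(u_p))
    z = np.empty(n)
    for i in range(n):
        n_p = rng.normal(0.0, noise_sigma_p * scale) if noise_sigma_p else 0.0
        n_f = rng.normal(0.0, noise_sigma_f * scale) if noise_sigma_f else 0.0
        inp = UnitInput(u_p=u_p[i], u_f=u_f, n_p=n_p, n_f=n_f)
        st = step_unit(st, params, inp, dt)
        z[i] = rates(st, params)[0]
    t = (np.arange(n) + 1) * dt
    return t, z, st


def dominant_frequency(trace: np.ndarray, dt: float) -> tuple[float, bool]:
    """Frequency (Hz) of the largest nonzero-frequency spectral peak.

    Returns ``(frequency, is_oscillatory)``.  A (numerically) constant trace
    yields ``(0.0, False)`` rather than raising.  The caller is expected to
    have removed any transient prefix.
    """
    x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    if x.size < 4 or np.max(np.abs(x)) < 1e-12:
        return 0.0, False
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=dt)
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if spec[k] == 0.0:
        return 0.0, False
    return float(freqs[k]), True
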