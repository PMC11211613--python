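"""Assembly and simulation of the three-layer theta-gamma memory network.

The architecture is three layers of identical feature-coding Units — a
working-memory layer (``WM``), an auto-associative layer (``L1``) and a
hetero-associative output layer (``L2``), 75 Units each by default — plus a
single external theta pacemaker Unit.  Fixed wiring: diagonal feature-
preserving feedforward WM->L1 and L1->L2, and a uniform excitatory synapse
from the theta generator to every L1 pyramidal population.  Plastic wiring
(all zero before training): within-L1 excitatory ``W_p``, within-L1
bi-synaptic inhibitory ``W_f``, within-L1 very fast desynchronizing ``A_f``,
and the L2->L1 excitatory ``W_p^{L1L2}`` that encodes episode succession.

Matrix orientation everywhere: rows are post-synaptic, columns pre-synaptic.

The simulator integrates every Unit's second-order synaptic kernels with a
fixed-step explicit Euler scheme and is vectorized over an arbitrary batch of
independent noise realizations, which is how the assessment protocol runs its
repeated trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .units import (
    DEFAULT_DT,
    PATHWAYS,
    THETA_INTRINSIC_DRIVE,
    Z_MAX,
    ConfigurationError,
    NumericalError,
    UnitParams,
    make_unit,
    sigmoid,
)

__all__ = [
    "N_FEATURES",
    "ConnectionSet",
    "NoiseSpec",
    "InputEvent",
    "Network",
    "SimulationResult",
    "build_network",
    "simulate",
    "scale_time_constants",
    "GAMMA_FAST_FACTOR",
]

N_FEATURES = 75

MODES = (
    "training",
    "retrieval",
    "imagination",
    "dreaming",
    "dreaming_fast_gamma",
    "dreaming_no_theta",
    "schizophrenia",
)

# fast-GABA time-constant multiplier that accelerates the intrinsic gamma
# rhythm of L1/L2 Units from the basal ~35 Hz network regime to ~45 Hz
GAMMA_FAST_FACTOR = 0.72

# discharge threshold of the very fast desynchronizing pathway: A_f synapses
# transmit the supra-baseline part of the pre-synaptic spike density, so they
# convey episode bursts and ignore the sub-threshold background hum
AF_PRE_THRESHOLD = 3.5

# fixed wiring strengths (dimensionless gains on pre-synaptic spike density)
K_WM_L1 = 100.0    # diagonal WM -> L1
K_L1_L2 = 185.0    # diagonal L1 -> L2
K_THETA = 88.0     # uniform theta generator -> L1

# the L2 layer reads L1 through fast (AMPA-like) feedforward kernels, so its
# output follows the brief L1 gamma bursts with little attenuation
L2_INPUT_KERNEL = {"w_in": 300.0, "g_in": 8.8636}

# L1 units carry a slow-GABA adaptation loop (spike-frequency fatigue) that
# damps immediate re-activation of an episode after its burst
L1_ADAPTATION = {"c_ps": 30.0, "c_sp": 60.0}


@dataclass
class ConnectionSet:
    """All inter-unit synapses.  Plastic matrices have zero diagonals."""

    wp_l1l1: np.ndarray
    wf_l1l1: np.ndarray
    af_l1l1: np.ndarray
    wp_l1l2: np.ndarray
    k_wm_l1: float = K_WM_L1
    k_l1_l2: float = K_L1_L2
    k_theta: float = K_THETA

    @classmethod
    def zeros(cls, n: int = N_FEATURES, **kw) -> "ConnectionSet":
        return cls(
            wp_l1l1=np.zeros((n, n)),
            wf_l1l1=np.zeros((n, n)),
            af_l1l1=np.zeros((n, n)),
            wp_l1l2=np.zeros((n, n)),
            **kw,
        )

    @property
    def plastic(self) -> dict[str, np.ndarray]:
        return {
            "Wp_L1L1": self.wp_l1l1,
            "Wf_L1L1": self.wf_l1l1,
            "Af_L1L1": self.af_l1l1,
            "Wp_L1L2": self.wp_l1l2,
        }

    def copy(self) -> "ConnectionSet":
        return ConnectionSet(
            wp_l1l1=self.wp_l1l1.copy(),
            wf_l1l1=self.wf_l1l1.copy(),
            af_l1l1=self.af_l1l1.copy(),
            wp_l1l2=self.wp_l1l2.copy(),
            k_wm_l1=self.k_wm_l1,
            k_l1_l2=self.k_l1_l2,
            k_theta=self.k_theta,
        )

    def validate(self, n: int) -> None:
        for name, m in self.plastic.items():
            if m.shape != (n, n):
                raise ConfigurationError(f"{name} has shape {m.shape}, expected {(n, n)}")
            if np.any(m < 0):
                raise ConfigurationError(f"{name} contains negative weights")
            if name != "Wp_L1L2" and np.any(np.diag(m) != 0):
                raise ConfigurationError(f"{name} has nonzero self-connections")


@dataclass
class NoiseSpec:
    """Noise routing.  ``sigma_*`` are per-step standard deviations of the
    zero-mean Gaussian terms at the default dt (rescaled as
    1/sqrt(dt/dt_default) for other steps).  ``uniform_l1`` is the
    (min, max) range of the strong positive uniform noise fed to L1
    pyramidal inputs in the isolation modes."""

    sigma_p: float = 120.0
    sigma_f: float = 120.0
    uniform_l1: tuple[float, float] | None = None


@dataclass
class InputEvent:
    """Rectangular environmental drive to a set of Units.

    ``units`` are global unit indices; ``population`` selects the pyramidal
    ('p') or fast-inhibitory ('f') target; ``batch`` restricts the event to
    one batch element (None = all).  ``reset_wm`` zeroes the WM
    self-excitation state at onset (the working-memory reset)."""

    t0: float
    t1: float
    units: np.ndarray
    population: str = "p"
    amplitude: float = 0.0
    batch: int | None = None
    reset_wm: bool = False


@dataclass
class SimulationResult:
    """Recorded pyramidal spike-density traces plus run metadata."""

    z: dict[str, np.ndarray]     # layer name -> (batch, steps, n) in spikes/s
    theta: np.ndarray            # (batch, steps) theta generator z_p
    dt: float
    duration: float
    seed: int | None
    mode: str
    events: list[InputEvent] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        n = self.theta.shape[1]
        return (np.arange(n) + 1) * self.dt


class Network:
    """The assembled network: stacked unit parameters + wiring + mode flags."""

    def __init__(
        self,
        n_features: int = N_FEATURES,
        mode: str = "retrieval",
        noise: NoiseSpec | None = None,
        unit_overrides: dict[str, dict[str, float]] | None = None,
        connections: ConnectionSet | None = None,
    ):
        if mode not in MODES:
            raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
        self.n_features = int(n_features)
        self.mode = mode
        self.noise = noise or NoiseSpec()
        overrides = unit_overrides or {}
        l2_over = dict(L2_INPUT_KERNEL)
        l2_over.update(overrides.get("l2", overrides.get("gamma", {})) or {})
        l1_over = dict(L1_ADAPTATION)
        l1_over.update(overrides.get("l1", overrides.get("gamma", {})) or {})
        self.unit_params = {
            "wm": make_unit("wm", overrides.get("wm")),
            "l1": make_unit("gamma", l1_over),
            "l2": make_unit("gamma", l2_over),
            "theta": make_unit("theta", overrides.get("theta")),
        }
        self.connections = connections if connections is not None else ConnectionSet.zeros(self.n_features)
        self.connections.validate(self.n_features)
        self.theta_drive = THETA_INTRINSIC_DRIVE
        self._build_param_arrays()

    # -- layout ------------------------------------------------------------
    @property
    def n_units(self) -> int:
        return 3 * self.n_features + 1

    @property
    def sl_wm(self) -> slice:
        return slice(0, self.n_features)

    @property
    def sl_l1(self) -> slice:
        return slice(self.n_features, 2 * self.n_features)

    @property
    def sl_l2(self) -> slice:
        return slice(2 * self.n_features, 3 * self.n_features)

    @property
    def i_theta(self) -> int:
        return 3 * self.n_features

    # -- mode-dependent routing flags --------------------------------------
    @property
    def wm_connected(self) -> bool:
        return self.mode in ("retrieval",)

    @property
    def theta_oscillating(self) -> bool:
        return self.mode not in ("training", "dreaming_no_theta")

    @property
    def theta_constant_level(self) -> float:
        """Replacement drive used when theta modulation is removed: the
        generator's on-phase plateau held constant, i.e. sustained
        disinhibition (the non-theta state keeps L1 continuously
        responsive rather than periodically gated)."""
        return THETA_PLATEAU

    # -- parameter stacking ------------------------------------------------
    _COUPLINGS = ("c_pe", "c_ep", "c_ps", "c_sp", "c_pf", "c_fp", "c_fs", "c_ff", "c_pp", "bias_p")
    _KERNELS = ("g_glu", "w_glu", "g_slow", "w_slow", "g_fast", "w_fast", "g_in", "w_in")

    def _build_param_arrays(self) -> None:
        n, f = self.n_units, self.n_features
        per_unit = {}
        for name in self._COUPLINGS + self._KERNELS:
            arr = np.empty(n)
            arr[self.sl_wm] = getattr(self.unit_params["wm"], name)
            arr[self.sl_l1] = getattr(self.unit_params["l1"], name)
            arr[self.sl_l2] = getattr(self.unit_params["l2"], name)
            arr[self.i_theta] = getattr(self.unit_params["theta"], name)
            per_unit[name] = arr
        self.p = per_unit
        # kernel constants per pathway, order follows units.PATHWAYS
        g = per_unit
        self.kernel_g = np.stack([g["g_glu"], g["g_glu"], g["g_slow"], g["g_fast"], g["g_in"], g["g_in"]])
        self.kernel_w = np.stack([g["w_glu"], g["w_glu"], g["w_slow"], g["w_fast"], g["w_in"], g["w_in"]])

    def copy(self) -> "Network":
        import copy as _copy

        new = _copy.copy(self)
        new.connections = self.connections.copy()
        new.noise = NoiseSpec(self.noise.sigma_p, self.noise.sigma_f, self.noise.uniform_l1)
        new.p = {k: v.copy() for k, v in self.p.items()}
        new.kernel_g = self.kernel_g.copy()
        new.kernel_w = self.kernel_w.copy()
        return new


# plateau discharge of the theta generator during its on-phase (spikes/s),
# measured once on the isolated unit; used as the constant replacement drive
# in the no-theta mode
THETA_PLATEAU = 4.9


def build_network(
    n_features: int = N_FEATURES,
    mode: str = "retrieval",
    noise: NoiseSpec | None = None,
    unit_overrides: dict | None = None,
) -> Network:
    """Assemble the full architecture with plastic matrices zero-initialized."""
    return Network(n_features=n_features, mode=mode, noise=noise, unit_overrides=unit_overrides)


def scale_time_constants(
    network: Network, population_classes: Iterable[str], factor: float
) -> Network:
    """Multiply the named synaptic-kernel time constants by ``factor``.

    Gains are scaled with the time constants so the kernel area G/w (the DC
    synaptic efficacy) is unchanged; for the autonomous theta Unit this makes
    the operation an exact time rescaling, so frequency scales as 1/factor.

    ``population_classes`` subset of:

    - ``theta_glutamatergic_and_slowGABA`` — the theta generator's slow loop
      (sets the theta frequency)
    - ``L1L2_fastGABA`` — fast-GABA kernels of all L1/L2 Units (sets the
      gamma frequency; see ``GAMMA_FAST_FACTOR``)
    """
    if factor <= 0:
        raise ConfigurationError("factor must be > 0")
    known = {"theta_glutamatergic_and_slowGABA", "L1L2_fastGABA"}
    classes = set(population_classes)
    if not classes <= known:
        raise ConfigurationError(f"unknown population class(es): {sorted(classes - known)}")
    for cls_name in classes:
        if cls_name == "theta_glutamatergic_and_slowGABA":
            i = network.i_theta
            for name in ("g_glu", "w_glu", "g_slow", "w_slow", "g_in", "w_in"):
                network.p[name][i] /= factor
        else:
            sl = np.r_[
                np.arange(network.sl_l1.start, network.sl_l1.stop),
                np.arange(network.sl_l2.start, network.sl_l2.stop),
            ]
            for name in ("g_fast", "w_fast"):
                network.p[name][sl] /= factor
    g = network.p
    network.kernel_g = np.stack([g["g_glu"], g["g_glu"], g["g_slow"], g["g_fast"], g["g_in"], g["g_in"]])
    network.kernel_w = np.stack([g["w_glu"], g["w_glu"], g["w_slow"], g["w_fast"], g["w_in"], g["w_in"]])
    return network


class NetworkState:
    """Batched kernel state: (pathway, batch, unit) arrays for y and dy."""

    def __init__(self, batch: int, n_units: int):
        self.y = np.zeros((len(PATHWAYS), batch, n_units))
        self.dy = np.zeros_like(self.y)

    def copy(self) -> "NetworkState":
        new = NetworkState(self.y.shape[1], self.y.shape[2])
        new.y[:] = self.y
        new.dy[:] = self.dy
        return new


def _rates_p(net: Network, state: NetworkState, af_vec: np.ndarray) -> np.ndarray:
    yp, ye, ys, yf, yup, yuf = state.y
    p = net.p
    v_p = (p["c_pe"] * ye - p["c_ps"] * ys - p["c_pf"] * yf
           + p["c_pp"] * yp + yup + p["bias_p"])
    return sigmoid(v_p)


def simulate(
    net: Network,
    duration: float,
    events: Sequence[InputEvent] = (),
    seed: int | None = None,
    batch: int = 1,
    dt: float = DEFAULT_DT,
    record: Sequence[str] = ("L2",),
    state: NetworkState | None = None,
    learn: Callable[[np.ndarray, np.ndarray, int], None] | None = None,
    record_dtype=np.float32,
) -> SimulationResult:
    """Advance the whole network and record pyramidal spike densities.

    Per step, each Unit's pyramidal drive ``u_p`` accumulates the W_p-weighted
    pre-synaptic pyramidal densities, the fixed feedforward and theta drives,
    environmental input and Gaussian noise; each fast-inhibitory drive ``u_f``
    accumulates the W_f-weighted densities, environmental input and noise.
    A_f contributions bypass the synaptic kernels and enter the fast-
    interneuron potential algebraically (their dynamics are faster than the
    integration step).  ``learn``, if given, is called every step with the
    current (z_p(L1), z_p(L2), step) — the plasticity hook used in training.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    n_steps = int(round(duration / dt))
    f = net.n_features
    n = net.n_units
    sl_wm, sl_l1, sl_l2, i_th = net.sl_wm, net.sl_l1, net.sl_l2, net.i_theta
    conn = net.connections
    conn.validate(f)
    rng = np.random.default_rng(seed)
    noise_scale = 1.0 / np.sqrt(dt / DEFAULT_DT)

    st = state if state is not None else NetworkState(batch, n)
    if st.y.shape[1] != batch:
        raise ConfigurationError("state batch size mismatch")

    p = net.p
    kg, kw = net.kernel_g * net.kernel_w, net.kernel_w  # precompute g*w and w
    two_w = 2.0 * kw
    w_sq = kw * kw

    rec_layers = {name.upper(): np.empty((batch, n_steps, f), dtype=record_dtype) for name in record}
    theta_rec = np.empty((batch, n_steps), dtype=record_dtype)
    layer_slices = {"WM": sl_wm, "L1": sl_l1, "L2": sl_l2}

    # event bookkeeping: step ranges
    ev_steps = [(int(round(e.t0 / dt)), int(round(e.t1 / dt)), e) for e in events]
    for s0, s1, e in ev_steps:
        if np.any((e.units < 0) | (e.units >= n)):
            raise ConfigurationError("event references units outside the network")

    af_vec = np.zeros((batch, n))
    drives = np.empty((len(PATHWAYS), batch, n))
    sig_p = np.zeros(n)
    sig_p[: 3 * f] = net.noise.sigma_p
    sig_f = np.zeros(n)
    sig_f[: 3 * f] = net.noise.sigma_f
    uniform = net.noise.uniform_l1 if net.mode not in ("training", "retrieval") else None

    theta_osc = net.theta_oscillating
    theta_const = conn.k_theta * net.theta_constant_level
    wm_on = net.wm_connected
    training = net.mode == "training"
    # The theta generator disinhibits L1 through fast (AMPA-like) synapses:
    # its drive enters the pyramidal potential through a single brief
    # low-pass stage (5 ms), scaled by the input kernel's DC gain — fast
    # enough that the on-phase edge stays sharp, slow enough that the
    # onset does not overshoot the whole layer.
    gin_dc = net.p["g_in"][net.sl_l1.start] / net.p["w_in"][net.sl_l1.start]
    theta_vec = None
    theta_mask = np.zeros(n)
    theta_mask[sl_l1] = 1.0
    theta_lp = np.zeros((batch, 1))
    theta_alpha = dt / 0.005

    for step in range(n_steps):
        yp, ye, ys, yf, yup, yuf = st.y
        # membrane potentials and spike densities
        v_p = (p["c_pe"] * ye - p["c_ps"] * ys - p["c_pf"] * yf
               + p["c_pp"] * yp + yup + p["bias_p"])
        if theta_vec is not None:
            v_p = v_p + theta_vec
        v_e = p["c_ep"] * yp
        v_s = p["c_sp"] * yp
        v_f = p["c_fp"] * yp - p["c_fs"] * ys - p["c_ff"] * yf + yuf + af_vec
        z_p = sigmoid(v_p)
        z_e = sigmoid(v_e)
        z_s = sigmoid(v_s)
        z_f = sigmoid(v_f)

        zl1 = z_p[:, sl_l1]
        zl2 = z_p[:, sl_l2]

        # next-step theta disinhibition (fast pathway)
        if not training:
            if theta_osc:
                level = conn.k_theta * z_p[:, i_th][:, None]
            else:
                level = np.full((batch, 1), theta_const)
            theta_lp += theta_alpha * (level - theta_lp)
            theta_vec = gin_dc * theta_lp * theta_mask

        # record
        for name, buf in rec_layers.items():
            buf[:, step, :] = z_p[:, layer_slices[name]]
        theta_rec[:, step] = z_p[:, i_th]

        if learn is not None:
            learn(zl1, zl2, step)

        # assemble external + long-range inputs
        u_p = np.zeros((batch, n))
        u_f = np.zeros((batch, n))
        u_p[:, i_th] = net.theta_drive
        if not training:
            pass
            if wm_on:
                u_p[:, sl_l1] += conn.k_wm_l1 * z_p[:, sl_wm]
            u_p[:, sl_l1] += zl1 @ conn.wp_l1l1.T + zl2 @ conn.wp_l1l2.T
            u_f[:, sl_l1] += zl1 @ conn.wf_l1l1.T
            u_p[:, sl_l2] += conn.k_l1_l2 * zl1
        if uniform is not None:
            lo, hi = uniform
            u_p[:, sl_l1] += rng.uniform(lo, hi, size=(batch, f))
        for s0, s1, e in ev_steps:
            if s0 <= step < s1:
                tgt = u_p if e.population == "p" else u_f
                if e.batch is None:
                    tgt[:, e.units] += e.amplitude
                else:
                    tgt[e.batch, e.units] += e.amplitude
            if step == s0 and e.reset_wm:
                if e.batch is None:
                    st.y[0][:, sl_wm] = 0.0
                    st.dy[0][:, sl_wm] = 0.0
                else:
                    st.y[0][e.batch, sl_wm] = 0.0
                    st.dy[0][e.batch, sl_wm] = 0.0
                    yp = st.y[0]  # refresh local view

        # next-step algebraic desynchronizing drive (supra-baseline part)
        af_vec[:, sl_l1] = np.clip(zl1 - AF_PRE_THRESHOLD, 0.0, None) @ conn.af_l1l1.T

        # noise
        n_p = rng.standard_normal((batch, n)) * (sig_p * noise_scale)
        n_f = rng.standard_normal((batch, n)) * (sig_f * noise_scale)

        # kernel drives, order = PATHWAYS (p, e, s, f, up, uf)
        drives[0] = z_p
        drives[1] = z_e
        drives[2] = z_s
        drives[3] = z_f
        drives[4] = u_p + n_p
        drives[5] = u_f + n_f

        # Euler update of all second-order kernels
        y, dy = st.y, st.dy
        y += dt * dy
        dy += dt * (kg[:, None, :] * drives - two_w[:, None, :] * dy - w_sq[:, None, :] * y)

    if not np.all(np.isfinite(st.y)):
        raise NumericalError("non-finite network state at end of simulation")

    return SimulationResult(
        z={k: v for k, v in rec_layers.items()},
        theta=theta_rec,
        dt=dt,
        duration=duration,
        seed=seed,
        mode=net.mode,
        events=list(events),
    )
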