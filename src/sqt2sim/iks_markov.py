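"""Markov-chain model of the slow delayed-rectifier potassium current (IKs).

The channel (KCNQ1 + KCNE1) is represented by a 17-state Markov chain with
15 closed states and two open states.  Each of the four voltage sensors
undergoes two sequential voltage-dependent transitions
(resting -> intermediate, rates ``alpha``/``beta``; intermediate ->
activated, rates ``gamma``/``delta``).  Closed states are labelled by the
occupation numbers ``(n1, n2, n3)`` of the three sensor configurations
(``n1 + n2 + n3 = 4``), giving ``C(6, 2) = 15`` distinct closed states.
Once all four sensors are activated (state C15) the channel opens
(``theta``/``eta``) and can enter a second open state (``psi``/``omega``).

Every transition class carries a single-exponential voltage dependence

    rate(V) = prefactor * exp(voltage_sensitivity * V)

with the prefactor in 1/ms and the sensitivity in 1/mV.  The
second-open-state steps (``psi``, ``omega``) are taken
voltage-independent; sensitivity signs follow gating-charge
directionality (forward steps and opening accelerate, backward steps
and closure decelerate with depolarisation), which guarantees a
monotone equilibrium activation curve.

Macroscopic current follows the usual ohmic law

    I_Ks = g_Ks * scale * (O1 + O2) * (V - E_Ks)        [pA/pF]

Genotypes: ``WT``, homozygous mutant ``V307L`` and the heterozygote
``WT-V307L`` modelled as two independent half-populations (50 % WT,
50 % mutant channels) sharing the membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

__all__ = [
    "N_STATES",
    "N_CLOSED",
    "TRANSITION_CLASSES",
    "STATE_LABELS",
    "IKsParams",
    "ChannelState",
    "GenotypeModel",
    "build_generator",
    "transition_rates",
    "steady_state",
    "advance",
    "iks",
    "open_probability",
    "edge_arrays",
    "wt_params",
    "v307l_params",
    "genotype_model",
    "write_params",
    "read_params",
    "write_channel_state",
    "read_channel_state",
]

N_CLOSED = 15
N_STATES = 17

#: order of the rate classes; (prefactor, sensitivity) pairs are stored in
#: this order throughout the package.
TRANSITION_CLASSES = (
    "alpha", "beta", "gamma", "delta", "theta", "eta", "psi", "omega",
)

_CLASS_INDEX = {name: i for i, name in enumerate(TRANSITION_CLASSES)}

# classes whose voltage sensitivity is structurally zero
_V_INDEPENDENT = ("psi", "omega")


def _closed_states() -> List[Tuple[int, int, int]]:
    """Enumerate closed states (n1, n2, n3), ordered by activation progress."""
    states = []
    for n3 in range(5):
        for n2 in range(5 - n3):
            n1 = 4 - n2 - n3
            states.append((n1, n2, n3))
    # sort so that C1 = fully resting (4,0,0) ... C15 = fully activated (0,0,4)
    states.sort(key=lambda s: (s[2], s[1]))
    return states


_CLOSED = _closed_states()
_CLOSED_INDEX = {s: i for i, s in enumerate(_CLOSED)}

STATE_LABELS = tuple(f"C{i + 1}" for i in range(N_CLOSED)) + ("O1", "O2")


def _build_edges() -> List[Tuple[int, int, int, int]]:
    """Directed edges (from, to, class index, multiplicity) of the scheme."""
    edges = []
    for (n1, n2, n3), i in _CLOSED_INDEX.items():
        if n1 > 0:  # first sensor step forward, multiplicity n1
            j = _CLOSED_INDEX[(n1 - 1, n2 + 1, n3)]
            edges.append((i, j, _CLASS_INDEX["alpha"], n1))
        if n2 > 0:  # first step backward
            j = _CLOSED_INDEX[(n1 + 1, n2 - 1, n3)]
            edges.append((i, j, _CLASS_INDEX["beta"], n2))
        if n2 > 0:  # second sensor step forward
            j = _CLOSED_INDEX[(n1, n2 - 1, n3 + 1)]
            edges.append((i, j, _CLASS_INDEX["gamma"], n2))
        if n3 > 0:  # second step backward
            j = _CLOSED_INDEX[(n1, n2 + 1, n3 - 1)]
            edges.append((i, j, _CLASS_INDEX["delta"], n3))
    c15 = _CLOSED_INDEX[(0, 0, 4)]
    o1, o2 = N_CLOSED, N_CLOSED + 1
    edges.append((c15, o1, _CLASS_INDEX["theta"], 1))
    edges.append((o1, c15, _CLASS_INDEX["eta"], 1))
    edges.append((o1, o2, _CLASS_INDEX["psi"], 1))
    edges.append((o2, o1, _CLASS_INDEX["omega"], 1))
    return edges


_EDGES = _build_edges()


def edge_arrays() -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Edge list of the state-transition graph as four int/float arrays.

    Returns ``(src, dst, cls, mult)``; the rate of edge ``e`` at voltage
    ``V`` is ``mult[e] * rate_cls[cls[e]](V)``.  Used by the compiled
    tissue kernels.
    """
    src = np.array([e[0] for e in _EDGES], dtype=np.int64)
    dst = np.array([e[1] for e in _EDGES], dtype=np.int64)
    cls = np.array([e[2] for e in _EDGES], dtype=np.int64)
    mult = np.array([e[3] for e in _EDGES], dtype=np.float64)
    return src, dst, cls, mult


@dataclass
class IKsParams:
    """Rate coefficients and conductance of one IKs channel population.

    ``rate_coefficients`` maps each transition class to a
    ``(prefactor [1/ms], voltage_sensitivity [1/mV])`` pair.
    """

    genotype_label: str
    rate_coefficients: Dict[str, Tuple[float, float]]
    g_ks: float = 1.0          # nS/pF, maximal conductance
    scale_factor: float = 1.0  # relative-amplitude multiplier

    def __post_init__(self) -> None:
        missing = set(TRANSITION_CLASSES) - set(self.rate_coefficients)
        if missing:
            raise ValueError(f"missing rate classes: {sorted(missing)}")
        for name, (a, b) in self.rate_coefficients.items():
            if not (a > 0 and np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"invalid coefficients for {name}: {(a, b)}")
        if self.g_ks < 0:
            raise ValueError("g_ks must be non-negative")
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be positive")

    def coefficient_vector(self) -> np.ndarray:
        """(8, 2) array of (prefactor, sensitivity) in class order."""
        return np.array(
            [self.rate_coefficients[c] for c in TRANSITION_CLASSES], float
        )

    def with_block(self, fraction: float) -> "IKsParams":
        """Return a copy with conductance scaled by ``1 - fraction``."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("block fraction must lie in [0, 1]")
        return replace(self, g_ks=self.g_ks * (1.0 - fraction))


@dataclass
class ChannelState:
    """Occupancy over the 17 Markov states (C1..C15, O1, O2)."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (N_STATES,):
            raise ValueError(f"occupancy must have length {N_STATES}")
        if np.any(self.occupancy < -1e-12) or np.any(self.occupancy > 1 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(self.occupancy.sum() - 1.0) > 1e-8:
            raise ValueError("occupancies must sum to 1 within 1e-8")

    @property
    def open_probability(self) -> float:
        return float(self.occupancy[N_CLOSED] + self.occupancy[N_CLOSED + 1])

    @classmethod
    def ground(cls) -> "ChannelState":
        """All channels in the fully resting closed state C1."""
        occ = np.zeros(N_STATES)
        occ[0] = 1.0
        return cls(occ)


def transition_rates(V: float, params: IKsParams) -> np.ndarray:
    """The 8 class rates (1/ms) at membrane potential ``V`` (mV)."""
    if not np.isfinite(V):
        raise ValueError(f"membrane potential must be finite, got {V}")
    coef = params.coefficient_vector()
    return coef[:, 0] * np.exp(coef[:, 1] * V)


def build_generator(V: float, params: IKsParams) -> np.ndarray:
    """17x17 transition-rate (generator) matrix Q at voltage ``V``.

    Convention: ``d occupancy / dt = Q @ occupancy``; column sums are zero
    so total probability is conserved by construction.
    """
    rates = transition_rates(V, params)
    Q = np.zeros((N_STATES, N_STATES))
    for i, j, c, m in _EDGES:
        r = m * rates[c]
        Q[j, i] += r
        Q[i, i] -= r
    return Q


def steady_state(V: float, params: IKsParams) -> ChannelState:
    """Equilibrium occupancy at fixed voltage: normalised null vector of Q."""
    Q = build_generator(V, params)
    # null space via SVD; the generator of an irreducible chain has a
    # one-dimensional kernel
    _, s, vh = np.linalg.svd(Q)
    if s[-2] < 1e-12:
        raise np.linalg.LinAlgError(
            f"generator numerically rank-deficient at V={V} mV"
        )
    vec = vh[-1]
    vec = vec / vec.sum()
    vec = np.clip(vec, 0.0, None)
    vec = vec / vec.sum()
    return ChannelState(vec)


def _max_exit_rate(Q: np.ndarray) -> float:
    return float(np.max(-np.diag(Q)))


def advance(
    state: ChannelState,
    V: float,
    dt: float,
    params: IKsParams,
    max_substep: float = 0.02,
) -> ChannelState:
    """Advance the occupancy by ``dt`` ms at fixed voltage ``V``.

    Classical RK4 with adaptive sub-stepping (sub-step bounded by
    ``max_substep`` and by the stiffness of the generator) and post-step
    renormalisation.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return ChannelState(state.occupancy.copy())
    Q = build_generator(V, params)
    h_stab = 1.0 / max(_max_exit_rate(Q), 1e-12)
    h = min(max_substep, h_stab, dt)
    n = int(np.ceil(dt / h))
    h = dt / n
    y = state.occupancy.copy()
    for _ in range(n):
        k1 = Q @ y
        k2 = Q @ (y + 0.5 * h * k1)
        k3 = Q @ (y + 0.5 * h * k2)
        k4 = Q @ (y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    total = y.sum()
    if abs(total - 1.0) > 1e-8:
        raise FloatingPointError(
            f"occupancy drifted by {total - 1.0:.2e} during integration"
        )
    y = np.clip(y, 0.0, None)
    return ChannelState(y / y.sum())


def advance_exact(state: ChannelState, V: float, dt: float,
                  params: IKsParams) -> ChannelState:
    """Matrix-exponential propagation at fixed voltage (oracle-grade)."""
    Q = build_generator(V, params)
    y = expm(Q * dt) @ state.occupancy
    y = np.clip(y, 0.0, None)
    return ChannelState(y / y.sum())


@dataclass
class GenotypeModel:
    """A genotype's channel complement: one or two populations.

    ``populations`` is a list of ``(weight, IKsParams, ChannelState)``;
    weights sum to one.  Homozygotes carry a single population of weight
    1.0, the heterozygote two half-populations (WT and mutant) that evolve
    under their own rates but share the membrane potential.
    """

    kind: str
    populations: List[Tuple[float, IKsParams, ChannelState]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        w = sum(p[0] for p in self.populations)
        if abs(w - 1.0) > 1e-12:
            raise ValueError("population weights must sum to 1")

    def initialise(self, V: float) -> None:
        """Equilibrate every population at the holding potential ``V``."""
        self.populations = [
            (w, p, steady_state(V, p)) for (w, p, _) in self.populations
        ]

    def step(self, V: float, dt: float) -> None:
        self.populations = [
            (w, p, advance(s, V, dt, p)) for (w, p, s) in self.populations
        ]

    def copy(self) -> "GenotypeModel":
        return GenotypeModel(
            self.kind,
            [(w, p, ChannelState(s.occupancy.copy()))
             for (w, p, s) in self.populations],
        )


def open_probability(model: GenotypeModel) -> float:
    """Population-weighted open probability (O1 + O2)."""
    return sum(w * s.open_probability for (w, _, s) in model.populations)


def iks(model: GenotypeModel, V: float, e_ks: float) -> float:
    """Macroscopic IKs current density (pA/pF).

    The heterozygote current is the 50:50 average of the two population
    currents, each population carrying the full maximal conductance.
    """
    total = 0.0
    for w, p, s in model.populations:
        total += w * p.g_ks * p.scale_factor * s.open_probability * (V - e_ks)
    return total


# ---------------------------------------------------------------------------
# Genotype presets
# ---------------------------------------------------------------------------
# Rate coefficients below are the package's fitted defaults, produced by
# clamp_and_fit.fit_default_presets() against the synthetic clamp targets
# (fixtures module): a Boltzmann-shaped activation I-V (WT half-activation
# +20 mV, slope 12 mV; mutant shifted -36 mV), two-fold faster activation
# and two-fold slower deactivation in the mutant.  g_ks values are placed
# by the conductance calibration (calibrate module); scale factors follow
# the AP-clamp relative peak-current convention.

WT_RATE_COEFFICIENTS: Dict[str, Tuple[float, float]] = {
    # placeholder values; overwritten by the frozen fit results below
    "alpha": (0.02, 0.03),
    "beta": (0.04, -0.04),
    "gamma": (0.008, 0.025),
    "delta": (0.03, -0.02),
    "theta": (0.06, 0.0),
    "eta": (0.04, -0.02),
    "psi": (0.01, 0.0),
    "omega": (0.02, 0.0),
}

V307L_RATE_COEFFICIENTS: Dict[str, Tuple[float, float]] = dict(
    WT_RATE_COEFFICIENTS
)


def _load_frozen_presets() -> None:
    """Replace the placeholder coefficients with the frozen fit results."""
    try:
        from . import _presets
    except ImportError:  # pragma: no cover - presets generated at build time
        return
    WT_RATE_COEFFICIENTS.clear()
    WT_RATE_COEFFICIENTS.update(_presets.WT_RATE_COEFFICIENTS)
    V307L_RATE_COEFFICIENTS.clear()
    V307L_RATE_COEFFICIENTS.update(_presets.V307L_RATE_COEFFICIENTS)


_load_frozen_presets()


def wt_params(g_ks: float = 1.0, scale_factor: float = 1.0) -> IKsParams:
    return IKsParams("WT", dict(WT_RATE_COEFFICIENTS), g_ks, scale_factor)


def v307l_params(g_ks: float = 1.0, scale_factor: float = 1.0) -> IKsParams:
    return IKsParams("V307L", dict(V307L_RATE_COEFFICIENTS), g_ks,
                     scale_factor)


GENOTYPES = ("WT", "WT-V307L", "V307L")


def write_params(params: IKsParams, path) -> None:
    """Write rate coefficients as flat key-value text."""
    lines = [f"genotype = {params.genotype_label}",
             f"g_ks = {params.g_ks!r}",
             f"scale_factor = {params.scale_factor!r}"]
    for c in TRANSITION_CLASSES:
        a, b = params.rate_coefficients[c]
        lines.append(f"{c}.prefactor = {a!r}")
        lines.append(f"{c}.voltage_sensitivity = {b!r}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> IKsParams:
    """Read rate coefficients from flat key-value text."""
    from pathlib import Path
    fields = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        k, v = (x.strip() for x in line.split("=", 1))
        fields[k] = v
    coeffs = {
        c: (float(fields[f"{c}.prefactor"]),
            float(fields[f"{c}.voltage_sensitivity"]))
        for c in TRANSITION_CLASSES
    }
    return IKsParams(fields["genotype"], coeffs,
                     float(fields.get("g_ks", 1.0)),
                     float(fields.get("scale_factor", 1.0)))


def write_channel_state(state: ChannelState, path) -> None:
    """Write an occupancy snapshot as CSV columns C1..C15,O1,O2."""
    from pathlib import Path
    Path(path).write_text(
        ",".join(STATE_LABELS) + "\n"
        + ",".join(repr(float(x)) for x in state.occupancy) + "\n")


def read_channel_state(path) -> ChannelState:
    """Read an occupancy snapshot written by :func:`write_channel_state`."""
    from pathlib import Path
    header, values = Path(path).read_text().strip().splitlines()
    if tuple(header.split(",")) != STATE_LABELS:
        raise ValueError("unexpected channel-state column labels")
    return ChannelState(np.array([float(x) for x in values.split(",")]))


def genotype_model(kind: str, g_ks: float = 1.0,
                   mutant_scale: float = 1.0,
                   holding_potential: float = -80.0) -> GenotypeModel:
    """Build an equilibrated channel model for one genotype.

    ``g_ks`` is the WT maximal conductance; the mutant population carries
    ``g_ks * mutant_scale`` through its scale factor.
    """
    if kind == "WT":
        pops = [(1.0, wt_params(g_ks), ChannelState.ground())]
    elif kind == "V307L":
        pops = [(1.0, v307l_params(g_ks, mutant_scale), ChannelState.ground())]
    elif kind == "WT-V307L":
        pops = [
            (0.5, wt_params(g_ks), ChannelState.ground()),
            (0.5, v307l_params(g_ks, mutant_scale), ChannelState.ground()),
        ]
    else:
        raise ValueError(f"unknown genotype {kind!r}; expected one of {GENOTYPES}")
    model = GenotypeModel(kind, pops)
    model.initialise(holding_potential)
    return model
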