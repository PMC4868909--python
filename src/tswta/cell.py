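"""Adaptive disparity-selective cells built from grids of ts-WTA units.

A disparity cell is an h x w receptive field of ts-WTA units, one per
position of an interlaced binocular window (left subfield | right
subfield).  Each unit's two synapses are driven by the window bit and
its complement, so during training with a pattern and its complement the
opposing synapses are always stimulated alternately.  The unit
activations drain onto a common output node; the cell's response is the
resource-capped mean activation over the grid (normalised by h*w so
cells of different sizes are comparable).

Training follows a random-inside-epoch protocol: every pattern of the
set is presented once per epoch in a seeded random order, the evoked
response is fed back to every unit, and each unit's weight pair moves by
the threshold-linear ts-WTA rule.  The feedback comparator level is a
leaky running maximum of recent responses — the software counterpart of
the peak-holding RC feedback network: only patterns whose response is
close to the best recent response reinforce their synapses, all others
weaken them.  This makes the pattern-level competition winner-take-all,
so the cell converges on (almost always) the pattern that evoked the
maximal initial response, and its tuning curve sharpens around that
disparity.

Cells can be coupled through their diffusion nodes.  A one-way buffer
conveys each cell's output to its diffusion node; resistors mix the
diffusion nodes of neighbours, and the mixed level — not the raw output
— is what the units' feedback sees.  A strongly biased neighbour can
therefore steer a weakly biased cell toward its own disparity, while the
neighbour's output node is never back-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import TsWtaParams
from .synth import DisparityPattern

__all__ = [
    "DEFAULT_CELL_PARAMS",
    "TrainProtocol",
    "ReceptiveField",
    "DisparityCellState",
    "TuningCurve",
    "HalfHeightUndefined",
    "representable_disparities",
    "init_receptive_field",
    "bias_toward",
    "cell_response",
    "train_cell",
    "train_bank",
    "tuning_curve",
    "hwhh",
    "couple_cells",
    "CoupledEnsemble",
    "train_ensemble",
]

# Within a cell the feedback signal is a response difference of a few
# percent of the resource cap, far smaller than the resource-share
# signal of a standalone unit, so injection is much stronger and
# tunneling/leak much weaker: the pattern gated in by the comparator is
# reinforced decisively while sub-threshold patterns barely erode the
# field.  The comparator threshold is supplied per presentation by the
# leaky-max tracker, so theta_fb here is only a placeholder.
DEFAULT_CELL_PARAMS = TsWtaParams(eta_inj=5.0, eta_tun=0.02, eta_leak=0.001, theta_fb=0.5)


@dataclass(frozen=True)
class TrainProtocol:
    """Training-protocol constants.

    ``epochs``: presentations of the full set (random order inside each
    epoch).  ``comparator_fraction``: a pattern reinforces its synapses
    only while its feedback exceeds this fraction of the running-maximum
    response; everything below weakens its drive.  ``comparator_decay``:
    per-presentation leak of the running maximum (lets the comparator
    track a slowly changing cell).
    """

    epochs: int = 80
    comparator_fraction: float = 0.98
    comparator_decay: float = 0.002


DEFAULT_PROTOCOL = TrainProtocol()


def representable_disparities(total_width: int) -> int:
    """Number of integer disparities a spliced field of this width encodes.

    With the near-even split w_L = floor(w/2), w_R = ceil(w/2), a shift
    of d columns fits iff d < min(w_L, w_R), so the count is
    floor(total_width / 2): a 9-wide field holds disparities 0-3, a
    40-wide field holds 0-19.
    """
    if total_width < 2:
        raise ValueError("a spliced field needs at least 2 columns")
    return total_width // 2


@dataclass
class ReceptiveField:
    """h x w grid of ts-WTA weight pairs.

    ``vfg1`` is the ON-side synapse (driven when the window bit is ON),
    ``vfg2`` the OFF-side.  The developed template of the field is the
    bit map ``vfg1 < vfg2`` (ON-side stronger).
    """

    vfg1: np.ndarray
    vfg2: np.ndarray
    init_range: tuple[float, float] = (4.8, 5.5)

    @property
    def h(self) -> int:
        return self.vfg1.shape[0]

    @property
    def w(self) -> int:
        return self.vfg1.shape[1]

    @property
    def w_l(self) -> int:
        return self.w // 2

    def copy(self) -> "ReceptiveField":
        return ReceptiveField(self.vfg1.copy(), self.vfg2.copy(), self.init_range)

    def template(self) -> np.ndarray:
        return self.vfg1 < self.vfg2


@dataclass
class DisparityCellState:
    """A disparity cell: receptive field plus node levels and geometry.

    ``output_level`` mirrors the last computed response; the buffer
    copies it one-way onto ``diffusion_level``, which coupling may mix
    with neighbours.  ``r_d``/``r_f`` are the diffusive and feedback
    resistances (ohms), ``c_d`` the diffusion capacitor (farads); the
    network is solved quasi-statically because its RC time constant is
    negligible against the pulse width.
    """

    rf: ReceptiveField
    params: TsWtaParams = field(default_factory=lambda: DEFAULT_CELL_PARAMS)
    output_level: float = 0.0
    diffusion_level: float = 0.0
    r_d: float = 1000.0
    r_f: float = 1000.0
    c_d: float = 10e-12
    learned_disparity: int | None = None

    def __post_init__(self) -> None:
        if self.r_d <= 0 or self.r_f <= 0:
            raise ValueError("r_d and r_f must be positive")


@dataclass
class TuningCurve:
    disparities: list[int]
    responses: list[float]

    def __post_init__(self) -> None:
        if len(self.disparities) != len(self.responses):
            raise ValueError("disparities and responses must have equal length")
        if any(r < 0 for r in self.responses):
            raise ValueError("responses must be non-negative")


class HalfHeightUndefined(ValueError):
    """The tuning curve never falls to half-height inside its support."""


def init_receptive_field(
    h: int,
    w: int,
    seed: int = 0,
    init_range: tuple[float, float] = (4.8, 5.5),
) -> ReceptiveField:
    """Seeded random initial biases, uniform in ``init_range``."""
    if h < 1 or w < 1:
        raise ValueError("field dimensions must be >= 1")
    lo, hi = init_range
    if not lo < hi:
        raise ValueError("empty init range")
    rng = np.random.default_rng(seed)
    return ReceptiveField(
        vfg1=rng.uniform(lo, hi, (h, w)),
        vfg2=rng.uniform(lo, hi, (h, w)),
        init_range=init_range,
    )


def bias_toward(
    rf: ReceptiveField, pattern: DisparityPattern, bias_volts: float
) -> ReceptiveField:
    """Strengthen the synapses a pattern drives, emulating a genetic bias.

    Lowers the ON-side gate voltage where the pattern is ON and the
    OFF-side voltage where it is OFF, clipped to the init range floor.
    """
    out = rf.copy()
    lo = rf.init_range[0]
    out.vfg1 = np.where(pattern.bits, np.maximum(lo, out.vfg1 - bias_volts), out.vfg1)
    out.vfg2 = np.where(pattern.bits, out.vfg2, np.maximum(lo, out.vfg2 - bias_volts))
    return out


def _efficacies(rf: ReceptiveField, params: TsWtaParams):
    e1 = np.exp(-params.kappa * (rf.vfg1 - params.vfg_min))
    e2 = np.exp(-params.kappa * (rf.vfg2 - params.vfg_min))
    return e1, e2


def cell_response(cell: DisparityCellState, pattern: DisparityPattern) -> float:
    """Output-node response of the cell to an interlaced pattern.

    The feed-forward drains share one bias-limited output node, so the
    response is the fraction of the total standing synaptic efficacy
    recruited by the stimulated synapses, scaled to the resource cap:

        r = i_b * sum(eff of driven synapse) / sum(eff of all synapses).

    It lies in [0, i_b]; a pattern and its complement always sum to
    ``i_b`` (they recruit complementary halves of the same resource);
    an undeveloped symmetric field answers ``i_b / 2`` to everything.
    """
    rf = cell.rf
    if pattern.bits.shape != (rf.h, rf.w):
        raise ValueError(
            f"pattern shape {pattern.bits.shape} != field shape {(rf.h, rf.w)}"
        )
    e1, e2 = _efficacies(rf, cell.params)
    act = np.where(pattern.bits, e1, e2)
    return float(cell.params.i_b * act.sum() / (e1.sum() + e2.sum()))


def _grid_pulse(
    rf: ReceptiveField, bits: np.ndarray, feedback: float, theta: float, p: TsWtaParams
) -> None:
    """Vectorised ts-WTA pulse on every unit of the grid, in place."""
    delta = -p.eta_inj * max(0.0, feedback - theta) + p.eta_tun * max(0.0, theta - feedback)
    rf.vfg1 += np.where(bits, delta, p.eta_leak)
    rf.vfg2 += np.where(bits, p.eta_leak, delta)
    np.clip(rf.vfg1, p.vfg_min, p.vfg_max, out=rf.vfg1)
    np.clip(rf.vfg2, p.vfg_min, p.vfg_max, out=rf.vfg2)


def _check_complements(pattern_set: list[DisparityPattern]) -> None:
    keys = {p.bits.tobytes() for p in pattern_set}
    for p in pattern_set:
        if (~p.bits).tobytes() not in keys:
            raise ValueError(
                "pattern set must contain the complement of every pattern "
                "(alternating ON/OFF drive of each synapse pair)"
            )


def train_cell(
    cell: DisparityCellState,
    pattern_set: list[DisparityPattern],
    epochs: int | None = None,
    seed: int = 0,
    protocol: TrainProtocol = DEFAULT_PROTOCOL,
):
    """Train one standalone cell on a pattern set (with complements).

    Returns ``(cell, trace)`` where ``trace[e, d]`` is the disparity-``d``
    tuning after epoch ``e`` (``trace[0]`` is pre-training).  A cell may
    converge on either phase of a disparity — the pattern or its
    complement carry the same disparity label — so the tuning entry for
    disparity ``d`` is the better of the two phases,
    ``max(r_d, i_b - r_d)``, which is computable from the probe response
    alone because a pattern and its complement sum to ``i_b``.

    The trained cell's ``learned_disparity`` is the disparity label of
    the set member (pattern or complement) evoking the maximal final
    response, or None if that maximum is not unique across disparities.
    """
    _check_complements(pattern_set)
    epochs = protocol.epochs if epochs is None else epochs
    probes = sorted(
        (p for p in pattern_set if not p.is_complement), key=lambda p: p.disparity
    )
    i_b = cell.params.i_b
    rng = np.random.default_rng(seed)

    def tuning_row():
        r = np.array([cell_response(cell, p) for p in probes])
        return np.maximum(r, i_b - r)

    trace = np.empty((epochs + 1, len(probes)))
    trace[0] = tuning_row()

    # comparator: leaky running maximum of the feedback level
    m = max(cell_response(cell, p) for p in pattern_set)
    for e in range(epochs):
        for idx in rng.permutation(len(pattern_set)):
            p = pattern_set[idx]
            r = cell_response(cell, p)
            cell.output_level = r
            cell.diffusion_level = r  # one-way buffer copy (standalone)
            theta = protocol.comparator_fraction * m
            _grid_pulse(cell.rf, p.bits, r, theta, cell.params)
            m = max(r, (1.0 - protocol.comparator_decay) * m)
        trace[e + 1] = tuning_row()

    final = trace[-1]
    best = np.flatnonzero(final == final.max())
    cell.learned_disparity = int(probes[best[0]].disparity) if best.size == 1 else None
    return cell, trace


def tuning_curve(cell: DisparityCellState, pattern_bank: list[DisparityPattern]) -> TuningCurve:
    """Response versus probe disparity, one probe per disparity."""
    if not pattern_bank:
        raise ValueError("empty probe bank")
    probes = sorted(pattern_bank, key=lambda p: p.disparity)
    return TuningCurve(
        disparities=[p.disparity for p in probes],
        responses=[cell_response(cell, p) for p in probes],
    )


def hwhh(curve: TuningCurve) -> float:
    """Half-width at half-height of a tuning curve, in disparity units.

    Half-height is (max + min) / 2.  From the unique peak, the crossing
    on each side is located by linear interpolation between samples; the
    two side-widths are averaged when both exist, and the single defined
    one is returned otherwise.
    """
    y = np.asarray(curve.responses, dtype=float)
    x = np.asarray(curve.disparities, dtype=float)
    peaks = np.flatnonzero(y == y.max())
    if peaks.size != 1:
        raise ValueError("tuning curve has no unique maximum")
    p = int(peaks[0])
    half = 0.5 * (y.max() + y.min())

    def side_width(indices) -> float | None:
        prev = p
        for i in indices:
            if y[i] < half:
                frac = (y[prev] - half) / (y[prev] - y[i])
                return abs(x[prev] + frac * (x[i] - x[prev]) - x[p])
            prev = i
        return None

    widths = [
        w
        for w in (side_width(range(p - 1, -1, -1)), side_width(range(p + 1, len(y))))
        if w is not None
    ]
    if not widths:
        raise HalfHeightUndefined(
            "response never falls below half-height inside the sampled support"
        )
    return float(np.mean(widths))


def train_bank(
    pattern_set: list[DisparityPattern],
    seed: int = 0,
    bias_volts: float = 0.3,
    protocol: TrainProtocol = DEFAULT_PROTOCOL,
    params: TsWtaParams | None = None,
) -> list[DisparityCellState]:
    """One trained cell per disparity of the set (a detector bank).

    Each cell starts from its own seeded random field, pre-biased toward
    its target disparity's pattern (the hardware analogue of a genetic
    bias), and is trained on the full set.  Raises if any cell fails to
    learn its target, so a returned bank always covers every disparity.
    """
    params = DEFAULT_CELL_PARAMS if params is None else params
    probes = sorted(
        (p for p in pattern_set if not p.is_complement), key=lambda p: p.disparity
    )
    h, w = probes[0].bits.shape
    child = np.random.SeedSequence(seed).generate_state(2 * len(probes))
    bank = []
    for i, probe in enumerate(probes):
        rf = init_receptive_field(h, w, seed=int(child[2 * i]))
        rf = bias_toward(rf, probe, bias_volts)
        cell = DisparityCellState(rf=rf, params=params)
        cell, _ = train_cell(cell, pattern_set, seed=int(child[2 * i + 1]), protocol=protocol)
        # the detector must learn its target disparity in the probe phase
        # (not the complement), otherwise its template is anti-matched
        if (
            cell.learned_disparity != probe.disparity
            or cell_response(cell, probe) <= 0.5 * cell.params.i_b
        ):
            raise RuntimeError(
                f"bank cell for disparity {probe.disparity} learned "
                f"{cell.learned_disparity}; increase bias_volts"
            )
        bank.append(cell)
    return bank


@dataclass
class CoupledEnsemble:
    """Cells whose diffusion nodes are resistively coupled.

    ``edges`` is an undirected neighbour graph on cell indices; ``r_c``
    is the inter-cell diffusive resistance (ohms).  During training each
    cell's feedback level is the steady-state voltage of its diffusion
    node: its own (buffered) output mixed with neighbours' through the
    resistor network, solved by Kirchhoff's current law each
    presentation.  Output nodes are never back-driven.
    """

    cells: list[DisparityCellState]
    edges: list[tuple[int, int]]
    r_c: float = 100.0

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("coupling resistance must be positive")
        n = len(self.cells)
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loops are not allowed in the coupling graph")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError("edge endpoint out of range")

    def diffusion_levels(self, outputs: np.ndarray) -> np.ndarray:
        """Steady-state diffusion-node voltages for given cell outputs.

        Node i satisfies (r_i - V_i)/R_f + sum_j (V_j - V_i)/R_c = 0 over
        its neighbours j; with no neighbours V_i = r_i (the buffered
        output), which is also the r_c -> infinity limit.
        """
        n = len(self.cells)
        g_f = np.array([1.0 / c.r_f for c in self.cells])
        a = np.diag(g_f)
        for i, j in self.edges:
            g = 1.0 / self.r_c
            a[i, i] += g
            a[j, j] += g
            a[i, j] -= g
            a[j, i] -= g
        return np.linalg.solve(a, g_f * outputs)


def couple_cells(
    cells: list[DisparityCellState],
    edges: list[tuple[int, int]],
    r_c: float = 100.0,
) -> CoupledEnsemble:
    """Build a diffusively coupled ensemble over a neighbour graph."""
    return CoupledEnsemble(cells=cells, edges=edges, r_c=r_c)


def train_ensemble(
    ensemble: CoupledEnsemble,
    pattern_set: list[DisparityPattern],
    epochs: int | None = None,
    seed: int = 0,
    protocol: TrainProtocol = DEFAULT_PROTOCOL,
) -> CoupledEnsemble:
    """Train all cells of an ensemble on a shared visual stream.

    Every cell sees the same presentation order (the same stimulus); the
    feedback each cell's units receive is its diffusion-node level, so
    coupled neighbours reinforce the same patterns and tend to converge
    on a common disparity.
    """
    _check_complements(pattern_set)
    epochs = protocol.epochs if epochs is None else epochs
    probes = sorted(
        (p for p in pattern_set if not p.is_complement), key=lambda p: p.disparity
    )
    rng = np.random.default_rng(seed)
    n = len(ensemble.cells)
    m = np.array(
        [max(cell_response(c, p) for p in pattern_set) for c in ensemble.cells]
    )
    for _ in range(epochs):
        for idx in rng.permutation(len(pattern_set)):
            p = pattern_set[idx]
            outputs = np.array([cell_response(c, p) for c in ensemble.cells])
            fb = ensemble.diffusion_levels(outputs)
            for i, cell in enumerate(ensemble.cells):
                cell.output_level = float(outputs[i])
                cell.diffusion_level = float(fb[i])
                theta = protocol.comparator_fraction * m[i]
                _grid_pulse(cell.rf, p.bits, float(fb[i]), theta, cell.params)
            m = np.maximum(fb, (1.0 - protocol.comparator_decay) * m)
    for cell in ensemble.cells:
        r = np.array([cell_response(cell, p) for p in probes])
        u = np.maximum(r, cell.params.i_b - r)  # best phase per disparity
        best = np.flatnonzero(u == u.max())
        cell.learned_disparity = (
            int(probes[best[0]].disparity) if best.size == 1 else None
        )
    return ensemble
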