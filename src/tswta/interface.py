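"""Configuration, serialization, reproducible runs, and the sweep harness.

A single ``RunConfig`` carries every tunable of a run: geometry, ts-WTA
rates, training protocol, pipeline options and reaction-diffusion
options, and round-trips through YAML.  One global seed fans out to
per-component child seeds through a stable named derivation, so any
stage can be reproduced in isolation.

Receptive fields and banks serialize to CSV (one row per grid position,
both gate voltages), images and maps to ASCII PGM (P2) and CSV, tuning
curves to CSV.  The sweep harness re-runs the registered behavioural
invariants of the competition dynamics over a parameter grid and tables
the per-point pass fractions — the robustness / stress analysis of the
model under parameter variation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell as cell_mod
from . import core, synth
from .cell import (
    DEFAULT_CELL_PARAMS,
    DisparityCellState,
    ReceptiveField,
    TrainProtocol,
    representable_disparities,
    train_bank,
    tuning_curve,
)
from .core import Synapse, TsWtaParams, TsWtaState, make_schedule, run_competition
from .stereo import PipelineConfig

__all__ = [
    "RunConfig",
    "SweepSpec",
    "ValidationError",
    "child_seed",
    "save_config",
    "load_config",
    "write_pgm",
    "read_pgm",
    "field_to_csv",
    "field_from_csv",
    "save_bank",
    "load_bank",
    "run_train",
    "INVARIANTS",
    "run_sweep",
]


class ValidationError(ValueError):
    """A configuration field violates a module precondition."""


def child_seed(seed: int, name: str) -> int:
    """Stable per-component child of a global seed (below 2**31)."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Everything a training / mapping / map-formation run needs.

    Defaults reproduce the 4-disparity study: 9x9 receptive fields
    (4|5 splice), the 8-pattern training set, 80 epochs of
    random-inside-epoch presentations, and the 80x80 four-quadrant test
    pair.
    """

    seed: int = 0
    h: int = 9
    w_l: int = 4
    w_r: int = 5
    n_disparities: int = 4
    epochs: int = 80
    pattern_style: str = "random_dot"
    bias_volts: float = 0.3
    init_range: tuple[float, float] = (4.8, 5.5)
    wta: TsWtaParams = field(default_factory=lambda: DEFAULT_CELL_PARAMS)
    protocol: TrainProtocol = field(default_factory=TrainProtocol)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    rd_alpha: float = 1.5
    rd_du: float = 0.1
    rd_steps: int = 300
    rd_shape: tuple[int, int] = (64, 64)
    rd_boundary: str = "reflect"
    log_level: str = "INFO"

    def validate(self) -> None:
        problems = []
        w = self.w_l + self.w_r
        if self.w_l < 1 or self.w_r < 1 or abs(self.w_l - self.w_r) > 1:
            problems.append("w_l/w_r must be a near-even split (|w_l - w_r| <= 1)")
        if w >= 2 and self.n_disparities > representable_disparities(w):
            problems.append(
                f"{self.n_disparities} disparities exceed capacity "
                f"{representable_disparities(w)} of a {w}-wide field "
                "(representable_disparities)"
            )
        if self.epochs < 1:
            problems.append("epochs must be >= 1")
        if not self.init_range[0] < self.init_range[1]:
            problems.append("init_range must be a nonempty interval")
        if self.rd_alpha <= 0 or self.rd_alpha >= 2:
            problems.append("rd_alpha must lie in (0, 2) for a stable explicit step")
        if not 0 <= self.rd_du <= 0.25:
            problems.append("rd_du must lie in [0, 1/4] for a stable explicit step")
        if self.rd_boundary not in ("reflect", "wrap"):
            problems.append("rd_boundary must be 'reflect' or 'wrap'")
        if problems:
            raise ValidationError("; ".join(problems))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_to_plain(config), f, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    raw["wta"] = TsWtaParams(**raw.get("wta", {}))
    raw["protocol"] = TrainProtocol(**raw.get("protocol", {}))
    raw["pipeline"] = PipelineConfig(**raw.get("pipeline", {}))
    for key in ("init_range", "rd_shape"):
        if key in raw:
            raw[key] = tuple(raw[key])
    config = RunConfig(**raw)
    config.validate()
    return config


# ---------------------------------------------------------------- serialization


def write_pgm(path, image: np.ndarray, max_val: int = 255) -> None:
    """ASCII (P2) PGM; float images are scaled from [0, 1]."""
    img = np.asarray(image)
    if img.dtype.kind == "f":
        img = np.clip(np.rint(img * max_val), 0, max_val).astype(int)
    else:
        img = np.clip(img, 0, max_val).astype(int)
    h, w = img.shape
    lines = [f"P2\n{w} {h}\n{max_val}\n"]
    for row in img:
        lines.append(" ".join(str(v) for v in row) + "\n")
    Path(path).write_text("".join(lines))


def read_pgm(path) -> np.ndarray:
    """Reads ASCII (P2) PGM to floats in [0, 1]."""
    tokens = []
    for line in Path(path).read_text().splitlines():
        tokens.extend(line.split("#", 1)[0].split())
    if tokens[0] != "P2":
        raise ValueError("only ASCII (P2) PGM is supported")
    w, h, max_val = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array([int(t) for t in tokens[4 : 4 + w * h]], dtype=float)
    return (data / max_val).reshape(h, w)


def field_to_csv(rf: ReceptiveField, path) -> None:
    rows, cols = np.mgrid[0 : rf.h, 0 : rf.w]
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "vfg1": rf.vfg1.ravel(),
            "vfg2": rf.vfg2.ravel(),
        }
    ).to_csv(path, index=False)


def field_from_csv(path) -> ReceptiveField:
    df = pd.read_csv(path)
    h, w = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    vfg1 = np.zeros((h, w))
    vfg2 = np.zeros((h, w))
    vfg1[df["row"], df["col"]] = df["vfg1"]
    vfg2[df["row"], df["col"]] = df["vfg2"]
    return ReceptiveField(vfg1=vfg1, vfg2=vfg2)


def field_to_pgm(rf: ReceptiveField, path) -> None:
    """Developed-template rendering: ON-side dominance as brightness."""
    span = rf.vfg2 - rf.vfg1  # positive where the ON-side synapse is stronger
    lo, hi = span.min(), span.max()
    img = (span - lo) / (hi - lo) if hi > lo else np.full(span.shape, 0.5)
    write_pgm(path, img)


def save_bank(bank: list[DisparityCellState], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, cell in enumerate(bank):
        field_to_csv(cell.rf, out / f"cell_{i}.csv")
        field_to_pgm(cell.rf, out / f"cell_{i}.pgm")
        meta.append(
            {
                "file": f"cell_{i}.csv",
                "learned_disparity": cell.learned_disparity,
                "params": _to_plain(cell.params),
            }
        )
    (out / "bank.json").write_text(json.dumps(meta, indent=2))


def load_bank(bank_dir) -> list[DisparityCellState]:
    bank_dir = Path(bank_dir)
    meta = json.loads((bank_dir / "bank.json").read_text())
    bank = []
    for entry in meta:
        rf = field_from_csv(bank_dir / entry["file"])
        params = TsWtaParams(**entry["params"])
        cell = DisparityCellState(rf=rf, params=params)
        cell.learned_disparity = entry["learned_disparity"]
        bank.append(cell)
    return bank


# ------------------------------------------------------------------- run_train


def run_train(config: RunConfig, out_dir=None):
    """Train a full bank per the config; optionally write all artifacts.

    Returns ``(bank, pattern_set)``.  With ``out_dir`` set, writes one
    CSV + PGM per receptive field, the bank metadata, per-cell tuning
    curves (CSV) and the config used.  Reproducible: identical config
    (including seed) gives identical artifacts.
    """
    config.validate()
    pattern_set = synth.make_pattern_set(
        config.h,
        config.w_l + config.w_r,
        config.n_disparities,
        style=config.pattern_style,
        seed=child_seed(config.seed, "patterns"),
    )
    bank = train_bank(
        pattern_set,
        seed=child_seed(config.seed, "bank"),
        bias_volts=config.bias_volts,
        protocol=config.protocol,
        params=config.wta,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")
        save_bank(bank, out)
        probes = [p for p in pattern_set if not p.is_complement]
        curves = []
        for i, c in enumerate(bank):
            curve = tuning_curve(c, probes)
            curves.append(
                pd.DataFrame(
                    {
                        "cell": i,
                        "disparity": curve.disparities,
                        "response": curve.responses,
                    }
                )
            )
        pd.concat(curves).to_csv(out / "tuning_curves.csv", index=False)
    return bank, pattern_set


# --------------------------------------------------------------- sweep harness


def _draw_states(rng, params, gap_min, gap_max):
    lo, hi = 4.8, 5.5
    g = rng.uniform(gap_min, gap_max)
    a = rng.uniform(lo, hi - g)
    return a, a + g


def _inv_l1(params: TsWtaParams, seed: int) -> bool:
    """Equal stimulation: the lower-initial-vfg synapse wins."""
    rng = np.random.default_rng(seed)
    a, b = _draw_states(rng, params, 0.1, 0.7)
    first = rng.random() < 0.5
    state = TsWtaState(a, b) if first else TsWtaState(b, a)
    out = run_competition(state, make_schedule(120, 120), params)
    return out.winner is (Synapse.S1 if first else Synapse.S2)


def _inv_l2(params: TsWtaParams, seed: int) -> bool:
    """3x stimulation overrides a bias gap of up to 0.1 V."""
    rng = np.random.default_rng(seed)
    a, b = _draw_states(rng, params, 0.0, 0.1)
    out = run_competition(TsWtaState(a, b), make_schedule(60, 180), params)
    return out.winner is Synapse.S2


def _inv_elimination(params: TsWtaParams, seed: int) -> bool:
    """The losing synapse is driven to (near) elimination."""
    rng = np.random.default_rng(seed)
    a, b = _draw_states(rng, params, 0.1, 0.7)
    out = run_competition(TsWtaState(a, b), make_schedule(120, 120), params)
    if out.winner is Synapse.UNDECIDED:
        return False
    v1, v2 = out.trajectory[-1]
    e1, e2 = core.efficacy(v1, params), core.efficacy(v2, params)
    return min(e1, e2) < 0.1 * max(e1, e2)


def _inv_resource_cap(params: TsWtaParams, seed: int) -> bool:
    """The per-pulse activation never exceeds the bias resource."""
    rng = np.random.default_rng(seed)
    a, b = _draw_states(rng, params, 0.0, 0.7)
    state = TsWtaState(a, b)
    for s in make_schedule(40, 40):
        fb = core.resource_share(state, s, params)
        if fb > params.i_b + 1e-12:
            return False
        state = core.apply_pulse(state, s, fb, params)
    return True


def _inv_clipping(params: TsWtaParams, seed: int) -> bool:
    """No trajectory leaves the admissible gate range."""
    rng = np.random.default_rng(seed)
    a, b = _draw_states(rng, params, 0.0, 0.7)
    out = run_competition(TsWtaState(a, b), make_schedule(100, 100), params)
    return bool(
        (out.trajectory >= params.vfg_min - 1e-12).all()
        and (out.trajectory <= params.vfg_max + 1e-12).all()
    )


INVARIANTS = {
    "L1": _inv_l1,
    "L2": _inv_l2,
    "elimination": _inv_elimination,
    "resource_cap": _inv_resource_cap,
    "clipping": _inv_clipping,
}


@dataclass
class SweepSpec:
    """Grid specification for the robustness harness.

    ``parameters`` maps TsWtaParams field names to value lists; the
    cartesian product forms the grid.  At each grid point every named
    invariant is evaluated on ``seeds_per_point`` seeded runs.
    """

    parameters: dict[str, list]
    seeds_per_point: int = 20
    invariants: tuple[str, ...] = ("L1", "L2", "elimination", "resource_cap", "clipping")
    base: TsWtaParams = field(default_factory=TsWtaParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.invariants:
            if name not in INVARIANTS:
                raise ValidationError(f"unknown invariant {name!r}")
        for p in self.parameters:
            if p not in {f.name for f in dataclasses.fields(TsWtaParams)}:
                raise ValidationError(f"unknown ts-WTA parameter {p!r}")


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Pass fraction of every invariant at every grid point.

    Returns a table with one row per grid point: the parameter values,
    a ``<invariant>`` pass-fraction column per invariant, and ``ok``
    (all invariants passed on all seeds).
    """
    names = list(spec.parameters)
    grids = [spec.parameters[n] for n in names]
    rows = []
    mesh = np.meshgrid(*[np.arange(len(g)) for g in grids], indexing="ij")
    for idx in zip(*[m.ravel() for m in mesh]):
        values = {n: grids[i][j] for i, (n, j) in enumerate(zip(names, idx))}
        params = dataclasses.replace(spec.base, **values)
        row = dict(values)
        all_ok = True
        for inv in spec.invariants:
            fn = INVARIANTS[inv]
            passed = sum(
                fn(params, child_seed(spec.seed, f"{inv}-{k}"))
                for k in range(spec.seeds_per_point)
            )
            frac = passed / spec.seeds_per_point
            row[inv] = frac
            all_ok &= frac == 1.0
        row["ok"] = all_ok
        rows.append(row)
    return pd.DataFrame(rows)
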