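"""Agent-based moral-argument opinion dynamics with discussion-frequency
heterogeneity.

A population of liberal and conservative agents holds a binary opinion on
one issue; one side has an HVFL argument advantage ``A`` in [-1, 1].  Each
time step every agent initiates a discussion with probability equal to its
frequency-class rate ``f``; the partner is drawn from the agent's own
ideological group with probability ``b(f)`` (ingroup bias), otherwise from
the other group, uniformly within the chosen group.  Both parties present
one argument for their own current opinion: the argument is of an HVFL
kind with probability (1 + A)/2 when arguing the advantaged opinion and
(1 - A)/2 when arguing the disadvantaged one.  A listener holding the
opposite opinion switches with probability ``s`` if the argument's kind is
relevant to it: liberals are moved only by HVFL arguments, conservatives
by arguments of any kind.  Both parties are evaluated on pre-encounter
opinions and all switches are applied simultaneously.

Under the *calibrated* ingroup bias b(f) = 1 - kappa/f (kappa = slowest
class rate), cross-ideology contact f * (1 - b(f)) is the same for every
class, which makes the expected discussion-frequency effect among
conservatives exactly zero while leaving a positive effect among liberals
— the regime behind the theory's fifth prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

IDEOLOGIES = ("liberal", "conservative")


@dataclass(frozen=True)
class FreqClass:
    """A discussion-frequency class: per-step initiation rate and the share
    of each ideological group assigned to it."""

    name: str
    rate: float
    share: float


#: Default classes: a frequent/infrequent split.  Rates are per-step
#: discussion probabilities chosen so that, at persuasion probability 0.5
#: and the largest advantage typically studied (0.3), the fastest class
#: completes its logistic transition within a 500-step horizon while the
#: slowest does not — the regime in which frequency gaps are visible.
DEFAULT_FREQ_CLASSES = (
    FreqClass("infrequent", 0.004, 0.5),
    FreqClass("frequent", 0.02, 0.5),
)


def calibrate_ingroup_bias(rates: Sequence[float]) -> dict[float, float]:
    """Bias schedule making cross-ideology contact equal across classes.

    Returns b(f) = 1 - kappa/f with kappa the minimum rate, so that
    f * (1 - b(f)) = kappa for every class.  With a single class this
    yields b = 0.
    """
    rates = list(rates)
    if len(rates) == 0:
        raise ValidationError("calibrate_ingroup_bias needs at least one rate")
    if min(rates) <= 0:
        raise ValidationError(f"all rates must be > 0, got {rates}")
    kappa = min(rates)
    out = {}
    for f in rates:
        b = 1.0 - kappa / f
        if not (0.0 <= b <= 1.0):
            raise ValidationError(f"calibrated bias b({f})={b} outside [0, 1]")
        out[f] = b
    return out


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    ``ingroup_bias`` is either the string ``"calibrated"``, a constant in
    [0, 1], or an explicit mapping rate -> bias.  ``init_prevalence`` gives
    the initial share of the advantaged opinion per ideology; the default
    0.1 starts the advantaged opinion as a minority position, matching the
    long-run liberalization framing in which an advantaged opinion rises
    from rarity.
    """

    n_agents: int = 2000
    prop_liberal: float = 0.5
    advantage: float = 0.2
    persuade_prob: float = 0.5
    freq_classes: Sequence[FreqClass] = DEFAULT_FREQ_CLASSES
    ingroup_bias: str | float | Mapping[float, float] = "calibrated"
    init_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"liberal": 0.1, "conservative": 0.1}
    )
    horizon: int = 500
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValidationError("n_agents must be >= 2")
        if not (0.0 <= self.prop_liberal <= 1.0):
            raise ValidationError(f"prop_liberal {self.prop_liberal} not in [0, 1]")
        if not (-1.0 <= self.advantage <= 1.0):
            raise ValidationError(f"advantage {self.advantage} not in [-1, 1]")
        if not (0.0 <= self.persuade_prob <= 1.0):
            raise ValidationError(
                f"persuade_prob {self.persuade_prob} not in [0, 1]"
            )
        classes = list(self.freq_classes)
        if len(classes) == 0:
            raise ValidationError("freq_classes must be non-empty")
        if any(c.rate <= 0 or c.rate > 1 for c in classes):
            raise ValidationError("class rates must lie in (0, 1]")
        if abs(sum(c.share for c in classes) - 1.0) > 1e-9:
            raise ValidationError("class shares must sum to 1 within each ideology")
        for v in self.init_prevalence.values():
            if not (0.0 <= v <= 1.0):
                raise ValidationError("init_prevalence values must be probabilities")
        if isinstance(self.ingroup_bias, (int, float)) and not (
            0.0 <= float(self.ingroup_bias) <= 1.0
        ):
            raise ValidationError("constant ingroup bias must be in [0, 1]")
        if self.horizon < 0 or self.n_replicates < 1:
            raise ValidationError("horizon must be >= 0 and n_replicates >= 1")

    def bias_map(self) -> dict[float, float]:
        rates = [c.rate for c in self.freq_classes]
        if isinstance(self.ingroup_bias, str):
            if self.ingroup_bias != "calibrated":
                raise ValidationError(
                    f"unknown ingroup_bias mode {self.ingroup_bias!r}"
                )
            return calibrate_ingroup_bias(rates)
        if isinstance(self.ingroup_bias, (int, float)):
            return {f: float(self.ingroup_bias) for f in rates}
        mp = {float(k): float(v) for k, v in dict(self.ingroup_bias).items()}
        for f in rates:
            if f not in mp:
                raise ValidationError(f"ingroup_bias map lacks rate {f}")
            if not (0.0 <= mp[f] <= 1.0):
                raise ValidationError(f"ingroup_bias b({f})={mp[f]} outside [0, 1]")
        return mp


def liberal_drift_oracle(x: float, advantage: float, persuade_prob: float,
                         contact_rate: float) -> float:
    """Expected one-step change in advantaged-opinion prevalence in a
    large, single-class, all-liberal population.

    Each agent initiates with probability f = ``contact_rate`` and is also
    the partner of f expected discussions, so it takes part in 2f
    encounters per step.  In a mixed-opinion encounter the listener gains
    the advantaged opinion at net probability s*A, giving

        dx = 2 * s * A * x * (1 - x) * f.
    """
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"prevalence {x} not in [0, 1]")
    return 2.0 * persuade_prob * advantage * x * (1.0 - x) * contact_rate


class OpinionDynamicsModel:
    """Agent-based moral-argument model built from a :class:`SimConfig`.

    ``simulate()`` runs all replicates in one vectorized state array and
    returns a :class:`SimulationResults` with per-cell prevalence
    trajectories.
    """

    def __init__(self, config: SimConfig) -> None:
        self.config = config
        self._build_population()

    def _build_population(self) -> None:
        cfg = self.config
        n = cfg.n_agents
        n_lib = int(round(cfg.prop_liberal * n))
        is_lib = np.zeros(n, dtype=bool)
        is_lib[:n_lib] = True
        classes = list(cfg.freq_classes)
        bias = cfg.bias_map()

        class_idx = np.zeros(n, dtype=int)
        for lib_flag, grp_idx in ((True, np.flatnonzero(is_lib)),
                                  (False, np.flatnonzero(~is_lib))):
            g = len(grp_idx)
            # deterministic composition: rounded cumulative shares
            bounds = np.round(np.cumsum([c.share for c in classes]) * g).astype(int)
            start = 0
            for ci, stop in enumerate(bounds):
                class_idx[grp_idx[start:stop]] = ci
                start = stop
        rates = np.array([c.rate for c in classes])
        self.is_lib = is_lib
        self.class_idx = class_idx
        self.rate = rates[class_idx]
        self.bias = np.array([bias[r] for r in self.rate])
        self.lib_idx = np.flatnonzero(is_lib)
        self.con_idx = np.flatnonzero(~is_lib)
        self.cells = [
            (ideo, c.name)
            for ideo in IDEOLOGIES
            for c in classes
        ]
        self.cell_members = [
            np.flatnonzero((is_lib == (ideo == "liberal")) & (class_idx == ci))
            for ideo in IDEOLOGIES
            for ci, _ in enumerate(classes)
        ]

    def simulate(self) -> "SimulationResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        R, N, T = cfg.n_replicates, cfg.n_agents, cfg.horizon
        A, s = cfg.advantage, cfg.persuade_prob
        is_lib = self.is_lib
        f = self.rate
        b = self.bias
        lib_idx, con_idx = self.lib_idx, self.con_idx
        n_lib, n_con = len(lib_idx), len(con_idx)

        p0 = np.where(
            is_lib,
            cfg.init_prevalence.get("liberal", 0.5),
            cfg.init_prevalence.get("conservative", 0.5),
        )
        S = rng.random((R, N)) < p0  # True = advantaged opinion

        n_cells = len(self.cells)
        prev = np.empty((n_cells, T + 1, R))
        sizes = np.array([len(m) for m in self.cell_members])

        def record(t: int) -> None:
            for k, members in enumerate(self.cell_members):
                if len(members):
                    prev[k, t] = S[:, members].mean(axis=1)
                else:
                    prev[k, t] = np.nan

        record(0)
        rep_rows = np.arange(R)[:, None]
        for t in range(1, T + 1):
            act = rng.random((R, N)) < f
            own = rng.random((R, N)) < b
            # partner pool per (replicate, initiator)
            if n_lib and n_con:
                target_lib = np.where(own, is_lib, ~is_lib)
            else:  # one-group population: partners always from that group
                target_lib = np.broadcast_to(n_lib > 0, (R, N))
            pl = (
                lib_idx[rng.integers(0, n_lib, size=(R, N))]
                if n_lib
                else np.zeros((R, N), dtype=int)
            )
            pc = (
                con_idx[rng.integers(0, n_con, size=(R, N))]
                if n_con
                else np.zeros((R, N), dtype=int)
            )
            partner = np.where(target_lib, pl, pc)
            S_p = S[rep_rows, partner]
            differ = S != S_p
            live = act & differ
            # argument kinds: HVFL with prob (1 + A)/2 for the advantaged side
            arg_init_hvfl = rng.random((R, N)) < (1.0 + A * np.where(S, 1, -1)) / 2.0
            arg_part_hvfl = rng.random((R, N)) < (1.0 + A * np.where(S_p, 1, -1)) / 2.0
            acc_init = rng.random((R, N)) < s
            acc_part = rng.random((R, N)) < s
            # initiator listens to partner's argument
            switch_init = live & acc_init & (arg_part_hvfl | ~is_lib[None, :])
            # partner listens to initiator's argument
            switch_part = live & acc_part & (arg_init_hvfl | ~is_lib[partner])
            flip = switch_init.copy()
            r_idx, c_idx = np.nonzero(switch_part)
            flip[r_idx, partner[r_idx, c_idx]] = True
            S ^= flip
            record(t)

        return SimulationResults(self.config, self.cells, sizes, prev)


def run_simulation(config: SimConfig) -> "SimulationResults":
    """Run the agent-based model; convenience wrapper over
    :class:`OpinionDynamicsModel`."""
    return OpinionDynamicsModel(config).simulate()


@dataclass(frozen=True)
class DFEffect:
    """Replicate-averaged prevalence gap (fastest minus slowest class)."""

    gap: float
    ci_low: float
    ci_high: float


class SimulationResults:
    """Prevalence trajectories per (ideology x frequency class) cell.

    ``prevalence`` has shape (n_cells, horizon + 1, n_replicates).
    """

    def __init__(
        self,
        config: SimConfig,
        cells: list[tuple[str, str]],
        cell_sizes: np.ndarray,
        prevalence: np.ndarray,
    ) -> None:
        self.config = config
        self.cells = cells
        self.cell_sizes = cell_sizes
        self.prevalence = prevalence

    def trajectories(self) -> pd.DataFrame:
        """Long-format trajectory table: replicate, t, ideology,
        freq_class, prevalence."""
        n_cells, n_t, R = self.prevalence.shape
        cell_ideo = np.repeat([c[0] for c in self.cells], n_t * R)
        cell_cls = np.repeat([c[1] for c in self.cells], n_t * R)
        t = np.tile(np.repeat(np.arange(n_t), R), n_cells)
        rep = np.tile(np.arange(R), n_cells * n_t)
        return pd.DataFrame(
            {
                "replicate": rep,
                "t": t,
                "ideology": cell_ideo,
                "freq_class": cell_cls,
                "prevalence": self.prevalence.reshape(-1),
            }
        )

    def _cell(self, ideology: str, freq_class: str) -> int:
        try:
            return self.cells.index((ideology, freq_class))
        except ValueError:
            raise ValidationError(
                f"no simulated cell ({ideology}, {freq_class})"
            ) from None

    def group_prevalence(self, ideology: str, t: int) -> np.ndarray:
        """Per-replicate prevalence in one ideology at time t (cell sizes
        as weights)."""
        self._check_time(t)
        ks = [k for k, c in enumerate(self.cells) if c[0] == ideology]
        w = self.cell_sizes[ks].astype(float)
        if w.sum() == 0:
            raise ValidationError(f"no agents with ideology {ideology!r}")
        return (self.prevalence[ks, t, :] * w[:, None]).sum(axis=0) / w.sum()

    def _check_time(self, t: int) -> None:
        if not (0 <= t <= self.config.horizon):
            raise ValidationError(
                f"time {t} outside simulated horizon 0..{self.config.horizon}"
            )

    def summarize_df_effect(
        self, at_time: int | None = None, level: float = 0.95
    ) -> dict[str, DFEffect]:
        """Prevalence gap between the fastest and slowest frequency class
        per ideology, with a percentile CI over replicates."""
        classes = list(self.config.freq_classes)
        if len(classes) < 2:
            raise ValidationError("summarize_df_effect needs >= 2 frequency classes")
        t = self.config.horizon if at_time is None else at_time
        self._check_time(t)
        hi = max(classes, key=lambda c: c.rate).name
        lo = min(classes, key=lambda c: c.rate).name
        alpha = (1.0 - level) / 2.0
        out = {}
        for ideo in IDEOLOGIES:
            gaps = (
                self.prevalence[self._cell(ideo, hi), t, :]
                - self.prevalence[self._cell(ideo, lo), t, :]
            )
            # CI for the replicate mean: normal approximation over replicates
            se = gaps.std(ddof=1) / np.sqrt(len(gaps))
            z = stats.norm.ppf(1.0 - alpha)
            out[ideo] = DFEffect(
                gap=float(gaps.mean()),
                ci_low=float(gaps.mean() - z * se),
                ci_high=float(gaps.mean() + z * se),
            )
        return out

    def to_csv(self, path) -> None:
        self.trajectories().to_csv(path, index=False)
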