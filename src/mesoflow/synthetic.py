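"""Ground-truthed synthetic inputs for every downstream analysis stage.

Three generators emulate the three kinds of data the pipeline consumes:

* coupled nonlinear stochastic networks standing in for multichannel
  population-activity (MUA) epochs, with directed couplings that can differ
  between behavioral conditions (hub structure reshuffling between movement
  generation and movement inhibition);
* race-model behavioral sessions — independent GO and STOP processes racing
  to a threshold, with the stop-signal delay tracked by a one-up/one-down
  +-100 ms staircase;
* raw broadband extracellular surrogates (spike trains convolved with a
  stereotyped waveform plus white noise) for testing spectral MUA
  extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import SimulatedSessionConfig

__all__ = [
    "CONDITIONS",
    "Edge",
    "GroundTruthNetwork",
    "simulate_coupled_network",
    "simulate_race_session",
    "simulate_raw_broadband",
    "hub_network",
    "chain_network",
]

CONDITIONS = ("go", "correct_stop", "wrong_stop")


@dataclass(frozen=True)
class Edge:
    """Directed coupling source -> target active in a set of conditions."""

    source: int
    target: int
    lag: int            # ms (samples at 1 ms resolution)
    strength: float
    conditions: frozenset = frozenset(CONDITIONS)

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError("self-edges are not allowed")
        if not 1 <= self.lag <= 10:
            raise ValueError("edge lags must be within 1..10 ms")
        if self.strength < 0:
            raise ValueError("edge strengths must be >= 0")
        object.__setattr__(self, "conditions", frozenset(self.conditions))
        unknown = self.conditions - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")


@dataclass
class GroundTruthNetwork:
    """Driver -> target coupling structure the TE stage must recover."""

    n_nodes: int
    edges: list[Edge] = field(default_factory=list)
    self_decay: float = 0.5

    def __post_init__(self):
        if abs(self.self_decay) >= 1:
            raise ValueError("unstable parameterization: |self-decay| must be < 1")
        for e in self.edges:
            if not (0 <= e.source < self.n_nodes and 0 <= e.target < self.n_nodes):
                raise ValueError("edge endpoint outside the node range")

    def edges_for(self, condition: str) -> list[Edge]:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return [e for e in self.edges if condition in e.conditions]

    def adjacency(self, condition: str) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for e in self.edges_for(condition):
            a[e.source, e.target] = max(a[e.source, e.target], e.strength)
        return a

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "lag_ms": e.lag,
                    "strength": e.strength,
                    "conditions": "|".join(sorted(e.conditions)),
                }
                for e in self.edges
            ]
        )


def with_wrong_stop_mixture(go_edges: list[Edge], stop_edges: list[Edge]) -> list[Edge]:
    """Wrong-Stop wiring as a stated mixture of the two correct conditions:
    movement-generation (go) edges at full strength plus inhibition
    (correct-stop) edges at half strength — errors look midway between the
    two outcomes, closer to movement generation."""
    out = []
    for e in go_edges:
        out.append(Edge(e.source, e.target, e.lag, e.strength,
                        e.conditions | {"wrong_stop"}))
    for e in stop_edges:
        out.append(Edge(e.source, e.target, e.lag, e.strength, e.conditions))
        out.append(Edge(e.source, e.target, e.lag, e.strength / 2.0,
                        frozenset({"wrong_stop"})))
    return out


def hub_network(
    n_nodes: int = 10,
    hub_conditions: dict[int, tuple[str, ...]] | None = None,
    hub_strength: float = 0.7,
    ring_strength: float = 0.6,
    hub_lag: int = 3,
    ring_lag: int = 1,
    wrong_stop_mixture: bool = True,
) -> GroundTruthNetwork:
    """Condition-reshuffled hub structure on a weakly coupled ring.

    Every node drives its successor on a ring (all conditions), which gives
    the network a strongly connected backbone; each entry of
    ``hub_conditions`` maps a node to the conditions in which it acts as an
    out-degree hub, driving every other node.  Default: node 0 is the
    movement-generation (go) hub and the diametrically opposite node the
    inhibition (correct-stop) hub, so no static ring edge links the two hubs
    and the hub-to-hub information flow is purely condition-dependent.
    """
    if hub_conditions is None:
        hub_conditions = {0: ("go",), n_nodes // 2: ("correct_stop",)}
    edges: list[Edge] = []
    for i in range(n_nodes):
        edges.append(Edge(i, (i + 1) % n_nodes, ring_lag, ring_strength))
    go_hub_edges, stop_hub_edges = [], []
    for hub, conds in hub_conditions.items():
        for j in range(n_nodes):
            if j == hub or j == (hub + 1) % n_nodes:
                continue  # ring edge already drives the successor
            if "go" in conds:
                go_hub_edges.append(Edge(hub, j, hub_lag, hub_strength,
                                         frozenset({"go"})))
            if "correct_stop" in conds:
                stop_hub_edges.append(Edge(hub, j, hub_lag, hub_strength,
                                           frozenset({"correct_stop"})))
    if wrong_stop_mixture:
        edges += with_wrong_stop_mixture(go_hub_edges, stop_hub_edges)
    else:
        edges += go_hub_edges + stop_hub_edges
    return GroundTruthNetwork(n_nodes=n_nodes, edges=edges)


def chain_network(strength: float = 0.6, lag: int = 2, n_nodes: int = 3) -> GroundTruthNetwork:
    """Feed-forward chain 0 -> 1 -> ... active in every condition."""
    edges = [Edge(i, i + 1, lag, strength) for i in range(n_nodes - 1)]
    return GroundTruthNetwork(n_nodes=n_nodes, edges=edges)


def simulate_coupled_network(
    truth: GroundTruthNetwork,
    n_samples: int = 400,
    n_trials: int = 40,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    conditions: tuple[str, ...] = CONDITIONS,
    burn_in: int = 100,
) -> dict[str, np.ndarray]:
    """Simulate per-condition trial tensors (channels x time x trials).

    Each node evolves as a stable nonlinear autoregressive process:

        x_i[t] = a * x_i[t-1] + tanh( sum_e strength_e * x_src(e)[t - lag_e] )
                 + noise_sd * eps,

    with the sum over the edges targeting node i that are active in the
    simulated condition.  The odd-sigmoid squashing makes the interactions
    nonlinear, which is the regime transfer entropy is meant to capture
    without a generative model.  Trials are independent realizations; the
    output is standardized per channel within each trial.
    """
    if n_samples < 400:
        raise ValueError("n_samples must be >= 400 (epoch length)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    max_lag = max((e.lag for e in truth.edges), default=1)
    if max_lag >= n_samples:
        raise ValueError("edge lag must be < n_samples")
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    cond_seeds = dict(zip(CONDITIONS, ss.spawn(len(CONDITIONS))))

    a = truth.self_decay
    total = burn_in + n_samples
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        rng = np.random.default_rng(cond_seeds[cond])
        edges = truth.edges_for(cond)
        tensor = np.empty((truth.n_nodes, n_samples, n_trials))
        for tr in range(n_trials):
            eps = rng.standard_normal((truth.n_nodes, total)) * noise_sd
            x = np.zeros((truth.n_nodes, total))
            for t in range(1, total):
                drive = np.zeros(truth.n_nodes)
                for e in edges:
                    if t - e.lag >= 0:
                        drive[e.target] += e.strength * x[e.source, t - e.lag]
                x[:, t] = a * x[:, t - 1] + np.tanh(drive) + eps[:, t]
            seg = x[:, burn_in:]
            sd = seg.std(axis=1, keepdims=True)
            tensor[:, :, tr] = (seg - seg.mean(axis=1, keepdims=True)) / sd
        out[cond] = tensor
    return out


# ---------------------------------------------------------------------------
# race-model behavior
# ---------------------------------------------------------------------------

def _go_finish_sampler(cfg: SimulatedSessionConfig):
    lo = (0.0 - cfg.go_rt_mean) / cfg.go_rt_sd
    return truncnorm(lo, np.inf, loc=cfg.go_rt_mean, scale=cfg.go_rt_sd)


def simulate_race_session(cfg: SimulatedSessionConfig) -> pd.DataFrame:
    """Behavioral session from the independent race model with staircase SSD.

    Every trial draws a GO finish time from the (truncated-normal) Go-RT
    distribution.  In a Stop trial the movement is produced — a wrong Stop —
    iff the GO process finishes before the STOP process, i.e. iff
    GO finish < SSD + ssrt_true; otherwise the trial is a correct Stop.  The
    SSD rises by ``staircase_step`` after a correct Stop and falls by the
    same amount after a wrong Stop (floor at 0), driving p(response) to 1/2.

    Returns a trial table with columns trial_id, type, ssd_ms, rt_ms, outcome.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dist = _go_finish_sampler(cfg)

    types = np.array(["go"] * cfg.n_go_trials + ["stop"] * cfg.n_stop_trials)
    rng.shuffle(types)
    rows = []
    ssd = float(cfg.initial_ssd)
    for i, ttype in enumerate(types):
        go_finish = float(dist.rvs(random_state=rng))
        if ttype == "go":
            rows.append((i, "go", np.nan, go_finish, "go_correct"))
            continue
        if go_finish < ssd + cfg.ssrt_true:
            rows.append((i, "stop", ssd, go_finish, "stop_wrong"))
            ssd = max(0.0, ssd - cfg.staircase_step)
        else:
            rows.append((i, "stop", ssd, np.nan, "stop_correct"))
            ssd = ssd + cfg.staircase_step
    return pd.DataFrame(rows, columns=["trial_id", "type", "ssd_ms", "rt_ms", "outcome"])


# ---------------------------------------------------------------------------
# raw broadband surrogate
# ---------------------------------------------------------------------------

def default_waveform(fs: float = 24400.0) -> np.ndarray:
    """Stereotyped biphasic single-unit waveform (~1 ms), unit peak."""
    t = np.arange(int(round(1.2e-3 * fs))) / fs
    w = np.exp(-((t - 0.25e-3) ** 2) / (2 * (0.08e-3) ** 2))
    w -= 0.6 * np.exp(-((t - 0.55e-3) ** 2) / (2 * (0.15e-3) ** 2))
    return w / np.abs(w).max()


def simulate_raw_broadband(
    firing_rate_profile: np.ndarray,
    fs: float = 24400.0,
    rate_dt: float = 1e-3,
    waveform: np.ndarray | None = None,
    noise_sd: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Raw extracellular surrogate: Poisson spikes convolved with a waveform.

    ``firing_rate_profile`` is (channels x time) in spikes/s on a ``rate_dt``
    grid.  Each channel is an inhomogeneous Poisson process (thinned on the
    fs grid) convolved with the stereotyped spike shape, plus white noise.
    Used to validate the spectral MUA-extraction stage, whose band-ratio
    output should track the set firing rate.
    """
    rates = np.atleast_2d(np.asarray(firing_rate_profile, dtype=float))
    if np.any(rates < 0):
        raise ValueError("firing rates must be nonnegative")
    rng = np.random.default_rng(seed)
    waveform = default_waveform(fs) if waveform is None else np.asarray(waveform)
    n_ch, n_bins = rates.shape
    n_samp = int(round(n_bins * rate_dt * fs))
    out = np.empty((n_ch, n_samp))
    bin_idx = np.minimum((np.arange(n_samp) / (fs * rate_dt)).astype(int),
                         n_bins - 1)
    for c in range(n_ch):
        rate_per_sample = rates[c, bin_idx]
        spikes = rng.random(n_samp) < rate_per_sample / fs
        sig = np.convolve(spikes.astype(float), waveform)[:n_samp]
        out[c] = sig + noise_sd * rng.standard_normal(n_samp)
    return out
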