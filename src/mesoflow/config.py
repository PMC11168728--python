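"""Configuration dataclasses shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional
import hashlib
import json


@dataclass
class EmbeddingCandidates:
    """Candidate past terms for nonuniform embedding.

    The candidate pool contains, for every series (target, source and all
    conditioning channels), the past samples at lags ``u, u + tau, ...`` up to
    ``max_lag`` milliseconds.  Defaults follow the relaxed uniform initial
    vector used for cortical population activity: past up to 50 ms with unit
    embedding lag and offset.
    """

    max_lag: int = 50
    tau: int = 1
    u: int = 1

    def lags(self) -> list[int]:
        return list(range(self.u, self.max_lag + 1, self.tau))

    def validate(self) -> None:
        if self.max_lag < 1 or self.u < 1 or self.tau < 1:
            raise ValueError("max_lag, tau and u must all be >= 1")
        if self.u > self.max_lag:
            raise ValueError("offset u exceeds max_lag")


@dataclass
class KernelConfig:
    """Heaviside-kernel estimator and surrogate-test settings.

    Parameters
    ----------
    r_fraction : kernel radius as a fraction of the per-series SD (series are
        standardized, so this is the radius itself), 0 < r < 1.
    norm : only the Chebyshev (maximum) norm is supported; with the Heaviside
        kernel it makes the estimator coincide with sample entropy.
    surrogates : number of time-shift surrogates per candidate test.
    alpha : familywise significance level of each embedding step.
    min_shift : minimum circular shift (samples) of a surrogate, large enough
        to destroy short-lag dependence; shifts are drawn uniformly from
        [min_shift, n - min_shift].
    candidate_test : "max-z" (default) tests the winning candidate against a
        Gaussian fit of its own surrogate gains at the Sidak/Bonferroni level
        alpha / n_candidates, which keeps the per-step familywise error near
        alpha despite the max-selection over the pool; "quantile" is the
        uncorrected toolbox convention (gain above the empirical (1 - alpha)
        surrogate quantile).
    max_terms : safety cap on the number of selected embedding terms.
    """

    r_fraction: float = 0.2
    norm: str = "chebyshev"
    surrogates: int = 300
    alpha: float = 0.01
    min_shift: int = 20
    candidate_test: str = "max-z"
    max_terms: int = 20

    def validate(self) -> None:
        if not 0.0 < self.r_fraction < 1.0:
            raise ValueError("r_fraction must be in (0, 1)")
        if self.norm != "chebyshev":
            raise ValueError("only the Chebyshev (maximum) norm is supported")
        if self.surrogates < 100:
            raise ValueError("at least 100 surrogates are required")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.candidate_test not in ("max-z", "quantile"):
            raise ValueError("candidate_test must be 'max-z' or 'quantile'")
        if self.min_shift < 1:
            raise ValueError("min_shift must be >= 1")


@dataclass
class SimulatedSessionConfig:
    """Race-model behavioral session with staircase SSD tracking.

    Durations in ms.  The one-up/one-down staircase moves the stop-signal
    delay by ``staircase_step`` (+ after a correct Stop, - after a wrong
    Stop, floored at 0), which drives the response rate in Stop trials
    towards 50%.
    """

    n_go_trials: int = 1000
    n_stop_trials: int = 250
    go_rt_mean: float = 650.0
    go_rt_sd: float = 130.0
    ssrt_true: float = 215.0
    initial_ssd: float = 200.0
    staircase_step: float = 100.0
    trial_length: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("go_rt_mean", "go_rt_sd", "ssrt_true", "staircase_step",
                     "trial_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.initial_ssd < 0:
            raise ValueError("initial_ssd must be >= 0")
        if self.n_go_trials < 0 or self.n_stop_trials < 0:
            raise ValueError("trial counts must be >= 0")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the published defaults.

    Stage toggles plus every module parameter; serializable so a run is fully
    described by (config, master seed).
    """

    # synthetic network
    n_nodes: int = 10
    n_trials: int = 40
    n_samples: int = 400
    noise_sd: float = 1.0
    coupling: float = 0.7
    # behavior
    session: SimulatedSessionConfig = field(default_factory=SimulatedSessionConfig)
    # preprocessing
    epoch_ms: int = 400
    outlier_sd_mult: float = 2.0
    outlier_channel_frac: float = 0.8
    # TE
    embedding: EmbeddingCandidates = field(default_factory=EmbeddingCandidates)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    # null model
    null_reps: int = 500
    # stage toggles
    run_behavior: bool = True
    run_preprocess: bool = True
    run_te: bool = True
    run_network: bool = True
    run_interaction: bool = True
    run_null: bool = False
    # bookkeeping
    seed: int = 0

    def validate(self) -> None:
        self.session.validate()
        self.embedding.validate()
        self.kernel.validate()
        if self.run_network and not self.run_te:
            raise ValueError("network stage requires the TE stage")
        if self.run_interaction and not self.run_network:
            raise ValueError("interaction stage requires the network stage")
        if self.run_null and not self.run_te:
            raise ValueError("null-model stage requires the TE stage")
        if self.n_samples < self.epoch_ms:
            raise ValueError("n_samples must cover the analysis epoch")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("session"), dict):
            d["session"] = SimulatedSessionConfig(**d["session"])
        if isinstance(d.get("embedding"), dict):
            d["embedding"] = EmbeddingCandidates(**d["embedding"])
        if isinstance(d.get("kernel"), dict):
            d["kernel"] = KernelConfig(**d["kernel"])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
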