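"""Multivariate transfer entropy with nonuniform embedding.

Transfer entropy from a source series X to a target Y, conditioned on the
remaining recorded series Z, is

    TE_{X->Y|Z} = H(Y_n | Y_n^-, Z_n^-) - H(Y_n | Y_n^-, X_n^-, Z_n^-),

a nonnegative, directed measure of how much the past of X improves the
prediction of the present of Y beyond Y's own past and the past of every
other channel.  Entropies are estimated with the Heaviside (step) kernel
under the Chebyshev norm — the sample-entropy estimator — with the radius a
fraction of the per-series SD, and the relevant past terms are chosen by a
greedy nonuniform-embedding procedure: at each step the candidate past
sample (any series, lag 1..max_lag) that most reduces the conditional
entropy of the target's present is admitted only if its gain survives a
time-shift surrogate test; the first non-significant candidate terminates
the selection.  A source with no admitted past term transfers, by
construction, exactly zero information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm as _norm

from ._engine import TrialEngine
from .config import EmbeddingCandidates, KernelConfig

logger = logging.getLogger("mesoflow.te")

__all__ = [
    "TEMatrix",
    "EmbeddingSpec",
    "kernel_entropy",
    "conditional_entropy_terms",
    "select_nonuniform_embedding",
    "transfer_entropy_mv",
    "te_matrix_single_trial",
    "trial_average_te",
    "standardize",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingSpec:
    """Selected past terms for one target channel.

    ``terms`` is the ordered list of (series index, lag in samples) admitted
    by the greedy selection; ``p_values`` and ``gains`` are per-term test
    results (conditional-entropy reduction in nats).
    """

    target: int
    terms: list[tuple[int, int]] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    gains: list[float] = field(default_factory=list)

    def source_terms(self, source: int) -> list[tuple[int, int]]:
        return [t for t in self.terms if t[0] == source]


@dataclass
class TEMatrix:
    """N x N nonnegative directed adjacency of significant TE values (nats).

    ``values[i, j]`` is the information transfer i -> j; the diagonal is
    identically zero (no self-loops).
    """

    values: np.ndarray
    condition: str = ""
    session: str = ""
    trial: object = None
    trial_averaged: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("TE matrix must be square")
        if np.any(np.diag(v) != 0):
            raise ValueError("TE matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("TE values must be nonnegative")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        v = self.values
        return v[~np.eye(v.shape[0], dtype=bool)]

    def link_count(self) -> int:
        return int(np.count_nonzero(self.offdiag()))

    def normalized(self, vmax: float | None = None) -> np.ndarray:
        """Display normalization to [0, 1] by a shared maximum (e.g. across
        behavioral conditions); computation always stays in nats."""
        vmax = float(np.max(self.values)) if vmax is None else float(vmax)
        return self.values / vmax if vmax > 0 else self.values.copy()


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Zero-mean, unit-SD scaling (population SD); rejects constant series."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant series cannot be standardized")
    return (x - x.mean(axis=axis, keepdims=True)) / sd


def kernel_entropy(points: np.ndarray, cfg: KernelConfig | None = None,
                   r: float | None = None) -> float:
    """Heaviside-kernel (sample) entropy of a d-dimensional sample, in nats.

    H = -(1/n) sum_i ln( (1/n) sum_j Theta(r - ||p_i - p_j||_inf) ), with the
    self-match included so every inner sum is >= 1/n and H is finite.
    Coordinates are expected to be standardized so that the radius r (a
    fraction of the SD) has the same meaning in every dimension.
    """
    cfg = cfg or KernelConfig()
    r = cfg.r_fraction if r is None else float(r)
    if r <= 0:
        raise ValueError("kernel radius must be > 0")
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < 10:
        raise ValueError("kernel_entropy requires at least 10 points")
    h = 0.0
    chunk = max(1, int(4e6) // max(n, 1))
    for lo in range(0, n, chunk):
        d = cdist(pts[lo:lo + chunk], pts, metric="chebyshev")
        cnt = (d <= r).sum(axis=1)
        h -= np.log(cnt / n).sum()
    return h / n


def conditional_entropy_terms(target_now: np.ndarray,
                              past_matrix: np.ndarray | None,
                              cfg: KernelConfig | None = None) -> float:
    """H(Y_n | V) = H(Y_n, V) - H(V) via the kernel estimator.

    ``past_matrix`` holds the conditioning vectors as columns (n x d);
    conditioning on an empty set returns the plain entropy H(Y_n).
    """
    y = np.asarray(target_now, dtype=float).ravel()
    if past_matrix is None or np.size(past_matrix) == 0:
        return kernel_entropy(y, cfg)
    v = np.asarray(past_matrix, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[0] != y.shape[0]:
        raise ValueError("target and conditioning set have mismatched lengths")
    joint = np.column_stack([y, v])
    return kernel_entropy(joint, cfg) - kernel_entropy(v, cfg)


# ---------------------------------------------------------------------------
# nonuniform embedding
# ---------------------------------------------------------------------------

def _candidate_pool(n_series: int, candidates: EmbeddingCandidates):
    """Pool ordered by (lag, series index): ties in the greedy argmax resolve
    to the lower lag, then the lower series index."""
    lags = candidates.lags()
    cand_s = np.array([s for lag in lags for s in range(n_series)], dtype=np.int64)
    cand_l = np.array([lag for lag in lags for _ in range(n_series)], dtype=np.int64)
    return cand_s, cand_l


def _accept(gain: float, sur_gains: np.ndarray, n_cands: int,
            cfg: KernelConfig) -> tuple[bool, float]:
    """Significance decision for the winning candidate.

    "max-z": the winner of the pool-wide argmax is compared with a Gaussian
    fit of its own time-shift surrogate gains at level alpha / n_cands
    (Bonferroni over the pool), which bounds the per-step familywise
    false-acceptance rate near alpha.  "quantile": plain empirical
    (1 - alpha) surrogate quantile, the uncorrected toolbox convention.
    """
    ns = len(sur_gains)
    if cfg.candidate_test == "quantile":
        p = (1 + int(np.sum(sur_gains >= gain))) / (1 + ns)
        return p <= cfg.alpha, p
    mu = float(np.mean(sur_gains))
    sd = float(np.std(sur_gains, ddof=1))
    sd = max(sd, 1e-12)
    z = (gain - mu) / sd
    p_single = _norm.sf(z)
    p = min(1.0, n_cands * p_single)
    return p <= cfg.alpha, p


def select_nonuniform_embedding(
    series: np.ndarray,
    target: int,
    candidates: EmbeddingCandidates | None = None,
    cfg: KernelConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    engine: TrialEngine | None = None,
) -> EmbeddingSpec:
    """Greedy maximum-relevance / minimum-redundancy selection of past terms.

    ``series`` is (n_series, n_samples); each series is standardized
    internally.  At every step the candidate past sample maximizing the
    decrease of H(Y_n | selected + candidate) is tested against time-shift
    surrogates of itself; selection terminates at the first rejection.
    Deterministic for a fixed seed.
    """
    candidates = candidates or EmbeddingCandidates()
    cfg = cfg or KernelConfig()
    candidates.validate()
    cfg.validate()
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-d (n_series x n_samples)")
    n_series, n = series.shape
    if n <= candidates.max_lag + 1:
        raise ValueError("series shorter than max_lag + 1")
    if engine is None:
        engine = TrialEngine(standardize(series), cfg.r_fraction, candidates.max_lag)

    rng = np.random.default_rng(seed)
    cand_s, cand_l = _candidate_pool(n_series, candidates)
    active = np.ones(cand_s.shape[0], dtype=bool)

    jp = engine.ones()
    jyp = jp & engine.window(target, 0)
    h_base = engine.entropy(jyp) - engine.entropy(jp)

    spec = EmbeddingSpec(target=target)
    shift_hi = engine.n - cfg.min_shift
    if shift_hi <= cfg.min_shift:
        raise ValueError("series too short for the configured min_shift")

    while active.any() and len(spec.terms) < cfg.max_terms:
        s_idx = cand_s[active]
        l_idx = cand_l[active]
        h1, h2 = engine.scan(s_idx, l_idx, jp, jyp)
        gains = h_base - (h2 - h1)
        k = int(np.argmax(gains))
        gain = float(gains[k])
        s_best, l_best = int(s_idx[k]), int(l_idx[k])

        shifts = rng.integers(cfg.min_shift, shift_hi + 1, size=cfg.surrogates)
        sh1, sh2 = engine.scan(
            np.full(cfg.surrogates, s_best), np.full(cfg.surrogates, l_best),
            jp, jyp, shifts=shifts,
        )
        sur_gains = h_base - (sh2 - sh1)
        ok, p = _accept(gain, sur_gains, int(active.sum()), cfg)
        if not ok:
            break
        spec.terms.append((s_best, l_best))
        spec.p_values.append(p)
        spec.gains.append(gain)
        w = engine.window(s_best, l_best)
        jp &= w
        jyp &= w
        h_base = engine.entropy(jyp) - engine.entropy(jp)
        active &= ~((cand_s == s_best) & (cand_l == l_best))

    return spec


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

def transfer_entropy_mv(
    series: np.ndarray,
    source: int,
    target: int,
    spec: EmbeddingSpec,
    cfg: KernelConfig | None = None,
    candidates: EmbeddingCandidates | None = None,
    engine: TrialEngine | None = None,
) -> float:
    """Conditional TE source -> target given the selected embedding (nats).

    TE = H(Y_n | selected \\ source terms) - H(Y_n | selected), floored at 0;
    exactly 0 when the selection admitted no past term of the source.
    """
    if spec.target != target:
        raise ValueError("embedding spec was computed for a different target")
    cfg = cfg or KernelConfig()
    candidates = candidates or EmbeddingCandidates()
    if not spec.source_terms(source):
        return 0.0
    if engine is None:
        series = np.asarray(series, dtype=float)
        engine = TrialEngine(standardize(series), cfg.r_fraction, candidates.max_lag)
    yp = engine.window(target, 0)
    jp_full = engine.joint_packed(spec.terms)
    jp_red = engine.joint_packed([t for t in spec.terms if t[0] != source])
    h_red = engine.entropy(jp_red & yp) - engine.entropy(jp_red)
    h_full = engine.entropy(jp_full & yp) - engine.entropy(jp_full)
    return max(0.0, h_red - h_full)


def te_matrix_single_trial(
    trial: np.ndarray,
    candidates: EmbeddingCandidates | None = None,
    cfg: KernelConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    condition: str = "",
) -> TEMatrix:
    """Full multivariate TE matrix of one trial (channels x samples).

    For every target channel the nonuniform embedding is selected once over
    all channels' pasts; the ordered-pair entry (i, j) is then the
    conditional TE i -> j given every remaining channel, zero when no past
    term of i was admitted.  Per-target randomness is derived from ``seed``
    so results are independent of evaluation order.
    """
    candidates = candidates or EmbeddingCandidates()
    cfg = cfg or KernelConfig()
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be 2-d (channels x samples)")
    if np.any(~np.isfinite(trial)):
        raise ValueError("trial contains NaN or infinite values")
    n_ch = trial.shape[0]
    if n_ch < 3:
        raise ValueError("multivariate TE requires at least 3 channels")

    engine = TrialEngine(standardize(trial), cfg.r_fraction, candidates.max_lag)
    if isinstance(seed, np.random.SeedSequence):
        child_seeds = seed.spawn(n_ch)
    else:
        child_seeds = np.random.SeedSequence(seed).spawn(n_ch)

    values = np.zeros((n_ch, n_ch))
    for j in range(n_ch):
        spec = select_nonuniform_embedding(
            trial, j, candidates, cfg, seed=child_seeds[j], engine=engine)
        for i in range(n_ch):
            if i == j:
                continue
            values[i, j] = transfer_entropy_mv(
                trial, i, j, spec, cfg, candidates, engine=engine)
    return TEMatrix(values=values, condition=condition)


def trial_average_te(matrices: list[TEMatrix]) -> TEMatrix:
    """Element-wise mean of same-condition single-trial TE matrices."""
    if len(matrices) < 2:
        raise ValueError("trial averaging requires at least 2 matrices")
    shape = matrices[0].values.shape
    cond = matrices[0].condition
    for m in matrices[1:]:
        if m.values.shape != shape:
            raise ValueError("TE matrices have mismatched shapes")
        if m.condition != cond:
            raise ValueError("TE matrices come from different conditions")
    mean = np.mean([m.values for m in matrices], axis=0)
    return TEMatrix(values=mean, condition=cond,
                    session=matrices[0].session, trial_averaged=True)
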