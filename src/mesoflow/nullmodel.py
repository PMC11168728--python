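"""Permutation null model for the TE network metrics.

The null hypothesis is that the observed topology is explained by the
marginal distribution of MUA values and the series length alone, with no
temporal dependence.  Each channel of each trial is independently permuted
in time — preserving its histogram exactly while destroying auto- and
cross-temporal structure — the single-trial TE matrices are recomputed, the
link density of each surrogate single-trial graph is matched to its
empirical counterpart (the k strongest links are retained, k = the
empirical significant-link count), and the matrices are trial-averaged.
Repeating the procedure yields a null ensemble of graph metrics against
which the empirical descent point and slope are ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import EmbeddingCandidates, KernelConfig
from .network import percolation_curve
from .te import TEMatrix, te_matrix_single_trial, trial_average_te

logger = logging.getLogger("mesoflow.null")

__all__ = ["NullEnsemble", "permute_trial", "match_link_density",
           "null_te_network", "compare_to_null"]


@dataclass
class NullEnsemble:
    """Per-repetition metrics (and optionally matrices) of the null model."""

    n_reps: int
    descent_points: np.ndarray
    slopes: np.ndarray
    matrices: list = field(default_factory=list)
    seed: int | None = None

    def percentile(self, metric: str, q: float) -> float:
        return float(np.nanpercentile(getattr(self, metric), q))


def permute_trial(trial: np.ndarray,
                  seed: int | np.random.SeedSequence | np.random.Generator = 0
                  ) -> np.ndarray:
    """Independent random time permutation of every channel of one trial.

    The per-channel histogram (hence mean and variance) is preserved
    exactly; all temporal relationships within and across channels are
    destroyed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trial = np.asarray(trial)
    out = np.empty_like(trial)
    for c in range(trial.shape[0]):
        out[c] = trial[c, rng.permutation(trial.shape[1])]
    return out


def match_link_density(null_values: np.ndarray, k: int) -> np.ndarray:
    """Keep the k strongest off-diagonal links (ties broken by node-index
    order: lower source row, then lower target column, wins)."""
    v = np.asarray(null_values, dtype=float).copy()
    np.fill_diagonal(v, 0.0)
    n = v.shape[0]
    off = [(i, j) for i in range(n) for j in range(n) if i != j and v[i, j] > 0]
    if k >= len(off):
        return v
    # stable sort: descending weight, ascending (i, j) among ties
    off.sort(key=lambda ij: (-v[ij], ij))
    out = np.zeros_like(v)
    for i, j in off[:k]:
        out[i, j] = v[i, j]
    return out


def null_te_network(
    tensor: np.ndarray,
    empirical_trial_matrices: list[TEMatrix],
    candidates: EmbeddingCandidates | None = None,
    cfg: KernelConfig | None = None,
    n_reps: int = 500,
    seed: int | np.random.SeedSequence = 0,
    keep_matrices: bool = False,
    force: bool = False,
) -> NullEnsemble:
    """Null ensemble of trial-averaged TE networks and their percolation
    metrics.

    ``tensor`` is channels x time x trials; per repetition every trial is
    channel-wise permuted, its TE matrix recomputed, thinned to the link
    count of the corresponding empirical single-trial matrix, and the
    repetition's matrices are trial-averaged.  Degenerate null averages
    with no positive link record NaN metrics.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("tensor must be channels x time x trials")
    n_trials = tensor.shape[2]
    if len(empirical_trial_matrices) != n_trials:
        raise ValueError("one empirical single-trial matrix per trial is required")
    if n_reps < 10 and not force:
        raise ValueError("fewer than 10 repetitions gives unstable percentiles "
                         "(pass force=True to override)")
    candidates = candidates or EmbeddingCandidates()
    cfg = cfg or KernelConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_reps)
    k_links = [m.link_count() for m in empirical_trial_matrices]

    descents = np.full(n_reps, np.nan)
    slopes = np.full(n_reps, np.nan)
    matrices = []
    for rep in range(n_reps):
        trial_seeds = rep_seeds[rep].spawn(2 * n_trials)
        null_trials = []
        for tr in range(n_trials):
            surrogate = permute_trial(
                tensor[:, :, tr], np.random.default_rng(trial_seeds[2 * tr]))
            m = te_matrix_single_trial(
                surrogate, candidates, cfg, seed=trial_seeds[2 * tr + 1])
            null_trials.append(TEMatrix(match_link_density(m.values, k_links[tr])))
        avg = trial_average_te(null_trials) if n_trials > 1 else null_trials[0]
        if keep_matrices:
            matrices.append(avg)
        if np.any(avg.values > 0):
            curve = percolation_curve(avg)
            if curve.descent_point is not None:
                descents[rep] = curve.descent_point
            slopes[rep] = curve.slope
    return NullEnsemble(n_reps=n_reps, descent_points=descents, slopes=slopes,
                        matrices=matrices)


def compare_to_null(value: float, null_values: np.ndarray,
                    direction: str = "greater") -> dict:
    """Empirical percentile and add-one-corrected p-value of a metric.

    p = (1 + #{null >= value}) / (1 + n) for direction "greater" (the
    probability of the null producing a value at least as extreme);
    NaN repetitions (degenerate null graphs) count as non-exceeding.
    """
    null_values = np.asarray(null_values, dtype=float)
    n = len(null_values)
    if n == 0:
        raise ValueError("empty null ensemble")
    finite = null_values[np.isfinite(null_values)]
    if direction == "greater":
        exceed = int(np.sum(finite >= value))
    elif direction == "less":
        exceed = int(np.sum(finite <= value))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    p = (1 + exceed) / (1 + n)
    percentile = 100.0 * np.sum(finite < value) / n
    return {"p_value": float(p), "percentile": float(percentile),
            "n_reps": n, "direction": direction}
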