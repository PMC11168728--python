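"""End-to-end orchestration: simulate -> preprocess -> TE -> topology -> nulls.

`InformationFlowModel` is the central modelling object: built from
per-condition trial tensors (channels x time x trials), its ``fit`` estimates
the single-trial multivariate TE matrices, trial-averages them per
behavioral condition, and returns an `InformationFlowResults` carrying the
directed-network topology (percolation, hubs, C1-C4 clusters), the
cluster-interaction matrices and hooks for the permutation null model.

`run_session` wires a full synthetic session: race-model behavior, a
ground-truth coupled network, outlier exclusion, the information-flow fit
and a serializable report; `compare_conditions` pools the per-condition
complexity metrics across sessions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .behavior import RaceModel, RaceModelResults
from .config import RunConfig
from .interaction import InteractionMatrix, interaction_matrix
from .network import (PercolationCurve, ClusterAssignment, assign_clusters,
                      compare_groups, detect_hubs, percolation_curve,
                      robustness_curves, threshold_for_analysis, vertex_degrees)
from .nullmodel import NullEnsemble, compare_to_null, null_te_network
from .preprocess import TrialTensor, exclude_outlier_trials
from .synthetic import hub_network, simulate_coupled_network, simulate_race_session
from .te import TEMatrix, te_matrix_single_trial, trial_average_te

logger = logging.getLogger("mesoflow.pipeline")

__all__ = ["InformationFlowModel", "InformationFlowResults", "run_session",
           "compare_conditions", "SessionReport"]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


class InformationFlowModel:
    """Directed information-flow network model of multichannel epochs.

    Parameters
    ----------
    tensors : mapping condition -> TrialTensor or (channels x time x trials)
        array of standardizable population-activity epochs.
    config : RunConfig (embedding candidates, kernel settings, outlier rule).
    """

    def __init__(self, tensors: dict, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.config.kernel.validate()
        self.config.embedding.validate()
        self.tensors: dict[str, TrialTensor] = {}
        for cond, t in tensors.items():
            if not isinstance(t, TrialTensor):
                t = TrialTensor(mua=np.asarray(t, dtype=float), condition=cond)
            self.tensors[cond] = t

    def fit(self, seed: int | np.random.SeedSequence = 0,
            exclude_outliers: bool = True) -> "InformationFlowResults":
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        cond_seeds = dict(zip(sorted(self.tensors), ss.spawn(len(self.tensors))))
        trial_matrices: dict[str, list[TEMatrix]] = {}
        averaged: dict[str, TEMatrix] = {}
        exclusion_reports: dict[str, dict] = {}
        kept_tensors: dict[str, TrialTensor] = {}
        for cond in sorted(self.tensors):
            tensor = self.tensors[cond]
            if exclude_outliers and tensor.n_trials >= 2:
                keep, report = exclude_outlier_trials(
                    tensor, self.config.outlier_sd_mult,
                    self.config.outlier_channel_frac)
                tensor = tensor.subset(keep)
                exclusion_reports[cond] = report
            kept_tensors[cond] = tensor
            t_seeds = cond_seeds[cond].spawn(tensor.n_trials)
            mats = [
                te_matrix_single_trial(
                    tensor.trial(k), self.config.embedding, self.config.kernel,
                    seed=t_seeds[k], condition=cond)
                for k in range(tensor.n_trials)
            ]
            trial_matrices[cond] = mats
            averaged[cond] = (trial_average_te(mats) if len(mats) > 1
                              else mats[0])
        return InformationFlowResults(
            model=self, te=averaged, trial_matrices=trial_matrices,
            exclusion_reports=exclusion_reports, tensors=kept_tensors)


@dataclass
class InformationFlowResults:
    """Fitted trial-averaged TE networks and their topology read-outs."""

    model: InformationFlowModel
    te: dict[str, TEMatrix]
    trial_matrices: dict[str, list[TEMatrix]]
    exclusion_reports: dict[str, dict] = field(default_factory=dict)
    tensors: dict[str, TrialTensor] = field(default_factory=dict)

    # -- topology --------------------------------------------------------
    def percolation(self, condition: str) -> PercolationCurve | None:
        """Percolation curve, or None for a degenerate all-zero TE matrix."""
        if not np.any(self.te[condition].values > 0):
            logger.warning("condition %r has no significant link", condition)
            return None
        return percolation_curve(self.te[condition])

    def analysis_graph(self, condition: str) -> np.ndarray:
        curve = self.percolation(condition)
        if curve is None:
            return np.zeros_like(self.te[condition].values)
        return threshold_for_analysis(curve, self.te[condition])

    def hubs(self, condition: str) -> set[int]:
        return detect_hubs(vertex_degrees(self.analysis_graph(condition)))

    def clusters(self) -> ClusterAssignment:
        """C1-C4 assignment from the Go / correct-Stop hub sets (wrong-Stop
        hubs only flag anomalies)."""
        n = next(iter(self.te.values())).n_nodes
        hubs_go = self.hubs("go") if "go" in self.te else set()
        hubs_cs = self.hubs("correct_stop") if "correct_stop" in self.te else set()
        hubs_ws = self.hubs("wrong_stop") if "wrong_stop" in self.te else set()
        return assign_clusters(hubs_go, hubs_cs, hubs_ws, n_nodes=n)

    def robustness(self, condition: str,
                   clusters: ClusterAssignment | None = None) -> pd.DataFrame:
        clusters = clusters or self.clusters()
        return robustness_curves(self.te[condition], clusters)

    def interactions(self, clusters: ClusterAssignment | None = None
                     ) -> dict[str, InteractionMatrix]:
        clusters = clusters or self.clusters()
        return {cond: interaction_matrix(m, clusters, condition=cond)
                for cond, m in self.te.items()}

    # -- null model ------------------------------------------------------
    def null_ensemble(self, condition: str, n_reps: int = 500,
                      seed: int | np.random.SeedSequence = 0,
                      force: bool = False) -> NullEnsemble:
        tensor = self.tensors[condition]
        return null_te_network(
            tensor.mua, self.trial_matrices[condition],
            self.model.config.embedding, self.model.config.kernel,
            n_reps=n_reps, seed=seed, force=force)

    def null_comparison(self, condition: str, ensemble: NullEnsemble) -> dict:
        curve = self.percolation(condition)
        out = {}
        if curve is None:
            return out
        if curve.descent_point is not None:
            out["descent_point"] = compare_to_null(
                curve.descent_point, ensemble.descent_points, "greater")
        if np.isfinite(curve.slope):
            out["slope"] = compare_to_null(curve.slope, ensemble.slopes, "greater")
        return out

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        lines = ["Information-flow network results", "=" * 48]
        clusters = self.clusters()
        for cond in sorted(self.te):
            m = self.te[cond]
            curve = self.percolation(cond)
            dp = ("%.4f" % curve.descent_point
                  if curve is not None and curve.descent_point is not None
                  else "none")
            slope = f"{curve.slope:.3g}" if curve is not None else "none"
            lines.append(
                f"{cond:>13s}: {m.n_nodes} nodes, {m.link_count()} links, "
                f"descent point {dp}, slope "
                f"{slope}, hubs {sorted(self.hubs(cond))}")
        sizes = clusters.sizes()
        lines.append("clusters: " + ", ".join(f"{k}={v}" for k, v in sizes.items()))
        if clusters.anomalies:
            lines.append(f"ANOMALY: wrong-Stop-only hubs {sorted(clusters.anomalies)}")
        return "\n".join(lines)

    def plot_percolation(self, ax=None):
        """GSCC fraction vs pruning threshold per condition (step plot)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for cond in sorted(self.te):
            curve = self.percolation(cond)
            if curve is None:
                continue
            ax.step(curve.thresholds, curve.gscc_fraction, where="post",
                    label=cond)
            if curve.descent_point is not None:
                ax.axvline(curve.descent_point, ls=":", alpha=0.5)
        ax.set_xlabel("link-weight threshold (TE, nats)")
        ax.set_ylabel("GSCC fraction")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# full synthetic session
# ---------------------------------------------------------------------------

@dataclass
class SessionReport:
    """Everything one synthetic session produced, JSON-serializable."""

    config_hash: str
    seed: int
    behavior: dict
    conditions: list
    network: dict
    interaction: dict
    null: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=1, default=str)


def run_session(config: RunConfig, out_dir: str | Path | None = None
                ) -> tuple[SessionReport, InformationFlowResults, RaceModelResults]:
    """Execute the enabled stages in order on one synthetic session.

    Per-stage seeds are derived from the master seed through a spawned
    SeedSequence tree, so a rerun with the same config produces identical
    output. Stage failures raise with a stage-tagged message.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_behavior, s_data, s_te, s_null = ss.spawn(4)

    # behavior ----------------------------------------------------------
    race_results = None
    behavior_summary = {}
    if config.run_behavior:
        try:
            scfg = config.session
            scfg.seed = _child_seed(s_behavior)
            trials = simulate_race_session(scfg)
            race_results = RaceModel(trials).fit()
            behavior_summary = dict(race_results.session_summary)
            behavior_summary["race_check_p"] = race_results.race_check.p_value
        except Exception as e:
            raise RuntimeError(f"[behavior] stage failed: {e}") from e

    # synthetic network data ---------------------------------------------
    try:
        truth = hub_network(n_nodes=config.n_nodes, hub_strength=config.coupling)
        tensors = simulate_coupled_network(
            truth, config.n_samples, config.n_trials, config.noise_sd,
            seed=s_data)
    except Exception as e:
        raise RuntimeError(f"[synthetic] stage failed: {e}") from e

    # TE + topology -------------------------------------------------------
    flow_results = None
    network_report: dict = {}
    interaction_report: dict = {}
    if config.run_te:
        try:
            model = InformationFlowModel(tensors, config)
            flow_results = model.fit(seed=s_te,
                                     exclude_outliers=config.run_preprocess)
        except Exception as e:
            raise RuntimeError(f"[te] stage failed: {e}") from e
    if config.run_network and flow_results is not None:
        try:
            clusters = flow_results.clusters()
            network_report = {
                "clusters": {str(k): v for k, v in clusters.labels.items()},
                "anomalies": sorted(clusters.anomalies),
                "per_condition": {},
            }
            for cond in sorted(flow_results.te):
                curve = flow_results.percolation(cond)
                network_report["per_condition"][cond] = {
                    "links": flow_results.te[cond].link_count(),
                    "descent_point": (None if curve is None
                                      else curve.descent_point),
                    "slope": (curve.slope if curve is not None
                              and np.isfinite(curve.slope) else None),
                    "hubs": sorted(flow_results.hubs(cond)),
                }
        except Exception as e:
            raise RuntimeError(f"[network] stage failed: {e}") from e
        if config.run_interaction:
            try:
                inter = flow_results.interactions(clusters)
                interaction_report = {
                    cond: im.to_frame().to_dict() for cond, im in inter.items()
                }
            except Exception as e:
                raise RuntimeError(f"[interaction] stage failed: {e}") from e

    # null model ----------------------------------------------------------
    null_report: dict = {}
    if config.run_null and flow_results is not None:
        try:
            for cond in sorted(flow_results.te):
                ens = flow_results.null_ensemble(
                    cond, n_reps=config.null_reps, seed=s_null)
                null_report[cond] = flow_results.null_comparison(cond, ens)
        except Exception as e:
            raise RuntimeError(f"[null] stage failed: {e}") from e

    import mesoflow
    report = SessionReport(
        config_hash=config.hash(),
        seed=config.seed,
        behavior=behavior_summary,
        conditions=sorted(tensors),
        network=network_report,
        interaction=interaction_report,
        null=null_report,
        provenance={"package": "mesoflow", "version": mesoflow.__version__,
                    "seed_policy": "SeedSequence spawn tree"},
    )
    if out_dir is not None:
        _write_session(Path(out_dir), report, truth, tensors, flow_results,
                       race_results)
    return report, flow_results, race_results


def _write_session(out: Path, report: SessionReport, truth, tensors,
                   flow_results, race_results) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    mio.write_edge_list(out / "ground_truth.csv", truth)
    epochs = out / "epochs"
    epochs.mkdir(exist_ok=True)
    for cond, tensor in tensors.items():
        mio.write_tensor(epochs / f"{cond}.h5", tensor if isinstance(
            tensor, TrialTensor) else TrialTensor(mua=tensor, condition=cond))
    if race_results is not None:
        behavior_dir = out / "behavior"
        behavior_dir.mkdir(exist_ok=True)
        race_results.model.session.to_csv(behavior_dir / "trials.csv")
        (behavior_dir / "summary.txt").write_text(race_results.summary())
    if flow_results is not None:
        te_dir = out / "te"
        te_dir.mkdir(exist_ok=True)
        for cond, m in flow_results.te.items():
            mio.write_te_matrix(te_dir / f"{cond}.csv", m)


def compare_conditions(reports: list[SessionReport], alpha: float = 0.01) -> dict:
    """Cross-session distributions of descent point and slope per condition,
    with Kruskal-Wallis + Bonferroni when at least two sessions exist."""
    if not reports:
        raise ValueError("no session reports given")
    rows = []
    for rep in reports:
        for cond, d in rep.network.get("per_condition", {}).items():
            rows.append({"session": rep.config_hash, "condition": cond,
                         "descent_point": d["descent_point"], "slope": d["slope"]})
    table = pd.DataFrame(rows)
    out = {"table": table, "tests": {}}
    if len(reports) >= 2:
        for metric in ("descent_point", "slope"):
            groups = {
                cond: g[metric].dropna().to_numpy()
                for cond, g in table.groupby("condition")
            }
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) >= 2:
                out["tests"][metric] = compare_groups(groups, alpha=alpha)
    return out
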