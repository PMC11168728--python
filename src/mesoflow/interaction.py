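"""Cluster-level information flow.

The interaction measure I_ij sums the transfer entropy over every ordered
node pair from cluster C_i to cluster C_j and normalizes by the source
cluster's size (rho = 1/|C_i|), so heterogeneous cluster sizes do not
distort the comparison.  I is exactly the node out-strength computed on the
cluster-renormalized graph: collapse each cluster to one node whose edge to
another cluster carries the size-normalized sum of the underlying TE
weights.  The values and directions of I place each cluster in the
network's communication hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CLUSTER_LABELS, ClusterAssignment
from .te import TEMatrix

__all__ = ["InteractionMatrix", "interaction_matrix", "session_average_interactions"]


@dataclass
class InteractionMatrix:
    """M x M cluster-interaction values (nats, source clusters on rows).

    Entries whose source or target cluster is empty are undefined (NaN),
    not zero: an absent cluster is not a zero-flow cluster.
    """

    values: np.ndarray
    cluster_sizes: dict[str, int]
    labels: tuple[str, ...] = CLUSTER_LABELS
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def dominant_direction(self, a: str, b: str) -> str:
        """Which of I_ab / I_ba dominates (hierarchy read-out)."""
        ia, ib = self.labels.index(a), self.labels.index(b)
        return a if self.values[ia, ib] >= self.values[ib, ia] else b


def interaction_matrix(te: TEMatrix | np.ndarray,
                       clusters: ClusterAssignment,
                       condition: str = "") -> InteractionMatrix:
    """I_ij = (1/|C_i|) sum_{m in C_i} sum_{n in C_j} TE(m -> n).

    Self-pairs never contribute (the TE diagonal is zero by construction);
    the within-cluster diagonal entries I_ii are computed and reported.
    """
    values = te.values if isinstance(te, TEMatrix) else np.asarray(te, dtype=float)
    n = values.shape[0]
    members = {lab: sorted(clusters.nodes(lab)) for lab in CLUSTER_LABELS}
    covered = sorted(set().union(*members.values()))
    if covered != list(range(n)):
        raise ValueError("clusters must partition the node set of the TE matrix")
    m = len(CLUSTER_LABELS)
    out = np.full((m, m), np.nan)
    for i, lab_i in enumerate(CLUSTER_LABELS):
        ci = members[lab_i]
        if not ci:
            continue
        for j, lab_j in enumerate(CLUSTER_LABELS):
            cj = members[lab_j]
            if not cj:
                continue
            out[i, j] = values[np.ix_(ci, cj)].sum() / len(ci)
    return InteractionMatrix(
        values=out,
        cluster_sizes={lab: len(members[lab]) for lab in CLUSTER_LABELS},
        condition=condition,
    )


def session_average_interactions(
    matrices: list[InteractionMatrix],
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Element-wise mean and SEM over sessions (SEM absent for one session)."""
    if not matrices:
        raise ValueError("no interaction matrices given")
    labels = matrices[0].labels
    if any(m.labels != labels for m in matrices):
        raise ValueError("inconsistent cluster label conventions across sessions")
    stack = np.stack([m.values for m in matrices])
    mean = pd.DataFrame(np.nanmean(stack, axis=0), index=list(labels),
                        columns=list(labels))
    if len(matrices) < 2:
        return mean, None
    n_eff = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(n_eff)
        sem[n_eff < 2] = np.nan
    return mean, pd.DataFrame(sem, index=list(labels), columns=list(labels))
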