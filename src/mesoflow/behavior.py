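"""Race-model behavioral analysis of stop-signal sessions.

The stop-signal paradigm is modelled as a race between a GO process
(duration = the reaction time) and a STOP process (duration = the stop-signal
reaction time, SSRT) started at the stop-signal delay (SSD).  The SSRT is
latent; the integration method recovers it from the probability of
responding at a given SSD: the nth fastest Go RT, with n = p(response) x
(number of Go trials), marks the finishing time the STOP process must beat,
so SSRT = nth Go RT - SSD.  The race assumption (same GO process in Go and
Stop trials) predicts that wrong-Stop RTs are stochastically faster than Go
RTs, because responses in Stop trials are the censored fast tail of the GO
finish-time distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger("mesoflow.behavior")

__all__ = [
    "BehavioralSession",
    "SSRTEstimate",
    "RaceCheck",
    "estimate_ssrt_integration",
    "check_race_assumption",
    "summarize_session",
    "RaceModel",
    "RaceModelResults",
]

REQUIRED_COLUMNS = ("trial_id", "type", "ssd_ms", "rt_ms", "outcome")


class BehavioralSession:
    """Per-trial records of one stop-signal session.

    Wraps a trial table with columns trial_id, type {go, stop}, ssd_ms
    (stop trials only), rt_ms (responded trials only) and outcome
    {go_correct, stop_correct, stop_wrong}.
    """

    def __init__(self, trials: pd.DataFrame):
        missing = set(REQUIRED_COLUMNS) - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        if len(trials) == 0:
            raise ValueError("empty session")
        trials = trials.copy()
        rts = trials["rt_ms"].dropna()
        if (rts <= 0).any():
            raise ValueError("reaction times must be > 0")
        stop = trials[trials["type"] == "stop"]
        if stop["ssd_ms"].isna().any():
            raise ValueError("every stop trial must carry an SSD")
        self.trials = trials

    @classmethod
    def from_csv(cls, path) -> "BehavioralSession":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    # -- derived views ---------------------------------------------------
    @property
    def go_rts(self) -> np.ndarray:
        m = (self.trials["type"] == "go") & self.trials["rt_ms"].notna()
        return np.sort(self.trials.loc[m, "rt_ms"].to_numpy(dtype=float))

    @property
    def wrong_stop_rts(self) -> np.ndarray:
        m = self.trials["outcome"] == "stop_wrong"
        return np.sort(self.trials.loc[m, "rt_ms"].to_numpy(dtype=float))

    def p_response_by_ssd(self) -> pd.DataFrame:
        """p(response | SSD) with stop-trial counts, one row per SSD."""
        stop = self.trials[self.trials["type"] == "stop"]
        if len(stop) == 0:
            return pd.DataFrame(columns=["ssd_ms", "n_stop", "p_response"])
        grp = stop.groupby("ssd_ms")["outcome"]
        tab = grp.agg(
            n_stop="size",
            p_response=lambda s: float(np.mean(s == "stop_wrong")),
        ).reset_index()
        return tab


@dataclass
class SSRTEstimate:
    """SSRT (ms) with the per-SSD breakdown of the integration method."""

    ssrt: float
    per_ssd: pd.DataFrame  # columns ssd_ms, n_stop, p_response, n_th, nth_go_rt, ssrt
    method: str = "integration-per-ssd"


@dataclass
class RaceCheck:
    """One-sided rank test that wrong-Stop RTs are faster than Go RTs."""

    status: str                 # "tested" | "untestable"
    passed: bool | None = None
    statistic: float | None = None
    p_value: float | None = None
    alpha: float = 0.05


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def estimate_ssrt_integration(
    session: BehavioralSession,
    method: str = "per-ssd",
) -> SSRTEstimate:
    """SSRT by the integration method.

    For each SSD with 0 < p(response) < 1: n = round(p_response x number of
    Go RTs), clamped to [1, count]; the nth smallest Go RT minus the SSD is
    that SSD's estimate.  The overall SSRT is the stop-trial-count-weighted
    mean over SSDs ("per-ssd", default, unbiased under the uneven SSD
    sampling a staircase produces) or the single estimate from the overall
    response rate and the mean SSD ("mean-ssd").

    SSDs at which p(response) is exactly 0 or 1 carry no timing information
    and are excluded with a warning.
    """
    go_rts = session.go_rts
    if len(go_rts) < 20:
        raise ValueError("at least 20 Go RTs are required")
    tab = session.p_response_by_ssd()
    informative = tab[(tab["p_response"] > 0) & (tab["p_response"] < 1)]
    dropped = len(tab) - len(informative)
    if dropped:
        logger.warning(
            "excluded %d SSD level(s) with p_response in {0, 1}", dropped)
    if len(informative) == 0:
        raise ValueError("no SSD with 0 < p(response) < 1; SSRT not estimable")

    n_go = len(go_rts)
    rows = []
    for _, row in informative.iterrows():
        n_th = min(max(_round_half_up(row["p_response"] * n_go), 1), n_go)
        nth_rt = go_rts[n_th - 1]
        rows.append({
            "ssd_ms": row["ssd_ms"], "n_stop": int(row["n_stop"]),
            "p_response": row["p_response"], "n_th": n_th,
            "nth_go_rt": nth_rt, "ssrt": nth_rt - row["ssd_ms"],
        })
    per_ssd = pd.DataFrame(rows)

    if method == "per-ssd":
        w = per_ssd["n_stop"].to_numpy(float)
        ssrt = float(np.average(per_ssd["ssrt"], weights=w))
        tag = "integration-per-ssd"
    elif method == "mean-ssd":
        stop = session.trials[session.trials["type"] == "stop"]
        p_overall = float((stop["outcome"] == "stop_wrong").mean())
        n_th = min(max(_round_half_up(p_overall * n_go), 1), n_go)
        ssrt = float(go_rts[n_th - 1] - stop["ssd_ms"].mean())
        tag = "integration-mean-ssd"
    else:
        raise ValueError("method must be 'per-ssd' or 'mean-ssd'")
    return SSRTEstimate(ssrt=ssrt, per_ssd=per_ssd, method=tag)


def check_race_assumption(session: BehavioralSession, alpha: float = 0.05) -> RaceCheck:
    """Mann-Whitney one-sided test: wrong-Stop RTs < Go RTs."""
    wrong = session.wrong_stop_rts
    go = session.go_rts
    if len(wrong) < 10 or len(go) < 10:
        return RaceCheck(status="untestable", alpha=alpha)
    stat, p = mannwhitneyu(wrong, go, alternative="less")
    return RaceCheck(status="tested", passed=bool(p < alpha),
                     statistic=float(stat), p_value=float(p), alpha=alpha)


def summarize_session(session: BehavioralSession) -> dict:
    """Counts, RT moments, stop fraction and (when estimable) the SSRT."""
    t = session.trials
    go_rts = session.go_rts
    out = {
        "n_trials": int(len(t)),
        "n_go": int((t["type"] == "go").sum()),
        "n_stop": int((t["type"] == "stop").sum()),
        "stop_fraction": float((t["type"] == "stop").mean()),
        "go_rt_mean": float(go_rts.mean()) if len(go_rts) else None,
        "go_rt_sd": float(go_rts.std(ddof=1)) if len(go_rts) > 1 else None,
        "n_correct_stop": int((t["outcome"] == "stop_correct").sum()),
        "n_wrong_stop": int((t["outcome"] == "stop_wrong").sum()),
        "ssrt": None,
    }
    try:
        out["ssrt"] = estimate_ssrt_integration(session).ssrt
    except ValueError:
        pass
    return out


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class RaceModel:
    """Race-model analysis of one behavioral session.

    Accepts a :class:`BehavioralSession` or a raw trial DataFrame; ``fit``
    estimates the SSRT by the integration method, runs the race-assumption
    check and assembles the session summary into a results object.
    """

    def __init__(self, session: BehavioralSession | pd.DataFrame,
                 ssrt_method: str = "per-ssd", alpha: float = 0.05):
        if isinstance(session, pd.DataFrame):
            session = BehavioralSession(session)
        self.session = session
        self.ssrt_method = ssrt_method
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, **kw) -> "RaceModel":
        return cls(BehavioralSession(trials), **kw)

    def fit(self) -> "RaceModelResults":
        est = estimate_ssrt_integration(self.session, method=self.ssrt_method)
        race = check_race_assumption(self.session, alpha=self.alpha)
        summary = summarize_session(self.session)
        return RaceModelResults(model=self, ssrt_estimate=est,
                                race_check=race, session_summary=summary)


@dataclass
class RaceModelResults:
    model: RaceModel
    ssrt_estimate: SSRTEstimate
    race_check: RaceCheck
    session_summary: dict = field(default_factory=dict)

    @property
    def ssrt(self) -> float:
        return self.ssrt_estimate.ssrt

    def summary(self) -> str:
        s = self.session_summary
        lines = [
            "Race-model session results",
            "=" * 44,
            f"trials            {s['n_trials']:>8d}  (go {s['n_go']}, stop {s['n_stop']})",
            f"stop fraction     {s['stop_fraction']:>8.3f}",
            f"go RT mean (SD)   {s['go_rt_mean']:>8.1f}  ({s['go_rt_sd']:.1f}) ms",
            f"correct stops     {s['n_correct_stop']:>8d}",
            f"wrong stops       {s['n_wrong_stop']:>8d}",
            f"SSRT ({self.ssrt_estimate.method})  {self.ssrt:>8.1f} ms",
        ]
        rc = self.race_check
        if rc.status == "tested":
            verdict = "satisfied" if rc.passed else "VIOLATED"
            lines.append(
                f"race assumption   {verdict} (wrong-stop < go, p = {rc.p_value:.2e})")
        else:
            lines.append("race assumption   untestable (too few trials)")
        return "\n".join(lines)
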