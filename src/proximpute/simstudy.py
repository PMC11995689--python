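"""Replication engine and metric calculators for the simulation studies.

A scenario is one parameter setting (sample size, error law, queried
proportion, ...).  Each replicate generates a fresh two-phase dataset and
runs the gold-standard, naive, complete-case and imputation analyses; the
log-prevalence-ratio estimates are aggregated into the study metrics:

* Bias — empirical relative bias of beta1-hat (absolute bias at the null,
  where relative bias is undefined);
* ESE  — empirical standard deviation of beta1-hat;
* ASE  — average of the estimated standard errors (reported for the
  imputation estimator, whose variance estimator is under scrutiny);
* CP   — empirical coverage of the 95% confidence interval;
* RE   — relative efficiency, var(gold) / var(estimator).

Replicates are seeded by child seeds spawned deterministically from the
master seed, so results are independent of execution order and can be
parallelized reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mi import METHODS, run_analysis
from .synth import SimConfig, simulate_dataset

__all__ = [
    "SimMetrics",
    "ReplicateRecord",
    "run_scenario",
    "metric_bias",
    "metric_ese",
    "metric_ase",
    "metric_cp",
    "metric_re",
    "emit_table",
]


def metric_bias(estimates: Sequence[float], truth: float) -> float:
    """Empirical bias: relative when truth != 0, absolute at the null."""
    est = np.asarray(estimates, float)
    if len(est) < 2:
        raise ValueError("need at least two estimates")
    raw = est.mean() - truth
    return float(raw / truth) if truth != 0 else float(raw)


def metric_ese(estimates: Sequence[float]) -> float:
    """Empirical standard error: sample SD of the estimates."""
    return float(np.std(np.asarray(estimates, float), ddof=1))


def metric_ase(ses: Sequence[float]) -> float:
    """Average of the per-replicate standard error estimates."""
    return float(np.mean(np.asarray(ses, float)))


def metric_cp(ci_list: Sequence[tuple[float, float]], truth: float) -> float:
    """Fraction of confidence intervals containing the truth."""
    if len(ci_list) == 0:
        raise ValueError("no intervals given")
    hits = 0
    for lo, hi in ci_list:
        if lo > hi:
            raise ValueError(f"malformed interval ({lo}, {hi})")
        hits += lo <= truth <= hi
    return hits / len(ci_list)


def metric_re(gold_estimates: Sequence[float], other_estimates: Sequence[float]) -> float:
    """Relative efficiency: var(gold) / var(other)."""
    g = np.asarray(gold_estimates, float)
    o = np.asarray(other_estimates, float)
    if len(g) < 2 or len(o) < 2:
        raise ValueError("need at least two estimates per method")
    vo = np.var(o, ddof=1)
    if vo == 0:
        raise ValueError("zero variance in the comparison estimator")
    return float(np.var(g, ddof=1) / vo)


@dataclass
class ReplicateRecord:
    """beta1-hat, its SE and CI, per method, for one replicate."""

    estimates: dict
    ses: dict
    cis: dict


@dataclass
class SimMetrics:
    """Aggregated metrics for one scenario."""

    config: SimConfig
    methods: tuple[str, ...]
    bias: dict
    ese: dict
    ase: dict
    cp: dict
    re: dict
    replicates_used: int
    replicates_failed: int
    raw: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        row: dict = {
            "n": self.config.n,
            "error_kind": self.config.error_kind,
            "sigma": (
                self.config.sigma_u
                if self.config.error_kind == "additive"
                else self.config.sigma_w
            ),
            "q": self.config.q,
            "beta0": self.config.beta0,
            "beta1": self.config.beta1,
            "replicates": self.replicates_used,
        }
        for m in self.methods:
            row[f"bias_{m}"] = self.bias[m]
            row[f"ese_{m}"] = self.ese[m]
            if m in ("complete_case", "imputation"):
                row[f"re_{m}"] = self.re.get(m, np.nan)
            if m == "imputation":
                row["ase_imputation"] = self.ase.get(m, np.nan)
                row["cp_imputation"] = self.cp.get(m, np.nan)
        return row


def _run_replicate(
    config: SimConfig, seed_seq: np.random.SeedSequence, methods: Sequence[str]
) -> ReplicateRecord:
    rng = np.random.default_rng(seed_seq)
    df = simulate_dataset(config, rng)
    est, ses, cis = {}, {}, {}
    for m in methods:
        res = run_analysis(df, m, b=config.b, rng=rng)
        est[m] = res.beta1
        ses[m] = res.beta1_se
        cis[m] = res.beta1_ci()
    return ReplicateRecord(est, ses, cis)


def run_scenario(
    config: SimConfig,
    methods: Sequence[str] = METHODS,
    max_failure_fraction: float = 0.01,
) -> SimMetrics:
    """Run a full scenario and aggregate its metrics.

    Replicates that fail to converge are excluded and counted; the
    scenario errors if they exceed ``max_failure_fraction``.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.replicates)
    records: list[ReplicateRecord] = []
    failures = 0
    for child in children:
        try:
            records.append(_run_replicate(config, child, methods))
        except (RuntimeError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failure_fraction * config.replicates:
        raise RuntimeError(
            f"{failures}/{config.replicates} replicates failed to converge"
        )

    raw = pd.DataFrame(
        {
            **{f"est_{m}": [r.estimates[m] for r in records] for m in methods},
            **{f"se_{m}": [r.ses[m] for r in records] for m in methods},
        }
    )
    truth = config.beta1
    bias = {m: metric_bias(raw[f"est_{m}"], truth) for m in methods}
    ese = {m: metric_ese(raw[f"est_{m}"]) for m in methods}
    ase = {m: metric_ase(raw[f"se_{m}"]) for m in methods}
    cp = {
        m: metric_cp([r.cis[m] for r in records], truth)
        for m in methods
    }
    re = {}
    if "gold" in methods:
        for m in methods:
            re[m] = metric_re(raw["est_gold"], raw[f"est_{m}"])
    return SimMetrics(
        config=config,
        methods=tuple(methods),
        bias=bias,
        ese=ese,
        ase=ase,
        cp=cp,
        re=re,
        replicates_used=len(records),
        replicates_failed=failures,
        raw=raw,
    )


def emit_table(metrics_list: Sequence[SimMetrics], decimals: int = 3) -> pd.DataFrame:
    """Scenario grid as a table in the standard column order.

    Columns follow the published layout: per-method Bias and ESE (gold,
    naive, complete case, imputation), RE for complete case, then ASE, CP
    and RE for imputation.  Values are rounded half-to-even to
    ``decimals`` places.
    """
    order = [
        "n", "error_kind", "sigma", "q", "beta0", "beta1", "replicates",
        "bias_gold", "ese_gold",
        "bias_naive", "ese_naive",
        "bias_complete_case", "ese_complete_case", "re_complete_case",
        "bias_imputation", "ese_imputation", "ase_imputation",
        "cp_imputation", "re_imputation",
    ]
    rows = [m.to_row() for m in metrics_list]
    frame = pd.DataFrame(rows)
    cols = [c for c in order if c in frame.columns]
    frame = frame[cols + [c for c in frame.columns if c not in cols]]
    num = frame.select_dtypes(include=[np.number]).columns
    frame[num] = frame[num].round(decimals)
    return frame
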