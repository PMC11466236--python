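"""Non-parametric bootstrap for edge-weight accuracy.

Subjects are resampled with replacement to the original n; the full
network fit is repeated per replicate (re-selecting the penalty by CV
when ``refit_lambda``, or holding it at the full-sample selection for
speed) and percentile confidence intervals are formed from the replicate
edge-weight distribution.  Replicate seeds are spawned from the master
seed, so the whole replicate stream is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateColumnError, InputError, ValidationError
from .estimator import EstimationConfig, fit_network_matrices
from .panel import PanelDataset

#: a bootstrap run aborts when more than this fraction of replicates fail
MAX_FAILURE_RATE = 0.05


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: 1,000 iterations and 95% percentile intervals
    by default; ``refit_lambda`` re-runs CV penalty selection inside each
    replicate (set False to hold the full-sample penalties fixed)."""

    n_iterations: int = 1000
    ci_level: float = 0.95
    master_seed: int = 0
    refit_lambda: bool = True

    def __post_init__(self):
        if self.n_iterations < 2:
            raise ValidationError("n_iterations must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")


@dataclass
class EdgeCITable:
    """Percentile CIs for all n^2 directed edge weights.

    ``replicates`` holds the retained replicate weight matrices
    (n_ok x n_nodes x n_nodes) so intervals at other coverage levels can
    be recomputed without refitting.
    """

    estimate: np.ndarray      # full-sample point estimates (n x n)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    prop_nonzero: np.ndarray
    node_ids: list[str]
    ci_level: float
    n_failed: int
    replicates: np.ndarray | None = None
    run_log: pd.DataFrame | None = None  # per-replicate seed + status

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ids = self.node_ids
        for i, src in enumerate(ids):
            for j, dst in enumerate(ids):
                rows.append(
                    {
                        "from": src,
                        "to": dst,
                        "estimate": float(self.estimate[i, j]),
                        "ci_lower": float(self.ci_lower[i, j]),
                        "ci_upper": float(self.ci_upper[i, j]),
                        "prop_nonzero": float(self.prop_nonzero[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def percentile_interval(draws: np.ndarray, level: float, axis: int = 0):
    """Percentile CI whose endpoints are order statistics of the draws.

    With B draws and alpha = 1 - level, the lower endpoint is the
    k-th order statistic with k = ceil(B * alpha/2) (at least 1) and the
    upper endpoint the (B - k + 1)-th: the symmetric percentile
    convention.  Both endpoints are actual replicate values and the
    interval widens monotonically with the coverage level.
    """
    draws = np.asarray(draws, dtype=float)
    B = draws.shape[axis]
    alpha = 1.0 - level
    # round before ceil so exact integer positions are not bumped up by
    # binary floating-point representation of alpha/2
    k = max(int(np.ceil(np.round(alpha / 2 * B, 10))), 1)
    srt = np.sort(draws, axis=axis)
    lo = np.take(srt, k - 1, axis=axis)
    hi = np.take(srt, B - k, axis=axis)
    return lo, hi


def bootstrap_edge_cis(
    data: PanelDataset,
    est_config: EstimationConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    group_filter: int | None = None,
    keep_replicates: bool = True,
) -> EdgeCITable:
    """Edge-weight percentile CIs by subject resampling.

    Failed replicates (e.g. a zero-variance column in a degenerate
    resample) are dropped and counted, never silently ignored; the run
    aborts if more than 5% fail.
    """
    est_config = est_config or EstimationConfig()
    boot_config = boot_config or BootstrapConfig()

    if group_filter is None:
        analysis = data.analysis_set()
        covs = pd.DataFrame({"gender": analysis.gender.astype(float)})
    else:
        analysis = data.subset_by_gender(group_filter)
        covs = None
    n = analysis.n_subjects
    if n < 10:
        raise InputError(f"analysis set too small to bootstrap (n={n})")
    return bootstrap_network_matrices(
        analysis.scores(1),
        analysis.scores(2),
        data.catalog,
        covariates=covs,
        est_config=est_config,
        boot_config=boot_config,
        keep_replicates=keep_replicates,
    )


def bootstrap_network_matrices(
    t1: np.ndarray,
    t2: np.ndarray,
    catalog,
    covariates: pd.DataFrame | None = None,
    est_config: EstimationConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    keep_replicates: bool = True,
) -> EdgeCITable:
    """Array-level bootstrap (see :func:`bootstrap_edge_cis`)."""
    est_config = est_config or EstimationConfig()
    boot_config = boot_config or BootstrapConfig()
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n = t1.shape[0]
    covs = covariates

    full = fit_network_matrices(t1, t2, catalog, covariates=covs, config=est_config)
    fixed_lambdas = None if boot_config.refit_lambda else full.lambda_selected

    seeds = np.random.SeedSequence(boot_config.master_seed).spawn(
        boot_config.n_iterations
    )
    p = len(catalog)
    draws = np.empty((boot_config.n_iterations, p, p))
    ok = np.zeros(boot_config.n_iterations, dtype=bool)
    for b, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        try:
            net = fit_network_matrices(
                t1[idx],
                t2[idx],
                catalog,
                covariates=None if covs is None else covs.iloc[idx].reset_index(drop=True),
                config=est_config,
                lambdas=fixed_lambdas,
            )
        except DegenerateColumnError as exc:
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
            continue
        draws[b] = net.W
        ok[b] = True

    n_failed = int((~ok).sum())
    if n_failed > MAX_FAILURE_RATE * boot_config.n_iterations:
        raise InputError(
            f"{n_failed}/{boot_config.n_iterations} bootstrap replicates failed"
        )
    kept = draws[ok]
    lo, hi = percentile_interval(kept, boot_config.ci_level, axis=0)
    run_log = pd.DataFrame(
        {
            "replicate": np.arange(boot_config.n_iterations),
            "seed_entropy": [str(s.entropy) for s in seeds],
            "spawn_key": [s.spawn_key[-1] for s in seeds],
            "status": np.where(ok, "ok", "failed"),
        }
    )
    return EdgeCITable(
        estimate=full.W,
        ci_lower=lo,
        ci_upper=hi,
        prop_nonzero=(kept != 0).mean(axis=0),
        node_ids=catalog.node_ids,
        ci_level=boot_config.ci_level,
        n_failed=n_failed,
        replicates=kept if keep_replicates else None,
        run_log=run_log,
    )


def reinterval(table: EdgeCITable, level: float) -> EdgeCITable:
    """Recompute the CIs of an existing table at another coverage level
    (requires kept replicates)."""
    if table.replicates is None:
        raise InputError("table was built without kept replicates")
    if not 0 < level < 1:
        raise InputError("level must be in (0, 1)")
    lo, hi = percentile_interval(table.replicates, level, axis=0)
    return EdgeCITable(
        estimate=table.estimate,
        ci_lower=lo,
        ci_upper=hi,
        prop_nonzero=table.prop_nonzero,
        node_ids=table.node_ids,
        ci_level=level,
        n_failed=table.n_failed,
        replicates=table.replicates,
        run_log=table.run_log,
    )


def edge_stability_report(
    table: EdgeCITable, min_nonzero_prop: float = 0.5
) -> pd.DataFrame:
    """Edges whose nonzero-replicate proportion meets the threshold,
    sorted by |point estimate| descending."""
    if not 0 <= min_nonzero_prop <= 1:
        raise InputError("min_nonzero_prop must be in [0, 1]")
    df = table.to_frame()
    kept = df[df["prop_nonzero"] >= min_nonzero_prop].copy()
    kept["abs_est"] = kept["estimate"].abs()
    kept = kept.sort_values(
        by=["abs_est", "from", "to"], ascending=[False, True, True]
    ).drop(columns="abs_est")
    return kept.reset_index(drop=True)
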