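"""Synthetic two-wave ordinal symptom panels with known cross-lagged truth.

Generative model
----------------
Wave-1 latent scores are multivariate standard normal with a
block-structured correlation matrix over the three symptom communities
and are discretized to the 0-4 ordinal scale through per-node strictly
increasing cut-points.  Wave-2 latents follow the linear cross-lagged
structure

    eta2 = B' s1 + eps,   eps ~ N(0, noise_sd^2 I)

where ``B[i, j]`` is the effect of T1 node *i* on T2 node *j* (diagonal =
autoregressive paths) and ``s1`` is the wave-1 predictor vector on the
drive scale, then are discretized the same way.  Zero inflation of the
NSSI items is produced by a high first cut-point, calibrated so that the
wave-1 "any NSSI behaviour" prevalence matches the 23.3% observed in the
adolescent sample the generator emulates.

Two drive scales are supported.  The default, ``"observed"``, takes
``s1`` to be the z-scored wave-1 *ordinal* scores — the scale on which
the network estimator operates — so the ground-truth weights are the
estimands of the fitted cross-lagged regressions and parameter recovery
is well defined.  ``"latent"`` drives wave 2 from the wave-1 latents
directly; there the mapping from ground truth to observed-scale edge
weights is attenuated by the discretization (strongly so for the
zero-inflated NSSI items), which makes that mode useful for structural
checks but not for weight recovery.

Randomness: per-stage child streams (group assignment, wave-1 latents,
wave-2 noise) are spawned from a master ``numpy.random.SeedSequence`` so
each stage is independently reproducible from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import integrate, optimize, stats

from .catalog import ANX, DEP, NSSI, SymptomCatalog, default_catalog
from .errors import InputError, ParameterError
from .panel import GENDER_BOY, GENDER_GIRL, PanelDataset

# ---------------------------------------------------------------------------
# defaults of the generative model (study-design constants)
# ---------------------------------------------------------------------------

#: wave-1 latent correlations: within NSSI, within DEP, within ANX,
#: between DEP and ANX, and between NSSI and the affect communities.
DEFAULT_CORR = {
    (NSSI, NSSI): 0.4,
    (DEP, DEP): 0.5,
    (ANX, ANX): 0.5,
    (DEP, ANX): 0.3,
    (NSSI, DEP): 0.15,
    (NSSI, ANX): 0.15,
}

#: target proportion of subjects with >=1 nonzero NSSI item at wave 1
DEFAULT_ANY_NSSI_PREVALENCE = 0.233

#: cut-points for the 0-4 scale on depression/anxiety latents
AFFECT_THRESHOLDS = (0.2, 1.0, 1.7, 2.4)

#: spacing of the upper NSSI cut-points above the calibrated first one
NSSI_THRESHOLD_STEP = 0.6

DEFAULT_NOISE_SD = 1.0

#: group sizes of the emulated two-school cohort (boys:girls)
DEFAULT_GROUP_MIX = {"boys": 403 / 884, "girls": 481 / 884}

#: autoregressive path strength per group (mean reported value)
DEFAULT_AUTOREGRESSIVE = {"boys": 0.12, "girls": 0.17}

#: nonzero cross-lagged ground-truth edges per group, (from, to): beta
DEFAULT_CROSS_EDGES = {
    "boys": {
        ("N9", "D2"): -0.57,
        ("N9", "A6"): -0.52,
        ("N9", "D1"): -0.49,
        ("A6", "D2"): 0.23,
        ("A4", "D6"): 0.14,
    },
    "girls": {
        ("A4", "D1"): 0.16,
        ("A4", "D4"): 0.14,
        ("A4", "D6"): 0.14,
        ("N12", "D1"): -0.31,
        ("N11", "D1"): -0.21,
    },
}


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Generative parameters for one subject group.

    B
        n_nodes x n_nodes weight matrix on the standardized latent scale;
        ``B[i, j]`` = effect of T1 node i on T2 node j, diagonal =
        autoregressive paths.
    t1_latent_corr
        Wave-1 latent correlation matrix (symmetric positive definite,
        unit diagonal).
    thresholds
        Per-node strictly increasing cut-points (n_nodes x scale_max);
        ordinal score = number of cut-points below the latent value.
    noise_sd
        Residual standard deviation of the wave-2 latents.
    """

    B: np.ndarray
    t1_latent_corr: np.ndarray
    thresholds: np.ndarray
    noise_sd: float = DEFAULT_NOISE_SD

    def validate(self, n_nodes: int, scale_max: int = 4) -> None:
        B = np.asarray(self.B, dtype=float)
        if B.shape != (n_nodes, n_nodes) or not np.all(np.isfinite(B)):
            raise ParameterError("B must be a finite n_nodes x n_nodes matrix")
        C = np.asarray(self.t1_latent_corr, dtype=float)
        if C.shape != (n_nodes, n_nodes):
            raise ParameterError("t1_latent_corr has wrong shape")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ParameterError("t1_latent_corr must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("t1_latent_corr is not positive definite") from exc
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.shape != (n_nodes, scale_max):
            raise ParameterError(
                f"thresholds must be n_nodes x {scale_max} (one per scale step)"
            )
        if not np.all(np.diff(thr, axis=1) > 0):
            raise ParameterError("thresholds must be strictly increasing per node")
        if not self.noise_sd > 0:
            raise ParameterError("noise_sd must be positive")


@dataclass
class GroundTruthSpec:
    """Complete generative specification: catalog, per-group parameters,
    group mixing proportions."""

    catalog: SymptomCatalog
    groups: dict[str, GroupParams]
    group_mix: dict[str, float]
    drive_scale: str = "observed"

    def validate(self) -> None:
        p = len(self.catalog)
        if self.drive_scale not in ("observed", "latent"):
            raise ParameterError("drive_scale must be 'observed' or 'latent'")
        if set(self.groups) != set(self.group_mix):
            raise ParameterError("groups and group_mix must list the same labels")
        if not np.isclose(sum(self.group_mix.values()), 1.0):
            raise ParameterError("group_mix must sum to 1")
        scale_max = self.catalog.nodes[0].scale_max
        for g in self.groups.values():
            g.validate(p, scale_max)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "catalog": self.catalog.to_records(),
            "group_mix": self.group_mix,
            "drive_scale": self.drive_scale,
            "groups": {
                label: {
                    "B": g.B.tolist(),
                    "t1_latent_corr": g.t1_latent_corr.tolist(),
                    "thresholds": g.thresholds.tolist(),
                    "noise_sd": g.noise_sd,
                }
                for label, g in self.groups.items()
            },
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthSpec":
        spec = cls(
            catalog=SymptomCatalog.from_records(d["catalog"]),
            group_mix={k: float(v) for k, v in d["group_mix"].items()},
            drive_scale=d.get("drive_scale", "observed"),
            groups={
                label: GroupParams(
                    B=np.asarray(g["B"], dtype=float),
                    t1_latent_corr=np.asarray(g["t1_latent_corr"], dtype=float),
                    thresholds=np.asarray(g["thresholds"], dtype=float),
                    noise_sd=float(g["noise_sd"]),
                )
                for label, g in d["groups"].items()
            },
        )
        spec.validate()
        return spec

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulationResult:
    data: PanelDataset
    truth: GroundTruthSpec
    group_assignment: list[str]
    seed: int


# ---------------------------------------------------------------------------
# default ground truth
# ---------------------------------------------------------------------------

def block_correlation(catalog: SymptomCatalog, corr: dict | None = None) -> np.ndarray:
    """Community-block correlation matrix with unit diagonal."""
    corr = dict(DEFAULT_CORR if corr is None else corr)
    comms = catalog.communities
    p = len(catalog)
    C = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            key = (comms[i], comms[j])
            rho = corr.get(key, corr.get((key[1], key[0]), 0.0))
            C[i, j] = C[j, i] = rho
    return C


@lru_cache(maxsize=8)
def calibrate_nssi_threshold(
    n_items: int = 12,
    rho: float = 0.4,
    prevalence: float = DEFAULT_ANY_NSSI_PREVALENCE,
) -> float:
    """First NSSI cut-point t such that P(max of ``n_items`` equicorrelated
    standard normals > t) equals the target any-NSSI prevalence.

    Uses the one-factor representation of the equicorrelated normal:
    P(all <= t) = E_Z[ Phi((t - sqrt(rho) Z)/sqrt(1-rho))^k ].
    """
    if not 0 < prevalence < 1:
        raise ParameterError("prevalence must be in (0, 1)")

    def p_none(t: float) -> float:
        f = lambda z: stats.norm.pdf(z) * stats.norm.cdf(
            (t - np.sqrt(rho) * z) / np.sqrt(1.0 - rho)
        ) ** n_items
        return integrate.quad(f, -8.0, 8.0)[0]

    return float(optimize.brentq(lambda t: p_none(t) - (1.0 - prevalence), 0.0, 6.0))


def default_thresholds(catalog: SymptomCatalog) -> np.ndarray:
    """Per-node cut-points: calibrated zero-inflating first cut-point for
    NSSI items, moderate cut-points for the affect items."""
    n_nssi = len(catalog.members(NSSI))
    t0 = calibrate_nssi_threshold(n_items=n_nssi, rho=DEFAULT_CORR[(NSSI, NSSI)])
    scale_max = catalog.nodes[0].scale_max
    nssi_thr = t0 + NSSI_THRESHOLD_STEP * np.arange(scale_max)
    affect_thr = np.asarray(AFFECT_THRESHOLDS[:scale_max], dtype=float)
    thr = np.empty((len(catalog), scale_max))
    for i, node in enumerate(catalog):
        thr[i] = nssi_thr if node.community == NSSI else affect_thr
    return thr


def default_ground_truth(catalog: SymptomCatalog | None = None) -> GroundTruthSpec:
    """Two-group (boys/girls) ground truth seeded with the reported
    cross-lagged edge weights; all unlisted cross-lagged entries are 0."""
    catalog = catalog or default_catalog()
    p = len(catalog)
    corr = block_correlation(catalog)
    thresholds = default_thresholds(catalog)
    groups = {}
    for label in ("boys", "girls"):
        B = np.eye(p) * DEFAULT_AUTOREGRESSIVE[label]
        for (src, dst), beta in DEFAULT_CROSS_EDGES[label].items():
            B[catalog.index(src), catalog.index(dst)] = beta
        groups[label] = GroupParams(
            B=B,
            t1_latent_corr=corr.copy(),
            thresholds=thresholds.copy(),
            noise_sd=DEFAULT_NOISE_SD,
        )
    spec = GroundTruthSpec(catalog=catalog, groups=groups, group_mix=dict(DEFAULT_GROUP_MIX))
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_GROUP_GENDER = {"boys": GENDER_BOY, "girls": GENDER_GIRL}


def discretize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Ordinal score = number of cut-points strictly below the latent value."""
    return (latent[:, :, None] > thresholds[None, :, :]).sum(axis=2)


def simulate_panel(
    spec: GroundTruthSpec, n_subjects: int, seed: int
) -> SimulationResult:
    """Draw a two-wave ordinal panel from the generative model.

    Deterministic given ``(spec, n_subjects, seed)``: group assignment,
    wave-1 latents and wave-2 noise come from separate child streams of
    ``SeedSequence(seed)`` and subjects are processed in a fixed order.
    """
    if n_subjects < 2:
        raise InputError("n_subjects must be >= 2")
    spec.validate()
    p = len(spec.catalog)
    labels = sorted(spec.groups)  # fixed label order for reproducibility
    mix = np.array([spec.group_mix[l] for l in labels])

    ss = np.random.SeedSequence(seed)
    rng_group, rng_t1, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    group_idx = rng_group.choice(len(labels), size=n_subjects, p=mix)
    e1 = rng_t1.standard_normal((n_subjects, p))
    eps = rng_noise.standard_normal((n_subjects, p))

    t1_scores = np.empty((n_subjects, p), dtype=int)
    t2_scores = np.empty((n_subjects, p), dtype=int)
    for gi, label in enumerate(labels):
        rows = group_idx == gi
        if not rows.any():
            continue
        g = spec.groups[label]
        L = np.linalg.cholesky(g.t1_latent_corr)
        z1 = e1[rows] @ L.T  # wave-1 latents, standard scale
        s1_obs = discretize(z1, g.thresholds)
        t1_scores[rows] = s1_obs
        if spec.drive_scale == "observed":
            # z-score the ordinal scores within the group; a column the
            # group left constant (possible for rare NSSI items at small
            # n) falls back to its latent, which is already standard
            obs = s1_obs.astype(float)
            mu, sd = obs.mean(axis=0), obs.std(axis=0)
            s1 = np.where(sd > 0, (obs - mu) / np.where(sd > 0, sd, 1.0), z1)
        else:
            s1 = z1
        eta2 = s1 @ g.B + g.noise_sd * eps[rows]
        t2_scores[rows] = discretize(eta2, g.thresholds)

    import pandas as pd

    ids = [f"S{k + 1:05d}" for k in range(n_subjects)]
    assignment = [labels[i] for i in group_idx]
    gender = np.array([_GROUP_GENDER.get(a, gi) for a, gi in zip(assignment, group_idx)])
    data = PanelDataset(
        subject_ids=ids,
        gender=gender,
        t1=pd.DataFrame(t1_scores.astype(float), columns=spec.catalog.node_ids),
        t2=pd.DataFrame(t2_scores.astype(float), columns=spec.catalog.node_ids),
        catalog=spec.catalog,
    )
    return SimulationResult(data=data, truth=spec, group_assignment=assignment, seed=seed)


def simulate_linear_panel(
    B: np.ndarray,
    n_subjects: int,
    seed: int,
    t1_corr: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous linear-Gaussian two-wave panel with estimand exactly B.

    Wave 1 is multivariate normal with correlation ``t1_corr`` (identity
    by default); wave 2 is ``t2 = B' t1 + eps`` with per-column noise
    variance ``1 - var(B' t1)_j`` so every wave-2 column has unit
    variance and the standardized regression estimand equals ``B``.
    Used for calibration studies of the estimator and bootstrap where
    the target coefficients must be known exactly on the fitted scale.
    """
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    if B.shape != (p, p):
        raise ParameterError("B must be square")
    if n_subjects < 2:
        raise InputError("n_subjects must be >= 2")
    C = np.eye(p) if t1_corr is None else np.asarray(t1_corr, dtype=float)
    col_var = np.einsum("ij,ik,kj->j", B, C, B)
    if np.any(col_var >= 1.0):
        raise ParameterError(
            "B' t1 explains >= 100% of a wave-2 column's unit variance"
        )
    L = np.linalg.cholesky(C)
    ss = np.random.SeedSequence(seed)
    rng_t1, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    t1 = rng_t1.standard_normal((n_subjects, p)) @ L.T
    t2 = t1 @ B + rng_noise.standard_normal((n_subjects, p)) * np.sqrt(1.0 - col_var)
    return t1, t2


def nssi_prevalence(data: PanelDataset, wave: int = 1) -> float:
    """Fraction of analysis-set subjects with >=1 nonzero NSSI item."""
    analysis = data.analysis_set()
    if analysis.n_subjects == 0:
        raise InputError("empty analysis set")
    cols = [data.catalog.index(nid) for nid in data.catalog.members(NSSI)]
    if not cols:
        raise InputError("catalog has no NSSI community")
    scores = analysis.scores(wave)[:, cols]
    return float((scores > 0).any(axis=1).mean())
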