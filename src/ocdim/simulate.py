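"""Synthetic cohorts with a known bifactor/testlet symptom structure.

The generator stands in for the access-restricted clinical samples: it draws a
latent OCD propensity per person, domain-specific testlet effects that induce
extra within-domain dependence, a 64-item binary checklist bank spanning a
realistic range of discrimination and severity, and 10 correlated ordinal
clinician ratings under a graded response model. Every draw is recorded in a
truth object so downstream estimators can be tested for parameter recovery.

Response model for checklist item j in domain d(j):

    P(y_ij = 1) = logistic(D * a_j * (theta_i - b_j - gamma_{i,d(j)}))

with theta_i the general propensity, gamma_{i,d} ~ N(0, sigma_d^2) the testlet
effect (independent across domains), a_j > 0 the discrimination and b_j the
propensity level at which endorsement probability is 1/2. The equivalent
bifactor parameterization (orthogonal standard-normal general and specific
factors) is also exposed.

The default cohort mixes a diagnosed stratum (theta ~ N(0,1)) with an
undiagnosed-relative stratum whose propensity is shifted downward, producing
roughly a quarter of persons with symptom-free checklists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._quad import sigmoid
from .datasets import (
    DEFAULT_DOMAIN_SIZES,
    DOMAINS,
    AffectedFlags,
    DomainMap,
    ItemResponseMatrix,
    SeverityMatrix,
    SEVERITY_ITEM_IDS,
)

#: default testlet SDs; contamination and hoarding carry the strongest
#: domain-specific variance, the pattern reported for lifetime symptom data.
DEFAULT_TESTLET_SDS = {
    "doubt_checking": 0.5,
    "contamination": 1.0,
    "symmetry_ordering": 0.5,
    "hoarding": 1.0,
    "taboo": 0.5,
}

#: default severity-rating bank (10 clinician ratings, 0-4): discrimination
#: and four ordered thresholds per item, modelled on published calibrations of
#: the clinician severity scale (time/interference/distress highly
#: discriminating; resistance items least; thresholds rising steeply for the
#: time items).
DEFAULT_SEVERITY_A = np.array(
    [3.19, 2.60, 3.10, 1.59, 2.00, 2.94, 2.70, 2.90, 1.42, 1.90]
)
DEFAULT_SEVERITY_B = np.array(
    [
        [-0.52, 1.73, 3.20, 4.46],
        [-0.09, 1.02, 2.28, 3.92],
        [-0.30, 1.10, 2.40, 3.80],
        [-0.21, 0.59, 1.59, 2.15],
        [-0.40, 0.70, 1.80, 2.60],
        [-0.62, 2.01, 3.66, 5.25],
        [-0.16, 1.20, 2.56, 4.25],
        [-0.35, 1.05, 2.30, 3.70],
        [-0.53, 0.51, 1.50, 2.02],
        [-0.45, 0.65, 1.70, 2.40],
    ]
)


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_persons: int = 1000
    domain_sizes: dict = field(default_factory=lambda: dict(DEFAULT_DOMAIN_SIZES))
    a_range: tuple = (0.5, 3.0)
    b_range: tuple = (0.3, 2.7)
    testlet_sds: dict = field(default_factory=lambda: dict(DEFAULT_TESTLET_SDS))
    #: fraction of undiagnosed relatives and their downward propensity shift
    unaffected_fraction: float = 0.375
    unaffected_shift: float = 3.6
    severity_a: np.ndarray = field(default_factory=lambda: DEFAULT_SEVERITY_A.copy())
    severity_b: np.ndarray = field(default_factory=lambda: DEFAULT_SEVERITY_B.copy())
    #: correlation between checklist propensity and the severity trait
    latent_corr: float = 0.85
    #: fraction of administered severity rows lost at random
    severity_missing_rate: float = 0.02
    scale_D: float = 1.0  # logistic scaling constant; 1.702 for normal-ogive metric
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if not all(v > 0 for v in self.domain_sizes.values()):
            raise ValueError("domain sizes must be positive")
        for lo, hi in (self.a_range, self.b_range):
            if hi < lo:
                raise ValueError("parameter range upper bound below lower bound")
        if self.a_range[0] <= 0:
            raise ValueError("discrimination range must be positive")
        if any(s < 0 for s in self.testlet_sds.values()):
            raise ValueError("testlet SDs must be non-negative")
        if not -1.0 <= self.latent_corr <= 1.0:
            raise ValueError("latent_corr must lie in [-1, 1]")
        sb = np.asarray(self.severity_b, dtype=float)
        if np.any(np.diff(sb, axis=1) < 0):
            raise ValueError("severity thresholds must be ordered per item")
        if len(self.severity_a) != sb.shape[0]:
            raise ValueError("severity a/b size mismatch")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["severity_a"] = np.asarray(self.severity_a).tolist()
        d["severity_b"] = np.asarray(self.severity_b).tolist()
        d["a_range"] = list(self.a_range)
        d["b_range"] = list(self.b_range)
        return d


@dataclass
class TrueParams:
    """Ground truth for one synthetic cohort."""

    item_ids: list
    a: np.ndarray  # (J,) discrimination
    b: np.ndarray  # (J,) severity/difficulty
    item_domains: list  # (J,) domain label per item
    testlet_sd: dict  # domain -> sigma_d
    theta: np.ndarray | None = None  # (n,)
    gamma: np.ndarray | None = None  # (n, n_domains)
    affected: np.ndarray | None = None  # (n,) bool
    eta: np.ndarray | None = None  # (n,) severity trait
    person_ids: list | None = None
    severity_a: np.ndarray | None = None
    severity_b: np.ndarray | None = None
    config: SimConfig | None = None

    def domain_map(self, strict: bool = True) -> DomainMap:
        return DomainMap(dict(zip(self.item_ids, self.item_domains)), strict=strict)

    @property
    def domains(self) -> list:
        seen = []
        for d in self.item_domains:
            if d not in seen:
                seen.append(d)
        return seen

    def domain_index(self) -> np.ndarray:
        order = {d: k for k, d in enumerate(self.domains)}
        return np.array([order[d] for d in self.item_domains])

    def sigma_vector(self) -> np.ndarray:
        return np.array([self.testlet_sd[d] for d in self.domains])


def endorse_prob(a, b, gamma, theta, D: float = 1.0):
    """Testlet item response function P(y=1 | theta, gamma)."""
    a = np.asarray(a, dtype=float)
    return sigmoid(D * a * (np.asarray(theta, dtype=float) - b - gamma))


# ---------------------------------------------------------------------------
# draws


def draw_item_bank(config: SimConfig, rng: np.random.Generator) -> TrueParams:
    """Draw discrimination/severity uniformly on the configured ranges."""
    config.validate()
    domains, ids = [], []
    k = 1
    for d in DOMAINS:
        if d not in config.domain_sizes:
            continue
        for _ in range(config.domain_sizes[d]):
            ids.append(f"item{k:02d}")
            domains.append(d)
            k += 1
    j = len(ids)
    a = rng.uniform(config.a_range[0], config.a_range[1], size=j)
    b = rng.uniform(config.b_range[0], config.b_range[1], size=j)
    return TrueParams(
        item_ids=ids,
        a=a,
        b=b,
        item_domains=domains,
        testlet_sd={d: config.testlet_sds.get(d, 0.0) for d in dict.fromkeys(domains)},
        severity_a=np.asarray(config.severity_a, dtype=float),
        severity_b=np.asarray(config.severity_b, dtype=float),
        config=config,
    )


def draw_persons(
    params: TrueParams, config: SimConfig, rng: np.random.Generator
) -> TrueParams:
    """Draw person latents: propensity, testlet effects, severity trait, flags."""
    n = config.n_persons
    affected = rng.random(n) >= config.unaffected_fraction
    theta = rng.normal(0.0, 1.0, size=n)
    theta[~affected] -= config.unaffected_shift
    sig = params.sigma_vector()
    gamma = rng.normal(0.0, 1.0, size=(n, len(sig))) * sig[None, :]
    rho = config.latent_corr
    eta_core = rho * theta + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(
        0.0, 1.0, size=n
    )
    params.theta = theta
    params.gamma = gamma
    params.affected = affected
    params.eta = eta_core
    params.person_ids = [f"p{k:05d}" for k in range(1, n + 1)]
    return params


def simulate_testlet_responses(
    params: TrueParams, rng: np.random.Generator, D: float = 1.0
) -> ItemResponseMatrix:
    """Bernoulli checklist draws under the testlet response model."""
    if params.theta is None or params.gamma is None:
        raise ValueError("person latents not drawn; call draw_persons first")
    dj = params.domain_index()
    p = endorse_prob(
        params.a[None, :],
        params.b[None, :],
        params.gamma[:, dj],
        params.theta[:, None],
        D=D,
    )
    y = (rng.random(p.shape) < p).astype(float)
    return ItemResponseMatrix(list(params.person_ids), list(params.item_ids), y)


def simulate_bifactor_responses(
    a_general: np.ndarray,
    a_specific: np.ndarray,
    intercepts: np.ndarray,
    item_domain_index: np.ndarray,
    rng: np.random.Generator,
    n_persons: int | None = None,
    theta_general: np.ndarray | None = None,
    theta_specific: np.ndarray | None = None,
    item_ids: list | None = None,
    return_latents: bool = False,
):
    """Binary draws under an orthogonal bifactor model.

    P(y=1) = logistic(a0_j * theta0 + as_j * theta_{d(j)} + c_j) with theta0
    and each theta_d independent standard normal. Each item loads on exactly
    one specific dimension, given by ``item_domain_index``.
    """
    a_general = np.asarray(a_general, dtype=float)
    a_specific = np.asarray(a_specific, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    dj = np.asarray(item_domain_index)
    if dj.ndim != 1 or dj.shape != a_general.shape:
        raise ValueError("each item must map to exactly one specific dimension")
    n_dom = int(dj.max()) + 1
    if theta_general is None:
        if n_persons is None:
            raise ValueError("give n_persons or explicit latents")
        theta_general = rng.normal(size=n_persons)
        theta_specific = rng.normal(size=(n_persons, n_dom))
    n = len(theta_general)
    eta = (
        a_general[None, :] * np.asarray(theta_general)[:, None]
        + a_specific[None, :] * np.asarray(theta_specific)[:, dj]
        + intercepts[None, :]
    )
    y = (rng.random(eta.shape) < sigmoid(eta)).astype(float)
    ids = item_ids or [f"item{k:02d}" for k in range(1, len(a_general) + 1)]
    mat = ItemResponseMatrix([f"p{k:05d}" for k in range(1, n + 1)], ids, y)
    if return_latents:
        return mat, {"theta_general": theta_general, "theta_specific": theta_specific}
    return mat


def simulate_severity(
    params: TrueParams, rng: np.random.Generator, D: float = 1.0
) -> SeverityMatrix:
    """Ordinal 0-4 clinician ratings from a graded response model on eta."""
    if params.eta is None:
        raise ValueError("person latents not drawn; call draw_persons first")
    a = np.asarray(params.severity_a, dtype=float)
    bmat = np.asarray(params.severity_b, dtype=float)
    if np.any(np.diff(bmat, axis=1) < 0):
        raise ValueError("severity thresholds must be ordered")
    n, j = len(params.eta), len(a)
    # P(Y >= k) for k = 1..4, then draw from the category distribution
    cum = sigmoid(
        D * a[None, :, None] * (params.eta[:, None, None] - bmat[None, :, :])
    )  # (n, J, 4)
    upper = np.concatenate(
        [np.ones((n, j, 1)), cum, np.zeros((n, j, 1))], axis=2
    )  # P(Y>=0..5)
    probs = upper[:, :, :-1] - upper[:, :, 1:]  # (n, J, 5)
    u = rng.random((n, j, 1))
    y = (u > np.cumsum(probs, axis=2)).sum(axis=2).astype(float)
    return SeverityMatrix(list(params.person_ids), list(SEVERITY_ITEM_IDS)[:j], y)


def apply_severity_administration(
    sev: SeverityMatrix,
    resp: ItemResponseMatrix,
    affected: np.ndarray,
    rng: np.random.Generator,
    missing_rate: float = 0.02,
) -> SeverityMatrix:
    """Blank rows the clinic would not have rated.

    Undiagnosed persons with symptom-free checklists are not administered the
    severity interview (their rows later become zeros through the explicit
    zero-assignment rule); an additional random fraction of rows is lost, as
    happens in archival data.
    """
    values = sev.values.copy()
    zero_row = ~np.any(resp.values == 1.0, axis=1) & resp.observed_mask().all(axis=1)
    not_administered = (~affected) & zero_row
    lost = rng.random(len(values)) < missing_rate
    values[not_administered | lost, :] = np.nan
    return SeverityMatrix(list(sev.person_ids), list(sev.item_ids), values)


def simulate_cohort(config: SimConfig, seed: int | None = None):
    """Draw a complete cohort: truth, checklist, severity, flags."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    params = draw_item_bank(config, rng)
    draw_persons(params, config, rng)
    resp = simulate_testlet_responses(params, rng, D=config.scale_D)
    sev_full = simulate_severity(params, rng, D=config.scale_D)
    sev = apply_severity_administration(
        sev_full, resp, params.affected, rng, config.severity_missing_rate
    )
    flags = AffectedFlags(dict(zip(params.person_ids, params.affected)))
    return params, resp, sev, flags


def make_fixture(config: SimConfig, out_dir) -> tuple[dict, TrueParams]:
    """Write a complete synthetic study to ``out_dir``; returns paths + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params, resp, sev, flags = simulate_cohort(config)
    paths = {
        "responses": out / "responses.csv",
        "domain_map": out / "domain_map.csv",
        "severity": out / "severity.csv",
        "flags": out / "flags.csv",
        "truth": out / "truth.json",
    }
    resp.write(paths["responses"])
    params.domain_map(strict=len(params.domains) == 5).write(paths["domain_map"])
    sev.write(paths["severity"])
    flags.write(paths["flags"])
    truth = {
        "config": config.to_jsonable(),
        "item_ids": params.item_ids,
        "a": params.a.tolist(),
        "b": params.b.tolist(),
        "item_domains": params.item_domains,
        "testlet_sd": params.testlet_sd,
        "theta": params.theta.tolist(),
        "gamma": params.gamma.tolist(),
        "eta": params.eta.tolist(),
        "affected": params.affected.astype(int).tolist(),
        "person_ids": params.person_ids,
        "severity_a": params.severity_a.tolist(),
        "severity_b": params.severity_b.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}, params
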