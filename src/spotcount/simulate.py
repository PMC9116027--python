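"""Synthetic count-matrix generators with known ground truth.

Three generators mirror the structures the analysis probes:

* ``simulate_dataset`` — per-gene counts from one of the four families with
  log-link means and per-location depth offsets;
* ``simulate_cluster_mixture`` — Poisson within each location cluster,
  overdispersed marginally when cluster rates differ;
* ``simulate_celltype_mixture`` — Poisson counts whose means mix cell-type
  rates through Dirichlet compositions.

Location totals are drawn once per location from a log-normal and act as the
generator-side offsets; downstream fitting always recomputes offsets from
the realized column sums, so simulated and real data share one code path.
Zero-inflated draws are Bernoulli thinning of the count component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_cluster_mixture",
    "simulate_celltype_mixture",
]


@dataclass
class SimConfig:
    """Configuration for the per-gene four-family generator."""

    n_genes: int = 100
    n_locations: int = 200
    family_weights: dict = field(
        default_factory=lambda: {"poisson": 0.25, "nb": 0.25, "zip": 0.25, "zinb": 0.25}
    )
    mean_range: tuple = (0.5, 5.0)       # baseline rate lambda per unit offset
    phi_range: tuple = (0.5, 2.0)
    pi_range: tuple = (0.1, 0.5)
    depth_log_mean: float = 0.0
    depth_log_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_locations < 1:
            raise ValueError("n_genes and n_locations must be positive")
        w = self.family_weights
        if not w or any(f not in ("poisson", "nb", "zip", "zinb") for f in w):
            raise ValueError("family_weights keys must be among the four families")
        if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1.0) > 1e-8:
            raise ValueError("family_weights must be non-negative and sum to 1")
        for name, rng_ in (("mean_range", self.mean_range), ("phi_range", self.phi_range)):
            lo, hi = rng_
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive interval")
        lo, hi = self.pi_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("pi_range must lie in [0, 1)")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be non-negative")


@dataclass
class SimTruth:
    """Ground-truth record: one row per gene, plus dataset-level structure."""

    genes: pd.DataFrame  # columns: gene, family, lambda, phi, pi
    seed: int
    cluster_labels: np.ndarray | None = None
    compositions: pd.DataFrame | None = None


def _depths(rng, n, log_mean, log_sd):
    return np.exp(rng.normal(log_mean, log_sd, size=n))


def _uniform(rng, lo_hi, size=None):
    lo, hi = lo_hi
    return rng.uniform(lo, hi, size=size)


def _draw_counts(rng, family, mu, phi=None, pi=None):
    if family == "poisson":
        y = rng.poisson(mu)
    elif family == "nb":
        y = rng.negative_binomial(phi, phi / (phi + mu))
    elif family == "zip":
        y = rng.poisson(mu)
    elif family == "zinb":
        y = rng.negative_binomial(phi, phi / (phi + mu))
    else:  # pragma: no cover
        raise ValueError(family)
    if family in ("zip", "zinb"):
        y = np.where(rng.random(len(mu)) < pi, 0, y)
    return y


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a gene x location matrix with per-gene families and parameters."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_locations

    depths = _depths(rng, n, config.depth_log_mean, config.depth_log_sd)
    fams = list(config.family_weights)
    probs = np.array([config.family_weights[f] for f in fams], dtype=float)
    family = rng.choice(fams, size=G, p=probs)
    lam = _uniform(rng, config.mean_range, G)
    phi = _uniform(rng, config.phi_range, G)
    pi = _uniform(rng, config.pi_range, G)

    counts = np.empty((G, n), dtype=np.int64)
    for g in range(G):
        mu = lam[g] * depths
        counts[g] = _draw_counts(
            rng, family[g], mu,
            phi=phi[g] if family[g] in ("nb", "zinb") else None,
            pi=pi[g] if family[g] in ("zip", "zinb") else None,
        )

    truth = pd.DataFrame(
        {
            "gene": [f"gene{i}" for i in range(G)],
            "family": family,
            "lambda": lam,
            "phi": np.where(np.isin(family, ["nb", "zinb"]), phi, np.nan),
            "pi": np.where(np.isin(family, ["zip", "zinb"]), pi, np.nan),
        }
    )
    m = CountMatrix(counts)
    return m, SimTruth(genes=truth, seed=config.seed)


def simulate_cluster_mixture(
    K: int,
    per_cluster_rates: np.ndarray,
    cluster_sizes,
    depth_log_mean: float = 0.0,
    depth_log_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray, SimTruth]:
    """Poisson counts within clusters; overdispersed marginally.

    ``per_cluster_rates`` is K x G; location ``i`` in cluster ``c`` has mean
    ``N_i * rate[c, g]`` for gene ``g``.
    """
    rates = np.atleast_2d(np.asarray(per_cluster_rates, dtype=float))
    sizes = np.asarray(cluster_sizes, dtype=int)
    if K < 1 or rates.shape[0] != K or len(sizes) != K:
        raise ValueError("K, per_cluster_rates rows and cluster_sizes must agree")
    if (sizes < 1).any():
        raise ValueError("empty cluster")
    if (rates <= 0).any():
        raise ValueError("rates must be positive")

    rng = np.random.default_rng(seed)
    G = rates.shape[1]
    n = int(sizes.sum())
    labels = np.repeat(np.arange(K), sizes)
    depths = _depths(rng, n, depth_log_mean, depth_log_sd)
    mu = rates[labels].T * depths[None, :]  # G x n
    counts = rng.poisson(mu).astype(np.int64)

    truth = pd.DataFrame(
        {
            "gene": [f"gene{i}" for i in range(G)],
            "family": "poisson_mixture",
            "lambda": rates.mean(axis=0),
            "phi": np.nan,
            "pi": np.nan,
        }
    )
    m = CountMatrix(counts)
    return m, labels, SimTruth(genes=truth, seed=seed, cluster_labels=labels)


def simulate_celltype_mixture(
    K_types: int,
    type_rates: np.ndarray,
    dirichlet_alpha,
    n_locations: int,
    depth_log_mean: float = 0.0,
    depth_log_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Poisson counts whose means mix type rates by Dirichlet compositions.

    Location ``i`` draws ``w_i ~ Dirichlet(alpha)``; gene ``g`` has mean
    ``N_i * sum_k w_ik * theta[k, g]``.
    """
    rates = np.atleast_2d(np.asarray(type_rates, dtype=float))
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if K_types < 1 or rates.shape[0] != K_types or len(alpha) != K_types:
        raise ValueError("K_types, type_rates rows and dirichlet_alpha must agree")
    if (alpha <= 0).any():
        raise ValueError("dirichlet_alpha must be positive")
    if (rates <= 0).any():
        raise ValueError("rates must be positive")

    rng = np.random.default_rng(seed)
    G = rates.shape[1]
    n = int(n_locations)
    depths = _depths(rng, n, depth_log_mean, depth_log_sd)
    W = rng.dirichlet(alpha, size=n) if K_types > 1 else np.ones((n, 1))
    mu = (W @ rates).T * depths[None, :]  # G x n
    counts = rng.poisson(mu).astype(np.int64)

    comp = pd.DataFrame(
        W,
        index=[f"loc{i}" for i in range(n)],
        columns=[f"type{k}" for k in range(K_types)],
    )
    truth = pd.DataFrame(
        {
            "gene": [f"gene{i}" for i in range(G)],
            "family": "celltype_mixture",
            "lambda": (alpha / alpha.sum()) @ rates,
            "phi": np.nan,
            "pi": np.nan,
        }
    )
    m = CountMatrix(counts)
    return m, comp, SimTruth(genes=truth, seed=seed, compositions=comp)
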