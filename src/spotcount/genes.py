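"""Per-gene summaries, likelihood ratio tests and AIC model selection.

The panel fits all four families to every gene (NB through the GEE-fallback
route), runs the four nested likelihood ratio tests

    Poisson vs ZIP, Poisson vs NB, NB vs ZINB, ZIP vs ZINB

each on one degree of freedom, applies a Bonferroni threshold of
``alpha / G`` with G the number of genes retained in the current analysis
unit, and picks the preferred family by lowest AIC.

Two of the contrasts place the dispersion parameter on its boundary; the
default reference is a plain chi-square(1) (conservative). Setting
``boundary_mixture=True`` switches those two tests to the
0.5*chi2(0) + 0.5*chi2(1) mixture.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .matrix import CountMatrix
from .models import ModelFit, fit_gene, fit_nb_with_fallback

__all__ = [
    "filter_genes",
    "summarize_genes",
    "lrt",
    "run_gene_panel",
    "overlap_proportions",
    "dataset_summary",
    "LRT_CONTRASTS",
]

logger = logging.getLogger(__name__)

LRT_CONTRASTS = {
    "p_zip": ("poisson", "zip"),
    "p_nb": ("poisson", "nb"),
    "nb_zinb": ("nb", "zinb"),
    "zip_zinb": ("zip", "zinb"),
}
_BOUNDARY_TESTS = ("p_nb", "zip_zinb")  # dispersion parameter on its boundary
_FAMILY_ORDER = ("poisson", "nb", "zip", "zinb")


def filter_genes(m: CountMatrix) -> CountMatrix:
    """Drop zero-total locations, then genes with zero counts everywhere."""
    loc_keep = np.flatnonzero(m.counts.sum(axis=0) > 0)
    if len(loc_keep) < m.n_locations:
        logger.info("dropping %d zero-total locations", m.n_locations - len(loc_keep))
        m = m.subset_locations(loc_keep)
    gene_keep = np.flatnonzero(m.counts.sum(axis=1) > 0)
    if len(gene_keep) == 0:
        raise ValueError("no genes left after filtering")
    if len(gene_keep) < m.n_genes:
        m = m.subset_genes(gene_keep)
    return m


def summarize_genes(m: CountMatrix) -> pd.DataFrame:
    """Per-gene mean, sample variance (n-1), zero proportion and ratio."""
    y = m.counts
    mean = y.mean(axis=1)
    var = y.var(axis=1, ddof=1)
    zero = (y == 0).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, var / mean, np.nan)
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "mean": mean,
            "variance": var,
            "zero_prop": zero,
            "var_mean_ratio": ratio,
        }
    )


def lrt(fit_null: ModelFit, fit_alt: ModelFit, boundary_mixture: bool = False):
    """Likelihood ratio test between two nested fits on the same data.

    Returns ``(stat, df, p)``. Statistics are clamped at zero (unconverged
    fallback fits can produce tiny negative differences).
    """
    pair = (fit_null.family, fit_alt.family)
    if pair not in set(LRT_CONTRASTS.values()):
        raise ValueError(f"{pair} is not one of the four nested contrasts")
    df = fit_alt.n_params - fit_null.n_params
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    if stat == 0.0:
        return 0.0, df, 1.0
    p = float(chi2.sf(stat, df))
    if boundary_mixture:
        p = 0.5 * p
    return stat, df, p


def _preferred_family(aics: dict, ks: dict) -> str:
    order = {f: i for i, f in enumerate(_FAMILY_ORDER)}
    return min(aics, key=lambda f: (aics[f], ks[f], order[f]))


def fit_four(y, offsets, covariates=None) -> dict:
    """Fit all four families to one gene (NB via the GEE fallback route)."""
    return {
        "poisson": fit_gene("poisson", y, offsets, covariates),
        "nb": fit_nb_with_fallback(y, offsets, covariates),
        "zip": fit_gene("zip", y, offsets, covariates),
        "zinb": fit_gene("zinb", y, offsets, covariates),
    }


def run_gene_panel(
    m: CountMatrix,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    boundary_mixture: bool = False,
    use_offset: bool = True,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Four fits + four LRTs + AIC selection for every gene of a matrix.

    Significance uses the Bonferroni threshold ``alpha / G`` where G is the
    number of genes in ``m`` (the current analysis unit). Per-gene failures
    are recorded in the ``error`` column and never abort the panel.
    """
    offsets = m.offsets if use_offset else np.ones(m.n_locations)
    G = m.n_genes
    thresh = alpha / G if bonferroni else alpha
    rows = []
    for g in range(G):
        row: dict = {"gene": m.gene_ids[g], "error": ""}
        y = m.counts[g]
        try:
            fits = fit_four(y, offsets, covariates)
            for fam, fit in fits.items():
                row[f"loglik_{fam}"] = fit.loglik
                row[f"aic_{fam}"] = fit.aic
                row[f"converged_{fam}"] = fit.converged
            row["phi_nb"] = fits["nb"].phi
            row["pi_zip"] = fits["zip"].pi
            row["phi_zinb"] = fits["zinb"].phi
            row["pi_zinb"] = fits["zinb"].pi
            row["nb_method"] = fits["nb"].method
            for name, (f0, f1) in LRT_CONTRASTS.items():
                mix = boundary_mixture and name in _BOUNDARY_TESTS
                stat, _, p = lrt(fits[f0], fits[f1], boundary_mixture=mix)
                row[f"lrt_{name}"] = stat
                row[f"pval_{name}"] = p
                row[f"sig_{name}"] = p < thresh
            aics = {f: fits[f].aic for f in fits}
            ks = {f: fits[f].n_params for f in fits}
            row["preferred_family"] = _preferred_family(aics, ks)
        except Exception as exc:  # pragma: no cover - defensive per-gene guard
            logger.warning("gene %s failed: %s", m.gene_ids[g], exc)
            row["error"] = str(exc)
            row["preferred_family"] = ""
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_genes_tested"] = G
    out.attrs["bonferroni_threshold"] = thresh
    out.attrs["alpha"] = alpha
    return out


def overlap_proportions(set_a, set_b):
    """(|A&B|/|A|, |A&B|/|B|); ``None`` for a proportion with empty base."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    pa = inter / len(a) if a else None
    pb = inter / len(b) if b else None
    return pa, pb


def dataset_summary(summaries: pd.DataFrame) -> dict:
    """Dataset-level metrics from per-gene summaries.

    The overall zero proportion equals the mean per-gene zero proportion
    because every gene spans the same locations.
    """
    if summaries.empty:
        raise ValueError("empty summary table")
    ratio = summaries["var_mean_ratio"].to_numpy(dtype=float)
    return {
        "prop_var_gt_mean": float(
            (summaries["variance"] > summaries["mean"]).mean()
        ),
        "median_ratio": float(np.nanmedian(ratio)),
        "overall_zero_prop": float(summaries["zero_prop"].mean()),
    }
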