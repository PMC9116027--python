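"""Gene panel conditioned on per-location cell-type compositions.

Compositions (rows summing to one) enter every model's count-component mean
as covariates. Because the composition columns sum to the intercept, the
last cell-type column is dropped before fitting; constant columns are
dropped too, and remaining columns are centered. Estimating compositions is
out of scope — they are an input (or simulated ground truth).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genes import run_gene_panel
from .matrix import CountMatrix

__all__ = ["validate_compositions", "encode_covariates", "conditional_panel"]

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-6


def validate_compositions(comp: pd.DataFrame, m: CountMatrix | None = None) -> pd.DataFrame:
    arr = comp.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("compositions must be non-negative")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=_ROW_SUM_TOL):
        raise ValueError("composition rows must sum to 1")
    if m is not None:
        if len(comp) != m.n_locations:
            raise ValueError("composition rows do not match matrix locations")
        if list(comp.index.astype(str)) != list(m.location_ids) and not (
            comp.index == pd.RangeIndex(len(comp))
        ).all():
            raise ValueError("composition location ids do not match the count matrix")
    return comp


def encode_covariates(comp: pd.DataFrame) -> tuple[np.ndarray | None, list[str]]:
    """Identifiable, centered design from a composition matrix.

    Drops the last cell-type column (collinear with the intercept), then any
    constant column. Returns ``(None, [])`` when nothing informative remains,
    in which case callers fall back to the unconditional panel.
    """
    validate_compositions(comp)
    cols = list(comp.columns[:-1])
    arr = comp.to_numpy(dtype=float)[:, :-1]
    keep = []
    for j, name in enumerate(cols):
        if np.ptp(arr[:, j]) < 1e-12:
            logger.warning("dropping constant composition column %r", name)
            continue
        keep.append(j)
    if not keep:
        return None, []
    design = arr[:, keep]
    design = design - design.mean(axis=0, keepdims=True)
    return design, [cols[j] for j in keep]


def conditional_panel(
    m: CountMatrix,
    comp: pd.DataFrame,
    alpha: float = 0.05,
    boundary_mixture: bool = False,
    use_offset: bool = True,
) -> pd.DataFrame:
    """Run the full four-model panel with compositions as mean covariates."""
    validate_compositions(comp, m)
    design, names = encode_covariates(comp)
    if design is None:
        logger.warning("no informative composition columns; unconditional panel")
    out = run_gene_panel(
        m,
        covariates=design,
        alpha=alpha,
        boundary_mixture=boundary_mixture,
        use_offset=use_offset,
    )
    out.attrs["covariates"] = names
    return out
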