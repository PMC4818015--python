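"""Elastic-net deconvolution of cell-type abundances from marker expression.

Each tissue sample's marker expression vector y^(s,u) is regressed on the
reference signatures X^(u) restricted to the same markers,

    y^(s,u) = X^(u) . theta^(s,u),

and the coefficient vector theta is read off as relative cell-type
abundances. Because the number of candidate cell types can exceed the number
of markers, and abundance changes are expected in only a few cell types, the
fit is regularized with an elastic net (mostly-ridge mixing, alpha = 0.05 on
the L1 side). The reported solution sits at the small-penalty end of a
geometric path, lambda_min = lambda_min_ratio * lambda_max, where lambda_max
is the smallest penalty that zeroes every coefficient. Abundances are
relative quantities and may be negative when the expression data are
baseline-subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
import warnings

from .core_data import GeneExpressionMatrix, ReferenceMatrix
from .markers import MarkerSet

SOLVER_TOL = 1e-7


@dataclass
class PenaltyConfig:
    """Elastic-net settings; defaults follow the DCQ/glmnet parameterization."""

    alpha: float = 0.05  # L1 mixing weight in [0, 1]
    lambda_min_ratio: float = 0.2
    path_length: int = 100
    intercept: bool = True
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")


@dataclass
class ImmuneTraitMatrix:
    """Estimated relative abundances, cell types x samples, for one marker set."""

    data: pd.DataFrame
    marker_set_index: int

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="cell_type")


def _prepare_design(x: np.ndarray, cfg: PenaltyConfig):
    """Standardize columns (population sd, glmnet-style); drop constant ones.

    Columns are centered only when an intercept is fitted; without one the
    predictors keep their raw location so the model stays a pure mixture.
    """
    sd = x.std(axis=0)  # ddof=0, as glmnet
    keep = sd > 0
    if cfg.standardize:
        xs = x[:, keep] / sd[keep]
        if cfg.intercept:
            xs = xs - xs.mean(axis=0)
        return xs, sd, keep
    xs = x[:, keep]
    if cfg.intercept:
        xs = xs - xs.mean(axis=0)
    return xs, np.ones(x.shape[1]), keep


def deconvolve_sample(ref_sub: ReferenceMatrix, y_sub: np.ndarray,
                      cfg: PenaltyConfig | None = None,
                      lambda_override: float | None = None) -> np.ndarray:
    """Estimate abundances for one sample from its marker expression.

    ``ref_sub`` holds the reference restricted to one marker set (replicates
    are collapsed); ``y_sub`` is the sample's expression of the same markers,
    in the same gene order. Coefficients are returned on the original
    predictor scale; the intercept is discarded. ``lambda_override`` forces a
    specific penalty instead of lambda_min (e.g. lambda_max for full
    shrinkage).
    """
    cfg = cfg or PenaltyConfig()
    x = ref_sub.collapse().data.to_numpy(dtype=float)
    y = np.asarray(y_sub, dtype=float)
    n_obs, n_types = x.shape
    if n_obs < 2:
        raise ValueError("deconvolution needs at least 2 markers")
    if y.shape != (n_obs,):
        raise ValueError(f"marker vector length {y.shape} does not match {n_obs} markers")
    theta = np.zeros(n_types)
    if not np.any(y):
        return theta  # nothing to explain

    xs, sd, keep = _prepare_design(x, cfg)
    if not keep.any():
        return theta
    yc = y - y.mean() if cfg.intercept else y

    l1r = max(cfg.alpha, 1e-3)  # pure ridge has no finite lambda_max
    lambda_max = np.abs(xs.T @ yc).max() / (n_obs * l1r)
    if lambda_max <= 0:
        return theta
    lam = lambda_override if lambda_override is not None \
        else cfg.lambda_min_ratio * lambda_max
    model = ElasticNet(alpha=lam, l1_ratio=cfg.alpha, fit_intercept=False,
                       tol=SOLVER_TOL, max_iter=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(xs, yc)
    theta[keep] = model.coef_ / sd[keep]
    return theta


def coefficient_path(ref_sub: ReferenceMatrix, y_sub: np.ndarray,
                     cfg: PenaltyConfig | None = None):
    """The elastic-net coefficient path (lambdas descending, coefs per lambda).

    Returns ``(lambdas, coefs)`` with ``coefs`` of shape (n_cell_types,
    path_length), on the standardized scale; used for path diagnostics.
    """
    cfg = cfg or PenaltyConfig()
    x = ref_sub.collapse().data.to_numpy(dtype=float)
    y = np.asarray(y_sub, dtype=float)
    xs, _, keep = _prepare_design(x, cfg)
    yc = y - y.mean() if cfg.intercept else y
    lambdas, coefs, _ = enet_path(xs, yc, l1_ratio=max(cfg.alpha, 1e-3),
                                  eps=cfg.lambda_min_ratio,
                                  alphas=cfg.path_length)
    full = np.zeros((x.shape[1], coefs.shape[1]))
    full[keep] = coefs
    return lambdas, full


def deconvolve_population(ref: ReferenceMatrix, expr: GeneExpressionMatrix,
                          markers: MarkerSet,
                          cfg: PenaltyConfig | None = None) -> ImmuneTraitMatrix:
    """Deconvolve every sample using one marker set.

    Genes of the marker set absent from either matrix are dropped; an empty
    remainder is an error naming the set index. The immune trait of cell type
    c is the row of estimated abundances across samples.
    """
    cfg = cfg or PenaltyConfig()
    shared = set(expr.gene_ids) & set(ref.gene_ids)
    genes = [g for g in markers.genes if g in shared]
    if not genes:
        raise ValueError(f"marker set {markers.index}: no marker genes present "
                         "in both reference and expression data")
    ref_sub = ReferenceMatrix(ref.data.loc[genes].copy(),
                              dict(ref.replicate_map) if ref.replicate_map else None)
    ref_collapsed = ref_sub.collapse()
    y_block = expr.data.loc[genes]
    out = np.column_stack([
        deconvolve_sample(ref_collapsed, y_block[s].to_numpy(dtype=float), cfg)
        for s in expr.sample_ids
    ])
    frame = pd.DataFrame(out, index=ref_collapsed.cell_type_ids,
                         columns=expr.sample_ids)
    return ImmuneTraitMatrix(frame, marker_set_index=markers.index)
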