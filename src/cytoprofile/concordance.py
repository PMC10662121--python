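"""Pairwise-PCA confidence-ellipse concordance for MoA ranking.

The core statistic of bacterial cytological profiling as implemented
here: for a pair of treatments, pool their (QC'd, balanced) cells,
standardise the cytological parameters, take the first two principal
components, fit a 95% confidence ellipse to each treatment's scores, and
report the proportion of cells inside both ellipses among cells inside
either. A query compound is ranked against a panel of reference
antibiotics by descending concordance; the top references suggest its
mechanism of action.

:class:`BCPConcordance` is the model-style entry point: build it from a
query feature table and a panel of reference tables, call :meth:`fit`,
and read the ranking off the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import parameter_columns
from .qc import balanced_subsample

__all__ = [
    "PCAModel",
    "ConfidenceEllipse",
    "ConcordanceResult",
    "PairResult",
    "fit_pairwise_pca",
    "confidence_ellipse",
    "concordance",
    "pairwise_concordance",
    "rank_references",
    "BCPConcordance",
    "BCPConcordanceResults",
]


@dataclass
class PCAModel:
    """Standardise-then-rotate model fitted on the pooled pair of treatments.

    ``loadings`` columns are orthonormal; explained variance is the
    variance of the scores along each component (non-increasing).
    """

    parameters: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    def transform(self, table: pd.DataFrame, n_components: int = 2) -> np.ndarray:
        x = table[self.parameters].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        return z @ self.loadings[:, :n_components]


def fit_pairwise_pca(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[PCAModel, np.ndarray, np.ndarray]:
    """PCA of the pooled, standardised cells of two treatments.

    Centring and scaling use the pooled mean and pooled sample SD so both
    treatments live in one comparable space; zero-variance parameters are
    dropped with a warning before scaling. Returns the model and each
    treatment's scores on the first two components. The sign of each
    loading column is fixed so its largest-magnitude entry is positive.
    """
    params_a = parameter_columns(table_a)
    params_b = set(parameter_columns(table_b))
    params = [p for p in params_a if p in params_b]
    if not params:
        raise ValueError("tables share no parameter columns")
    n_a, n_b = len(table_a), len(table_b)
    if n_a + n_b < 3:
        raise ValueError("need at least 3 cells in the pooled pair")

    x = np.vstack(
        [
            table_a[params].to_numpy(dtype=float),
            table_b[params].to_numpy(dtype=float),
        ]
    )
    if np.isnan(x).any():
        raise ValueError("tables contain missing values; run QC first")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.all():
        dropped = [p for p, k in zip(params, keep) if not k]
        warnings.warn(f"dropping zero-variance parameters: {dropped}")
        params = [p for p, k in zip(params, keep) if k]
        x, center, scale = x[:, keep], center[keep], scale[keep]
        if not params:
            raise ValueError("all parameters have zero variance")

    z = (x - center) / scale
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    # resolve the sign ambiguity of each component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), range(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    explained = s**2 / (len(z) - 1)

    model = PCAModel(
        parameters=params,
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance=explained,
    )
    scores = z @ loadings[:, :2]
    return model, scores[:n_a], scores[n_a:]


@dataclass
class ConfidenceEllipse:
    """An elliptical confidence region for one treatment's PC1-PC2 scores.

    Membership of a point x is exact: (x-center)' shape^-1 (x-center)
    <= radius2. ``method="t"`` uses the small-sample F-based radius
    2 (n-1)/(n-2) F(level; 2, n-2) (the construction of the usual
    plotting-package ellipse); ``method="normal"`` uses the chi-square
    radius, appropriate for large Gaussian samples.
    """

    center: np.ndarray
    shape: np.ndarray
    radius2: float
    level: float
    method: str
    n: int

    def __post_init__(self) -> None:
        self._inv_shape = np.linalg.inv(self.shape)

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, self._inv_shape, d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact membership test via the quadratic form."""
        return self.mahalanobis2(points) <= self.radius2


def confidence_ellipse(
    scores: np.ndarray, level: float = 0.95, method: str = "t"
) -> ConfidenceEllipse:
    """Fit the level-confidence ellipse to a 2-D score cloud."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 points to fit an ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    center = scores.mean(axis=0)
    shape = np.cov(scores, rowvar=False, ddof=1)
    if np.linalg.det(shape) <= np.finfo(float).tiny:
        raise ValueError("degenerate covariance: points are collinear")
    if method == "t":
        radius2 = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    elif method == "normal":
        radius2 = stats.chi2.ppf(level, 2)
    else:
        raise ValueError(f"unknown ellipse method {method!r}")
    return ConfidenceEllipse(
        center=center, shape=shape, radius2=float(radius2), level=level,
        method=method, n=n,
    )


@dataclass
class ConcordanceResult:
    """Concordance of one treatment pair: |both| / |either| over all cells."""

    treatment_a: str
    treatment_b: str
    n_both: int
    n_either: int
    proportion: float
    n_cells_per_treatment: int = 0
    seed: int | None = None
    level: float = 0.95
    method: str = "t"


def concordance(
    ellipse_a: ConfidenceEllipse,
    ellipse_b: ConfidenceEllipse,
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    treatment_a: str = "a",
    treatment_b: str = "b",
) -> ConcordanceResult:
    """Proportion of cells inside both ellipses among cells inside either.

    Membership is evaluated over the union of the two treatments' cells;
    the statistic is symmetric in the pair and lies in [0, 1]. An empty
    union yields 0 with a warning.
    """
    pts = np.vstack([scores_a, scores_b])
    in_a = ellipse_a.contains(pts)
    in_b = ellipse_b.contains(pts)
    n_both = int((in_a & in_b).sum())
    n_either = int((in_a | in_b).sum())
    if n_either == 0:
        warnings.warn("no cell falls inside either ellipse; concordance set to 0")
        prop = 0.0
    else:
        prop = n_both / n_either
    return ConcordanceResult(
        treatment_a=treatment_a,
        treatment_b=treatment_b,
        n_both=n_both,
        n_either=n_either,
        proportion=prop,
        n_cells_per_treatment=min(len(scores_a), len(scores_b)),
        level=ellipse_a.level,
        method=ellipse_a.method,
    )


@dataclass
class PairResult:
    """Everything computed for one query/reference pair."""

    result: ConcordanceResult
    pca: PCAModel
    ellipse_a: ConfidenceEllipse
    ellipse_b: ConfidenceEllipse
    scores_a: np.ndarray
    scores_b: np.ndarray


def pairwise_concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    level: float = 0.95,
    method: str = "t",
    subsample_n: int | None = None,
    seed: int = 0,
) -> PairResult:
    """Balanced subsample -> pooled PCA -> per-treatment ellipses -> concordance."""
    name_a = str(table_a["treatment"].iloc[0])
    name_b = str(table_b["treatment"].iloc[0])
    pooled = pd.concat([table_a, table_b], ignore_index=True)
    pooled = balanced_subsample(pooled, n=subsample_n, seed=seed)
    sub_a = pooled[pooled["treatment"] == name_a]
    sub_b = pooled[pooled["treatment"] == name_b]
    pca, scores_a, scores_b = fit_pairwise_pca(sub_a, sub_b)
    ell_a = confidence_ellipse(scores_a, level=level, method=method)
    ell_b = confidence_ellipse(scores_b, level=level, method=method)
    res = concordance(ell_a, ell_b, scores_a, scores_b, name_a, name_b)
    res.seed = seed
    return PairResult(res, pca, ell_a, ell_b, scores_a, scores_b)


def rank_references(
    query: pd.DataFrame,
    references: dict[str, pd.DataFrame],
    level: float = 0.95,
    method: str = "t",
    subsample_n: int | None = None,
    seed: int = 0,
) -> list[ConcordanceResult]:
    """Concordance of the query against each reference, best first."""
    return [
        pr.result
        for pr in _fit_panel(query, references, level, method, subsample_n, seed)
    ]


def _fit_panel(
    query: pd.DataFrame,
    references: dict[str, pd.DataFrame],
    level: float,
    method: str,
    subsample_n: int | None,
    seed: int,
) -> list[PairResult]:
    rng = np.random.default_rng(seed)
    pairs = []
    for name in references:
        pair_seed = int(rng.integers(2**31))
        pairs.append(
            pairwise_concordance(
                query,
                references[name],
                level=level,
                method=method,
                subsample_n=subsample_n,
                seed=pair_seed,
            )
        )
    pairs.sort(key=lambda pr: -pr.result.proportion)
    return pairs


class BCPConcordance:
    """Cytological-profile concordance model for MoA ranking.

    Parameters
    ----------
    query : feature table of the compound under study (post-QC or raw
        but complete; the fit subsamples to balance each pair).
    references : mapping of reference name -> feature table.
    level : confidence level of the per-treatment ellipses.
    method : ellipse radius rule, ``"t"`` (small-sample, default) or
        ``"normal"`` (chi-square).
    """

    def __init__(
        self,
        query: pd.DataFrame,
        references: dict[str, pd.DataFrame],
        level: float = 0.95,
        method: str = "t",
        subsample_n: int | None = None,
    ):
        self.query = query
        self.references = dict(references)
        self.level = level
        self.method = method
        self.subsample_n = subsample_n

    @classmethod
    def from_tables(cls, query: pd.DataFrame, references: dict, **kw) -> "BCPConcordance":
        return cls(query, references, **kw)

    def fit(self, seed: int = 0) -> "BCPConcordanceResults":
        pairs = _fit_panel(
            self.query,
            self.references,
            self.level,
            self.method,
            self.subsample_n,
            seed,
        )
        return BCPConcordanceResults(model=self, pairs=pairs, seed=seed)


@dataclass
class BCPConcordanceResults:
    """Ranked concordance results with full per-pair provenance."""

    model: BCPConcordance
    pairs: list[PairResult]
    seed: int
    _by_ref: dict[str, PairResult] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_ref = {pr.result.treatment_b: pr for pr in self.pairs}

    @property
    def results(self) -> list[ConcordanceResult]:
        return [pr.result for pr in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair": f"{r.treatment_a}|{r.treatment_b}",
                "reference": r.treatment_b,
                "n_both": r.n_both,
                "n_either": r.n_either,
                "proportion": r.proportion,
                "rank": i + 1,
            }
            for i, r in enumerate(self.results)
        ]
        return pd.DataFrame(
            rows, columns=["pair", "reference", "n_both", "n_either", "proportion", "rank"]
        )

    def summary(self) -> str:
        m = self.model
        head = [
            "Cytological-profile concordance ranking",
            "=======================================",
            f"ellipse level {m.level:.2f} ({m.method}); seed {self.seed}; "
            f"references: {len(m.references)}",
            "",
            f"{'rank':>4} {'reference':<16} {'n_both':>7} {'n_either':>8} {'concordance':>12}",
        ]
        for i, r in enumerate(self.results):
            head.append(
                f"{i + 1:>4} {r.treatment_b:<16} {r.n_both:>7} {r.n_either:>8} "
                f"{r.proportion:>12.3f}"
            )
        return "\n".join(head)

    def scores_frame(self) -> pd.DataFrame:
        """PC1/PC2 scores for every pair, long format (for plotting/export)."""
        frames = []
        for pr in self.pairs:
            r = pr.result
            for trt, sc in ((r.treatment_a, pr.scores_a), (r.treatment_b, pr.scores_b)):
                frames.append(
                    pd.DataFrame(
                        {
                            "pair": f"{r.treatment_a}|{r.treatment_b}",
                            "treatment": trt,
                            "pc1": sc[:, 0],
                            "pc2": sc[:, 1],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def plot_pair(self, reference: str, ax=None):
        """Scatter the pair's PC1-PC2 scores with both confidence ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse

        pr = self._by_ref[reference]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        r = pr.result
        for trt, sc, ell, color in (
            (r.treatment_a, pr.scores_a, pr.ellipse_a, "tab:blue"),
            (r.treatment_b, pr.scores_b, pr.ellipse_b, "tab:orange"),
        ):
            ax.scatter(sc[:, 0], sc[:, 1], s=6, alpha=0.4, color=color, label=trt)
            evals, evecs = np.linalg.eigh(ell.shape)
            angle = np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1]))
            w, h = 2 * np.sqrt(evals[-1] * ell.radius2), 2 * np.sqrt(evals[0] * ell.radius2)
            ax.add_patch(
                MplEllipse(
                    ell.center, w, h, angle=angle, fill=False, color=color, lw=1.5
                )
            )
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(frameon=False)
        ax.set_title(f"concordance = {r.proportion:.3f}")
        return ax
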