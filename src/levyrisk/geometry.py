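"""One-dimensional gene-expression-space geometry.

Given a genes × samples expression matrix with normal/tumor labels, this
module computes the coordinate system of the one-dimensional model:

1. a per-gene reference level e_ref (geometric mean over normal samples);
2. log-fold coordinates ê = log₂(e/e_ref), which place the normal-cloud
   center at the origin;
3. the first principal axis v₁ of the sample covariance of ê — the "cancer
   axis" along which normal and tumor clouds separate;
4. scalar projections x₁ = ê·v₁ and their summaries: normal radius Rₙ
   (r.m.s. about the origin), tumor center x̄₁ and radius Rₜ (r.m.s. about
   x̄₁), and the fluctuation scale D = max|v₁ᵢ|.

Conventions: the covariance is taken about the grand mean of ê (standard
PCA) while projections are uncentered dot products ê·v₁, so the origin
remains the normal-cloud center; v₁ is oriented so the mean tumor
projection is positive; radii are one-dimensional (along PC1 only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NORMAL",
    "TUMOR",
    "ExpressionCohort",
    "GEGeometry",
    "reference_levels",
    "log_fold_coordinates",
    "principal_axis",
    "project_and_summarize",
    "compute_geometry",
    "read_expression_tsv",
    "read_labels_tsv",
]

NORMAL = "normal"
TUMOR = "tumor"

#: relative eigenvalue gap below which PC1/PC2 are treated as tied
_TIE_RTOL = 1e-12


@dataclass
class ExpressionCohort:
    """A genes × samples matrix of nonnegative expression values with labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match the matrix")
        if len(self.sample_ids) != n_samples or len(self.labels) != n_samples:
            raise ValueError("sample_ids/labels length does not match the matrix")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        bad = set(self.labels) - {NORMAL, TUMOR}
        if bad:
            raise ValueError(f"labels must be 'normal' or 'tumor', got {sorted(bad)}")
        if self.normal_mask.sum() < 2 or self.tumor_mask.sum() < 2:
            raise ValueError("need at least 2 normal and 2 tumor samples")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite and >= 0")

    @property
    def normal_mask(self) -> np.ndarray:
        return np.array([l == NORMAL for l in self.labels])

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.array([l == TUMOR for l in self.labels])


@dataclass
class GEGeometry:
    """PC1-space summary of an expression cohort.

    v1 is the unit principal direction over (retained) genes; xbar1 the mean
    tumor projection; rn/rt the normal/tumor r.m.s. radii along PC1;
    d_scale = max|v1_i| the fluctuation scale; pc1_variance_fraction the
    share of total variance carried by PC1.
    """

    v1: np.ndarray
    xbar1: float = np.nan
    rn: float = np.nan
    rt: float = np.nan
    d_scale: float = np.nan
    pc1_variance_fraction: float = np.nan
    e_ref: np.ndarray | None = None
    gene_ids: list[str] = field(default_factory=list)
    projections: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=float)
        n = np.linalg.norm(self.v1)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError(f"v1 must be a unit vector, |v1| = {n}")

    def to_dict(self) -> dict:
        return {
            "xbar1": self.xbar1,
            "rn": self.rn,
            "rt": self.rt,
            "r_walk": self.xbar1 - self.rn - self.rt,
            "d_scale": self.d_scale,
            "pc1_variance_fraction": self.pc1_variance_fraction,
            "n_genes": int(self.v1.size),
        }


def reference_levels(
    cohort: ExpressionCohort, pseudocount: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene reference: geometric mean of (e + pseudocount) over normals.

    Returns ``(e_ref, keep)`` where ``keep`` flags genes whose reference is
    strictly positive.  With pseudocount 0, genes with any zero among the
    normal samples would have a zero geometric mean; they are flagged for
    exclusion with a warning rather than raising.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    normals = cohort.values[:, cohort.normal_mask] + pseudocount
    keep = np.all(normals > 0, axis=1)
    e_ref = np.full(cohort.values.shape[0], np.nan)
    e_ref[keep] = np.exp(np.mean(np.log(normals[keep]), axis=1))
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} gene(s) with zero reference level "
            "(zero expression in a normal sample at pseudocount 0)",
            stacklevel=2,
        )
    return e_ref, keep


def log_fold_coordinates(
    cohort: ExpressionCohort, e_ref: np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """ê = log₂((e + pseudocount)/e_ref), genes × samples.

    Because e_ref is the geometric mean over normal samples, the mean of ê
    over normals is exactly zero for every gene: the normal-cloud center is
    the origin.
    """
    e_ref = np.asarray(e_ref, dtype=float)
    if np.any(~(e_ref > 0)):
        raise ValueError("e_ref must be strictly positive on retained genes")
    return np.log2((cohort.values + pseudocount) / e_ref[:, None])


def principal_axis(ehat: np.ndarray, tumor_mask: np.ndarray | None = None) -> GEGeometry:
    """First principal axis of the sample covariance of ê.

    Standard PCA: the covariance is taken about the grand mean over samples;
    computed via SVD of the centered matrix so large gene counts are cheap.
    Returns a :class:`GEGeometry` with ``v1`` and ``pc1_variance_fraction``
    filled.

    Orientation: if ``tumor_mask`` is given, v₁ is flipped so the mean
    (uncentered) tumor projection is positive; otherwise the entry of
    largest magnitude is made positive (deterministic).  Exact eigenvalue
    ties are broken toward the eigenvector whose absolute component
    sequence is lexicographically largest.
    """
    ehat = np.asarray(ehat, dtype=float)
    if ehat.ndim != 2 or ehat.shape[1] < 2:
        raise ValueError("ehat must be genes x samples with >= 2 samples")
    if not np.all(np.isfinite(ehat)):
        raise ValueError("ehat must be finite")
    centered = ehat - ehat.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    ev = s**2  # proportional to covariance eigenvalues
    if ev[0] <= 0:
        raise ValueError("no variance: all samples are identical")

    tied = np.flatnonzero(ev >= ev[0] * (1.0 - _TIE_RTOL))
    if tied.size > 1:
        key = lambda j: tuple(np.round(np.abs(u[:, j]), 12))
        best = max(tied, key=key)
    else:
        best = 0
    v1 = u[:, best]

    if tumor_mask is not None:
        mean_tumor_proj = float(np.mean(ehat[:, np.asarray(tumor_mask, bool)].T @ v1))
        if mean_tumor_proj < 0:
            v1 = -v1
    elif v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1

    return GEGeometry(
        v1=v1,
        d_scale=float(np.max(np.abs(v1))),
        pc1_variance_fraction=float(ev[best] / ev.sum()),
    )


def project_and_summarize(
    ehat: np.ndarray, labels: list[str], v1: np.ndarray
) -> GEGeometry:
    """Project samples on v₁ and summarize the two clouds.

    x₁ = ê·v₁ (uncentered, so the origin is the normal-cloud center);
    Rₙ = r.m.s. of normal projections about the origin; x̄₁ = mean tumor
    projection; Rₜ = r.m.s. of tumor projections about x̄₁;
    D = max|v₁ᵢ|.  v₁ (and all projections) are flipped if x̄₁ < 0.
    """
    ehat = np.asarray(ehat, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    if not np.isclose(np.linalg.norm(v1), 1.0, atol=1e-9):
        raise ValueError("v1 must be unit norm")
    if len(labels) != ehat.shape[1]:
        raise ValueError("one label per sample is required")
    bad = set(labels) - {NORMAL, TUMOR}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")

    x1 = ehat.T @ v1
    normal = np.array([l == NORMAL for l in labels])
    tumor = ~normal
    xbar1 = float(x1[tumor].mean())
    if xbar1 < 0:  # orient the cancer axis toward the tumor cloud
        v1, x1, xbar1 = -v1, -x1, -xbar1
    return GEGeometry(
        v1=v1,
        xbar1=xbar1,
        rn=float(np.sqrt(np.mean(x1[normal] ** 2))),
        rt=float(np.sqrt(np.mean((x1[tumor] - xbar1) ** 2))),
        d_scale=float(np.max(np.abs(v1))),
        projections=x1,
    )


def compute_geometry(cohort: ExpressionCohort, pseudocount: float = 0.0) -> GEGeometry:
    """Full pipeline: reference levels → ê → PCA → projection summary."""
    e_ref, keep = reference_levels(cohort, pseudocount)
    ehat = log_fold_coordinates(
        ExpressionCohort(
            values=cohort.values[keep],
            gene_ids=[g for g, k in zip(cohort.gene_ids, keep) if k],
            sample_ids=cohort.sample_ids,
            labels=cohort.labels,
        ),
        e_ref[keep],
        pseudocount,
    )
    axis = principal_axis(ehat, tumor_mask=np.array([l == TUMOR for l in cohort.labels]))
    geom = project_and_summarize(ehat, cohort.labels, axis.v1)
    geom.pc1_variance_fraction = axis.pc1_variance_fraction
    geom.e_ref = e_ref[keep]
    geom.gene_ids = [g for g, k in zip(cohort.gene_ids, keep) if k]
    return geom


def read_expression_tsv(expr_path, labels_path) -> ExpressionCohort:
    """Read a genes × samples TSV (first column gene id) plus a two-column
    (sample_id, class) label TSV into an :class:`ExpressionCohort`."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels = read_labels_tsv(labels_path)
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ValueError(f"no label for sample(s): {missing[:5]}")
    return ExpressionCohort(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        labels=[labels[str(s)] for s in df.columns],
    )


def read_labels_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"])
    return {str(r.sample_id): str(r.label) for r in df.itertuples()}
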