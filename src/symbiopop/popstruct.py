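"""Population structure: allele frequencies, Hudson F_ST, ordination.

Each metagenomic sample (or a pool of samples) is treated as a population
whose allele counts at a site are the read counts — every read an
independent allele draw, the pooled-sequencing convention when strain
ploidy is unknown. The genome-wide fixation index is Hudson's estimator
with the finite-sample correction, combined across sites as a ratio of
averages:

    num_i = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den_i = p1(1-p2) + p2(1-p1)
    F_ST  = sum_i num_i / sum_i den_i    (sites with den_i > 0; n >= 2 each)

Ratio-of-averages is robust to rare alleles and unequal sample sizes;
negative genome-wide values are reported as computed, with a zero-clamped
convenience copy alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, PipelineError
from .mapping import NucleotideCountMatrix, VariantTable

# ---------------------------------------------------------------------------
# Allele counts and frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleCounts:
    """Per-site (ref, alt) allele counts for one population (sample or pool)."""

    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=float)
        self.alt = np.asarray(self.alt, dtype=float)
        if self.ref.shape != self.alt.shape:
            raise ConfigurationError("ref/alt count arrays must align")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ConfigurationError("allele counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


def pooled_allele_counts(vt: VariantTable, samples: Sequence[str]) -> AlleleCounts:
    """Sum ref/alt counts across member samples per site (depth-weighted pooling)."""
    if not samples:
        raise ConfigurationError("population must contain at least one sample")
    idx = vt.sample_index(samples)
    return AlleleCounts(
        ref=vt.ref_counts[:, idx].sum(axis=1), alt=vt.alt_counts[:, idx].sum(axis=1)
    )


def allele_frequencies(vt: VariantTable, samples: Sequence[str]) -> np.ndarray:
    """Pooled alt-allele frequency per site; NaN marks zero-depth sites."""
    ac = pooled_allele_counts(vt, samples)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ac.depth > 0, ac.alt / np.where(ac.depth > 0, ac.depth, 1), np.nan)


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------


@dataclass
class HudsonFst:
    fst: float
    per_site_num: np.ndarray  # NaN at excluded sites
    per_site_den: np.ndarray
    n_sites_used: int


def hudson_fst(pop1: AlleleCounts, pop2: AlleleCounts) -> HudsonFst:
    """Genome-wide Hudson F_ST between two populations (ratio of averages)."""
    if pop1.ref.shape != pop2.ref.shape:
        raise ConfigurationError("populations must share the same site set")
    n1, n2 = pop1.depth, pop2.depth
    valid = (n1 >= 2) & (n2 >= 2)
    num = np.full(n1.shape, np.nan)
    den = np.full(n1.shape, np.nan)
    if valid.any():
        p1 = pop1.alt[valid] / n1[valid]
        p2 = pop2.alt[valid] / n2[valid]
        v1, v2 = n1[valid], n2[valid]
        num[valid] = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (v1 - 1)
            - p2 * (1 - p2) / (v2 - 1)
        )
        den[valid] = p1 * (1 - p2) + p2 * (1 - p1)
    use = valid & (den > 0)
    if not use.any():
        raise PipelineError("Hudson F_ST undefined: no usable sites (den > 0, n >= 2)")
    fst = float(num[use].sum() / den[use].sum())
    return HudsonFst(fst=fst, per_site_num=num, per_site_den=den, n_sites_used=int(use.sum()))


# ---------------------------------------------------------------------------
# Pairwise F_ST over a grouping
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    labels: List[str]
    fst: pd.DataFrame  # unclamped, symmetric, zero diagonal
    fst_clamped: pd.DataFrame  # negatives clamped to 0
    details: Dict[Tuple[str, str], HudsonFst]

    def to_tsv(self, path) -> None:
        self.fst.to_csv(path, sep="\t", float_format="%.6g")


def make_groups(metadata: pd.DataFrame, grouping: str) -> Dict[str, List[str]]:
    """Grouping helper over a metadata table with sample_id / vent_field /
    lifestyle columns; grouping is 'sample', 'vent_field' or 'lifestyle'."""
    md = metadata.reset_index() if "sample_id" not in metadata.columns else metadata
    if grouping == "sample":
        return {s: [s] for s in md["sample_id"]}
    if grouping not in md.columns:
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    out: Dict[str, List[str]] = {}
    for _, row in md.iterrows():
        out.setdefault(str(row[grouping]), []).append(row["sample_id"])
    return out


def pairwise_fst(vt: VariantTable, groups: Mapping[str, Sequence[str]]) -> FstResult:
    """Hudson F_ST for every unordered pair of populations under a grouping.

    Populations are single samples or depth-summed pooled count sets.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ConfigurationError("pairwise F_ST needs >= 2 populations")
    pools = {g: pooled_allele_counts(vt, groups[g]) for g in labels}
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    details: Dict[Tuple[str, str], HudsonFst] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            res = hudson_fst(pools[a], pools[b])
            mat.loc[a, b] = mat.loc[b, a] = res.fst
            details[(a, b)] = res
    return FstResult(
        labels=labels, fst=mat, fst_clamped=mat.clip(lower=0.0), details=details
    )


def classify_differentiation(fst: float) -> str:
    """Differentiation bands: weak < 0.2 <= moderate <= 0.5 < strong."""
    if fst is None or math.isnan(fst):
        raise ValueError("F_ST is NaN; cannot classify")
    if fst < 0.2:
        return "weak"
    if fst <= 0.5:
        return "moderate"
    return "strong"


# ---------------------------------------------------------------------------
# Distance matrices and PCoA
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: List[str]
    matrix: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ConfigurationError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ConfigurationError("distance matrix must be symmetric")
        if (np.abs(np.diag(m)) > 1e-12).any():
            raise ConfigurationError("distance matrix must have a zero diagonal")
        if (m < -1e-12).any():
            raise ConfigurationError("distances must be non-negative")
        self.matrix = m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")


def bray_curtis_matrix(
    ncm: NucleotideCountMatrix,
    normalization: str = "per_site_freq",
    site_mask: Optional[np.ndarray] = None,
) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples from nucleotide counts.

    Default sample vectors concatenate, over sites, the per-site nucleotide
    proportions (counts / site depth), removing depth artifacts between
    samples; ``normalization='raw'`` keeps raw counts.
    """
    counts = ncm.counts if site_mask is None else ncm.counts[site_mask]
    if len(ncm.samples) < 2:
        raise ConfigurationError("Bray-Curtis needs >= 2 samples")
    X = counts.astype(float)  # (S, N, 4)
    if normalization == "per_site_freq":
        depth = X.sum(axis=2, keepdims=True)
        X = np.divide(X, depth, out=np.zeros_like(X), where=depth > 0)
    elif normalization != "raw":
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    V = X.transpose(1, 0, 2).reshape(len(ncm.samples), -1)  # samples x (sites*4)
    zero = np.flatnonzero(V.sum(axis=1) == 0)
    if zero.size:
        raise ConfigurationError(
            "all-zero count profile for sample(s): "
            + ", ".join(ncm.samples[i] for i in zero)
        )
    D = squareform(pdist(V, metric="braycurtis"))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(ncm.samples), matrix=D, metric_name="bray_curtis")


def bray_curtis_from_variants(vt: VariantTable, normalization: str = "per_site_freq") -> DistanceMatrix:
    """Bray-Curtis on a VariantTable's per-site (ref, alt) profiles — the
    count matrix restricted to filtered variant sites."""
    R = vt.ref_counts.astype(float)
    A = vt.alt_counts.astype(float)
    if normalization == "per_site_freq":
        depth = R + A
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(depth > 0, R / np.where(depth > 0, depth, 1), 0.0)
            A = np.where(depth > 0, A / np.where(depth > 0, depth, 1), 0.0)
    elif normalization != "raw":
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    V = np.stack([R, A], axis=2).transpose(1, 0, 2).reshape(len(vt.samples), -1)
    zero = np.flatnonzero(V.sum(axis=1) == 0)
    if zero.size:
        raise ConfigurationError(
            "all-zero count profile for sample(s): "
            + ", ".join(vt.samples[i] for i in zero)
        )
    D = squareform(pdist(V, metric="braycurtis"))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(vt.samples), matrix=D, metric_name="bray_curtis")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes ("PC1", ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per returned axis, denominator sum(|eigenvalues|)

    def to_tsv(self, path) -> None:
        df = self.coordinates.copy()
        df.to_csv(path, sep="\t", float_format="%.6g")


def pcoa(d: DistanceMatrix, n_axes: Optional[int] = None) -> PCoAResult:
    """Classical metric MDS (principal coordinates analysis).

    Gower-center the squared distances (B = -1/2 J D^2 J), eigendecompose,
    and scale eigenvectors by sqrt of positive eigenvalues. Negative
    eigenvalues are reported, contribute no coordinates, and enter the
    proportion_explained denominator by absolute value (no Cailliez/Lingoes
    correction).
    """
    D = d.matrix
    n = D.shape[0]
    if n_axes is not None and n_axes > n - 1:
        raise ConfigurationError("n_axes must be <= n_samples - 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    n_pos = int((evals > tol).sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    denom = np.abs(evals).sum()
    prop = evals[:k] / denom if denom > 0 else np.zeros(k)
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=d.labels, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def axis_separates(result: PCoAResult, groups: Mapping[str, Sequence[str]], axis: str = "PC1") -> bool:
    """True when group intervals on the given axis do not overlap (two groups)."""
    names = list(groups)
    if len(names) != 2:
        raise ConfigurationError("axis separation check is defined for two groups")
    a = result.coordinates.loc[list(groups[names[0]]), axis]
    b = result.coordinates.loc[list(groups[names[1]]), axis]
    return bool(a.max() < b.min() or b.max() < a.min())
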