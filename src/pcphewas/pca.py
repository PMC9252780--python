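"""Per-gene principal components of the dosage matrix.

Each gene region is summarized by the PCA of its (mean-imputed, centered,
unscaled) dosage matrix, keeping the smallest number of components whose
cumulative explained-variance ratio reaches the retention target (default
95%).  The deterministic full SVD is used — gene regions are small enough
that reproducibility outranks speed — and each loading column is oriented so
its largest-magnitude entry is positive, making serialized PCs stable across
runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import DosageMatrix

DEFAULT_VARIANCE_RETAINED = 0.95

#: Relative tolerance for treating trailing singular values as numerically
#: zero when determining rank.
_RANK_RTOL = 1e-9


@dataclass
class GenePCs:
    """Gene-based principal components: loadings, variance ratios, scores."""

    gene_id: str
    variant_ids: list[str]
    loadings: np.ndarray = field(repr=False)          # variants x k
    explained_variance_ratio: np.ndarray = field(repr=False)  # length k
    scores: np.ndarray = field(repr=False)            # samples x k
    sample_ids: list[str] = field(repr=False)
    variant_means: np.ndarray = field(repr=False)     # length m
    variance_retained_target: float = DEFAULT_VARIANCE_RETAINED

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())

    def to_files(self, directory: str | Path) -> None:
        """Serialize scores/loadings as TSV plus a JSON sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pc_cols = [f"PC{i + 1}" for i in range(self.k)]
        scores = pd.DataFrame(self.scores, columns=pc_cols)
        scores.insert(0, "sample_id", self.sample_ids)
        scores.to_csv(d / f"{self.gene_id}.scores.tsv", sep="\t", index=False,
                      float_format="%.10g")
        loadings = pd.DataFrame(self.loadings, columns=pc_cols)
        loadings.insert(0, "variant_id", self.variant_ids)
        loadings.to_csv(d / f"{self.gene_id}.loadings.tsv", sep="\t",
                        index=False, float_format="%.10g")
        sidecar = {
            "gene_id": self.gene_id,
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "variance_retained_target": self.variance_retained_target,
            "variant_means": self.variant_means.tolist(),
        }
        with open(d / f"{self.gene_id}.pca.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)

    @classmethod
    def from_files(cls, directory: str | Path, gene_id: str) -> "GenePCs":
        d = Path(directory)
        scores = pd.read_csv(d / f"{gene_id}.scores.tsv", sep="\t")
        loadings = pd.read_csv(d / f"{gene_id}.loadings.tsv", sep="\t")
        with open(d / f"{gene_id}.pca.json") as fh:
            sidecar = json.load(fh)
        return cls(
            gene_id=gene_id,
            variant_ids=loadings["variant_id"].astype(str).tolist(),
            loadings=loadings.iloc[:, 1:].to_numpy(float),
            explained_variance_ratio=np.asarray(
                sidecar["explained_variance_ratio"], float),
            scores=scores.iloc[:, 1:].to_numpy(float),
            sample_ids=scores["sample_id"].astype(str).tolist(),
            variant_means=np.asarray(sidecar["variant_means"], float),
            variance_retained_target=float(sidecar["variance_retained_target"]),
        )


def _impute_and_center(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per variant, then center columns."""
    X = np.array(dosages, dtype=float)
    means = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    if nan_idx[0].size:
        X[nan_idx] = means[nan_idx[1]]
    return X - means, means


def compute_gene_pcs(
    dm: DosageMatrix,
    variance_retained: float = DEFAULT_VARIANCE_RETAINED,
    seed: int = 0,
    gene_id: str | None = None,
) -> GenePCs:
    """PCA of a gene's dosage matrix, retaining the minimal PC set whose
    cumulative explained-variance ratio reaches ``variance_retained``.

    Missing dosages are mean-imputed per variant; columns are centered but
    not variance-scaled.  ``seed`` is accepted for interface stability but
    unused: the full SVD is deterministic.
    """
    del seed
    if dm.n_variants == 0:
        raise ValueError("no variants in region")
    if dm.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not 0.0 < variance_retained <= 1.0:
        raise ValueError("variance_retained must be in (0, 1]")

    Xc, means = _impute_and_center(dm.dosages)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    if total <= 0.0:
        raise ValueError("no genetic variance in region")
    rank = int((s > s[0] * _RANK_RTOL).sum())
    s, U, Vt = s[:rank], U[:, :rank], Vt[:rank]

    evr = s ** 2 / total
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    k = min(k, rank)

    loadings = Vt[:k].T
    # orient each loading column so its largest-|entry| is positive
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                             np.arange(k)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = (U[:, :k] * s[:k]) * signs

    return GenePCs(
        gene_id=gene_id or "gene",
        variant_ids=dm.variant_ids(),
        loadings=loadings,
        explained_variance_ratio=evr[:k],
        scores=scores,
        sample_ids=list(dm.sample_ids),
        variant_means=means,
        variance_retained_target=variance_retained,
    )


def project(dm: DosageMatrix, pcs: GenePCs) -> np.ndarray:
    """Project samples onto a gene's PC space using the stored centering."""
    ids = dm.variant_ids()
    if ids != pcs.variant_ids:
        missing = [v for v in pcs.variant_ids if v not in set(ids)]
        extra = [v for v in ids if v not in set(pcs.variant_ids)]
        raise ValueError(
            f"variant mismatch with {pcs.gene_id} PCs: "
            f"missing={missing[:5]}, extra={extra[:5]}"
        )
    X = np.array(dm.dosages, dtype=float)
    nan_idx = np.where(np.isnan(X))
    if nan_idx[0].size:
        X[nan_idx] = pcs.variant_means[nan_idx[1]]
    return (X - pcs.variant_means) @ pcs.loadings
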