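"""PCA of a reference panel with least-squares projection of low-coverage
samples (smartpca/lsqproject-style).

Genotypes are centred by twice the panel allele frequency and scaled by
sqrt(p(1-p)); the principal axes come from the SVD of the normalised panel.
A heavily missing (possibly pseudo-haploid) sample is placed by regressing
its normalised genotypes at its non-missing sites onto the eigenvector rows
at those sites, which is unbiased under missingness at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix


@dataclass
class PcaModel:
    site_index: np.ndarray  # indices into the fitting panel's site list
    mean: np.ndarray  # per-site 2*p_hat
    scale: np.ndarray  # per-site sqrt(p_hat (1 - p_hat))
    eigenvectors: np.ndarray  # (n_sites, k), orthonormal columns
    eigenvalues: np.ndarray  # length k, non-increasing
    coordinates: pd.DataFrame = field(repr=False)  # reference individuals x PCs

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def fit_pca(
    panel: GenotypeMatrix,
    n_components: int = 2,
    max_missing_rate: float = 0.05,
) -> PcaModel:
    """PCA of a reference panel.

    Sites with missing rate above ``max_missing_rate`` are dropped;
    remaining missing entries are mean-imputed. Monomorphic sites carry no
    information and are dropped as well. Each eigenvector is oriented so its
    largest-magnitude loading is positive, making signs reproducible.
    Reference coordinates are the PC scores (left singular vectors scaled by
    singular values), so a reference individual's least-squares projection
    reproduces its own coordinates.
    """
    calls = panel.calls.astype(float)
    miss = panel.calls == MISSING
    keep = miss.mean(axis=1) <= max_missing_rate
    calls = calls[keep]
    miss = miss[keep]
    n_sites, n_inds = calls.shape
    if n_components > min(n_sites, n_inds):
        raise ValueError(
            f"n_components={n_components} exceeds min(sites, individuals)="
            f"{min(n_sites, n_inds)}"
        )
    with np.errstate(invalid="ignore"):
        p_hat = np.where(
            (~miss).sum(axis=1) > 0,
            np.where(miss, 0.0, calls).sum(axis=1) / (2.0 * np.maximum((~miss).sum(axis=1), 1)),
            np.nan,
        )
    poly = (p_hat > 0) & (p_hat < 1)
    keep_idx = np.flatnonzero(keep)[poly]
    calls = calls[poly]
    miss = miss[poly]
    p_hat = p_hat[poly]
    mean = 2.0 * p_hat
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    norm = (np.where(miss, mean[:, None], calls) - mean[:, None]) / scale[:, None]

    # economy SVD of individuals x sites
    u, s, vt = np.linalg.svd(norm.T, full_matrices=False)
    k = n_components
    vecs = vt[:k].T  # (sites, k)
    # orient: largest-|loading| positive
    signs = np.ones(k)
    for c in range(k):
        j = np.argmax(np.abs(vecs[:, c]))
        if vecs[j, c] < 0:
            signs[c] = -1.0
    vecs = vecs * signs
    scores = u[:, :k] * s[:k] * signs
    eigvals = (s[:k] ** 2) / max(calls.shape[0], 1)
    coords = pd.DataFrame(
        scores,
        columns=[f"PC{c + 1}" for c in range(k)],
    )
    coords.insert(0, "ind_id", [i.ind_id for i in panel.individuals])
    coords.insert(1, "population", [i.population for i in panel.individuals])
    return PcaModel(keep_idx, mean, scale, vecs, eigvals, coords)


def project_sample(model: PcaModel, sample_calls: np.ndarray) -> np.ndarray:
    """Least-squares projection of a (possibly pseudo-haploid, heavily
    missing) sample onto the model's principal axes.

    ``sample_calls`` is indexed like the panel the model was fitted on; the
    model's own site filter is applied internally. Requires at least
    ``n_components`` non-missing sites among the model's sites.
    """
    sample_calls = np.asarray(sample_calls)
    calls = sample_calls[model.site_index].astype(float)
    obs = sample_calls[model.site_index] != MISSING
    if obs.sum() < model.n_components:
        raise ValueError(
            f"sample has {int(obs.sum())} usable sites; "
            f"projection needs at least {model.n_components}"
        )
    x = (calls[obs] - model.mean[obs]) / model.scale[obs]
    v = model.eigenvectors[obs]
    coords, *_ = np.linalg.lstsq(v, x, rcond=None)
    return coords


def coordinates_table(model: PcaModel) -> pd.DataFrame:
    return model.coordinates.copy()
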