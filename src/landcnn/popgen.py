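"""Population-genetic summary statistics and the simulated-vs-observed check.

Pairwise differentiation uses Hudson's F_ST estimator in ratio-of-averages
form: per SNP, with sample allele frequencies ``p1, p2`` and sample sizes
``n1, n2`` haploid sequences,

    N = (p1 - p2)^2 - p1 (1 - p1)/(n1 - 1) - p2 (1 - p2)/(n2 - 1)
    D = p1 (1 - p2) + p2 (1 - p1)

and F_ST = sum(N) / sum(D) over SNPs.  The estimator is unbiased under the
island model, so small negative values are legitimate sampling noise.

``pca_match`` operationalizes the visual check that simulations bracket the
observed data: the lower triangles of simulated F_ST matrices are summarized
with a 2-component PCA and the observed matrix is projected into that space;
a match requires the projected point to lie inside the simulated convex hull
and within the per-component min-max ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from sklearn.decomposition import PCA

from .simulate import GenotypeMatrix

__all__ = ["FstMatrix", "pairwise_fst", "heterozygosity", "PcaMatchReport", "pca_match"]


@dataclass
class FstMatrix:
    deme_ids: list[int]
    values: np.ndarray
    estimator: str = "hudson_ratio_of_averages"

    def lower_triangle(self) -> np.ndarray:
        n = len(self.deme_ids)
        iu = np.tril_indices(n, k=-1)
        return self.values[iu]


def _hudson_terms(p1, p2, n1, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pairwise_fst(g: GenotypeMatrix) -> FstMatrix:
    """Hudson's F_ST between every pair of demes, averaged over SNPs
    (ratio of averages).  Demes with fewer than 2 sequences get NaN rows
    rather than fabricated values."""
    deme_ids = sorted(np.unique(g.deme_ids).tolist())
    k = len(deme_ids)
    counts = {}
    freqs = {}
    for d in deme_ids:
        rows = g.genotypes[g.deme_ids == d]
        counts[d] = rows.shape[0]
        freqs[d] = rows.mean(axis=0) if rows.shape[0] > 0 else None
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            da, db = deme_ids[a], deme_ids[b]
            if counts[da] < 2 or counts[db] < 2:
                out[a, b] = out[b, a] = np.nan
                continue
            num, den = _hudson_terms(freqs[da], freqs[db], counts[da], counts[db])
            d_sum = den.sum()
            out[a, b] = out[b, a] = num.sum() / d_sum if d_sum > 0 else np.nan
    return FstMatrix(deme_ids=deme_ids, values=out)


def heterozygosity(g: GenotypeMatrix) -> tuple[float, float]:
    """Mean expected (He) and observed (Ho) heterozygosity.

    He is the sample-size-corrected per-SNP expected heterozygosity
    ``n/(n-1) * 2 p (1-p)`` over all sequences; Ho is the mean fraction of
    heterozygous diploid individuals (consecutive sequence pairs).
    """
    n = g.n_sequences
    if n < 2:
        raise ValueError("need at least 2 sequences for heterozygosity")
    p = g.genotypes.mean(axis=0)
    he = float(np.mean(2.0 * p * (1.0 - p) * n / (n - 1)))
    inds = np.unique(g.individual_ids)
    pairs = []
    for i in inds:
        rows = np.where(g.individual_ids == i)[0]
        if rows.size != 2:
            raise ValueError(f"individual {i} does not have exactly 2 sequences")
        pairs.append(g.genotypes[rows[0]] != g.genotypes[rows[1]])
    ho = float(np.mean(np.stack(pairs)))
    return he, ho


@dataclass
class PcaMatchReport:
    match: bool
    inside_hull: bool | None        # None when the simulated cloud is degenerate
    within_ranges: bool
    target_scores: np.ndarray
    simulated_scores: np.ndarray
    distance_to_centroid: float
    distance_to_nearest: float
    degenerate: bool = False


def pca_match(sim_fsts: Sequence[FstMatrix], target: FstMatrix) -> PcaMatchReport:
    """Project the observed F_ST matrix into the PCA of simulated matrices
    and report whether it falls inside the simulated variation."""
    if len(sim_fsts) < 10:
        raise ValueError("need at least 10 simulated matrices")
    vecs = np.stack([f.lower_triangle() for f in sim_fsts])
    tvec = target.lower_triangle()
    if tvec.shape[0] != vecs.shape[1]:
        raise ValueError("target and simulations must share the deme set")
    if np.allclose(vecs.std(axis=0), 0):
        scores = np.zeros((vecs.shape[0], 2))
        tsc = np.zeros(2)
        same = np.allclose(tvec, vecs[0])
        return PcaMatchReport(
            match=bool(same), inside_hull=None, within_ranges=bool(same),
            target_scores=tsc, simulated_scores=scores,
            distance_to_centroid=0.0 if same else float(np.linalg.norm(tvec - vecs[0])),
            distance_to_nearest=0.0 if same else float(np.linalg.norm(tvec - vecs[0])),
            degenerate=True,
        )
    pca = PCA(n_components=2)
    scores = pca.fit_transform(vecs)
    tsc = pca.transform(tvec[None])[0]
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    within = bool(np.all(tsc >= lo - 1e-9) and np.all(tsc <= hi + 1e-9))
    inside: bool | None
    try:
        tri = Delaunay(scores)
        inside = bool(tri.find_simplex(tsc) >= 0)
    except QhullError:
        inside = None  # collinear cloud: fall back to the range criterion
    centroid = scores.mean(axis=0)
    d_centroid = float(np.linalg.norm(tsc - centroid))
    d_nearest = float(np.linalg.norm(scores - tsc, axis=1).min())
    match = within and (inside is not False)
    return PcaMatchReport(
        match=match, inside_hull=inside, within_ranges=within,
        target_scores=tsc, simulated_scores=scores,
        distance_to_centroid=d_centroid, distance_to_nearest=d_nearest,
    )
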