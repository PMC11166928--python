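"""Deterministic binary-image encoding of genotype matrices.

The classifier never sees raw genotypes: each matrix is converted into a
black-and-white image whose pixels are SNP alleles.  Per column, the major
allele is recoded 0 and the minor allele 1 (ties leave allele 0 as major);
columns are then stably sorted from higher to lower minor-allele frequency,
and rows (haploid sequences) are grouped by deme in ascending deme id.  The
encoding is idempotent and fully determined by the input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simulate import GenotypeMatrix

__all__ = ["SNPImage", "encode_image", "save_images", "load_images"]


@dataclass
class SNPImage:
    """A binary SNP image with its row manifest and (optional) model label."""

    pixels: np.ndarray           # (n_sequences, n_snps) uint8 in {0,1}
    deme_ids: np.ndarray
    individual_ids: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("pixels must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_genotype_matrix(self) -> GenotypeMatrix:
        """View the image as a genotype matrix (e.g. to re-encode or to
        compute summary statistics on encoded data)."""
        return GenotypeMatrix(
            genotypes=self.pixels,
            deme_ids=self.deme_ids,
            individual_ids=self.individual_ids,
            label=self.label,
        )


def encode_image(g: GenotypeMatrix) -> SNPImage:
    """Encode a genotype matrix as a sorted binary image.

    Raises if any column is monomorphic (an upstream-contract violation: the
    simulator and the variant caller both guarantee polymorphic columns).
    """
    if g.n_sequences == 0 or g.n_snps == 0:
        raise ValueError("cannot encode an empty genotype matrix")
    pixels = np.asarray(g.genotypes, dtype=np.uint8)
    n = pixels.shape[0]
    counts = pixels.sum(axis=0)
    if np.any(counts == 0) or np.any(counts == n):
        raise ValueError("monomorphic column encountered during encoding")
    # Major allele -> 0: flip columns where 1s are the strict majority.
    flip = counts * 2 > n
    pixels = np.where(flip[None, :], 1 - pixels, pixels)
    counts = np.where(flip, n - counts, counts)
    # Stable sort by descending minor-allele frequency (ties keep input order).
    col_order = np.argsort(-counts, kind="stable")
    # Rows grouped by deme, then individual, then original sequence order.
    row_order = np.lexsort((np.arange(n), g.individual_ids, g.deme_ids))
    return SNPImage(
        pixels=pixels[row_order][:, col_order],
        deme_ids=g.deme_ids[row_order],
        individual_ids=g.individual_ids[row_order],
        label=g.label,
    )


def save_images(images: list[SNPImage], path: str | Path) -> None:
    """Persist a corpus of equally shaped images as a compressed npz archive."""
    pixels = np.stack([im.pixels for im in images])
    labels = np.array([-1 if im.label is None else im.label for im in images])
    np.savez_compressed(
        path,
        pixels=pixels,
        labels=labels,
        deme_ids=images[0].deme_ids,
        individual_ids=images[0].individual_ids,
    )


def load_images(path: str | Path) -> list[SNPImage]:
    with np.load(path) as data:
        return [
            SNPImage(
                pixels=p,
                deme_ids=data["deme_ids"],
                individual_ids=data["individual_ids"],
                label=None if lab < 0 else int(lab),
            )
            for p, lab in zip(data["pixels"], data["labels"])
        ]
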