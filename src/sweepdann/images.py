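"""Windowed multilocus-genotype images.

A replicate becomes an ``n_sample x W`` image: the sequence is split into W
equal half-open windows and each pixel is the window mean of the individual's
major-allele dosage divided by 2, so pixels live in [0, 1] with 1 = every
site homozygous for the sample-wise major allele.  A completed sweep shows up
as a tall high-value band in the central columns; rendering maps high values
to dark.

Rows keep sampling order (no resorting), so row identity is stable across a
dataset -- saliency maps refer to fixed individuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .reads import DosageMatrix, GenotypeMatrix, collapse_to_genotypes
from .sim import HaplotypeSample

__all__ = [
    "GenotypeImage",
    "ImageSet",
    "determine_major",
    "major_dosage",
    "encode_image",
    "image_from_genotypes",
    "image_from_dosage",
    "image_from_haplotypes",
    "render_heatmap",
]

DEFAULT_WINDOWS = 64


@dataclass
class GenotypeImage:
    """One classifier input: pixels in [0,1], class label and domain tag."""

    pixels: np.ndarray  # (n_sample, W)
    label: str
    domain: str
    W: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not self.W:
            self.W = self.pixels.shape[1]
        if self.pixels.shape[1] != self.W:
            raise ValueError("W does not match pixel columns")
        if (self.pixels < 0).any() or (self.pixels > 1).any():
            raise ValueError("pixels must lie in [0, 1]")


@dataclass
class ImageSet:
    """Stacked images with aligned labels/domains (the training container)."""

    pixels: np.ndarray  # (n_images, n_sample, W)
    labels: np.ndarray  # int8: 0 = neutral, 1 = sweep, -1 = unlabeled
    domains: np.ndarray  # int8: 0 = source, 1 = target

    LABEL_NAMES = ("neutral", "sweep")
    DOMAIN_NAMES = ("source", "target")

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.domains = np.asarray(self.domains, dtype=np.int8)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (n_images, n_sample, W)")
        if not (len(self.labels) == len(self.domains) == self.pixels.shape[0]):
            raise ValueError("labels/domains/pixels length mismatch")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def from_images(cls, images: Sequence[GenotypeImage]) -> "ImageSet":
        if not images:
            raise ValueError("empty image collection")
        pixels = np.stack([im.pixels for im in images])
        labels = np.array(
            [cls.LABEL_NAMES.index(im.label) if im.label in cls.LABEL_NAMES else -1
             for im in images], dtype=np.int8,
        )
        domains = np.array([cls.DOMAIN_NAMES.index(im.domain) for im in images], dtype=np.int8)
        return cls(pixels, labels, domains)

    def subset(self, idx) -> "ImageSet":
        return ImageSet(self.pixels[idx], self.labels[idx], self.domains[idx])

    def save(self, path: Union[str, Path], provenance: Optional[dict] = None) -> None:
        """Array container (.npz) plus a JSON sidecar with labels/provenance."""
        path = Path(path)
        np.savez(path, pixels=self.pixels, labels=self.labels, domains=self.domains)
        sidecar = {
            "n_images": len(self),
            "n_sample": int(self.pixels.shape[1]),
            "W": int(self.pixels.shape[2]),
            "labels": self.labels.tolist(),
            "domains": self.domains.tolist(),
            "provenance": provenance or {},
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ImageSet":
        with np.load(Path(path).with_suffix(".npz")) as z:
            return cls(z["pixels"], z["labels"], z["domains"])


def determine_major(freq: np.ndarray) -> np.ndarray:
    """True where allele 1 (derived) is the major allele.

    A site at exactly frequency 0.5 counts allele 0 as major (fixed tie rule).
    """
    freq = np.asarray(freq, dtype=np.float64)
    if (freq < 0).any() or (freq > 1).any():
        raise ValueError("frequencies must be in [0, 1]")
    return freq > 0.5


def major_dosage(dosage: np.ndarray, major_is_derived: np.ndarray) -> np.ndarray:
    """Polarize derived-allele dosages onto the major allele (2 - d where
    allele 0 is major)."""
    dosage = np.asarray(dosage, dtype=np.float64)
    if (dosage < 0).any() or (dosage > 2).any():
        raise ValueError("dosages must lie in [0, 2]")
    return np.where(np.asarray(major_is_derived, dtype=bool)[None, :], dosage, 2.0 - dosage)


def encode_image(
    major_dos: np.ndarray,
    positions: np.ndarray,
    L: float,
    W: int = DEFAULT_WINDOWS,
    label: str = "neutral",
    domain: str = "source",
) -> GenotypeImage:
    """Average major-allele dosage/2 over W equal windows of [0, L).

    Windows with no segregating site get fill value 1.0: an invariant
    region is homozygous-major by definition.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    major_dos = np.asarray(major_dos, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    if (positions < 0).any() or (positions >= L).any():
        raise ValueError("positions must lie in [0, L)")
    n = major_dos.shape[0]
    win = np.minimum((positions / L * W).astype(np.int64), W - 1)
    counts = np.bincount(win, minlength=W).astype(np.float64)
    sums = np.zeros((n, W))
    np.add.at(sums.T, win, (major_dos / 2.0).T)
    with np.errstate(invalid="ignore", divide="ignore"):
        pixels = sums / counts[None, :]
    pixels[:, counts == 0] = 1.0
    return GenotypeImage(pixels=np.clip(pixels, 0.0, 1.0), label=label, domain=domain, W=W)


def image_from_genotypes(
    genotypes: GenotypeMatrix, L: float, W: int = DEFAULT_WINDOWS,
    label: str = "neutral", domain: str = "source",
) -> GenotypeImage:
    """Exact-genotype path: sample frequencies polarize, then window-average."""
    g = genotypes.values.astype(np.float64)
    freq = g.sum(axis=0) / (2.0 * genotypes.n_sample)
    md = major_dosage(g, determine_major(freq))
    return encode_image(md, genotypes.positions, L, W, label=label, domain=domain)


def image_from_dosage(
    dosage: DosageMatrix, L: float, W: int = DEFAULT_WINDOWS,
    label: str = "neutral", domain: str = "target",
) -> GenotypeImage:
    """Uncertainty path: polarize expected dosages by the EM frequency."""
    if dosage.positions is None:
        raise ValueError("dosage matrix carries no positions")
    md = major_dosage(np.clip(dosage.dosage, 0.0, 2.0), determine_major(dosage.freq))
    return encode_image(md, dosage.positions, L, W, label=label, domain=domain)


def image_from_haplotypes(
    sample: HaplotypeSample, W: int = DEFAULT_WINDOWS
) -> GenotypeImage:
    return image_from_genotypes(
        collapse_to_genotypes(sample), sample.L, W, label=sample.label, domain=sample.domain
    )


def render_heatmap(image, sink, cmap: str = "Greys", dpi: int = 100) -> None:
    """Write a PNG heatmap; high (major-rich) pixel values render dark.

    Accepts a GenotypeImage or a bare 2-D array (e.g. a saliency map, with
    ``cmap='viridis'``); pixel (0, 0) is top-left.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    fig, ax = plt.subplots(figsize=(6, 2), dpi=dpi)
    ax.imshow(pixels, cmap=cmap, aspect="auto", interpolation="nearest",
              vmin=0.0, vmax=max(1.0, float(pixels.max())))
    ax.set_xlabel("genomic window")
    ax.set_ylabel("individual")
    fig.tight_layout()
    fig.savefig(sink, format="png")
    plt.close(fig)
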