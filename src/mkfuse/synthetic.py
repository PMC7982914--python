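"""Synthetic multi-view labeled datasets with controllable class separation.

Each view follows a Gaussian class-conditional model: class c has a mean
vector living in the first ``informative_dims`` coordinates, samples are
that mean plus isotropic N(0, sigma^2) noise, and the remaining ambient
coordinates are pure noise.  Class means are scaled standard-basis vectors
(separation * sigma / sqrt(2)) * e_c, so every pair of class means sits at
Euclidean distance ``separation * sigma`` — separation is expressed in
units of the noise standard deviation.

All views share the same samples and labels; per-view ``separation``
controls how informative each view is (0 = pure noise), which is what the
kernel-weighting methods are expected to detect.  Sample ids are either
plain (``S0001``) or synthesized TCGA-style barcodes with a fake project
code, optionally mixing in non-tumor sample-type codes to exercise the
barcode filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AlignedDataset, FeatureView, LabelSet, write_feature_matrix, write_label_file

__all__ = ["SyntheticConfig", "generate", "make_view_informative_only", "write_dataset"]


@dataclass
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults give a three-class, three-view problem of comparable shape to
    a multi-omics subtype study after down-scaling: 60 samples per class,
    high ambient dimension (500) with a low-dimensional informative
    subspace (10), unit noise, and moderate per-view separation 6 (class
    means 6 sigma apart).
    """

    n_per_class: list[int] = field(default_factory=lambda: [60, 60, 60])
    n_views: int = 3
    ambient_dims: list[int] = field(default_factory=lambda: [500, 500, 500])
    informative_dims: list[int] = field(default_factory=lambda: [10, 10, 10])
    separation: list[float] = field(default_factory=lambda: [6.0, 6.0, 6.0])
    noise_sigma: float = 1.0
    seed: int = 0
    view_names: list[str] = field(default_factory=lambda: ["gene", "isoform", "meth"])
    class_names: list[str] | None = None
    barcode_ids: bool = False
    nontumor_fraction: float = 0.0

    def __post_init__(self) -> None:
        J = self.n_views
        if len(self.ambient_dims) != J or len(self.informative_dims) != J:
            raise ValueError("ambient_dims/informative_dims must have one entry per view")
        if len(self.separation) != J:
            raise ValueError("separation must have one entry per view")
        if len(self.view_names) != J:
            self.view_names = [f"view{j}" for j in range(J)]
        if any(i > a for i, a in zip(self.informative_dims, self.ambient_dims)):
            raise ValueError("informative_dims cannot exceed ambient_dims")
        if any(k < 1 for k in self.n_per_class) or J < 1:
            raise ValueError("all counts must be >= 1")
        if any(s < 0 for s in self.separation):
            raise ValueError("separation must be nonnegative")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.class_names is None:
            self.class_names = [f"sub{c + 1}" for c in range(len(self.n_per_class))]
        if len(self.class_names) != len(self.n_per_class):
            raise ValueError("class_names must match n_per_class")
        if not 0.0 <= self.nontumor_fraction < 1.0:
            raise ValueError("nontumor_fraction must be in [0, 1)")


def _sample_ids(cfg: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    n = sum(cfg.n_per_class)
    if not cfg.barcode_ids:
        return [f"S{i:04d}" for i in range(n)]
    # fake project code "ZZ"; sample-type 01 (tumor) or 11 (normal)
    codes = np.full(n, 1)
    if cfg.nontumor_fraction > 0:
        k = int(round(n * cfg.nontumor_fraction))
        idx = rng.choice(n, size=k, replace=False)
        codes[idx] = 11
    return [f"TCGA-ZZ-{i:04d}-{codes[i]:02d}A" for i in range(n)]


def generate(cfg: SyntheticConfig) -> AlignedDataset:
    """Draw one dataset; identical seeds give identical datasets."""
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.n_per_class)
    labels = [c for c, cnt in zip(cfg.class_names, cfg.n_per_class) for _ in range(cnt)]
    ids = _sample_ids(cfg, rng)
    n = len(ids)
    views = []
    for j in range(cfg.n_views):
        p, q, sep = cfg.ambient_dims[j], cfg.informative_dims[j], cfg.separation[j]
        if sep > 0 and q < k:
            raise ValueError(
                f"view {j}: informative_dims={q} < {k} classes with separation>0"
            )
        X = rng.normal(0.0, cfg.noise_sigma, size=(n, p))
        if sep > 0:
            # mean of class c = (sep*sigma/sqrt(2)) e_c: equal pairwise distances
            scale = sep * cfg.noise_sigma / np.sqrt(2.0)
            row = 0
            for c, cnt in enumerate(cfg.n_per_class):
                X[row : row + cnt, c] += scale
                row += cnt
        views.append(FeatureView(cfg.view_names[j], ids, X))
    label_set = LabelSet(ids, labels)
    order = sorted(range(n), key=lambda i: ids[i])
    sorted_ids = [ids[i] for i in order]
    return AlignedDataset(
        views=[FeatureView(v.name, sorted_ids, v.matrix[order]) for v in views],
        labels=LabelSet(sorted_ids, [labels[i] for i in order]),
    )


def make_view_informative_only(cfg: SyntheticConfig, view_index: int) -> SyntheticConfig:
    """Copy of the config with nonzero separation only in one view."""
    if not 0 <= view_index < cfg.n_views:
        raise IndexError(f"view_index {view_index} out of range [0, {cfg.n_views})")
    base = max(cfg.separation) if max(cfg.separation) > 0 else 6.0
    sep = [0.0] * cfg.n_views
    sep[view_index] = cfg.separation[view_index] if cfg.separation[view_index] > 0 else base
    return replace(cfg, separation=sep)


def write_dataset(dataset: AlignedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the view-matrix + label-file layout the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for v in dataset.views:
        p = outdir / f"{v.name}.tsv"
        write_feature_matrix(v, p)
        paths[v.name] = p
    lp = outdir / "labels.tsv"
    write_label_file(dataset.labels, lp)
    paths["labels"] = lp
    return paths
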