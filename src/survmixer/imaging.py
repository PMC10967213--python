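"""Turn a gene expression matrix into per-sample pathway-patch images.

Each pathway becomes one square patch: its genes, in pathway order, fill the
patch row-major and the tail is zero-padded to ``patch_side**2`` entries.
Patches are tiled row-major onto a ``grid_side x grid_side`` grid; grid slots
beyond the last pathway are *blank patches* that stay identically zero and
are masked out of the model downstream. With the defaults (7x7 patches on a
7x7 grid) a 40-pathway collection yields a 49x49 image with nine trailing
blank patches.

Expression values are min-max normalized per gene across samples before
imaging, so every pixel lies in [0, 1]. A gene that is constant across
samples maps to zero rather than being dropped, keeping the image geometry
independent of the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geneset import PathwayCollection, max_pathway_size


class ImagingError(ValueError):
    """Raised for geometry or normalization problems."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Samples x genes real matrix with unique row/column identifiers."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ImagingError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ImagingError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ImagingError("duplicate gene ids")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def expr_of(self, sample_id: str) -> dict[str, float]:
        i = self.sample_ids.index(sample_id)
        return dict(zip(self.gene_ids, self.values[i]))


def read_expression(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a samples-in-rows expression table (first column = sample id).

    The separator is sniffed from the extension (.csv → comma, else tab)
    unless given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix.from_dataframe(df)


def write_expression(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    m.to_dataframe().to_csv(path, sep=sep, index_label="sample_id")


def minmax_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene min-max scaling: (X - X_min) / (X_max - X_min).

    X runs over samples for one gene. Genes constant across samples (zero
    range) map to all-zeros. Idempotent: columns already spanning [0, 1]
    are fixed points.
    """
    values = np.asarray(m.values, dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        j = int(np.argwhere(bad.any(axis=0)).ravel()[0])
        raise ImagingError(f"non-finite expression values in gene {m.gene_ids[j]!r}")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    scaled = (values - lo) / safe
    scaled[:, rng == 0] = 0.0
    return ExpressionMatrix(list(m.sample_ids), list(m.gene_ids), scaled)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageLayout:
    """Assignment of pathways to grid slots plus the blank-slot list.

    ``pathway_slots`` maps pathway name → (row, col) of its patch, filled
    row-major from (0, 0); ``blank_slots`` are the remaining trailing grid
    positions. ``pad_len`` (= patch_side**2) is the padded per-pathway
    vector length.
    """

    patch_side: int
    grid_side: int
    pathway_slots: dict[str, tuple[int, int]]
    blank_slots: tuple[tuple[int, int], ...]
    gene_order: dict[str, tuple[str, ...]] = field(default_factory=dict, compare=False)

    @property
    def pad_len(self) -> int:
        return self.patch_side ** 2

    @property
    def image_side(self) -> int:
        return self.patch_side * self.grid_side

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_slots)

    def pixel_of(self, pathway: str, gene_index: int) -> tuple[int, int]:
        """Absolute image pixel for the ``gene_index``-th entry of a patch."""
        r, c = self.pathway_slots[pathway]
        pr, pc = divmod(gene_index, self.patch_side)
        return r * self.patch_side + pr, c * self.patch_side + pc

    def to_json(self) -> str:
        return json.dumps(
            {
                "patch_side": self.patch_side,
                "grid_side": self.grid_side,
                "pathway_slots": {k: list(v) for k, v in self.pathway_slots.items()},
                "blank_slots": [list(s) for s in self.blank_slots],
                "gene_order": {k: list(v) for k, v in self.gene_order.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ImageLayout":
        d = json.loads(text)
        return cls(
            patch_side=int(d["patch_side"]),
            grid_side=int(d["grid_side"]),
            pathway_slots={k: tuple(v) for k, v in d["pathway_slots"].items()},
            blank_slots=tuple(tuple(s) for s in d["blank_slots"]),
            gene_order={k: tuple(v) for k, v in d.get("gene_order", {}).items()},
        )


def build_layout(
    collection: PathwayCollection, patch_side: int = 7, grid_side: int = 7
) -> ImageLayout:
    """Assign pathways row-major to grid slots; trailing slots become blank.

    Raises a sizing error when the collection does not fit the geometry
    (too many pathways, or a pathway longer than ``patch_side**2``).
    """
    n = len(collection)
    if n > grid_side ** 2:
        raise ImagingError(
            f"{n} pathways exceed the {grid_side}x{grid_side} grid "
            f"({grid_side ** 2} slots); need grid_side >= {int(np.ceil(np.sqrt(n)))}"
        )
    longest = max_pathway_size(collection)
    if longest > patch_side ** 2:
        raise ImagingError(
            f"longest pathway has {longest} genes > patch capacity "
            f"{patch_side}x{patch_side} = {patch_side ** 2}; need patch_side >= "
            f"{int(np.ceil(np.sqrt(longest)))}"
        )
    slots: dict[str, tuple[int, int]] = {}
    for k, p in enumerate(collection):
        slots[p.name] = (k // grid_side, k % grid_side)
    blanks = tuple((k // grid_side, k % grid_side) for k in range(n, grid_side ** 2))
    return ImageLayout(
        patch_side=patch_side,
        grid_side=grid_side,
        pathway_slots=slots,
        blank_slots=blanks,
        gene_order={p.name: p.genes for p in collection},
    )


# ---------------------------------------------------------------------------
# Vectors, patches, images
# ---------------------------------------------------------------------------

def pathway_vector(sample_expr: dict[str, float], genes, pad_len: int) -> np.ndarray:
    """Expression of ``genes`` in pathway order, zero-padded to ``pad_len``.

    Genes absent from ``sample_expr`` contribute 0 at their position.
    """
    genes = list(genes)
    if pad_len < len(genes):
        raise ImagingError(f"pad_len {pad_len} < pathway size {len(genes)}")
    v = np.zeros(pad_len, dtype=float)
    for k, g in enumerate(genes):
        v[k] = sample_expr.get(g, 0.0)
    return v


def vector_to_patch(v: np.ndarray, side: int) -> np.ndarray:
    """Row-major reshape of a length-``side**2`` vector into a patch."""
    v = np.asarray(v, dtype=float)
    if v.size != side ** 2:
        raise ImagingError(f"vector length {v.size} != {side}x{side}")
    return v.reshape(side, side)


@dataclass
class PathwayImageSet:
    """Per-sample pathway images plus the layout that generated them."""

    sample_ids: list[str]
    images: np.ndarray  # (n_samples, image_side, image_side)
    layout: ImageLayout

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        side = self.layout.image_side
        if self.images.shape != (len(self.sample_ids), side, side):
            raise ImagingError(
                f"images shape {self.images.shape} != ({len(self.sample_ids)}, {side}, {side})"
            )

    def save(self, directory: str | Path, stem: str = "images") -> None:
        """Persist as a .npy tensor plus a JSON layout sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{stem}.npy", self.images)
        (directory / f"{stem}.layout.json").write_text(self.layout.to_json())
        (directory / f"{stem}.samples.json").write_text(json.dumps(self.sample_ids))

    @classmethod
    def load(cls, directory: str | Path, stem: str = "images") -> "PathwayImageSet":
        directory = Path(directory)
        images = np.load(directory / f"{stem}.npy")
        layout = ImageLayout.from_json((directory / f"{stem}.layout.json").read_text())
        sample_ids = json.loads((directory / f"{stem}.samples.json").read_text())
        return cls(sample_ids, images, layout)


def build_images(
    m: ExpressionMatrix,
    collection: PathwayCollection,
    patch_side: int = 7,
    grid_side: int = 7,
    normalize: bool = False,
) -> PathwayImageSet:
    """Assemble one pathway image per sample.

    ``m`` is expected to be already normalized; pass ``normalize=True`` to
    apply per-gene min-max scaling here. Genes in the collection but absent
    from the matrix are zero-filled; genes in the matrix but in no pathway
    are ignored.
    """
    if normalize:
        m = minmax_normalize(m)
    layout = build_layout(collection, patch_side=patch_side, grid_side=grid_side)
    n = len(m.sample_ids)
    side = layout.image_side
    images = np.zeros((n, side, side), dtype=float)

    gene_index = {g: j for j, g in enumerate(m.gene_ids)}
    s = patch_side
    for p in collection:
        r, c = layout.pathway_slots[p.name]
        # (n_samples, pad_len) block for this pathway, missing genes zero
        block = np.zeros((n, layout.pad_len), dtype=float)
        for k, g in enumerate(p.genes):
            j = gene_index.get(g)
            if j is not None:
                block[:, k] = m.values[:, j]
        images[:, r * s:(r + 1) * s, c * s:(c + 1) * s] = block.reshape(n, s, s)
    return PathwayImageSet(list(m.sample_ids), images, layout)


def extract_pathway_vector(images: PathwayImageSet, sample_id: str, pathway: str) -> np.ndarray:
    """Inverse lookup: read a pathway's padded vector back out of an image."""
    layout = images.layout
    i = images.sample_ids.index(sample_id)
    r, c = layout.pathway_slots[pathway]
    s = layout.patch_side
    patch = images.images[i, r * s:(r + 1) * s, c * s:(c + 1) * s]
    return patch.reshape(-1)
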