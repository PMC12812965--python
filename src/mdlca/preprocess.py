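"""Deterministic preprocessing of MRI volumes and gene-expression tables.

MRI side: skull-strip by mask multiplication (with morphological closing of
the mask), z-score intensities within the brain, and resample to a cubic
grid.  Genomic side: quality-control filtering, log2(x+1) normalization, and
construction of a gene-interaction graph from either co-expression
correlation or an explicit edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import (ConstantVolumeError, DegenerateMaskError,
                         DimensionError, EmptyPanelError)

__all__ = ["VolumeImage", "BrainMask", "PreprocessConfig", "ExpressionProfile",
           "GeneGraph", "load_volume", "save_volume", "load_mask",
           "fallback_brain_mask", "close_mask", "apply_brain_mask",
           "zscore_normalize", "resize_volume", "load_expression_table",
           "log_normalize_expression", "qc_filter", "build_gene_graph",
           "preprocess_volume"]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class VolumeImage:
    """A 3-D scalar intensity grid with voxel spacing (mm) and a patient id."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionError(
                f"volume must be 3-D with all dims >= 1, got {self.data.shape}")
        if np.isnan(self.data).any():
            raise ValueError(f"volume {self.id!r} contains NaN intensities")


@dataclass
class BrainMask:
    """Binary brain mask aligned voxel-for-voxel with its volume."""

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionError(f"mask must be 3-D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be binary, found {vals[:5]}")
        self.data = arr.astype(np.uint8)

    @property
    def n_brain_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class PreprocessConfig:
    target_side: int = 128
    closing_kernel: int = 3
    interpolation: str = "trilinear"  # or "nearest"
    min_brain_voxels: int = 10

    def __post_init__(self):
        if self.target_side < 4:
            raise ValueError("target_side must be >= 4")
        if self.closing_kernel not in (1, 3, 5):
            raise ValueError("closing_kernel must be one of {1, 3, 5}")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError("interpolation must be 'trilinear' or 'nearest'")
        if self.min_brain_voxels < 1:
            raise ValueError("min_brain_voxels must be positive")


@dataclass
class ExpressionProfile:
    """Per-patient gene-expression vector indexed by gene symbol."""

    values: pd.Series
    patient_id: str = ""

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=np.float64)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class GeneGraph:
    """Undirected gene-interaction graph with optional per-node features.

    Edges are stored once as (i, j) index pairs with i < j and no
    self-loops; node_features is an (N, F0) matrix or None until a patient's
    expression values are attached.
    """

    nodes: list[str]
    edges: set = field(default_factory=set)
    node_features: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("duplicate gene symbols in node list")
        canon = set()
        for i, j in self.edges:
            if i == j:
                continue  # self-loops are handled inside the GAT layer
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) endpoint out of range [0, {n})")
            canon.add((min(i, j), max(i, j)))
        self.edges = canon
        if self.node_features is not None:
            self.node_features = np.asarray(self.node_features, dtype=np.float64)
            if self.node_features.ndim == 1:
                self.node_features = self.node_features[:, None]
            if self.node_features.shape[0] != n:
                raise DimensionError("node_features row count != node count")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def with_features(self, profile: ExpressionProfile) -> "GeneGraph":
        """Attach one patient's expression values as (N, 1) node features."""
        feats = profile.values.reindex(self.nodes)
        if feats.isna().any():
            missing = feats.index[feats.isna()].tolist()
            raise KeyError(f"profile lacks genes: {missing[:5]}")
        return GeneGraph(nodes=list(self.nodes), edges=set(self.edges),
                         node_features=feats.to_numpy()[:, None])

    def edge_index(self, add_self_loops: bool = True) -> np.ndarray:
        """Directed (2, E) index array with both edge directions
        (and self-loops when requested) — the message-passing layout."""
        src, dst = [], []
        for i, j in sorted(self.edges):
            src += [i, j]
            dst += [j, i]
        if add_self_loops:
            for i in range(self.n_nodes):
                src.append(i)
                dst.append(i)
        return np.array([src, dst], dtype=np.intp)


# ---------------------------------------------------------------------------
# I/O

def load_volume(path: str, patient_id: str = "") -> VolumeImage:
    import nibabel as nib
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data=data, spacing=spacing, id=patient_id)


def save_volume(volume: VolumeImage, path: str) -> None:
    import nibabel as nib
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), path)


def load_mask(path: str) -> BrainMask:
    import nibabel as nib
    data = np.asarray(nib.load(path).get_fdata())
    return BrainMask(data=(data > 0.5).astype(np.uint8))


def save_mask(mask: BrainMask, path: str, spacing=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), path)


def load_expression_table(path: str, sep: str | None = None
                          ) -> list[ExpressionProfile]:
    """Read a genes x patients table (first column = gene symbol)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep, index_col=0)
    return [ExpressionProfile(values=table[col], patient_id=str(col))
            for col in table.columns]


# ---------------------------------------------------------------------------
# MRI operations

def fallback_brain_mask(volume: VolumeImage) -> BrainMask:
    """Otsu threshold + largest connected component.

    A stand-in mask generator for synthetic or toy volumes when no
    segmentation-derived mask is available.
    """
    from skimage.filters import threshold_otsu
    data = volume.data
    if np.ptp(data) == 0:
        raise ConstantVolumeError("cannot threshold a constant volume")
    fg = data > threshold_otsu(data)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise DegenerateMaskError("thresholding found no foreground voxels")
    largest = np.argmax(ndimage.sum_labels(fg, labels, range(1, n + 1))) + 1
    return BrainMask(data=(labels == largest).astype(np.uint8))


def close_mask(mask: BrainMask, kernel: int) -> BrainMask:
    """Morphological closing with a cubic structuring element."""
    if kernel == 1:
        return BrainMask(data=mask.data.copy())
    structure = np.ones((kernel,) * 3, dtype=bool)
    closed = ndimage.binary_closing(mask.data.astype(bool), structure=structure)
    return BrainMask(data=closed.astype(np.uint8))


def apply_brain_mask(volume: VolumeImage, mask: BrainMask,
                     cfg: PreprocessConfig | None = None) -> VolumeImage:
    """Skull-strip: morphologically close the mask, then multiply elementwise."""
    cfg = cfg or PreprocessConfig()
    if volume.data.shape != mask.data.shape:
        raise DimensionError(
            f"volume shape {volume.data.shape} != mask shape {mask.data.shape}")
    closed = close_mask(mask, cfg.closing_kernel)
    if closed.n_brain_voxels < cfg.min_brain_voxels:
        raise DegenerateMaskError(
            f"mask has {closed.n_brain_voxels} brain voxels "
            f"(< {cfg.min_brain_voxels})")
    return VolumeImage(data=volume.data * closed.data,
                       spacing=volume.spacing, id=volume.id)


def zscore_normalize(volume: VolumeImage, mask: BrainMask) -> VolumeImage:
    """Zero-mean, unit-sd intensities within the mask; zeros outside.

    Uses the sample standard deviation (ddof = 1) of the brain voxels.
    """
    if volume.data.shape != mask.data.shape:
        raise DimensionError("volume and mask shapes differ")
    brain = volume.data[mask.data == 1]
    if brain.size < 2:
        raise ConstantVolumeError("need >= 2 brain voxels to z-score")
    mu = brain.mean()
    sigma = brain.std(ddof=1)
    if sigma == 0:
        raise ConstantVolumeError("brain region is constant (sigma = 0)")
    out = np.zeros_like(volume.data)
    sel = mask.data == 1
    out[sel] = (volume.data[sel] - mu) / sigma
    return VolumeImage(data=out, spacing=volume.spacing, id=volume.id)


def resize_volume(volume: VolumeImage, cfg: PreprocessConfig) -> VolumeImage:
    """Resample to target_side^3 with half-pixel-center coordinate mapping."""
    s = cfg.target_side
    if volume.data.shape == (s, s, s):
        return VolumeImage(data=volume.data.copy(), spacing=volume.spacing,
                           id=volume.id)
    coords = np.meshgrid(*[
        (np.arange(s) + 0.5) * (n / s) - 0.5 for n in volume.data.shape],
        indexing="ij")
    order = 1 if cfg.interpolation == "trilinear" else 0
    data = ndimage.map_coordinates(volume.data, np.array(coords), order=order,
                                   mode="nearest")
    new_spacing = tuple(sp * n / s
                        for sp, n in zip(volume.spacing, volume.data.shape))
    return VolumeImage(data=data, spacing=new_spacing, id=volume.id)


def preprocess_volume(volume: VolumeImage, mask: BrainMask | None,
                      cfg: PreprocessConfig | None = None) -> VolumeImage:
    """Full MRI path: mask (fallback if absent) -> z-score -> resize."""
    cfg = cfg or PreprocessConfig()
    if mask is None:
        mask = fallback_brain_mask(volume)
    stripped = apply_brain_mask(volume, mask, cfg)
    closed = close_mask(mask, cfg.closing_kernel)
    normed = zscore_normalize(stripped, closed)
    return resize_volume(normed, cfg)


# ---------------------------------------------------------------------------
# genomic operations

def log_normalize_expression(profile: ExpressionProfile) -> ExpressionProfile:
    """log2(x + 1) on every expression value."""
    vals = profile.values
    if (vals < 0).any():
        bad = vals.index[vals < 0].tolist()
        raise ValueError(f"negative expression values for genes {bad[:5]}")
    return ExpressionProfile(values=np.log2(vals + 1.0),
                             patient_id=profile.patient_id)


def qc_filter(profiles: list[ExpressionProfile], max_missing_frac: float = 0.2,
              min_variance: float = 1e-8) -> list[ExpressionProfile]:
    """Drop genes with too many missing values or near-zero cross-patient
    variance; impute remaining missing values by the gene-wise median."""
    if not profiles:
        return []
    index = profiles[0].values.index
    for p in profiles[1:]:
        if not p.values.index.equals(index):
            raise ValueError("profiles do not share a gene index")
    table = pd.DataFrame({p.patient_id or i: p.values
                          for i, p in enumerate(profiles)})
    missing_frac = table.isna().mean(axis=1)
    variance = table.var(axis=1, ddof=0)
    keep = (missing_frac <= max_missing_frac) & \
           (variance.fillna(0.0) >= min_variance)
    if not keep.any():
        raise EmptyPanelError("QC removed every gene from the panel")
    table = table.loc[keep]
    medians = table.median(axis=1)
    table = table.apply(lambda col: col.fillna(medians))
    return [ExpressionProfile(values=table[col], patient_id=p.patient_id)
            for col, p in zip(table.columns, profiles)]


def build_gene_graph(profiles: list[ExpressionProfile],
                     edge_source: str = "correlation",
                     corr_threshold: float = 0.7,
                     edge_list: list[tuple[str, str]] | None = None
                     ) -> GeneGraph:
    """Gene-interaction graph from co-expression or an explicit edge list.

    Correlation mode links genes i != j when |Pearson r| >= corr_threshold
    across patients; a zero-variance gene simply receives no correlation
    edges.  Edge-list mode takes symbol pairs verbatim (deduplicated).
    """
    if not profiles:
        raise ValueError("at least one profile required")
    genes = profiles[0].genes
    n = len(genes)
    edges: set = set()
    if edge_source == "correlation":
        if len(profiles) < 2:
            raise ValueError("correlation mode needs >= 2 patients")
        mat = np.stack([p.values.reindex(genes).to_numpy() for p in profiles],
                       axis=1)  # genes x patients
        sd = mat.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(mat)
        r = np.nan_to_num(r, nan=0.0)  # zero-variance rows get no edges
        ii, jj = np.where(np.abs(np.triu(r, k=1)) >= corr_threshold)
        ok = (sd[ii] > 0) & (sd[jj] > 0)
        edges = {(int(i), int(j)) for i, j in zip(ii[ok], jj[ok])}
    elif edge_source == "edge_list":
        if edge_list is None:
            raise ValueError("edge_list mode requires an edge list")
        lookup = {g: i for i, g in enumerate(genes)}
        for a, b in edge_list:
            if a not in lookup or b not in lookup:
                raise KeyError(f"unknown gene symbol in edge ({a!r}, {b!r})")
            i, j = lookup[a], lookup[b]
            if i != j:
                edges.add((min(i, j), max(i, j)))
    else:
        raise ValueError(f"unknown edge_source {edge_source!r}")
    return GeneGraph(nodes=genes, edges=edges)


def load_edge_list(path: str) -> list[tuple[str, str]]:
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(a), str(b)) for a, b in zip(table[0], table[1])]
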