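"""3D RNA-FISH focus counting.

Re-implements a batch confocal-stack pipeline for counting resolvable XIST
RNA foci per nucleus: nuclei are segmented from the DAPI channel slice by
slice (Gaussian blur, Otsu threshold, hole filling), linked into 3D objects
and filtered against the lateral image border; RNA-FISH particles are
segmented with a single Otsu threshold over the 3D volume, assigned to
nuclei by maximal voxel overlap, and summarized per nucleus (focus count,
total focus volume, mean nearest-neighbour distance).

All physical measurements honour anisotropic voxel spacing, given as
``(dz, dy, dx)`` in micrometres; arrays are indexed ``(z, y, x)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack3D",
    "SegmentationParams",
    "NucleusObject",
    "FocusObject",
    "NucleusSummary",
    "otsu_threshold",
    "otsu_threshold_array",
    "segment_nuclei",
    "segment_foci",
    "assign_foci",
    "pairwise_distances",
    "summarize_nuclei",
    "process_stack",
    "batch_process",
]

UNASSIGNED = "unassigned"

#: connectivity name -> rank passed to scipy.ndimage.generate_binary_structure
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ImageStack3D:
    """A multi-channel confocal stack.

    voxels
        Intensity array of shape ``(n_z, n_y, n_x, n_channels)``.
    spacing
        Voxel size ``(dz, dy, dx)`` in micrometres; all strictly positive.
    channel_names
        One label per channel, e.g. ``["dapi", "fish"]``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (z, y, x, channel)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[3])]
        if len(self.channel_names) != self.voxels.shape[3]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def channel(self, index: int) -> np.ndarray:
        return self.voxels[..., index]


@dataclass
class SegmentationParams:
    """Tunable knobs of the counting pipeline.

    ``blur_sigma_px`` is the lateral Gaussian sigma applied to each DAPI
    slice before thresholding; minimum volumes are in voxels; connectivity
    is the 3D neighbourhood (6, 18 or 26). ``fish_threshold_mode``:
    ``"global"`` thresholds the whole FISH volume once (default),
    ``"per_slice"`` mirrors the nucleus-channel treatment.
    ``assignment_rule``: ``"overlap"`` assigns a focus to the nucleus with
    maximal voxel overlap; ``"centroid"`` uses centroid containment.
    """

    blur_sigma_px: float = 2.0
    min_nucleus_volume_vox: int = 500
    min_focus_volume_vox: int = 2
    connectivity: int = 26
    assignment_rule: str = "overlap"
    fish_threshold_mode: str = "global"
    min_slice_overlap: float = 0.0  # optional overlap fraction for z-linking

    def __post_init__(self) -> None:
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")
        if self.min_nucleus_volume_vox < 1 or self.min_focus_volume_vox < 1:
            raise ValueError("minimum volumes must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.assignment_rule not in ("overlap", "centroid"):
            raise ValueError("assignment_rule must be 'overlap' or 'centroid'")
        if self.fish_threshold_mode not in ("global", "per_slice"):
            raise ValueError("fish_threshold_mode must be 'global' or 'per_slice'")


@dataclass
class NucleusObject:
    """A retained 3D nucleus component."""

    label: int
    volume_vox: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    touches_xy_edge: bool
    label_volume: np.ndarray = field(repr=False)


@dataclass
class FocusObject:
    """A segmented RNA-FISH particle."""

    label: int
    volume_vox: int
    centroid_um: tuple[float, float, float]
    integrated_intensity: float
    voxel_indices: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )
    assigned_nucleus: int | str = UNASSIGNED


@dataclass
class NucleusSummary:
    nucleus_id: int
    n_foci: int
    total_focus_volume_vox: int
    mean_nn_um: float | None  # undefined (None) when fewer than 2 foci


def otsu_threshold(counts: np.ndarray, values: np.ndarray | None = None) -> float:
    """Otsu threshold of an intensity histogram.

    Returns the bin value ``t`` maximizing the between-class variance of the
    two classes ``value <= t`` and ``value > t``; foreground is therefore
    ``intensity > t``. For a single-valued histogram the threshold equals
    that value (empty foreground). Ties are broken toward the lowest
    threshold, which is deterministic.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if values is None:
        values = np.arange(counts.size, dtype=np.float64)
    else:
        values = np.asarray(values, dtype=np.float64)
    nz = counts > 0
    if not nz.any():
        raise ValueError("histogram has no nonzero bin")
    counts, values = counts[nz], values[nz]
    order = np.argsort(values)
    counts, values = counts[order], values[order]
    if counts.size == 1:
        return float(values[0])

    w0 = np.cumsum(counts)
    total = w0[-1]
    w1 = total - w0
    csum = np.cumsum(counts * values)
    # candidate cuts place bins [0..i] in class 0; last cut is degenerate
    valid = slice(0, counts.size - 1)
    mu0 = csum[valid] / w0[valid]
    mu1 = (csum[-1] - csum[valid]) / w1[valid]
    between = w0[valid] * w1[valid] * (mu0 - mu1) ** 2
    return float(values[int(np.argmax(between))])


def otsu_threshold_array(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of an intensity array via its histogram."""
    image = np.asarray(image)
    flat = image.ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(flat, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    return otsu_threshold(counts, centers)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def _touches_xy_edge(mask_indices, shape_zyx) -> bool:
    _, yy, xx = mask_indices
    n_y, n_x = shape_zyx[1], shape_zyx[2]
    return bool(
        (yy == 0).any() or (yy == n_y - 1).any() or (xx == 0).any() or (xx == n_x - 1).any()
    )


def segment_nuclei(
    stack: ImageStack3D,
    dapi_channel: int,
    params: SegmentationParams | None = None,
) -> list[NucleusObject]:
    """Segment nuclei from the DAPI channel.

    Each z-slice is Gaussian-blurred and thresholded with Otsu on its own
    histogram, with the threshold floored at the Otsu threshold of the whole
    blurred volume so that slices containing no nucleus (background noise
    only) contribute no foreground; holes are filled per slice. Slice masks
    are linked into 3D connected components; components touching the lateral
    (x/y) image border anywhere, and components below
    ``min_nucleus_volume_vox``, are discarded.
    """
    params = params or SegmentationParams()
    dapi = stack.channel(dapi_channel).astype(np.float64)
    n_z = dapi.shape[0]

    blurred = np.empty_like(dapi)
    for z in range(n_z):
        blurred[z] = ndimage.gaussian_filter(dapi[z], sigma=params.blur_sigma_px)

    if blurred.min() == blurred.max():
        return []
    global_t = otsu_threshold_array(blurred)

    mask = np.zeros(dapi.shape, dtype=bool)
    for z in range(n_z):
        sl = blurred[z]
        if sl.min() == sl.max():
            continue  # zero-contrast slice: no foreground
        t = max(otsu_threshold_array(sl), global_t)
        m = sl > t
        if m.any():
            mask[z] = ndimage.binary_fill_holes(m)

    labels, n_labels = ndimage.label(mask, structure=_structure(params.connectivity))
    if n_labels == 0:
        return []

    dz, dy, dx = stack.spacing
    voxel_um3 = dz * dy * dx
    out_labels = np.zeros_like(labels)
    nuclei: list[NucleusObject] = []
    kept = 0
    for lab in range(1, n_labels + 1):
        idx = np.nonzero(labels == lab)
        vol = idx[0].size
        if vol < params.min_nucleus_volume_vox:
            continue
        if _touches_xy_edge(idx, dapi.shape):
            continue
        kept += 1
        out_labels[idx] = kept
        centroid = (
            float(idx[0].mean() * dz),
            float(idx[1].mean() * dy),
            float(idx[2].mean() * dx),
        )
        nuclei.append(
            NucleusObject(
                label=kept,
                volume_vox=int(vol),
                volume_um3=float(vol * voxel_um3),
                centroid_um=centroid,
                touches_xy_edge=False,
                label_volume=out_labels,
            )
        )
    return nuclei


def segment_foci(
    stack: ImageStack3D,
    fish_channel: int,
    params: SegmentationParams | None = None,
) -> list[FocusObject]:
    """Segment RNA-FISH particles.

    One global Otsu threshold over the whole 3D FISH volume (default), 3D
    connected components at the configured connectivity, and a minimum
    volume filter. ``fish_threshold_mode="per_slice"`` switches to
    slice-wise thresholding for comparison.
    """
    params = params or SegmentationParams()
    fish = stack.channel(fish_channel).astype(np.float64)
    if fish.min() == fish.max():
        return []

    if params.fish_threshold_mode == "global":
        t = otsu_threshold_array(fish)
        mask = fish > t
    else:
        mask = np.zeros(fish.shape, dtype=bool)
        for z in range(fish.shape[0]):
            sl = fish[z]
            if sl.min() == sl.max():
                continue
            mask[z] = sl > otsu_threshold_array(sl)
    if not mask.any():
        return []

    labels, n_labels = ndimage.label(mask, structure=_structure(params.connectivity))
    dz, dy, dx = stack.spacing
    foci: list[FocusObject] = []
    next_label = 0
    for lab in range(1, n_labels + 1):
        idx = np.nonzero(labels == lab)
        if idx[0].size < params.min_focus_volume_vox:
            continue
        next_label += 1
        centroid = (
            float(idx[0].mean() * dz),
            float(idx[1].mean() * dy),
            float(idx[2].mean() * dx),
        )
        foci.append(
            FocusObject(
                label=next_label,
                volume_vox=int(idx[0].size),
                centroid_um=centroid,
                integrated_intensity=float(fish[idx].sum()),
                voxel_indices=idx,
            )
        )
    return foci


def assign_foci(
    foci: Sequence[FocusObject],
    nuclei: Sequence[NucleusObject],
    rule: str = "overlap",
    spacing: tuple[float, float, float] | None = None,
) -> list[FocusObject]:
    """Assign each focus to a nucleus.

    ``overlap`` (default): the nucleus whose mask shares the most voxels
    with the focus; ties broken toward the smaller nucleus label; zero
    overlap leaves the focus ``"unassigned"``. ``centroid``: the nucleus
    containing the focus centroid voxel.
    """
    if not nuclei:
        for f in foci:
            f.assigned_nucleus = UNASSIGNED
        return list(foci)
    label_volume = nuclei[0].label_volume
    for f in foci:
        zz, yy, xx = f.voxel_indices
        if zz.size and (
            zz.max() >= label_volume.shape[0]
            or yy.max() >= label_volume.shape[1]
            or xx.max() >= label_volume.shape[2]
        ):
            raise ValueError("focus voxels outside nucleus label volume: mismatched stacks")
        if rule == "centroid":
            if spacing is None:
                raise ValueError("centroid rule requires spacing")
            dz, dy, dx = spacing
            cz, cy, cx = f.centroid_um
            vz, vy, vx = int(round(cz / dz)), int(round(cy / dy)), int(round(cx / dx))
            lab = int(label_volume[vz, vy, vx])
            f.assigned_nucleus = lab if lab > 0 else UNASSIGNED
            continue
        hit = label_volume[zz, yy, xx]
        hit = hit[hit > 0]
        if hit.size == 0:
            f.assigned_nucleus = UNASSIGNED
            continue
        labs, cnt = np.unique(hit, return_counts=True)
        best = cnt.max()
        f.assigned_nucleus = int(labs[cnt == best].min())  # tie -> smaller label
    return list(foci)


def pairwise_distances(
    foci: Sequence[FocusObject],
    spacing: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Pairwise Euclidean centroid distances in micrometres.

    Centroids are already physical coordinates; ``spacing`` is accepted for
    interface symmetry and ignored. Symmetric with zero diagonal.
    """
    if not foci:
        raise ValueError("need at least one focus")
    pts = np.array([f.centroid_um for f in foci], dtype=np.float64)
    d = cdist(pts, pts)
    np.fill_diagonal(d, 0.0)
    return d


def summarize_nuclei(
    nuclei: Sequence[NucleusObject],
    foci: Sequence[FocusObject],
    distances: np.ndarray | None = None,
) -> tuple[list[NucleusSummary], int]:
    """Per-nucleus focus count, total volume and mean NN distance.

    Returns ``(summaries, n_unassigned)``; the counts conserve the focus
    total: sum of per-nucleus counts plus unassigned equals ``len(foci)``.
    """
    if distances is None and foci:
        distances = pairwise_distances(foci)
    by_nucleus: dict[int, list[int]] = {n.label: [] for n in nuclei}
    n_unassigned = 0
    for i, f in enumerate(foci):
        if f.assigned_nucleus == UNASSIGNED:
            n_unassigned += 1
        else:
            by_nucleus.setdefault(int(f.assigned_nucleus), []).append(i)

    summaries = []
    for n in nuclei:
        members = by_nucleus.get(n.label, [])
        mean_nn = None
        if len(members) >= 2:
            sub = distances[np.ix_(members, members)].astype(np.float64).copy()
            np.fill_diagonal(sub, np.inf)
            mean_nn = float(sub.min(axis=1).mean())
        summaries.append(
            NucleusSummary(
                nucleus_id=n.label,
                n_foci=len(members),
                total_focus_volume_vox=int(sum(foci[i].volume_vox for i in members)),
                mean_nn_um=mean_nn,
            )
        )
    return summaries, n_unassigned


def process_stack(
    stack: ImageStack3D,
    dapi_channel: int = 0,
    fish_channel: int = 1,
    params: SegmentationParams | None = None,
) -> tuple[list[NucleusSummary], list[NucleusObject], list[FocusObject], int]:
    """Full single-stack pipeline: segment, assign, summarize."""
    params = params or SegmentationParams()
    nuclei = segment_nuclei(stack, dapi_channel, params)
    foci = segment_foci(stack, fish_channel, params)
    assign_foci(foci, nuclei, rule=params.assignment_rule, spacing=stack.spacing)
    distances = pairwise_distances(foci) if foci else None
    summaries, n_unassigned = summarize_nuclei(nuclei, foci, distances)
    return summaries, nuclei, foci, n_unassigned


def _summary_rows(image_id, genotype, replicate, summaries, nuclei):
    vol = {n.label: n.volume_um3 for n in nuclei}
    for s in summaries:
        yield {
            "image_id": image_id,
            "nucleus_id": s.nucleus_id,
            "n_foci": s.n_foci,
            "volume_um3": vol[s.nucleus_id],
            "mean_nn_um": s.mean_nn_um if s.mean_nn_um is not None else np.nan,
            "genotype": genotype,
            "replicate": replicate,
        }


def summaries_to_table(
    per_image: Sequence[tuple[str, str, object, Sequence[NucleusSummary], Sequence[NucleusObject]]],
) -> pd.DataFrame:
    """Pool per-image summaries into the long per-nucleus table."""
    rows = []
    for image_id, genotype, replicate, summaries, nuclei in per_image:
        rows.extend(_summary_rows(image_id, genotype, replicate, summaries, nuclei))
    cols = ["image_id", "nucleus_id", "n_foci", "volume_um3", "mean_nn_um", "genotype", "replicate"]
    return pd.DataFrame(rows, columns=cols)


def _load_stack(path: Path, spacing, channel_axis: str = "last") -> ImageStack3D:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[..., np.newaxis]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected 3 or 4 dimensional TIFF, got shape {arr.shape}")
    if channel_axis == "first":
        arr = np.moveaxis(arr, 0, -1)
    return ImageStack3D(voxels=arr, spacing=tuple(spacing))


def batch_process(
    manifest: str | Path | pd.DataFrame,
    params: SegmentationParams | None = None,
    spacing: tuple[float, float, float] = (0.2, 0.1, 0.1),
    channel_axis: str = "first",
) -> tuple[pd.DataFrame, dict]:
    """Unsupervised batch run over a manifest of stacks.

    ``manifest`` is a CSV (or DataFrame) with columns
    ``path, genotype, replicate, dapi_channel, fish_channel``. Unreadable or
    ill-shaped files are logged and skipped; the run log reports them and
    the pooled per-nucleus table tags every row with image id, genotype and
    replicate, in manifest order.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    params = params or SegmentationParams()
    per_image = []
    log = {"n_images": 0, "n_failed": 0, "failed": [], "n_unassigned_foci": 0}
    if manifest.empty:
        logger.warning("empty manifest: no images to process")
    for _, row in manifest.iterrows():
        log["n_images"] += 1
        try:
            stack = _load_stack(Path(row["path"]), spacing, channel_axis)
            summaries, nuclei, _, n_un = process_stack(
                stack, int(row["dapi_channel"]), int(row["fish_channel"]), params
            )
        except Exception as exc:  # deliberate: skip-and-log batch semantics
            logger.error("failed to process %s: %s", row["path"], exc)
            log["n_failed"] += 1
            log["failed"].append(str(row["path"]))
            continue
        log["n_unassigned_foci"] += n_un
        per_image.append((str(row["path"]), row["genotype"], row["replicate"], summaries, nuclei))
    table = summaries_to_table(per_image)
    log["n_nuclei"] = int(len(table))
    log["params"] = {
        "blur_sigma_px": params.blur_sigma_px,
        "min_nucleus_volume_vox": params.min_nucleus_volume_vox,
        "min_focus_volume_vox": params.min_focus_volume_vox,
        "connectivity": params.connectivity,
        "assignment_rule": params.assignment_rule,
        "fish_threshold_mode": params.fish_threshold_mode,
        "spacing_um": list(spacing),
    }
    return table, log


def write_run(table: pd.DataFrame, log: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "per_nucleus.tsv", sep="\t", index=False)
    (out / "run_metadata.json").write_text(json.dumps(log, indent=2))
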