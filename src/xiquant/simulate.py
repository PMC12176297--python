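"""Synthetic data generators with known ground truth.

Every input the analysis pipelines consume can be simulated here, seeded
and reproducible:

* two-channel 3D nuclei stacks (DAPI-like fill + RNA-FISH puncta under a
  Gaussian PSF with Poisson photon noise and Gaussian read noise), with
  per-nucleus ground truth including the number of *resolvable* foci —
  puncta merged by single linkage at twice the lateral PSF sigma;
* FRAP traces following a single-exponential recovery with configurable
  half-time, immobile fraction and bleach depth, at the acquisition
  protocol of the imaging experiments (10 pre-bleach frames, 65 ms frame
  interval, 30 s of post-bleach acquisition);
* allele-specific count tables (DNA validation SNPs plus expression
  libraries) with autosomal balance, strong inactive-X skew, escape genes
  and a planted set of biased SNPs;
* random nucleotide sequence sets with a planted motif.

The ``wt`` image preset keeps ~95% of puncta inside a tight Xi-like
territory; the ``depleted`` preset disperses enough puncta that the mean
ground-truth resolvable focus count doubles (calibrated numerically).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .foci import ImageStack3D
from .frap import FrapTrace

__all__ = [
    "ImageSimParams",
    "NucleusTruth",
    "GroundTruth",
    "FrapSimParams",
    "AlleleSimParams",
    "PlacementError",
    "resolvable_count",
    "sim_image_population",
    "sim_frap_traces",
    "sim_allele_tables",
    "sim_reactivation_tables",
    "sim_sequences",
    "preset_image_params",
    "calibrate_dispersed_fraction",
]


class PlacementError(RuntimeError):
    """Raised when a nucleus cannot be placed fully inside the field."""


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclass
class ImageSimParams:
    """Geometry, optics and noise of the synthetic confocal stacks.

    Lengths are micrometres. ``psf_sigma`` is ``(lateral, axial)``;
    ``dispersed_fraction`` is the per-punctum probability of being placed
    uniformly in the nucleus rather than inside the Xi-like territory
    sphere. ``photon_scale`` is the peak photon count of one punctum;
    ``dapi_scale`` the photon rate inside the nucleus in the DAPI channel;
    ``full_well`` clips the recorded counts, emulating a 12-bit detector
    with the gain set high enough to render single transcripts at roughly
    half range (the dense Xi territory therefore saturates, as it does in
    single-molecule-sensitive acquisitions). Set ``full_well <= 0`` to
    disable clipping.
    """

    stack_shape: tuple[int, int, int] = (64, 256, 256)
    spacing: tuple[float, float, float] = (0.2, 0.1, 0.1)
    n_nuclei: int = 4
    nucleus_radii: tuple[float, float] = (3.0, 4.0)
    n_puncta: int = 50
    territory_radius: float = 0.35
    dispersed_fraction: float = 0.05
    psf_sigma: tuple[float, float] = (0.12, 0.16)
    photon_scale: float = 3000.0
    dapi_scale: float = 1000.0
    background: float = 100.0
    read_noise_sd: float = 10.0
    full_well: float = 4095.0
    edge_nucleus: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dispersed_fraction <= 1.0:
            raise ValueError("dispersed_fraction must be in [0, 1]")
        if min(self.nucleus_radii) <= 0 or self.territory_radius <= 0:
            raise ValueError("radii must be positive")
        if min(self.psf_sigma) <= 0:
            raise ValueError("psf_sigma must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        n_z, n_y, n_x = self.stack_shape
        dz, dy, dx = self.spacing
        a_max = max(self.nucleus_radii)
        if 2 * a_max >= (n_y - 2) * dy or 2 * a_max >= (n_x - 2) * dx or 2 * a_max >= n_z * dz:
            raise PlacementError(
                "stack too small to hold one nucleus clear of the XY border"
            )

    @property
    def merge_distance(self) -> float:
        """Single-linkage cutoff defining a resolvable focus (2 x lateral sigma)."""
        return 2.0 * self.psf_sigma[0]


@dataclass
class NucleusTruth:
    label: int
    centroid_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    puncta_um: np.ndarray  # (n, 3) in (z, y, x) micrometres
    n_resolvable: int
    touches_edge: bool = False


@dataclass
class GroundTruth:
    """Per-image truth: nucleus label volume plus per-nucleus records."""

    label_volume: np.ndarray
    nuclei: list[NucleusTruth] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "label": n.label,
                    "centroid_um": list(n.centroid_um),
                    "semi_axes_um": list(n.semi_axes_um),
                    "puncta_um": n.puncta_um.tolist(),
                    "n_resolvable": n.n_resolvable,
                    "touches_edge": n.touches_edge,
                }
                for n in self.nuclei
            ],
            indent=2,
        )


def resolvable_count(coords_um: np.ndarray, merge_distance: float) -> int:
    """Number of single-linkage clusters at the given distance cutoff.

    Two puncta closer than ``merge_distance`` cannot be resolved as
    separate foci; resolvable foci are the connected components of the
    "closer than cutoff" graph.
    """
    coords_um = np.asarray(coords_um, dtype=np.float64)
    n = coords_um.shape[0]
    if n == 0:
        return 0
    if n == 1:
        return 1
    adj = squareform(pdist(coords_um)) < merge_distance
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return int(n_comp)


def _sample_nuclei_geometry(params: ImageSimParams, rng: np.random.Generator):
    """Place non-overlapping ellipsoids fully inside the field (XY margin >=
    one voxel); optionally add one ellipsoid crossing the x = 0 border."""
    n_z, n_y, n_x = params.stack_shape
    dz, dy, dx = params.spacing
    extent = (n_z * dz, n_y * dy, n_x * dx)
    r_lo, r_hi = params.nucleus_radii

    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(params.n_nuclei):
        ok = False
        for _attempt in range(5000):
            axes = rng.uniform(r_lo, r_hi, size=3)
            # clearance: blur can spread the mask ~8 voxels toward the border
            lo = axes + np.array([0.0, 8 * dy, 8 * dx])
            hi = np.array(extent) - lo
            if np.any(hi <= lo):
                continue
            center = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(center - c0) > axes.max() + a0.max() + 1.0
                for c0, a0 in placed
            ):
                placed.append((center, axes))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place {params.n_nuclei} non-overlapping nuclei "
                f"in a {extent} um field"
            )
    edge = []
    if params.edge_nucleus:
        axes = rng.uniform(r_lo, r_hi, size=3)
        cz = rng.uniform(axes[0], extent[0] - axes[0])
        cy = rng.uniform(axes[1], extent[1] - axes[1])
        edge.append((np.array([cz, cy, 0.0]), axes))  # crosses x = 0
    return placed, edge


def _ellipsoid_mask_into(label_volume, center, axes, spacing, label) -> None:
    dz, dy, dx = spacing
    shape = label_volume.shape
    lo = [max(0, int((center[i] - axes[i]) / spacing[i]) - 1) for i in range(3)]
    hi = [min(shape[i], int((center[i] + axes[i]) / spacing[i]) + 2) for i in range(3)]
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) + 0.5) * dz,
        (np.arange(lo[1], hi[1]) + 0.5) * dy,
        (np.arange(lo[2], hi[2]) + 0.5) * dx,
        indexing="ij",
    )
    inside = (
        ((zz - center[0]) / axes[0]) ** 2
        + ((yy - center[1]) / axes[1]) ** 2
        + ((xx - center[2]) / axes[2]) ** 2
    ) <= 1.0
    sub = label_volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside] = label


def _inside_ellipsoid(p, center, axes) -> bool:
    return float(np.sum(((p - center) / axes) ** 2)) <= 1.0


def _sample_puncta(params: ImageSimParams, center, axes, rng) -> np.ndarray:
    """Sample punctum coordinates: territory sphere vs uniform in nucleus."""
    # territory centre drawn from the shrunken ellipsoid so the sphere fits
    shrink = np.maximum(axes - params.territory_radius, 1e-3)
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) <= 1.0:
            terr_center = center + u * shrink
            break
    pts = np.empty((params.n_puncta, 3))
    for i in range(params.n_puncta):
        dispersed = rng.random() < params.dispersed_fraction
        for _ in range(10000):
            if dispersed:
                u = rng.uniform(-1.0, 1.0, size=3)
                if np.sum(u**2) > 1.0:
                    continue
                p = center + u * axes
            else:
                u = rng.uniform(-1.0, 1.0, size=3)
                if np.sum(u**2) > 1.0:
                    continue
                p = terr_center + u * params.territory_radius
            if _inside_ellipsoid(p, center, axes):
                pts[i] = p
                break
        else:  # pragma: no cover - rejection sampling practically never fails
            pts[i] = terr_center
    return pts


def _render_puncta(signal: np.ndarray, puncta_um: np.ndarray, params: ImageSimParams) -> None:
    """Add a Gaussian blob of peak ``photon_scale`` per punctum, in place."""
    dz, dy, dx = params.spacing
    s_lat, s_ax = params.psf_sigma
    sig_vox = np.array([s_ax / dz, s_lat / dy, s_lat / dx])
    half = np.ceil(4 * sig_vox).astype(int)
    shape = signal.shape
    for p in puncta_um:
        c_vox = np.array([p[0] / dz, p[1] / dy, p[2] / dx])
        lo = np.maximum(np.floor(c_vox - half).astype(int), 0)
        hi = np.minimum(np.ceil(c_vox + half).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        zz = (np.arange(lo[0], hi[0]) + 0.5) - (c_vox[0] + 0.5) + 0.5
        yy = (np.arange(lo[1], hi[1]) + 0.5) - (c_vox[1] + 0.5) + 0.5
        xx = (np.arange(lo[2], hi[2]) + 0.5) - (c_vox[2] + 0.5) + 0.5
        gz = np.exp(-0.5 * ((np.arange(lo[0], hi[0]) + 0.5 - c_vox[0]) / sig_vox[0]) ** 2)
        gy = np.exp(-0.5 * ((np.arange(lo[1], hi[1]) + 0.5 - c_vox[1]) / sig_vox[1]) ** 2)
        gx = np.exp(-0.5 * ((np.arange(lo[2], hi[2]) + 0.5 - c_vox[2]) / sig_vox[2]) ** 2)
        signal[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            params.photon_scale * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )


def sim_image_population(
    params: ImageSimParams, n_cells: int, seed: int
) -> tuple[list[ImageStack3D], list[GroundTruth]]:
    """Simulate ``n_cells`` two-channel stacks with matching ground truth.

    Channel 0 is a DAPI-like nuclear fill, channel 1 the RNA-FISH puncta;
    both are PSF-blurred, Poisson photon noise is applied to the expected
    photon signal, then the background offset and Gaussian read noise are
    added. The same seed gives bit-identical output.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    dz, dy, dx = params.spacing
    s_lat, s_ax = params.psf_sigma
    sig_vox = (s_ax / dz, s_lat / dy, s_lat / dx)

    stacks: list[ImageStack3D] = []
    truths: list[GroundTruth] = []
    for _ in range(n_cells):
        placed, edge = _sample_nuclei_geometry(params, rng)
        label_volume = np.zeros(params.stack_shape, dtype=np.int16)
        nuclei: list[NucleusTruth] = []
        fish_signal = np.zeros(params.stack_shape, dtype=np.float64)
        for i, ((center, axes), is_edge) in enumerate(
            [(p, False) for p in placed] + [(e, True) for e in edge]
        ):
            label = i + 1
            _ellipsoid_mask_into(label_volume, center, axes, params.spacing, label)
            pts = _sample_puncta(params, center, axes, rng)
            _render_puncta(fish_signal, pts, params)
            nuclei.append(
                NucleusTruth(
                    label=label,
                    centroid_um=tuple(float(v) for v in center),
                    semi_axes_um=tuple(float(v) for v in axes),
                    puncta_um=pts,
                    n_resolvable=resolvable_count(pts, params.merge_distance),
                    touches_edge=is_edge,
                )
            )
        dapi_signal = ndimage.gaussian_filter(
            (label_volume > 0).astype(np.float64) * params.dapi_scale, sigma=sig_vox
        )
        chans = []
        for signal in (dapi_signal, fish_signal):
            ch = rng.poisson(signal).astype(np.float64)
            ch += params.background
            if params.read_noise_sd > 0:
                ch += rng.normal(0.0, params.read_noise_sd, size=ch.shape)
            if params.full_well > 0:
                np.clip(ch, None, params.full_well, out=ch)
            chans.append(ch.astype(np.float32))
        voxels = np.stack(chans, axis=-1)
        stacks.append(
            ImageStack3D(voxels=voxels, spacing=params.spacing, channel_names=["dapi", "fish"])
        )
        truths.append(GroundTruth(label_volume=label_volume, nuclei=nuclei))
    return stacks, truths


def _mean_resolvable(params: ImageSimParams, n_nuclei: int, seed: int) -> float:
    """Geometry-only mean resolvable count (no rendering; used for calibration)."""
    rng = np.random.default_rng(seed)
    extent_z = params.stack_shape[0] * params.spacing[0]
    counts = []
    r_lo, r_hi = params.nucleus_radii
    for _ in range(n_nuclei):
        axes = rng.uniform(r_lo, r_hi, size=3)
        center = np.array([extent_z / 2, 10.0, 10.0])
        pts = _sample_puncta(params, center, axes, rng)
        counts.append(resolvable_count(pts, params.merge_distance))
    return float(np.mean(counts))


def calibrate_dispersed_fraction(
    base: ImageSimParams,
    target_ratio: float = 2.0,
    n_nuclei: int = 400,
    seed: int = 20240901,
    tol: float = 0.02,
) -> float:
    """Dispersed fraction whose mean resolvable count is ``target_ratio``
    times the base preset's, found by bisection on a common-random-numbers
    geometry simulation (monotone in the dispersed fraction)."""
    base_mean = _mean_resolvable(base, n_nuclei, seed)
    target = target_ratio * base_mean

    def mean_at(f: float) -> float:
        return _mean_resolvable(replace(base, dispersed_fraction=f), n_nuclei, seed)

    lo, hi = base.dispersed_fraction, 1.0
    if mean_at(hi) < target:
        raise ValueError("target ratio unreachable even at full dispersion")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m = mean_at(mid)
        if abs(m - target) <= tol * target:
            return mid
        if m < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@lru_cache(maxsize=8)
def _calibrated_depleted_fraction(wt_fraction: float) -> float:
    base = ImageSimParams(dispersed_fraction=wt_fraction)
    return calibrate_dispersed_fraction(base)


def preset_image_params(name: str) -> ImageSimParams:
    """Shipping presets: ``wt`` (tight territory, 5% dispersed) and
    ``depleted`` (dispersion calibrated to double the mean ground-truth
    resolvable focus count, emulating loss of XIST anchoring)."""
    if name == "wt":
        return ImageSimParams(dispersed_fraction=0.05)
    if name == "depleted":
        return ImageSimParams(dispersed_fraction=_calibrated_depleted_fraction(0.05))
    raise KeyError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# FRAP simulation
# ---------------------------------------------------------------------------

@dataclass
class FrapSimParams:
    """Single-exponential recovery with plateau
    ``F_inf = F0 + (1 - immobile_fraction) * (1 - F0)``."""

    t_half: float = 2.58
    immobile_fraction: float = 0.18
    bleach_depth: float = 0.2  # normalized first post-bleach intensity F0
    n_prebleach: int = 10
    frame_interval: float = 0.065
    duration_post: float = 30.0
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.t_half <= 0 or self.frame_interval <= 0:
            raise ValueError("t_half and frame_interval must be positive")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if not 0.0 <= self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must be in [0, 1)")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")

    @property
    def f_inf(self) -> float:
        return self.bleach_depth + (1.0 - self.immobile_fraction) * (1.0 - self.bleach_depth)

    def model(self, tau: np.ndarray) -> np.ndarray:
        """Noise-free post-bleach intensity at time ``tau`` after the bleach."""
        f0, f_inf = self.bleach_depth, self.f_inf
        return f_inf - (f_inf - f0) * np.exp(-np.log(2.0) * np.asarray(tau) / self.t_half)


def sim_frap_traces(params: FrapSimParams, n_traces: int, seed: int, condition: str | None = None) -> list[FrapTrace]:
    """Simulate normalized FRAP traces on the acquisition grid."""
    rng = np.random.default_rng(seed)
    n_post = int(round(params.duration_post / params.frame_interval))
    n_total = params.n_prebleach + n_post
    times = np.arange(n_total) * params.frame_interval
    tau = times[params.n_prebleach:] - times[params.n_prebleach]
    traces = []
    for i in range(n_traces):
        f = np.empty(n_total)
        f[: params.n_prebleach] = 1.0
        f[params.n_prebleach:] = params.model(tau)
        if params.noise_sd > 0:
            f = f + rng.normal(0.0, params.noise_sd, size=n_total)
        traces.append(
            FrapTrace(
                times=times.copy(),
                intensities=f,
                n_prebleach=params.n_prebleach,
                cell_id=f"cell{i:03d}",
                condition=condition,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# allele-specific count simulation
# ---------------------------------------------------------------------------

@dataclass
class AlleleSimParams:
    """Count model for the allele-specific tables.

    Gene totals are negative-binomial (mean ``mean_total_count``,
    dispersion ``dispersion``); per-gene totals are split uniformly over
    SNPs and each SNP's 'a' count is binomial at the class proportion.
    Planted biased SNPs shift the DNA-library 'a' proportion by
    ``biased_shift_sd`` binomial standard deviations.
    """

    n_autosomal: int = 100
    n_x_inactivated: int = 60
    n_x_escape: int = 10
    mean_total_count: float = 200.0
    dispersion: float = 0.3
    p_a_autosome: float = 0.5
    p_a_x_inactivated: float = 0.95
    p_a_escape: float = 0.5
    n_snps_per_gene: int = 3
    n_biased_snps: int = 5
    biased_shift_sd: float = 5.0
    dna_depth: int = 200

    def __post_init__(self) -> None:
        for p in (self.p_a_autosome, self.p_a_x_inactivated, self.p_a_escape):
            if not 0.0 <= p <= 1.0:
                raise ValueError("class proportions must be in [0, 1]")
        if min(self.n_autosomal, self.n_x_inactivated, self.n_x_escape) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.dispersion <= 0 or self.mean_total_count < 0:
            raise ValueError("invalid count model parameters")


_SNP_COLS = ["chrom", "pos", "gene", "a_count", "b_count"]


def _gene_catalog(params: AlleleSimParams) -> pd.DataFrame:
    rows = []
    for cls, n, chrom, p_a in [
        ("autosome", params.n_autosomal, "chr1", params.p_a_autosome),
        ("x_inactivated", params.n_x_inactivated, "chrX", params.p_a_x_inactivated),
        ("x_escape", params.n_x_escape, "chrX", params.p_a_escape),
    ]:
        for i in range(n):
            rows.append({"gene": f"{cls}_{i:04d}", "chrom": chrom, "class": cls, "p_a": p_a})
    return pd.DataFrame(rows, columns=["gene", "chrom", "class", "p_a"])


def _nb_totals(rng, mean, dispersion, size):
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


@dataclass
class AlleleLibrary:
    """Per-SNP allele counts for one sequencing library."""

    assay: str  # RNA | ATAC | antibody | IgG
    condition: str
    replicate: int
    snp_counts: pd.DataFrame  # chrom, pos, gene, a_count, b_count
    gene_totals: pd.Series  # total reads per gene, as emitted by the count model


def sim_allele_tables(
    params: AlleleSimParams,
    n_replicates: int,
    seed: int,
    condition: str = "control",
    p_a_override: dict[str, float] | None = None,
    assay: str = "RNA",
) -> tuple[pd.DataFrame, list[AlleleLibrary], pd.DataFrame]:
    """Simulate a DNA validation table and per-replicate count libraries.

    Returns ``(snp_dna_table, libraries, truth)`` where the DNA table holds
    per-SNP a/b counts at proportion 0.5 apart from the planted biased
    SNPs, and ``truth`` carries per-gene class labels / proportions plus a
    ``biased`` flag per SNP id (``chrom:pos``).
    """
    rng = np.random.default_rng(seed)
    genes = _gene_catalog(params)
    if p_a_override:
        for cls, p in p_a_override.items():
            genes.loc[genes["class"] == cls, "p_a"] = p

    # SNP map: n_snps_per_gene positions per gene
    snp_rows = []
    pos = 1000
    for _, g in genes.iterrows():
        for _ in range(params.n_snps_per_gene):
            snp_rows.append({"chrom": g["chrom"], "pos": pos, "gene": g["gene"]})
            pos += 1000
    snp_map = pd.DataFrame(snp_rows, columns=["chrom", "pos", "gene"])

    n_snps = len(snp_map)
    biased_idx = (
        rng.choice(n_snps, size=min(params.n_biased_snps, n_snps), replace=False)
        if n_snps
        else np.array([], dtype=int)
    )
    p_dna = np.full(n_snps, 0.5)
    sd0 = np.sqrt(0.25 / params.dna_depth) if params.dna_depth > 0 else 0.0
    p_dna[biased_idx] = np.clip(0.5 + params.biased_shift_sd * sd0, 0.0, 1.0)

    depth = rng.poisson(params.dna_depth, size=n_snps)
    a_dna = rng.binomial(depth, p_dna) if n_snps else np.array([], dtype=int)
    snp_dna = snp_map.copy()
    snp_dna["a_count"] = a_dna
    snp_dna["b_count"] = depth - a_dna
    snp_dna = snp_dna[_SNP_COLS]

    truth = genes.copy()
    truth_biased = snp_map.copy()
    truth_biased["biased"] = False
    if len(biased_idx):
        truth_biased.loc[truth_biased.index[biased_idx], "biased"] = True
    truth = truth.merge(
        truth_biased.groupby("gene")["biased"].any().rename("has_biased_snp"),
        left_on="gene",
        right_index=True,
        how="left",
    )
    truth.attrs["biased_snps"] = truth_biased

    libraries: list[AlleleLibrary] = []
    p_a_by_gene = genes.set_index("gene")["p_a"]
    for rep in range(1, n_replicates + 1):
        totals = _nb_totals(rng, params.mean_total_count, params.dispersion, len(genes))
        gene_totals = pd.Series(totals, index=genes["gene"].to_numpy(), name="total")
        rows = []
        for (gene, chrom), grp in snp_map.groupby(["gene", "chrom"], sort=False):
            tot = int(gene_totals[gene])
            split = rng.multinomial(tot, np.full(len(grp), 1.0 / len(grp)))
            p_a = float(p_a_by_gene[gene])
            for (_idx, snp), t in zip(grp.iterrows(), split):
                a = rng.binomial(t, p_a)
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": snp["pos"],
                        "gene": gene,
                        "a_count": int(a),
                        "b_count": int(t - a),
                    }
                )
        snp_counts = pd.DataFrame(rows, columns=_SNP_COLS)
        libraries.append(
            AlleleLibrary(
                assay=assay,
                condition=condition,
                replicate=rep,
                snp_counts=snp_counts,
                gene_totals=gene_totals,
            )
        )
    return snp_dna, libraries, truth


def sim_reactivation_tables(
    params: AlleleSimParams,
    n_reactivated: int,
    n_replicates: int,
    seed: int,
    p_a_after: float = 0.6,
) -> tuple[list[AlleleLibrary], list[AlleleLibrary], pd.DataFrame]:
    """Paired control/treated libraries with a planted reactivated subset.

    ``n_reactivated`` inactive-X genes switch their 'a' proportion to
    ``p_a_after`` in the treated condition (partial loss of silencing);
    everything else is shared between conditions. Returns
    ``(control_libs, treated_libs, truth)`` with a ``reactivated`` column.
    """
    rng = np.random.default_rng(seed)
    _, ctrl_libs, truth = sim_allele_tables(
        params, n_replicates, int(rng.integers(2**31)), condition="control"
    )
    xi_genes = truth.loc[truth["class"] == "x_inactivated", "gene"].to_numpy()
    if n_reactivated > len(xi_genes):
        raise ValueError("more reactivated genes than inactive-X genes")
    reactivated = set(rng.choice(xi_genes, size=n_reactivated, replace=False))
    truth = truth.copy()
    truth["reactivated"] = truth["gene"].isin(reactivated)

    override = None
    _, treat_libs, _ = sim_allele_tables(
        params,
        n_replicates,
        int(rng.integers(2**31)),
        condition="treated",
        p_a_override=override,
    )
    # re-draw allele splits of reactivated genes at the post-treatment skew
    for lib in treat_libs:
        sc = lib.snp_counts
        mask = sc["gene"].isin(reactivated)
        tot = (sc.loc[mask, "a_count"] + sc.loc[mask, "b_count"]).to_numpy()
        a = rng.binomial(tot, p_a_after)
        sc.loc[mask, "a_count"] = a
        sc.loc[mask, "b_count"] = tot - a
    return ctrl_libs, treat_libs, truth


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

_ALPHABET = np.array(list("ACGT"))


def sim_sequences(
    n_exp: int,
    n_ctrl: int,
    length: int,
    motif: str,
    planted_fraction: float,
    seed: int,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Uniform-random ACGT sequences; a fixed fraction of the experimental
    set carries one copy of ``motif`` overwritten at a random position.

    Returns ``(experimental, control)`` as lists of ``(id, sequence)``.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over the ACGT alphabet")
    if len(motif) > length:
        raise ValueError("motif longer than sequence length")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def draw(n: int, prefix: str) -> list[tuple[str, str]]:
        chars = rng.integers(0, 4, size=(n, length))
        return [(f"{prefix}{i:05d}", "".join(_ALPHABET[row])) for i, row in enumerate(chars)]

    exp = draw(n_exp, "exp")
    ctrl = draw(n_ctrl, "ctrl")
    n_plant = int(round(planted_fraction * n_exp))
    planted = rng.choice(n_exp, size=n_plant, replace=False) if n_plant else []
    for i in planted:
        start = int(rng.integers(0, length - len(motif) + 1))
        sid, s = exp[i]
        exp[i] = (sid, s[:start] + motif + s[start + len(motif):])
    return exp, ctrl


# ---------------------------------------------------------------------------
# file output helpers (used by the CLI)
# ---------------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def write_stack_ome_tiff(stack: ImageStack3D, path: str | Path) -> None:
    import tifffile

    arr = np.moveaxis(stack.voxels, -1, 0)  # CZYX
    arr = np.clip(arr, 0, 65535).astype(np.uint16)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        path,
        arr,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "Channel": {"Name": stack.channel_names},
        },
    )
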