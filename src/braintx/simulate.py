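"""Seeded generator of donor-directory fixtures with known ground truth.

The generator emulates the structure of a six-donor stereotactic microarray
survey at desk scale:

* an even number of regions placed symmetrically about the midline on a
  jittered lattice, painted as cubic parcels into a labeled volume;
* a latent regional signal ``G(r, g)`` composed of a per-module mean, a
  module-shared Gaussian field and a gene-private Gaussian field, both with
  spatial covariance ``exp(-d(r, r') / lambda)`` across regions — so
  transcriptional similarity decays with separation distance and genes of a
  module share a spatial expression pattern;
* donors measuring noisy affine transforms of the signal
  (``scale(d,g) * G + offset(d,g) + bias(p) + eps``) through redundant probes
  of heterogeneous quality (per-probe intensity bias, noise multiplier and
  background-failure rate);
* hemispherically asymmetric sampling: only the first ``n_bilateral_donors``
  donors carry right-hemisphere samples, and those donors also carry
  gene-level RNAseq values (a monotone transform of the sample signal plus
  noise);
* a regional phenotype built as an affine function of the first principal
  component of the true regional expression plus noise.

The field is simulated at region level and broadcast to samples (samples are
placed by jittering region centroids), keeping the generator O(regions^2).
One donor includes a sample placed far outside the atlas to exercise
unassigned-sample code paths.  All randomness flows from a single seeded
generator, so equal seeds give byte-identical output directories.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import io as btio
from .analyses import pc1_scores
from .errors import ParameterError
from .types import Atlas, DonorBundle

#: lattice coordinates (mm) from which right-hemisphere centroids are drawn
_LATTICE_X = (18.0, 42.0)
_LATTICE_Y = (-54.0, -30.0, -6.0, 18.0, 42.0)
_LATTICE_Z = (-30.0, -6.0, 18.0, 42.0)

#: sd (log2 units) of the noise inside the RNAseq monotone transform
_RNASEQ_NOISE_SD = 0.2


@dataclass
class SimulationParams:
    """Study conditions for the synthetic dataset.

    Magnitudes are log2 expression units.  Defaults emulate a six-donor
    survey with two bilaterally sampled donors (which also carry RNAseq),
    redundant probes of varying quality, donor batch effects, and a 20 mm
    spatial correlation length.
    """

    n_donors: int = 6
    n_bilateral_donors: int = 2
    n_genes: int = 200
    probes_per_gene_range: Tuple[int, int] = (1, 4)
    n_samples_per_donor: int = 90
    n_regions: int = 30
    n_modules: int = 4
    decay_length: float = 20.0
    donor_offset_sd: float = 1.5
    donor_scale_sd: float = 0.1
    probe_bias_sd: float = 0.3
    noise_sd: float = 0.3
    background_fail_rate: float = 0.1
    seed: int = 0
    # geometry
    voxel_size: float = 3.0
    block_radius: int = 2  # parcels are cubes of (2r+1)^3 voxels
    sample_jitter: float = 2.0  # sd of sample placement around centroids, mm
    mni_error: float = 1.0  # sd of reported-vs-true coordinate error, mm
    # signal composition
    baseline: float = 8.0
    gene_level_sd: float = 2.0  # spread of per-gene baseline expression, log2
    amplitude_log_sd: float = 0.4  # log-sd of per-gene spatial amplitude
    module_mean_spacing: float = 1.5
    gradient_weight: float = 0.55
    homotopic_similarity: float = 0.35  # field variance shared by L/R partners
    region_coverage: float = 0.5  # probability a unilateral donor samples a region
    module_field_weight: float = 0.3
    gene_field_weight: float = 1.0
    phenotype_noise: float = 0.1  # fraction of sd(PC1)
    n_unannotated_probes: int = 3
    include_unassignable_sample: bool = True

    def __post_init__(self):
        counts = (
            self.n_donors, self.n_genes,
            self.n_samples_per_donor, self.n_regions, self.n_modules,
        )
        if any(c < 1 for c in counts):
            raise ParameterError("all counts must be >= 1")
        if self.n_regions % 2:
            raise ParameterError("n_regions must be even (split L/R)")
        if not (0 <= self.n_bilateral_donors <= self.n_donors):
            raise ParameterError(
                "n_bilateral_donors must be between 0 and n_donors"
            )
        if self.n_regions // 2 > len(_LATTICE_X) * len(_LATTICE_Y) * len(_LATTICE_Z):
            raise ParameterError("n_regions exceeds the centroid lattice capacity")
        if self.n_samples_per_donor < self.n_regions:
            raise ParameterError(
                "n_samples_per_donor must be >= n_regions so every region "
                "can receive a sample"
            )
        lo, hi = self.probes_per_gene_range
        if lo < 1 or hi < lo:
            raise ParameterError("invalid probes_per_gene_range")
        if not (0 <= self.background_fail_rate <= 1):
            raise ParameterError("background_fail_rate must be in [0, 1]")
        if not (0 < self.region_coverage <= 1):
            raise ParameterError("region_coverage must be in (0, 1]")
        if self.decay_length <= 0:
            raise ParameterError("decay_length must be positive")


def recovery_params(seed: int = 0, **overrides) -> SimulationParams:
    """Conditions for parameter-recovery experiments: mild donor batch
    effects, so the planted spatial structure (distance decay, gene modules,
    principal gradient) is the dominant feature of the data."""
    overrides.setdefault("donor_offset_sd", 0.25)
    return SimulationParams(seed=seed, **overrides)


def batch_effect_params(seed: int = 0, **overrides) -> SimulationParams:
    """Conditions for the processing-variability (multiverse) experiment:
    donor batch effects strong enough that, without gene normalization, the
    leading principal component of the aggregated matrix reflects the batch
    contrast between the bilaterally sampled donors and the rest rather than
    the planted expression gradient."""
    overrides.setdefault("donor_offset_sd", 2.5)
    return SimulationParams(seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Latent quantities the tests recover."""

    true_regional_expression: pd.DataFrame  # region x gene
    module_labels: pd.Series  # gene -> module id
    phenotype: pd.Series  # region -> float
    region_centroids: pd.DataFrame  # region -> x, y, z (mm)


@dataclass
class SimulatedDataset:
    params: SimulationParams
    bundles: List[DonorBundle]
    atlas: Atlas
    ground_truth: GroundTruth
    root: Optional[Path] = None
    corrected_coordinates: Optional[pd.DataFrame] = None
    reannotation: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _region_table(params: SimulationParams):
    """Region metadata and centroids: mirrored L/R pairs on the lattice."""
    n_half = params.n_regions // 2
    lattice = list(itertools.product(_LATTICE_X, _LATTICE_Y, _LATTICE_Z))[:n_half]
    rows, cent = [], {}
    for i, (x, y, z) in enumerate(lattice):
        acronym = f"A{i + 1:02d}"
        left_id, right_id = i + 1, n_half + i + 1
        rows.append((left_id, f"L_{acronym}", "L", "cortex", acronym))
        rows.append((right_id, f"R_{acronym}", "R", "cortex", acronym))
        cent[left_id] = (-x, y, z)
        cent[right_id] = (x, y, z)
    regions = pd.DataFrame(
        rows, columns=["region_id", "label", "hemisphere", "structure_class",
                       "acronym"]
    ).set_index("region_id").sort_index()
    centroids = pd.DataFrame.from_dict(cent, orient="index",
                                       columns=["x", "y", "z"]).sort_index()
    centroids.index.name = "region_id"
    return regions, centroids


def _build_atlas(params: SimulationParams, regions, centroids) -> Atlas:
    extent = 72.0
    size = int(round(2 * extent / params.voxel_size)) + 1
    labels = np.zeros((size, size, size), int)
    affine = np.diag([params.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -extent
    r = params.block_radius
    for rid, row in centroids.iterrows():
        ijk = np.rint((row.to_numpy(float) + extent) / params.voxel_size).astype(int)
        sl = tuple(slice(c - r, c + r + 1) for c in ijk)
        labels[sl] = rid
    return Atlas(
        space="volume",
        regions=regions[["label", "hemisphere", "structure_class"]],
        label_array=labels,
        affine=affine,
    )


def _field_factory(params: SimulationParams, centroids):
    """Sampler for unit-variance spatial Gaussian fields.

    The covariance combines distance decay with homotopic similarity:

        cov(r, r') = (1 - h) * exp(-d(r, r') / lambda) + h * 1[homotopic]

    with ``h = homotopic_similarity``: transcriptional similarity decays
    with physical separation everywhere, while homologous left/right
    partners additionally share a pair-local component — the minimal
    lateralization of cortical expression that makes hemispheric mirroring
    a defensible operation on the real data.  Both summands are positive
    semi-definite, so one Cholesky factor suffices.
    """
    coords = centroids[["x", "y", "z"]].to_numpy(float)
    folded = coords.copy()
    folded[:, 0] = np.abs(folded[:, 0])
    _, pair_id = np.unique(folded, axis=0, return_inverse=True)
    homotopic = (pair_id[:, None] == pair_id[None, :]).astype(float)
    decay = np.exp(-cdist(coords, coords) / params.decay_length)
    h = params.homotopic_similarity
    cov = (1.0 - h) * decay + h * homotopic
    cov += 1e-8 * np.eye(len(coords))
    chol = np.linalg.cholesky(cov)

    def draw(rng, n_fields) -> np.ndarray:
        return (chol @ rng.standard_normal((len(coords), n_fields))).T

    return draw


def _ground_truth(rng, params: SimulationParams, centroids) -> GroundTruth:
    genes = [f"G{i + 1:03d}" for i in range(params.n_genes)]
    modules = pd.Series(
        [i % params.n_modules + 1 for i in range(params.n_genes)],
        index=genes, name="module_id",
    )
    draw_fields = _field_factory(params, centroids)
    module_fields = draw_fields(rng, params.n_modules)
    # centre the module fields across modules within each region: the planted
    # spatial signal is a contrast between modules and carries no common-mode
    # (all-gene) component.  Common-mode shifts in real microarray data are
    # technical, which is the premise of sample-wise normalization; keeping
    # the signal orthogonal to them makes the ground truth recoverable under
    # any sample-normalization choice.
    module_fields = module_fields - module_fields.mean(axis=0, keepdims=True)
    gene_fields = draw_fields(rng, params.n_genes)
    # a dominant transcriptomic gradient shared by all genes with zero-mean
    # per-gene loadings, emulating the principal spatial axis of cortical
    # expression; it dominates PC1 without adding a common-mode component
    gradient = draw_fields(rng, 1)[0]
    loadings = rng.standard_normal(params.n_genes)
    mu = params.module_mean_spacing * (
        np.arange(params.n_modules) - (params.n_modules - 1) / 2
    )
    # microarray expression levels and spatial amplitudes vary widely across
    # genes; without gene normalization these dominate distances and
    # correlations, which is what the gene-normalization options counteract
    levels = params.baseline + params.gene_level_sd * rng.standard_normal(
        params.n_genes
    )
    amplitudes = np.exp(params.amplitude_log_sd * rng.standard_normal(
        params.n_genes
    ))
    values = np.empty((len(centroids), params.n_genes))
    for j, gene in enumerate(genes):
        k = modules[gene] - 1
        values[:, j] = (
            levels[j]
            + mu[k]
            + amplitudes[j] * (
                params.gradient_weight * loadings[j] * gradient
                + params.module_field_weight * module_fields[k]
                + params.gene_field_weight * gene_fields[j]
            )
        )
    expr = pd.DataFrame(values, index=centroids.index, columns=genes)
    pc1 = pc1_scores(values)
    noise = params.phenotype_noise * pc1.std(ddof=1) * rng.standard_normal(len(pc1))
    phenotype = pd.Series(pc1 + noise + 0.5, index=centroids.index, name="value")
    return GroundTruth(
        true_regional_expression=expr,
        module_labels=modules,
        phenotype=phenotype,
        region_centroids=centroids,
    )


def _probe_table(rng, params: SimulationParams, genes):
    """Probe annotations plus per-probe quality parameters."""
    lo, hi = params.probes_per_gene_range
    counts = rng.integers(lo, hi + 1, size=params.n_genes)
    rows = []
    for gene_idx, gene in enumerate(genes):
        for _ in range(int(counts[gene_idx])):
            rows.append((gene, 1000 + gene_idx))
    for _ in range(params.n_unannotated_probes):
        rows.append((np.nan, None))
    probe_ids = np.arange(1001, 1001 + len(rows))
    probes = pd.DataFrame(
        {
            "probe_name": [f"P{pid:05d}" for pid in probe_ids],
            "gene_symbol": [g for g, _ in rows],
            "entrez_id": pd.array([e for _, e in rows], dtype="Int64"),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    # background-failure rates are bimodal, as on real arrays: most probes
    # rarely fall below background, but a "dead" subset fails in most
    # samples and is what intensity-based filtering removes
    n = len(probes)
    dead = rng.random(n) < min(1.0, 1.5 * params.background_fail_rate)
    dead_rates = rng.uniform(0.55, 0.95, n)
    live_rates = np.clip(
        params.background_fail_rate * rng.gamma(2.0, 0.5, n), 0.0, 0.45
    )
    quality = pd.DataFrame(
        {
            "bias": params.probe_bias_sd * rng.standard_normal(n),
            "noise_mult": rng.uniform(0.5, 2.0, n),
            "fail_rate": np.where(dead, dead_rates, live_rates),
        },
        index=probes.index,
    )
    return probes, quality


def _reannotation_table(rng, probes, genes) -> pd.DataFrame:
    """Updated annotations: most probes unchanged, ~5% dropped, ~5% remapped."""
    annotated = probes[probes["gene_symbol"].notna()]
    fate = rng.random(len(annotated))
    rows = []
    for (pid, row), f in zip(annotated.iterrows(), fate):
        if f < 0.05:
            continue  # dropped from the updated annotation -> null gene
        if f < 0.10:
            gene = genes[int(rng.integers(len(genes)))]
            entrez = 1000 + genes.index(gene)
        else:
            gene, entrez = row["gene_symbol"], row["entrez_id"]
        rows.append((row["probe_name"], gene, entrez))
    return pd.DataFrame(rows, columns=["probe_name", "gene_symbol", "entrez_id"])


def _draw_coverage(rng, params, regions) -> list:
    """Per-donor sets of sampled regions.

    The bilaterally sampled donors cover all regions of both hemispheres
    (they are the only source of right-hemisphere data); the remaining
    donors cover an uneven random subset of the left hemisphere, so the
    donor composition behind each region varies — the condition under which
    donor batch effects distort unnormalized aggregates."""
    left_ids = list(regions.index[regions["hemisphere"] == "L"])
    all_ids = list(regions.index)
    sets = []
    for donor_idx in range(params.n_donors):
        if donor_idx < params.n_bilateral_donors:
            sets.append(list(all_ids))
            continue
        mask = rng.random(len(left_ids)) < params.region_coverage
        covered = [r for r, m in zip(left_ids, mask) if m]
        if not covered:
            covered = [left_ids[int(rng.integers(len(left_ids)))]]
        sets.append(covered)
    return sets


def _donor_bundle(
    rng, params, donor_idx, covered, regions, centroids, truth, probes,
    quality, batch_direction
):
    donor_id = f"D{donor_idx + 1:02d}"
    bilateral = donor_idx < params.n_bilateral_donors
    n = params.n_samples_per_donor
    fill = rng.choice(covered, size=n - len(covered), replace=True)
    region_seq = np.concatenate([covered, fill]).astype(int)

    jitter = np.clip(
        params.sample_jitter * rng.standard_normal((n, 3)), -4.0, 4.0
    )
    true_pos = centroids.loc[region_seq].to_numpy(float) + jitter
    err = np.clip(params.mni_error * rng.standard_normal((n, 3)), -2.0, 2.0)
    mni = true_pos + err

    meta = pd.DataFrame(
        {
            "donor_id": donor_id,
            "structure_acronym": regions.loc[region_seq, "acronym"].to_numpy(),
            "slab_type": "CX",
            "hemisphere": regions.loc[region_seq, "hemisphere"].to_numpy(),
            "mni_x": mni[:, 0],
            "mni_y": mni[:, 1],
            "mni_z": mni[:, 2],
            "structure_class": "cortex",
        },
        index=pd.Index(np.arange(1, n + 1), name="well_id"),
    )
    region_of_sample = pd.Series(region_seq, index=meta.index)

    # per-sample latent gene signal (region signal broadcast to samples)
    signal = truth.true_regional_expression.loc[region_seq].to_numpy(float)

    if params.include_unassignable_sample and donor_idx == 0:
        # last sample placed far outside every parcel
        far = np.array([-66.0, -66.0, -66.0])
        meta.iloc[-1, meta.columns.get_indexer(["mni_x", "mni_y", "mni_z"])] = far
        meta.iloc[-1, meta.columns.get_loc("structure_acronym")] = "XX"
        meta.iloc[-1, meta.columns.get_loc("hemisphere")] = "L"
        true_pos[-1] = far
        region_of_sample.iloc[-1] = -1
        signal[-1] = truth.true_regional_expression.mean(axis=0).to_numpy()

    genes = list(truth.true_regional_expression.columns)
    gene_pos = {g: j for j, g in enumerate(genes)}
    scale = np.clip(
        1.0 + params.donor_scale_sd * rng.standard_normal(len(genes)), 0.05, None
    )
    # batch effects are low-dimensional: a donor-level factor expressed
    # through a gene-sensitivity direction shared across donors, plus an
    # independent per-gene part.  The factor carries a systematic component
    # separating the bilaterally sampled donors from the rest — those donors
    # were acquired as a separate batch, so the right hemisphere is served
    # by a systematically different batch than most left-hemisphere data.
    factor = (1.0 if bilateral else -1.0) + 0.5 * rng.standard_normal()
    offset = params.donor_offset_sd * (
        0.8 * factor * batch_direction
        + 0.6 * rng.standard_normal(len(genes))
    )

    values = np.empty((len(probes), n))
    annotated = probes["gene_symbol"].notna().to_numpy()
    for i, (pid, prow) in enumerate(probes.iterrows()):
        q = quality.loc[pid]
        eps = q["noise_mult"] * params.noise_sd * rng.standard_normal(n)
        if annotated[i]:
            j = gene_pos[prow["gene_symbol"]]
            values[i] = scale[j] * signal[:, j] + offset[j] + q["bias"] + eps
        else:
            values[i] = params.baseline + q["bias"] + eps
    expression = pd.DataFrame(values, index=probes.index, columns=meta.index)

    fail = rng.random((len(probes), n)) < quality["fail_rate"].to_numpy()[:, None]
    pacall = pd.DataFrame((~fail).astype(int), index=probes.index,
                          columns=meta.index)

    rnaseq = None
    if bilateral:
        log_tpm = np.empty((len(genes), n))
        for j in range(len(genes)):
            eps = _RNASEQ_NOISE_SD * rng.standard_normal(n)
            log_tpm[j] = 0.5 * (signal[:, j] + eps)
        rnaseq = pd.DataFrame(
            np.power(2.0, log_tpm),
            index=pd.Index(genes, name="gene_symbol"),
            columns=meta.index,
        )

    corrected = pd.DataFrame(
        {
            "well_id": meta.index,
            "donor_id": donor_id,
            "x": true_pos[:, 0],
            "y": true_pos[:, 1],
            "z": true_pos[:, 2],
        }
    )
    bundle = DonorBundle(
        donor_id=donor_id,
        expression=expression,
        pacall=pacall,
        probes=probes.copy(),
        samples=meta,
        rnaseq=rnaseq,
    )
    return bundle, corrected


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def simulate_dataset(
    params: SimulationParams, out_dir=None
) -> SimulatedDataset:
    """Generate a full synthetic dataset; optionally write it to ``out_dir``.

    The on-disk layout is::

        out_dir/
          donors/donor-D01/ ... (donor-directory dialect)
          atlas/volume.nii + regions.csv
          ground_truth/{true_expression.tsv, module_labels.csv,
                        phenotype.csv, centroids.tsv}
          corrected_coordinates.csv
          reannotation.csv
    """
    rng = np.random.default_rng(params.seed)
    regions, centroids = _region_table(params)
    atlas = _build_atlas(params, regions, centroids)
    truth = _ground_truth(rng, params, centroids)
    genes = list(truth.true_regional_expression.columns)
    probes, quality = _probe_table(rng, params, genes)
    reannotation = _reannotation_table(rng, probes, genes)

    coverage_sets = _draw_coverage(rng, params, regions)
    batch_direction = rng.standard_normal(params.n_genes)
    bundles, corrected_parts = [], []
    for donor_idx in range(params.n_donors):
        bundle, corrected = _donor_bundle(
            rng, params, donor_idx, coverage_sets[donor_idx], regions,
            centroids, truth, probes, quality, batch_direction
        )
        bundles.append(bundle)
        corrected_parts.append(corrected)
    corrected_coords = pd.concat(corrected_parts, ignore_index=True)

    dataset = SimulatedDataset(
        params=params,
        bundles=bundles,
        atlas=atlas,
        ground_truth=truth,
        corrected_coordinates=corrected_coords,
        reannotation=reannotation,
    )
    if out_dir is not None:
        dataset.root = _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: SimulatedDataset, root: Path) -> Path:
    root.mkdir(parents=True, exist_ok=True)
    for bundle in dataset.bundles:
        btio.write_donor(bundle, root / "donors" / f"donor-{bundle.donor_id}")
    btio.write_atlas_volume(dataset.atlas, root / "atlas")
    gt = root / "ground_truth"
    gt.mkdir(exist_ok=True)
    truth = dataset.ground_truth
    truth.true_regional_expression.rename_axis("region_id").to_csv(
        gt / "true_expression.tsv", sep="\t"
    )
    truth.module_labels.rename("module_id").rename_axis("gene_symbol").to_csv(
        gt / "module_labels.csv"
    )
    truth.phenotype.rename("value").rename_axis("region_id").to_csv(
        gt / "phenotype.csv"
    )
    truth.region_centroids.to_csv(gt / "centroids.tsv", sep="\t")
    dataset.corrected_coordinates.to_csv(
        root / "corrected_coordinates.csv", index=False
    )
    dataset.reannotation.to_csv(root / "reannotation.csv", index=False)
    return root
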