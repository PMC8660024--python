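"""Pipeline configuration, sample aggregation and the full orchestrator.

A :class:`PipelineConfig` holds the 17 processing choices of the workflow as
one validated record.  :func:`run_pipeline` executes the canonical stage
order::

    load -> reannotate -> intensity filter -> probe selection ->
    coordinate update -> mirror -> similarity filter -> assignment ->
    sample normalization -> gene normalization -> aggregation ->
    missing-data handling

Intensity-based filtering always precedes probe selection; the relative order
of sample and gene normalization is fixed (sample first) and not exposed.
Every error raised during a run names the stage that produced it.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as btio
from .errors import (
    BrainTxError,
    ConfigurationError,
    EmptyResultError,
    ParameterError,
)
from .normalize import METHODS as NORM_METHODS
from .normalize import normalize_genes, normalize_samples
from .probes import (
    DONOR_INDEPENDENT_METHODS,
    DONOR_MODES,
    METHODS as PROBE_METHODS,
    ProbeSelectionSpec,
    filter_probes_by_intensity,
    reannotate_probes,
    select_probes,
)
from .samples import (
    MIRROR_MODES,
    apply_corrected_coordinates,
    assign_samples,
    filter_samples_by_similarity,
    mirror_samples,
)
from .types import Atlas, DonorBundle, ExpressionMatrix

logger = logging.getLogger("braintx")

ATLAS_SPACES = ("volume", "surface")
MISSING_METHODS = ("omit", "nearest")
COMBINE_METHODS = ("donors_first", "pooled")
METRICS = ("mean", "median")

#: sentinel used in config files for a disabled threshold
DISABLED = "disabled"


@dataclass
class PipelineConfig:
    """The 17 processing options as one validated record.

    ``intensity_threshold`` and ``similarity_threshold`` use ``None`` for
    the disabled state (distinct from a threshold of 0).  ``donor_mode`` is
    coerced to ``aggregate`` for probe-selection methods whose criterion
    already integrates across donors.  ``individualized`` (donor-specific
    atlases) is carried as an option but only the group-level value False is
    supported.
    """

    atlas_space: str = "volume"
    individualized: bool = False
    use_corrected_coords: bool = True
    mirror: str = "none"
    reannotate: bool = False
    intensity_threshold: Optional[float] = 0.5
    similarity_threshold: Optional[float] = None
    probe_method: str = "diff_stability"
    donor_mode: str = "aggregate"
    missing: str = "omit"
    tolerance: float = 2.0
    sample_norm: str = "srs"
    gene_norm: str = "srs"
    norm_matched_only: bool = True
    norm_within_structures: bool = True
    combine: str = "donors_first"
    metric: str = "mean"

    def __post_init__(self):
        def check(value, allowed, name):
            if value not in allowed:
                raise ConfigurationError(
                    f"{name} must be one of {allowed}; got {value!r}"
                )

        check(self.atlas_space, ATLAS_SPACES, "atlas_space")
        check(self.mirror, MIRROR_MODES, "mirror")
        check(self.probe_method, PROBE_METHODS, "probe_method")
        check(self.donor_mode, DONOR_MODES, "donor_mode")
        check(self.missing, MISSING_METHODS, "missing")
        check(self.sample_norm, NORM_METHODS, "sample_norm")
        check(self.gene_norm, NORM_METHODS, "gene_norm")
        check(self.combine, COMBINE_METHODS, "combine")
        check(self.metric, METRICS, "metric")
        for name in ("individualized", "use_corrected_coords", "reannotate",
                     "norm_matched_only", "norm_within_structures"):
            if not isinstance(getattr(self, name), (bool, np.bool_)):
                raise ConfigurationError(f"{name} must be a boolean")
        if self.individualized:
            raise ConfigurationError(
                "individualized (donor-specific) atlases are not supported; "
                "only the group-level atlas (individualized: false)"
            )
        if self.intensity_threshold is not None and not (
            0 <= self.intensity_threshold < 1
        ):
            raise ConfigurationError(
                f"intensity_threshold must be in [0, 1) or disabled; "
                f"got {self.intensity_threshold}"
            )
        if self.similarity_threshold is not None and not (
            -1 <= self.similarity_threshold <= 1
        ):
            raise ConfigurationError(
                f"similarity_threshold must be in [-1, 1] or disabled; "
                f"got {self.similarity_threshold}"
            )
        if self.tolerance < 0:
            raise ConfigurationError("tolerance must be non-negative")
        if self.probe_method in DONOR_INDEPENDENT_METHODS:
            self.donor_mode = "aggregate"

    # -- (de)serialization --------------------------------------------------

    @classmethod
    def option_names(cls):
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.option_names())
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        kwargs = dict(data)
        for key in ("intensity_threshold", "similarity_threshold"):
            if kwargs.get(key) == DISABLED:
                kwargs[key] = None
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {name: getattr(self, name) for name in self.option_names()}
        for key in ("intensity_threshold", "similarity_threshold"):
            if out[key] is None:
                out[key] = DISABLED
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def effective(self) -> "PipelineConfig":
        """The post-collapse configuration (donor_mode redundancy applied)."""
        return replace(self)  # __post_init__ re-coerces


def executed_stages(config: PipelineConfig) -> list:
    """Names of the processing stages this configuration actually runs.

    Shared between the orchestrator's stage log and the methods report so
    the two always agree.
    """
    stages = []
    if config.reannotate:
        stages.append("reannotate")
    if config.intensity_threshold is not None:
        stages.append("intensity_filter")
    stages.append("probe_selection")
    if config.use_corrected_coords:
        stages.append("corrected_coordinates")
    if config.mirror != "none":
        stages.append("mirror")
    if config.similarity_threshold is not None:
        stages.append("similarity_filter")
    stages.append("assignment")
    if config.sample_norm != "none":
        stages.append("sample_normalization")
    if config.gene_norm != "none":
        stages.append("gene_normalization")
    stages.append("aggregation")
    if config.missing == "nearest":
        stages.append("missing_data")
    return stages


@contextmanager
def _stage(name: str):
    """Re-raise package errors with the stage name prepended."""
    try:
        yield
    except BrainTxError as exc:
        msg = str(exc)
        if not msg.startswith(f"[{name}]"):
            raise type(exc)(f"[{name}] {msg}") from exc
        raise


# ---------------------------------------------------------------------------
# aggregation and missing-data handling
# ---------------------------------------------------------------------------

def _agg(frame_or_group, metric: str):
    return frame_or_group.mean() if metric == "mean" else frame_or_group.median()


def aggregate(
    expressions: Dict[str, pd.DataFrame],
    assignments: Dict[str, pd.Series],
    region_ids: Sequence[int],
    combine: str,
    metric: str,
) -> ExpressionMatrix:
    """Aggregate assigned samples into a region x gene matrix.

    ``expressions`` maps donor_id to a sample x gene matrix; ``assignments``
    maps donor_id to a well_id -> region_id Series (NA = unassigned).

    ``donors_first`` applies the metric within each region per donor and then
    across the donors having at least one sample there; ``pooled`` applies it
    once over all donors' samples, so donors with more samples in a region
    contribute more.  Rows are sorted deterministically before reduction, so
    the result is exactly invariant to donor ordering.
    """
    if combine not in COMBINE_METHODS:
        raise ParameterError(f"unknown combine method {combine!r}")
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}")
    donors = sorted(expressions)
    genes = None
    pieces = []
    for donor in donors:
        expr = expressions[donor]
        if genes is None:
            genes = list(expr.columns)
        elif list(expr.columns) != genes:
            raise ParameterError("donor matrices do not share a gene list")
        assigned = assignments[donor].reindex(expr.index)
        keep = assigned.notna()
        if not keep.any():
            continue
        block = expr.loc[keep[keep].index].copy()
        block.insert(0, "_region", assigned[keep].astype(int).to_numpy())
        block.insert(1, "_donor", donor)
        pieces.append(block)
    if not pieces:
        raise EmptyResultError("no region received any tissue sample")

    stacked = pd.concat(pieces)
    stacked = stacked.sort_values(["_region", "_donor"], kind="stable")
    if combine == "donors_first":
        per_donor = _agg(
            stacked.groupby(["_region", "_donor"], sort=True), metric
        )
        values = _agg(per_donor.groupby(level="_region", sort=True), metric)
    else:
        values = _agg(stacked.drop(columns="_donor").groupby("_region", sort=True),
                      metric)

    region_ids = np.asarray(sorted(int(r) for r in region_ids))
    values = values.reindex(region_ids)
    missing = values.isna().all(axis=1).to_numpy()
    return ExpressionMatrix(
        region_ids=region_ids,
        gene_symbols=genes,
        values=values.to_numpy(float),
        missing_mask=missing,
    )


def fill_missing(
    matrix: ExpressionMatrix,
    expressions: Dict[str, pd.DataFrame],
    sample_coords: Dict[str, pd.DataFrame],
    centroids: pd.DataFrame,
    strategy: str,
    metric: str = "mean",
) -> ExpressionMatrix:
    """Handle regions that received no samples.

    ``omit`` leaves the matrix unchanged (missing rows stay flagged and are
    dropped by the analyses).  ``nearest`` fills each missing region from the
    tissue sample nearest (Euclidean mm) to the region's centroid in each
    donor, aggregating those per-donor values with the pipeline's metric.
    """
    if strategy not in MISSING_METHODS:
        raise ParameterError(f"unknown missing-data strategy {strategy!r}")
    if strategy == "omit" or not matrix.missing_mask.any():
        return matrix
    if all(len(df) == 0 for df in expressions.values()):
        raise EmptyResultError("nearest-neighbour fill requires tissue samples")

    values = matrix.values.copy()
    mask = matrix.missing_mask.copy()
    donors = sorted(expressions)
    for pos in np.flatnonzero(mask):
        rid = int(matrix.region_ids[pos])
        if rid not in centroids.index:
            logger.warning("missing region %d has no centroid; left missing", rid)
            continue
        target = centroids.loc[rid, ["x", "y", "z"]].to_numpy(float)
        rows = []
        for donor in donors:
            expr = expressions[donor]
            if expr.empty:
                continue
            coords = sample_coords[donor].loc[
                expr.index, ["mni_x", "mni_y", "mni_z"]
            ].to_numpy(float)
            nearest = int(np.argmin(np.linalg.norm(coords - target, axis=1)))
            rows.append(expr.iloc[nearest].to_numpy(float))
        if not rows:
            continue
        stacked = np.vstack(rows)
        filled = stacked.mean(axis=0) if metric == "mean" else np.median(
            stacked, axis=0
        )
        values[pos] = filled
        mask[pos] = False
    return ExpressionMatrix(
        region_ids=matrix.region_ids,
        gene_symbols=list(matrix.gene_symbols),
        values=values,
        missing_mask=mask,
    )


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Output of one pipeline run."""

    expression: ExpressionMatrix
    assignments: pd.DataFrame  # well_id, donor_id, region_id, distance_mm
    probe_report: pd.DataFrame
    stages: list = field(default_factory=list)
    config: Optional[PipelineConfig] = None


def run_pipeline(
    config: PipelineConfig,
    bundles: Sequence[DonorBundle],
    atlas: Atlas,
    *,
    corrected_coords: Optional[pd.DataFrame] = None,
    reannotation: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run the full processing pipeline and return the region x gene matrix."""
    with _stage("validate"):
        if atlas.space != config.atlas_space:
            raise ConfigurationError(
                f"config requests a {config.atlas_space} atlas but a "
                f"{atlas.space} atlas was supplied"
            )
        if not bundles:
            raise ConfigurationError("no donor bundles supplied")
    config = config.effective()

    probes = bundles[0].probes
    with _stage("reannotate"):
        if config.reannotate:
            if reannotation is None:
                raise ConfigurationError(
                    "reannotation requested but no mapping table supplied"
                )
            probes = reannotate_probes(probes, reannotation)

    with _stage("intensity_filter"):
        kept = filter_probes_by_intensity(bundles, config.intensity_threshold)

    with _stage("probe_selection"):
        spec = ProbeSelectionSpec(config.probe_method, config.donor_mode)
        if spec.method == "rnaseq" and not any(
            b.rnaseq is not None for b in bundles
        ):
            raise ConfigurationError(
                "rnaseq probe selection requires RNAseq data for at least "
                "one donor"
            )
        gene_expr, probe_report = select_probes(bundles, spec, kept, probes)

    samples_by_donor = {}
    with _stage("corrected_coordinates"):
        for bundle in bundles:
            samples_by_donor[bundle.donor_id] = apply_corrected_coordinates(
                bundle.samples, config.use_corrected_coords, corrected_coords
            )

    with _stage("mirror"):
        for donor in list(gene_expr):
            samples_by_donor[donor], gene_expr[donor] = mirror_samples(
                samples_by_donor[donor], gene_expr[donor], config.mirror
            )

    with _stage("similarity_filter"):
        for donor in list(gene_expr):
            kept_wells = filter_samples_by_similarity(
                gene_expr[donor].T, config.similarity_threshold
            )
            gene_expr[donor] = gene_expr[donor][kept_wells]
            samples_by_donor[donor] = samples_by_donor[donor].loc[kept_wells]

    with _stage("assignment"):
        assignments = pd.concat(
            [
                assign_samples(samples_by_donor[d], atlas, config.tolerance)
                for d in sorted(gene_expr)
            ]
        )

    # orientation flips to sample x gene for the normalization stages
    expr_sg = {donor: gene_expr[donor].T for donor in gene_expr}

    with _stage("sample_normalization"):
        expr_sg = {
            donor: normalize_samples(expr, config.sample_norm)
            for donor, expr in expr_sg.items()
        }

    with _stage("gene_normalization"):
        out = {}
        for donor, expr in expr_sg.items():
            donor_assign = assignments.loc[
                assignments["donor_id"] == donor, "region_id"
            ]
            out[donor] = normalize_genes(
                expr,
                config.gene_norm,
                matched_only=config.norm_matched_only,
                within_structures=config.norm_within_structures,
                assigned=donor_assign.notna(),
                structure_class=samples_by_donor[donor]["structure_class"],
            )
        expr_sg = out

    with _stage("aggregation"):
        assign_series = {
            donor: assignments.loc[assignments["donor_id"] == donor, "region_id"]
            for donor in expr_sg
        }
        matrix = aggregate(
            expr_sg, assign_series, atlas.region_ids, config.combine, config.metric
        )

    with _stage("missing_data"):
        if config.missing == "nearest":
            matrix = fill_missing(
                matrix,
                expr_sg,
                samples_by_donor,
                btio.region_centroids(atlas),
                "nearest",
                config.metric,
            )

    n_missing = int(matrix.missing_mask.sum())
    logger.info(
        "pipeline complete: %d probes kept, %d/%d samples assigned, "
        "%d region(s) missing",
        len(kept),
        int(assignments["region_id"].notna().sum()),
        len(assignments),
        n_missing,
    )
    return PipelineResult(
        expression=matrix,
        assignments=assignments,
        probe_report=probe_report,
        stages=executed_stages(config),
        config=config,
    )
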