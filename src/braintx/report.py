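"""Automated methods-report generation.

Given a pipeline configuration and a dataset summary, render a deterministic,
manuscript-style paragraph with one sentence per executed processing step,
parameter values interpolated.  Disabled steps are omitted entirely; the
report ends with a reference-placeholder list.  The set of steps mentioned is
derived from the same :func:`braintx.pipeline.executed_stages` helper the
orchestrator logs, so report and run always agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import __version__
from .pipeline import PipelineConfig, executed_stages
from .probes import DONOR_INDEPENDENT_METHODS

_PROBE_METHOD_TEXT = {
    "max_intensity": "selecting, for each gene, the probe with the highest "
                     "mean expression across samples",
    "corr_intensity": "selecting, for each gene with three or more probes, "
                      "the probe most correlated with its sibling probes "
                      "(falling back to the highest mean expression for "
                      "two-probe genes)",
    "corr_variance": "selecting, for each gene with three or more probes, "
                     "the probe most correlated with its sibling probes "
                     "(falling back to the highest variance for two-probe "
                     "genes)",
    "diff_stability": "selecting, for each gene, the probe with the highest "
                      "differential stability (mean inter-donor Spearman "
                      "correlation of structure-averaged expression profiles)",
    "rnaseq": "selecting, for each gene, the probe most correlated with "
              "matched RNAseq measurements across the donors providing them",
    "average": "averaging expression values across all probes indexing the "
               "same gene",
}

_DONOR_MODE_TEXT = {
    "aggregate": "with the selection criterion evaluated on samples pooled "
                 "across donors",
    "independent": "with probes selected independently for each donor",
    "common": "applying the probe most commonly selected across donors to "
              "all donors",
}

_MIRROR_TEXT = {
    "bidirectional": "every tissue sample was mirrored across the left-right "
                     "hemisphere boundary (bilateral mirroring)",
    "left_to_right": "left-hemisphere tissue samples were mirrored into the "
                     "right hemisphere",
    "right_to_left": "right-hemisphere tissue samples were mirrored into the "
                     "left hemisphere",
}

_NORM_TEXT = {"zscore": "a z-score transform", "srs": "a scaled robust sigmoid "
              "transform"}


@dataclass
class ReportContext:
    """Everything the report needs: configuration plus dataset summary."""

    config: PipelineConfig
    n_donors: int = 0
    n_probes: int = 0
    n_samples: int = 0
    version: str = field(default=__version__)


def _sentences(ctx: ReportContext) -> dict:
    """Stage name -> rendered sentence, for the executed stages only."""
    cfg = ctx.config
    out = {}
    if cfg.reannotate:
        out["reannotate"] = (
            "Probe-to-gene annotations were updated using a supplied "
            "reannotation table; probes without an updated annotation were "
            "discarded."
        )
    if cfg.intensity_threshold is not None:
        out["intensity_filter"] = (
            f"Probes were retained only if their expression exceeded "
            f"background in more than "
            f"{cfg.intensity_threshold:.0%} of tissue samples pooled across "
            f"donors."
        )
    probe = (
        f"Probe-level expression was collapsed to gene level by "
        f"{_PROBE_METHOD_TEXT[cfg.probe_method]}"
    )
    if cfg.probe_method not in DONOR_INDEPENDENT_METHODS:
        probe += f", {_DONOR_MODE_TEXT[cfg.donor_mode]}"
    out["probe_selection"] = probe + "."
    if cfg.use_corrected_coords:
        out["corrected_coordinates"] = (
            "Sample coordinates were updated to values from a corrected "
            "nonlinear registration to standard space."
        )
    if cfg.mirror != "none":
        out["mirror"] = (
            f"To improve spatial coverage, {_MIRROR_TEXT[cfg.mirror]}."
        )
    if cfg.similarity_threshold is not None:
        out["similarity_filter"] = (
            f"Tissue samples whose mean inter-areal Spearman correlation "
            f"with the donor's remaining samples fell below "
            f"{cfg.similarity_threshold:g} were discarded."
        )
    if cfg.atlas_space == "volume":
        out["assignment"] = (
            f"Samples were assigned to regions of a volumetric atlas; "
            f"samples not falling directly within a region were matched to "
            f"the nearest region within {cfg.tolerance:g} mm, restricted to "
            f"regions of the same hemisphere and structural class."
        )
    else:
        out["assignment"] = (
            f"Samples were matched to the nearest labeled surface vertex in "
            f"their hemisphere; samples more than {cfg.tolerance:g} "
            f"standard deviation(s) above the mean sample-to-surface "
            f"distance were excluded."
        )
    if cfg.sample_norm != "none":
        out["sample_normalization"] = (
            f"Expression values of each tissue sample were normalized "
            f"across genes using {_NORM_TEXT[cfg.sample_norm]}."
        )
    if cfg.gene_norm != "none":
        sentence = (
            f"Expression values of each gene were normalized across tissue "
            f"samples within each donor using {_NORM_TEXT[cfg.gene_norm]}"
        )
        if cfg.norm_matched_only:
            sentence += ", using only samples matched to atlas regions"
        if cfg.norm_within_structures:
            sentence += ", independently within each structural class"
        out["gene_normalization"] = sentence + "."
    how = ("within each region separately for each donor and then across "
           "donors" if cfg.combine == "donors_first"
           else "simultaneously across all donors' samples in each region")
    out["aggregation"] = (
        f"Samples assigned to the same region were aggregated using the "
        f"{cfg.metric} {how}."
    )
    if cfg.missing == "nearest":
        out["missing_data"] = (
            "Regions receiving no samples were filled using "
            "nearest-neighbors interpolation from each donor's closest "
            "tissue sample."
        )
    return out


def generate_report(ctx: ReportContext) -> str:
    """Render the deterministic methods paragraph for one configuration."""
    stages = executed_stages(ctx.config)
    sentences = _sentences(ctx)
    header = (
        f"Regional gene expression was derived from microarray data of "
        f"{ctx.n_donors} donors ({ctx.n_probes} probes; {ctx.n_samples} "
        f"tissue samples) using braintx version {ctx.version}."
    )
    body = " ".join(sentences[name] for name in stages)
    references = "\n".join(
        f"[{i + 1}] <reference placeholder: {name}>"
        for i, name in enumerate(stages)
    )
    return f"{header} {body}\n\nReferences\n{references}\n"
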