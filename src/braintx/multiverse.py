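"""Parameter grids, pipeline enumeration, impact scoring and estimate PCA.

A :class:`ParameterGrid` declares, for each processing option, its ordered
choice list, its measurement scale (binary / ordinal / categorical) and an
optional *redundancy rule*: a declarative statement that the option is
collapsed to a single value whenever another option takes one of a set of
trigger choices.  The one rule needed for the standard grid encodes that the
donor-integrating probe-selection methods (average, differential stability,
RNAseq fidelity) render donor-specific probe selection redundant, collapsing
``donor_mode`` to ``aggregate``.  With that collapse the standard 17-option
grid enumerates exactly 746,496 distinct pipelines.

Impact scores quantify how much changing one option — holding all the others
fixed — moves each analysis estimate:

* binary options: the absolute difference between the two choices;
* ordinal options with more than two choices: the mean absolute difference
  between adjacent choices;
* categorical options with more than two choices: the mean absolute
  difference over all unordered pairs of choices.

Scores are averaged over all matched tuples (contexts in which every choice
of the option exists as an effective, post-collapse pipeline; collapsed
cells are skipped, never double counted) and rank-ordered per analysis with
rank 1 = most impactful.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .analyses import compute_estimates
from .errors import IncompleteGridError, ParameterError
from .pipeline import PipelineConfig, run_pipeline

logger = logging.getLogger("braintx")

SCALES = ("binary", "ordinal", "categorical")
ESTIMATE_COLUMNS = ("cge_rho", "gce_silhouette", "rge_rho")


@dataclass(frozen=True)
class OptionSpec:
    """One processing option: ordered choices, scale, optional redundancy.

    ``collapse_when`` maps another option's name to the tuple of its choices
    under which this option is redundant; when any rule fires, this option
    is forced to ``collapse_to`` (defaults to its first choice).
    """

    name: str
    choices: tuple
    scale: str = "categorical"
    collapse_when: Optional[dict] = None
    collapse_to: object = None

    def __post_init__(self):
        if len(self.choices) < 1:
            raise ParameterError(f"option {self.name}: needs at least one choice")
        if len(set(self.choices)) != len(self.choices):
            raise ParameterError(f"option {self.name}: duplicate choices")
        if self.scale not in SCALES:
            raise ParameterError(f"option {self.name}: unknown scale {self.scale!r}")
        if (self.scale == "binary") != (len(self.choices) == 2):
            raise ParameterError(
                f"option {self.name}: binary scale if and only if 2 choices"
            )
        if self.collapse_when is not None:
            target = self.collapse_to if self.collapse_to is not None \
                else self.choices[0]
            object.__setattr__(self, "collapse_to", target)
            if target not in self.choices:
                raise ParameterError(
                    f"option {self.name}: collapse_to {target!r} not a choice"
                )


@dataclass
class ParameterGrid:
    """An ordered list of options covering the pipeline configuration."""

    options: List[OptionSpec]

    def __post_init__(self):
        names = [o.name for o in self.options]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate option names in grid")
        by_name = {o.name: o for o in self.options}
        for opt in self.options:
            for ref in (opt.collapse_when or {}):
                if ref not in by_name:
                    raise ParameterError(
                        f"option {opt.name}: redundancy rule references "
                        f"unknown option {ref!r}"
                    )
                if by_name[ref].collapse_when:
                    raise ParameterError(
                        "nested redundancy rules (trigger options that are "
                        "themselves collapsible) are not supported"
                    )

    def __getitem__(self, name: str) -> OptionSpec:
        for opt in self.options:
            if opt.name == name:
                return opt
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [o.name for o in self.options]

    def collapsed(self, option: OptionSpec, assignment: dict) -> bool:
        """Is ``option`` collapsed under the (partial) assignment?"""
        for ref, triggers in (option.collapse_when or {}).items():
            if ref in assignment and assignment[ref] in triggers:
                return True
        return False

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "ParameterGrid":
        data = yaml.safe_load(Path(path).read_text())
        options = []
        for entry in data:
            collapse = entry.get("collapse_when")
            if collapse is not None:
                collapse = {k: tuple(v) for k, v in collapse.items()}
            options.append(
                OptionSpec(
                    name=entry["name"],
                    choices=tuple(entry["choices"]),
                    scale=entry.get("scale", "categorical"),
                    collapse_when=collapse,
                    collapse_to=entry.get("collapse_to"),
                )
            )
        return cls(options)

    def to_yaml(self, path) -> None:
        data = []
        for opt in self.options:
            entry = {
                "name": opt.name,
                "choices": list(opt.choices),
                "scale": opt.scale,
            }
            if opt.collapse_when is not None:
                entry["collapse_when"] = {
                    k: list(v) for k, v in opt.collapse_when.items()
                }
                entry["collapse_to"] = opt.collapse_to
            data.append(entry)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# enumeration and counting
# ---------------------------------------------------------------------------

def enumerate_grid(grid: ParameterGrid) -> Iterator[dict]:
    """Lazily yield every distinct effective configuration exactly once, in
    deterministic lexicographic order of the option declaration."""
    names = grid.names
    collapsible = [
        (i, opt) for i, opt in enumerate(grid.options) if opt.collapse_when
    ]
    trigger_pos = {
        name: names.index(name)
        for _, opt in collapsible
        for name in opt.collapse_when
    }
    choice_lists = [opt.choices for opt in grid.options]
    for combo in itertools.product(*choice_lists):
        ok = True
        for i, opt in collapsible:
            fired = any(
                combo[trigger_pos[ref]] in triggers
                for ref, triggers in opt.collapse_when.items()
            )
            if fired and combo[i] != opt.collapse_to:
                ok = False
                break
        if ok:
            yield dict(zip(names, combo))


def count_grid(grid: ParameterGrid) -> int:
    """Closed-form count of distinct effective configurations.

    Equals ``len(list(enumerate_grid(grid)))`` but runs in time proportional
    to the product of the *trigger* options' choice counts only.
    """
    trigger_names = sorted(
        {ref for opt in grid.options if opt.collapse_when
         for ref in opt.collapse_when}
    )
    triggers = [grid[name] for name in trigger_names]
    plain = [
        opt for opt in grid.options
        if opt.name not in trigger_names and not opt.collapse_when
    ]
    base = int(np.prod([len(opt.choices) for opt in plain], dtype=object)) \
        if plain else 1
    collapsible = [opt for opt in grid.options if opt.collapse_when]
    total = 0
    for combo in itertools.product(*[t.choices for t in triggers]):
        assignment = dict(zip(trigger_names, combo))
        factor = 1
        for opt in collapsible:
            factor *= 1 if grid.collapsed(opt, assignment) else len(opt.choices)
        total += factor
    return base * total


def matched_tuple_count(grid: ParameterGrid, option_name: str) -> int:
    """Number of matched tuples entering ``option_name``'s impact score.

    A matched tuple is a context (an assignment of every other option) in
    which *every* choice of the option exists as an effective configuration.
    For a binary option on the standard grid this is the familiar N/2.
    """
    option = grid[option_name]
    if len(option.choices) < 2:
        return 0
    trigger_names = {
        ref for opt in grid.options if opt.collapse_when
        for ref in opt.collapse_when
    }
    collapsible = [o for o in grid.options if o.collapse_when]
    special_names = sorted(
        (trigger_names | {o.name for o in collapsible}) - {option_name}
    )
    special = [grid[name] for name in special_names]
    plain = [
        o for o in grid.options
        if o.name != option_name and o.name not in special_names
    ]
    base = int(np.prod([len(o.choices) for o in plain], dtype=object)) \
        if plain else 1

    total = 0
    for combo in itertools.product(*[s.choices for s in special]):
        ctx = dict(zip(special_names, combo))
        valid = True
        complete = True
        for opt in collapsible:
            if opt.name == option_name:
                # the option under study must not be collapsed in the context
                if grid.collapsed(opt, ctx):
                    complete = False
                continue
            refs_option = option_name in opt.collapse_when
            collapsed_by_ctx = grid.collapsed(opt, ctx)
            if collapsed_by_ctx and ctx[opt.name] != opt.collapse_to:
                valid = False  # such an effective config does not exist
                break
            if refs_option and ctx[opt.name] != opt.collapse_to:
                # some choices of the option would collapse opt away from
                # its current value: the tuple cannot be complete
                if any(
                    c in opt.collapse_when[option_name] for c in option.choices
                ):
                    complete = False
        if valid and complete:
            total += 1
    return base * total


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def config_hash(assignment: dict) -> str:
    """Stable short identifier for one pipeline configuration."""
    payload = "|".join(f"{k}={assignment[k]}" for k in sorted(assignment))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def run_multiverse(
    grid: ParameterGrid,
    bundles,
    atlas,
    centroids: pd.DataFrame,
    *,
    module_labels: Optional[pd.Series] = None,
    phenotype: Optional[pd.Series] = None,
    corrected_coords: Optional[pd.DataFrame] = None,
    reannotation: Optional[pd.DataFrame] = None,
    n_jobs: int = 1,
    pipeline_fn: Optional[Callable] = None,
) -> pd.DataFrame:
    """Execute every pipeline of the grid and collect the three estimates.

    Returns one row per configuration, keyed by a stable config hash, with
    the option values, the estimates, and an ``error`` column recording
    per-config failures (results are never silently dropped).  The table is
    independent of execution order.  ``pipeline_fn`` may replace the real
    pipeline in tests.
    """
    assignments = list(enumerate_grid(grid))

    def one(assignment: dict) -> dict:
        row = {"pipeline_id": config_hash(assignment), **assignment}
        try:
            if pipeline_fn is not None:
                matrix = pipeline_fn(assignment)
            else:
                config = PipelineConfig.from_dict(assignment)
                matrix = run_pipeline(
                    config, bundles, atlas,
                    corrected_coords=corrected_coords,
                    reannotation=reannotation,
                ).expression
            est = compute_estimates(matrix, centroids, module_labels, phenotype)
            row.update(zip(ESTIMATE_COLUMNS, est.as_tuple()))
            row["error"] = None
        except Exception as exc:  # recorded, not raised
            row.update(zip(ESTIMATE_COLUMNS, (np.nan,) * 3))
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("pipeline %s failed: %s", row["pipeline_id"], exc)
        return row

    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(a) for a in assignments)
    else:
        rows = [one(a) for a in assignments]
    table = pd.DataFrame(rows).set_index("pipeline_id")
    return table.sort_index()


# ---------------------------------------------------------------------------
# impact scoring
# ---------------------------------------------------------------------------

def _tuple_impact(values: np.ndarray, scale: str) -> float:
    """Difference score of one matched tuple, ordered by choice order."""
    if len(values) == 2:
        return float(abs(values[0] - values[1]))
    if scale == "ordinal":
        return float(np.mean(np.abs(np.diff(values))))
    pairs = [
        abs(values[i] - values[j])
        for i in range(len(values))
        for j in range(i + 1, len(values))
    ]
    return float(np.mean(pairs))


def _choice_key(value) -> str:
    """Canonical string key for a choice; None and NaN (pandas' rendering of
    a disabled threshold) compare equal."""
    if value is None:
        return "<disabled>"
    if isinstance(value, float) and np.isnan(value):
        return "<disabled>"
    return str(value)


def _expected_choices(
    grid: ParameterGrid, option: OptionSpec, context: dict
) -> tuple:
    """Choices of ``option`` that exist as effective configs in ``context``."""
    out = []
    for choice in option.choices:
        assignment = {**context, option.name: choice}
        exists = True
        for opt in grid.options:
            if opt.collapse_when and grid.collapsed(opt, assignment):
                if assignment.get(opt.name, opt.collapse_to) != opt.collapse_to:
                    exists = False
                    break
        if exists:
            out.append(choice)
    return tuple(out)


def impact_scores(
    estimates: pd.DataFrame, grid: ParameterGrid
) -> pd.DataFrame:
    """Per-option, per-analysis mean |difference| (impact score) and rank.

    ``estimates`` must hold one row per effective configuration of the grid
    (a full factorial up to the redundancy collapse) with the option values
    and the estimate columns.  Options with a single choice carry no
    variation and are excluded.  Returns a table indexed by option name with
    ``<analysis>_impact`` and ``<analysis>_rank`` columns; rank 1 = most
    impactful, ties broken by option declaration order.
    """
    analyses = [c for c in ESTIMATE_COLUMNS if c in estimates.columns]
    if not analyses:
        raise ParameterError("estimates table has no estimate columns")
    scored = [o for o in grid.options if len(o.choices) >= 2]
    records = {}
    for option in scored:
        others = [n for n in grid.names if n != option.name]
        sums = {a: 0.0 for a in analyses}
        count = 0
        grouped = estimates.groupby(others, sort=False, dropna=False) \
            if others else [((), estimates)]
        for key, block in grouped:
            if others:
                key = key if isinstance(key, tuple) else (key,)
                context = dict(zip(others, key))
            else:
                context = {}
            expected = _expected_choices(grid, option, context)
            got_keys = sorted(_choice_key(v) for v in block[option.name])
            if got_keys != sorted(_choice_key(c) for c in expected):
                raise IncompleteGridError(
                    f"option {option.name}: context {context} has cells "
                    f"{got_keys}, expected "
                    f"{sorted(_choice_key(c) for c in expected)}"
                )
            if len(expected) != len(option.choices):
                continue  # redundancy-collapsed context: skipped, not counted
            pos = {
                _choice_key(v): i for i, v in enumerate(block[option.name])
            }
            order = [pos[_choice_key(c)] for c in option.choices]
            for a in analyses:
                values = block[a].to_numpy(float)[order]
                sums[a] += _tuple_impact(values, option.scale)
            count += 1
        if count == 0:
            raise IncompleteGridError(
                f"option {option.name}: no complete matched tuples"
            )
        records[option.name] = {
            **{f"{a}_impact": sums[a] / count for a in analyses},
            "n_tuples": count,
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "option"
    order_index = {o.name: i for i, o in enumerate(scored)}
    for a in analyses:
        impacts = table[f"{a}_impact"]
        keys = sorted(
            table.index, key=lambda n: (-impacts[n], order_index[n])
        )
        table[f"{a}_rank"] = pd.Series(
            {name: r + 1 for r, name in enumerate(keys)}
        )
    return table


def pca_estimates(estimates: pd.DataFrame):
    """PCA of the pipeline-by-estimate matrix.

    Columns are mean-centered and the first two principal components
    extracted by singular value decomposition.  Returns (scores, fractions):
    scores is an n x 2 array of pipeline coordinates, fractions the
    variance-explained of the two components (non-increasing, in [0, 1]).
    """
    cols = [c for c in ESTIMATE_COLUMNS if c in estimates.columns]
    values = estimates[cols].to_numpy(float)
    values = values[~np.isnan(values).any(axis=1)]
    if len(values) < 3:
        raise ParameterError("PCA requires at least 3 pipelines")
    centered = values - values.mean(axis=0, keepdims=True)
    if not np.any(centered):
        from .errors import DegenerateInputError

        raise DegenerateInputError("all estimates identical; PCA undefined")
    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    var = sv**2
    fractions = var / var.sum()
    scores = u[:, :2] * sv[:2]
    return scores, fractions[:2]


# ---------------------------------------------------------------------------
# preset grids
# ---------------------------------------------------------------------------

def table_grid() -> ParameterGrid:
    """The standard 17-option grid (746,496 effective pipelines)."""
    return ParameterGrid([
        OptionSpec("atlas_space", ("volume", "surface"), "binary"),
        OptionSpec("individualized", (False,), "categorical"),
        OptionSpec("use_corrected_coords", (False, True), "binary"),
        OptionSpec("mirror", ("none", "left_to_right", "bidirectional"),
                   "categorical"),
        OptionSpec("reannotate", (False, True), "binary"),
        OptionSpec("intensity_threshold", (None, 0.25, 0.5), "ordinal"),
        OptionSpec("similarity_threshold", (None,), "categorical"),
        OptionSpec(
            "probe_method",
            ("max_intensity", "corr_intensity", "corr_variance",
             "diff_stability", "rnaseq", "average"),
            "categorical",
        ),
        OptionSpec(
            "donor_mode",
            ("aggregate", "independent", "common"),
            "categorical",
            collapse_when={
                "probe_method": ("diff_stability", "rnaseq", "average")
            },
            collapse_to="aggregate",
        ),
        OptionSpec("missing", ("omit", "nearest"), "binary"),
        OptionSpec("tolerance", (0, 1, 2), "ordinal"),
        OptionSpec("sample_norm", ("none", "zscore", "srs"), "categorical"),
        OptionSpec("gene_norm", ("none", "zscore", "srs"), "categorical"),
        OptionSpec("norm_matched_only", (False, True), "binary"),
        OptionSpec("norm_within_structures", (False, True), "binary"),
        OptionSpec("combine", ("donors_first", "pooled"), "binary"),
        OptionSpec("metric", ("mean", "median"), "binary"),
    ])


def _fixed_options(overrides: Dict[str, OptionSpec]) -> List[OptionSpec]:
    """All 17 options, defaults pinned to single choices unless overridden."""
    defaults = PipelineConfig()
    out = []
    for opt in table_grid().options:
        if opt.name in overrides:
            out.append(overrides[opt.name])
        else:
            out.append(OptionSpec(opt.name, (getattr(defaults, opt.name),),
                                  "categorical"))
    return out


def smoke_grid() -> ParameterGrid:
    """A 16-config grid over four binary-ized options, for quick recovery
    checks: sample/gene normalization, aggregation metric and mirroring."""
    return ParameterGrid(_fixed_options({
        "sample_norm": OptionSpec("sample_norm", ("none", "zscore"), "binary"),
        "gene_norm": OptionSpec("gene_norm", ("none", "zscore"), "binary"),
        "metric": OptionSpec("metric", ("mean", "median"), "binary"),
        "mirror": OptionSpec("mirror", ("none", "bidirectional"), "binary"),
    }))


def reduced_grid() -> ParameterGrid:
    """A 96-config grid over five options (gene_norm x sample_norm x metric
    x mirror x tolerance = 3*2*2*4*2), used for the scaled-down multiverse
    analysis of normalization impact."""
    return ParameterGrid(_fixed_options({
        "gene_norm": OptionSpec("gene_norm", ("none", "zscore", "srs"),
                                "categorical"),
        "sample_norm": OptionSpec("sample_norm", ("none", "zscore"), "binary"),
        "metric": OptionSpec("metric", ("mean", "median"), "binary"),
        "mirror": OptionSpec(
            "mirror",
            ("none", "left_to_right", "right_to_left", "bidirectional"),
            "categorical",
        ),
        "tolerance": OptionSpec("tolerance", (0, 2), "binary"),
    }))
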