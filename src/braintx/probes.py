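"""Probe reannotation, intensity-based filtering, and probe-to-gene collapse.

Microarray probes are redundant — several probes usually index the same gene —
so the transition from probe-level to gene-level expression requires either
selecting a representative probe per gene or averaging across probes.  Six
selection methods are supported:

* ``max_intensity`` — probe with the highest mean expression over the
  evaluation samples;
* ``corr_intensity`` — for genes with >= 3 probes, the probe with the highest
  mean pairwise correlation to its sibling probes; with exactly 2 probes the
  choice falls back to max intensity;
* ``corr_variance`` — as above, falling back to max variance;
* ``diff_stability`` — probe maximizing differential stability: the mean over
  donor pairs of the Spearman correlation between the probe's
  structure-averaged expression profiles (structures matched by acronym);
* ``rnaseq`` — probe maximizing the mean Spearman correlation with the gene's
  RNAseq values across samples of the donors carrying RNAseq; genes absent
  from the RNAseq data are dropped;
* ``average`` — no selection: the per-donor mean across the gene's probes.

Donor modes control how donor data enter the criterion: ``aggregate`` pools
samples across donors and applies one probe to all donors; ``independent``
selects per donor (donors may use different probes); ``common`` selects per
donor and then applies the modal probe to all donors.  ``average``,
``diff_stability`` and ``rnaseq`` already integrate across donors (or ignore
the distinction), so they force ``aggregate``.

Intensity-based filtering must run before probe selection; ties in any argmax
are broken by lowest probe_id for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, FormatError, ParameterError
from .types import DonorBundle

logger = logging.getLogger("braintx")

METHODS = (
    "max_intensity",
    "corr_intensity",
    "corr_variance",
    "diff_stability",
    "rnaseq",
    "average",
)
DONOR_MODES = ("aggregate", "independent", "common")
#: methods whose criterion already integrates across donors (or ignores the
#: distinction), rendering donor-specific selection redundant
DONOR_INDEPENDENT_METHODS = ("diff_stability", "rnaseq", "average")


@dataclass
class ProbeSelectionSpec:
    method: str = "diff_stability"
    donor_mode: str = "aggregate"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ParameterError(f"unknown probe selection method {self.method!r}")
        if self.donor_mode not in DONOR_MODES:
            raise ParameterError(f"unknown donor mode {self.donor_mode!r}")
        if self.method in DONOR_INDEPENDENT_METHODS:
            self.donor_mode = "aggregate"


# ---------------------------------------------------------------------------
# reannotation and filtering
# ---------------------------------------------------------------------------

def reannotate_probes(
    probes: pd.DataFrame, mapping: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Replace gene annotations using an updated probe_name -> gene mapping.

    Probes absent from the mapping (or mapped to no gene) get null gene
    fields; a null mapping is the identity.
    """
    if mapping is None:
        return probes.copy()
    if mapping["probe_name"].duplicated().any():
        raise FormatError("reannotation mapping has duplicate probe_name entries")
    mapping = mapping.set_index("probe_name")
    out = probes.copy()
    symbols = out["probe_name"].map(mapping["gene_symbol"])
    entrez = out["probe_name"].map(mapping["entrez_id"])
    # keep the null-together invariant
    null = symbols.isna() | entrez.isna()
    out["gene_symbol"] = symbols.where(~null)
    out["entrez_id"] = entrez.where(~null).astype("Int64")
    return out


def filter_probes_by_intensity(
    bundles: Sequence[DonorBundle], threshold: Optional[float]
) -> set:
    """Keep probes whose above-background fraction, pooled across all donors'
    samples, strictly exceeds ``threshold``.

    ``threshold=None`` disables filtering (all probes kept).  The comparison
    is strict: a probe flagged in exactly 50% of samples is dropped at 0.50.
    """
    index = bundles[0].pacall.index
    for bundle in bundles[1:]:
        if not bundle.pacall.index.equals(index):
            raise FormatError("donor bundles do not share a probe list")
    if threshold is None:
        return set(int(p) for p in index)
    if not (0 <= threshold < 1):
        raise ParameterError(f"intensity threshold must be in [0, 1); got {threshold}")
    flags = sum(b.pacall.sum(axis=1) for b in bundles)
    total = sum(b.pacall.shape[1] for b in bundles)
    frac = flags / total
    return set(int(p) for p in index[frac > threshold])


# ---------------------------------------------------------------------------
# selection criteria
# ---------------------------------------------------------------------------

def _first_max(scores: np.ndarray, probe_ids: np.ndarray) -> int:
    """Argmax with deterministic ties: lowest probe_id wins (rows are sorted
    ascending by probe_id, NaN scores never win)."""
    scores = np.where(np.isnan(scores), -np.inf, scores)
    return int(probe_ids[int(np.argmax(scores))])


def _mean_pairwise_corr(rows: np.ndarray) -> np.ndarray:
    """Per-row mean Pearson correlation with the other rows."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rows)
    np.fill_diagonal(corr, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(corr, axis=1)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between corresponding rows of two matrices."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _rowwise_pearson(
        rankdata(a, axis=1).astype(float), rankdata(b, axis=1).astype(float)
    )


def _max_intensity_pick(expr: pd.DataFrame, gene_of: pd.Series) -> pd.Series:
    means = expr.mean(axis=1)
    return means.groupby(gene_of).agg(
        lambda s: _first_max(s.to_numpy(), s.index.to_numpy())
    )


def _corr_fallback_pick(
    expr: pd.DataFrame, gene_of: pd.Series, fallback: str
) -> pd.Series:
    """corr_intensity / corr_variance: mean inter-probe correlation for genes
    with >= 3 probes; 2-probe genes fall back to max intensity or variance."""
    values = expr.to_numpy(float)
    means = values.mean(axis=1)
    variances = values.var(axis=1, ddof=1) if values.shape[1] > 1 else means * 0
    fall_scores = means if fallback == "intensity" else variances
    picks = {}
    for gene, idx in expr.groupby(gene_of, sort=True).groups.items():
        pos = expr.index.get_indexer(idx)
        pids = np.asarray(idx, int)
        if len(pos) == 1:
            picks[gene] = int(pids[0])
        elif len(pos) == 2:
            picks[gene] = _first_max(fall_scores[pos], pids)
        else:
            scores = _mean_pairwise_corr(values[pos])
            if np.isnan(scores).all():
                scores = fall_scores[pos]
            picks[gene] = _first_max(scores, pids)
    return pd.Series(picks)


def _diff_stability_scores(
    bundles: Sequence[DonorBundle], probe_ids: pd.Index
) -> np.ndarray:
    """Mean over donor pairs of the Spearman correlation between
    structure-averaged probe profiles (structures matched by acronym)."""
    profiles = []
    for bundle in sorted(bundles, key=lambda b: b.donor_id):
        expr = bundle.expression.loc[probe_ids]
        acronyms = bundle.samples["structure_acronym"]
        prof = expr.T.groupby(acronyms.reindex(expr.columns)).mean().T
        profiles.append(prof)
    n = len(profiles)
    scores = np.full((len(probe_ids), n * (n - 1) // 2), np.nan)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            common = profiles[i].columns.intersection(profiles[j].columns)
            if len(common) < 3:
                k += 1
                continue
            a = profiles[i][common].to_numpy(float)
            b = profiles[j][common].to_numpy(float)
            scores[:, k] = _rowwise_spearman(a, b)
            k += 1
    with np.errstate(invalid="ignore"):
        return np.nanmean(scores, axis=1)


def _rnaseq_scores(
    bundles: Sequence[DonorBundle], probe_ids: pd.Index, gene_of: pd.Series
) -> pd.Series:
    """Mean over RNAseq donors of the Spearman correlation between each
    probe's expression and its gene's RNAseq values across that donor's
    samples.  Probes of genes absent from all RNAseq tables score NaN."""
    rnaseq_bundles = sorted(
        (b for b in bundles if b.rnaseq is not None), key=lambda b: b.donor_id
    )
    if not rnaseq_bundles:
        raise ConfigurationError(
            "rnaseq probe selection requires at least one donor with RNAseq data"
        )
    per_donor = []
    for bundle in rnaseq_bundles:
        genes = gene_of.loc[probe_ids]
        available = genes.isin(bundle.rnaseq.index)
        scores = pd.Series(np.nan, index=probe_ids)
        if available.any():
            pids = probe_ids[available]
            expr = bundle.expression.loc[pids].to_numpy(float)
            ref = bundle.rnaseq.loc[
                genes[available], bundle.expression.columns
            ].to_numpy(float)
            scores.loc[pids] = _rowwise_spearman(expr, ref)
        per_donor.append(scores)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return pd.Series(
            np.nanmean(np.column_stack(per_donor), axis=1), index=probe_ids
        )


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def select_probes(
    bundles: Sequence[DonorBundle],
    spec: ProbeSelectionSpec,
    kept_probes: Iterable[int],
    probes: Optional[pd.DataFrame] = None,
):
    """Collapse probe-level expression to gene-level, per donor.

    Parameters
    ----------
    bundles : donor bundles sharing one probe list.
    spec : selection method and donor mode.
    kept_probes : probe ids surviving intensity filtering (applied first).
    probes : optional probe-annotation table overriding the bundles' own
        (used after reannotation); indexed by probe_id.

    Returns
    -------
    (per_donor, report) : per_donor maps donor_id to a gene x sample
        DataFrame; report maps gene_symbol to the chosen probe_id per donor
        (or "average").
    """
    if probes is None:
        probes = bundles[0].probes
    kept = set(int(p) for p in kept_probes)
    annotated = probes[probes["gene_symbol"].notna()]
    annotated = annotated.loc[[p for p in annotated.index if int(p) in kept]]
    if annotated.empty:
        raise ConfigurationError("no annotated probes survive filtering")
    probe_ids = annotated.index.sort_values()
    gene_of = annotated.loc[probe_ids, "gene_symbol"]
    donors = sorted(b.donor_id for b in bundles)
    by_id = {b.donor_id: b for b in bundles}

    def rows_for(bundle, picks: pd.Series) -> pd.DataFrame:
        out = bundle.expression.loc[picks.to_numpy(int)]
        out.index = pd.Index(picks.index, name="gene_symbol")
        return out.sort_index()

    if spec.method == "average":
        per_donor = {}
        for donor in donors:
            expr = by_id[donor].expression.loc[probe_ids]
            avg = expr.groupby(gene_of).mean()
            avg.index.name = "gene_symbol"
            per_donor[donor] = avg.sort_index()
        genes = per_donor[donors[0]].index
        report = pd.DataFrame("average", index=genes, columns=donors)
        report.index.name = "gene_symbol"
        return per_donor, report

    if spec.method == "diff_stability":
        scores = pd.Series(
            _diff_stability_scores(bundles, probe_ids), index=probe_ids
        )
        picks = scores.groupby(gene_of).agg(
            lambda s: _first_max(s.to_numpy(), s.index.to_numpy())
        )
        picks_by_donor = {donor: picks for donor in donors}
    elif spec.method == "rnaseq":
        scores = _rnaseq_scores(bundles, probe_ids, gene_of)
        valid = scores.notna()
        if not valid.any():
            raise ConfigurationError("no gene is present in the RNAseq data")
        dropped = sorted(set(gene_of[~valid]) - set(gene_of[valid]))
        if dropped:
            logger.info("rnaseq selection dropped %d genes absent from RNAseq",
                        len(dropped))
        scores = scores[valid]
        picks = scores.groupby(gene_of[valid]).agg(
            lambda s: _first_max(s.to_numpy(), s.index.to_numpy())
        )
        picks_by_donor = {donor: picks for donor in donors}
    else:
        # sample-pooled or per-donor criteria
        def criterion(expr: pd.DataFrame) -> pd.Series:
            if spec.method == "max_intensity":
                return _max_intensity_pick(expr, gene_of)
            fallback = "intensity" if spec.method == "corr_intensity" else "variance"
            return _corr_fallback_pick(expr, gene_of, fallback)

        if spec.donor_mode == "aggregate":
            pooled = pd.DataFrame(
                np.hstack([by_id[d].expression.loc[probe_ids].to_numpy(float)
                           for d in donors]),
                index=probe_ids,
            )
            picks = criterion(pooled)
            picks_by_donor = {donor: picks for donor in donors}
        else:
            per = {
                donor: criterion(by_id[donor].expression.loc[probe_ids])
                for donor in donors
            }
            if spec.donor_mode == "independent":
                picks_by_donor = per
            else:  # common: modal probe, ties -> lowest probe_id
                stacked = pd.DataFrame(per)
                modal = stacked.apply(
                    lambda row: int(row.value_counts().sort_index()
                                    .sort_values(ascending=False, kind="stable")
                                    .index[0]),
                    axis=1,
                )
                picks_by_donor = {donor: modal for donor in donors}

    per_donor = {
        donor: rows_for(by_id[donor], picks_by_donor[donor]) for donor in donors
    }
    report = pd.DataFrame(
        {donor: picks_by_donor[donor].sort_index() for donor in donors}
    )
    report.index.name = "gene_symbol"
    return per_donor, report
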