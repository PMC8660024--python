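"""Domain containers for donor microarray bundles, atlases and output matrices.

The canonical in-memory representations are pandas objects (tables indexed by
probe, sample well, or region id); the dataclasses here add validated structure
around them.  Conventions used throughout the package:

* world coordinates are MNI-style millimetres; the left hemisphere has x < 0,
  so hemispheric mirroring is a sign flip of x;
* voxel indexing is 0-based and the affine maps a voxel index to the mm
  coordinate of the voxel centre;
* expression values are log2 microarray intensities, already normalized
  upstream by the data provider — no background subtraction is performed here;
* standard deviations use the (n-1) denominator everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

STRUCTURE_CLASSES = ("cortex", "subcortex_brainstem", "cerebellum", "white_matter")
HEMISPHERES = ("L", "R")

#: columns required of a sample-annotation table (besides the well_id index)
SAMPLE_COLUMNS = (
    "structure_acronym",
    "slab_type",
    "hemisphere",
    "mni_x",
    "mni_y",
    "mni_z",
    "structure_class",
)


@dataclass(frozen=True)
class ProbeRecord:
    """One microarray probe and its gene annotation.

    ``gene_symbol`` and ``entrez_id`` are null together: a probe either maps
    to a gene or it does not.
    """

    probe_id: int
    probe_name: str
    gene_symbol: Optional[str]
    entrez_id: Optional[int]

    def __post_init__(self):
        if (self.gene_symbol is None) != (self.entrez_id is None):
            raise FormatError(
                f"probe {self.probe_id}: gene_symbol and entrez_id must be "
                "null together"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One tissue sample with its stereotactic (MNI, mm) location."""

    well_id: int
    donor_id: str
    structure_acronym: str
    structure_class: str
    hemisphere: str
    mni_xyz: tuple
    corrected_xyz: Optional[tuple] = None

    def __post_init__(self):
        if self.structure_class not in STRUCTURE_CLASSES:
            raise FormatError(
                f"well {self.well_id}: unknown structure_class "
                f"{self.structure_class!r}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise FormatError(
                f"well {self.well_id}: unknown hemisphere {self.hemisphere!r}"
            )


@dataclass
class DonorBundle:
    """One donor's probe-level data.

    Attributes
    ----------
    donor_id : str
    expression : pd.DataFrame
        probe x sample matrix of log2 intensities; index = probe_id,
        columns = well_id.
    pacall : pd.DataFrame
        Same shape/ordering; binary above-background flags.
    probes : pd.DataFrame
        Indexed by probe_id with columns probe_name, gene_symbol, entrez_id
        (gene fields null together).
    samples : pd.DataFrame
        Indexed by well_id with columns ``SAMPLE_COLUMNS`` (plus donor_id).
    rnaseq : pd.DataFrame or None
        Optional gene x sample matrix (gene-level, no probes); index =
        gene_symbol, columns = well_id.
    """

    donor_id: str
    expression: pd.DataFrame
    pacall: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame
    rnaseq: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.expression.shape != self.pacall.shape:
            raise FormatError(
                f"donor {self.donor_id}: expression {self.expression.shape} "
                f"and pacall {self.pacall.shape} shapes differ"
            )
        if not self.expression.index.equals(self.pacall.index):
            raise FormatError(f"donor {self.donor_id}: probe order mismatch")
        if not self.expression.columns.equals(self.pacall.columns):
            raise FormatError(f"donor {self.donor_id}: sample order mismatch")
        if self.expression.index.has_duplicates:
            raise FormatError(f"donor {self.donor_id}: duplicate probe_id")
        if self.samples.index.has_duplicates:
            raise FormatError(f"donor {self.donor_id}: duplicate well_id")
        if not self.expression.index.equals(self.probes.index):
            raise FormatError(
                f"donor {self.donor_id}: expression rows do not match probe table"
            )
        if list(self.expression.columns) != list(self.samples.index):
            raise FormatError(
                f"donor {self.donor_id}: expression columns do not match "
                "sample table"
            )
        sym_null = self.probes["gene_symbol"].isna()
        ent_null = self.probes["entrez_id"].isna()
        if not (sym_null == ent_null).all():
            raise FormatError(
                f"donor {self.donor_id}: gene_symbol/entrez_id must be null "
                "together"
            )

    def probe_records(self) -> Iterator[ProbeRecord]:
        for pid, row in self.probes.iterrows():
            null = pd.isna(row["gene_symbol"])
            yield ProbeRecord(
                probe_id=int(pid),
                probe_name=str(row["probe_name"]),
                gene_symbol=None if null else str(row["gene_symbol"]),
                entrez_id=None if null else int(row["entrez_id"]),
            )

    def sample_records(self) -> Iterator[SampleRecord]:
        for wid, row in self.samples.iterrows():
            yield SampleRecord(
                well_id=int(wid),
                donor_id=self.donor_id,
                structure_acronym=str(row["structure_acronym"]),
                structure_class=str(row["structure_class"]),
                hemisphere=str(row["hemisphere"]),
                mni_xyz=(float(row["mni_x"]), float(row["mni_y"]), float(row["mni_z"])),
            )


@dataclass
class Atlas:
    """A brain parcellation, volumetric or surface.

    Volumetric atlases hold a 3-D integer ``label_array`` (0 = unlabeled) and
    a 4x4 ``affine`` mapping 0-based voxel indices to mm at voxel centres.
    Surface atlases hold per-hemisphere vertex ``coordinates`` (mm) and
    integer ``labels`` arrays, keyed "L"/"R".

    ``regions`` is indexed by region_id with columns label, hemisphere,
    structure_class.
    """

    space: str
    regions: pd.DataFrame
    label_array: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None
    vertices: Optional[dict] = None  # hemi -> {"coords": (n,3), "labels": (n,)}

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.space not in ("volume", "surface"):
            raise MetadataError(f"unknown atlas space {self.space!r}")
        if self.regions.index.has_duplicates:
            raise MetadataError("duplicate region_id in atlas metadata")
        bad = set(self.regions["structure_class"]) - set(STRUCTURE_CLASSES)
        if bad:
            raise MetadataError(f"unknown structure_class values: {sorted(bad)}")
        if self.space == "volume":
            if self.label_array is None or self.affine is None:
                raise MetadataError("volume atlas requires label_array and affine")
            present = np.unique(self.label_array)
            present = set(int(v) for v in present if v != 0)
        else:
            if not self.vertices or set(self.vertices) != {"L", "R"}:
                raise MetadataError(
                    "surface atlas requires exactly two hemispheres (L, R)"
                )
            present = set()
            for hemi, data in self.vertices.items():
                coords = np.asarray(data["coords"], float)
                labels = np.asarray(data["labels"], int)
                if coords.shape[0] != labels.shape[0] or coords.shape[1] != 3:
                    raise MetadataError(f"hemisphere {hemi}: vertex table malformed")
                present |= set(int(v) for v in np.unique(labels) if v != 0)
        missing = present - set(int(i) for i in self.regions.index)
        if missing:
            raise MetadataError(
                f"labels present in atlas but absent from metadata: "
                f"{sorted(missing)}"
            )

    @property
    def region_ids(self) -> np.ndarray:
        return np.asarray(sorted(int(i) for i in self.regions.index))


@dataclass
class ExpressionMatrix:
    """Region-by-gene expression with an explicit missing-region mask.

    Rows flagged missing are all-NaN; gene symbols are unique and ordered.
    """

    region_ids: np.ndarray
    gene_symbols: list
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.region_ids = np.asarray(self.region_ids, int)
        self.values = np.asarray(self.values, float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values).all(axis=1)
        self.missing_mask = np.asarray(self.missing_mask, bool)
        self.validate()

    def validate(self) -> None:
        n_r, n_g = self.values.shape
        if len(self.region_ids) != n_r:
            raise FormatError("region_ids length does not match value rows")
        if len(self.gene_symbols) != n_g:
            raise FormatError("gene_symbols length does not match value columns")
        if len(set(self.gene_symbols)) != n_g:
            raise FormatError("duplicate gene symbols")
        if len(self.missing_mask) != n_r:
            raise FormatError("missing_mask length does not match value rows")
        for i, miss in enumerate(self.missing_mask):
            row_nan = np.isnan(self.values[i]).all()
            if miss and not row_nan:
                raise FormatError(
                    f"region {self.region_ids[i]} flagged missing but has values"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.region_ids, name="region_id"),
            columns=list(self.gene_symbols),
        )

    def drop_missing(self) -> "ExpressionMatrix":
        keep = ~self.missing_mask
        return ExpressionMatrix(
            region_ids=self.region_ids[keep],
            gene_symbols=list(self.gene_symbols),
            values=self.values[keep],
            missing_mask=np.zeros(int(keep.sum()), bool),
        )
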