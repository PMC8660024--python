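"""Readers and writers for the donor-directory dialect, atlases and matrices.

Donor-directory dialect (one directory per donor, public-release layout):

* ``MicroarrayExpression.csv`` — no header; column 1 = probe_id, remaining
  columns = samples (comma-separated floats).
* ``PACall.csv`` — same shape and ordering; entries in {0, 1}.
* ``Probes.csv`` — header row; probe_id, probe_name, gene_symbol, entrez_id
  (gene fields may be empty, in which case both are treated as null).
* ``SampleAnnot.csv`` — header row; well_id, structure_acronym, slab_type,
  hemisphere, mni_x, mni_y, mni_z, structure_class.
* ``RNAseq.csv`` (optional) — header row; gene_symbol then sample columns.

Atlases are accepted as NIfTI label volumes (via nibabel) or as a plain-text
JSON fallback ({"shape", "affine", "labels"}) plus a region-metadata CSV;
surface atlases as per-hemisphere vertex CSVs (vertex_id, x, y, z, label).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FileMissingError, FormatError, MetadataError
from .types import Atlas, DonorBundle, ExpressionMatrix, SAMPLE_COLUMNS

logger = logging.getLogger("braintx")

EXPRESSION_FILE = "MicroarrayExpression.csv"
PACALL_FILE = "PACall.csv"
PROBES_FILE = "Probes.csv"
SAMPLES_FILE = "SampleAnnot.csv"
RNASEQ_FILE = "RNAseq.csv"

#: decimal precision of the expression-matrix TSV round trip
TSV_DECIMALS = 6


# ---------------------------------------------------------------------------
# donor bundles
# ---------------------------------------------------------------------------

def _require(directory: Path, name: str) -> Path:
    path = directory / name
    if not path.exists():
        raise FileMissingError(f"missing file {name} in {directory}")
    return path


def load_donor(directory) -> DonorBundle:
    """Read one donor directory into a validated :class:`DonorBundle`.

    The donor id is taken from the directory name (a ``donor-`` prefix is
    stripped if present).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileMissingError(f"donor directory not found: {directory}")
    donor_id = directory.name
    if donor_id.startswith("donor-"):
        donor_id = donor_id[len("donor-"):]

    expr_path = _require(directory, EXPRESSION_FILE)
    pacall_path = _require(directory, PACALL_FILE)
    probes_path = _require(directory, PROBES_FILE)
    samples_path = _require(directory, SAMPLES_FILE)

    try:
        expression = pd.read_csv(expr_path, header=None, index_col=0)
        pacall = pd.read_csv(pacall_path, header=None, index_col=0)
    except ValueError as exc:
        raise FormatError(f"unparseable expression/pacall in {directory}: {exc}")
    if expression.shape != pacall.shape:
        raise FormatError(
            f"{EXPRESSION_FILE} shape {expression.shape} != "
            f"{PACALL_FILE} shape {pacall.shape} in {directory}"
        )
    if expression.index.has_duplicates:
        raise FormatError(f"duplicate probe_id in {EXPRESSION_FILE} ({directory})")
    if not expression.index.equals(pacall.index):
        raise FormatError(f"probe order differs between expression and pacall "
                          f"files in {directory}")

    probes = pd.read_csv(probes_path)
    required = {"probe_id", "probe_name", "gene_symbol", "entrez_id"}
    if not required.issubset(probes.columns):
        raise FormatError(
            f"{PROBES_FILE} missing columns {sorted(required - set(probes.columns))} "
            f"in {directory}"
        )
    probes = probes.set_index("probe_id")[["probe_name", "gene_symbol", "entrez_id"]]
    if probes.index.has_duplicates:
        raise FormatError(f"duplicate probe_id in {PROBES_FILE} ({directory})")
    # a probe either maps to a gene or it does not: a half-annotated row is
    # treated as unannotated
    half = probes["gene_symbol"].isna() != probes["entrez_id"].isna()
    if half.any():
        probes.loc[half, ["gene_symbol", "entrez_id"]] = np.nan
    probes["entrez_id"] = probes["entrez_id"].astype("Int64")
    if not probes.index.equals(expression.index):
        if set(probes.index) != set(expression.index):
            raise FormatError(
                f"probe ids differ between {PROBES_FILE} and "
                f"{EXPRESSION_FILE} in {directory}"
            )
        probes = probes.reindex(expression.index)

    samples = pd.read_csv(samples_path)
    missing_cols = {"well_id", *SAMPLE_COLUMNS} - set(samples.columns)
    if missing_cols:
        raise FormatError(
            f"{SAMPLES_FILE} missing columns {sorted(missing_cols)} in {directory}"
        )
    if samples["well_id"].duplicated().any():
        raise FormatError(f"duplicate well_id in {SAMPLES_FILE} ({directory})")
    samples = samples.set_index("well_id")[list(SAMPLE_COLUMNS)]
    samples.insert(0, "donor_id", donor_id)
    if len(samples) != expression.shape[1]:
        raise FormatError(
            f"{SAMPLES_FILE} lists {len(samples)} samples but "
            f"{EXPRESSION_FILE} has {expression.shape[1]} columns in {directory}"
        )
    expression.columns = samples.index
    expression.index.name = "probe_id"
    pacall.columns = samples.index
    pacall.index.name = "probe_id"
    pacall = pacall.astype(int)
    bad = ~pacall.isin((0, 1)).to_numpy()
    if bad.any():
        raise FormatError(f"{PACALL_FILE} has entries outside {{0,1}} in {directory}")

    rnaseq = None
    rnaseq_path = directory / RNASEQ_FILE
    if rnaseq_path.exists():
        rnaseq = pd.read_csv(rnaseq_path)
        if "gene_symbol" not in rnaseq.columns:
            raise FormatError(f"{RNASEQ_FILE} missing gene_symbol column "
                              f"in {directory}")
        rnaseq = rnaseq.set_index("gene_symbol")
        rnaseq.columns = pd.Index(rnaseq.columns.astype(int), name="well_id")
        extra = set(rnaseq.columns) - set(samples.index)
        if extra:
            raise FormatError(
                f"{RNASEQ_FILE} has sample columns absent from {SAMPLES_FILE}: "
                f"{sorted(extra)[:5]} in {directory}"
            )

    return DonorBundle(
        donor_id=donor_id,
        expression=expression,
        pacall=pacall,
        probes=probes,
        samples=samples,
        rnaseq=rnaseq,
    )


def write_donor(bundle: DonorBundle, directory) -> Path:
    """Write a bundle in the donor-directory dialect (inverse of load_donor)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.expression.to_csv(directory / EXPRESSION_FILE, header=False)
    bundle.pacall.astype(int).to_csv(directory / PACALL_FILE, header=False)
    probes = bundle.probes.reset_index()
    probes.to_csv(directory / PROBES_FILE, index=False)
    samples = bundle.samples.drop(columns=["donor_id"]).reset_index()
    samples.to_csv(directory / SAMPLES_FILE, index=False)
    if bundle.rnaseq is not None:
        bundle.rnaseq.to_csv(directory / RNASEQ_FILE)
    return directory


def load_donors(root) -> list:
    """Load every ``donor-*`` (or plain) subdirectory under ``root``."""
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not dirs:
        raise FileMissingError(f"no donor directories under {root}")
    return [load_donor(p) for p in dirs]


# ---------------------------------------------------------------------------
# atlases
# ---------------------------------------------------------------------------

def _read_regions(path) -> pd.DataFrame:
    regions = pd.read_csv(path)
    required = {"region_id", "label", "hemisphere", "structure_class"}
    if not required.issubset(regions.columns):
        raise MetadataError(
            f"region metadata missing columns "
            f"{sorted(required - set(regions.columns))}"
        )
    return regions.set_index("region_id")


def load_atlas_volume(image_path, regions_path) -> Atlas:
    """Load a labeled volume (NIfTI or plain-text JSON) plus region metadata."""
    image_path = Path(image_path)
    if image_path.suffix == ".json":
        payload = json.loads(image_path.read_text())
        labels = np.asarray(payload["labels"], int).reshape(payload["shape"])
        affine = np.asarray(payload["affine"], float)
    else:
        import nibabel as nib

        img = nib.load(str(image_path))
        labels = np.asarray(img.dataobj).astype(int)
        affine = np.asarray(img.affine, float)
    if (labels < 0).any():
        raise MetadataError("atlas labels must be non-negative integers")
    return Atlas(
        space="volume",
        regions=_read_regions(regions_path),
        label_array=labels,
        affine=affine,
    )


def _read_vertex_table(path) -> dict:
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        coords = np.asarray(img.darrays[0].data, float)
        labels = np.asarray(img.darrays[1].data, int)
    else:
        table = pd.read_csv(path)
        required = {"x", "y", "z", "label"}
        if not required.issubset(table.columns):
            raise FormatError(
                f"vertex table {path} missing columns "
                f"{sorted(required - set(table.columns))}"
            )
        coords = table[["x", "y", "z"]].to_numpy(float)
        labels = table["label"].to_numpy(int)
    return {"coords": coords, "labels": labels}


def load_atlas_surface(left_path, right_path, regions_path) -> Atlas:
    """Load per-hemisphere vertex tables (CSV or GIFTI) plus region metadata."""
    return Atlas(
        space="surface",
        regions=_read_regions(regions_path),
        vertices={
            "L": _read_vertex_table(left_path),
            "R": _read_vertex_table(right_path),
        },
    )


def load_atlas(paths, regions_path) -> Atlas:
    """Dispatch on input form: one volume path, or a (left, right) pair."""
    if isinstance(paths, (str, Path)):
        return load_atlas_volume(paths, regions_path)
    paths = list(paths)
    if len(paths) != 2:
        raise MetadataError("surface atlas requires exactly two hemisphere files")
    return load_atlas_surface(paths[0], paths[1], regions_path)


def load_atlas_dir(directory) -> Atlas:
    """Load an atlas from a directory written by the synthetic generator.

    Expects ``regions.csv`` plus either ``volume.nii``/``volume.nii.gz``/
    ``volume.json`` or ``surface_L.csv`` + ``surface_R.csv``.
    """
    directory = Path(directory)
    regions = directory / "regions.csv"
    if not regions.exists():
        raise FileMissingError(f"missing regions.csv in {directory}")
    for name in ("volume.nii", "volume.nii.gz", "volume.json"):
        if (directory / name).exists():
            return load_atlas_volume(directory / name, regions)
    left, right = directory / "surface_L.csv", directory / "surface_R.csv"
    if left.exists() and right.exists():
        return load_atlas_surface(left, right, regions)
    raise FileMissingError(f"no atlas image found in {directory}")


def write_atlas_volume(atlas: Atlas, directory, *, text=False) -> Path:
    """Write a volume atlas as volume.nii (or volume.json) + regions.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if text:
        payload = {
            "shape": list(atlas.label_array.shape),
            "affine": atlas.affine.tolist(),
            "labels": atlas.label_array.ravel().astype(int).tolist(),
        }
        (directory / "volume.json").write_text(json.dumps(payload))
    else:
        import nibabel as nib

        img = nib.Nifti1Image(atlas.label_array.astype(np.int32), atlas.affine)
        # uncompressed .nii keeps the output byte-deterministic
        nib.save(img, str(directory / "volume.nii"))
    atlas.regions.reset_index().to_csv(directory / "regions.csv", index=False)
    return directory


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (n, 3) to mm coordinates at voxel centres."""
    ijk = np.atleast_2d(np.asarray(ijk, float))
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map mm coordinates (n, 3) to fractional voxel indices."""
    xyz = np.atleast_2d(np.asarray(xyz, float))
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def region_centroids(atlas: Atlas) -> pd.DataFrame:
    """Per-region centroid in mm: mean voxel-centre (volume) or mean vertex
    coordinate (surface).  Regions with no voxels/vertices are excluded and
    logged."""
    rows = {}
    if atlas.space == "volume":
        for rid in atlas.region_ids:
            ijk = np.argwhere(atlas.label_array == rid)
            if ijk.size == 0:
                logger.warning("region %d has no voxels; excluded from centroids", rid)
                continue
            rows[rid] = voxel_to_world(atlas.affine, ijk).mean(axis=0)
    else:
        for rid in atlas.region_ids:
            pts = []
            for data in atlas.vertices.values():
                mask = np.asarray(data["labels"]) == rid
                if mask.any():
                    pts.append(np.asarray(data["coords"], float)[mask])
            if not pts:
                logger.warning("region %d has no vertices; excluded from centroids", rid)
                continue
            rows[rid] = np.vstack(pts).mean(axis=0)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["x", "y", "z"])
    frame.index.name = "region_id"
    return frame


# ---------------------------------------------------------------------------
# expression matrices and auxiliary tables
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path) -> Path:
    """Serialize as TSV: region_id rows, gene columns, 6 decimals, NA rows
    for missing regions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(
        path, sep="\t", float_format=f"%.{TSV_DECIMALS}f", na_rep="NA"
    )
    return path


def read_expression(path) -> ExpressionMatrix:
    # pandas mangles duplicate headers, so check the raw header line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({g for g in header if header.count(g) > 1})
        raise FormatError(f"duplicate gene columns on read: {dupes}")
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionMatrix(
        region_ids=frame.index.to_numpy(int),
        gene_symbols=list(frame.columns),
        values=frame.to_numpy(float),
    )


def read_corrected_coordinates(path) -> pd.DataFrame:
    """Coordinate-correction table: well_id, donor_id, x, y, z."""
    table = pd.read_csv(path)
    required = {"well_id", "donor_id", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"corrected-coordinates table missing columns "
            f"{sorted(required - set(table.columns))}"
        )
    return table


def read_reannotation(path) -> pd.DataFrame:
    """Probe-reannotation table: probe_name, gene_symbol, entrez_id."""
    table = pd.read_csv(path)
    required = {"probe_name", "gene_symbol", "entrez_id"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"reannotation table missing columns "
            f"{sorted(required - set(table.columns))}"
        )
    if table["probe_name"].duplicated().any():
        raise FormatError("reannotation table has duplicate probe_name entries")
    return table


def read_module_labels(path) -> pd.Series:
    """Gene-module labels: CSV gene_symbol, module_id."""
    table = pd.read_csv(path)
    return table.set_index("gene_symbol")["module_id"]


def read_phenotype(path) -> pd.Series:
    """Regional phenotype vector: CSV region_id, value."""
    table = pd.read_csv(path)
    return table.set_index("region_id")["value"]
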