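"""Readers and writers for the on-disk formats the pipeline touches.

Formats: MatrixMarket coordinate triplets with sidecar ``features.tsv`` /
``barcodes.tsv`` (10x-style, genes as MTX rows), a spot-positions CSV
(``spot_id,row,col,x,y`` with an optional ``in_tissue`` flag), GMT gene
sets, and the alteration-table TSV.  Every reader is total over valid
files and raises a typed error otherwise — there are no partial silent
loads.  Each writer has a reader that round-trips it exactly.

Grid row/col indices are carried for reporting, but the continuous x,y
columns are authoritative for every distance computation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

from .enrich import GeneSetCollection
from .errors import FormatError, InputError
from .spatial import SECTION_ID_KEY, SPATIAL_KEY

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
METADATA_FILE = "metadata.tsv"

POSITION_COLUMNS = ("spot_id", "row", "col", "x", "y")


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    return [ln.rstrip("\n") for ln in path.read_text().splitlines()]


def deduplicate_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate gene symbols with ``.1``, ``.2`` suffixes.

    The first occurrence keeps the bare symbol; later occurrences get a
    numeric suffix in file order, so the mapping is deterministic.
    """
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_counts_mtx(path: str | Path, metadata: str | Path | None = None) -> AnnData:
    """Load an MTX triplet directory into a cells x genes AnnData.

    The matrix file stores genes as rows and cells as columns (the 10x
    convention); it is transposed on load.  Dimension mismatches between
    the matrix header and the sidecar files raise a :class:`FormatError`
    naming the offending file.  ``metadata`` optionally points at a TSV
    of per-cell columns keyed by barcode.
    """
    path = Path(path)
    mtx_path = path / MATRIX_FILE
    if not mtx_path.exists():
        raise FormatError(f"missing file: {mtx_path}")
    try:
        mat = mmread(mtx_path)
    except Exception as exc:  # malformed MatrixMarket payload
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    features = _read_lines(path / FEATURES_FILE)
    barcodes = _read_lines(path / BARCODES_FILE)
    genes = [ln.split("\t")[0] for ln in features if ln]
    cells = [ln.split("\t")[0] for ln in barcodes if ln]
    n_genes, n_cells = mat.shape
    if n_genes != len(genes):
        raise FormatError(
            f"{path / FEATURES_FILE}: {len(genes)} features but matrix "
            f"declares {n_genes} rows"
        )
    if n_cells != len(cells):
        raise FormatError(
            f"{path / BARCODES_FILE}: {len(cells)} barcodes but matrix "
            f"declares {n_cells} columns"
        )
    X = sp.csr_matrix(mat.T)
    adata = AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(deduplicate_symbols(genes), name="gene")),
    )
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", index_col=0)
        missing = [c for c in adata.obs_names if c not in meta.index]
        if missing:
            raise FormatError(
                f"{metadata}: no metadata for barcodes {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        adata.obs = meta.loc[adata.obs_names].copy()
    return adata


def write_counts_mtx(adata: AnnData, path: str | Path) -> None:
    """Write an AnnData as an MTX triplet directory (genes x cells)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(np.asarray(X))
    mmwrite(path / MATRIX_FILE, sp.coo_matrix(X.T))
    (path / FEATURES_FILE).write_text(
        "".join(f"{g}\n" for g in adata.var_names)
    )
    (path / BARCODES_FILE).write_text(
        "".join(f"{c}\n" for c in adata.obs_names)
    )
    if len(adata.obs.columns):
        adata.obs.to_csv(
            path / METADATA_FILE, sep="\t", float_format=FLOAT_FORMAT
        )


def read_spatial_positions(path: str | Path) -> pd.DataFrame:
    """Read the spot-positions CSV, keyed by spot id.

    Requires the header columns ``spot_id,row,col,x,y``; an optional
    ``in_tissue`` 0/1 column is preserved.  Duplicate spot ids raise a
    :class:`FormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing position columns {missing}")
    dups = df["spot_id"][df["spot_id"].duplicated()].unique()
    if len(dups):
        raise FormatError(f"{path}: duplicate spot_id values {list(dups[:5])}")
    return df.set_index("spot_id")


def write_spatial_positions(section: AnnData, path: str | Path) -> None:
    xy = np.asarray(section.obsm[SPATIAL_KEY], dtype=float)
    df = pd.DataFrame(
        {
            "spot_id": section.obs_names,
            "row": section.obs.get("row", np.round(xy[:, 1]).astype(int)),
            "col": section.obs.get("col", np.round(xy[:, 0]).astype(int)),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def attach_positions(adata: AnnData, positions: pd.DataFrame) -> AnnData:
    """Join coordinates onto a spot-by-gene matrix.

    Spots present in the matrix but absent from the positions table raise
    an :class:`InputError` listing the missing ids.  When an ``in_tissue``
    column is present, only flagged spots are kept.
    """
    missing = [s for s in adata.obs_names if s not in positions.index]
    if missing:
        raise InputError(
            f"positions missing for spots {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    pos = positions.loc[adata.obs_names]
    out = adata.copy()
    out.obsm[SPATIAL_KEY] = pos[["x", "y"]].to_numpy(dtype=float)
    out.obs["row"] = pos["row"].to_numpy()
    out.obs["col"] = pos["col"].to_numpy()
    if "in_tissue" in pos.columns:
        keep = pos["in_tissue"].to_numpy().astype(bool)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("attach_positions: dropping %d out-of-tissue spots", n_drop)
        out = out[keep].copy()
    return out


def read_spatial_section(
    counts_dir: str | Path,
    positions_path: str | Path,
    section_id: str | None = None,
) -> AnnData:
    """Convenience loader: counts triplet + positions CSV -> section."""
    adata = read_counts_mtx(counts_dir)
    section = attach_positions(adata, read_spatial_positions(positions_path))
    section.uns[SECTION_ID_KEY] = section_id or Path(counts_dir).name
    return section


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name/description/members.

    Duplicate members within a set are deduplicated; sets left empty are
    dropped with a logged warning.  A line with fewer than three fields
    raises a :class:`FormatError` carrying the line number.
    """
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(Path(path)), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = frozenset(m for m in members if m)
        if not members:
            logger.warning("%s:%d: dropping empty set %r", path, lineno, name)
            continue
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


ALTERATION_KEY_COLUMNS = ("patient_id", "site", "histology", "sample_type")


def read_alteration_table(path: str | Path) -> pd.DataFrame:
    """Read the alteration-table TSV (one row per patient)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALTERATION_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dups = df["patient_id"][df["patient_id"].duplicated()].unique()
    if len(dups):
        raise FormatError(f"{path}: duplicate patient_id values {list(dups[:5])}")
    for col in df.columns:
        if col.startswith("mut_"):
            df[col] = df[col].astype(bool)
    return df


def write_alteration_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
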