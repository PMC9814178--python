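"""Plain-text readers and writers for every core type.

Matrices travel as TSV (index in the first column, ``# key: value`` comment
headers) or as MatrixMarket with ``.rows.txt`` / ``.cols.txt`` sidecars.
Abundance matrices carry a ``# scale: relative|absolute`` header line.
Mapping records are ``sample<TAB>read_id<TAB>gene1,gene2,...``; module
definitions are ``module_id<TAB>name<TAB>comp1|comp1alt,comp2,...`` with an
optional database column.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .catalog import RANKS, GeneCatalog, MgsDefinitionSet, Module, ModuleCatalog
from .errors import FormatError
from .profiling import ReadMappingTable
from .quantify import MgsAbundanceMatrix

__all__ = [
    "write_matrix_tsv", "read_matrix_tsv",
    "write_matrix_mtx", "read_matrix_mtx",
    "write_abundance_tsv", "read_abundance_tsv",
    "write_catalog_tsv", "read_catalog_tsv",
    "write_mgs_definitions_tsv", "read_mgs_definitions_tsv",
    "write_taxonomy_tsv", "read_taxonomy_tsv",
    "write_module_definitions", "read_module_definitions",
    "write_mappings_tsv", "read_mappings_tsv",
    "write_cell_counts_tsv", "read_cell_counts_tsv",
    "write_metadata_tsv", "read_metadata_tsv",
]


# ---------------------------------------------------------------- matrices

def write_matrix_tsv(df: pd.DataFrame, path, header: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index_label=df.index.name or "id")


def read_matrix_tsv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    header: dict[str, str] = {}
    lines = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                if ":" not in line:
                    raise FormatError(f"{path}:{lineno}: malformed header line")
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            else:
                lines.append(line)
    if not lines:
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", index_col=0)
    return df, header


def write_matrix_mtx(df: pd.DataFrame, prefix) -> None:
    """MatrixMarket file ``<prefix>.mtx`` with row/column index sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")),
                     scipy.sparse.csr_matrix(df.to_numpy(dtype=float)))
    prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, df.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, df.columns)) + "\n")


def read_matrix_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    rows = prefix.with_suffix(".rows.txt")
    cols = prefix.with_suffix(".cols.txt")
    for sidecar in (rows, cols):
        if not sidecar.exists():
            raise FormatError(f"missing sidecar index file {sidecar}")
    matrix = scipy.io.mmread(str(mtx)).toarray()
    index = rows.read_text().splitlines()
    columns = cols.read_text().splitlines()
    if matrix.shape != (len(index), len(columns)):
        raise FormatError(f"{mtx}: shape {matrix.shape} does not match sidecars")
    return pd.DataFrame(matrix, index=index, columns=columns)


def write_abundance_tsv(ab: MgsAbundanceMatrix, path) -> None:
    write_matrix_tsv(ab.values, path, header={"scale": ab.scale})


def read_abundance_tsv(path) -> MgsAbundanceMatrix:
    df, header = read_matrix_tsv(path)
    scale = header.get("scale")
    if scale not in ("relative", "absolute"):
        raise FormatError(f"{path}: missing or invalid '# scale:' header")
    return MgsAbundanceMatrix(values=df, scale=scale)


# ---------------------------------------------------------------- catalogue

def write_catalog_tsv(catalog: GeneCatalog, path) -> None:
    out = catalog.table.copy()
    out["components"] = [",".join(sorted(c)) for c in out["components"]]
    out["is_marker"] = out["is_marker"].astype(int)
    out["is_core"] = out["is_core"].astype(int)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_catalog_tsv(path) -> GeneCatalog:
    try:
        df = pd.read_csv(path, sep="\t", index_col="gene_id",
                         dtype={"mgs_id": str}, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise FormatError(f"{path}: {exc}") from exc
    df["components"] = [
        frozenset(str(c).split(",")) - {""} for c in df["components"].fillna("")
    ]
    df["is_marker"] = df["is_marker"].astype(bool)
    df["is_core"] = df["is_core"].astype(bool)
    df["length"] = df["length"].astype(int)
    return GeneCatalog(table=df)


def write_mgs_definitions_tsv(defs: MgsDefinitionSet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mgs_id\trole\tgene_id\n")
        for mgs_id in defs.mgs_ids:
            for role, genes in (("marker", defs.markers[mgs_id]),
                                ("core", defs.core[mgs_id]),
                                ("accessory", defs.accessory[mgs_id])):
                for gene in genes:
                    fh.write(f"{mgs_id}\t{role}\t{gene}\n")


def read_mgs_definitions_tsv(path, taxonomy: pd.DataFrame | None = None) -> MgsDefinitionSet:
    markers: dict[str, list[str]] = {}
    core: dict[str, list[str]] = {}
    accessory: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if header.strip() != "mgs_id\trole\tgene_id":
            raise FormatError(f"{path}:1: expected header 'mgs_id\\trole\\tgene_id'")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            mgs_id, role, gene = parts
            bucket = {"marker": markers, "core": core, "accessory": accessory}.get(role)
            if bucket is None:
                raise FormatError(f"{path}:{lineno}: unknown role {role!r}")
            bucket.setdefault(mgs_id, []).append(gene)
    for mgs_id in set(markers) | set(core) | set(accessory):
        markers.setdefault(mgs_id, [])
        core.setdefault(mgs_id, [])
        accessory.setdefault(mgs_id, [])
    if taxonomy is None:
        taxonomy = pd.DataFrame("unclassified", index=sorted(markers), columns=list(RANKS))
    return MgsDefinitionSet(markers=markers, core=core, accessory=accessory, taxonomy=taxonomy)


def write_taxonomy_tsv(taxonomy: pd.DataFrame, path) -> None:
    taxonomy[list(RANKS)].to_csv(path, sep="\t", index_label="mgs_id")


def read_taxonomy_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="mgs_id", dtype=str)
    missing = set(RANKS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: taxonomy lacks ranks {sorted(missing)}")
    return df[list(RANKS)]


# ------------------------------------------------------------------ modules

def write_module_definitions(modules: ModuleCatalog, path) -> None:
    with Path(path).open("w") as fh:
        for mod in modules:
            comps = ",".join("|".join(sorted(c)) for c in mod.components)
            fh.write(f"{mod.module_id}\t{mod.name}\t{comps}\t{mod.database}\n")


def read_module_definitions(path) -> ModuleCatalog:
    modules = ModuleCatalog()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (3, 4):
                raise FormatError(f"{path}:{lineno}: expected 3 or 4 columns")
            module_id, name, comps = parts[:3]
            database = parts[3] if len(parts) == 4 else "GMM"
            components = tuple(
                frozenset(alt for alt in comp.split("|") if alt)
                for comp in comps.split(",") if comp
            )
            if not components:
                raise FormatError(f"{path}:{lineno}: module {module_id!r} has no components")
            modules.add(Module(module_id=module_id, name=name,
                               components=components, database=database))
    return modules


# ----------------------------------------------------------------- mappings

def write_mappings_tsv(mappings: ReadMappingTable, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tread_id\tgenes\n")
        for sample in mappings.sample_ids:
            sm = mappings[sample]
            r = 0
            for gene, count in sm.unique.items():
                for _ in range(count):
                    fh.write(f"{sample}\tr{r:07d}\t{gene}\n")
                    r += 1
            for rec in sm.shared:
                fh.write(f"{sample}\tr{r:07d}\t{','.join(rec)}\n")
                r += 1


def read_mappings_tsv(path) -> ReadMappingTable:
    table = ReadMappingTable()
    with Path(path).open() as fh:
        header = fh.readline()
        if header.strip() != "sample\tread_id\tgenes":
            raise FormatError(f"{path}:1: expected header 'sample\\tread_id\\tgenes'")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            sample, _, genes = parts
            candidates = tuple(g for g in genes.split(",") if g)
            if not candidates:
                raise FormatError(f"{path}:{lineno}: empty candidate list")
            table.add_record(sample, candidates)
    return table


# ------------------------------------------------------- cohort side tables

def write_cell_counts_tsv(cells: pd.Series, path) -> None:
    cells.rename("cells_per_gram").to_csv(path, sep="\t", index_label="sample_id")


def read_cell_counts_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "cells_per_gram" not in df.columns:
        raise FormatError(f"{path}: expected a 'cells_per_gram' column")
    return df["cells_per_gram"].astype(float)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label=metadata.index.name or "sample_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
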