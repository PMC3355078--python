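"""Readers and writers for the tabular and graph formats the pipeline uses.

Karyotype tables are delimited text (TSV by default, CSV accepted): one row
per sample, a ``sample_id`` column, 16 chromosome columns (Roman numerals
canonical, Arabic and ``chr`` prefixes accepted, any case), and an optional
``role`` column marking the population row of a strain matrix.  Networks are
exchanged as GML text files.  Every CLI run writes a JSON metadata record
(seed, parameters, version) sufficient to reproduce it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .chromosomes import CHROMOSOMES, normalize_chromosome_id
from .karyotype import Karyotype
from .network import KaryotypeMatrix, KaryotypeNetwork

__all__ = [
    "read_karyotype_table",
    "write_karyotype_table",
    "read_karyotype_matrix",
    "export_network",
    "read_network",
    "read_ct_table",
    "read_facs_table",
    "write_run_metadata",
]


class KaryotypeTableError(ValueError):
    """Malformed karyotype table; the message names the offending row/column."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _normalize_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Map chromosome-like column names to canonical Roman numerals."""
    rename: dict[str, str] = {}
    for col in df.columns:
        if str(col).lower() in {"sample_id", "role"}:
            continue
        try:
            rename[col] = normalize_chromosome_id(col)
        except ValueError:
            continue
    df = df.rename(columns=rename)
    chrom_cols = [c for c in CHROMOSOMES if c in df.columns]
    missing = [c for c in CHROMOSOMES if c not in chrom_cols]
    if missing:
        raise KaryotypeTableError(
            f"karyotype table is missing chromosome column(s): {', '.join(missing)}"
        )
    return df, chrom_cols


def read_karyotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a karyotype table.

    Returns a DataFrame with ``sample_id``, the 16 chromosome columns in
    canonical order, and ``role`` if present.  Non-integer or negative cells
    raise with the row and column named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise KaryotypeTableError("karyotype table needs a 'sample_id' column")
    df, _ = _normalize_columns(df)
    for col in CHROMOSOMES:
        for row_idx, value in df[col].items():
            try:
                as_int = int(value)
                if as_int != float(value) or as_int < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise KaryotypeTableError(
                    f"non-integer copy number at row {row_idx + 2} "
                    f"(sample {df.loc[row_idx, 'sample_id']!r}), column {col}: {value!r}"
                ) from None
        df[col] = df[col].astype(int)
    cols = ["sample_id", *CHROMOSOMES]
    if "role" in df.columns:
        cols.append("role")
    return df[cols]


def write_karyotype_table(
    path: str | Path,
    karyotypes: Sequence[Karyotype],
    sample_ids: Sequence[str],
    roles: Sequence[str] | None = None,
) -> None:
    path = Path(path)
    data = {"sample_id": list(sample_ids)}
    for i, chrom in enumerate(CHROMOSOMES):
        data[chrom] = [k.copies[i] for k in karyotypes]
    if roles is not None:
        data["role"] = list(roles)
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


def read_karyotype_matrix(path: str | Path) -> KaryotypeMatrix:
    """Read a strain matrix: the ``role`` column must mark one 'population' row."""
    df = read_karyotype_table(path)
    if "role" not in df.columns:
        raise KaryotypeTableError(
            "strain matrix needs a 'role' column marking the population row"
        )
    roles = df["role"].str.lower()
    pop_rows = df.index[roles == "population"].tolist()
    if len(pop_rows) != 1:
        raise KaryotypeTableError(
            f"expected exactly one 'population' role row, found {len(pop_rows)}"
        )
    rows = tuple(
        tuple(int(df.loc[i, c]) for c in CHROMOSOMES) for i in df.index
    )
    return KaryotypeMatrix(
        rows=rows,
        root_row=df.index.get_loc(pop_rows[0]),
        sample_ids=tuple(df["sample_id"].astype(str)),
    )


def export_network(network: KaryotypeNetwork, path: str | Path) -> None:
    """Write a karyotype network as a GML text file.

    Nodes carry the karyotype string and observation frequency; edges carry
    the signed chromosome-change label (e.g. ``+VII,-X``), chromosomes in
    index order.
    """
    out = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        out.add_node(
            "/".join(str(c) for c in node),
            frequency=int(data.get("frequency", 0)),
            is_root=int(data.get("is_root", False)),
        )
    for u, v, data in network.graph.edges(data=True):
        out.add_edge(
            "/".join(str(c) for c in u),
            "/".join(str(c) for c in v),
            label=data.get("label", ""),
        )
    nx.write_gml(out, str(path))


def read_network(path: str | Path) -> KaryotypeNetwork:
    """Re-import an exported network; topology and frequencies round-trip."""
    gml = nx.read_gml(str(path), label="label")
    graph = nx.Graph()
    frequencies: dict[tuple[int, ...], int] = {}
    root = None
    for name, data in gml.nodes(data=True):
        vec = tuple(int(c) for c in str(name).split("/"))
        graph.add_node(vec)
        frequencies[vec] = int(data.get("frequency", 0))
        if data.get("is_root"):
            root = vec
    for u, v in gml.edges:
        graph.add_edge(
            tuple(int(c) for c in str(u).split("/")),
            tuple(int(c) for c in str(v).split("/")),
        )
    if root is None:
        raise KaryotypeTableError("network file does not mark a root node")
    return KaryotypeNetwork(graph, root, frequencies)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "probe_id", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise KaryotypeTableError(
            f"Ct table is missing column(s): {', '.join(sorted(missing))}"
        )
    if (df["ct"] <= 0).any():
        raise KaryotypeTableError("Ct values must be positive")
    return df


def read_facs_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "g1_peak"}
    missing = required - set(df.columns)
    if missing:
        raise KaryotypeTableError(
            f"FACS table is missing column(s): {', '.join(sorted(missing))}"
        )
    if (df["g1_peak"] <= 0).any():
        raise KaryotypeTableError("G1 peak positions must be positive")
    return df


def write_run_metadata(path: str | Path, **params) -> None:
    """Record seed and parameters of a run for bit-exact reproduction."""
    from . import __version__

    record = {"version": __version__, **params}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
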