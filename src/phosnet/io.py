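"""TSV/JSON input-output and run reporting.

Native dialect: tab-separated, UTF-8, mandatory header row, ``NA`` as the
missing-value sentinel. Identifiers are opaque strings — any mapping
between database accession systems stays upstream of this package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .network import LayerAssignment
from .stats import ComparisonResult

__all__ = [
    "read_annotation_table",
    "write_annotation_table",
    "read_edge_list",
    "write_edge_list",
    "write_report",
    "write_trajectory",
]

MANDATORY_COLUMNS = ("id", "enzyme_class")
NUMERIC_COLUMNS = (
    "abundance", "essential", "ppi_degree", "de_responsive",
    "de_perturbation_count", "half_life", "phospho_curated",
    "phospho_peptide", "phospho_conserved", "conserved_sites", "ngi_count",
)


def read_annotation_table(path) -> pd.DataFrame:
    """Read an enzyme annotation TSV into a records DataFrame.

    Requires ``id`` and ``enzyme_class`` columns; known numeric columns
    are typed (a non-numeric entry raises with its row number), unknown
    columns pass through untouched. ``NA`` denotes missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate id(s): {sorted(set(dup))}")
    if df["id"].isna().any() or df["enzyme_class"].isna().any():
        raise ValueError(f"{path}: missing id or enzyme_class entries")
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        df[col] = converted
    return df


def write_annotation_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_edge_list(path) -> list[tuple]:
    """Read a directed edge list TSV (columns source, target[, provenance]).

    Tolerates trailing newlines and CRLF line endings; a blank endpoint
    raises with its line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    edges: list[tuple] = []
    has_prov = "provenance" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        src = getattr(row, "source")
        dst = getattr(row, "target")
        if pd.isna(src) or pd.isna(dst) or not str(src).strip() or not str(dst).strip():
            raise ValueError(f"{path}: blank endpoint at line {i + 2}")
        if has_prov and not pd.isna(getattr(row, "provenance")):
            edges.append((str(src).strip(), str(dst).strip(),
                          str(getattr(row, "provenance"))))
        else:
            edges.append((str(src).strip(), str(dst).strip()))
    return edges


def write_edge_list(edges, path) -> None:
    rows = [
        {"source": e[0], "target": e[1],
         "provenance": e[2] if len(e) > 2 else ""}
        for e in edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_report(
    results,
    layers: LayerAssignment | None,
    profiles,
    out_dir,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the standard output bundle to ``out_dir``.

    * ``report.tsv`` — one row per comparison, fixed column order;
    * ``layers.tsv`` — layer assignment (when given);
    * ``profiles.tsv`` — per-layer profiles (when given);
    * ``report.json`` — full-precision mirror with run metadata
      (package version, seed, config hash).

    Ordering is deterministic, so identical inputs reproduce identical
    bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = [r.to_dict() for r in results]
    columns = ["metric", "group_a", "group_b", "n_a", "n_b", "summary_a",
               "summary_b", "test", "tail", "statistic", "p_value", "stars"]
    report_df = pd.DataFrame(rows, columns=columns)
    paths["report_tsv"] = out / "report.tsv"
    report_df.to_csv(paths["report_tsv"], sep="\t", index=False, na_rep="NA")

    if layers is not None:
        paths["layers_tsv"] = out / "layers.tsv"
        layers.to_frame().to_csv(paths["layers_tsv"], sep="\t", index=False)

    if profiles:
        prof_rows = []
        for p in profiles:
            row = {"focal": p.focal, "metric": p.metric,
                   "p_value": p.result.p_value, "stars": p.result.stars,
                   "test": p.result.test, "tail": p.result.tail}
            row.update({f"summary_{k}": v for k, v in sorted(p.per_group.items())})
            prof_rows.append(row)
        paths["profiles_tsv"] = out / "profiles.tsv"
        pd.DataFrame(prof_rows).to_csv(paths["profiles_tsv"], sep="\t",
                                       index=False, na_rep="NA")

    config = config or {}
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    payload = {
        "metadata": {
            "package": "phosnet",
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash,
        },
        "results": rows,
        "layers": dict(sorted(layers.labels.items())) if layers is not None else None,
    }
    paths["report_json"] = out / "report.json"
    with open(paths["report_json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
    return paths


def write_trajectory(traj, path) -> None:
    """Two-column TSV: time, phosphorylated level."""
    pd.DataFrame({"t": traj.t, "y_p": traj.y}).to_csv(path, sep="\t", index=False)
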