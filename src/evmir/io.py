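"""File formats: intensity TSV, metadata TSV, GMT gene sets, target-map
TSV, model JSON, ground-truth JSON.

Intensity TSVs are probes-as-rows (microarray export convention): first
column ``probe_id``, one column per sample, header row required. Empty
cells and explicit zeros read back as undetected. Every writer/reader pair
is a lossless round trip for in-range data.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import LogisticEnsemble
from .errors import FormatError
from .matrix import IntensityMatrix, CohortLabels

MODEL_SCHEMA_VERSION = 1
FLOAT_FMT = "%.12g"


def write_intensity_tsv(m: IntensityMatrix, path) -> None:
    """Undetected entries are written as empty cells."""
    vals = m.values.where(m.mask, other=np.nan)
    vals.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep="",
                index_label="probe_id")


def read_intensity_tsv(path, state: str = "raw", transpose: bool = False) -> IntensityMatrix:
    """Parse an intensity TSV; empty cells and explicit 0 become undetected.

    Raises
    ------
    FormatError
        On ragged rows (with the line number) or duplicate probe ids.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or len(header) < 2:
            raise FormatError(f"{path}: need a header with probe_id + sample columns")
        width = len(header)
        ids, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})")
            ids.append(row[0])
            rows.append([float(c) if c.strip() != "" else np.nan for c in row[1:]])
    idx = pd.Index(ids, name="probe_id")
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    values = pd.DataFrame(rows, index=idx, columns=pd.Index(header[1:], name="sample_id"))
    if transpose:
        values = values.T
        values.index.name, values.columns.name = "probe_id", "sample_id"
    mask = values.notna() & (values != 0.0)
    return IntensityMatrix(values=values.fillna(0.0).astype(float),
                           mask=mask, state=state)


def write_metadata_tsv(labels: CohortLabels, path) -> None:
    labels.table.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path) -> CohortLabels:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    df["stage"] = df["stage"].fillna("NA")
    return CohortLabels(df)


def write_gmt(pathways: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            genes = "\t".join(sorted(pathways[pid]))
            fh.write(f"{pid}\t{description}\t{genes}\n")


def read_gmt(path, background=None):
    """Read a GMT file into a PathwayDB.

    If ``background`` is None the universe is the union of all pathway
    genes.
    """
    from .enrichment import PathwayDB

    pathways = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and >= 1 gene")
            name = parts[0]
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            pathways[name] = frozenset(g for g in parts[2:] if g)
    if background is None:
        background = frozenset(set().union(*pathways.values()))
    return PathwayDB(pathways=pathways, background=frozenset(background))


def write_target_map(tmap, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mid in sorted(tmap.targets):
            for gid in sorted(tmap.targets[mid]):
                fh.write(f"{mid}\t{gid}\n")


def read_target_map(path):
    from .enrichment import TargetMap

    targets: dict = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for mid, gid in zip(df["mirna_id"], df["gene_id"]):
        targets.setdefault(mid, set()).add(gid)
    return TargetMap(targets={k: frozenset(v) for k, v in targets.items()})


def write_model_json(model: LogisticEnsemble, path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "alpha": model.alpha,
        "lambda": model.lam,
        "beta": {k: model.beta[k] for k in sorted(model.beta)},
        "feature_ids": list(model.feature_ids),
        "trace_summary": None if model.trace is None else {
            "n_fits": int(model.trace.n_fits),
            "mean_alpha": float(model.trace.mean_alpha),
            "seed": int(model.trace.seed),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> LogisticEnsemble:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise FormatError(f"unsupported model schema {doc.get('schema_version')!r}")
    return LogisticEnsemble(beta=dict(doc["beta"]), alpha=float(doc["alpha"]),
                            lam=float(doc["lambda"]),
                            feature_ids=list(doc["feature_ids"]), trace=None)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_stats_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)
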