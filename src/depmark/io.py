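"""Plain-text readers and writers for every artifact the pipeline touches.

Matrices travel as TSV (probe id column + one column per sample), sample
sheets and long-format Ct/clinical tables as CSV, truth labels and manifests
as JSON, gene sets as GMT, prior candidate lists as one symbol per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import ExpressionMatrix, PlantedTruth
from .errors import DataError


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, sheet_path) -> None:
    matrix.values.rename_axis("probe").to_csv(matrix_path, sep="\t")
    matrix.samples.rename_axis("sample").to_csv(sheet_path)


def read_expression_tsv(matrix_path, sheet_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(sheet_path, index_col=0)
    return ExpressionMatrix(values=values, samples=samples)


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "gene_classes": truth.gene_classes.to_dict(),
        "mouse_status": truth.mouse_status.to_dict(),
        "human_gene_classes": truth.human_gene_classes.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        gene_classes=pd.Series(payload.get("gene_classes", {}), dtype=object),
        mouse_status=pd.Series(payload.get("mouse_status", {}), dtype=object),
        human_gene_classes=pd.Series(payload.get("human_gene_classes", {}), dtype=object),
    )


def read_gene_list(path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: tab-separated 'name<TAB>description<TAB>member...'."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = set(filter(None, fields[2:]))
    return sets


def read_probe_map(path) -> pd.Series:
    """Two-column TSV probe -> gene."""
    table = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"])
    return table.set_index("probe")["gene"]


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
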