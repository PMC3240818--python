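"""Readers and writers for the plain-text formats used throughout.

* expression matrices: TSV, genes as rows, first column ``gene_id``, missing
  values encoded as ``NA``;
* sample tables: CSV indexed by ``sample_id``;
* gene sets: GMT (set name, description, then tab-separated gene ids);
* interaction networks: SIF (``nodeA <tab> type <tab> nodeB``; a line with a
  single token is an isolated node);
* planted truth: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .de import GeneSet
from .synthetic import StudyTruth


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = "gene_id"
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def read_samples_csv(path, ef_cutoff: float = 40.0) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "sample_id"
    if "ef_class" not in df.columns and "ef_percent" in df.columns:
        df["ef_class"] = pd.Series(df["ef_percent"] <= ef_cutoff, index=df.index) \
            .map({True: "low", False: "high"})
    return df


def write_samples_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index_label="sample_id")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets.append(GeneSet(name=parts[0], description=parts[1], genes=frozenset(parts[2:])))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in ([gene_sets] if isinstance(gene_sets, GeneSet) else gene_sets):
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:
            g.add_node(parts[0])
        elif len(parts) >= 3:
            src, _interaction = parts[0], parts[1]
            for target in parts[2:]:
                if src != target:
                    g.add_edge(src, target)
                else:
                    g.add_node(src)
        else:
            raise ValueError(f"malformed SIF line: {line!r}")
    return g


def write_sif(g: nx.Graph, path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted((sorted((str(u), str(v))) for u, v in g.edges())):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for node in sorted(map(str, nx.isolates(g))):
            fh.write(f"{node}\n")


def write_truth_json(truth: StudyTruth, path) -> None:
    payload = {
        "de_genes": {g: {"direction": truth.de.loc[g, "direction"],
                         "effect_log2": float(truth.de.loc[g, "effect_log2"])}
                     for g in truth.de.index},
        "trio": list(truth.trio),
        "modules": [list(m) for m in truth.modules],
        "annotation_overlap": list(truth.annotation_overlap),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth_json(path) -> StudyTruth:
    payload = json.loads(Path(path).read_text())
    de = pd.DataFrame.from_dict(payload["de_genes"], orient="index")
    de.index.name = "gene_id"
    return StudyTruth(de=de, trio=payload["trio"], modules=payload["modules"],
                      annotation_overlap=payload["annotation_overlap"])
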