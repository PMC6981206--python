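"""File dialects: TSV tables with metadata headers, SIF/GraphML, configs.

All tabular outputs are tab-separated with ``#``-prefixed metadata lines
declaring the producing stage and a hash of the run configuration, so any
file can be traced back to the run that made it.
"""

from __future__ import annotations

import hashlib
import json

import networkx as nx
import pandas as pd
import yaml


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, stage: str, cfg_hash: str = "", index=False):
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n")
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_sif(net: nx.Graph, path, relation: str = "pp"):
    """Simple interaction format: node <relation> node per edge."""
    with open(path, "w") as fh:
        for u, v, data in net.edges(data=True):
            rel = data.get("category", relation)
            fh.write(f"{u}\t{rel}\t{v}\n")
        for n in nx.isolates(net):
            fh.write(f"{n}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                g.add_edge(parts[0], parts[2], category=parts[1])
            elif parts[0]:
                g.add_node(parts[0])
    return g


def write_graphml(net: nx.Graph, path):
    nx.write_graphml(net, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def read_effectors(path):
    """Effector catalogue from TSV (name, total_conc_nM, kd_nM[, pathway])
    or JSON (list of objects with the same fields)."""
    from ppindiff.competition import EffectorSpec

    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            records = json.load(fh)
    else:
        records = read_table(path).to_dict("records")
    return [
        EffectorSpec(
            name=r["name"],
            total_conc=float(r["total_conc_nM"]),
            kd=float(r["kd_nM"]),
            pathway=r.get("pathway"),
        )
        for r in records
    ]


def write_effectors(effectors, path):
    df = pd.DataFrame(
        [
            {
                "name": e.name,
                "total_conc_nM": e.total_conc,
                "kd_nM": e.kd,
                "pathway": e.pathway,
            }
            for e in effectors
        ]
    )
    write_table(df, path, stage="effector_catalogue")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)
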