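"""CSV/JSON serialization of cohorts, designs and networks.

Layout: one CSV per instrument (subjects as rows, ``subject_id`` first
column, item codes as headers: DH01.., LE01.., WHO01.., BSI01..,
GSE01..GSE10), a demographics CSV, and ground truth (when present) as JSON.
Comma-separated, UTF-8, header row.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .netest import NetworkModel
from .synthetic import CohortData, GroundTruth

__all__ = ["write_cohort", "read_cohort", "write_network", "read_network",
           "GSE_NODES"]

GSE_NODES = tuple(f"GSE{i + 1:02d}" for i in range(10))

_INSTRUMENTS = {
    # file stem -> (attribute, item prefix, lo, hi)
    "dh_freq": ("dh_freq", "DH", 0, 7),
    "dh_sev": ("dh_sev", "DH", 0, 5),
    "le_sev": ("le_sev", "LE", 0, 5),
    "who5": ("who5", "WHO", 0, 5),
    "bsi": ("bsi", "BSI", 1, 5),
    "gse": ("gse", "GSE", 1, 4),
}


def _item_cols(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(k)]


def write_cohort(cohort: CohortData, out_dir) -> Path:
    """Write a cohort to a directory of CSVs (plus ground-truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = np.arange(1, cohort.n_subjects + 1)
    for stem, (attr, prefix, _, _) in _INSTRUMENTS.items():
        m = getattr(cohort, attr)
        df = pd.DataFrame(m, columns=_item_cols(prefix, m.shape[1]))
        df.insert(0, "subject_id", ids)
        df.to_csv(out / f"{stem}.csv", index=False)
    demo = pd.DataFrame(
        {"subject_id": ids, "age": cohort.age, "gender": cohort.gender}
    )
    demo.to_csv(out / "demographics.csv", index=False)
    if cohort.truth is not None:
        t = cohort.truth
        payload = {
            "latent_stress": t.latent_stress.tolist(),
            "latent_health": t.latent_health.tolist(),
            "resilience_offset": t.resilience_offset.tolist(),
            "group_label_true": t.group_label_true.tolist(),
            "precision_high": t.precision_high.tolist(),
            "precision_low": t.precision_low.tolist(),
        }
        (out / "ground_truth.json").write_text(
            json.dumps(payload, sort_keys=True)
        )
    return out


def _read_table(path: Path, prefix: str, lo: int, hi: int) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path.name}: missing subject_id column")
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise ValueError(f"{path.name}: duplicate subject_id {dup}")
    items = [c for c in df.columns if c != "subject_id"]
    vals = df[items].to_numpy(dtype=float)
    # NaN compares False against both bounds; handle missingness explicitly
    bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path.name}: value {vals[i, j]} in row {i + 1} column "
            f"{items[j]} outside [{lo}, {hi}]"
        )
    return df.set_index("subject_id")


def read_cohort(in_dir) -> CohortData:
    """Read a cohort directory; validates ranges and subject alignment.

    Subjects with any missing item value are dropped (complete-case
    filtering) with a warning stating the count.
    """
    d = Path(in_dir)
    tables = {}
    for stem, (attr, prefix, lo, hi) in _INSTRUMENTS.items():
        tables[attr] = _read_table(d / f"{stem}.csv", prefix, lo, hi)
    demo = pd.read_csv(d / "demographics.csv").set_index("subject_id")
    ref = tables["dh_freq"].index
    for name, t in {**tables, "demographics": demo}.items():
        if len(t.index) != len(ref) or (t.index != ref).any():
            raise ValueError(
                f"{name}: subject ids misaligned with dh_freq"
            )
    complete = np.ones(len(ref), dtype=bool)
    for t in list(tables.values()) + [demo]:
        complete &= ~t.isna().any(axis=1).to_numpy()
    if not complete.all():
        warnings.warn(
            f"dropped {int((~complete).sum())} subject(s) with missing values"
        )
        tables = {k: t.loc[ref[complete]] for k, t in tables.items()}
        demo = demo.loc[ref[complete]]
    truth = None
    tf = d / "ground_truth.json"
    if tf.exists():
        p = json.loads(tf.read_text())
        truth = GroundTruth(
            latent_stress=np.array(p["latent_stress"])[complete],
            latent_health=np.array(p["latent_health"])[complete],
            resilience_offset=np.array(p["resilience_offset"])[complete],
            group_label_true=np.array(p["group_label_true"])[complete],
            precision_high=np.array(p["precision_high"]),
            precision_low=np.array(p["precision_low"]),
        )
    return CohortData(
        dh_freq=tables["dh_freq"].to_numpy(np.int64),
        dh_sev=tables["dh_sev"].to_numpy(np.int64),
        le_sev=tables["le_sev"].to_numpy(np.int64),
        who5=tables["who5"].to_numpy(np.int64),
        bsi=tables["bsi"].to_numpy(np.int64),
        gse=tables["gse"].to_numpy(np.int64),
        age=demo["age"].to_numpy(float),
        gender=demo["gender"].to_numpy(),
        truth=truth,
    ).validate()


def write_network(net: NetworkModel, out_dir, name: str,
                  nodes=GSE_NODES) -> None:
    """Edge-list CSV + JSON header (+ adjacency CSV) for one network."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = net.to_edge_list(list(nodes))
    pd.DataFrame(edges, columns=["node_i", "node_j", "weight"]).to_csv(
        out / f"{name}_edges.csv", index=False
    )
    pd.DataFrame(net.weights, index=list(nodes), columns=list(nodes)).to_csv(
        out / f"{name}_adjacency.csv"
    )
    header = {
        "lambda_selected": net.lambda_selected,
        "ebic": None if np.isnan(net.ebic) else net.ebic,
        "gamma": net.gamma,
        "n": net.n,
        "n_edges": net.n_edges,
        "settings": net.settings,
    }
    (out / f"{name}_model.json").write_text(
        json.dumps(header, sort_keys=True, indent=2)
    )


def read_network(out_dir, name: str, k: int = 10) -> np.ndarray:
    """Read back the adjacency CSV written by :func:`write_network`."""
    df = pd.read_csv(Path(out_dir) / f"{name}_adjacency.csv", index_col=0)
    return df.to_numpy(float)
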