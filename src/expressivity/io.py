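"""Delimited-table I/O for feature matrices and attribute vectors.

Feature tables have a ``sample_id`` column followed by ``f_0 .. f_{d-1}``;
attribute tables have ``sample_id`` plus one named attribute column. The
reader joins the two on ``sample_id``, so row order need not match.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mine import AttributeVector, ExpressivityResult, FeatureMatrix

__all__ = ["write_feature_csv", "read_feature_csv", "write_attribute_csv",
           "read_attribute_csv", "join_features_attribute",
           "write_expressivity_json", "read_expressivity_json"]


def write_feature_csv(fm: FeatureMatrix, path, sep=","):
    df = pd.DataFrame(fm.values, columns=[f"f_{j}" for j in range(fm.d)])
    df.insert(0, "sample_id", fm.sample_ids)
    df.to_csv(path, index=False, sep=sep)


def read_feature_csv(path, layer_tag=None, sep=None) -> FeatureMatrix:
    df = pd.read_csv(path, sep=sep, engine="python")
    if "sample_id" not in df.columns:
        raise ValueError("feature table must have a 'sample_id' column")
    cols = [c for c in df.columns if c.startswith("f_")]
    if not cols:
        raise ValueError("feature table has no f_* columns")
    cols = sorted(cols, key=lambda c: int(c.split("_", 1)[1]))
    return FeatureMatrix(df[cols].to_numpy(dtype=float),
                         sample_ids=df["sample_id"].tolist(),
                         layer_tag=layer_tag)


def write_attribute_csv(av: AttributeVector, sample_ids, path, sep=","):
    pd.DataFrame({"sample_id": list(sample_ids),
                  av.name: av.values}).to_csv(path, index=False, sep=sep)


def read_attribute_csv(path, name=None, kind=None, sep=None):
    """Returns (AttributeVector, sample_ids); kind inferred if omitted."""
    df = pd.read_csv(path, sep=sep, engine="python")
    if "sample_id" not in df.columns:
        raise ValueError("attribute table must have a 'sample_id' column")
    others = [c for c in df.columns if c != "sample_id"]
    if name is None:
        if len(others) != 1:
            raise ValueError(f"ambiguous attribute column among {others}; "
                             "pass name=")
        name = others[0]
    vals = df[name].to_numpy(dtype=float)
    if kind is None:
        kind = "binary" if set(np.unique(vals)) <= {0.0, 1.0} else "continuous"
    return AttributeVector(vals, kind=kind, name=name), df["sample_id"].tolist()


def join_features_attribute(fm: FeatureMatrix, av: AttributeVector,
                            attr_sample_ids) -> tuple[FeatureMatrix, AttributeVector]:
    """Inner-join on sample_id, reordering the attribute to feature order."""
    pos = {sid: i for i, sid in enumerate(attr_sample_ids)}
    missing = [sid for sid in fm.sample_ids if sid not in pos]
    if missing:
        raise ValueError(f"{len(missing)} feature sample_ids missing from "
                         f"attribute table (first: {missing[0]!r})")
    order = [pos[sid] for sid in fm.sample_ids]
    return fm, AttributeVector(av.values[order], kind=av.kind, name=av.name)


def write_expressivity_json(result: ExpressivityResult, path):
    Path(path).write_text(result.to_json(indent=2))


def read_expressivity_json(path) -> ExpressivityResult:
    return ExpressivityResult(**json.loads(Path(path).read_text()))
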